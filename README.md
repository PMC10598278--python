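# isletchip

Pre-transplantation potency assessment of donor pancreatic islet
preparations from their extracellular electrical activity, implemented as a
complete offline pipeline: synthetic multi-electrode-array (MEA) recording
generation, slow-potential detection, decision-tree potency scoring
(CHIP-score 1–6), recipient graft-function β-scores (0–8), and cohort-level
rank correlation of the two.

## The problem

Islet transplantation restores glycemic control in unstable type 1
diabetes, but there is no accepted predictive measure of donor islet
quality at the moment of transplantation.  Coupled β-cells in an islet
produce *slow potentials* (SPs) — sub-hertz extracellular field-potential
events recordable with a planar MEA — whose frequency `f` (Hz) tracks
insulin-secretory drive.  A small aliquot of a clinical islet preparation
seeded on an MEA can therefore be ranked functionally before the graft is
infused, by challenging it with a battery of stimuli and scoring the
responses:

| Decision point | Stimulus | Physiology probed |
|---|---|---|
| ① | 1 mmol/L glucose (G1) | β-cells should be silent (mean f ≤ 0.5 Hz) |
| ② | + epinephrine 5 µmol/L | silencing = hyperactive β-cells; enhancement = α-cell-dominated → disqualified |
| ③ | 15 mmol/L glucose (G15) | glucose responsiveness |
| ④ | glucose 1 / 3 / 5.5 / 8.2 / 11 mmol/L | dose dependence over the physiological range |
| ⑤ | fresh low→high glucose step | biphasic activation (first-phase peak ≈ 5 min, oscillating second phase) |
| ⑥ | G15 + GLP-1 50 pmol/L | incretin potentiation |
| ⑦ | + epinephrine | functional α₂-adrenergic inhibition |
| ⑧ | G15 + glibenclamide 100 nmol/L | K_ATP-channel closure |

The CHIP-score is the highest rank attained: **6** biphasic, **5**
dose-dependent, **4** high-glucose response only, **3** GLP-1 response
inhibited by epinephrine, **2** at least a GLP-1 or glibenclamide effect,
**1** none.  Scores 1–2 / 3–4 / 5–6 band into low / moderate / excellent
subgroups.  Recipient outcome is summarized by the β-score: 2 points each
for fasting glucose ≤ 5.5 mmol/L, HbA1c ≤ 6.1 %, C-peptide ≥ 0.3 nmol/L and
no insulin or oral agents; 0 points past the zero cut-offs (diabetic-range
glucose, HbA1c > 6.9 %, absent stimulated C-peptide, insulin > 0.24
U/kg/day); 1 point in between.  Totals 7–8 are optimal, 4–6 suboptimal,
≤ 3 poor.

Because raw clinical recordings are not publicly deposited, the package
ships a first-class, seeded synthetic-MEA module whose eight archetype
profiles (from `unresponsive` to `biphasic`, plus `alpha_dominant` and
`hyperactive`) realize each branch of the decision tree with known ground
truth, so the whole chain is testable end to end.

## Worked example

```python
import isletchip as ic

timeline = ic.standard_chip_protocol(segment_s=180, biphasic_s=1380,
                                     washout_s=120, short_s=120)
rec, truth = ic.simulate_recording(ic.archetype_profile("biphasic"), timeline,
                                   n_electrodes=8, occupied_fraction=0.75, seed=42)
result, res = ic.score_recording(rec)
print(result.summary())
```

prints

```
CHIP-score: 6 (subgroup: excellent)
decision path: 1 -> 3 -> 4 -> 5
  [1] g1_activity: no statistic=0.01111 threshold=0.5
  [3] g15_response: yes statistic=0.1583 p=0.0156
  [4] dose_dependence: yes statistic=0.3806 p=0.0156
  [4] glp1_on_responsive_branch: yes statistic=0.2958 p=0.0156 does not enter the score on the glucose-responsive branch
  [5] biphasic: yes statistic=5.365 peak 5.37 min, nadir 0.65, second phase 0.72
```

Reading this: the preparation is silent at 1 mmol/L glucose (0.011 Hz, ①),
responds significantly to 15 mmol/L (+0.158 Hz across six electrodes,
one-sided paired p = 0.016, ③), is dose-dependent over 1–11 mmol/L
(top−bottom +0.38 Hz, ④), and shows a biphasic activation with the
first-phase peak at 5.4 min after the glucose step (⑤) — the full
phenotype, hence the highest score.  The β-score side:

```python
from isletchip import RecipientMetrics, beta_score
beta_score(RecipientMetrics(fasting_glucose_mmol_per_L=6.0, hba1c_percent=6.0,
                            c_peptide_value=1.3, c_peptide_unit="ng/mL",
                            insulin_units_per_kg_day=0.18)).total   # -> 6 (suboptimal)
```

The same flows are available from the shell:

```bash
isletchip simulate --archetype biphasic --seed 42 --out rec.yaml
isletchip detect rec.yaml --out events.csv
isletchip profile events.csv --out profile.csv
isletchip score profile.csv --timeline rec.timeline.yaml --out report.yaml
isletchip run-all --seed 42 --out report.yaml        # all of the above
isletchip beta-score recipients.csv --out scored.csv
isletchip correlate cohort.csv
```

## Layout

- `src/isletchip/protocol.py` — stimulation timelines and the canonical potency protocol
- `src/isletchip/profiles.py` — ground-truth islet archetypes and biphasic kinetics
- `src/isletchip/simulate.py` — seeded synthetic MEA recordings with ground truth
- `src/isletchip/sigproc.py` — filtering, SP detection, frequency profiles, segment statistics
- `src/isletchip/scoring.py` — the CHIP-score decision tree
- `src/isletchip/beta.py` — recipient β-scores
- `src/isletchip/cohort.py` — Spearman correlation (exact small-sample permutation p) and subgroups
- `src/isletchip/io.py`, `cli.py`, `config.py` — file formats, command line, configuration

See `docs/methods.md` for the models, parameter choices and limitations.
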