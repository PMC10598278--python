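"""Potency ranking of islet preparations (CHIP-score 1-6, or disqualified).

The score is assigned by a decision tree over condition-level slow-potential
statistics.  Decision points, numbered 1-8 as in the protocol:

1.  Activity at 1 mmol/L glucose (>0.5 Hz mean across electrodes means the
    preparation is *not* silent when β-cells should be).
2.  If active: epinephrine at low glucose separates hyperactive islets
    (silenced, analysis continues) from α-cell-dominated preparations
    (activity enhanced — disqualified from ranking).
3.  Response to a 15 mmol/L glucose step (paired one-sided test across
    electrodes plus an effect-size floor).
4.  Dose dependence over the physiological range 1/3/5.5/8.2/11 mmol/L
    (rank trend across electrodes, top-vs-bottom ratio).
5.  Biphasic activation on a fresh low-to-high glucose step: first-phase
    peak at 2-10 min, decline, sustained oscillating second phase.
6.  If glucose-unresponsive: GLP-1 potentiation at 15 mmol/L.
7.  If GLP-1 responds: epinephrine inhibition of that response (functional
    α₂-adrenergic receptors).
8.  If GLP-1 does not respond: glibenclamide (K_ATP-channel closure).

The score is the highest rank attained: 6 biphasic, 5 dose-dependent,
4 high-glucose response only, 3 GLP-1 response inhibited by epinephrine,
2 at least a GLP-1 or glibenclamide effect, 1 none of these.  Scores 1-2,
3-4 and 5-6 band into low / moderate / excellent subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .config import BiphasicConfig, DecisionConfig
from .profiles import LOW_GLUCOSE_MMOL, STIM_GLUCOSE_MMOL
from .protocol import EPI, GLI, GLP1, ProtocolSegment, ProtocolTimeline
from .sigproc import FrequencyProfile, SegmentStats

__all__ = [
    "ChipScoreResult",
    "DecisionEvidence",
    "ResponseFlags",
    "ScoringError",
    "assign_chip_score",
    "check_biphasic",
    "check_dose_dependence",
    "check_epi_disambiguation",
    "check_g1_activity",
    "check_response",
    "evaluate_preparation",
    "subgroup_of",
]

DOSE_CONCENTRATIONS = (1.0, 3.0, 5.5, 8.2, 11.0)


class ScoringError(ValueError):
    """A required decision step cannot be evaluated."""


@dataclass
class DecisionEvidence:
    """What a decision point measured and how it was judged."""

    point: int
    name: str
    passed: bool | None
    statistic: float | None = None
    p_value: float | None = None
    threshold: float | None = None
    detail: str = ""
    per_electrode: dict[str, list[float]] = field(default_factory=dict)


@dataclass
class ResponseFlags:
    """Outcomes of the decision points; ``None`` marks points that were not
    evaluated (unreachable on the path taken, or missing data)."""

    active_at_g1: bool | None = None
    epi_silences: bool | None = None
    epi_enhances: bool | None = None
    g15_response: bool | None = None
    dose_dependent: bool | None = None
    biphasic: bool | None = None
    glp1_response: bool | None = None
    epi_inhibits_glp1: bool | None = None
    gli_response: bool | None = None
    evidence: dict[str, DecisionEvidence] = field(default_factory=dict)


SUBGROUPS = {1: "low", 2: "low", 3: "moderate", 4: "moderate", 5: "excellent", 6: "excellent"}


def subgroup_of(score: int | None) -> str | None:
    """Cohort subgroup band: 1-2 low, 3-4 moderate, 5-6 excellent."""
    return SUBGROUPS.get(score)


@dataclass
class ChipScoreResult:
    """Outcome of the ranking: a score 1-6 or disqualification, the ordered
    decision points visited, the flags and their evidence."""

    score: int | None
    disqualified: bool
    decision_path: list[int]
    flags: ResponseFlags

    @property
    def subgroup(self) -> str | None:
        return subgroup_of(self.score)

    def summary(self) -> str:
        lines = []
        if self.disqualified:
            lines.append("CHIP-score: disqualified (alpha-cell-dominated preparation)")
        else:
            lines.append(f"CHIP-score: {self.score} (subgroup: {self.subgroup})")
        lines.append("decision path: " + " -> ".join(str(p) for p in self.decision_path))
        for key, ev in self.flags.evidence.items():
            state = {True: "yes", False: "no", None: "not evaluated"}[ev.passed]
            extra = ""
            if ev.statistic is not None:
                extra += f" statistic={ev.statistic:.4g}"
            if ev.p_value is not None:
                extra += f" p={ev.p_value:.3g}"
            if ev.threshold is not None:
                extra += f" threshold={ev.threshold:.4g}"
            lines.append(f"  [{ev.point}] {key}: {state}{extra} {ev.detail}".rstrip())
        return "\n".join(lines)


def check_g1_activity(stats: SegmentStats, threshold_hz: float = 0.5) -> bool:
    """Activity gate at 1 mmol/L glucose: strictly above ``threshold_hz``.

    A mean of exactly the threshold counts as inactive (strict inequality).
    """
    if stats is None:
        raise ScoringError("missing low-glucose (G1) segment; cannot score")
    return stats.mean_hz > threshold_hz


def check_epi_disambiguation(
    g1_stats: SegmentStats,
    epi_stats: SegmentStats,
    fall_fraction: float = 0.5,
    rise_factor: float = 1.5,
) -> str:
    """Classify the epinephrine effect at low glucose.

    Returns ``"silences"`` (activity falls below ``fall_fraction`` of the G1
    mean: hyperactive β-cells, analysis continues), ``"enhances"`` (activity
    rises above ``rise_factor`` times the G1 mean: α-cell-dominated,
    preparation disqualified) or ``"neither"``.
    """
    if epi_stats is None:
        raise ScoringError("missing epinephrine segment required to disambiguate G1 activity")
    if epi_stats.mean_hz < fall_fraction * g1_stats.mean_hz:
        return "silences"
    if epi_stats.mean_hz > rise_factor * g1_stats.mean_hz:
        return "enhances"
    return "neither"


@dataclass
class _ResponseTest:
    passed: bool
    p_value: float | None
    baseline_hz: float
    stimulated_hz: float
    n_electrodes: int
    low_confidence: bool = False


def _paired_one_sided_p(base: np.ndarray, stim: np.ndarray) -> float:
    """Wilcoxon signed-rank p for stimulated > baseline across electrodes."""
    diffs = stim - base
    if np.allclose(diffs, 0):
        return 1.0
    try:
        return float(sstats.wilcoxon(stim, base, alternative="greater").pvalue)
    except ValueError:
        return 1.0


def _effect_floor_met(
    base_mean: float,
    stim_mean: float,
    fold_floor: float,
    abs_floor: float,
    fold_min_stim: float = 0.05,
) -> bool:
    # Either a fold-change or an absolute rise clears the floor; the fold
    # branch additionally requires non-negligible stimulated activity — a
    # 2-fold rise between near-zero rates is a counting artifact, not an
    # effect.
    rise = stim_mean - base_mean
    fold_ok = stim_mean >= fold_floor * base_mean and rise > 0 and stim_mean >= fold_min_stim
    return fold_ok or rise >= abs_floor


def check_response(
    baseline_stats: SegmentStats,
    stimulated_stats: SegmentStats,
    alpha: float = 0.05,
    fold_floor: float = 2.0,
    abs_floor_hz: float = 0.1,
    min_electrodes: int = 5,
    fold_min_stim_hz: float = 0.05,
) -> _ResponseTest:
    """Significant increase of SP frequency under a stimulus.

    Electrodes are the replicates: a paired one-sided Wilcoxon signed-rank
    test across electrodes present in both segments must reject at ``alpha``
    AND the mean effect must clear a floor (``fold_floor``-fold rise or an
    absolute rise of ``abs_floor_hz``).  With fewer than ``min_electrodes``
    shared electrodes the flag comes from the effect floor alone and is
    marked low-confidence.
    """
    shared = [e for e in baseline_stats.electrodes_used if e in stimulated_stats.electrodes_used]
    base = baseline_stats.values(shared)
    stim = stimulated_stats.values(shared)
    base_mean, stim_mean = float(base.mean()), float(stim.mean())
    floor = _effect_floor_met(base_mean, stim_mean, fold_floor, abs_floor_hz,
                              fold_min_stim_hz)
    if len(shared) < min_electrodes:
        return _ResponseTest(
            passed=floor, p_value=None, baseline_hz=base_mean,
            stimulated_hz=stim_mean, n_electrodes=len(shared), low_confidence=True,
        )
    p = _paired_one_sided_p(base, stim)
    return _ResponseTest(
        passed=(p < alpha) and floor, p_value=p, baseline_hz=base_mean,
        stimulated_hz=stim_mean, n_electrodes=len(shared),
    )


@dataclass
class _DoseTest:
    passed: bool
    p_value: float | None
    bottom_hz: float
    top_hz: float
    rhos: list[float]


def check_dose_dependence(
    stats_by_conc: dict[float, SegmentStats],
    alpha: float = 0.05,
    ratio: float = 2.0,
    abs_floor_hz: float = 0.05,
) -> _DoseTest:
    """Monotone increase of SP frequency with glucose over 1-11 mmol/L.

    Judged by a rank trend over electrodes: each electrode's Spearman
    correlation between concentration and its segment frequency, tested
    across electrodes (one-sided Wilcoxon against zero) at ``alpha``;
    additionally the top concentration's mean must be at least ``ratio``
    times the bottom's and exceed it by ``abs_floor_hz`` — a ratio alone is
    meaningless between near-zero rates.
    """
    missing = [c for c in DOSE_CONCENTRATIONS if c not in stats_by_conc]
    if missing:
        raise ScoringError(f"missing dose-range concentrations: {missing}")
    concs = np.asarray(DOSE_CONCENTRATIONS)
    shared = set(stats_by_conc[concs[0]].electrodes_used)
    for c in concs[1:]:
        shared &= set(stats_by_conc[c].electrodes_used)
    shared = sorted(shared)
    mat = np.column_stack([stats_by_conc[c].values(shared) for c in concs])
    rhos = []
    for row in mat:
        if np.ptp(row) == 0:
            continue  # constant electrode carries no trend information
        rhos.append(float(sstats.spearmanr(concs, row).statistic))
    bottom = float(mat[:, 0].mean())
    top = float(mat[:, -1].mean())
    effect = (top >= ratio * bottom) and (top - bottom >= abs_floor_hz)
    if not rhos:
        return _DoseTest(False, None, bottom, top, [])
    if np.allclose(rhos, 0):
        p = 1.0
    else:
        try:
            p = float(sstats.wilcoxon(rhos, alternative="greater").pvalue)
        except ValueError:
            p = 1.0
    return _DoseTest((p < alpha) and effect, p, bottom, top, rhos)


@dataclass
class _BiphasicTest:
    passed: bool
    first_peak_min: float | None
    peak_amplitude_hz: float | None
    nadir_fraction: float | None
    second_phase_fraction: float | None


def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or len(y) < 2:
        return y.astype(float)
    kernel = np.ones(min(width, len(y)))
    return np.convolve(y, kernel, mode="same") / np.convolve(
        np.ones_like(y), kernel, mode="same"
    )


def check_biphasic(
    profile: FrequencyProfile,
    stimulus_onset_s: float,
    end_s: float | None = None,
    baseline_hz: float | None = None,
    config: BiphasicConfig | None = None,
) -> _BiphasicTest:
    """Biphasic activation of the aggregate SP frequency after a glucose step.

    The smoothed, baseline-subtracted aggregate profile must show (i) a
    first-phase peak within the configured latency window after onset,
    (ii) a decline to at most ``decline_fraction`` of that peak, and (iii) a
    sustained second phase averaging at least ``plateau_fraction`` of the
    peak for the remainder of the observation.  Returns the first-phase peak
    latency (minutes, parabolic sub-window refinement) whenever a peak above
    the amplitude floor exists, regardless of the overall verdict.
    """
    cfg = config or BiphasicConfig()
    if end_s is None:
        end_s = float(profile.window_starts_s[-1] + profile.window_s)
    if (end_s - stimulus_onset_s) < cfg.min_span_min * 60.0:
        raise ScoringError(
            f"post-onset span {(end_s - stimulus_onset_s) / 60:.1f} min too short "
            f"for the biphasic check (needs >= {cfg.min_span_min:g} min)"
        )
    starts = profile.window_starts_s
    tol = 1e-9
    sel = (starts >= stimulus_onset_s - tol) & (starts + profile.window_s <= end_s + tol)
    if sel.sum() < 3:
        raise ScoringError("too few frequency windows after stimulus onset")
    if baseline_hz is None:
        pre = (starts + profile.window_s <= stimulus_onset_s + tol) & (
            starts >= stimulus_onset_s - 2 * profile.window_s - tol
        )
        baseline_hz = float(profile.aggregate_mean_hz[pre].mean()) if pre.any() else 0.0
    y = _smooth(profile.aggregate_mean_hz[sel], cfg.smooth_windows) - baseline_hz
    centers_min = (starts[sel] + profile.window_s / 2 - stimulus_onset_s) / 60.0

    in_window = (centers_min >= cfg.peak_min_min) & (centers_min <= cfg.peak_max_min)
    if not in_window.any():
        return _BiphasicTest(False, None, None, None, None)
    cand = np.flatnonzero(in_window)
    i_pk = cand[np.argmax(y[cand])]
    amplitude = float(y[i_pk])
    if amplitude < cfg.min_peak_hz:
        return _BiphasicTest(False, None, amplitude, None, None)

    latency = float(centers_min[i_pk])
    if 0 < i_pk < len(y) - 1:
        denom = y[i_pk - 1] - 2 * y[i_pk] + y[i_pk + 1]
        if denom < 0:
            delta = 0.5 * (y[i_pk - 1] - y[i_pk + 1]) / denom
            latency += float(np.clip(delta, -1, 1)) * profile.window_s / 60.0

    n_search = max(int(np.ceil(cfg.decline_search_min * 60.0 / profile.window_s)), 1)
    after = y[i_pk + 1 : i_pk + 1 + n_search]
    if len(after) == 0:
        return _BiphasicTest(False, latency, amplitude, None, None)
    i_nadir = i_pk + 1 + int(np.argmin(after))
    nadir_frac = float(y[i_nadir] / amplitude)
    declined = nadir_frac <= cfg.decline_fraction

    second = y[i_nadir:]
    second_frac = float(second.mean() / amplitude) if len(second) else 0.0
    sustained = len(second) >= 2 and second_frac >= cfg.plateau_fraction

    peak_in_window = cfg.peak_min_min <= latency <= cfg.peak_max_min
    return _BiphasicTest(
        passed=bool(peak_in_window and declined and sustained),
        first_peak_min=latency,
        peak_amplitude_hz=amplitude,
        nadir_fraction=nadir_frac,
        second_phase_fraction=second_frac,
    )


def _truthy(flag: bool | None) -> bool:
    return bool(flag)


def _validate_flags(f: ResponseFlags) -> None:
    if _truthy(f.epi_silences) and _truthy(f.epi_enhances):
        raise ScoringError("epi_silences and epi_enhances are mutually exclusive")
    if (f.epi_silences is not None or f.epi_enhances is not None) and not _truthy(
        f.active_at_g1
    ):
        raise ScoringError("epinephrine disambiguation requires activity at G1")
    if f.dose_dependent is not None and not _truthy(f.g15_response):
        raise ScoringError("dose dependence evaluated without a G15 response")
    if f.biphasic is not None and not _truthy(f.dose_dependent):
        raise ScoringError("biphasic flag set without dose dependence")
    if f.glp1_response is not None and _truthy(f.g15_response):
        raise ScoringError("GLP-1 branch evaluated despite a G15 response")
    if f.epi_inhibits_glp1 is not None and not _truthy(f.glp1_response):
        raise ScoringError("EPI inhibition of GLP-1 evaluated without a GLP-1 response")
    if f.gli_response is not None and _truthy(f.glp1_response):
        raise ScoringError("glibenclamide branch evaluated despite a GLP-1 response")


def assign_chip_score(flags: ResponseFlags) -> ChipScoreResult:
    """Map decision-point flags to the final ranking.

    The score is the highest rank attained; an epinephrine-*enhanced*
    preparation is α-cell-dominated and disqualified (no numeric score).
    Internally inconsistent flag combinations (unreachable in the tree) are
    rejected.
    """
    _validate_flags(flags)
    path = [1]
    if _truthy(flags.active_at_g1):
        path.append(2)
        if _truthy(flags.epi_enhances):
            return ChipScoreResult(score=None, disqualified=True, decision_path=path, flags=flags)
    path.append(3)
    if _truthy(flags.g15_response):
        path.append(4)
        if _truthy(flags.dose_dependent):
            path.append(5)
    else:
        path.append(6)
        if _truthy(flags.glp1_response):
            path.append(7)
        else:
            path.append(8)

    ranks = [1]
    if _truthy(flags.glp1_response) or _truthy(flags.gli_response):
        ranks.append(2)
    if _truthy(flags.glp1_response) and _truthy(flags.epi_inhibits_glp1):
        ranks.append(3)
    if _truthy(flags.g15_response):
        ranks.append(4)
    if _truthy(flags.dose_dependent):
        ranks.append(5)
    if _truthy(flags.biphasic):
        ranks.append(6)
    return ChipScoreResult(score=max(ranks), disqualified=False, decision_path=path, flags=flags)


# ---------------------------------------------------------------------------
# Mapping protocol segments to decision-tree roles


def _is_plain(seg: ProtocolSegment) -> bool:
    return seg.calcium_present and not seg.active_drugs()


def resolve_roles(
    timeline: ProtocolTimeline, min_biphasic_span_s: float = 1200.0
) -> dict[str, ProtocolSegment]:
    """Identify which timeline segments realize each decision point, by
    composition (labels are not trusted)."""
    roles: dict[str, ProtocolSegment] = {}
    segs = timeline.segments
    for seg in segs:
        glc = seg.glucose_mmol_per_L
        drugs = set(seg.active_drugs())
        if _is_plain(seg) and glc == 1.0 and "g1" not in roles:
            roles["g1"] = seg
        elif seg.calcium_present and glc == 1.0 and drugs == {EPI} and "epi_g1" not in roles:
            roles["epi_g1"] = seg
        elif _is_plain(seg) and glc == 15.0 and "g15" not in roles:
            roles["g15"] = seg
        elif seg.calcium_present and glc == 15.0 and drugs == {GLP1} and "glp1" not in roles:
            roles["glp1"] = seg
        elif seg.calcium_present and glc == 15.0 and drugs == {GLP1, EPI} and "glp1_epi" not in roles:
            roles["glp1_epi"] = seg
        elif seg.calcium_present and glc == 15.0 and drugs == {GLI} and "gli" not in roles:
            roles["gli"] = seg

    for conc in DOSE_CONCENTRATIONS[1:]:
        for seg in segs:
            if _is_plain(seg) and seg.glucose_mmol_per_L == conc:
                roles[f"dose_{conc:g}"] = seg
                break
    # The range's 1 mmol/L point: the plain G1 immediately preceding the
    # 3 mmol/L segment if adjacent, otherwise the baseline G1.
    if "dose_3" in roles:
        prev = timeline.previous(roles["dose_3"])
        if prev is not None and _is_plain(prev) and prev.glucose_mmol_per_L == 1.0:
            roles["dose_1"] = prev
        elif "g1" in roles:
            roles["dose_1"] = roles["g1"]

    # Biphasic observation: a long plain stimulating segment whose
    # predecessor is plain low glucose.
    for seg in segs:
        if not (_is_plain(seg) and seg.glucose_mmol_per_L >= STIM_GLUCOSE_MMOL):
            continue
        prev = timeline.previous(seg)
        if prev is None or not _is_plain(prev) or prev.glucose_mmol_per_L > LOW_GLUCOSE_MMOL:
            continue
        if seg.duration_s >= min_biphasic_span_s:
            roles["biphasic_obs"] = seg
            roles["biphasic_baseline"] = prev
            break
    return roles


def evaluate_preparation(
    stats: list[SegmentStats],
    profile: FrequencyProfile,
    timeline: ProtocolTimeline,
    config: DecisionConfig | None = None,
) -> ChipScoreResult:
    """Walk the decision tree over condition-level statistics and assign the
    potency score.

    ``stats`` are per-segment summaries (see :func:`isletchip.sigproc.segment_stats`),
    ``profile`` the windowed frequency profile of the same recording (needed
    for the biphasic kinetic check).
    """
    cfg = config or DecisionConfig()
    roles = resolve_roles(timeline, min_biphasic_span_s=cfg.biphasic.min_span_min * 60.0)
    by_label = {s.label: s for s in stats}

    def stats_of(role: str) -> SegmentStats | None:
        seg = roles.get(role)
        return by_label.get(seg.label) if seg is not None else None

    flags = ResponseFlags()
    g1 = stats_of("g1")
    if g1 is None:
        raise ScoringError("missing low-glucose (G1) baseline segment; scoring aborted")
    flags.active_at_g1 = check_g1_activity(g1, cfg.g1_threshold_hz)
    flags.evidence["g1_activity"] = DecisionEvidence(
        point=1, name="activity at 1 mmol/L glucose", passed=flags.active_at_g1,
        statistic=g1.mean_hz, threshold=cfg.g1_threshold_hz,
        per_electrode={"G1": list(g1.values())},
    )

    if flags.active_at_g1:
        epi = stats_of("epi_g1")
        outcome = check_epi_disambiguation(g1, epi, cfg.epi_fall_fraction, cfg.epi_rise_factor)
        flags.epi_silences = outcome == "silences"
        flags.epi_enhances = outcome == "enhances"
        flags.evidence["epi_disambiguation"] = DecisionEvidence(
            point=2, name="epinephrine at low glucose", passed=flags.epi_silences,
            statistic=epi.mean_hz, threshold=cfg.epi_rise_factor * g1.mean_hz,
            detail=outcome, per_electrode={"G1+EPI": list(epi.values())},
        )
        if flags.epi_enhances:
            return assign_chip_score(flags)

    g15 = stats_of("g15")
    if g15 is None:
        raise ScoringError("missing 15 mmol/L glucose segment; scoring aborted")
    r = check_response(
        g1, g15, cfg.alpha, cfg.fold_floor, cfg.abs_floor_hz, cfg.min_electrodes,
        cfg.fold_min_stim_hz,
    )
    flags.g15_response = r.passed
    flags.evidence["g15_response"] = DecisionEvidence(
        point=3, name="response to 15 mmol/L glucose", passed=r.passed,
        statistic=r.stimulated_hz - r.baseline_hz, p_value=r.p_value,
        detail="low-confidence (few electrodes)" if r.low_confidence else "",
    )

    if flags.g15_response:
        dose_stats = {c: stats_of(f"dose_{c:g}") for c in DOSE_CONCENTRATIONS}
        if any(v is None for v in dose_stats.values()):
            flags.evidence["dose_dependence"] = DecisionEvidence(
                point=4, name="glucose dose dependence", passed=None,
                detail="missing concentrations; step skipped",
            )
        else:
            d = check_dose_dependence(
                dose_stats, cfg.dose_alpha, cfg.dose_ratio, cfg.dose_abs_floor_hz
            )
            flags.dose_dependent = d.passed
            flags.evidence["dose_dependence"] = DecisionEvidence(
                point=4, name="glucose dose dependence", passed=d.passed,
                statistic=d.top_hz - d.bottom_hz, p_value=d.p_value,
                per_electrode={"rho": list(d.rhos)},
            )
        # GLP-1 applied within the responsive branch: recorded as evidence
        # only; it does not move the score here.
        glp1 = stats_of("glp1")
        if glp1 is not None:
            aux = check_response(g15, glp1, cfg.alpha, cfg.fold_floor, cfg.abs_floor_hz,
                                 cfg.min_electrodes, cfg.fold_min_stim_hz)
            flags.evidence["glp1_on_responsive_branch"] = DecisionEvidence(
                point=4, name="GLP-1 potentiation (evidence only)", passed=aux.passed,
                statistic=aux.stimulated_hz - aux.baseline_hz, p_value=aux.p_value,
                detail="does not enter the score on the glucose-responsive branch",
            )
        if flags.dose_dependent:
            obs = roles.get("biphasic_obs")
            if obs is None:
                flags.evidence["biphasic"] = DecisionEvidence(
                    point=5, name="biphasic activation", passed=None,
                    detail="no observation segment long enough; step skipped",
                )
            else:
                base_stats = by_label.get(roles["biphasic_baseline"].label)
                try:
                    b = check_biphasic(
                        profile, obs.start_s, obs.end_s,
                        baseline_hz=None if base_stats is None else base_stats.mean_hz,
                        config=cfg.biphasic,
                    )
                except ScoringError as err:
                    flags.evidence["biphasic"] = DecisionEvidence(
                        point=5, name="biphasic activation", passed=None, detail=str(err),
                    )
                else:
                    flags.biphasic = b.passed
                    flags.evidence["biphasic"] = DecisionEvidence(
                        point=5, name="biphasic activation", passed=b.passed,
                        statistic=b.first_peak_min,
                        detail=(
                            f"peak {b.first_peak_min:.2f} min, nadir "
                            f"{b.nadir_fraction:.2f}, second phase {b.second_phase_fraction:.2f}"
                            if b.first_peak_min is not None else "no first-phase peak"
                        ),
                    )
    else:
        glp1 = stats_of("glp1")
        if glp1 is not None:
            r6 = check_response(g15, glp1, cfg.alpha, cfg.fold_floor, cfg.abs_floor_hz,
                                cfg.min_electrodes, cfg.fold_min_stim_hz)
            flags.glp1_response = r6.passed
            flags.evidence["glp1_response"] = DecisionEvidence(
                point=6, name="GLP-1 potentiation at 15 mmol/L", passed=r6.passed,
                statistic=r6.stimulated_hz - r6.baseline_hz, p_value=r6.p_value,
            )
        if flags.glp1_response:
            ge = stats_of("glp1_epi")
            if ge is not None:
                inhibited = ge.mean_hz < cfg.epi_fall_fraction * glp1.mean_hz
                flags.epi_inhibits_glp1 = bool(inhibited)
                flags.evidence["epi_inhibits_glp1"] = DecisionEvidence(
                    point=7, name="epinephrine inhibition of the GLP-1 response",
                    passed=flags.epi_inhibits_glp1, statistic=ge.mean_hz,
                    threshold=cfg.epi_fall_fraction * glp1.mean_hz,
                )
        elif flags.glp1_response is False:
            gli = stats_of("gli")
            if gli is not None:
                r8 = check_response(g15, gli, cfg.alpha, cfg.fold_floor, cfg.abs_floor_hz,
                                    cfg.min_electrodes, cfg.fold_min_stim_hz)
                flags.gli_response = r8.passed
                flags.evidence["gli_response"] = DecisionEvidence(
                    point=8, name="glibenclamide stimulation", passed=r8.passed,
                    statistic=r8.stimulated_hz - r8.baseline_hz, p_value=r8.p_value,
                )
    return assign_chip_score(flags)
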