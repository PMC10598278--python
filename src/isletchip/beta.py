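"""Recipient β-score: a 0-8 composite of islet graft function.

Two points each for normal fasting glucose (≤5.5 mmol/L), HbA1c ≤6.1%,
stimulated and/or basal C-peptide ≥0.3 nmol/L, and absence of insulin or
oral hypoglycemic agent use; zero points for fasting glucose in the
diabetic range, HbA1c >6.9%, absent C-peptide secretion on stimulation, or
daily insulin >0.24 U/kg; one point for intermediate values.  Totals of
7-8 are optimal graft function, 4-6 suboptimal, ≤3 poor.

The diabetic-range fasting glucose cut is taken as ≥7.0 mmol/L (the
standard fasting threshold for diabetes); absent C-peptide secretion, when
no stimulation result is recorded, is operationalized as a basal value
below 0.1 nmol/L.  Both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import BetaScoreConfig

__all__ = [
    "BetaScoreResult",
    "RecipientMetrics",
    "beta_score",
    "component_points",
    "convert_c_peptide",
    "hba1c_to_percent",
    "score_table",
]

#: C-peptide molar mass, g/mol (31 amino acids, human sequence).
C_PEPTIDE_MOLAR_MASS = 3020.3

_C_PEPTIDE_UNITS = {"nmol/L", "ng/mL"}


def convert_c_peptide(value: float, from_unit: str, to_unit: str = "nmol/L") -> float:
    """Convert C-peptide between mass and molar concentration.

    1 ng/mL = 1 µg/L; dividing by the molar mass (3020.3 g/mol) gives
    nmol/L.  Round-trips are exact to floating point.
    """
    if from_unit not in _C_PEPTIDE_UNITS or to_unit not in _C_PEPTIDE_UNITS:
        raise ValueError(
            f"unknown C-peptide unit; supported: {sorted(_C_PEPTIDE_UNITS)}"
        )
    if value < 0:
        raise ValueError("C-peptide concentration must be >= 0")
    if from_unit == to_unit:
        return value
    if from_unit == "ng/mL":  # -> nmol/L
        return value * 1000.0 / C_PEPTIDE_MOLAR_MASS
    return value * C_PEPTIDE_MOLAR_MASS / 1000.0  # nmol/L -> ng/mL


def hba1c_to_percent(value: float, unit: str = "percent") -> float:
    """HbA1c in NGSP percent; IFCC mmol/mol converted by the standard
    linear relation (% = 0.09148 × mmol/mol + 2.152)."""
    if unit in ("percent", "%"):
        return value
    if unit in ("mmol/mol", "mmol_per_mol"):
        return 0.09148 * value + 2.152
    raise ValueError(f"unknown HbA1c unit {unit!r}")


@dataclass(frozen=True)
class RecipientMetrics:
    """Clinical inputs of the β-score for one recipient at one visit."""

    fasting_glucose_mmol_per_L: float
    hba1c_percent: float
    c_peptide_value: float
    c_peptide_unit: str = "nmol/L"
    stimulated_c_peptide_absent: bool | None = None
    insulin_units_per_kg_day: float = 0.0
    on_oral_agents: bool = False

    def __post_init__(self) -> None:
        if self.fasting_glucose_mmol_per_L < 0:
            raise ValueError("fasting glucose must be >= 0")
        if self.c_peptide_value < 0:
            raise ValueError("C-peptide must be >= 0")
        if self.insulin_units_per_kg_day < 0:
            raise ValueError("insulin dose must be >= 0")
        if not (3.0 <= self.hba1c_percent <= 20.0):
            raise ValueError(
                f"HbA1c {self.hba1c_percent}% outside the plausible 3-20% range"
            )
        if self.c_peptide_unit not in _C_PEPTIDE_UNITS:
            raise ValueError(f"unknown C-peptide unit {self.c_peptide_unit!r}")

    @property
    def c_peptide_nmol(self) -> float:
        return convert_c_peptide(self.c_peptide_value, self.c_peptide_unit, "nmol/L")


@dataclass(frozen=True)
class BetaScoreResult:
    """Total β-score with its per-component points and clinical category."""

    total: int
    points: dict[str, int]  # glucose, hba1c, c_peptide, insulin_use ∈ {0,1,2}
    category: str  # optimal / suboptimal / poor


def component_points(
    metrics: RecipientMetrics, config: BetaScoreConfig | None = None
) -> dict[str, int]:
    """Points (0/1/2) per β-score component."""
    cfg = config or BetaScoreConfig()

    g = metrics.fasting_glucose_mmol_per_L
    if g <= cfg.glucose_full_mmol:
        glucose = 2
    elif g >= cfg.glucose_zero_mmol:
        glucose = 0
    else:
        glucose = 1

    h = metrics.hba1c_percent
    if h <= cfg.hba1c_full_pct:
        hba1c = 2
    elif h > cfg.hba1c_zero_pct:
        hba1c = 0
    else:
        hba1c = 1

    cp = metrics.c_peptide_nmol
    if metrics.stimulated_c_peptide_absent is True:
        c_peptide = 0
    elif cp >= cfg.c_peptide_full_nmol:
        c_peptide = 2
    elif metrics.stimulated_c_peptide_absent is None and cp < cfg.c_peptide_absent_nmol:
        c_peptide = 0
    else:
        c_peptide = 1

    ins = metrics.insulin_units_per_kg_day
    if ins == 0 and not metrics.on_oral_agents:
        insulin_use = 2
    elif ins > cfg.insulin_zero_u_per_kg or (metrics.on_oral_agents and ins > 0):
        insulin_use = 0
    else:
        insulin_use = 1

    return {"glucose": glucose, "hba1c": hba1c, "c_peptide": c_peptide,
            "insulin_use": insulin_use}


def beta_score(
    metrics: RecipientMetrics, config: BetaScoreConfig | None = None
) -> BetaScoreResult:
    """Total β-score (sum of components) and its category band."""
    cfg = config or BetaScoreConfig()
    pts = component_points(metrics, cfg)
    total = sum(pts.values())
    if total >= cfg.optimal_min:
        category = "optimal"
    elif total >= cfg.suboptimal_min:
        category = "suboptimal"
    else:
        category = "poor"
    return BetaScoreResult(total=total, points=pts, category=category)


def score_table(
    table: pd.DataFrame, config: BetaScoreConfig | None = None
) -> pd.DataFrame:
    """β-scores for a table of recipients (one row per recipient/visit).

    Expected columns mirror :class:`RecipientMetrics` field names; optional
    columns may be omitted.  ``hba1c_mmol_per_mol`` may replace
    ``hba1c_percent``.  Returns the input with points, total and category
    columns appended.
    """
    rows = []
    for _, row in table.iterrows():
        if "hba1c_percent" in row and pd.notna(row.get("hba1c_percent")):
            hba1c = float(row["hba1c_percent"])
        elif "hba1c_mmol_per_mol" in row and pd.notna(row.get("hba1c_mmol_per_mol")):
            hba1c = hba1c_to_percent(float(row["hba1c_mmol_per_mol"]), "mmol/mol")
        else:
            raise ValueError("table needs hba1c_percent or hba1c_mmol_per_mol")
        stim = row.get("stimulated_c_peptide_absent")
        metrics = RecipientMetrics(
            fasting_glucose_mmol_per_L=float(row["fasting_glucose_mmol_per_L"]),
            hba1c_percent=hba1c,
            c_peptide_value=float(row["c_peptide_value"]),
            c_peptide_unit=str(row.get("c_peptide_unit", "nmol/L")),
            stimulated_c_peptide_absent=None if pd.isna(stim) else bool(stim),
            insulin_units_per_kg_day=float(row.get("insulin_units_per_kg_day", 0.0)),
            on_oral_agents=bool(row.get("on_oral_agents", False)),
        )
        res = beta_score(metrics, config)
        rows.append({**res.points, "beta_score": res.total, "category": res.category})
    return pd.concat([table.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
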