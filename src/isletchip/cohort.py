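"""Cohort-level pairing of preparation potency scores with recipient
β-scores: Spearman rank correlation with small-sample permutation p-values,
and the low / moderate / excellent subgroup banding."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .scoring import subgroup_of

__all__ = [
    "CohortReport",
    "classify_subgroups",
    "correlate_cohort",
    "spearman",
]

log = logging.getLogger(__name__)

#: Below this sample size the permutation null is enumerated exhaustively;
#: beyond it the asymptotic t approximation is used.
EXACT_PERMUTATION_MAX_N = 10


def _tied_ranks(x: np.ndarray) -> np.ndarray:
    return sstats.rankdata(x, method="average")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ranks are tie-corrected (mid-ranks).  For n ≤ 10 the p-value is exact,
    from complete enumeration of all n! pairings of the observed ranks —
    asymptotic approximations are unreliable at the cohort sizes this
    pipeline targets; larger samples use the asymptotic approximation.
    Constant input is an error (rank correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant series")
    rx = _tied_ranks(x)
    ry = _tied_ranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= EXACT_PERMUTATION_MAX_N:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        observed = abs(rx_c @ ry_c)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            s = abs(rx_c @ ry_c[list(perm)])
            count += s >= observed - 1e-12
            total += 1
        p = count / total
    else:
        p = float(sstats.spearmanr(x, y).pvalue)
    return rho, float(p)


def classify_subgroups(table: pd.DataFrame) -> pd.Series:
    """Per-row potency subgroup: scores 1-2 low (no detectable β-cell
    activity), 3-4 moderate, 5-6 excellent; disqualified rows unclassified."""
    def one(v):
        if pd.isna(v) or v == "disqualified":
            return "unclassified"
        return subgroup_of(int(v)) or "unclassified"

    return table["chip_score"].map(one)


@dataclass
class CohortReport:
    """Correlation of potency and graft-function scores over a cohort."""

    rho: float
    p_value: float
    n: int
    n_disqualified: int
    method: str
    subgroup_counts: dict[str, int]

    def summary(self) -> str:
        lines = [
            f"Spearman rho = {self.rho:.3f}, p = {self.p_value:.3g} "
            f"({self.method}, n = {self.n})",
        ]
        if self.n_disqualified:
            lines.append(
                f"{self.n_disqualified} disqualified preparation(s) excluded pairwise"
            )
        lines.append(
            "subgroups: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.subgroup_counts.items()))
        )
        return "\n".join(lines)


def correlate_cohort(
    table: pd.DataFrame, beta_column: str = "beta_pre_second"
) -> CohortReport:
    """Spearman correlation of CHIP-score against a β-score column.

    Disqualified (α-dominant) preparations carry no numeric score and are
    dropped pairwise, with a logged count; rows with a missing β-score are
    dropped likewise.
    """
    subgroups = classify_subgroups(table)
    chip = pd.to_numeric(table["chip_score"], errors="coerce")
    beta = pd.to_numeric(table[beta_column], errors="coerce")
    disqualified = int((subgroups == "unclassified").sum())
    if disqualified:
        log.info("excluding %d disqualified/unscored preparations", disqualified)
    keep = chip.notna() & beta.notna()
    rho, p = spearman(chip[keep].to_numpy(), beta[keep].to_numpy())
    n = int(keep.sum())
    method = (
        "exact permutation" if n <= EXACT_PERMUTATION_MAX_N else "asymptotic"
    )
    counts = subgroups[keep].value_counts().to_dict()
    return CohortReport(
        rho=rho, p_value=p, n=n, n_disqualified=disqualified,
        method=method, subgroup_counts={str(k): int(v) for k, v in counts.items()},
    )
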