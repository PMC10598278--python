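"""Stimulation protocol timelines.

A recording session is described as an ordered, gap-free sequence of
:class:`ProtocolSegment` s, each holding the bath composition applied during
that interval: glucose concentration (mmol/L), drug concentrations (GLP-1 in
pmol/L, epinephrine in µmol/L, glibenclamide in nmol/L) and whether
extracellular Ca²⁺ is present.  Removing Ca²⁺ abolishes all electrical
activity and serves as a negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GLP1",
    "EPI",
    "GLI",
    "ProtocolSegment",
    "ProtocolTimeline",
    "condition_key",
    "standard_chip_protocol",
]

#: Canonical drug names used in :attr:`ProtocolSegment.drugs`.
GLP1 = "GLP1"  # glucagon-like peptide 1, pmol/L
EPI = "EPI"    # epinephrine (adrenalin), µmol/L
GLI = "GLI"    # glibenclamide, nmol/L

_DRUG_ORDER = (GLP1, EPI, GLI)

_TIME_TOL = 1e-9


@dataclass(frozen=True)
class ProtocolSegment:
    """One constant-composition interval of a stimulation protocol."""

    label: str
    start_s: float
    end_s: float
    glucose_mmol_per_L: float
    drugs: dict[str, float] = field(default_factory=dict)
    calcium_present: bool = True

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError(f"segment {self.label!r}: start_s must be >= 0")
        if self.end_s <= self.start_s:
            raise ValueError(
                f"segment {self.label!r}: end_s ({self.end_s}) must exceed "
                f"start_s ({self.start_s})"
            )
        if self.glucose_mmol_per_L < 0:
            raise ValueError(f"segment {self.label!r}: glucose must be >= 0")
        for name, conc in self.drugs.items():
            if conc < 0:
                raise ValueError(
                    f"segment {self.label!r}: drug {name!r} concentration "
                    "must be >= 0"
                )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def active_drugs(self) -> tuple[str, ...]:
        """Drug names with strictly positive concentration, canonical order."""
        return tuple(d for d in _DRUG_ORDER if self.drugs.get(d, 0) > 0) + tuple(
            d for d in sorted(self.drugs) if d not in _DRUG_ORDER and self.drugs[d] > 0
        )


def condition_key(segment: ProtocolSegment) -> str:
    """Canonical descriptor of a segment's composition, e.g. ``"G15+GLP1"``.

    Used to look up ground-truth rates in an islet profile's rate map.  The
    Ca²⁺-free state is not encoded here: Ca²⁺-free segments are silenced
    unconditionally by the simulator.
    """
    key = f"G{segment.glucose_mmol_per_L:g}"
    for drug in segment.active_drugs():
        key += f"+{drug}"
    return key


@dataclass(frozen=True)
class ProtocolTimeline:
    """Ordered, contiguous, non-overlapping sequence of protocol segments."""

    segments: tuple[ProtocolSegment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("timeline must contain at least one segment")
        for prev, cur in zip(segs, segs[1:]):
            if cur.start_s < prev.end_s - _TIME_TOL:
                raise ValueError(
                    f"segments {prev.label!r} and {cur.label!r} overlap"
                )
            if cur.start_s > prev.end_s + _TIME_TOL:
                raise ValueError(
                    f"gap between segments {prev.label!r} and {cur.label!r}; "
                    "timelines must be gap-free"
                )

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def start_s(self) -> float:
        return self.segments[0].start_s

    @property
    def end_s(self) -> float:
        return self.segments[-1].end_s

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def segment_at(self, t: float) -> ProtocolSegment:
        """Segment containing time ``t`` (end-exclusive except the last)."""
        for seg in self.segments:
            if seg.start_s <= t < seg.end_s:
                return seg
        if abs(t - self.end_s) <= _TIME_TOL:
            return self.segments[-1]
        raise ValueError(f"time {t} s outside timeline [{self.start_s}, {self.end_s}]")

    def by_label(self, label: str) -> ProtocolSegment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(f"no segment labelled {label!r}")

    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    def previous(self, segment: ProtocolSegment) -> ProtocolSegment | None:
        idx = self.segments.index(segment)
        return self.segments[idx - 1] if idx > 0 else None


#: Canonical test concentrations of the potency protocol.
GLUCOSE_RANGE_MMOL = (1.0, 3.0, 5.5, 8.2, 11.0)
GLUCOSE_HIGH_MMOL = 15.0
GLP1_PMOL = 50.0
EPI_UMOL = 5.0
GLI_NMOL = 100.0


def standard_chip_protocol(
    segment_s: float = 900.0,
    biphasic_s: float = 1500.0,
    washout_s: float | None = None,
    short_s: float | None = None,
) -> ProtocolTimeline:
    """Canonical stimulation timeline covering all decision points of the
    potency ranking tree.

    Order of application:

    1.  ``G1`` — 1 mmol/L glucose baseline (β-cells should be silent).
    2.  ``G1+EPI`` — epinephrine 5 µmol/L at low glucose, separating
        hyperactive (silenced) from α-cell-dominated (enhanced) preparations.
    3.  ``G15`` — 15 mmol/L glucose step.
    4.  ``G1``…``G11`` — the physiological glucose range 1/3/5.5/8.2/11
        mmol/L for dose-dependence.
    5.  ``G11_biphasic`` — a washout to 1 mmol/L followed by a step to
        11 mmol/L observed long enough to resolve a biphasic activation.
    6.  ``G15+GLP1`` — incretin potentiation (GLP-1 50 pmol/L).
    7.  ``G15+GLP1+EPI`` — α₂-adrenergic inhibition of the incretin response.
    8.  ``G15+GLI`` — glibenclamide 100 nmol/L (K_ATP-channel closure).
    9.  ``G1_Ca0`` — Ca²⁺-free negative control.

    Parameters
    ----------
    segment_s:
        Duration of each evaluated stimulation segment (default 15 min).
    biphasic_s:
        Duration of the biphasic observation segment (default 25 min; must
        leave ≥20 min after onset for the biphasic check).
    washout_s:
        Duration of washout/return-to-baseline segments (default
        ``segment_s``).
    short_s:
        Duration of auxiliary segments (EPI disambiguation, the GLP-1+EPI
        inhibition step, the Ca²⁺-free control; default ``segment_s``).
    """
    if washout_s is None:
        washout_s = segment_s
    if short_s is None:
        short_s = segment_s

    specs: list[tuple[str, float, float, dict[str, float], bool]] = [
        ("G1", segment_s, 1.0, {}, True),
        ("G1+EPI", short_s, 1.0, {EPI: EPI_UMOL}, True),
        ("G1_wash", washout_s, 1.0, {}, True),
        ("G15", segment_s, GLUCOSE_HIGH_MMOL, {}, True),
        ("G1_range", segment_s, 1.0, {}, True),
        ("G3", segment_s, 3.0, {}, True),
        ("G5.5", segment_s, 5.5, {}, True),
        ("G8.2", segment_s, 8.2, {}, True),
        ("G11", segment_s, 11.0, {}, True),
        ("G1_wash2", washout_s, 1.0, {}, True),
        ("G11_biphasic", biphasic_s, 11.0, {}, True),
        ("G15+GLP1", segment_s, GLUCOSE_HIGH_MMOL, {GLP1: GLP1_PMOL}, True),
        ("G15+GLP1+EPI", short_s, GLUCOSE_HIGH_MMOL, {GLP1: GLP1_PMOL, EPI: EPI_UMOL}, True),
        ("G15+GLI", segment_s, GLUCOSE_HIGH_MMOL, {GLI: GLI_NMOL}, True),
        ("G1_Ca0", short_s, 1.0, {}, False),
    ]
    segments = []
    t = 0.0
    for label, dur, glucose, drugs, ca in specs:
        segments.append(
            ProtocolSegment(
                label=label,
                start_s=t,
                end_s=t + dur,
                glucose_mmol_per_L=glucose,
                drugs=drugs,
                calcium_present=ca,
            )
        )
        t += dur
    return ProtocolTimeline(segments=tuple(segments))
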