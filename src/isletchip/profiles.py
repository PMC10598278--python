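"""Ground-truth islet activity profiles for the simulator.

An :class:`IsletProfile` maps protocol conditions to ground-truth slow
potential (SP) rates and describes the SP waveform and electrode noise floor.
Eight archetypes emulate the functional phenotypes the potency decision tree
discriminates, from a fully unresponsive preparation to one with the full
dose-dependent, biphasic glucose response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .protocol import ProtocolSegment, ProtocolTimeline, condition_key

__all__ = [
    "ARCHETYPES",
    "BiphasicKinetics",
    "IsletProfile",
    "archetype_profile",
    "intended_outcome",
]

#: Glucose at or below which a segment counts as "low" (kinetics baseline).
LOW_GLUCOSE_MMOL = 1.0
#: Glucose at or above which a step from low glucose triggers biphasic
#: kinetics in the biphasic archetype.
STIM_GLUCOSE_MMOL = 5.5


@dataclass(frozen=True)
class BiphasicKinetics:
    """Shape of the biphasic activation following a low→high glucose step.

    The ground-truth rate rises linearly from the pre-step baseline to
    ``first_peak_rate_hz`` at ``first_peak_latency_min``, declines to
    ``nadir_fraction`` of the peak over ``fall_min``, ramps back up to a
    plateau at ``plateau_fraction`` of the peak over ``ramp_min`` and then
    oscillates sinusoidally about that plateau with amplitude
    ``oscillation_fraction`` of the peak and period ``oscillation_period_min``.
    """

    first_peak_latency_min: float = 5.0
    first_peak_rate_hz: float = 0.409
    nadir_fraction: float = 0.45
    plateau_fraction: float = 0.65
    oscillation_period_min: float = 7.5
    fall_min: float = 3.0
    ramp_min: float = 2.0
    oscillation_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.first_peak_latency_min <= 0:
            raise ValueError("first_peak_latency_min must be > 0")
        if not (0 <= self.nadir_fraction <= self.plateau_fraction <= 1):
            raise ValueError("need 0 <= nadir_fraction <= plateau_fraction <= 1")
        if self.first_peak_rate_hz < 0:
            raise ValueError("first_peak_rate_hz must be >= 0")

    def rate(self, t_s: float | np.ndarray, baseline_hz: float = 0.0) -> np.ndarray:
        """Ground-truth rate at time ``t_s`` (seconds) after stimulus onset."""
        t = np.asarray(t_s, dtype=float) / 60.0  # minutes
        peak = self.first_peak_rate_hz
        t1 = self.first_peak_latency_min
        t2 = t1 + self.fall_min
        t3 = t2 + self.ramp_min
        nadir = self.nadir_fraction * peak
        plateau = self.plateau_fraction * peak

        r = np.empty_like(t)
        rise = t < t1
        r[rise] = baseline_hz + (peak - baseline_hz) * np.clip(t[rise], 0, None) / t1
        fall = (t >= t1) & (t < t2)
        r[fall] = peak + (nadir - peak) * (t[fall] - t1) / self.fall_min
        ramp = (t >= t2) & (t < t3)
        r[ramp] = nadir + (plateau - nadir) * (t[ramp] - t2) / self.ramp_min
        osc = t >= t3
        r[osc] = plateau + self.oscillation_fraction * peak * np.sin(
            2 * np.pi * (t[osc] - t3) / self.oscillation_period_min
        )
        return np.clip(r, 0.0, None)

    def max_rate_hz(self, baseline_hz: float = 0.0) -> float:
        return max(self.first_peak_rate_hz, baseline_hz)


@dataclass(frozen=True)
class IsletProfile:
    """Ground-truth description of one simulated islet preparation."""

    archetype: str
    baseline_rate_hz: float = 0.02
    rate_map: dict[str, float] = field(default_factory=dict)
    biphasic_kinetics: BiphasicKinetics | None = None
    noise_rms_uV: float = 5.0
    sp_amplitude_uV: float = 50.0
    sp_duration_s: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_rate_hz < 0 or any(r < 0 for r in self.rate_map.values()):
            raise ValueError("all rates must be >= 0")
        if self.sp_amplitude_uV <= 0:
            raise ValueError("sp_amplitude_uV must be > 0")
        if self.sp_duration_s <= 0:
            raise ValueError("sp_duration_s must be > 0")
        if self.noise_rms_uV < 0:
            raise ValueError("noise_rms_uV must be >= 0")

    @property
    def refractory_s(self) -> float:
        """Minimum separation of ground-truth events on one electrode.

        One SP waveform width plus a 10% guard, so that physically distinct
        events can never overlap nor be merged by a detector whose dead time
        equals the waveform width.
        """
        return 1.1 * self.sp_duration_s

    def segment_rate_hz(self, segment: ProtocolSegment) -> float:
        """Constant ground-truth rate for a segment (Ca²⁺-free → 0)."""
        if not segment.calcium_present:
            return 0.0
        return self.rate_map.get(condition_key(segment), self.baseline_rate_hz)

    def triggers_kinetics(
        self, segment: ProtocolSegment, timeline: ProtocolTimeline
    ) -> bool:
        """Whether ``segment`` is a low→high glucose step that follows the
        biphasic kinetics instead of an instantaneous rate switch."""
        if self.biphasic_kinetics is None or not segment.calcium_present:
            return False
        if segment.active_drugs() or segment.glucose_mmol_per_L < STIM_GLUCOSE_MMOL:
            return False
        prev = timeline.previous(segment)
        return prev is not None and prev.glucose_mmol_per_L <= LOW_GLUCOSE_MMOL

    def rate_at(
        self, t_s: float | np.ndarray, timeline: ProtocolTimeline
    ) -> np.ndarray:
        """Ground-truth rate (Hz) at absolute time(s) ``t_s``."""
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        out = np.zeros_like(t)
        for seg in timeline:
            sel = (t >= seg.start_s) & (t < seg.end_s)
            if seg is timeline.segments[-1]:
                sel |= t == seg.end_s
            if not np.any(sel):
                continue
            if self.triggers_kinetics(seg, timeline):
                prev = timeline.previous(seg)
                base = self.segment_rate_hz(prev) if prev is not None else 0.0
                out[sel] = self.biphasic_kinetics.rate(t[sel] - seg.start_s, base)
            else:
                out[sel] = self.segment_rate_hz(seg)
        return out

    def max_rate_hz(self) -> float:
        rates = [self.baseline_rate_hz, *self.rate_map.values()]
        if self.biphasic_kinetics is not None:
            rates.append(self.biphasic_kinetics.max_rate_hz(self.baseline_rate_hz))
        return max(rates)


def _range_rates(g3: float, g55: float, g82: float, g11: float) -> dict[str, float]:
    return {"G3": g3, "G5.5": g55, "G8.2": g82, "G11": g11}


# Ground-truth rate maps per archetype.  Values are condition keys as built
# by protocol.condition_key.  Rates were chosen to realize each phenotype
# with clear margins relative to the decision thresholds while respecting
# the physical rate ceiling 1/refractory (~0.9 Hz at the default waveform).
_ARCHETYPE_SPECS: dict[str, dict] = {
    # Silent everywhere: no response to glucose, GLP-1 or glibenclamide.
    "unresponsive": dict(rate_map={}),
    # K_ATP closure works, nothing upstream does: only glibenclamide fires.
    "secretagogue_only": dict(rate_map={"G15+GLI": 0.35}),
    # GLP-1 rescues the high-glucose response and EPI inhibits it (functional
    # α₂-adrenergic receptors); glibenclamide responsive too.
    "incretin_competent": dict(
        rate_map={"G15+GLP1": 0.35, "G15+GLP1+EPI": 0.05, "G15+GLI": 0.35}
    ),
    # Responds to 15 mmol/L but flat over the physiological range.
    "high_glucose_only": dict(
        rate_map={
            "G15": 0.35,
            **_range_rates(0.035, 0.035, 0.035, 0.035),
            "G15+GLP1": 0.40,
            "G15+GLP1+EPI": 0.08,
            "G15+GLI": 0.40,
        }
    ),
    # Graded, monotone response over 1–11 mmol/L but no biphasic pattern.
    "dose_dependent": dict(
        rate_map={
            "G15": 0.40,
            **_range_rates(0.05, 0.12, 0.25, 0.40),
            "G15+GLP1": 0.45,
            "G15+GLP1+EPI": 0.06,
            "G15+GLI": 0.45,
        }
    ),
    # Full phenotype: dose dependence plus biphasic activation kinetics on
    # every low→high glucose step.
    "biphasic": dict(
        rate_map={
            "G15": 0.40,
            **_range_rates(0.05, 0.12, 0.25, 0.40),
            "G15+GLP1": 0.45,
            "G15+GLP1+EPI": 0.06,
            "G15+GLI": 0.45,
        },
        biphasic_kinetics=BiphasicKinetics(),
    ),
    # α-cell dominated: active at low glucose, *enhanced* by epinephrine.
    # Rates sit near the physical ceiling 1/refractory.
    "alpha_dominant": dict(
        baseline_rate_hz=0.56,
        rate_map={"G1": 0.56, "G1+EPI": 0.89},
    ),
    # Constitutively active β-cells: silenced by epinephrine, insensitive to
    # glucose, GLP-1 and glibenclamide.
    "hyperactive": dict(
        baseline_rate_hz=0.80,
        rate_map={"G1+EPI": 0.08, "G15+GLP1+EPI": 0.08},
    ),
}

ARCHETYPES: tuple[str, ...] = tuple(_ARCHETYPE_SPECS)

#: Intended potency outcome of each archetype under the standard protocol;
#: "disqualified" marks α-dominant preparations excluded from ranking.
_INTENDED: dict[str, int | str] = {
    "unresponsive": 1,
    "secretagogue_only": 2,
    "incretin_competent": 3,
    "high_glucose_only": 4,
    "dose_dependent": 5,
    "biphasic": 6,
    "alpha_dominant": "disqualified",
    "hyperactive": 1,
}


def archetype_profile(name: str, **overrides) -> IsletProfile:
    """Build the named archetype profile; keyword overrides replace fields."""
    try:
        spec = _ARCHETYPE_SPECS[name]
    except KeyError:
        raise ValueError(
            f"unknown archetype {name!r}; choose from {ARCHETYPES}"
        ) from None
    profile = IsletProfile(archetype=name, **spec)
    return replace(profile, **overrides) if overrides else profile


def intended_outcome(name: str) -> int | str:
    """Potency score (or "disqualified") the archetype is designed to earn."""
    return _INTENDED[name]
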