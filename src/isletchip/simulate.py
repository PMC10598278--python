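"""Seeded, ground-truthed synthetic MEA recordings of islet slow potentials.

Occupied electrodes carry slow-potential (SP) waveforms generated by an
inhomogeneous point process whose rate follows the islet profile's
condition-dependent ground truth, superposed on white Gaussian electrode
noise; unoccupied electrodes carry noise only.  The event process is Poisson
with a physical dead time (one waveform width plus a guard) and is
rate-compensated so that the realized mean rate equals the ground-truth rate
exactly: after each event the process is silent for the refractory interval
``τ`` and then fires with intensity ``λ' = λ/(1 − λτ)``, giving a mean
inter-event interval of ``τ + 1/λ' = 1/λ``.  This requires ``λτ < 1``
(rates above ``1/τ`` are physically unrealizable on one electrode).

Identical inputs and seed give bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import IsletProfile
from .protocol import ProtocolTimeline

__all__ = [
    "GroundTruth",
    "Recording",
    "render_waveform",
    "simulate_events",
    "simulate_recording",
]


@dataclass
class Recording:
    """Multichannel voltage recording (µV) with acquisition metadata."""

    samples: np.ndarray  # (n_channels, n_samples) float32, µV
    sampling_rate_hz: float
    electrode_ids: list[int]
    occupied: np.ndarray  # (n_channels,) bool
    timeline: ProtocolTimeline | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels, samples) array")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if len(self.electrode_ids) != self.samples.shape[0]:
            raise ValueError("electrode_ids length must match channel count")
        if self.occupied.shape[0] != self.samples.shape[0]:
            raise ValueError("occupied length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel(self, electrode_id: int) -> np.ndarray:
        return self.samples[self.electrode_ids.index(electrode_id)]

    def with_samples(self, samples: np.ndarray, sampling_rate_hz: float | None = None) -> "Recording":
        """Copy of this recording with new sample data (same metadata)."""
        return Recording(
            samples=samples,
            sampling_rate_hz=sampling_rate_hz or self.sampling_rate_hz,
            electrode_ids=list(self.electrode_ids),
            occupied=self.occupied.copy(),
            timeline=self.timeline,
        )


@dataclass
class GroundTruth:
    """Per-electrode true event times and the rate function behind them."""

    event_times: dict[int, np.ndarray]  # electrode_id -> sorted times (s)
    profile: IsletProfile
    timeline: ProtocolTimeline
    occupied_ids: list[int]

    def rate_at(self, t_s) -> np.ndarray:
        """True SP rate (Hz) on occupied electrodes at time(s) ``t_s``."""
        return self.profile.rate_at(t_s, self.timeline)

    def expected_count(self, start_s: float, end_s: float) -> float:
        """Expected event count per occupied electrode in [start_s, end_s)."""
        grid = np.linspace(start_s, end_s, max(int(end_s - start_s), 2) * 4 + 1)
        return float(np.trapezoid(self.rate_at(grid), grid))

    def total_events(self) -> int:
        return int(sum(len(t) for t in self.event_times.values()))


_SHAPE_GRID = np.linspace(0.0, 1.0, 20001)
_SHAPE_PEAK = float(
    np.max(np.abs(np.sin(2 * np.pi * _SHAPE_GRID) * 0.5 * (1 - np.cos(2 * np.pi * _SHAPE_GRID))))
)


def _waveform_shape(u: np.ndarray) -> np.ndarray:
    """Unit-peak biphasic pulse on u in [0, 1]: one sine cycle under a Hann
    window.  Odd-symmetric about the midpoint, hence exactly zero-mean, with
    smooth zero tails; spectral energy concentrated near 1/duration."""
    w = np.sin(2 * np.pi * u) * 0.5 * (1 - np.cos(2 * np.pi * u))
    return w / _SHAPE_PEAK


def render_waveform(
    event_time_s: float,
    sp_amplitude_uV: float,
    sp_duration_s: float,
    sampling_rate_hz: float,
) -> tuple[int, np.ndarray]:
    """Sample one SP waveform on the global sampling grid.

    Returns ``(first_sample_index, snippet)`` where the snippet covers
    ``[event_time_s, event_time_s + sp_duration_s]`` sampled at
    ``n / sampling_rate_hz`` with correct sub-sample alignment.  The peak
    absolute value equals ``sp_amplitude_uV`` (up to sampling of the
    continuous peak).
    """
    if sp_duration_s <= 0 or sp_amplitude_uV < 0:
        raise ValueError("sp_duration_s must be > 0 and amplitude >= 0")
    n_span = int(np.floor((event_time_s + sp_duration_s) * sampling_rate_hz)) - int(
        np.ceil(event_time_s * sampling_rate_hz)
    ) + 1
    if n_span < 3:
        raise ValueError(
            "sp_duration_s shorter than 3 samples at this sampling rate"
        )
    first = int(np.ceil(event_time_s * sampling_rate_hz))
    t = np.arange(first, first + n_span) / sampling_rate_hz
    u = (t - event_time_s) / sp_duration_s
    return first, (sp_amplitude_uV * _waveform_shape(np.clip(u, 0.0, 1.0))).astype(np.float32)


def _segment_rate_bound(profile: IsletProfile, seg, timeline: ProtocolTimeline) -> float:
    if profile.triggers_kinetics(seg, timeline):
        prev = timeline.previous(seg)
        base = profile.segment_rate_hz(prev) if prev is not None else 0.0
        return profile.biphasic_kinetics.max_rate_hz(base)
    return profile.segment_rate_hz(seg)


def _compensated_intensity(rate_hz: float, tau_s: float) -> float:
    occupancy = rate_hz * tau_s
    if occupancy >= 1.0:
        raise ValueError(
            f"ground-truth rate {rate_hz:.3g} Hz is unrealizable with a "
            f"{tau_s:.3g} s refractory interval (rate*refractory must be < 1)"
        )
    return rate_hz / (1.0 - occupancy)


def _draw_electrode_events(
    profile: IsletProfile, timeline: ProtocolTimeline, rng: np.random.Generator
) -> np.ndarray:
    """Dead-time-compensated inhomogeneous point process on one electrode."""
    tau = profile.refractory_s
    events: list[float] = []
    segments = timeline.segments
    idx = 0
    t = timeline.start_s
    # The last waveform must fit inside the recording: a pulse truncated by
    # the recording end is an acquisition artifact, not an event.
    end = timeline.end_s - profile.sp_duration_s
    while t < end and idx < len(segments):
        seg = segments[idx]
        if t >= seg.end_s:
            idx += 1
            continue
        t = max(t, seg.start_s)
        kinetic = profile.triggers_kinetics(seg, timeline)
        if kinetic:
            bound = _compensated_intensity(_segment_rate_bound(profile, seg, timeline), tau)
        else:
            rate = profile.segment_rate_hz(seg)
            if rate <= 0:
                t = seg.end_s
                continue
            bound = _compensated_intensity(rate, tau)
        wait = rng.exponential(1.0 / bound)
        if t + wait >= seg.end_s:
            t = seg.end_s
            continue
        t += wait
        if t > end:
            break
        if kinetic:
            lam = float(profile.rate_at(t, timeline)[0])
            if lam <= 0 or rng.random() * bound > _compensated_intensity(lam, tau):
                continue
        events.append(t)
        t += tau
    return np.asarray(events, dtype=float)


def _resolve_occupancy(n_electrodes: int, occupied_fraction: float) -> np.ndarray:
    if n_electrodes < 2:
        raise ValueError("need at least 2 electrodes (one occupied, one noise)")
    n_occ = int(round(n_electrodes * occupied_fraction))
    if n_occ < 1 or n_occ > n_electrodes - 1:
        raise ValueError(
            "occupied_fraction must leave at least one occupied and one "
            "unoccupied (noise) electrode"
        )
    occupied = np.zeros(n_electrodes, dtype=bool)
    occupied[:n_occ] = True
    return occupied


def simulate_events(
    profile: IsletProfile,
    timeline: ProtocolTimeline,
    n_electrodes: int = 60,
    occupied_fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> GroundTruth:
    """Draw ground-truth event times only (no voltage rendering).

    Uses the same random stream layout as :func:`simulate_recording`, so the
    ground truth for a given seed is identical between the two.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    occupied = _resolve_occupancy(n_electrodes, occupied_fraction)
    electrode_ids = list(range(1, n_electrodes + 1))
    event_times = {
        eid: (_draw_electrode_events(profile, timeline, rng) if occ else np.empty(0))
        for eid, occ in zip(electrode_ids, occupied)
    }
    return GroundTruth(
        event_times=event_times,
        profile=profile,
        timeline=timeline,
        occupied_ids=[e for e, o in zip(electrode_ids, occupied) if o],
    )


def simulate_recording(
    profile: IsletProfile,
    timeline: ProtocolTimeline,
    n_electrodes: int = 60,
    occupied_fraction: float = 0.5,
    sampling_rate_hz: float = 1000.0,
    seed: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Simulate a full multichannel MEA recording under a protocol timeline.

    Parameters
    ----------
    profile:
        Ground-truth activity description (see :func:`archetype_profile`).
    timeline:
        Ordered stimulation segments; Ca²⁺-free segments produce no events
        regardless of the profile's rate map.
    n_electrodes, occupied_fraction:
        Electrode count (default 60, matching a standard 60-electrode MEA)
        and the fraction carrying islets; the rest record noise only.
    sampling_rate_hz:
        Simulation rate, default 1 kHz (the native acquisition runs at
        10 kHz, but SP content lives below ~3 Hz).  Must resolve the SP
        waveform: at least ``60 / sp_duration_s``.
    seed:
        Any fixed seed gives bit-identical output.
    """
    min_rate = 60.0 / profile.sp_duration_s  # 20x the ~3/duration pulse bandwidth
    if sampling_rate_hz < min_rate:
        raise ValueError(
            f"sampling_rate_hz must be >= {min_rate:.0f} Hz to resolve the "
            "SP waveform (20x its bandwidth)"
        )
    rng = np.random.default_rng(seed)
    truth = simulate_events(profile, timeline, n_electrodes, occupied_fraction, rng)
    occupied = _resolve_occupancy(n_electrodes, occupied_fraction)
    n_samples = int(round(timeline.duration_s * sampling_rate_hz))
    if n_samples <= 0:
        raise ValueError("timeline duration too short at this sampling rate")

    samples = rng.standard_normal((n_electrodes, n_samples), dtype=np.float32)
    samples *= np.float32(profile.noise_rms_uV)

    t0 = timeline.start_s
    for ch, eid in enumerate(truth.event_times):
        for ev in truth.event_times[eid]:
            first, snippet = render_waveform(
                ev - t0, profile.sp_amplitude_uV, profile.sp_duration_s, sampling_rate_hz
            )
            stop = min(first + len(snippet), n_samples)
            if first < stop:
                samples[ch, first:stop] += snippet[: stop - first]

    rec = Recording(
        samples=samples,
        sampling_rate_hz=sampling_rate_hz,
        electrode_ids=list(range(1, n_electrodes + 1)),
        occupied=occupied,
        timeline=timeline,
    )
    return rec, truth
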