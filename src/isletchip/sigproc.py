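"""Offline re-implementation of the real-time MEA processing chain:
band filtering, slow-potential event detection, and windowed SP frequency
profiles per electrode with across-electrode aggregates.

All filtering is zero-phase (forward-backward), so detected event times are
not phase-shifted — appropriate for an offline pipeline where timing feeds
latency estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .simulate import Recording

__all__ = [
    "EventTrain",
    "FrequencyProfile",
    "SegmentStats",
    "acquisition_filter",
    "detect_events",
    "estimate_noise_sigma",
    "frequency_profile",
    "segment_stats",
    "sp_band_filter",
]

log = logging.getLogger(__name__)

#: Corner frequencies of the acquisition band (Hz); the upper corner is
#: clamped to 0.45x the sampling rate when simulating below 10 kHz.
ACQ_LOW_HZ = 0.1
ACQ_HIGH_HZ = 3000.0

_MAD_TO_SIGMA = 1.0 / 0.674489750196082  # Gaussian consistency factor


def acquisition_filter(recording: Recording) -> Recording:
    """Broadband acquisition band-pass, 0.1 Hz to min(3000, 0.45·fs) Hz.

    Zero-phase; output length equals input length.  Emulates the amplifier's
    analog band limits for offline use.
    """
    fs = recording.sampling_rate_hz
    high = min(ACQ_HIGH_HZ, 0.45 * fs)
    if high <= ACQ_LOW_HZ:
        raise ValueError(
            f"sampling rate {fs} Hz too low for the {ACQ_LOW_HZ} Hz lower corner"
        )
    sos_hp = signal.butter(2, ACQ_LOW_HZ, btype="high", fs=fs, output="sos")
    sos_lp = signal.butter(8, high, btype="low", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos_hp, recording.samples, axis=-1)
    x = signal.sosfiltfilt(sos_lp, x, axis=-1)
    return recording.with_samples(x.astype(np.float32))


def sp_band_filter(
    recording: Recording,
    corner_hz: float = 3.0,
    low_hz: float = ACQ_LOW_HZ,
    decimate_to_hz: float | None = 50.0,
) -> Recording:
    """Isolate the slow-potential band (``low_hz``–``corner_hz`` Hz).

    By default the signal is first block-averaged down to ~50 Hz — the SP
    band lies far below that Nyquist, and the 0.1 Hz high-pass corner is far
    better conditioned at 50 Hz than at acquisition rates — then band-passed
    with a zero-phase Butterworth.  Pass ``decimate_to_hz=None`` to filter at
    the native rate (output length then equals input length).
    """
    fs = recording.sampling_rate_hz
    if corner_hz >= fs / 2:
        raise ValueError(f"corner {corner_hz} Hz must be below Nyquist ({fs / 2} Hz)")
    x = recording.samples
    if decimate_to_hz is not None and fs > 2 * decimate_to_hz:
        factor = max(int(fs // decimate_to_hz), 1)
        n_keep = (x.shape[1] // factor) * factor
        x = x[:, :n_keep].reshape(x.shape[0], -1, factor).mean(axis=2)
        fs = fs / factor
        if corner_hz >= fs / 2:
            raise ValueError("decimated rate too low for the requested corner")
    # Order 2: steep enough to isolate the SP band while keeping post-pulse
    # ringing well below the detection threshold.
    sos_lp = signal.butter(2, corner_hz, btype="low", fs=fs, output="sos")
    pad_lp = min(x.shape[-1] - 1, int(4.0 * fs / corner_hz))
    y = signal.sosfiltfilt(sos_lp, x, axis=-1, padlen=pad_lp)
    if low_hz > 0:
        # The high-pass settle time (~1/low_hz) far exceeds sosfiltfilt's
        # default padding; extend it so edge transients cannot masquerade
        # as slow-potential excursions in the first/last windows.
        sos_hp = signal.butter(2, low_hz, btype="high", fs=fs, output="sos")
        padlen = min(y.shape[-1] - 1, int(2.0 * fs / low_hz))
        y = signal.sosfiltfilt(sos_hp, y, axis=-1, padlen=padlen)
    return recording.with_samples(y.astype(np.float32), sampling_rate_hz=fs)


def estimate_noise_sigma(
    recording: Recording,
    sp_low_hz: float = ACQ_LOW_HZ,
    sp_high_hz: float = 3.0,
    noise_band_hz: tuple[float, float] = (25.0, 450.0),
    max_window_s: float = 120.0,
) -> np.ndarray:
    """Per-electrode noise standard deviation expected in the SP band (µV).

    The noise scale is measured robustly (MAD) in a slow-potential-free high
    band of the *raw* trace and rescaled to the SP bandwidth assuming a flat
    noise spectrum.  Unlike a MAD taken on the SP-band signal itself, this
    stays valid when slow potentials occupy most of the trace (their ~1 s
    width means >50% duty above 0.5 Hz event rates).
    """
    fs = recording.sampling_rate_hz
    lo, hi = noise_band_hz
    hi = min(hi, 0.45 * fs)
    if hi <= lo:
        raise ValueError("sampling rate too low for the noise estimation band")
    n = min(recording.n_samples, int(max_window_s * fs))
    sos = signal.butter(2, [lo, hi], btype="band", fs=fs, output="sos")
    seg = signal.sosfiltfilt(sos, recording.samples[:, :n], axis=-1)
    mad = np.median(np.abs(seg - np.median(seg, axis=-1, keepdims=True)), axis=-1)
    sigma_hf = mad * _MAD_TO_SIGMA
    return sigma_hf * np.sqrt((sp_high_hz - sp_low_hz) / (hi - lo))


@dataclass
class EventTrain:
    """Detected slow-potential times (s) per electrode."""

    events: dict[int, np.ndarray]
    duration_s: float
    electrode_ids: list[int]
    occupied: np.ndarray
    refractory_s: float = 1.0

    def __post_init__(self) -> None:
        self.occupied = np.asarray(self.occupied, dtype=bool)
        for eid, t in self.events.items():
            t = np.asarray(t, dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"electrode {eid}: event times must be strictly increasing")
            self.events[eid] = t

    @property
    def occupied_ids(self) -> list[int]:
        return [e for e, o in zip(self.electrode_ids, self.occupied) if o]

    def total_events(self) -> int:
        return int(sum(len(t) for t in self.events.values()))


def _excursion_events(x: np.ndarray, thr: float, min_gap: int) -> np.ndarray:
    """Indices of excursion extrema of |x| above thr, with dead time.

    Local maxima of the rectified signal above the threshold, pruned to the
    refractory spacing (largest first).  For isolated excursions this is one
    event at the excursion's extremum; when consecutive slow potentials run
    into a single excursion at high rates, each still contributes its own
    extremum rather than being swallowed.
    """
    mask = np.abs(x) > thr
    if not mask.any():
        return np.empty(0, dtype=np.int64)
    peaks, _ = signal.find_peaks(np.abs(x), height=thr)
    kept: list[int] = []
    last = -min_gap
    for p in peaks:
        if p - last >= min_gap:
            kept.append(int(p))
            last = p
    return np.asarray(kept, dtype=np.int64)


def detect_events(
    filtered: Recording,
    threshold_mode: str = "k_mad",
    k: float = 5.0,
    refractory_s: float = 1.0,
    threshold_uV: float | None = None,
    noise_sigma_uV: np.ndarray | float | None = None,
) -> EventTrain:
    """Detect slow potentials as threshold excursions of the SP-band signal.

    One event per excursion of ``|x|`` above the threshold, timed at the
    excursion's extremum; no two events closer than ``refractory_s`` per
    electrode.  Polarity is ignored (detection on absolute excursions).

    ``threshold_mode="k_mad"`` sets the threshold to ``k`` times a robust
    noise standard deviation — either ``noise_sigma_uV`` (e.g. from
    :func:`estimate_noise_sigma` on the raw trace) or, failing that, the MAD
    of the filtered signal itself.  ``threshold_mode="fixed_uV"`` uses
    ``threshold_uV`` directly.
    """
    x = filtered.samples
    fs = filtered.sampling_rate_hz
    n_ch = filtered.n_channels
    if threshold_mode == "fixed_uV":
        if threshold_uV is None:
            raise ValueError("fixed_uV mode requires threshold_uV")
        thresholds = np.full(n_ch, float(threshold_uV))
    elif threshold_mode == "k_mad":
        if noise_sigma_uV is not None:
            sigma = np.broadcast_to(np.asarray(noise_sigma_uV, dtype=float), (n_ch,))
        else:
            mad = np.median(np.abs(x - np.median(x, axis=-1, keepdims=True)), axis=-1)
            sigma = mad * _MAD_TO_SIGMA
        thresholds = k * sigma
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    min_gap = max(int(round(refractory_s * fs)), 1)
    # Zero-phase filtering is unreliable within its settle time of the
    # recording boundaries; guard one refractory interval at each end.
    guard_lo = refractory_s
    guard_hi = filtered.duration_s - refractory_s
    events: dict[int, np.ndarray] = {}
    for ch, eid in enumerate(filtered.electrode_ids):
        if x.shape[1] == 0:
            events[eid] = np.empty(0)
            continue
        idx = _excursion_events(x[ch], thresholds[ch], min_gap)
        t = idx / fs
        events[eid] = t[(t >= guard_lo) & (t <= guard_hi)]
    return EventTrain(
        events=events,
        duration_s=filtered.duration_s,
        electrode_ids=list(filtered.electrode_ids),
        occupied=filtered.occupied.copy(),
        refractory_s=refractory_s,
    )


@dataclass
class FrequencyProfile:
    """Windowed SP frequency per electrode plus across-electrode aggregate.

    ``aggregate_mean_hz``/``aggregate_sem_hz`` are the mean and standard
    error (sd/sqrt(n), sample sd) across ``electrodes_used`` per window;
    electrodes without islets are kept in ``per_electrode_hz`` for
    inspection but excluded from the aggregate.
    """

    window_starts_s: np.ndarray
    window_s: float
    electrode_ids: list[int]
    per_electrode_hz: np.ndarray  # (n_windows, n_electrodes)
    electrodes_used: list[int]
    aggregate_mean_hz: np.ndarray
    aggregate_sem_hz: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.window_starts_s)

    def column(self, electrode_id: int) -> np.ndarray:
        return self.per_electrode_hz[:, self.electrode_ids.index(electrode_id)]


def frequency_profile(
    events: EventTrain,
    window_s: float = 60.0,
    electrodes: list[int] | None = None,
) -> FrequencyProfile:
    """Event counts per electrode in consecutive windows, divided by the
    window length; aggregated (mean ± SEM) across occupied electrodes or an
    explicit subset.  A trailing partial window is dropped."""
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    if electrodes is not None:
        if len(electrodes) == 0:
            raise ValueError("electrode subset must not be empty")
        missing = set(electrodes) - set(events.electrode_ids)
        if missing:
            raise ValueError(f"unknown electrodes {sorted(missing)}")
        used = list(electrodes)
    else:
        used = events.occupied_ids
    n_windows = int(np.floor(events.duration_s / window_s + 1e-9))
    starts = np.arange(n_windows) * window_s
    bins = np.r_[starts, n_windows * window_s]
    rates = np.empty((n_windows, len(events.electrode_ids)))
    for j, eid in enumerate(events.electrode_ids):
        counts, _ = np.histogram(events.events[eid], bins=bins)
        rates[:, j] = counts / window_s
    cols = [events.electrode_ids.index(e) for e in used]
    sub = rates[:, cols]
    mean = sub.mean(axis=1)
    if len(used) > 1:
        sem = sub.std(axis=1, ddof=1) / np.sqrt(len(used))
    else:
        sem = np.full(n_windows, np.nan)
    return FrequencyProfile(
        window_starts_s=starts,
        window_s=window_s,
        electrode_ids=list(events.electrode_ids),
        per_electrode_hz=rates,
        electrodes_used=used,
        aggregate_mean_hz=mean,
        aggregate_sem_hz=sem,
    )


@dataclass
class SegmentStats:
    """Condition-level SP frequency summary for one protocol segment."""

    label: str
    start_s: float
    end_s: float
    n_windows: int
    electrode_ids: list[int]
    per_electrode_hz: np.ndarray  # (n_electrodes,) mean over windows
    electrodes_used: list[int]
    mean_hz: float
    sem_hz: float

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes_used)

    def values(self, electrodes: list[int] | None = None) -> np.ndarray:
        """Per-electrode mean frequencies for the given (default: used)
        electrodes, aligned with the electrode order."""
        ids = electrodes if electrodes is not None else self.electrodes_used
        cols = [self.electrode_ids.index(e) for e in ids]
        return self.per_electrode_hz[cols]


def segment_stats(
    profile: FrequencyProfile,
    timeline,
    discard_initial_s: float = 60.0,
) -> list[SegmentStats]:
    """Per-segment mean SP frequency per electrode.

    Only windows fully inside a segment after discarding its initial
    ``discard_initial_s`` (solution-exchange transient) contribute.  Segments
    too short to contain a single such window are logged and excluded.
    """
    out: list[SegmentStats] = []
    tol = 1e-9
    starts = profile.window_starts_s
    for seg in timeline:
        sel = (starts >= seg.start_s + discard_initial_s - tol) & (
            starts + profile.window_s <= seg.end_s + tol
        )
        if not sel.any():
            log.warning(
                "segment %r (%.0f-%.0f s) shorter than discard + one window; excluded",
                seg.label, seg.start_s, seg.end_s,
            )
            continue
        per_el = profile.per_electrode_hz[sel].mean(axis=0)
        cols = [profile.electrode_ids.index(e) for e in profile.electrodes_used]
        vals = per_el[cols]
        n = len(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        out.append(
            SegmentStats(
                label=seg.label,
                start_s=seg.start_s,
                end_s=seg.end_s,
                n_windows=int(sel.sum()),
                electrode_ids=list(profile.electrode_ids),
                per_electrode_hz=per_el,
                electrodes_used=list(profile.electrodes_used),
                mean_hz=float(vals.mean()),
                sem_hz=sem,
            )
        )
    return out
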