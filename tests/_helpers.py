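"""Shared builders for the test suite."""

from __future__ import annotations

import numpy as np

from isletchip.sigproc import FrequencyProfile, SegmentStats


def make_stats(label, values, start=0.0, end=120.0, n_windows=1):
    """SegmentStats from explicit per-electrode frequencies."""
    values = np.asarray(values, dtype=float)
    ids = list(range(1, len(values) + 1))
    sem = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else float("nan")
    return SegmentStats(
        label=label, start_s=start, end_s=end, n_windows=n_windows,
        electrode_ids=ids, per_electrode_hz=values, electrodes_used=ids,
        mean_hz=float(values.mean()), sem_hz=sem,
    )


def profile_from_rate(rate_fn, duration_s, window_s=60.0, n_electrodes=2):
    """Noise-free FrequencyProfile whose aggregate equals the windowed
    average of a deterministic rate function."""
    n = int(np.floor(duration_s / window_s + 1e-9))
    starts = np.arange(n) * window_s
    vals = np.empty(n)
    for i, s in enumerate(starts):
        g = np.linspace(s, s + window_s, 61)
        vals[i] = np.trapezoid(np.asarray(rate_fn(g), dtype=float), g) / window_s
    ids = list(range(1, n_electrodes + 1))
    per = np.tile(vals[:, None], (1, n_electrodes))
    return FrequencyProfile(
        window_starts_s=starts, window_s=window_s, electrode_ids=ids,
        per_electrode_hz=per, electrodes_used=ids,
        aggregate_mean_hz=vals.copy(), aggregate_sem_hz=np.zeros(n),
    )


def match_events(truth_times, detected_times, tol_s=1.0):
    """Greedy matching of detected to ground-truth events within ``tol_s``;
    returns (true positives, false positives, false negatives)."""
    truth_times = np.asarray(truth_times, dtype=float)
    used = np.zeros(len(truth_times), dtype=bool)
    tp = fp = 0
    for d in detected_times:
        if len(truth_times):
            i = int(np.argmin(np.abs(truth_times - d)))
            if abs(truth_times[i] - d) <= tol_s and not used[i]:
                used[i] = True
                tp += 1
                continue
        fp += 1
    fn = int((~used).sum())
    return tp, fp, fn
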