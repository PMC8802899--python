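"""sEMG-style preprocessing: rectification, smoothing, QC, burst segmentation.

Operates on :class:`Recording` objects — uniformly sampled multichannel time
series, either surface-EMG-like signals from the synthetic cohort or
motor-neuron population rates from the circuit model. The processing chain
mirrors the standard muscle-synergy pipeline: rectify, segment into
single-burst windows, low-pass filter at 4 Hz (second-order Butterworth) and
normalize each burst series to its maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Recording",
    "BurstMatrix",
    "rectify",
    "lowpass",
    "channel_qc",
    "segment_bursts",
    "normalize_burst",
    "burst_matrices",
]


@dataclass
class Recording:
    """Uniformly sampled multichannel signal."""

    channels: list[str]
    sample_rate: float                  # Hz
    data: np.ndarray                    # (n_samples, n_channels)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[1]} data columns for {len(self.channels)} channel names"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return np.arange(self.n_samples) / self.sample_rate * 1000.0

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channels.index(name)]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.data, columns=self.channels)
        out.insert(0, "time_ms", self.times)
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: dict | None = None) -> "Recording":
        if "time_ms" not in frame.columns:
            raise ValueError("expected a time_ms column")
        t = frame["time_ms"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError("recording too short")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform")
        chans = [c for c in frame.columns if c != "time_ms"]
        return cls(chans, 1000.0 / dt[0], frame[chans].to_numpy(dtype=float), meta or {})


@dataclass
class BurstMatrix:
    """Nonnegative muscles-by-time activity matrix for one burst."""

    D: np.ndarray                # (n_muscles, n_samples)
    channels: list[str]
    sample_rate: float           # Hz of the columns
    normalized: bool = False
    meta: dict = field(default_factory=dict)  # subject, position, angle, burst index, onset

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2 or self.D.shape[0] != len(self.channels):
            raise ValueError("D must be (n_muscles, n_samples) matching channel names")
        if np.any(self.D < 0):
            raise ValueError("burst matrix must be nonnegative")


def rectify(rec: Recording) -> Recording:
    """Full-wave rectification (elementwise absolute value)."""
    return replace(rec, data=np.abs(rec.data))


def lowpass(
    rec: Recording,
    cutoff: float = 4.0,
    order: int = 2,
    zero_phase: bool = False,
) -> Recording:
    """Butterworth low-pass per channel.

    Single-pass causal by default (``lfilter``); ``zero_phase`` switches to
    forward-backward filtering. ``cutoff`` must lie below the Nyquist rate.
    """
    nyq = rec.sample_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    b, a = signal.butter(order, cutoff, btype="low", fs=rec.sample_rate)
    if zero_phase:
        out = signal.filtfilt(b, a, rec.data, axis=0)
    else:
        out = signal.lfilter(b, a, rec.data, axis=0)
    return replace(rec, data=out)


def _envelope(x: np.ndarray, fs: float, cutoff: float = 4.0) -> np.ndarray:
    b, a = signal.butter(2, cutoff, btype="low", fs=fs)
    return signal.lfilter(b, a, np.abs(x))


def channel_qc(
    rec: Recording,
    snr_threshold: float = 2.0,
    cutoff: float = 1.0,
) -> list[str]:
    """Channels passing a burst-to-baseline amplitude check.

    For each channel a heavily smoothed envelope of the rectified signal
    (1 Hz by default, so stochastic amplitude fluctuation does not masquerade
    as signal) is summarised by its 90th (burst level) and 10th (baseline
    level) percentiles; channels whose ratio falls below ``snr_threshold``
    are dropped — the analogue of discarding electrodes whose recordings
    never rise above noise.
    """
    kept: list[str] = []
    for i, name in enumerate(rec.channels):
        env = _envelope(rec.data[:, i], rec.sample_rate, cutoff)
        skip = int(0.25 * rec.sample_rate)  # discard filter transient
        env = env[skip:] if len(env) > 2 * skip else env
        hi, lo = np.percentile(env, [90, 10])
        if lo <= 0:
            ratio = np.inf if hi > 0 else 0.0
        else:
            ratio = hi / lo
        if ratio >= snr_threshold:
            kept.append(name)
    if len(kept) < 2:
        raise ValueError(
            f"only {len(kept)} channel(s) pass QC at threshold {snr_threshold}"
        )
    return kept


def segment_bursts(
    rec: Recording,
    expected: int,
    reference_channel: str | None = None,
    k_sd: float = 3.0,
    baseline_s: float = 0.5,
    lead_fraction: float = 0.1,
    min_above_s: float = 0.25,
    min_off_s: float = 0.5,
) -> list[Recording]:
    """Split a rectified recording into equal-length single-burst windows.

    Onsets are detected on the reference channel (default: first channel)
    from its 4 Hz envelope with a hysteresis rule. The onset threshold is the
    baseline envelope mean (first ``baseline_s`` seconds) plus the larger of
    ``k_sd`` baseline standard deviations and 30% of the burst excursion (the
    floor guards against a slowly drifting baseline wandering past a pure
    SD-based level). A burst starts when the envelope crosses the onset
    threshold and stays up for ``min_above_s``; it only ends once the
    envelope has stayed below a lower offset threshold (half the excursion to
    onset) for ``min_off_s`` — so within-burst amplitude dips cannot
    retrigger. Windows have equal length (the median inter-onset interval, or
    the whole recording if ``expected == 1``) and start ``lead_fraction`` of
    a window before each onset. Raises if the detected burst count differs
    from ``expected``.
    """
    if expected < 1:
        raise ValueError("expected must be >= 1")
    if reference_channel is None:
        # Try channels in order; a locally weak burst can defeat detection on
        # one channel while the others carry the same timing.
        last_err: Exception | None = None
        for ref in rec.channels:
            try:
                return segment_bursts(
                    rec, expected, reference_channel=ref, k_sd=k_sd,
                    baseline_s=baseline_s, lead_fraction=lead_fraction,
                    min_above_s=min_above_s, min_off_s=min_off_s,
                )
            except ValueError as err:
                last_err = err
        raise ValueError(f"burst detection failed on every channel: {last_err}")
    ref = reference_channel
    raw = rec.channel(ref)
    env = _envelope(raw, rec.sample_rate)
    n_base = max(int(baseline_s * rec.sample_rate), 10)
    skip = int(0.25 * rec.sample_rate)  # filter transient
    base_env = env[skip:n_base] if n_base > skip + 10 else env[:n_base]
    # The envelope's own SD over a ~1 s baseline is a one-degree-of-freedom
    # estimate at 4 Hz, so the spread comes from the raw rectified samples.
    base_raw = np.abs(raw[:n_base])
    base_level = float(base_env.mean())
    p95 = float(np.percentile(env[skip:], 95))
    t_hi = base_level + max(k_sd * base_raw.std(), 0.3 * (p95 - base_level))
    t_lo = base_level + 0.5 * (t_hi - base_level)

    # Hysteresis state machine on a decimated envelope (10 ms resolution).
    stride = max(int(rec.sample_rate / 100), 1)
    e = env[::stride]
    n_confirm = max(int(min_above_s * 100), 1)
    n_off = max(int(min_off_s * 100), 1)
    onsets: list[int] = []
    in_burst = False
    below = 0
    i = 0
    while i < len(e):
        if not in_burst:
            if e[i] > t_hi:
                seg = e[i:i + n_confirm]
                if np.mean(seg > t_lo) > 0.9:
                    # Refine backwards to where the ramp actually left the
                    # baseline: last up-crossing of a low threshold within
                    # the preceding 2.5 s (a locally weak burst start can
                    # delay the confirm crossing by over a second).
                    t_low = base_level + 0.1 * (t_hi - base_level)
                    j0 = max(i - 250, 0)
                    win = e[j0:i + 1]
                    ups = np.flatnonzero((win[1:] > t_low) & (win[:-1] <= t_low))
                    start = (j0 + int(ups[-1]) + 1) if len(ups) else i
                    onsets.append(start * stride)
                    in_burst = True
                    below = 0
                else:
                    i += max(len(seg), 1)
                    continue
        else:
            if e[i] < t_lo:
                below += 1
                if below >= n_off:
                    in_burst = False
            else:
                below = 0
        i += 1
    if len(onsets) != expected:
        raise ValueError(f"detected {len(onsets)} bursts, expected {expected}")

    if expected >= 3:
        # The protocol repeats identical contractions at a fixed cadence
        # ("equal sections"), so snap the noisy per-burst estimates to the
        # best-fitting periodic grid.
        arr = np.asarray(onsets, dtype=float)
        idx = np.arange(expected)
        # Theil-Sen: median pairwise slope resists the correlated late
        # detections that tilt a least-squares line.
        slopes = [
            (arr[j] - arr[i]) / (j - i)
            for i in range(expected) for j in range(i + 1, expected)
        ]
        period = float(np.median(slopes))
        t0 = float(np.median(arr - period * idx))
        resid = arr - (t0 + period * idx)
        keep = np.abs(resid) <= 200.0  # ms
        if keep.sum() >= 3 and not keep.all():
            period, t0 = np.polyfit(idx[keep], arr[keep], 1)
        onsets = [int(round(t0 + i * period)) for i in range(expected)]

    if expected == 1:
        length = rec.n_samples
    else:
        length = int(np.median(np.diff(onsets)))
    lead = int(lead_fraction * length)
    out = []
    for j, onset in enumerate(onsets):
        start = max(onset - lead, 0)
        stop = min(start + length, rec.n_samples)
        start = max(stop - length, 0)
        seg = Recording(
            list(rec.channels),
            rec.sample_rate,
            rec.data[start:stop],
            {**rec.meta, "burst": j, "onset_ms": onset / rec.sample_rate * 1000.0,
             "window_start_ms": start / rec.sample_rate * 1000.0},
        )
        out.append(seg)
    return out


def normalize_burst(bm: BurstMatrix) -> BurstMatrix:
    """Scale each muscle row to unit maximum; all-zero rows stay zero."""
    peaks = bm.D.max(axis=1, keepdims=True)
    scale = np.where(peaks > 0, peaks, 1.0)
    return BurstMatrix(bm.D / scale, list(bm.channels), bm.sample_rate, True, dict(bm.meta))


def burst_matrices(
    rec: Recording,
    expected: int = 6,
    channels: Sequence[str] | None = None,
    cutoff: float = 4.0,
    order: int = 2,
    envelope_rate: float = 100.0,
    normalize: bool = True,
    reference_channel: str | None = None,
) -> list[BurstMatrix]:
    """Full preprocessing chain: rectify, segment, smooth, build burst matrices.

    Each detected burst becomes a muscles-by-time matrix of the 4 Hz envelope,
    decimated to ``envelope_rate`` Hz (the envelope carries no information
    above the filter cutoff, so the analysis rate is a pure efficiency
    choice), clipped at zero against filter undershoot, and optionally
    row-normalized.
    """
    use = list(channels) if channels is not None else list(rec.channels)
    rect = rectify(rec)
    segments = segment_bursts(rect, expected, reference_channel=reference_channel)
    stride = max(int(round(rec.sample_rate / envelope_rate)), 1)
    out = []
    for seg in segments:
        smooth = lowpass(seg, cutoff=cutoff, order=order)
        idx = [smooth.channels.index(c) for c in use]
        D = np.clip(smooth.data[::stride, idx].T, 0.0, None)
        bm = BurstMatrix(D, use, rec.sample_rate / stride, False, dict(seg.meta))
        out.append(normalize_burst(bm) if normalize else bm)
    return out
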