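"""Synthetic sEMG cohort with the experiment's structure and amplitude trends.

Emulates the study design — subjects performing six ~5 s maximal isometric
knee extensions at four knee angles (0/20/60/90 deg) in two hip positions,
five recorded muscles (RF, VL, VM, ST, BF), 2 kHz sampling — as
amplitude-modulated Gaussian noise:

    x(t) = noise_sd * (b + a * trapezoid(t)) * m(t) * xi(t)

where ``a`` is the condition's contraction amplitude, ``b`` the baseline
level, the trapezoid the burst envelope, ``m(t)`` a mean-one lognormal slow
drift (independent per channel) emulating effort nonstationarity, and
``xi(t)`` a unit-variance Gaussian carrier band-limited to the lower surface-
EMG band. The carrier bandwidth matters: a carrier that is white at the
2 kHz sampling rate would average to an implausibly clean envelope under the
4 Hz smoothing filter, whereas a band-limited carrier leaves the envelope
with the stochastic fluctuation real maximal-effort recordings show — which
is precisely what keeps a rank-1 factorization below the variance-accounted-
for threshold. Rectifying gives a half-normal signal whose smoothed envelope
tracks ``(b + a*trapezoid) * m``, so every downstream quantity (burst means,
synergy loadings) has a closed-form ground truth. Two noise-only channels
can be appended to emulate electrodes that never rise above baseline (the
discarded MG/TA recordings).

Amplitude units are arbitrary: surface-EMG amplitudes are not comparable
across muscles, so only the ordinal trends across angle and position are
meaningful, and those are what :func:`default_trend` encodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterator

import numpy as np

from scipy import signal as _signal

from .circuit import POSITIONS, ANGLES
from .preprocessing import Recording

__all__ = [
    "MUSCLES",
    "NOISE_CHANNELS",
    "CohortConfig",
    "TrendModel",
    "default_trend",
    "generate_burst",
    "generate_cohort",
    "Cohort",
]

MUSCLES = ("RF", "VL", "VM", "ST", "BF")
NOISE_CHANNELS = ("MG", "TA")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    n_subjects: int = 17
    positions: tuple[int, ...] = POSITIONS
    angles: tuple[int, ...] = ANGLES
    bursts_per_condition: int = 6
    sample_rate: float = 2000.0   # Hz
    ramp_ms: float = 500.0        # burst up/down ramp
    plateau_ms: float = 5000.0    # ~5 s contraction hold
    gap_ms: float = 2000.0        # rest between bursts
    lead_ms: float = 1000.0       # baseline before the first burst
    noise_sd: float = 1.0         # carrier noise scale
    carrier_cutoff_hz: float = 10.0  # carrier bandwidth (0 = white noise)
    drift_sd: float = 0.2         # lognormal sigma of the slow amplitude drift
    drift_rate_hz: float = 3.0    # knot rate of the drift process
    subject_sd: float = 0.2       # lognormal sigma of per-subject-muscle gains
    include_noise_channels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.bursts_per_condition < 1:
            raise ValueError("counts must be >= 1")
        if self.sample_rate <= 8.0:
            raise ValueError("sample_rate must exceed twice the 4 Hz envelope cutoff")
        if min(self.ramp_ms, self.plateau_ms, self.gap_ms, self.lead_ms) < 0:
            raise ValueError("durations must be >= 0")

    @property
    def burst_period_ms(self) -> float:
        return 2 * self.ramp_ms + self.plateau_ms + self.gap_ms

    @property
    def recording_ms(self) -> float:
        return self.lead_ms + self.bursts_per_condition * self.burst_period_ms

    def onsets_ms(self) -> list[float]:
        """Ground-truth burst onsets (start of the rising ramp)."""
        return [self.lead_ms + i * self.burst_period_ms
                for i in range(self.bursts_per_condition)]


@dataclass(frozen=True)
class TrendModel:
    """Per-condition contraction amplitudes and baselines.

    ``a[muscle][(position, angle)]`` is the plateau amplitude of the burst
    envelope, ``b[muscle][(position, angle)]`` the baseline level, both in
    arbitrary units. The two latent activation templates of every recording
    are the burst trapezoid (weight ``a``) and the constant baseline (weight
    ``b``).
    """

    a: dict[str, dict[tuple[int, int], float]]
    b: dict[str, dict[tuple[int, int], float]]

    def __post_init__(self) -> None:
        for table in (self.a, self.b):
            for m, vals in table.items():
                for cond, v in vals.items():
                    if v < 0:
                        raise ValueError(f"negative trend value for {m} {cond}")

    def amplitude(self, muscle: str, position: int, angle: int) -> float:
        return self.a[muscle][(position, angle)]

    def baseline(self, muscle: str, position: int, angle: int) -> float:
        return self.b[muscle][(position, angle)]


def default_trend() -> TrendModel:
    """Amplitude table encoding the reported task trends.

    Quadriceps activity falls with increasing knee angle — significantly from
    0 to 20 and 20 to 60 deg in position 1, with the whole drop concentrated
    in 0-to-20 in position 2; RF is higher in position 1 than position 2 at
    flexed angles; the hamstrings rise from 0 to 20 deg; ST keeps a raised
    baseline in position 1 away from full extension. Magnitudes are free
    parameters chosen so the marked contrasts are recoverable at n = 17 with
    the default noise levels.
    """
    quad_p1 = {0: 1.00, 20: 0.70, 60: 0.45, 90: 0.44}
    quad_p2 = {0: 1.00, 20: 0.45, 60: 0.44, 90: 0.43}
    rf_p2 = {0: 1.00, 20: 0.35, 60: 0.34, 90: 0.335}
    st_p1 = {0: 0.10, 20: 0.45, 60: 0.48, 90: 0.50}
    st_p2 = {0: 0.10, 20: 0.42, 60: 0.43, 90: 0.44}
    bf = {0: 0.32, 20: 0.40, 60: 0.41, 90: 0.42}

    def spread(p1: dict[int, float], p2: dict[int, float]) -> dict[tuple[int, int], float]:
        return {(1, ang): v for ang, v in p1.items()} | {(2, ang): v for ang, v in p2.items()}

    a = {
        "RF": spread(quad_p1, rf_p2),
        "VL": spread(quad_p1, quad_p2),
        "VM": spread(quad_p1, quad_p2),
        "ST": spread(st_p1, st_p2),
        "BF": spread(bf, bf),
    }
    # Hamstring baseline tone sits much closer to their (weak) contraction
    # level than in the quadriceps, which is what loads the second synergy
    # onto the antagonists at low angles.
    quad_base = {(p, ang): 0.08 for p in POSITIONS for ang in ANGLES}
    flex_base = {(p, ang): 0.30 for p in POSITIONS for ang in ANGLES}
    st_base = dict(flex_base)
    for ang in (20, 60, 90):
        st_base[(1, ang)] = 0.36  # raised ST baseline in position 1 away from 0 deg
    b = {m: dict(quad_base) for m in ("RF", "VL", "VM")}
    b["BF"] = dict(flex_base)
    b["ST"] = st_base
    return TrendModel(a=a, b=b)


def _trapezoid(n: int, fs: float, ramp_ms: float, plateau_ms: float) -> np.ndarray:
    """Unit-height burst envelope over ``n`` samples (ramp up, hold, ramp down,
    zero through the trailing gap)."""
    t = np.arange(n) / fs * 1000.0
    up_end = ramp_ms
    hold_end = ramp_ms + plateau_ms
    down_end = 2 * ramp_ms + plateau_ms
    env = np.zeros(n)
    env = np.where(t < up_end, t / ramp_ms, env)
    env = np.where((t >= up_end) & (t < hold_end), 1.0, env)
    env = np.where(
        (t >= hold_end) & (t < down_end), (down_end - t) / ramp_ms, env
    )
    return np.clip(env, 0.0, 1.0)


_CARRIER_NORM: dict[tuple[float, float], tuple[np.ndarray, np.ndarray, float]] = {}


def _carrier(n: int, fs: float, cutoff: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian carrier band-limited to ``cutoff`` Hz
    (second-order Butterworth); white noise when ``cutoff`` is falsy."""
    w = rng.standard_normal(n)
    if not cutoff or cutoff >= fs / 2:
        return w
    key = (fs, cutoff)
    if key not in _CARRIER_NORM:
        b, a = _signal.butter(2, cutoff, btype="low", fs=fs)
        imp = np.zeros(4096)
        imp[0] = 1.0
        h = _signal.lfilter(b, a, imp)
        _CARRIER_NORM[key] = (b, a, float(np.sqrt(np.sum(h**2))))
    b, a, norm = _CARRIER_NORM[key]
    return _signal.lfilter(b, a, w) / norm


def _slow_drift(n: int, fs: float, cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Mean-one lognormal amplitude drift: unit-variance knots at
    ``drift_rate_hz`` linearly interpolated to the sample rate."""
    if cfg.drift_sd <= 0:
        return np.ones(n)
    n_knots = max(int(np.ceil(n / fs * cfg.drift_rate_hz)) + 2, 2)
    knots = rng.standard_normal(n_knots)
    t = np.arange(n) / fs * cfg.drift_rate_hz
    g = np.interp(t, np.arange(n_knots), knots)
    return np.exp(cfg.drift_sd * g - cfg.drift_sd**2 / 2.0)


def generate_burst(
    trend: TrendModel,
    muscle: str,
    angle: int,
    position: int,
    cfg: CohortConfig,
    rng: np.random.Generator,
    gain: float = 1.0,
) -> tuple[np.ndarray, dict]:
    """One burst period (ramp-hold-ramp plus trailing gap) for one muscle.

    Returns the raw (signed, unrectified) series and its ground-truth record:
    onset within the series (0 ms), effective plateau amplitude ``a`` and
    baseline ``b`` after the subject gain.
    """
    a = trend.amplitude(muscle, position, angle) * gain
    b = trend.baseline(muscle, position, angle) * gain
    n = int(round(cfg.burst_period_ms / 1000.0 * cfg.sample_rate))
    env = b + a * _trapezoid(n, cfg.sample_rate, cfg.ramp_ms, cfg.plateau_ms)
    env = env * _slow_drift(n, cfg.sample_rate, cfg, rng)
    x = cfg.noise_sd * env * _carrier(n, cfg.sample_rate, cfg.carrier_cutoff_hz, rng)
    truth = {"muscle": muscle, "position": position, "angle": angle,
             "onset_ms": 0.0, "a": a, "b": b}
    return x, truth


class Cohort:
    """Lazily generated synthetic cohort.

    Recordings are produced on demand from seeds derived deterministically
    from the master seed, so any condition can be regenerated in isolation
    and the cohort never needs to be held in memory at once.
    """

    def __init__(self, cfg: CohortConfig, trend: TrendModel | None = None):
        self.cfg = cfg
        self.trend = trend or default_trend()
        gain_rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed), 10_007])
        )
        muscles = list(MUSCLES)
        self.gains = np.exp(
            cfg.subject_sd * gain_rng.standard_normal((cfg.n_subjects, len(muscles)))
        )
        self._muscles = muscles

    @property
    def channels(self) -> list[str]:
        chans = list(MUSCLES)
        if self.cfg.include_noise_channels:
            chans += list(NOISE_CHANNELS)
        return chans

    def conditions(self) -> Iterator[tuple[int, int, int]]:
        for s in range(self.cfg.n_subjects):
            for p in self.cfg.positions:
                for ang in self.cfg.angles:
                    yield s, p, ang

    def recording(self, subject: int, position: int, angle: int) -> Recording:
        cfg = self.cfg
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed), subject, position, angle])
        )
        n_lead = int(round(cfg.lead_ms / 1000.0 * cfg.sample_rate))
        cols = []
        for mi, muscle in enumerate(self._muscles):
            gain = float(self.gains[subject, mi])
            b = self.trend.baseline(muscle, position, angle) * gain
            lead_env = b * _slow_drift(n_lead, cfg.sample_rate, cfg, rng)
            pieces = [cfg.noise_sd * lead_env
                      * _carrier(n_lead, cfg.sample_rate, cfg.carrier_cutoff_hz, rng)]
            for _ in range(cfg.bursts_per_condition):
                x, _truth = generate_burst(
                    self.trend, muscle, angle, position, cfg, rng, gain
                )
                pieces.append(x)
            cols.append(np.concatenate(pieces))
        if cfg.include_noise_channels:
            n_total = len(cols[0])
            for _ in NOISE_CHANNELS:
                cols.append(cfg.noise_sd * 0.05
                            * _carrier(n_total, cfg.sample_rate, cfg.carrier_cutoff_hz, rng))
        data = np.column_stack(cols)
        return Recording(
            self.channels, cfg.sample_rate, data,
            {"subject": subject, "position": position, "angle": angle},
        )

    def latent_templates(self, n_samples: int, sample_rate: float,
                         lead_fraction: float = 0.1) -> dict[str, np.ndarray]:
        """Ground-truth activation templates aligned to a segmented burst
        window whose onset sits ``lead_fraction`` into the window: the burst
        trapezoid and the constant baseline. (Note ``b + a*trap`` equals
        ``(a+b)*trap + b*(1-trap)``, so the baseline template is recoverable
        from a factorization only up to this reparameterization — compare in
        the span sense.)"""
        cfg = self.cfg
        shift = int(lead_fraction * n_samples)
        trap = _trapezoid(n_samples, sample_rate, cfg.ramp_ms, cfg.plateau_ms)
        trap = np.concatenate([np.zeros(shift), trap[: n_samples - shift]])
        return {"burst": trap, "baseline": np.ones(n_samples)}

    def ground_truth(self, subject: int, position: int, angle: int) -> dict:
        out = {"onsets_ms": self.cfg.onsets_ms(), "muscles": {}}
        for mi, muscle in enumerate(self._muscles):
            gain = float(self.gains[subject, mi])
            out["muscles"][muscle] = {
                "a": self.trend.amplitude(muscle, position, angle) * gain,
                "b": self.trend.baseline(muscle, position, angle) * gain,
                "gain": gain,
            }
        return out

    def manifest(self) -> dict:
        cfg = asdict(self.cfg)
        return {
            "config": cfg,
            "channels": self.channels,
            "onsets_ms": self.cfg.onsets_ms(),
            "gains": {str(s): dict(zip(self._muscles, map(float, self.gains[s])))
                      for s in range(self.cfg.n_subjects)},
            "trend": {
                "a": {m: {f"{p}:{ang}": v for (p, ang), v in vals.items()}
                      for m, vals in self.trend.a.items()},
                "b": {m: {f"{p}:{ang}": v for (p, ang), v in vals.items()}
                      for m, vals in self.trend.b.items()},
            },
        }

    def write(self, out_dir: str | Path) -> Path:
        """One CSV per (subject, position, angle) plus a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s, p, ang in self.conditions():
            rec = self.recording(s, p, ang)
            rec.to_frame().to_csv(
                out / f"subject{s:02d}_pos{p}_angle{ang:02d}.csv", index=False
            )
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=1)
        return out


def generate_cohort(cfg: CohortConfig | None = None, trend: TrendModel | None = None) -> Cohort:
    """Construct the (lazy) synthetic cohort for the given configuration."""
    return Cohort(cfg or CohortConfig(), trend)
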