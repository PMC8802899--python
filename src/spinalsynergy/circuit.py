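"""Spinal circuit model: EIF populations coupled by Poisson firing rates.

The network is the eight-population spinal circuit for an isometric knee
extension: five motor-neuron pools (MN-RF, MN-VL, MN-VM for the knee
extensors; MN-ST, MN-BF for the flexors), reciprocally inhibiting Extensor
and Flexor interneuron pools, and an InhibRF pool that selectively inhibits
MN-RF. All neurons are exponential integrate-and-fire (EIF):

    tau dv/dt = -(v - v_rest) + delta_T * exp((v - v_thres) / delta_T)

with instantaneous synaptic jumps. Populations interact through their average
firing rates: each neuron of a target population receives an independent
Poisson event stream at rate ``n_connections x (delayed source rate)``, every
event stepping the membrane by ``efficacy`` (mV). External inputs (background,
cortical drive, three afferent channels) enter through the same contract with
piecewise-linear rate schedules.

The original study solved the population dynamics with a density method; here
a seeded Monte-Carlo ensemble honours the same rate-coupling contract. The
ensemble also carries an explicit membrane-noise term (see
``NeuronParameters.sigma_noise``) standing in for diffusion sources the
rate-coupling contract alone does not supply; without it the published
operating point has no baseline activity at all (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MN_POOLS",
    "EXTENSOR_POOLS",
    "FLEXOR_POOLS",
    "INTERNEURON_POOLS",
    "POSITIONS",
    "ANGLES",
    "NeuronParameters",
    "PopulationSpec",
    "ConnectionSpec",
    "InputSchedule",
    "NetworkSpec",
    "RateSeries",
    "DensityHistogram",
    "SimulationResult",
    "eif_drift",
    "make_cortical_drive",
    "make_afferent_condition",
    "build_default_network",
    "apply_condition",
    "simulate",
    "density_snapshot",
    "SENFLINT_PLATEAUS",
    "SENINHRF_PLATEAUS",
]

MN_POOLS = ("MN-RF", "MN-VL", "MN-VM", "MN-ST", "MN-BF")
EXTENSOR_POOLS = ("MN-RF", "MN-VL", "MN-VM")
FLEXOR_POOLS = ("MN-ST", "MN-BF")
INTERNEURON_POOLS = ("ExtensorInterneurons", "FlexorInterneurons", "InhibRF")
ALL_POOLS = MN_POOLS + INTERNEURON_POOLS

POSITIONS = (1, 2)
ANGLES = (0, 20, 60, 90)

#: Afferent plateau rates (Hz) per (position, angle). The position-1 ladder is
#: the published nonlinear reduction 150/75/38/0; position 2 drops immediately
#: to 38 Hz at 20 deg and continues halving (60 deg value is a modelling
#: choice, configurable).
SENFLINT_PLATEAUS: dict[tuple[int, int], float] = {
    (1, 0): 150.0, (1, 20): 75.0, (1, 60): 38.0, (1, 90): 0.0,
    (2, 0): 150.0, (2, 20): 38.0, (2, 60): 19.0, (2, 90): 0.0,
}

#: senInhRF plateau rates (Hz): off in position 1, 50 Hz in position 2 except
#: at full extension where the two positions are identical.
SENINHRF_PLATEAUS: dict[tuple[int, int], float] = {
    (1, 0): 0.0, (1, 20): 0.0, (1, 60): 0.0, (1, 90): 0.0,
    (2, 0): 0.0, (2, 20): 50.0, (2, 60): 50.0, (2, 90): 50.0,
}

#: Membrane-noise amplitude (mV/sqrt(ms)) calibrated once so that the
#: background input produces a low nonzero baseline rate and all condition
#: presets stay within 0-200 Hz. See docs/methods.md.
DEFAULT_SIGMA_NOISE = 1.25

_EXP_CLAMP = 20.0  # exponent cap; anything above it spikes within the step


@dataclass(frozen=True)
class NeuronParameters:
    """EIF constants plus the spike/reset conventions of the ensemble.

    ``v_rest``, ``delta_T``, ``v_thres`` and ``tau`` are the published
    constants; ``v_spike`` is the spike-detection cutoff (the -51 mV
    "threshold" visible in the published density plots), while ``v_reset``,
    ``t_refractory`` and ``sigma_noise`` are simulation conventions exposed in
    configuration.
    """

    v_rest: float = -70.0        # mV
    delta_T: float = 1.48        # mV
    v_thres: float = -56.0       # mV, soft exponential threshold
    tau: float = 3.3             # ms
    v_spike: float = -51.0       # mV, spike-detection cutoff
    v_reset: float = -70.0       # mV
    t_refractory: float = 0.0    # ms
    sigma_noise: float = DEFAULT_SIGMA_NOISE  # mV / sqrt(ms)

    def __post_init__(self) -> None:
        if not (self.v_rest < self.v_thres < self.v_spike):
            raise ValueError(
                f"require v_rest < v_thres < v_spike, got "
                f"{self.v_rest}, {self.v_thres}, {self.v_spike}"
            )
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.delta_T <= 0:
            raise ValueError("delta_T must be positive")
        if self.t_refractory < 0:
            raise ValueError("t_refractory must be >= 0")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")


def eif_drift(v, p: NeuronParameters):
    """Deterministic EIF membrane drift dv/dt in mV/ms.

    ``-(v - v_rest)/tau`` leak plus the exponential spike-initiation term.
    Total function of finite ``v``; accepts scalars or arrays. The exponent is
    clamped well above the spike cutoff so the drift stays finite for
    super-threshold excursions (those reset within the same step anyway).
    """
    v = np.asarray(v, dtype=float)
    expo = np.minimum((v - p.v_thres) / p.delta_T, _EXP_CLAMP)
    out = (-(v - p.v_rest) + p.delta_T * np.exp(expo)) / p.tau
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    neuron_params: NeuronParameters = field(default_factory=NeuronParameters)
    ensemble_size: int = 500

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")


@dataclass(frozen=True)
class ConnectionSpec:
    """One row of the connection table.

    ``source`` is either a population name or an external-input name. For
    constant-rate external sources (the background input) ``rate_hz`` holds
    the source rate; scheduled sources take their rate from the matching
    :class:`InputSchedule` instead.
    """

    target: str
    source: str
    efficacy: float        # mV per incoming event, signed
    n_connections: float   # average incoming connections per target neuron
    delay: float = 0.0     # ms
    rate_hz: float | None = None  # constant source rate for external inputs

    def __post_init__(self) -> None:
        if self.efficacy == 0:
            raise ValueError(f"{self.target} <- {self.source}: efficacy must be nonzero")
        if self.n_connections <= 0:
            raise ValueError(f"{self.target} <- {self.source}: n_connections must be > 0")
        if self.delay < 0:
            raise ValueError(f"{self.target} <- {self.source}: delay must be >= 0")
        if self.rate_hz is not None and self.rate_hz < 0:
            raise ValueError(f"{self.target} <- {self.source}: rate_hz must be >= 0")


@dataclass(frozen=True)
class InputSchedule:
    """Piecewise-linear external rate profile.

    ``breakpoints`` is an ordered sequence of (time ms, rate Hz) pairs; the
    rate is linearly interpolated between breakpoints and held constant
    outside them.
    """

    name: str
    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        bp = tuple((float(t), float(r)) for t, r in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        times = np.array([t for t, _ in bp])
        rates = np.array([r for _, r in bp])
        if len(bp) == 0:
            raise ValueError(f"{self.name}: empty schedule")
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{self.name}: breakpoint times must be strictly increasing")
        if np.any(rates < 0):
            raise ValueError(f"{self.name}: rates must be >= 0")

    def rate(self, t):
        """Rate (Hz) at time(s) ``t`` in ms."""
        times = np.array([p[0] for p in self.breakpoints])
        rates = np.array([p[1] for p in self.breakpoints])
        out = np.asarray(np.interp(np.asarray(t, dtype=float), times, rates))
        return out.item() if out.ndim == 0 else out

    @property
    def end_time(self) -> float:
        return self.breakpoints[-1][0]


def make_cortical_drive(
    t_start: float = 500.0,
    peak: float = 20.0,
    ramp: float = 1000.0,
    hold: float = 5000.0,
    name: str = "CorticalDrive",
) -> InputSchedule:
    """Trapezoidal cortical command: 0 -> ``peak`` Hz over ``ramp`` ms, held
    for ``hold`` ms, back to 0 over ``ramp`` ms, starting at ``t_start``."""
    if peak < 0:
        raise ValueError("peak must be >= 0")
    if ramp <= 0:
        raise ValueError("ramp must be > 0")
    if hold < 0:
        raise ValueError("hold must be >= 0")
    if t_start < 0:
        raise ValueError("t_start must be >= 0")
    pts = [(t_start, 0.0), (t_start + ramp, peak),
           (t_start + ramp + hold, peak), (t_start + 2 * ramp + hold, 0.0)]
    if t_start > 0:
        pts.insert(0, (0.0, 0.0))
    return InputSchedule(name, tuple(pts))


def make_afferent_condition(
    position: int,
    angle: int,
    t_start: float = 500.0,
    ramp: float = 1000.0,
    hold: float = 5000.0,
    senflint_plateaus: Mapping[tuple[int, int], float] | None = None,
    seninhrf_plateaus: Mapping[tuple[int, int], float] | None = None,
) -> dict[str, InputSchedule]:
    """Afferent schedules for one experimental condition.

    Afferent rates follow the cortical-drive trapezoid envelope scaled to the
    condition's plateau value. senExtInt is held at 0 Hz in every preset (it
    is only needed to flip the synergy bias, not to reproduce the task
    conditions).
    """
    if position not in POSITIONS:
        raise ValueError(f"unknown position {position!r}; expected one of {POSITIONS}")
    if angle not in ANGLES:
        raise ValueError(f"unknown angle {angle!r}; expected one of {ANGLES}")
    fl = dict(SENFLINT_PLATEAUS if senflint_plateaus is None else senflint_plateaus)
    inh = dict(SENINHRF_PLATEAUS if seninhrf_plateaus is None else seninhrf_plateaus)

    def trap(name: str, plateau: float) -> InputSchedule:
        return make_cortical_drive(t_start=t_start, peak=plateau, ramp=ramp, hold=hold, name=name)

    return {
        "senFlInt": trap("senFlInt", fl[(position, angle)]),
        "senExtInt": trap("senExtInt", 0.0),
        "senInhRF": trap("senInhRF", inh[(position, angle)]),
    }


@dataclass
class NetworkSpec:
    populations: list[PopulationSpec]
    connections: list[ConnectionSpec]
    inputs: list[InputSchedule]
    dt: float = 0.1                   # ms
    rate_sample_interval: float = 2.0  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.rate_sample_interval < self.dt:
            raise ValueError("rate_sample_interval must be >= dt")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        self._validate_endpoints()

    def _validate_endpoints(self) -> None:
        pop_names = {p.name for p in self.populations}
        input_names = {s.name for s in self.inputs}
        for c in self.connections:
            if c.target not in pop_names:
                raise ValueError(f"connection target {c.target!r} is not a declared population")
            if c.source in pop_names:
                continue
            if c.source in input_names or c.rate_hz is not None:
                continue
            raise ValueError(
                f"connection source {c.source!r} resolves to neither a population, "
                f"an input schedule, nor a constant rate"
            )

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def input(self, name: str) -> InputSchedule:
        for s in self.inputs:
            if s.name == name:
                return s
        raise KeyError(name)

    def with_inputs(self, schedules: Mapping[str, InputSchedule] | Iterable[InputSchedule]) -> "NetworkSpec":
        """Copy of the network with the named schedules replaced."""
        if isinstance(schedules, Mapping):
            schedules = list(schedules.values())
        new = {s.name: s for s in schedules}
        merged = [new.pop(s.name, s) for s in self.inputs] + list(new.values())
        return NetworkSpec(
            populations=list(self.populations),
            connections=list(self.connections),
            inputs=merged,
            dt=self.dt,
            rate_sample_interval=self.rate_sample_interval,
            seed=self.seed,
        )


@dataclass(frozen=True)
class RateSeries:
    name: str
    times: np.ndarray  # ms
    rates: np.ndarray  # Hz

    def __post_init__(self) -> None:
        if len(self.times) != len(self.rates):
            raise ValueError("times and rates must have equal length")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")

    def window_mean(self, t0: float, t1: float) -> float:
        """Mean rate over ``[t0, t1)`` ms."""
        m = (self.times >= t0) & (self.times < t1)
        if not np.any(m):
            raise ValueError(f"window [{t0}, {t1}) contains no samples")
        return float(self.rates[m].mean())


@dataclass(frozen=True)
class DensityHistogram:
    name: str
    time: float
    bin_edges: np.ndarray  # mV
    mass: np.ndarray       # probability per bin

    def __post_init__(self) -> None:
        if len(self.mass) != len(self.bin_edges) - 1:
            raise ValueError("mass must have one entry per bin")
        if np.any(self.mass < 0):
            raise ValueError("mass must be >= 0")


@dataclass
class SimulationResult:
    rates: dict[str, RateSeries]
    membrane_snapshots: dict[str, dict[float, np.ndarray]]
    spec: NetworkSpec

    def __getitem__(self, name: str) -> RateSeries:
        return self.rates[name]

    def mn_rates(self) -> dict[str, RateSeries]:
        return {k: v for k, v in self.rates.items() if k in MN_POOLS}

    def to_frame(self, populations: Sequence[str] | None = None) -> pd.DataFrame:
        names = list(populations) if populations is not None else list(self.rates)
        t = self.rates[names[0]].times
        data = {"time_ms": t}
        for n in names:
            data[n] = self.rates[n].rates
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Default network (published connection table)
# ---------------------------------------------------------------------------

def _table_connections() -> list[ConnectionSpec]:
    rows: list[ConnectionSpec] = []
    # Interneuron -> motor neuron pools: each interneuron pool inhibits its
    # own muscle group (20 connections) and excites the opposing group (70).
    for mn in EXTENSOR_POOLS:
        rows.append(ConnectionSpec(mn, "ExtensorInterneurons", -0.052, 20, 2.0))
    for mn in FLEXOR_POOLS:
        rows.append(ConnectionSpec(mn, "ExtensorInterneurons", +0.052, 70, 2.0))
    for mn in EXTENSOR_POOLS:
        rows.append(ConnectionSpec(mn, "FlexorInterneurons", +0.052, 70, 2.0))
    for mn in FLEXOR_POOLS:
        rows.append(ConnectionSpec(mn, "FlexorInterneurons", -0.052, 20, 2.0))
    # Dedicated RF inhibition.
    rows.append(ConnectionSpec("MN-RF", "InhibRF", -0.052, 70, 2.0))
    # Mutual inhibition between the interneuron pools.
    rows.append(ConnectionSpec("ExtensorInterneurons", "FlexorInterneurons", -0.052, 70, 2.0))
    rows.append(ConnectionSpec("FlexorInterneurons", "ExtensorInterneurons", -0.052, 70, 2.0))
    # Background: 300 Hz to interneuron pools, 320 Hz to motor-neuron pools.
    for pool in INTERNEURON_POOLS:
        rows.append(ConnectionSpec(pool, "Background", 0.1, 100, 0.0, rate_hz=300.0))
    for mn in MN_POOLS:
        rows.append(ConnectionSpec(mn, "Background", 0.1, 100, 0.0, rate_hz=320.0))
    # Cortical drive: all MN pools and both reciprocal interneuron pools.
    for pool in MN_POOLS + ("ExtensorInterneurons", "FlexorInterneurons"):
        rows.append(ConnectionSpec(pool, "CorticalDrive", 0.1, 100, 0.0))
    # Afferent channels.
    rows.append(ConnectionSpec("ExtensorInterneurons", "senExtInt", 0.1, 100, 0.0))
    rows.append(ConnectionSpec("FlexorInterneurons", "senFlInt", 0.1, 100, 0.0))
    rows.append(ConnectionSpec("InhibRF", "senInhRF", 0.1, 100, 0.0))
    return rows


def build_default_network(
    ensemble_size: int = 500,
    dt: float = 0.1,
    rate_sample_interval: float = 2.0,
    seed: int = 0,
    neuron_params: NeuronParameters | None = None,
    cortical_drive: InputSchedule | None = None,
) -> NetworkSpec:
    """The eight-population network with the full published connection table.

    Afferent schedules default to zero; use :func:`apply_condition` or
    :meth:`NetworkSpec.with_inputs` to set an experimental condition.
    """
    p = neuron_params or NeuronParameters()
    pops = [PopulationSpec(name, p, ensemble_size) for name in ALL_POOLS]
    drive = cortical_drive or make_cortical_drive()
    end = max(drive.end_time, 7500.0)
    zero = tuple([(0.0, 0.0), (end, 0.0)])
    inputs = [
        drive,
        InputSchedule("senFlInt", zero),
        InputSchedule("senExtInt", zero),
        InputSchedule("senInhRF", zero),
    ]
    return NetworkSpec(
        populations=pops,
        connections=_table_connections(),
        inputs=inputs,
        dt=dt,
        rate_sample_interval=rate_sample_interval,
        seed=seed,
    )


def apply_condition(
    net: NetworkSpec,
    position: int,
    angle: int,
    **schedule_kwargs,
) -> NetworkSpec:
    """Network configured for one (position, angle) experimental condition."""
    return net.with_inputs(make_afferent_condition(position, angle, **schedule_kwargs))


# ---------------------------------------------------------------------------
# Monte-Carlo ensemble engine
# ---------------------------------------------------------------------------

#: Time constant (ms) of the exponential smoothing applied to each
#: population's instantaneous rate before it is delivered to its targets.
#: Undamped per-step estimates would inject artificial feedback noise at
#: small ensemble sizes.
RATE_SMOOTHING_TAU = 1.0


def simulate(
    net: NetworkSpec,
    duration: float,
    membrane_times: Sequence[float] = (),
    membrane_populations: Sequence[str] | None = None,
) -> SimulationResult:
    """Run the Monte-Carlo ensemble for ``duration`` ms.

    Every neuron of a target population receives an independent Poisson event
    stream at rate ``n_connections x (delayed source rate)``; each event jumps
    the membrane by the connection efficacy. Between events the membrane
    follows :func:`eif_drift` (Euler steps of ``net.dt``) plus the membrane
    noise term. Crossing ``v_spike`` emits a spike and resets to ``v_reset``
    for ``t_refractory`` ms. Population rates are spike counts per
    ``rate_sample_interval`` bin divided by ensemble size and bin width.
    Identical ``NetworkSpec`` (including seed) gives bit-identical output.

    ``membrane_times`` requests membrane-potential snapshots (for
    :func:`density_snapshot`) at the nearest integration step, for
    ``membrane_populations`` (default: all).
    """
    dt = net.dt
    n_steps = int(round(duration / dt))
    if n_steps <= 0:
        raise ValueError("duration must cover at least one step")
    # Schedules shorter than the run are held at their final rate (interp
    # semantics), so the full window is always defined.

    names = [p.name for p in net.populations]
    index = {n: i for i, n in enumerate(names)}
    n_pops = len(names)
    pops = net.populations
    rng = np.random.default_rng(net.seed)

    # External source rates per step, precomputed.
    input_names = {s.name for s in net.inputs}
    step_times = np.arange(n_steps) * dt
    ext_rates: dict[str, np.ndarray] = {
        s.name: np.asarray(s.rate(step_times), dtype=float) for s in net.inputs
    }

    # Connection plumbing: (target_idx, efficacy, n_conn, kind, payload)
    # kind "ext": payload = per-step rate array (Hz)
    # kind "pop": payload = (source_idx, delay_steps)
    plumbing = []
    max_delay = 0
    for c in net.connections:
        ti = index[c.target]
        if c.source in index and c.rate_hz is None:
            dsteps = int(round(c.delay / dt))
            max_delay = max(max_delay, dsteps)
            plumbing.append((ti, c.efficacy, c.n_connections, "pop", (index[c.source], dsteps)))
        elif c.rate_hz is not None:
            plumbing.append((ti, c.efficacy, c.n_connections,
                             "ext", np.full(n_steps, float(c.rate_hz))))
        else:
            plumbing.append((ti, c.efficacy, c.n_connections, "ext", ext_rates[c.source]))

    # State.
    v = [np.full(p.ensemble_size, p.neuron_params.v_rest) for p in pops]
    ref_left = [np.zeros(p.ensemble_size) for p in pops]  # ms of refractory left
    smoothed = np.zeros(n_pops)
    ring = np.zeros((max_delay + 1, n_pops))  # ring[i % (max_delay+1)] = smoothed rates
    alpha = dt / RATE_SMOOTHING_TAU

    # Output sampling.
    stride = int(round(net.rate_sample_interval / dt))
    n_bins = n_steps // stride
    spike_bins = np.zeros((n_pops, n_bins))
    bin_width_s = stride * dt / 1000.0

    # Membrane snapshots.
    snap_pops = list(membrane_populations) if membrane_populations is not None else names
    for sp in snap_pops:
        if sp not in index:
            raise KeyError(f"unknown population {sp!r}")
    snap_steps: dict[int, float] = {}
    for t_req in membrane_times:
        k = int(round(t_req / dt))
        if not (0 <= k < n_steps):
            raise ValueError(f"membrane snapshot time {t_req} outside simulated window")
        snap_steps[k] = float(t_req)
    snapshots: dict[str, dict[float, np.ndarray]] = {sp: {} for sp in snap_pops}

    sq_noise = [p.neuron_params.sigma_noise * np.sqrt(dt) for p in pops]
    params = [p.neuron_params for p in pops]
    sizes = [p.ensemble_size for p in pops]
    ring_len = max_delay + 1

    for step in range(n_steps):
        # Deliver events. Fixed iteration order keeps runs reproducible.
        for ti, eff, n_conn, kind, payload in plumbing:
            if kind == "pop":
                si, dsteps = payload
                src_rate = ring[(step - dsteps) % ring_len, si] if step >= dsteps else 0.0
            else:
                src_rate = payload[step]
            lam = n_conn * src_rate * dt * 1e-3
            if lam > 0.0:
                counts = rng.poisson(lam, sizes[ti])
                if params[ti].t_refractory > 0:
                    np.add(v[ti], eff * counts, out=v[ti], where=ref_left[ti] <= 0.0)
                else:
                    v[ti] += eff * counts

        new_rates = np.empty(n_pops)
        for i in range(n_pops):
            p = params[i]
            vi = v[i]
            if sq_noise[i] > 0:
                noise = sq_noise[i] * rng.standard_normal(sizes[i])
            else:
                noise = 0.0
            if p.t_refractory > 0:
                active = ref_left[i] <= 0.0
                expo = np.minimum((vi - p.v_thres) / p.delta_T, _EXP_CLAMP)
                dv = dt * (-(vi - p.v_rest) + p.delta_T * np.exp(expo)) / p.tau
                vi += np.where(active, dv + noise, 0.0)
                ref_left[i] -= dt
            else:
                expo = np.minimum((vi - p.v_thres) / p.delta_T, _EXP_CLAMP)
                vi += dt * (-(vi - p.v_rest) + p.delta_T * np.exp(expo)) / p.tau
                vi += noise
            sp_mask = vi >= p.v_spike
            k = int(np.count_nonzero(sp_mask))
            if k:
                vi[sp_mask] = p.v_reset
                if p.t_refractory > 0:
                    ref_left[i][sp_mask] = p.t_refractory
                b = step // stride
                if b < n_bins:
                    spike_bins[i, b] += k
            inst = k / (sizes[i] * dt * 1e-3)  # Hz
            smoothed[i] += alpha * (inst - smoothed[i])
            new_rates[i] = smoothed[i]
        ring[step % ring_len] = new_rates

        if step in snap_steps:
            t_req = snap_steps[step]
            for sp in snap_pops:
                snapshots[sp][t_req] = v[index[sp]].copy()

    sample_times = (np.arange(n_bins) + 1) * stride * dt
    rates = {
        names[i]: RateSeries(names[i], sample_times, spike_bins[i] / (sizes[i] * bin_width_s))
        for i in range(n_pops)
    }
    return SimulationResult(rates=rates, membrane_snapshots=snapshots, spec=net)


def density_snapshot(
    result: SimulationResult,
    population: str,
    time: float,
    n_bins: int = 60,
    v_range: tuple[float, float] | None = None,
) -> DensityHistogram:
    """Normalized membrane-potential histogram at the snapshot nearest ``time``.

    The simulation must have been run with ``membrane_times`` covering the
    requested time.
    """
    if population not in result.membrane_snapshots:
        raise KeyError(f"unknown population {population!r}")
    snaps = result.membrane_snapshots[population]
    if not snaps:
        raise ValueError(
            f"no membrane snapshots recorded for {population!r}; "
            f"pass membrane_times to simulate()"
        )
    t_near = min(snaps, key=lambda t: abs(t - time))
    vv = snaps[t_near]
    p = result.spec.population(population).neuron_params
    if v_range is None:
        lo = min(p.v_reset, p.v_rest) - 5.0
        v_range = (lo, p.v_spike)
    counts, edges = np.histogram(vv, bins=n_bins, range=v_range)
    mass = counts / counts.sum() if counts.sum() else counts.astype(float)
    return DensityHistogram(population, t_near, edges, mass)


def plateau_rate(
    series: RateSeries,
    t_start: float = 500.0,
    ramp: float = 1000.0,
    hold: float = 5000.0,
) -> float:
    """Mean firing rate over the drive's hold window."""
    return series.window_mean(t_start + ramp, t_start + ramp + hold)
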