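"""End-to-end experiment orchestration.

Runs the whole computational argument under one master seed: generate the
synthetic cohort, compute its condition statistics, simulate the spinal
circuit under all eight (position, angle) afferent presets plus the two
diagnostic runs (senExtInt raised above senFlInt; equal inputs), extract
synergies from both sides, and evaluate the model-versus-data trend
checklist. Every stage draws its seed deterministically from the master seed
so stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .circuit import (
    ANGLES,
    POSITIONS,
    NetworkSpec,
    SimulationResult,
    apply_condition,
    build_default_network,
    make_cortical_drive,
    make_afferent_condition,
    simulate,
)
from .cohort import Cohort, CohortConfig, default_trend
from .decomposition import SynergyDecomposition, normalize_synergies, synergies_from_rates
from . import io as sio
from .stats import TrendChecklist, cohort_condition_means, compare_conditions, trend_checklist

__all__ = [
    "ExperimentConfig",
    "stage_seed",
    "run_condition",
    "run_custom_afferents",
    "model_condition_synergies",
    "run_experiment",
    "validate_config",
]

log = logging.getLogger("spinalsynergy")


def stage_seed(master: int, stage: str, *keys) -> int:
    """Stable sub-seed below 2**31 derived from the master seed and a stage
    label, so any stage can be re-run in isolation."""
    payload = f"{master}|{stage}|" + "|".join(map(str, keys))
    digest = hashlib.sha256(payload.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one full experiment run."""

    out_dir: str = "results/experiment"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    ensemble_size: int = 500
    dt: float = 0.1                  # ms
    rate_sample_interval: float = 2.0  # ms
    t_start: float = 500.0           # settling period before the drive (ms)
    ramp: float = 1000.0             # drive ramp (ms)
    hold: float = 5000.0             # drive hold (ms)
    vaf_threshold: float = 0.90
    alpha: float = 0.05
    flip_senextint: float = 15.0     # Hz, for the bias-flip diagnostic run
    equal_input_rate: float = 75.0   # Hz, for the cancellation diagnostic run
    network_file: str | None = None
    write_cohort: bool = True

    @property
    def duration(self) -> float:
        return self.t_start + 2 * self.ramp + self.hold

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**doc.pop("cohort", {}))
        return cls(cohort=cohort, **doc)

    def to_dict(self) -> dict:
        return asdict(self)


def _base_network(cfg: ExperimentConfig, seed: int) -> NetworkSpec:
    drive = make_cortical_drive(t_start=cfg.t_start, ramp=cfg.ramp, hold=cfg.hold)
    if cfg.network_file:
        net = sio.load_network(cfg.network_file)
        net = net.with_inputs([drive])
        net.seed = seed
        return net
    return build_default_network(
        ensemble_size=cfg.ensemble_size,
        dt=cfg.dt,
        rate_sample_interval=cfg.rate_sample_interval,
        seed=seed,
        cortical_drive=drive,
    )


def run_condition(
    cfg: ExperimentConfig,
    position: int,
    angle: int,
    seed: int | None = None,
    seninhrf_override: float | None = None,
) -> SimulationResult:
    """Simulate one (position, angle) preset.

    ``seninhrf_override`` forces the senInhRF plateau (e.g. 0 for the
    ablation that removes the position-specific RF inhibition).
    """
    seed = stage_seed(cfg.seed, "simulate", position, angle) if seed is None else seed
    net = _base_network(cfg, seed)
    kwargs = dict(t_start=cfg.t_start, ramp=cfg.ramp, hold=cfg.hold)
    if seninhrf_override is not None:
        from .circuit import SENINHRF_PLATEAUS
        override = {k: seninhrf_override for k in SENINHRF_PLATEAUS}
        kwargs["seninhrf_plateaus"] = override
    net = apply_condition(net, position, angle, **kwargs)
    return simulate(net, cfg.duration)


def run_custom_afferents(
    cfg: ExperimentConfig,
    senflint: float,
    senextint: float,
    seninhrf: float = 0.0,
    seed: int | None = None,
) -> SimulationResult:
    """Simulate with explicit afferent plateau rates (diagnostic runs)."""
    seed = stage_seed(cfg.seed, "simulate-custom", senflint, senextint, seninhrf) \
        if seed is None else seed
    net = _base_network(cfg, seed)
    sched = make_afferent_condition(
        1, 0, t_start=cfg.t_start, ramp=cfg.ramp, hold=cfg.hold,
        senflint_plateaus={(1, 0): senflint},
        seninhrf_plateaus={(1, 0): seninhrf},
    )
    sched["senExtInt"] = make_cortical_drive(
        t_start=cfg.t_start, peak=senextint, ramp=cfg.ramp, hold=cfg.hold,
        name="senExtInt",
    )
    net = net.with_inputs(sched)
    return simulate(net, cfg.duration)


def model_condition_synergies(
    cfg: ExperimentConfig,
    results: dict[tuple[int, int], SimulationResult],
    normalize: bool = True,
) -> dict[tuple[int, int], SynergyDecomposition]:
    """Rank-2 synergies of the motor-neuron rates per condition.

    ``normalize`` controls whether each rate series is scaled to its maximum
    before factorization (the variant used for model-data comparison); the
    returned W and C are left unnormalized so energy ratios stay meaningful.
    """
    return {
        key: synergies_from_rates(
            res, rank=2, window=(cfg.t_start, cfg.duration), normalize=normalize
        )
        for key, res in results.items()
    }


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    data_means: pd.DataFrame
    contrasts: list
    model_synergies: dict[tuple[int, int], SynergyDecomposition]
    model_synergies_nonnorm: dict[tuple[int, int], SynergyDecomposition]
    checklist: TrendChecklist
    out_dir: Path | None


def run_experiment(cfg: ExperimentConfig, write: bool = True) -> ExperimentReport:
    """Execute the full chain and (optionally) write the report bundle.

    With a fixed master seed the bundle is byte-identical across runs: the
    provenance sidecar records seeds, configuration and package version but
    no wall-clock state.
    """
    from . import __version__

    t0 = time.perf_counter()
    out = Path(cfg.out_dir) if write else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # Stage 1: synthetic cohort and its condition statistics.
    cohort_cfg = CohortConfig(**{**asdict(cfg.cohort), "seed": stage_seed(cfg.seed, "cohort")})
    cohort = Cohort(cohort_cfg, default_trend())
    if out is not None and cfg.write_cohort:
        cohort.write(out / "cohort")
    data_means = cohort_condition_means(cohort)
    contrasts = compare_conditions(data_means, alpha=cfg.alpha)
    log.info("cohort stage done in %.1fs", time.perf_counter() - t0)

    # Stage 2: circuit simulations for the eight presets + diagnostics.
    t1 = time.perf_counter()
    sims: dict[tuple[int, int], SimulationResult] = {}
    for p in POSITIONS:
        for ang in ANGLES:
            sims[(p, ang)] = run_condition(cfg, p, ang)
            if out is not None:
                sio.save_rates(sims[(p, ang)], out / f"rates_pos{p}_angle{ang:02d}.csv")
    flip = run_custom_afferents(cfg, senflint=0.0, senextint=cfg.flip_senextint)
    equal = run_custom_afferents(
        cfg, senflint=cfg.equal_input_rate, senextint=cfg.equal_input_rate
    )
    log.info("simulation stage done in %.1fs", time.perf_counter() - t1)

    # Stage 3: synergies from the normalized rate series (the comparison
    # variant) plus the non-normalized variant of the same analysis.
    decs = model_condition_synergies(cfg, sims, normalize=True)
    decs_nonnorm = model_condition_synergies(cfg, sims, normalize=False)
    window = (cfg.t_start, cfg.duration)
    flip_dec = synergies_from_rates(flip, rank=2, window=window)
    equal_dec = synergies_from_rates(equal, rank=2, window=window)
    if out is not None:
        syn_dir = out / "synergies"
        syn_dir.mkdir(exist_ok=True)
        for (p, ang), d in decs.items():
            sio.save_decomposition(
                normalize_synergies(d), syn_dir / f"model_pos{p}_angle{ang:02d}_norm"
            )
        for (p, ang), d in decs_nonnorm.items():
            sio.save_decomposition(d, syn_dir / f"model_pos{p}_angle{ang:02d}_nonnorm")
        sio.save_decomposition(normalize_synergies(flip_dec), syn_dir / "model_flip")
        sio.save_decomposition(equal_dec, syn_dir / "model_equal")

    # Stage 4: checklist (only when the full condition grid was simulated).
    checklist = trend_checklist(data_means, decs, flip_dec, equal_dec, alpha=cfg.alpha)

    if out is not None:
        data_means.to_csv(out / "data_means.csv", index=False, float_format="%.8g")
        pd.DataFrame([c.to_dict() for c in contrasts]).to_csv(
            out / "contrasts.csv", index=False, float_format="%.8g"
        )
        with open(out / "checklist.json", "w") as fh:
            json.dump(checklist.to_dict(), fh, indent=1)
        provenance = {
            "package_version": __version__,
            "master_seed": cfg.seed,
            "config": cfg.to_dict(),
            "stage_seeds": {
                "cohort": stage_seed(cfg.seed, "cohort"),
                **{f"simulate_pos{p}_angle{a}": stage_seed(cfg.seed, "simulate", p, a)
                   for (p, a) in sims},
            },
            "multiple_testing_correction": "none",
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1)
    log.info("experiment done in %.1fs", time.perf_counter() - t0)

    return ExperimentReport(
        config=cfg,
        data_means=data_means,
        contrasts=contrasts,
        model_synergies=decs,
        model_synergies_nonnorm=decs_nonnorm,
        checklist=checklist,
        out_dir=out,
    )


def validate_config(cfg: ExperimentConfig) -> list[str]:
    """Schema and invariant diagnostics; empty list means valid."""
    out: list[str] = []
    try:
        CohortConfig(**asdict(cfg.cohort))
    except (ValueError, TypeError) as e:
        out.append(f"cohort: {e}")
    if cfg.ensemble_size < 1:
        out.append("ensemble_size must be >= 1")
    if cfg.dt <= 0:
        out.append("dt must be > 0")
    if cfg.rate_sample_interval < cfg.dt:
        out.append("rate_sample_interval must be >= dt")
    if not 0 < cfg.vaf_threshold <= 1:
        out.append("vaf_threshold must be in (0, 1]")
    if not 0 < cfg.alpha < 1:
        out.append("alpha must be in (0, 1)")
    if cfg.ramp <= 0 or cfg.hold < 0 or cfg.t_start < 0:
        out.append("drive timings must satisfy ramp > 0, hold >= 0, t_start >= 0")
    for p in cfg.cohort.positions:
        if p not in POSITIONS:
            out.append(f"unknown position {p}")
    for a in cfg.cohort.angles:
        if a not in ANGLES:
            out.append(f"unknown angle {a}")
    if cfg.network_file:
        path = Path(cfg.network_file)
        if not path.exists():
            out.append(f"network file {path} does not exist")
        else:
            with open(path) as fh:
                out.extend(sio.network_diagnostics(yaml.safe_load(fh)))
    return out
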