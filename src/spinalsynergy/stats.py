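"""Condition statistics and the model-versus-data trend checklist.

The experimental analysis summarises each burst by the mean of its central
4 s ("contraction activity"), compares conditions with two-sided t tests at
alpha = 0.05 (Welch by default; the unit of observation is the subject mean
over bursts), and mirrors the same tests on synergy contribution-vector
components. ``trend_checklist`` condenses the reported qualitative findings
into named booleans evaluated from computed quantities only.

No multiple-testing correction is applied, matching the original reporting;
the contrast records carry their raw p-values so any correction can be
applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .circuit import ANGLES, POSITIONS
from .cohort import Cohort, MUSCLES
from .decomposition import SynergyDecomposition, flexor_extensor_bias
from .preprocessing import burst_matrices

__all__ = [
    "ContrastResult",
    "TrendChecklist",
    "central_window_mean",
    "compare_conditions",
    "contribution_vector_tests",
    "trend_checklist",
    "cohort_condition_means",
]


@dataclass(frozen=True)
class ContrastResult:
    label: str              # muscle or synergy-component name
    kind: str               # "angle" (within position) or "position" (within angle)
    position: int | None    # set for angle contrasts
    angles: tuple[int, ...]  # (a1, a2) for angle contrasts, (angle,) for position
    statistic: float
    p_value: float
    alpha: float
    n: tuple[int, int]

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        d = asdict(self)
        d["significant"] = self.significant
        return d


def central_window_mean(
    x: np.ndarray,
    sample_rate: float,
    window_s: float = 4.0,
    center_s: float | None = None,
) -> float:
    """Mean of the central ``window_s`` seconds of a burst series.

    The window is anchored to the series midpoint by default (the segmented
    burst windows place the contraction roughly centrally), or to an explicit
    ``center_s``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    w = int(round(window_s * sample_rate))
    if w > n:
        raise ValueError(f"window of {window_s} s exceeds the {n / sample_rate:.2f} s burst")
    if w < 1:
        raise ValueError("window too short")
    center = n / 2.0 if center_s is None else center_s * sample_rate
    start = int(round(center - w / 2.0))
    start = min(max(start, 0), n - w)
    return float(x[start:start + w].mean())


def _welch(g1: np.ndarray, g2: np.ndarray, equal_var: bool) -> tuple[float, float]:
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least two observations per group")
    if np.allclose(g1, g1[0]) and np.allclose(g2, g2[0]) and np.isclose(g1[0], g2[0]):
        return 0.0, 1.0  # identical degenerate groups
    t, p = sps.ttest_ind(g1, g2, equal_var=equal_var)
    return float(t), float(p)


def _grid_contrasts(
    df: pd.DataFrame,
    value: str,
    label_col: str,
    alpha: float,
    equal_var: bool,
) -> list[ContrastResult]:
    """Adjacent-angle contrasts within each position and position contrasts
    within each angle, for every label (muscle or synergy component)."""
    out: list[ContrastResult] = []
    labels = df[label_col].unique()
    angles = sorted(df["angle"].unique())
    positions = sorted(df["position"].unique())
    for lab in labels:
        sub = df[df[label_col] == lab]
        for p in positions:
            for a1, a2 in zip(angles[:-1], angles[1:]):
                g1 = sub[(sub.position == p) & (sub.angle == a1)][value].to_numpy()
                g2 = sub[(sub.position == p) & (sub.angle == a2)][value].to_numpy()
                t, pv = _welch(g1, g2, equal_var)
                out.append(ContrastResult(lab, "angle", p, (a1, a2), t, pv,
                                          alpha, (len(g1), len(g2))))
        if len(positions) == 2:
            p1, p2 = positions
            for ang in angles:
                g1 = sub[(sub.position == p1) & (sub.angle == ang)][value].to_numpy()
                g2 = sub[(sub.position == p2) & (sub.angle == ang)][value].to_numpy()
                t, pv = _welch(g1, g2, equal_var)
                out.append(ContrastResult(lab, "position", None, (ang,), t, pv,
                                          alpha, (len(g1), len(g2))))
    return out


def compare_conditions(
    means: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> list[ContrastResult]:
    """Two-sided t tests on contraction activity across the condition grid.

    ``means`` is tidy with columns ``subject, position, angle, muscle, value``
    (one row per subject and condition — subject means over bursts). Welch's
    unequal-variance test by default.
    """
    required = {"subject", "position", "angle", "muscle", "value"}
    if not required <= set(means.columns):
        raise ValueError(f"means frame must have columns {sorted(required)}")
    return _grid_contrasts(means, "value", "muscle", alpha, equal_var)


def contribution_vector_tests(
    weights: pd.DataFrame,
    synergy: int = 2,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> list[ContrastResult]:
    """Two-sided t tests on per-subject synergy contribution components.

    ``weights`` is tidy with columns ``subject, position, angle, muscle,
    synergy, weight``; tests run on the requested synergy (default 2, the
    angle-dependent one).
    """
    required = {"subject", "position", "angle", "muscle", "synergy", "weight"}
    if not required <= set(weights.columns):
        raise ValueError(f"weights frame must have columns {sorted(required)}")
    sub = weights[weights.synergy == synergy].rename(columns={"weight": "value"})
    if sub.empty:
        raise ValueError(f"no rows for synergy {synergy}")
    return _grid_contrasts(sub, "value", "muscle", alpha, equal_var)


def cohort_condition_means(
    cohort: Cohort,
    window_s: float | None = None,
    expected: int | None = None,
    envelope_rate: float = 100.0,
) -> pd.DataFrame:
    """Tidy subject-level contraction activity for the whole cohort.

    Runs the preprocessing chain (rectify, segment, 4 Hz smooth) on every
    recording and averages the central-window mean of each muscle envelope
    over the condition's bursts. The default window is the central 4 s,
    shortened to the plateau duration for cohorts with briefer contractions.
    """
    if window_s is None:
        window_s = min(4.0, cohort.cfg.plateau_ms / 1000.0)
    expected = expected or cohort.cfg.bursts_per_condition
    rows = []
    for s, p, ang in cohort.conditions():
        rec = cohort.recording(s, p, ang)
        bms = burst_matrices(
            rec, expected=expected, channels=list(MUSCLES),
            envelope_rate=envelope_rate, normalize=False,
        )
        per_burst = np.array([
            [central_window_mean(bm.D[i], bm.sample_rate, window_s)
             for i in range(len(MUSCLES))]
            for bm in bms
        ])  # (bursts, muscles)
        for i, m in enumerate(MUSCLES):
            rows.append({"subject": s, "position": p, "angle": ang,
                         "muscle": m, "value": float(per_burst[:, i].mean())})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrendChecklist:
    """Named qualitative findings, each computed from model or cohort output."""

    quad_drop_0_20: bool           # quads fall 0->20 deg in both positions
    quad_drop_20_60_pos1_only: bool  # further fall 20->60 only in position 1
    st_rise_0_20: bool             # ST rises 0->20 deg in both positions
    rf_pos1_greater: bool          # RF higher in position 1 at 20/60/90 deg
    synergy2_antagonist_bias_at_0: bool   # model: flexor-loaded synergy 2 at 0 deg
    synergy2_flattening_with_angle: bool  # model: bias shrinks toward 90 deg
    bias_flip_under_senextint: bool       # model: agonist bias when senExtInt > senFlInt
    equal_input_cancellation: bool        # model: synergy 2 eliminated at equal inputs

    def to_dict(self) -> dict[str, bool]:
        return asdict(self)

    @property
    def all_true(self) -> bool:
        return all(self.to_dict().values())


def _sig(contrasts, label, kind, position, angles, direction) -> bool:
    """Is the named contrast significant with the given sign of change?

    ``direction`` +1 means the second group is larger (rise), -1 a drop; the
    t statistic is group1 - group2."""
    for c in contrasts:
        if (c.label == label and c.kind == kind and c.position == position
                and tuple(c.angles) == tuple(angles)):
            if not c.significant:
                return False
            return bool(np.sign(-c.statistic) == direction) if kind == "angle" else bool(
                np.sign(c.statistic) == direction
            )
    raise KeyError(f"contrast {label} {kind} {position} {angles} not found")


def _spread_cv(w: np.ndarray) -> float:
    mu = float(np.mean(w))
    if mu <= 0:
        return 0.0
    return float(np.std(w) / mu)


def synergy2_cancelled(
    dec: SynergyDecomposition,
    cv_tol: float = 0.1,
    energy_tol: float = 0.01,
) -> bool:
    """Whether the second synergy is effectively absent: either its share of
    the reconstruction energy is negligible or its contribution vector is flat
    across the five muscles (coefficient of variation below ``cv_tol``).

    Must be evaluated on an unnormalized decomposition — rescaling W columns
    and C rows to unit maximum destroys the energy ratio between components.
    """
    if dec.normalized:
        raise ValueError("cancellation check needs the unnormalized decomposition")
    energy = dec.component_energy()
    share = energy[1] / energy.sum() if energy.sum() > 0 else 0.0
    return bool(share < energy_tol or _spread_cv(dec.W[:, 1]) < cv_tol)


def trend_checklist(
    data_means: pd.DataFrame,
    model_synergies: dict[tuple[int, int], SynergyDecomposition],
    flip_synergies: SynergyDecomposition,
    equal_input_synergies: SynergyDecomposition,
    alpha: float = 0.05,
    cv_tol: float = 0.1,
) -> TrendChecklist:
    """Evaluate every reported trend from computed quantities.

    ``data_means`` is the tidy cohort table from
    :func:`cohort_condition_means`; ``model_synergies`` maps each of the eight
    (position, angle) presets to its rank-2 decomposition of the normalized
    rate series (W and C unnormalized — the checklist rescales internally
    where a scale-free comparison is needed); ``flip_synergies`` comes from a
    run with senExtInt raised above senFlInt and ``equal_input_synergies``
    from a run with the two inputs equal.
    """
    from .decomposition import normalize_synergies

    missing = [k for k in ((p, a) for p in POSITIONS for a in ANGLES)
               if k not in model_synergies]
    if missing:
        raise ValueError(f"missing model conditions: {missing}")
    con = compare_conditions(data_means, alpha=alpha)

    quads = ("RF", "VL", "VM")
    quad_drop_0_20 = all(
        _sig(con, m, "angle", p, (0, 20), -1) for m in quads for p in POSITIONS
    )
    quad_drop_20_60_pos1_only = all(
        _sig(con, m, "angle", 1, (20, 60), -1) for m in quads
    ) and not any(
        c.significant for c in con
        if c.label in quads and c.kind == "angle" and c.position == 2
        and tuple(c.angles) == (20, 60)
    )
    st_rise = all(_sig(con, "ST", "angle", p, (0, 20), +1) for p in POSITIONS)
    rf_pos1 = all(_sig(con, "RF", "position", None, (ang,), +1) for ang in (20, 60, 90))

    def bias(pos: int, ang: int) -> float:
        d = model_synergies[(pos, ang)]
        dn = normalize_synergies(d) if not d.normalized else d
        return flexor_extensor_bias(dn.W[:, 1], dn.channels)

    antag_bias = bias(1, 0) > 0 and bias(2, 0) > 0
    flattening = all(
        synergy2_cancelled(model_synergies[(p, 90)], cv_tol=cv_tol) or
        abs(bias(p, 90)) < abs(bias(p, 0)) for p in POSITIONS
    )
    flip_n = normalize_synergies(flip_synergies) if not flip_synergies.normalized \
        else flip_synergies
    flip = flexor_extensor_bias(flip_n.W[:, 1], flip_n.channels) < 0
    cancel = synergy2_cancelled(equal_input_synergies, cv_tol=cv_tol)

    return TrendChecklist(
        quad_drop_0_20=quad_drop_0_20,
        quad_drop_20_60_pos1_only=quad_drop_20_60_pos1_only,
        st_rise_0_20=st_rise,
        rf_pos1_greater=rf_pos1,
        synergy2_antagonist_bias_at_0=antag_bias,
        synergy2_flattening_with_angle=flattening,
        bias_flip_under_senextint=flip,
        equal_input_cancellation=cancel,
    )
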