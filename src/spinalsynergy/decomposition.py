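"""Muscle-synergy extraction by nonnegative matrix factorization.

A burst's smoothed activity matrix ``D`` (muscles x time) is factored as
``D ~ W C`` with ``W >= 0`` (5 x N muscle contribution vectors) and
``C >= 0`` (N x n activation patterns). The factorization minimises the
Frobenius reconstruction error by multiplicative updates from a deterministic
nonnegative-double-SVD start, so identical input yields identical synergies.
Rank is selected as the smallest N whose variance accounted for (VAF) clears
a threshold, 90% by default.

:class:`SynergyNMF` is a scikit-learn style transformer (``fit`` /
``transform`` / ``fit_transform``, ``components_``) and composes with sklearn
pipelines; the module-level functions wrap it in the domain's muscles-by-time
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .circuit import MN_POOLS, SimulationResult, RateSeries
from .preprocessing import BurstMatrix

__all__ = [
    "SynergyNMF",
    "SynergyDecomposition",
    "RankSelection",
    "nndsvd",
    "nmf",
    "vaf",
    "select_rank",
    "normalize_synergies",
    "cosine_similarity",
    "pairwise_similarity",
    "pair_components",
    "synergies_from_rates",
    "flexor_extensor_bias",
    "nonneg_projection_similarity",
]


def nndsvd(A: np.ndarray, rank: int, eps_fill: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic nonnegative double-SVD initialization.

    Splits each singular pair into its positive and negative parts and keeps
    the dominant one. Exact zeros are filled with a small epsilon so the
    multiplicative updates can repopulate them (they would otherwise be
    locked at zero).
    """
    A = np.asarray(A, dtype=float)
    m, n = A.shape
    if not 1 <= rank <= min(m, n):
        raise ValueError(f"rank must be in [1, {min(m, n)}]")
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    W = np.zeros((m, rank))
    H = np.zeros((rank, n))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, rank):
        x, y = U[:, j], Vt[j, :]
        xp, xn = np.maximum(x, 0), np.maximum(-x, 0)
        yp, yn = np.maximum(y, 0), np.maximum(-y, 0)
        mp = np.linalg.norm(xp) * np.linalg.norm(yp)
        mn = np.linalg.norm(xn) * np.linalg.norm(yn)
        if mp >= mn and mp > 0:
            u, v, sig = xp / np.linalg.norm(xp), yp / np.linalg.norm(yp), mp
        elif mn > 0:
            u, v, sig = xn / np.linalg.norm(xn), yn / np.linalg.norm(yn), mn
        else:
            continue
        W[:, j] = np.sqrt(S[j] * sig) * u
        H[j, :] = np.sqrt(S[j] * sig) * v
    if eps_fill is None:
        scale = A.mean()
        eps_fill = 1e-8 * scale if scale > 0 else 1e-12
    W[W == 0] = eps_fill
    H[H == 0] = eps_fill
    return W, H


class SynergyNMF(TransformerMixin, BaseEstimator):
    """Deterministic Frobenius-norm NMF by multiplicative updates.

    scikit-learn orientation: ``X`` is (n_samples, n_features) — here time
    samples by muscles. ``fit_transform(X)`` returns the activation patterns
    (n_samples, n_components) and ``components_`` holds the muscle
    contribution vectors (n_components, n_features).

    Parameters
    ----------
    n_components : rank of the factorization.
    tol : relative change of the squared Frobenius objective that stops the
        iteration.
    max_iter : iteration cap.

    Attributes
    ----------
    components_ : (n_components, n_features) nonnegative matrix.
    n_iter_ : iterations actually run.
    converged_ : whether ``tol`` was reached before ``max_iter``.
    reconstruction_err_ : final Frobenius norm ``||X - activations @ components_||``.
    objective_history_ : squared-error objective per iteration (non-increasing).
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-6, max_iter: int = 10_000):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _factorize(A: np.ndarray, rank: int, tol: float, max_iter: int):
        """Factor A (m x n) ~ W (m x r) @ H (r x n); returns W, H, history, converged."""
        if np.any(A < 0):
            raise ValueError("NMF input must be nonnegative")
        W, H = nndsvd(A, rank)
        eps = 1e-12
        obj = float(np.sum((A - W @ H) ** 2))
        history = [obj]
        converged = False
        for _ in range(max_iter):
            H *= (W.T @ A) / (W.T @ W @ H + eps)
            W *= (A @ H.T) / (W @ H @ H.T + eps)
            new_obj = float(np.sum((A - W @ H) ** 2))
            history.append(new_obj)
            if obj > 0 and abs(obj - new_obj) / obj < tol:
                converged = True
                obj = new_obj
                break
            obj = new_obj
        return W, H, np.array(history), converged

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not 1 <= self.n_components <= min(X.shape):
            raise ValueError(f"n_components must be in [1, {min(X.shape)}]")
        # Domain orientation inside: A = X.T is muscles x time.
        W, H, history, converged = self._factorize(
            X.T, self.n_components, self.tol, self.max_iter
        )
        self.components_ = W.T            # (n_components, n_features)
        self.n_components_ = self.n_components
        self.n_features_in_ = X.shape[1]
        self.objective_history_ = history
        self.n_iter_ = len(history) - 1
        self.converged_ = converged
        activations = H.T                 # (n_samples, n_components)
        self.reconstruction_err_ = float(np.linalg.norm(X - activations @ self.components_))
        return activations

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def transform(self, X):
        """Nonnegative least-squares-style projection of new samples onto the
        fitted components (multiplicative updates with components fixed)."""
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("NMF input must be nonnegative")
        Wt = self.components_.T           # (n_features, n_components)
        G = np.full((X.shape[0], self.n_components_), X.mean() + 1e-9)
        eps = 1e-12
        for _ in range(200):
            G *= (X @ Wt) / (G @ self.components_ @ Wt + eps)
        return G

    def inverse_transform(self, Xt):
        check_is_fitted(self, "components_")
        return np.asarray(Xt) @ self.components_


@dataclass
class SynergyDecomposition:
    """NMF result in the muscles-by-time orientation."""

    W: np.ndarray               # (n_muscles, N) contribution vectors
    C: np.ndarray               # (N, n_samples) activation patterns
    channels: list[str]
    vaf_global: float
    vaf_per_muscle: np.ndarray  # (n_muscles,)
    converged: bool
    normalized: bool = False    # True after normalize_synergies
    meta: dict = field(default_factory=dict)

    @property
    def rank(self) -> int:
        return self.W.shape[1]

    def component_energy(self) -> np.ndarray:
        """Squared Frobenius contribution of each synergy to W C."""
        return np.array(
            [np.sum(np.outer(self.W[:, s], self.C[s]) ** 2) for s in range(self.rank)]
        )


def vaf(D: np.ndarray, W: np.ndarray, C: np.ndarray) -> tuple[float, np.ndarray]:
    """Uncentered variance accounted for, global and per muscle row.

    ``VAF = 1 - sum((D - WC)^2) / sum(D^2)``. Uncentered because a muscle's
    baseline level is meaningful activity, not an offset to remove.
    """
    D = np.asarray(D, dtype=float)
    R = D - W @ C
    ss_tot = np.sum(D**2)
    if ss_tot == 0:
        raise ValueError("VAF undefined for an all-zero matrix")
    g = 1.0 - np.sum(R**2) / ss_tot
    row_tot = np.sum(D**2, axis=1)
    per = np.where(row_tot > 0, 1.0 - np.sum(R**2, axis=1) / np.where(row_tot > 0, row_tot, 1.0), 0.0)
    return float(g), per


def _as_matrix(D) -> tuple[np.ndarray, list[str], dict]:
    if isinstance(D, BurstMatrix):
        return D.D, list(D.channels), dict(D.meta)
    D = np.asarray(D, dtype=float)
    return D, [f"ch{i}" for i in range(D.shape[0])], {}


def nmf(D, rank: int, tol: float = 1e-6, max_iter: int = 10_000) -> SynergyDecomposition:
    """Rank-``rank`` synergy decomposition of a burst matrix.

    Components are ordered by their energy contribution, so synergy 1 is the
    dominant (coactivation) pattern.
    """
    A, channels, meta = _as_matrix(D)
    if np.any(A < 0):
        raise ValueError("burst matrix must be nonnegative")
    W, C, history, converged = SynergyNMF._factorize(A, rank, tol, max_iter)
    energy = np.array([np.sum(np.outer(W[:, s], C[s]) ** 2) for s in range(rank)])
    order = np.argsort(-energy)
    W, C = W[:, order], C[order]
    g, per = vaf(A, W, C)
    return SynergyDecomposition(W, C, channels, g, per, converged, meta=meta)


@dataclass
class RankSelection:
    rank: int
    decomposition: SynergyDecomposition
    discarded: bool
    vaf_by_rank: dict[int, float]


def select_rank(D, threshold: float = 0.90, max_rank: int = 5) -> RankSelection:
    """Smallest rank whose global VAF clears ``threshold``.

    Scans ranks 1..``max_rank`` in ascending order. The result is flagged
    ``discarded`` when no rank reaches the threshold (rank ``max_rank`` is
    then reported) or when any per-muscle VAF of the selected decomposition
    stays below the threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    A, _, _ = _as_matrix(D)
    max_rank = min(max_rank, min(A.shape))
    vaf_by_rank: dict[int, float] = {}
    chosen: SynergyDecomposition | None = None
    rank = max_rank
    for r in range(1, max_rank + 1):
        dec = nmf(D, r)
        vaf_by_rank[r] = dec.vaf_global
        if dec.vaf_global >= threshold:
            chosen, rank = dec, r
            break
    if chosen is None:
        chosen = nmf(D, max_rank)
        return RankSelection(max_rank, chosen, True, vaf_by_rank)
    discarded = bool(np.any(chosen.vaf_per_muscle < threshold))
    return RankSelection(rank, chosen, discarded, vaf_by_rank)


def normalize_synergies(S: SynergyDecomposition) -> SynergyDecomposition:
    """Scale each W column and C row to unit maximum.

    This is a presentation transform for cross-subject comparison: after it
    the product ``W C`` no longer reconstructs ``D``. VAF values are carried
    over from the unnormalized decomposition.
    """
    W = S.W.copy()
    C = S.C.copy()
    wmax = W.max(axis=0, keepdims=True)
    cmax = C.max(axis=1, keepdims=True)
    W /= np.where(wmax > 0, wmax, 1.0)
    C /= np.where(cmax > 0, cmax, 1.0)
    return SynergyDecomposition(
        W, C, list(S.channels), S.vaf_global, S.vaf_per_muscle.copy(),
        S.converged, normalized=True, meta=dict(S.meta),
    )


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def pairwise_similarity(items: Sequence[np.ndarray]) -> tuple[float, np.ndarray]:
    """Mean and full matrix of cosine similarities over all unordered pairs."""
    if len(items) < 2:
        raise ValueError("need at least two vectors")
    k = len(items)
    M = np.eye(k)
    vals = []
    for i in range(k):
        for j in range(i + 1, k):
            s = cosine_similarity(items[i], items[j])
            M[i, j] = M[j, i] = s
            vals.append(s)
    return float(np.mean(vals)), M


def pair_components(A: np.ndarray, B: np.ndarray) -> list[tuple[int, int]]:
    """Greedy pairing of the columns of ``A`` with the columns of ``B`` by
    descending cosine similarity (the component order of two NMF runs is not
    guaranteed to agree)."""
    ka, kb = A.shape[1], B.shape[1]
    sims = np.full((ka, kb), -np.inf)
    for i in range(ka):
        for j in range(kb):
            if np.linalg.norm(A[:, i]) > 0 and np.linalg.norm(B[:, j]) > 0:
                sims[i, j] = cosine_similarity(A[:, i], B[:, j])
    pairs: list[tuple[int, int]] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(-sims, axis=None), sims.shape))[0]
    for i, j in order:
        if i not in used_a and j not in used_b and np.isfinite(sims[i, j]):
            pairs.append((int(i), int(j)))
            used_a.add(int(i))
            used_b.add(int(j))
    return pairs


def nonneg_projection_similarity(template: np.ndarray, C: np.ndarray) -> float:
    """Cosine similarity between a template and its best nonnegative
    reconstruction from the rows of ``C``.

    NMF components are identifiable only up to the extreme rays of the data
    cone (several factorizations fit equally well), so recovery of a latent
    activation pattern is judged against the recovered components' span
    rather than by one-to-one matching.
    """
    from scipy.optimize import nnls

    template = np.asarray(template, dtype=float).ravel()
    coeffs, _ = nnls(C.T, template)
    proj = C.T @ coeffs
    return cosine_similarity(template, proj)


def flexor_extensor_bias(W_col: np.ndarray, channels: Sequence[str]) -> float:
    """Mean flexor (ST, BF) minus mean extensor (RF, VL, VM) contribution of
    one synergy column — positive for an antagonist bias."""
    ch = list(channels)
    flex = [ch.index(c) for c in ch if c.endswith(("ST", "BF"))]
    ext = [ch.index(c) for c in ch if c.endswith(("RF", "VL", "VM"))]
    if not flex or not ext:
        raise ValueError("channels must include flexor and extensor names")
    return float(np.mean(W_col[flex]) - np.mean(W_col[ext]))


def synergies_from_rates(
    result: SimulationResult | dict[str, RateSeries],
    rank: int = 2,
    window: tuple[float, float] = (500.0, 7500.0),
    cutoff: float = 4.0,
    normalize: bool = True,
    pools: Sequence[str] = MN_POOLS,
) -> SynergyDecomposition:
    """Synergy decomposition of the motor-neuron population rate series.

    The rate series are treated exactly like the experimental recordings:
    low-pass filtered at ``cutoff`` Hz (second-order Butterworth, causal),
    clipped at zero, optionally normalized to each series' maximum, then
    factored at the given rank over the analysis ``window`` (ms) — which by
    default excludes the settling period before the drive begins.
    """
    rates = result.rates if isinstance(result, SimulationResult) else result
    series = [rates[p] for p in pools]
    t = series[0].times
    m = (t >= window[0]) & (t < window[1])
    fs = 1000.0 / float(t[1] - t[0])
    b, a = _signal.butter(2, cutoff, btype="low", fs=fs)
    rows = []
    for s in series:
        smooth = _signal.lfilter(b, a, s.rates)[m]
        rows.append(np.clip(smooth, 0.0, None))
    D = np.vstack(rows)
    if normalize:
        peaks = D.max(axis=1, keepdims=True)
        D = D / np.where(peaks > 0, peaks, 1.0)
    bm = BurstMatrix(D, list(pools), fs, normalized=normalize)
    return nmf(bm, rank)
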