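"""MDS summaries of legacy-sensitive genes and causal mediation of drought.

Expression of the legacy-sensitive gene set (main-effect hits plus CI-rule
interaction hits) is summarized by non-metric multidimensional scaling of
Bray-Curtis distances into two axes, MDS1 and MDS2. For each plant trait,
linear mediator and outcome models

    M = alpha + a T          Y = beta + b M + c' T

decompose the total drought effect into the average causal mediation effect
ACME = a*b, the direct effect ADE = c', and total = a*b + c' (an identity in
the linear case). Uncertainty comes from a nonparametric percentile
bootstrap over samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .ecostats import pcoa

__all__ = [
    "nmds",
    "MDSEmbedding",
    "mediate_single",
    "mediate_joint",
    "select_legacy_sensitive",
    "MediationResult",
]


# -------------------------------------------------------------------- NMDS


@dataclass
class MDSEmbedding:
    scores: pd.DataFrame  # samples x k, centered, PCA-rotated
    stress: float  # Kruskal stress-1 in [0, 1]
    converged: bool
    metric: str = "precomputed"


def _kruskal_stress(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((dist**2).sum())
    if denom <= 0:
        return 0.0
    return float(np.sqrt(((dist - dhat) ** 2).sum() / denom))


def _nmds_single(
    d: np.ndarray, x0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool, list[float]]:
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    dvec = d[iu]
    order = np.argsort(dvec, kind="stable")
    iso = IsotonicRegression(increasing=True)  # primary (averaging) ties
    x = x0.copy()
    x_prev = x
    trace: list[float] = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        diff = x[:, None, :] - x[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        dvec_x = dist[iu]
        dhat = iso.fit(dvec[order], dvec_x[order]).predict(dvec[order])
        dhat_vec = np.empty_like(dvec_x)
        dhat_vec[order] = dhat
        stress = _kruskal_stress(dvec_x, dhat_vec)
        if stress > prev + 1e-12:
            # stress-1 renormalization can tick up at convergence: keep the
            # previous configuration so the reported trace stays monotone
            x = x_prev
            converged = True
            break
        trace.append(stress)
        if stress < 1e-12 or prev - stress < tol:
            converged = True
            break
        prev = stress
        x_prev = x
        # Guttman transform with disparities
        dhat_mat = np.zeros_like(dist)
        dhat_mat[iu] = dhat_vec
        dhat_mat += dhat_mat.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 1e-12, dhat_mat / dist, 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = (b @ x) / n
        x -= x.mean(axis=0)
    return x, trace[-1], converged, trace


def nmds(
    d: pd.DataFrame,
    k: int = 2,
    n_starts: int = 4,
    max_iter: int = 300,
    seed: int = 0,
    tol: float = 1e-7,
) -> MDSEmbedding:
    """Non-metric MDS minimizing Kruskal stress-1 by iterative majorization.

    Start 1 initializes from the PCoA configuration; the remaining starts are
    seeded random. The best final configuration is centered and PCA-rotated.
    Stress decreases monotonically within each majorization run.
    """
    arr = d.to_numpy(float)
    n = arr.shape[0]
    if n < k + 2:
        raise ValueError("need at least k + 2 samples")
    rng = np.random.default_rng(seed)
    ord0 = pcoa(d, k=min(k, n - 1))
    x0 = np.zeros((n, k))
    got = ord0.scores.to_numpy(float)
    x0[:, : got.shape[1]] = got[:, :k]
    starts = [x0] + [rng.normal(size=(n, k)) for _ in range(max(n_starts - 1, 0))]
    best: tuple[np.ndarray, float, bool] | None = None
    for s in starts:
        x, stress, conv, trace = _nmds_single(arr, s, max_iter, tol)
        if any(b > a + 1e-9 for a, b in zip(trace, trace[1:])):
            raise RuntimeError("stress increased within a majorization run")
        if best is None or stress < best[1]:
            best = (x, stress, conv)
    x, stress, conv = best
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    scores = pd.DataFrame(x, index=d.index, columns=[f"MDS{i + 1}" for i in range(k)])
    return MDSEmbedding(scores=scores, stress=stress, converged=conv)


# --------------------------------------------------------------- mediation


@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    prop_mediated: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_ci: tuple[float, float]
    acme_p: float
    ade_p: float
    total_p: float
    n_boot: int
    seed: int


def _ols(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(x, y, rcond=None)[0]


def _boot_p(draws: np.ndarray) -> float:
    lo = float(np.mean(draws <= 0))
    hi = float(np.mean(draws >= 0))
    return float(min(1.0, 2.0 * max(min(lo, hi), 1.0 / len(draws))))


def _paths(
    t: np.ndarray, m: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    xa = np.column_stack([np.ones_like(t), t])
    a = _ols(m, xa)[1]
    xb = np.column_stack([np.ones_like(t), m, t])
    coef = _ols(y, xb)
    return float(a), float(coef[1]), float(coef[2])


def mediate_single(
    trait: np.ndarray | pd.Series,
    mediator: np.ndarray | pd.Series,
    treatment: np.ndarray | pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Single-mediator linear mediation with a percentile bootstrap.

    ACME = a*b, ADE = c', total = ACME + ADE; the proportion mediated is
    ACME / total (signed; reported NaN when the total effect is ~0).
    """
    y = np.asarray(trait, float)
    m = np.asarray(mediator, float)
    t = np.asarray(treatment, float)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if np.std(y) == 0 or np.std(m) == 0:
        raise ValueError("constant trait or mediator")
    if len(np.unique(t)) < 2:
        raise ValueError("both treatment arms must be non-empty")
    a, b, cprime = _paths(t, m, y)
    acme, ade = a * b, cprime
    total = acme + ade

    rng = np.random.default_rng(seed)
    n = len(y)
    draws = np.empty((n_boot, 3))
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        while len(np.unique(t[idx])) < 2:
            idx = rng.integers(0, n, n)
        ab, bb, cb = _paths(t[idx], m[idx], y[idx])
        draws[i] = ab * bb, cb, ab * bb + cb
    ci = np.percentile(draws, [2.5, 97.5], axis=0)
    prop = acme / total if abs(total) > 1e-12 else np.nan
    return MediationResult(
        acme=acme, ade=ade, total=total, prop_mediated=prop,
        acme_ci=(ci[0, 0], ci[1, 0]), ade_ci=(ci[0, 1], ci[1, 1]),
        total_ci=(ci[0, 2], ci[1, 2]),
        acme_p=_boot_p(draws[:, 0]), ade_p=_boot_p(draws[:, 1]),
        total_p=_boot_p(draws[:, 2]), n_boot=n_boot, seed=seed,
    )


def mediate_joint(
    trait: np.ndarray | pd.Series,
    mediators: tuple[np.ndarray | pd.Series, np.ndarray | pd.Series],
    treatment: np.ndarray | pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, MediationResult | tuple[float, tuple[float, float], float]]:
    """Two simultaneous mediators: per-path ACMEs and the joint indirect effect.

    The outcome model includes both mediators; per-path indirect effects are
    a_i * b_i and the joint indirect effect is their sum, with a shared
    percentile bootstrap.
    """
    y = np.asarray(trait, float)
    m1 = np.asarray(mediators[0], float)
    m2 = np.asarray(mediators[1], float)
    t = np.asarray(treatment, float)
    r = np.corrcoef(m1, m2)[0, 1]
    if abs(r) > 0.99:
        raise ValueError("mediators are (near-)collinear")

    def joint_paths(tt, mm1, mm2, yy):
        xa = np.column_stack([np.ones_like(tt), tt])
        a1 = _ols(mm1, xa)[1]
        a2 = _ols(mm2, xa)[1]
        xb = np.column_stack([np.ones_like(tt), mm1, mm2, tt])
        coef = _ols(yy, xb)
        return a1 * coef[1], a2 * coef[2], coef[3]

    i1, i2, ade = joint_paths(t, m1, m2, y)
    rng = np.random.default_rng(seed)
    n = len(y)
    draws = np.empty((n_boot, 4))
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        while len(np.unique(t[idx])) < 2:
            idx = rng.integers(0, n, n)
        b1, b2, bd = joint_paths(t[idx], m1[idx], m2[idx], y[idx])
        draws[i] = b1, b2, b1 + b2, bd
    ci = np.percentile(draws, [2.5, 97.5], axis=0)

    def as_result(est, col):
        total = est + ade if col < 2 else i1 + i2 + ade
        return MediationResult(
            acme=float(est), ade=float(ade), total=float(total),
            prop_mediated=float(est / total) if abs(total) > 1e-12 else np.nan,
            acme_ci=(ci[0, col], ci[1, col]), ade_ci=(ci[0, 3], ci[1, 3]),
            total_ci=(np.nan, np.nan),
            acme_p=_boot_p(draws[:, col]), ade_p=_boot_p(draws[:, 3]),
            total_p=np.nan, n_boot=n_boot, seed=seed,
        )

    return {
        "M1": as_result(i1, 0),
        "M2": as_result(i2, 1),
        "joint_indirect": (float(i1 + i2), (float(ci[0, 2]), float(ci[1, 2])),
                           _boot_p(draws[:, 2])),
    }


def select_legacy_sensitive(
    de_main: pd.DataFrame,
    interactions: pd.DataFrame,
    q_threshold: float = 0.05,
) -> pd.Index:
    """Union of legacy main-effect hits (q < threshold) and interaction hits."""
    main_hits = de_main.index[(de_main["q"] < q_threshold).fillna(False)]
    inter_hits = interactions.index[interactions["interacting"].fillna(False)]
    return main_hits.union(inter_hits)
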