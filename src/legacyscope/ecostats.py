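"""Ecological statistics: diversity, dissimilarity, ordination, permutation tests.

Distance matrices are square pandas DataFrames with matching row/column sample
IDs. Permutation P values use the +1 correction, P = (1 + #{stat_perm >=
stat_obs}) / (1 + n_perm), which is exact under exchangeability and never
zero. PERMANOVA partitions the total sum of squared distances sequentially
(type I) in formula order, mirroring vegan's adonis2 defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._design import expand_terms, model_matrix
from .containers import OrdinationResult

__all__ = [
    "shannon_effective",
    "bray_curtis",
    "zscore",
    "rarefy",
    "pcoa",
    "permanova",
    "mantel",
    "betadispersion",
    "partial_constrained_ordination",
    "clr_transform",
]


# ---------------------------------------------------------------- diversity


def shannon_effective(counts_row) -> float:
    """Effective number of taxa, exp(H) with H the Shannon entropy (nats)."""
    x = np.asarray(counts_row, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero row")
    p = x[x > 0] / total
    return float(np.exp(-(p * np.log(p)).sum()))


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between rows (samples) of ``table``."""
    arr = table.to_numpy(float)
    if (arr < 0).any():
        raise ValueError("negative abundances")
    sums = arr.sum(axis=1)
    if (sums <= 0).any():
        bad = table.index[sums <= 0].tolist()
        raise ValueError(f"zero-sum rows: {bad}")
    d = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


def zscore(matrix: pd.DataFrame, axis: int = 0, on_constant: str = "raise") -> pd.DataFrame:
    """Standardize each vector along ``axis`` to mean 0, sd 1 (ddof=1).

    Constant vectors raise by default; ``on_constant='drop'`` removes them
    with a warning instead.
    """
    df = matrix if axis == 0 else matrix.T
    sd = df.std(axis=0, ddof=1)
    const = sd <= 0
    if const.any():
        names = sd.index[const].tolist()
        if on_constant == "drop":
            import warnings

            warnings.warn(f"dropping constant columns: {names}", stacklevel=2)
            df = df.loc[:, ~const]
            sd = sd[~const]
        else:
            raise ValueError(f"constant vectors cannot be z-scored: {names}")
    out = (df - df.mean(axis=0)) / sd
    return out if axis == 0 else out.T


def rarefy(counts: pd.DataFrame, depth: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Seeded subsampling without replacement of each sample (column).

    ``depth`` defaults to the minimum column sum.
    """
    rng = np.random.default_rng(seed)
    arr = counts.to_numpy(int)
    sums = arr.sum(axis=0)
    depth = int(sums.min()) if depth is None else int(depth)
    if (sums < depth).any():
        bad = counts.columns[sums < depth].tolist()
        raise ValueError(f"columns below rarefaction depth: {bad}")
    out = np.zeros_like(arr)
    for j in range(arr.shape[1]):
        pool = np.repeat(np.arange(arr.shape[0]), arr[:, j])
        take = rng.choice(pool, size=depth, replace=False)
        out[:, j] = np.bincount(take, minlength=arr.shape[0])
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def clr_transform(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform per sample (row): ln(x+c) - mean ln(x+c)."""
    arr = counts.to_numpy(float) + pseudocount
    if (arr <= 0).any():
        raise ValueError("pseudocount must make all entries positive")
    logs = np.log(arr)
    out = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------- ordination


def _check_distance(d: pd.DataFrame) -> np.ndarray:
    arr = d.to_numpy(float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0, atol=1e-10):
        raise ValueError("distance matrix must have zero diagonal")
    if (arr < -1e-12).any():
        raise ValueError("negative dissimilarities")
    return arr


def _gower_center(arr: np.ndarray) -> np.ndarray:
    a = -0.5 * arr**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(d: pd.DataFrame, k: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis (Gower centering + eigendecomposition).

    Negative eigenvalues are reported but excluded from scores and from the
    variance fractions (fractions are relative to the positive-eigenvalue sum).
    """
    arr = _check_distance(d)
    n = arr.shape[0]
    if k is None:
        k = n - 1
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}]")
    g = _gower_center(arr)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12
    pos_sum = vals[pos].sum()
    n_axes = min(k, int(pos.sum()))
    scores = vecs[:, :n_axes] * np.sqrt(vals[:n_axes])
    frac = vals[:n_axes] / pos_sum if pos_sum > 0 else np.zeros(n_axes)
    score_df = pd.DataFrame(
        scores, index=d.index, columns=[f"PCo{i + 1}" for i in range(n_axes)]
    )
    return OrdinationResult(scores=score_df, eigvals=vals, proportion_explained=frac)


# ---------------------------------------------------------------- PERMANOVA


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def permanova(
    d: pd.DataFrame,
    design: pd.DataFrame,
    formula_terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Sequential (type-I) PERMANOVA on a distance matrix.

    Returns a table with one row per term plus a Residual/Total row, holding
    df, sums of squares, R2, pseudo-F and permutation P (simultaneous
    row/column permutation of the distance matrix; +1 corrected).
    """
    arr = _check_distance(d)
    design = design.loc[list(d.index)]
    n = arr.shape[0]
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    terms = expand_terms(formula_terms)
    g = _gower_center(arr)
    ss_total = float(np.trace(g))

    hats, dfs = [], []
    running: list[str] = []
    for term in terms:
        running.append(term)
        x, _, _ = model_matrix(design, running)
        hats.append(_hat(x))
        dfs.append(int(np.round(np.trace(hats[-1]))) - 1
                   - sum(dfs))  # df beyond previous terms + intercept
    h_full = hats[-1]
    df_res = n - int(np.round(np.trace(h_full)))
    if df_res <= 0:
        raise ValueError("model saturates the samples; no residual df")
    ss_res = ss_total - float(np.sum(h_full * g))
    if any(df <= 0 for df in dfs):
        bad = [t for t, df in zip(terms, dfs) if df <= 0]
        raise ValueError(f"terms with no estimable levels: {bad}")

    def term_ss(gmat: np.ndarray) -> np.ndarray:
        explained = np.array([np.sum(h * gmat) for h in hats])
        return np.diff(np.concatenate([[0.0], explained]))

    ss_terms = term_ss(g)
    ms_res = ss_res / df_res
    f_obs = (ss_terms / np.array(dfs)) / ms_res

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    chunk = max(1, min(n_perm, int(2e7 / (n * n))))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.array([rng.permutation(n) for _ in range(b)])
        gp = g[perms[:, :, None], perms[:, None, :]]
        explained = np.stack([np.einsum("ij,bij->b", h, gp) for h in hats], axis=1)
        ssb = np.diff(np.concatenate([np.zeros((b, 1)), explained], axis=1), axis=1)
        ss_res_b = ss_total - explained[:, -1]
        with np.errstate(divide="ignore", invalid="ignore"):
            # zero residual SS (perfect separation) gives an infinite F
            fb = (ssb / np.array(dfs)) / (ss_res_b / df_res)[:, None]
        exceed += (fb >= f_obs[None, :] - 1e-12).sum(axis=0)
        done += b
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, term in enumerate(terms):
        rows.append({"term": term, "df": dfs[i], "ss": ss_terms[i],
                     "R2": ss_terms[i] / ss_total, "F": f_obs[i], "P": pvals[i]})
    rows.append({"term": "Residual", "df": df_res, "ss": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "P": np.nan})
    rows.append({"term": "Total", "df": n - 1, "ss": ss_total, "R2": 1.0,
                 "F": np.nan, "P": np.nan})
    return pd.DataFrame(rows).set_index("term")


def mantel(
    d1: pd.DataFrame, d2: pd.DataFrame, n_perm: int = 9999, seed: int = 0
) -> tuple[float, float]:
    """Mantel test: Pearson r of lower triangles, permutation P by relabeling."""
    if list(d1.index) != list(d2.index):
        d2 = d2.loc[d1.index, d1.index]
    a1 = _check_distance(d1)
    a2 = _check_distance(d2)
    n = a1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1, v2 = a1[iu], a2[iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("constant lower triangle")
    z1 = (v1 - v1.mean()) / v1.std()
    z2 = (v2 - v2.mean()) / v2.std()
    r_obs = float(np.mean(z1 * z2))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        vp = a2[p[:, None], p[None, :]][iu]
        zp = (vp - vp.mean()) / vp.std()
        if abs(float(np.mean(z1 * zp))) >= abs(r_obs) - 1e-12:
            exceed += 1
    return r_obs, (1.0 + exceed) / (1.0 + n_perm)


# ------------------------------------------------------------ dispersion


def betadispersion(
    d: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[pd.Series, float, float]:
    """Distance to group centroid in the PCoA embedding, with permutation F.

    Squared centroid distances subtract the components on negative-eigenvalue
    (imaginary) axes, as in vegan's betadisper; the F statistic is the one-way
    ANOVA F on the per-sample distances and P comes from permuting group
    labels.
    """
    groups = groups.loc[list(d.index)]
    labels, counts = np.unique(groups.astype(str), return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValueError(f"groups of size < 2: {small}")
    arr = _check_distance(d)
    g = _gower_center(arr)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = np.abs(vals).max() * 1e-10
    pos = vals > tol
    neg = vals < -tol
    xr = vecs[:, pos] * np.sqrt(vals[pos])
    xi = vecs[:, neg] * np.sqrt(-vals[neg])

    dist = np.empty(len(groups))
    gl = groups.astype(str).to_numpy()
    for lab in labels:
        m = gl == lab
        dr = ((xr[m] - xr[m].mean(axis=0)) ** 2).sum(axis=1)
        di = ((xi[m] - xi[m].mean(axis=0)) ** 2).sum(axis=1) if xi.size else 0.0
        dist[m] = np.sqrt(np.maximum(dr - di, 0.0))

    def anova_f(y: np.ndarray, lab_arr: np.ndarray) -> float:
        grand = y.mean()
        ss_b = sum(((y[lab_arr == la].mean() - grand) ** 2) * (lab_arr == la).sum()
                   for la in labels)
        ss_w = sum(((y[lab_arr == la] - y[lab_arr == la].mean()) ** 2).sum()
                   for la in labels)
        df_b, df_w = len(labels) - 1, len(y) - len(labels)
        return (ss_b / df_b) / (ss_w / df_w) if ss_w > 0 else np.inf

    f_obs = anova_f(dist, gl)
    rng = np.random.default_rng(seed)
    exceed = sum(
        anova_f(dist, gl[rng.permutation(len(gl))]) >= f_obs - 1e-12
        for _ in range(n_perm)
    )
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.Series(dist, index=d.index, name="centroid_distance"), float(f_obs), p


# --------------------------------------------------- constrained ordination


def _residualize(y: np.ndarray, z: np.ndarray | None) -> np.ndarray:
    if z is None or z.shape[1] == 0:
        return y - y.mean(axis=0, keepdims=True)
    h = _hat(z)
    return y - h @ y


def partial_constrained_ordination(
    response: pd.DataFrame,
    constraints: pd.DataFrame,
    conditions: pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> OrdinationResult:
    """(Partial) redundancy analysis with a permutation test.

    Response and constraint model matrices are residualized on the condition
    model matrix (which always includes an intercept), then the fitted values
    of the multivariate regression of response on constraints are decomposed
    by SVD. The overall and per-term (sequential) pseudo-F statistics are
    tested by permuting residuals under the conditions-only (reduced) model.
    """
    y = response.to_numpy(float)
    n = y.shape[0]
    cond_terms = []
    if conditions is not None:
        # single-level condition columns carry no information to partial out
        cond_terms = [c for c in conditions.columns
                      if conditions[c].nunique() > 1]
    if cond_terms:
        z, _, _ = model_matrix(conditions, cond_terms)
    else:
        z = np.ones((n, 1))
    rank_z = int(np.round(np.trace(_hat(z))))
    con_terms = list(constraints.columns)
    x_full, x_names, _ = model_matrix(constraints, con_terms, intercept=False)

    yr = _residualize(y, z)
    xr = _residualize(x_full, z)
    # a constraint column absorbed by the conditions (or duplicated) is aliased
    before = np.linalg.norm(x_full - x_full.mean(axis=0), axis=0)
    after = np.linalg.norm(xr, axis=0)
    aliased = after <= 1e-8 * np.maximum(before, 1e-12)
    if aliased.any() or np.linalg.matrix_rank(xr) < xr.shape[1]:
        bad = [x_names[i] for i in range(xr.shape[1]) if aliased[i]]
        raise ValueError(f"rank-deficient constraints after conditioning: {bad}")

    hx = _hat(xr)
    fitted = hx @ yr
    ss_total = float((yr**2).sum())
    ss_fit = float((fitted**2).sum())
    df_x = int(np.round(np.trace(hx)))
    df_res = n - rank_z - df_x
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    ss_res = ss_total - ss_fit
    f_obs = (ss_fit / df_x) / (ss_res / df_res)

    # sequential per-term partition
    hats, dfs = [], []
    col_term = []
    start = 0
    for term in con_terms:
        xt, _, _ = model_matrix(constraints[[term]], [term], intercept=False)
        col_term.append((start, start + xt.shape[1]))
        start += xt.shape[1]
    for _, stop in col_term:
        h = _hat(xr[:, :stop])
        hats.append(h)
        dfs.append(int(np.round(np.trace(h))) - sum(dfs))
    explained = np.array([float(np.sum((h @ yr) * yr)) for h in hats])
    ss_terms = np.diff(np.concatenate([[0.0], explained]))
    f_terms = (ss_terms / np.array(dfs)) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed_all = 0
    exceed_terms = np.zeros(len(con_terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        yp = yr[p]
        fit_p = hx @ yp
        ss_fit_p = float((fit_p**2).sum())
        ss_res_p = float((yp**2).sum()) - ss_fit_p
        fp = (ss_fit_p / df_x) / (ss_res_p / df_res)
        if fp >= f_obs - 1e-12:
            exceed_all += 1
        expl_p = np.array([float(np.sum((h @ yp) * yp)) for h in hats])
        ss_t_p = np.diff(np.concatenate([[0.0], expl_p]))
        ft_p = (ss_t_p / np.array(dfs)) / (ss_res_p / df_res)
        exceed_terms += ft_p >= f_terms - 1e-12
    p_all = (1.0 + exceed_all) / (1.0 + n_perm)
    p_terms = (1.0 + exceed_terms) / (1.0 + n_perm)

    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    k = min(df_x, (s > s[0] * 1e-10).sum() if s.size else 0)
    eig = (s[:k] ** 2) / max(n - 1, 1)
    scores = pd.DataFrame(
        u[:, :k] * s[:k], index=response.index,
        columns=[f"RDA{i + 1}" for i in range(k)],
    )
    term_stats = pd.DataFrame({
        "term": con_terms + ["Overall"],
        "df": dfs + [df_x],
        "ss": list(ss_terms) + [ss_fit],
        "R2": list(ss_terms / ss_total) + [ss_fit / ss_total],
        "F": list(f_terms) + [f_obs],
        "P": list(p_terms) + [p_all],
    }).set_index("term")
    frac = eig / eig.sum() * (ss_fit / ss_total) if eig.size else eig
    return OrdinationResult(
        scores=scores, eigvals=eig, proportion_explained=frac, term_stats=term_stats
    )
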