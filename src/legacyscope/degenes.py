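"""Simplified negative-binomial differential analysis and interaction calls.

Per-feature NB2 log-link GLMs with log size-factor offsets: the dispersion
alpha is estimated per feature by profile maximum likelihood (with a
method-of-moments fallback), the contrast of interest is tested by a Wald z
on the log2 scale, and P values are Benjamini-Hochberg adjusted across
features. There is no empirical-Bayes shrinkage of dispersions or fold
changes; calibration is by simulation, not by matching any particular
reference implementation.

The legacy x drought interaction classifier follows a confidence-interval
rule: a feature interacts when the 95% CIs of its drought log2FC in the
dry-legacy and wet-legacy groups do not overlap at all, and the sign pattern
of the two responses assigns a gene-set label (I-VI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from ._design import model_matrix
from .ecostats import clr_transform

__all__ = [
    "size_factors",
    "cpm",
    "tpm",
    "estimate_dispersion",
    "nb_glm_wald",
    "drought_response_by_legacy",
    "classify_interaction",
    "call_enriched",
    "clr_interaction_lm",
    "Z95",
]

#: 95% two-sided normal quantile used for every CI in this module
Z95 = 1.959964

_LN2 = np.log(2.0)


# ---------------------------------------------------------- normalization


def size_factors(counts: pd.DataFrame, mode: str = "median_ratio") -> pd.Series:
    """Per-sample size factors.

    ``median_ratio``: per sample, the median over all-positive features of
    count / geometric mean (the DESeq-style estimator). ``cpm``: column sum
    scaled to mean 1.
    """
    arr = counts.to_numpy(float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    if mode == "median_ratio":
        allpos = (arr > 0).all(axis=1)
        if not allpos.any():
            raise ValueError(
                "median_ratio needs >= 1 feature with all-positive counts; "
                "use mode='cpm' for sparse matrices"
            )
        sub = arr[allpos]
        geo = np.exp(np.log(sub).mean(axis=1, keepdims=True))
        sf = np.median(sub / geo, axis=0)
    elif mode == "cpm":
        tot = arr.sum(axis=0)
        sf = tot / np.exp(np.log(tot).mean())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(sf, index=counts.columns, name="size_factor")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million; columns sum to 1e6."""
    tot = counts.sum(axis=0)
    if (tot <= 0).any():
        raise ValueError("zero-sum sample columns")
    return counts * 1e6 / tot


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million given feature lengths; columns sum to 1e6."""
    lengths = lengths.loc[counts.index].to_numpy(float)
    if (lengths <= 0).any():
        raise ValueError("non-positive feature lengths")
    rate = counts.div(lengths, axis=0)
    return rate * 1e6 / rate.sum(axis=0)


# ------------------------------------------------------------- dispersion


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    size = 1.0 / alpha
    return float(np.sum(
        special.gammaln(y + size) - special.gammaln(size) - special.gammaln(y + 1)
        + size * np.log(size / (size + mu)) + y * np.log(mu / (size + mu))
    ))


def estimate_dispersion(
    y: np.ndarray, mu: np.ndarray, x: np.ndarray | None = None,
    bounds: tuple[float, float] = (1e-8, 50.0),
) -> float:
    """NB2 dispersion alpha by Cox-Reid adjusted profile ML given fitted means.

    Maximizes, in log-alpha, the profile likelihood penalized by
    -0.5 log det(X' W X) with W the NB working weights mu / (1 + alpha mu);
    the adjustment removes the downward bias of plain profile ML when the
    mean model uses several degrees of freedom. When the optimizer fails, the
    moments estimator alpha = sum((y-mu)^2 - mu) / sum(mu^2) (clipped to
    ``bounds``) is the fallback.
    """
    y = np.asarray(y, float)
    mu = np.maximum(np.asarray(mu, float), 1e-10)
    mom = float(np.sum((y - mu) ** 2 - mu) / np.sum(mu**2))
    mom = float(np.clip(mom, bounds[0], bounds[1]))

    def neg_apl(la: float) -> float:
        alpha = np.exp(la)
        ll = _nb_loglik(y, mu, alpha)
        if x is not None:
            w = mu / (1.0 + alpha * mu)
            sign, logdet = np.linalg.slogdet((x * w[:, None]).T @ x)
            if sign <= 0:
                return np.inf
            ll -= 0.5 * logdet
        return -ll

    try:
        res = minimize_scalar(
            neg_apl,
            bounds=(np.log(bounds[0]), np.log(bounds[1])),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if res.success and np.isfinite(res.fun):
            return float(np.exp(res.x))
    except (ValueError, FloatingPointError):
        pass
    return mom


# ----------------------------------------------------------------- NB GLM


def _fit_feature(
    y: np.ndarray, x: np.ndarray, offset: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Fit Poisson -> alpha -> NB GLM; returns (params, cov, alpha) or None."""
    try:
        pois = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset).fit()
        alpha = estimate_dispersion(y, pois.fittedvalues, x=x)
        nb = sm.GLM(
            y, x, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
        ).fit(start_params=pois.params)
        return np.asarray(nb.params), np.asarray(nb.cov_params()), alpha
    except (ValueError, np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return None


def _check_design(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        r = np.linalg.qr(x, mode="r")
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in range(x.shape[1]) if diag[i] <= 1e-10 * diag.max()]
        raise ValueError(f"rank-deficient design; aliased columns: {bad}")


def nb_glm_wald(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    formula_terms: list[str],
    contrast: str | np.ndarray,
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature NB GLM with a Wald test on one contrast.

    ``contrast`` is either a design-matrix column name or a vector over the
    design columns; estimates are reported as log2 fold changes with 95% CIs,
    Wald P and BH q. All-zero features are reported NA.
    """
    design = design.loc[list(counts.columns)]
    x, names, _ = model_matrix(design, formula_terms)
    _check_design(x, names)
    if isinstance(contrast, str):
        if contrast not in names:
            raise ValueError(f"contrast {contrast!r} not among columns {names}")
        cvec = np.zeros(x.shape[1])
        cvec[names.index(contrast)] = 1.0
    else:
        cvec = np.asarray(contrast, float)
        if cvec.shape != (x.shape[1],):
            raise ValueError("contrast vector length mismatch")
    if sf is None:
        sf = size_factors(counts, mode="median_ratio")
    offset = np.log(sf.loc[counts.columns].to_numpy(float))

    out = np.full((len(counts), 4), np.nan)  # lfc, se, p, alpha
    arr = counts.to_numpy(float)
    for i in range(len(counts)):
        y = arr[i]
        if y.sum() == 0:
            continue
        fit = _fit_feature(y, x, offset)
        if fit is None:
            continue
        params, cov, alpha = fit
        est = float(cvec @ params) / _LN2
        se = float(np.sqrt(cvec @ cov @ cvec)) / _LN2
        z = est / se if se > 0 else np.nan
        out[i] = est, se, 2 * stats.norm.sf(abs(z)), alpha

    res = pd.DataFrame(
        out, index=counts.index, columns=["log2fc", "se", "p", "dispersion"]
    )
    res["ci_lo"] = res["log2fc"] - Z95 * res["se"]
    res["ci_hi"] = res["log2fc"] + Z95 * res["se"]
    ok = res["p"].notna()
    res["q"] = np.nan
    if ok.any():
        res.loc[ok, "q"] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
    res.attrs["size_factors"] = sf
    return res[["log2fc", "se", "ci_lo", "ci_hi", "p", "q", "dispersion"]]


def drought_response_by_legacy(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    legacy_col: str = "legacy",
    water_col: str = "test_water",
    drought_level: str = "drought",
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Group-specific drought log2FCs from the interaction model.

    Fits counts ~ legacy * test_water per feature and extracts the drought
    (vs control) contrast separately for dry-legacy and wet-legacy samples,
    each with its own standard error and 95% CI on the log2 scale.
    """
    design = design.loc[list(counts.columns)]
    for col in (legacy_col, water_col):
        if design[col].nunique() != 2:
            raise ValueError(f"{col!r} must have exactly 2 levels")
    cells = design.groupby([legacy_col, water_col]).size()
    if len(cells) < 4:
        raise ValueError("empty legacy x water cell")
    x, names, _ = model_matrix(design, [f"{legacy_col}*{water_col}"])
    _check_design(x, names)
    # columns: Intercept, legacy[second], water[second], interaction
    water_levels = sorted(design[water_col].astype(str).unique())
    legacy_levels = sorted(design[legacy_col].astype(str).unique())
    sign = 1.0 if water_levels[1] == drought_level else -1.0
    # contrast for the reference legacy level and the second legacy level
    c_ref = np.array([0.0, 0.0, 1.0, 0.0]) * sign
    c_alt = np.array([0.0, 0.0, 1.0, 1.0]) * sign
    by_legacy = {legacy_levels[0]: c_ref, legacy_levels[1]: c_alt}
    if sf is None:
        sf = size_factors(counts, mode="median_ratio")
    offset = np.log(sf.loc[counts.columns].to_numpy(float))

    cols = {}
    for lab in ("dry", "wet"):
        cols[lab] = np.full((len(counts), 2), np.nan)  # lfc, se
    arr = counts.to_numpy(float)
    for i in range(len(counts)):
        y = arr[i]
        if y.sum() == 0:
            continue
        fit = _fit_feature(y, x, offset)
        if fit is None:
            continue
        params, cov, _ = fit
        for lab in ("dry", "wet"):
            c = by_legacy[lab]
            cols[lab][i, 0] = float(c @ params) / _LN2
            cols[lab][i, 1] = float(np.sqrt(c @ cov @ c)) / _LN2
    res = pd.DataFrame(index=counts.index)
    for lab in ("dry", "wet"):
        res[f"lfc_{lab}"] = cols[lab][:, 0]
        res[f"se_{lab}"] = cols[lab][:, 1]
        res[f"ci_lo_{lab}"] = res[f"lfc_{lab}"] - Z95 * res[f"se_{lab}"]
        res[f"ci_hi_{lab}"] = res[f"lfc_{lab}"] + Z95 * res[f"se_{lab}"]
    return res


# ------------------------------------------------------------- classifier


@dataclass
class InteractionCall:
    feature_id: str
    lfc_dry: float
    ci_dry: tuple[float, float]
    lfc_wet: float
    ci_wet: tuple[float, float]
    interacting: bool
    gene_set: str


def _classify_one(
    ci_dry: tuple[float, float], ci_wet: tuple[float, float]
) -> tuple[bool, str]:
    lo_d, hi_d = ci_dry
    lo_w, hi_w = ci_wet
    if not all(np.isfinite([lo_d, hi_d, lo_w, hi_w])):
        raise ValueError("non-finite CI")
    interacting = max(lo_d, lo_w) > min(hi_d, hi_w)
    if not interacting:
        return False, "none"
    dry_null = lo_d <= 0 <= hi_d
    wet_null = lo_w <= 0 <= hi_w
    if dry_null and not wet_null:
        return True, "I" if hi_w < 0 else "II"
    if wet_null and not dry_null:
        return True, "III" if hi_d < 0 else "IV"
    dry_sign = 1 if lo_d > 0 else -1
    wet_sign = 1 if lo_w > 0 else -1
    return True, "V" if dry_sign == wet_sign else "VI"


def classify_interaction(responses: pd.DataFrame) -> pd.DataFrame:
    """Apply the CI-non-overlap rule to the per-legacy drought responses.

    Input is the output of :func:`drought_response_by_legacy`; rows with any
    missing CI are labelled NA (not classified). A group is "null" when its
    CI contains 0; the sign pattern of the two CIs assigns gene sets I-VI.
    """
    interacting = []
    gene_set = []
    for _, row in responses.iterrows():
        vals = row[["ci_lo_dry", "ci_hi_dry", "ci_lo_wet", "ci_hi_wet"]].to_numpy(float)
        if not np.isfinite(vals).all():
            interacting.append(False)
            gene_set.append("NA")
            continue
        flag, lab = _classify_one((vals[0], vals[1]), (vals[2], vals[3]))
        interacting.append(flag)
        gene_set.append(lab)
    out = responses.copy()
    out["interacting"] = interacting
    out["gene_set"] = gene_set
    return out


def call_enriched(
    de: pd.DataFrame, q_max: float = 0.05, min_abs_lfc: float = 2.0
) -> pd.Index:
    """Features with q < q_max and |log2FC| > min_abs_lfc."""
    mask = (de["q"] < q_max) & (de["log2fc"].abs() > min_abs_lfc)
    return de.index[mask.fillna(False)]


def clr_interaction_lm(
    asv_counts: pd.DataFrame,
    design: pd.DataFrame,
    pseudocount: float = 0.5,
    legacy_col: str = "legacy",
    water_col: str = "test_water",
) -> pd.DataFrame:
    """Per-ASV linear model on CLR abundances with an interaction F test.

    CLR-transforms counts per sample, fits abundance ~ legacy * test_water
    per ASV by OLS, tests the interaction term with a partial F test and BH
    adjusts across ASVs. Constant CLR vectors are reported NA.
    """
    design = design.loc[list(asv_counts.columns)]
    for col in (legacy_col, water_col):
        if design[col].nunique() != 2:
            raise ValueError(f"{col!r} must have exactly 2 levels")
    clr = clr_transform(asv_counts.T, pseudocount=pseudocount).T
    x_full, names, _ = model_matrix(design, [f"{legacy_col}*{water_col}"])
    x_red = x_full[:, :3]
    _check_design(x_full, names)
    n = x_full.shape[0]
    pvals = np.full(len(clr), np.nan)
    fstats = np.full(len(clr), np.nan)
    arr = clr.to_numpy(float)
    h_full = np.linalg.pinv(x_full)
    h_red = np.linalg.pinv(x_red)
    for i in range(len(clr)):
        y = arr[i]
        if np.std(y) == 0:
            continue
        rss_full = float(((y - x_full @ (h_full @ y)) ** 2).sum())
        rss_red = float(((y - x_red @ (h_red @ y)) ** 2).sum())
        df_res = n - x_full.shape[1]
        f = (rss_red - rss_full) / (rss_full / df_res)
        fstats[i] = f
        pvals[i] = stats.f.sf(f, 1, df_res)
    res = pd.DataFrame({"F": fstats, "p": pvals}, index=clr.index)
    ok = res["p"].notna()
    res["q"] = np.nan
    if ok.any():
        res.loc[ok, "q"] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
    return res
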