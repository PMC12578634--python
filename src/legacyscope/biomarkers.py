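"""Marker-taxon identification along a precipitation gradient.

Candidate taxa pass abundance/prevalence filters; the per-taxon counts are
then modelled against standardized precipitation while adjusting for soil
porosity and the leading principal components of the z-scored elemental
profile. Five candidate models compete by AIC: Poisson, negative binomial,
zero-inflated Poisson, zero-inflated negative binomial and a Gaussian linear
regression. The precipitation term of the AIC-best converged model is tested
by likelihood ratio (count models) or partial F (linear model), and P values
are Benjamini-Hochberg adjusted across taxa.

The porosity / elemental-PC adjustment enters the linear predictor as free
covariates by default; ``adjustment='offset'`` instead reads the published
formula notation literally, summing the z-scored covariates into the linear
predictor with a fixed coefficient of 1. The literal reading is retained for
fidelity but is statistically aggressive (each offset term contributes a
full standard deviation of extraneous variation), so the estimable
free-covariate form is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.discrete.count_model import (
    ZeroInflatedNegativeBinomialP,
    ZeroInflatedPoisson,
)
from statsmodels.discrete.discrete_model import NegativeBinomial
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceTable, ElementalProfile
from .ecostats import zscore

__all__ = [
    "select_candidates",
    "elemental_pcs",
    "fit_marker_models",
    "marker_scan",
    "env_correlation",
    "MarkerCall",
]

MODELS = ("poisson", "negbin", "zip", "zinb", "linear")


def select_candidates(
    table: AbundanceTable,
    min_rel_abund: float = 0.01,
    min_prevalence: float = 0.20,
) -> list[str]:
    """Taxa with mean relative abundance > threshold and prevalence > threshold."""
    if table.counts.empty:
        raise ValueError("empty abundance table")
    if not (0 <= min_rel_abund <= 1 and 0 <= min_prevalence <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    rel = table.relative_abundance()
    mean_rel = rel.mean(axis=1)
    prev = (table.counts > 0).mean(axis=1)
    keep = (mean_rel > min_rel_abund) & (prev > min_prevalence)
    return table.counts.index[keep].tolist()


def elemental_pcs(profile: ElementalProfile, var_threshold: float = 0.8) -> pd.DataFrame:
    """Scores on the leading PCs of the z-scored elemental profile.

    Returns the smallest number of components whose cumulative variance
    fraction strictly exceeds ``var_threshold`` (at least one).
    """
    z = zscore(profile.concentrations, axis=0, on_constant="drop")
    if z.shape[1] < 2:
        raise ValueError("need >= 2 elements with positive variance")
    arr = z.to_numpy(float)
    u, s, _ = np.linalg.svd(arr - arr.mean(axis=0), full_matrices=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    m = int(np.searchsorted(frac, var_threshold, side="right")) + 1
    m = min(m, len(s))
    scores = u[:, :m] * s[:m]
    return pd.DataFrame(
        scores, index=profile.concentrations.index,
        columns=[f"PC{i + 1}" for i in range(m)],
    )


@dataclass
class MarkerCall:
    """Per-taxon result of the five-model selection procedure."""

    taxon_id: str
    chosen_model: str | None
    coef: float = np.nan  # precipitation coefficient of the chosen model
    se: float = np.nan
    p: float = np.nan
    q: float = np.nan
    aic: dict[str, float] = field(default_factory=dict)
    unfit: bool = False
    mean_z_abund: dict[str, float] = field(default_factory=dict)


def _adjustment(
    porosity: np.ndarray, pcs: np.ndarray, mode: str
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """(offset, free-covariate block) for the requested adjustment mode."""
    zp = (porosity - porosity.mean()) / porosity.std(ddof=1)
    zc = (pcs - pcs.mean(axis=0)) / pcs.std(axis=0, ddof=1)
    if mode == "offset":
        return zp + zc.sum(axis=1), None
    if mode == "covariate":
        return None, np.column_stack([zp, zc])
    raise ValueError(f"unknown adjustment mode {mode!r}")


def fit_marker_models(
    y: np.ndarray,
    precip_z: np.ndarray,
    porosity: np.ndarray,
    pcs: np.ndarray,
    adjustment: str = "covariate",
    maxiter: int = 200,
    taxon_id: str = "",
) -> MarkerCall:
    """Fit the five candidate models and test the precipitation term.

    The AIC-minimal converged candidate is chosen; its precipitation term is
    tested by a likelihood-ratio chi-square (count models) or the partial
    regression F test (linear model). A taxon where no candidate converges is
    flagged ``unfit`` rather than dropped.
    """
    y = np.asarray(y, float)
    if (y < 0).any():
        raise ValueError("negative counts")
    if not (np.isfinite(precip_z).all() and np.isfinite(porosity).all()
            and np.isfinite(pcs).all()):
        raise ValueError("non-finite covariates")
    offset, covs = _adjustment(np.asarray(porosity, float), np.asarray(pcs, float),
                               adjustment)
    ones = np.ones_like(y)
    x1 = np.column_stack([ones, precip_z])
    x0 = ones[:, None]
    if covs is not None:
        x1 = np.column_stack([x1, covs])
        x0 = np.column_stack([x0, covs])
    infl1 = ones[:, None] if covs is None else np.column_stack([ones, covs])

    fits: dict[str, tuple[float, float, float, float, float]] = {}
    # per model: (aic, coef, se, llf_full, llf_reduced)

    def try_fit(name, full_fn, red_fn):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                full = full_fn()
                red = red_fn()
                conv = getattr(full, "mle_retvals", {}).get("converged", True)
                if not (conv and np.isfinite(full.aic)):
                    return
                idx = 1  # precipitation column in the count/linear design
                fits[name] = (
                    float(full.aic), float(full.params[idx]),
                    float(np.sqrt(np.asarray(full.cov_params())[idx, idx])),
                    float(full.llf), float(red.llf),
                )
            except (ValueError, np.linalg.LinAlgError, IndexError):
                return

    kw = dict(disp=0, maxiter=maxiter)
    try_fit(
        "poisson",
        lambda: sm.Poisson(y, x1, offset=offset).fit(**kw),
        lambda: sm.Poisson(y, x0, offset=offset).fit(**kw),
    )
    try_fit(
        "negbin",
        lambda: NegativeBinomial(y, x1, offset=offset).fit(**kw),
        lambda: NegativeBinomial(y, x0, offset=offset).fit(**kw),
    )
    try_fit(
        "zip",
        lambda: ZeroInflatedPoisson(y, x1, exog_infl=ones[:, None], offset=offset)
        .fit(**kw),
        lambda: ZeroInflatedPoisson(y, x0, exog_infl=ones[:, None], offset=offset)
        .fit(**kw),
    )
    try_fit(
        "zinb",
        lambda: ZeroInflatedNegativeBinomialP(y, x1, exog_infl=infl1, offset=offset)
        .fit(**kw),
        lambda: ZeroInflatedNegativeBinomialP(y, x0, exog_infl=infl1, offset=offset)
        .fit(**kw),
    )
    # linear regression of counts; porosity/elements always free covariates here
    xl1 = np.column_stack([ones, precip_z, porosity,
                           np.asarray(pcs, float)])
    xl0 = np.column_stack([ones, porosity, np.asarray(pcs, float)])
    try:
        ols1 = sm.OLS(y, xl1).fit()
        ols0 = sm.OLS(y, xl0).fit()
        fits["linear"] = (float(ols1.aic), float(ols1.params[1]),
                          float(ols1.bse[1]), float(ols1.llf), float(ols0.llf))
    except (ValueError, np.linalg.LinAlgError):
        pass

    call = MarkerCall(taxon_id=taxon_id, chosen_model=None,
                      aic={k: v[0] for k, v in fits.items()})
    if not fits:
        call.unfit = True
        return call
    best = min(fits, key=lambda k: fits[k][0])
    aic, coef, se, llf1, llf0 = fits[best]
    if best == "linear":
        n = len(y)
        df_res = n - xl1.shape[1]
        tstat = coef / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(tstat), df_res)
    else:
        lr = max(2.0 * (llf1 - llf0), 0.0)
        p = stats.chi2.sf(lr, df=1)
    call.chosen_model = best
    call.coef, call.se, call.p = coef, se, float(p)
    return call


def marker_scan(
    table: AbundanceTable,
    profile: ElementalProfile,
    precip: pd.Series,
    porosity: pd.Series,
    min_rel_abund: float = 0.01,
    min_prevalence: float = 0.20,
    var_threshold: float = 0.8,
    adjustment: str = "covariate",
    legacy: pd.Series | None = None,
) -> pd.DataFrame:
    """Full marker procedure: filter, adjust, fit, select, BH-correct."""
    candidates = select_candidates(table, min_rel_abund, min_prevalence)
    pcs = elemental_pcs(profile, var_threshold)
    samples = list(table.counts.columns)
    pcs = pcs.loc[samples]
    pz = precip.loc[samples].to_numpy(float)
    pz = (pz - pz.mean()) / pz.std(ddof=1)
    por = porosity.loc[samples].to_numpy(float)
    rel = table.relative_abundance()

    rows = []
    for taxon in candidates:
        call = fit_marker_models(
            table.counts.loc[taxon].to_numpy(float), pz, por,
            pcs.to_numpy(float), adjustment=adjustment, taxon_id=taxon,
        )
        row = {
            "taxon_id": taxon, "chosen_model": call.chosen_model,
            "coef": call.coef, "se": call.se, "p": call.p, "unfit": call.unfit,
        }
        for m in MODELS:
            row[f"aic_{m}"] = call.aic.get(m, np.nan)
        if legacy is not None:
            zrel = (rel.loc[taxon] - rel.loc[taxon].mean()) / rel.loc[taxon].std(ddof=1)
            for lev in sorted(legacy.astype(str).unique()):
                row[f"mean_z_{lev}"] = float(zrel[legacy.astype(str) == lev].mean())
        rows.append(row)
    res = pd.DataFrame(rows).set_index("taxon_id")
    ok = res["p"].notna() & ~res["unfit"]
    res["q"] = np.nan
    if ok.any():
        res.loc[ok, "q"] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
    return res


def env_correlation(rel_abund: pd.DataFrame, precip: pd.Series) -> pd.DataFrame:
    """Per-taxon Pearson correlation with precipitation, two-tailed P, BH q.

    ``rel_abund`` is taxa x samples. Constant abundance vectors have
    undefined r and are flagged NA.
    """
    x = precip.loc[rel_abund.columns].to_numpy(float)
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 samples")
    arr = rel_abund.to_numpy(float)
    xc = x - x.mean()
    yc = arr - arr.mean(axis=1, keepdims=True)
    sy = np.sqrt((yc**2).sum(axis=1))
    sx = np.sqrt((xc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / (sy * sx)
    r = np.where(sy == 0, np.nan, r)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    res = pd.DataFrame({"r": r, "p": p}, index=rel_abund.index)
    ok = res["p"].notna()
    res["q"] = np.nan
    if ok.any():
        res.loc[ok, "q"] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
    return res
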