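"""Drought-susceptibility (S-index) scoring and legacy-effect estimation.

The S-index scales a droughted plant's trait value by the mean of matched
well-watered controls, S = trait_drought / mean(trait_control); S = 1 means
the droughted plant is phenotypically indistinguishable from controls.
Trait selection uses a seeded random-forest classifier of legacy with
permutation importance, pruning correlated traits (|r| >= 0.7 keeps the
higher-ranked one). Legacy effects on S are estimated by a random-intercept
model over conditioning groups, falling back to a fixed-effects model when
the random-effect variance is singular.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .containers import OrdinationResult, TraitTable
from .ecostats import partial_constrained_ordination, zscore

__all__ = [
    "iwue",
    "s_index",
    "flag_outliers",
    "select_top_traits",
    "legacy_effect_model",
    "trait_rda",
    "LegacyEffect",
]

log = logging.getLogger(__name__)


def iwue(a_rate, gs):
    """Intrinsic water-use efficiency A / gs.

    A in umol m-2 s-1, gs in mol m-2 s-1; the ratio is in umol mol-1.
    """
    a_rate = np.asarray(a_rate, float)
    gs = np.asarray(gs, float)
    if (gs <= 0).any():
        raise ValueError("stomatal conductance must be > 0")
    out = a_rate / gs
    return float(out) if out.ndim == 0 else out


def s_index(
    traits: TraitTable,
    control_grouping: list[str] | None = None,
    water_col: str = "test_water",
    drought_level: str = "drought",
    control_level: str = "control",
) -> TraitTable:
    """S-index per droughted plant and trait, against matched control means.

    ``control_grouping`` names the factor columns whose joint levels define
    the matched control group (default inoculum legacy x conditioning group).
    A control group with mean 0 for a trait yields NA for that trait with a
    warning; a droughted plant whose group has no controls is an error.
    """
    if control_grouping is None:
        control_grouping = [c for c in ("legacy", "cond_group")
                            if c in traits.factor_cols]
    data = traits.data
    is_drought = data[water_col].astype(str) == drought_level
    is_control = data[water_col].astype(str) == control_level
    if not is_drought.any():
        raise ValueError("no droughted plants")
    key = data[control_grouping].astype(str).agg("|".join, axis=1)
    ctrl_means = (
        data.loc[is_control, traits.trait_cols]
        .groupby(key[is_control])
        .mean()
    )
    missing = sorted(set(key[is_drought]) - set(ctrl_means.index))
    if missing:
        raise ValueError(f"no control plants for groups: {missing}")
    denom = ctrl_means.reindex(key[is_drought]).to_numpy(float)
    zero = denom == 0
    if zero.any():
        warnings.warn("control mean 0: S-index set NA", stacklevel=2)
        denom = np.where(zero, np.nan, denom)
    s_vals = data.loc[is_drought, traits.trait_cols].to_numpy(float) / denom
    out = data.loc[is_drought, traits.factor_cols].copy()
    for j, name in enumerate(traits.trait_cols):
        out[name] = s_vals[:, j]
    return TraitTable(data=out, factor_cols=list(traits.factor_cols))


def flag_outliers(values: pd.DataFrame, k: float = 3.0) -> pd.DataFrame:
    """Boolean mask of values beyond k x IQR outside the quartiles, per trait.

    An automated stand-in for per-trait visual outlier screening; flagged
    values can be masked via config before modelling.
    """
    q1 = values.quantile(0.25)
    q3 = values.quantile(0.75)
    iqr = q3 - q1
    lo = q1 - k * iqr
    hi = q3 + k * iqr
    return (values < lo) | (values > hi)


def select_top_traits(
    s: TraitTable,
    label_col: str = "legacy",
    k: int = 10,
    r_max: float = 0.7,
    seed: int = 0,
    n_estimators: int = 500,
    n_repeats: int = 10,
) -> list[str]:
    """Seeded ensemble-importance ranking of traits, pruned for collinearity.

    A random-forest classifier of ``label_col`` from the S-profiles is scored
    by permutation importance; the top ``k`` traits are kept and, within any
    pair with |Pearson r| >= ``r_max``, the lower-ranked trait is dropped.
    Rows with missing values are dropped (logged).
    """
    if k > len(s.trait_cols):
        raise ValueError("k exceeds number of traits")
    frame = s.data[[label_col] + s.trait_cols]
    complete = frame.dropna()
    n_dropped = len(frame) - len(complete)
    if n_dropped:
        log.info("dropped %d incomplete rows before ranking", n_dropped)
    y = complete[label_col].astype(str)
    if y.value_counts().min() < 2 or y.nunique() < 2:
        raise ValueError("need >= 2 plants per legacy level")
    xmat = complete[s.trait_cols]
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(xmat, y)
    imp = permutation_importance(
        rf, xmat, y, n_repeats=n_repeats, random_state=seed
    ).importances_mean
    order = np.argsort(-imp, kind="stable")
    ranked = [s.trait_cols[i] for i in order[:k]]
    survivors: list[str] = []
    for trait in ranked:
        collinear = any(
            abs(xmat[trait].corr(xmat[kept])) >= r_max for kept in survivors
        )
        if not collinear:
            survivors.append(trait)
    return survivors


@dataclass
class LegacyEffect:
    estimate: float  # legacy contrast on the (possibly transformed) S scale
    se: float
    ci: tuple[float, float]
    p: float
    group_means: pd.DataFrame  # legacy level -> mean, ci_lo, ci_hi
    model: str  # "mixed" or "fixed"
    transform: str


_TRANSFORMS = {
    "identity": lambda v: v,
    "sqrt": np.sqrt,
    "log": np.log,
    "exp": np.exp,
}


def _pick_transform(s_vals: np.ndarray, resid_fn) -> str:
    best, best_w = "identity", -np.inf
    for name, fn in _TRANSFORMS.items():
        if name in ("sqrt", "log") and (s_vals <= 0).any():
            continue
        if name == "exp" and s_vals.max() > 50:
            continue
        resid = resid_fn(fn(s_vals))
        if resid is None:
            continue
        w = stats.shapiro(resid).statistic if 3 <= len(resid) <= 5000 else -np.inf
        if w > best_w:
            best, best_w = name, w
    return best


def legacy_effect_model(
    s_values: pd.Series | np.ndarray,
    legacy: pd.Series,
    cond_group: pd.Series,
    transform: str = "identity",
) -> LegacyEffect:
    """Legacy contrast on S with a conditioning-group random intercept.

    Fits S ~ legacy + (1 | cond_group); when the random-effect variance is
    singular (~0) or the fit fails, refits the fixed-effects model
    S ~ legacy + cond_group. Group means are adjusted means averaged with
    equal weight over conditioning groups. ``transform='auto'`` picks the
    response transform (identity/sqrt/log/exp) with the most normal
    residuals.
    """
    y = np.asarray(s_values, float)
    leg = pd.Series(legacy).astype(str).reset_index(drop=True)
    cg = pd.Series(cond_group).astype(str).reset_index(drop=True)
    levels = sorted(leg.unique())
    if len(levels) != 2:
        raise ValueError("both legacy levels must be present")
    keep = np.isfinite(y)
    y, leg, cg = y[keep], leg[keep.nonzero()[0]].reset_index(drop=True), \
        cg[keep.nonzero()[0]].reset_index(drop=True)

    if transform == "auto":
        def resid_fn(v):
            try:
                df0 = pd.DataFrame({"s": v, "legacy": leg, "cg": cg})
                return smf.ols("s ~ C(legacy) + C(cg)", df0).fit().resid
            except (ValueError, np.linalg.LinAlgError):
                return None
        transform = _pick_transform(y, resid_fn)
    y = _TRANSFORMS[transform](y)

    frame = pd.DataFrame({"s": y, "legacy": leg, "cg": cg})
    mixed_ok = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mm = smf.mixedlm("s ~ C(legacy)", frame, groups=frame["cg"]).fit(reml=True)
            re_var = float(np.asarray(mm.cov_re)[0, 0])
            total_var = re_var + float(mm.scale)
            # a (near-)boundary variance estimate signals overfitting of the
            # random intercept; below 5% ICC the fixed-effects refit is used
            mixed_ok = mm.converged and re_var > 0.05 * total_var
        except (ValueError, np.linalg.LinAlgError):
            mixed_ok = False

    cg_levels = sorted(cg.unique())
    if mixed_ok:
        params = mm.params
        contrast = float(params[f"C(legacy)[T.{levels[1]}]"])
        se = float(mm.bse[f"C(legacy)[T.{levels[1]}]"])
        df_res = len(y) - 3
        base = float(params["Intercept"])
        model_name = "mixed"
        se_base = float(mm.bse["Intercept"])
    else:
        ols = smf.ols("s ~ C(legacy) + C(cg)", frame).fit()
        contrast = float(ols.params[f"C(legacy)[T.{levels[1]}]"])
        se = float(ols.bse[f"C(legacy)[T.{levels[1]}]"])
        df_res = int(ols.df_resid)
        cg_coefs = [float(ols.params.get(f"C(cg)[T.{lv}]", 0.0)) for lv in cg_levels]
        base = float(ols.params["Intercept"]) + float(np.mean(cg_coefs))
        model_name = "fixed"
        se_base = float(ols.bse["Intercept"])
    tcrit = stats.t.ppf(0.975, df_res)
    p = 2 * stats.t.sf(abs(contrast / se), df_res) if se > 0 else np.nan
    gm = pd.DataFrame({
        "mean": [base, base + contrast],
        "ci_lo": [base - tcrit * se_base, base + contrast - tcrit * np.hypot(se_base, se)],
        "ci_hi": [base + tcrit * se_base, base + contrast + tcrit * np.hypot(se_base, se)],
    }, index=pd.Index(levels, name="legacy"))
    return LegacyEffect(
        estimate=contrast, se=se, ci=(contrast - tcrit * se, contrast + tcrit * se),
        p=float(p), group_means=gm, model=model_name, transform=transform,
    )


def trait_rda(
    s: TraitTable,
    top_traits: list[str],
    legacy_col: str = "legacy",
    cond_col: str = "cond_group",
    n_perm: int = 999,
    seed: int = 0,
) -> OrdinationResult:
    """Redundancy analysis of z-scored top traits on legacy, conditioning out
    the conditioning group (Top_traits ~ legacy + Condition(cond_group))."""
    frame = s.data[[legacy_col, cond_col] + list(top_traits)].dropna()
    resp = zscore(frame[list(top_traits)], axis=0)
    constraints = frame[[legacy_col]]
    conditions = frame[[cond_col]]
    if conditions[cond_col].nunique() < 2:
        conditions = None
    return partial_constrained_ordination(
        resp, constraints, conditions, n_perm=n_perm, seed=seed
    )
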