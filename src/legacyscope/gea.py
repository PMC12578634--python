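"""Strain-level genetic structure and genotype-environment association.

Metagenome-derived genotypes are per-sample alternate-allele dosages in
[0, 1] at biallelic SNPs. The module filters variants on quality, minor
allele frequency, missingness and per-call depth; embeds samples by
allele-sharing distance and classical MDS; scans for SNPs whose dosage
tracks the precipitation gradient (correcting for genetic structure with
the leading genotype PCs and controlling family-wise error with a max-|t|
permutation threshold); and quantifies differentiation with Hudson FST and
a distance-based AMOVA Phi-statistic.
"""

from __future__ import annotations

import itertools
import warnings
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, OrdinationResult
from .ecostats import pcoa

__all__ = [
    "filter_variants",
    "genetic_mds",
    "gea_scan",
    "differentiation_stats",
    "write_vcf",
    "read_vcf",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- filtering


def filter_variants(
    g: GenotypeMatrix,
    qual_min: float = 20.0,
    maf_min: float = 0.01,
    miss_max: float = 0.5,
    depth_min: int = 10,
) -> GenotypeMatrix:
    """Apply the standard SNP filters.

    Calls with depth below ``depth_min`` are masked missing first; SNPs are
    then kept when QUAL > qual_min, minor allele frequency > maf_min over
    non-missing calls and the missing fraction < miss_max. The depth bound is
    inclusive (DP == depth_min is retained).
    """
    dosage = g.dosage.to_numpy(float).copy()
    dp = g.dp.to_numpy(float)
    dosage[dp < depth_min] = np.nan
    n_obs = np.sum(~np.isnan(dosage), axis=1)
    miss_frac = 1.0 - n_obs / dosage.shape[1]
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing SNPs
        freq = np.nanmean(dosage, axis=1)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (
        (g.qual.to_numpy(float) > qual_min)
        & (miss_frac < miss_max)
        & (n_obs > 0)
        & (maf > maf_min)
    )
    if not keep.any():
        log.warning("all SNPs removed by filters")
    idx = g.dosage.index[keep]
    return GenotypeMatrix(
        dosage=pd.DataFrame(dosage[keep], index=idx, columns=g.dosage.columns),
        dp=g.dp.loc[idx],
        qual=g.qual.loc[idx],
        chrom=g.chrom.loc[idx],
        pos=g.pos.loc[idx],
        env=g.env,
    )


# -------------------------------------------------------------- distances


def allele_sharing_distance(g: GenotypeMatrix) -> pd.DataFrame:
    """Mean |dosage_i - dosage_j| over SNPs observed in both samples."""
    arr = g.dosage.to_numpy(float)
    obs = ~np.isnan(arr)
    filled = np.nan_to_num(arr)
    n = arr.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        both = obs[:, i][:, None] & obs[:, i + 1:]
        counts = both.sum(axis=0)
        if (counts == 0).any():
            j = i + 1 + int(np.argmax(counts == 0))
            raise ValueError(
                f"samples {g.sample_ids[i]!r} and {g.sample_ids[j]!r} share no "
                "observed SNPs"
            )
        diff = np.abs(filled[:, i][:, None] - filled[:, i + 1:]) * both
        d[i, i + 1:] = d[i + 1:, i] = diff.sum(axis=0) / counts
    return pd.DataFrame(d, index=g.sample_ids, columns=g.sample_ids)


def genetic_mds(g: GenotypeMatrix, k: int = 2) -> OrdinationResult:
    """Classical MDS (PCoA) of the allele-sharing distance matrix."""
    if len(g.sample_ids) < k + 2:
        raise ValueError("need at least k + 2 samples")
    return pcoa(allele_sharing_distance(g), k=k)


# ------------------------------------------------------------------- scan


def _impute_mean(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    means = np.nanmean(out, axis=1)
    nan_rows, nan_cols = np.nonzero(np.isnan(out))
    out[nan_rows, nan_cols] = means[nan_rows]
    return out


def gea_scan(
    g: GenotypeMatrix,
    env: pd.Series | None = None,
    n_pcs: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    fwer: float = 0.05,
    permute_by: pd.Series | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-SNP association with the environment, PC-corrected, with a
    permutation family-wise significance threshold.

    Missing dosages are mean-imputed per SNP; genotype is regressed on the
    environment with the leading ``n_pcs`` genotype PCs as covariates. The
    threshold is the (1 - fwer) quantile of the maximum |t| over ``n_perm``
    permutations of the environment vector. When ``permute_by`` gives a
    site/group label per sample (environment constant within groups),
    permutations shuffle the group-to-environment assignment instead of
    individual samples -- the exchangeable unit for a site-level gradient.
    Monomorphic SNPs are flagged (t = NaN) and excluded from the maximum.
    """
    env = g.env if env is None else env
    if env is None:
        raise ValueError("no environment values supplied")
    e = env.loc[g.sample_ids].to_numpy(float)
    if np.std(e) == 0:
        raise ValueError("environment is constant")
    n = len(e)
    if not n_pcs < n - 2:
        raise ValueError("n_pcs must be < n_samples - 2")
    x = _impute_mean(g.dosage.to_numpy(float))
    poly = x.std(axis=1) > 0
    xc = x - x.mean(axis=1, keepdims=True)
    # genotype PCs for structure correction
    u, s, _ = np.linalg.svd(xc.T, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]
    q, _ = np.linalg.qr(np.column_stack([np.ones(n), pcs]))
    proj = np.eye(n) - q @ q.T
    df = n - 2 - n_pcs

    gr = xc @ proj  # residualized genotypes (rows)
    gnorm = np.sqrt((gr**2).sum(axis=1))

    def tstats(evec: np.ndarray) -> np.ndarray:
        er = proj @ evec
        enorm = np.sqrt((er**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (gr @ er) / (gnorm * enorm)
            r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
            t = r * np.sqrt(df / (1 - r**2))
        t[~poly] = np.nan
        t[gnorm == 0] = np.nan
        return t

    t_obs = tstats(e)
    er = proj @ e
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (gr @ er) / (er @ er)
    beta[~poly] = np.nan
    p = 2 * stats.t.sf(np.abs(t_obs), df)

    rng = np.random.default_rng(seed)
    if permute_by is not None:
        labels = permute_by.loc[g.sample_ids].astype(str).to_numpy()
        groups = pd.unique(labels)
        group_env = np.array([e[labels == lab][0] for lab in groups])
        if any(np.ptp(e[labels == lab]) > 0 for lab in groups):
            raise ValueError("environment varies within a permutation group")
        member = [np.flatnonzero(labels == lab) for lab in groups]

        def draw_env() -> np.ndarray:
            shuffled = group_env[rng.permutation(len(groups))]
            out = np.empty(n)
            for val, idx in zip(shuffled, member):
                out[idx] = val
            return out
    else:
        def draw_env() -> np.ndarray:
            return e[rng.permutation(n)]

    max_t = np.empty(n_perm)
    for b in range(n_perm):
        tp = tstats(draw_env())
        max_t[b] = np.nanmax(np.abs(tp))
    threshold = float(np.quantile(max_t, 1.0 - fwer))

    res = pd.DataFrame({
        "beta": beta, "t": t_obs, "p": p,
        "significant": np.abs(t_obs) > threshold,
    }, index=g.dosage.index)
    return res, threshold


# --------------------------------------------------------- differentiation


def _hudson_components(
    dosage: np.ndarray, mask1: np.ndarray, mask2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(invalid="ignore"):
        p1 = np.nanmean(dosage[:, mask1], axis=1)
        p2 = np.nanmean(dosage[:, mask2], axis=1)
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def differentiation_stats(
    g: GenotypeMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Hudson FST and distance-based AMOVA Phi with a permutation P.

    FST per SNP uses the frequency form (p1 - p2)^2 / (p1(1-p2) + p2(1-p1)),
    appropriate for pooled per-sample allele frequencies; the global value is
    the ratio of averages. With more than two groups, pairwise numerators and
    denominators are averaged. Phi comes from the among/within decomposition
    of squared allele-sharing distances, with P by group-label permutation.
    """
    groups = groups.loc[g.sample_ids].astype(str)
    labels = sorted(groups.unique())
    counts = groups.value_counts()
    if len(labels) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    dosage = g.dosage.to_numpy(float)
    gl = groups.to_numpy()

    nums = np.zeros(len(dosage))
    dens = np.zeros(len(dosage))
    for a, b in itertools.combinations(labels, 2):
        num, den = _hudson_components(dosage, gl == a, gl == b)
        ok = np.isfinite(num) & np.isfinite(den)
        nums[ok] += num[ok]
        dens[ok] += den[ok]
    n_pairs = len(labels) * (len(labels) - 1) / 2
    nums /= n_pairs
    dens /= n_pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        fst_snp = np.where(dens > 0, nums / dens, np.nan)
    global_fst = float(nums.sum() / dens.sum()) if dens.sum() > 0 else np.nan

    d = allele_sharing_distance(g).to_numpy()
    n = d.shape[0]
    d2 = d**2

    def phi_stat(lab_arr: np.ndarray) -> float:
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        sizes = []
        for la in labels:
            m = lab_arr == la
            ng = int(m.sum())
            sizes.append(ng)
            sub = d2[np.ix_(m, m)]
            ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
        ss_among = ss_total - ss_within
        k = len(labels)
        df_a, df_w = k - 1, n - k
        ms_a, ms_w = ss_among / df_a, ss_within / df_w
        n0 = (n - sum(s**2 for s in sizes) / n) / df_a
        sigma_w = ms_w
        sigma_a = (ms_a - ms_w) / n0
        tot = sigma_a + sigma_w
        return sigma_a / tot if tot > 0 else 0.0

    phi = phi_stat(gl)
    rng = np.random.default_rng(seed)
    exceed = sum(
        phi_stat(gl[rng.permutation(n)]) >= phi - 1e-12 for _ in range(n_perm)
    )
    phi_p = (1.0 + exceed) / (1.0 + n_perm)
    return {
        "fst_per_snp": pd.Series(fst_snp, index=g.dosage.index, name="fst"),
        "fst_global": global_fst,
        "phi": float(phi),
        "phi_p": float(phi_p),
    }


# --------------------------------------------------------------------- VCF


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT:DP:AD fields.

    AD carries (ref, alt) read counts so that pooled-sample allele-frequency
    dosages round-trip exactly; GT is the dosage rounded to the nearest
    diploid call (0/0, 0/1, 1/1) and ./. for missing.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    for contig in pd.unique(g.chrom):
        lines.append(f"##contig=<ID={contig}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT"] + list(g.sample_ids)
    lines.append("\t".join(header))
    dosage = g.dosage.to_numpy(float)
    dp = g.dp.to_numpy(float)
    for i, snp in enumerate(g.snp_ids):
        cells = []
        for j in range(dosage.shape[1]):
            v = dosage[i, j]
            depth = int(dp[i, j])
            if np.isnan(v):
                cells.append(f"./.:{depth}:.,.")
                continue
            alt = int(round(v * depth))
            gt = "0/0" if v < 0.25 else ("0/1" if v < 0.75 else "1/1")
            cells.append(f"{gt}:{depth}:{depth - alt},{alt}")
        lines.append("\t".join([
            str(g.chrom.iloc[i]), str(int(g.pos.iloc[i])), snp, "A", "G",
            f"{float(g.qual.iloc[i]):.2f}", "PASS", ".", "GT:DP:AD", *cells,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, env: pd.Series | None = None) -> GenotypeMatrix:
    """Read a minimal VCF v4.2 into a GenotypeMatrix via cyvcf2.

    Dosage is AD-derived (alt / (ref + alt)) when AD is present, otherwise
    half the diploid GT allele count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, quals, dos_rows, dp_rows = [], [], [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        quals.append(var.QUAL if var.QUAL is not None else np.nan)
        ad = var.format("AD")
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        gt_dose = np.select([gt == 0, gt == 1, gt == 3], [0.0, 0.5, 1.0], np.nan)
        if ad is not None:
            ad = ad.astype(float)
            ad[ad < 0] = np.nan  # cyvcf2 encodes '.' as negative
            tot = ad.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                dose = np.where(tot > 0, ad[:, 1] / tot, np.nan)
            dose = np.where(np.isnan(dose), gt_dose, dose)
        else:
            dose = gt_dose
        dos_rows.append(dose)
        dp = var.format("DP")
        dp_rows.append(
            dp.astype(float).ravel() if dp is not None else np.full(len(samples), np.nan)
        )
    idx = pd.Index(ids, name="snp_id")
    return GenotypeMatrix(
        dosage=pd.DataFrame(np.array(dos_rows), index=idx, columns=samples),
        dp=pd.DataFrame(np.array(dp_rows), index=idx, columns=samples),
        qual=pd.Series(quals, index=idx, name="qual"),
        chrom=pd.Series(chroms, index=idx, name="chrom"),
        pos=pd.Series(poss, index=idx, name="pos"),
        env=env,
    )
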