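"""Synthetic study generator with recorded ground truth.

Every input the pipeline consumes is generated here under a single global
seed: a 6-site precipitation gradient with a factorial conditioning/test
design, legacy-structured taxon counts, drifting ICP-MS runs, negative-
binomial expression counts with legacy x drought structure, legacy-shifted
plant traits and precipitation-associated SNPs. Each generator returns the
data plus a :class:`~legacyscope.containers.Truth` record of the planted
parameters, so downstream stages are testable by parameter recovery.

Counts use the NB2 parameterization: Var = mu + alpha * mu**2, matching the
negative-binomial GLMs fit downstream. The defaults emulate a modest but
realistic experiment; the generators make no attempt to simulate sequence
reads, amplification bias or phylogenetic structure.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from ._streams import child_rng
from .containers import (
    AbundanceTable,
    ElementalRun,
    ExpressionMatrix,
    GenotypeMatrix,
    StudyDesign,
    TraitTable,
    Truth,
)

__all__ = [
    "gen_design",
    "gen_community",
    "gen_expression",
    "gen_traits",
    "gen_icpms_run",
    "gen_genotypes",
    "GENE_SET_LABELS",
]

#: drought log2FC pattern per gene set, as (dry multiplier, wet multiplier)
#: of the planted |lfc|. I/II: response only with wet-legacy inoculum
#: (down/up); III/IV: response only with dry-legacy inoculum (down/up);
#: V: same sign, different magnitude; VI: reversed sign between legacies.
GENE_SET_LABELS: dict[str, tuple[float, float]] = {
    "I": (0.0, -1.0),
    "II": (0.0, 1.0),
    "III": (-1.0, 0.0),
    "IV": (1.0, 0.0),
    "V": (1.0, 0.25),
    "VI": (1.0, -1.0),
}

_FACTORIAL = list(itertools.product(
    ("drought", "watered"), ("plant", "none"), ("drought", "control")
))


def gen_design(
    n_sites: int = 6,
    n_reps: int = 8,
    precip_range: tuple[float, float] = (400.0, 1000.0),
    seed: int = 0,
) -> StudyDesign:
    """Evenly spaced sites with a balanced factorial sample sheet.

    ``n_reps`` samples per site cycle through the 8 factorial combinations of
    conditioning water x conditioning host x test water, so treatments are
    balanced within site up to the remainder. Legacy is the bottom/top half of
    the precipitation ranks. Porosity increases mildly with precipitation.
    """
    if n_sites < 2 or n_sites % 2:
        raise ValueError("n_sites must be even and >= 2 (legacy split undefined otherwise)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    lo, hi = precip_range
    precip = np.linspace(lo, hi, n_sites)
    sites = pd.DataFrame({
        "site_id": [f"S{i + 1:02d}" for i in range(n_sites)],
        "mean_annual_precip": precip,
    })
    legacy = np.where(np.arange(n_sites) < n_sites / 2, "dry", "wet")
    rng = child_rng(seed, "design")
    z = (precip - precip.mean()) / precip.std(ddof=1)
    rows = []
    for i, site in sites.iterrows():
        for r in range(n_reps):
            cw, ch, tw = _FACTORIAL[r % len(_FACTORIAL)]
            # porosity rises mildly with precipitation but varies within site
            por = float(np.clip(0.35 + 0.03 * z[i] + rng.normal(0, 0.05), 0.0, 1.0))
            rows.append({
                "sample_id": f"{site['site_id']}_r{r + 1:02d}",
                "site_id": site["site_id"],
                "legacy": legacy[i],
                "cond_water": cw,
                "cond_host": ch,
                "test_water": tw,
                "porosity": por,
            })
    return StudyDesign(sites=sites, samples=pd.DataFrame(rows), seed=seed)


def _nb_draws(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 draws with Var = mu + alpha mu^2 (Poisson limit as alpha -> 0)."""
    mu = np.maximum(mu, 1e-12)
    if alpha <= 1e-12:
        return rng.poisson(mu)
    size = 1.0 / alpha
    return rng.negative_binomial(size, size / (size + mu))


def gen_community(
    design: StudyDesign,
    n_taxa: int = 200,
    n_markers: int = 20,
    slope: float = 1.0,
    dispersion: float = 0.3,
    zero_prob: float = 0.1,
    depth: int = 50_000,
    seed: int = 0,
) -> tuple[AbundanceTable, Truth]:
    """Taxon counts with marker taxa whose log-mean tracks precipitation.

    Non-marker taxa draw NB counts around log-normal baselines independent of
    precipitation; the first ``n_markers`` taxa get a log-mean linear in
    standardized precipitation with slope ``+-slope`` (alternating sign).
    Structural zeros are injected with probability ``zero_prob``; expected
    column sums equal ``depth``.
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    if not 0 <= zero_prob < 1:
        raise ValueError("zero_prob must be in [0, 1)")
    if n_markers > n_taxa:
        raise ValueError("n_markers cannot exceed n_taxa")
    rng = child_rng(seed, "community")
    taxa = [f"tax{i + 1:04d}" for i in range(n_taxa)]
    sample_ids = design.samples["sample_id"].to_numpy()
    z = design.precip_z.to_numpy()

    log_base = rng.normal(0.0, 1.0, size=n_taxa)
    signs = np.where(np.arange(n_markers) % 2 == 0, 1.0, -1.0)
    slopes = np.zeros(n_taxa)
    slopes[:n_markers] = signs * slope
    log_mu = log_base[:, None] + slopes[:, None] * z[None, :]
    w = np.exp(log_mu)
    # rescale for structural zeros so expected column sums equal depth
    mu = depth * w / w.sum(axis=0, keepdims=True) / (1.0 - zero_prob)
    counts = _nb_draws(rng, mu, dispersion)
    if zero_prob > 0:
        counts = np.where(rng.random(counts.shape) < zero_prob, 0, counts)
    table = AbundanceTable(
        counts=pd.DataFrame(counts, index=taxa, columns=sample_ids),
        metadata=design.samples.set_index("sample_id"),
    )
    truth = Truth(marker_taxa={taxa[i]: float(slopes[i]) for i in range(n_markers)})
    return table, truth


def gen_expression(
    design: StudyDesign,
    n_genes: int = 2000,
    set_counts: dict[str, int] | None = None,
    lfc: float = 2.0,
    nb_dispersion: float = 0.1,
    n_legacy_main: int = 15,
    legacy_lfc: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, Truth]:
    """NB gene counts with planted legacy x drought interaction patterns.

    ``set_counts`` maps gene-set labels (I-VI, see :data:`GENE_SET_LABELS`)
    to member counts; set members get drought log2 fold changes per legacy
    group following the pattern with magnitude ``lfc``. ``n_legacy_main``
    genes get a legacy main-effect log2FC of ``legacy_lfc``. Remaining genes
    are null. Counts are NB2 with sample-specific size factors.
    """
    set_counts = dict(set_counts or {})
    unknown = set(set_counts) - set(GENE_SET_LABELS)
    if unknown:
        raise ValueError(f"unknown gene-set labels: {sorted(unknown)}")
    if lfc < 0:
        raise ValueError("lfc must be >= 0")
    n_planted = sum(set_counts.values()) + n_legacy_main
    if n_planted > n_genes:
        raise ValueError("planted genes exceed n_genes")
    rng = child_rng(seed, "expression")
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    samp = design.samples
    sample_ids = samp["sample_id"].to_numpy()
    is_drought = (samp["test_water"] == "drought").to_numpy()
    is_wet_leg = (samp["legacy"] == "wet").to_numpy()

    base = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=n_genes)
    sf = rng.lognormal(mean=0.0, sigma=0.2, size=len(sample_ids))

    lfc_dry = np.zeros(n_genes)
    lfc_wet = np.zeros(n_genes)
    lfc_main = np.zeros(n_genes)
    labels = np.array(["none"] * n_genes, dtype=object)
    i = 0
    for lab in sorted(set_counts):
        k = set_counts[lab]
        mult_dry, mult_wet = GENE_SET_LABELS[lab]
        lfc_dry[i:i + k] = mult_dry * lfc
        lfc_wet[i:i + k] = mult_wet * lfc
        labels[i:i + k] = lab
        i += k
    lfc_main[i:i + n_legacy_main] = legacy_lfc
    labels[i:i + n_legacy_main] = "main"

    drought_lfc = np.where(is_wet_leg[None, :], lfc_wet[:, None], lfc_dry[:, None])
    log2_mu = (
        np.log2(base)[:, None]
        + lfc_main[:, None] * is_wet_leg[None, :]
        + drought_lfc * is_drought[None, :]
    )
    mu = sf[None, :] * np.exp2(log2_mu)
    counts = _nb_draws(rng, mu, nb_dispersion)
    em = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        design=samp.set_index("sample_id"),
    )
    truth = Truth(de_genes=pd.DataFrame({
        "gene_set": labels,
        "lfc_legacy_main": lfc_main,
        "lfc_drought_dry": lfc_dry,
        "lfc_drought_wet": lfc_wet,
    }, index=pd.Index(genes, name="gene")))
    truth.mediation_params["size_factors_sigma"] = 0.2
    return em, truth


def gen_traits(
    design: StudyDesign,
    n_traits: int = 63,
    legacy_effect: float = 1.2,
    drought_effect: float = 0.7,
    noise_sd: float = 0.15,
    n_informative: int = 6,
    seed: int = 0,
) -> tuple[TraitTable, Truth]:
    """Positive plant traits with a legacy shift on droughted plants.

    Drought multiplies trait means by ``drought_effect``; for the first
    ``n_informative`` traits, dry-legacy droughted plants additionally get a
    multiplicative ``legacy_effect``. Remaining traits are pure noise around
    their baselines. Multiplicative log-normal noise has log-sd ``noise_sd``.
    """
    if drought_effect <= 0:
        raise ValueError("drought_effect must be > 0")
    n_informative = min(n_informative, n_traits)
    rng = child_rng(seed, "traits")
    samp = design.samples
    trait_names = [f"trait{i + 1:02d}" for i in range(n_traits)]
    baselines = rng.lognormal(mean=np.log(10.0), sigma=0.5, size=n_traits)
    is_drought = (samp["test_water"] == "drought").to_numpy()
    is_dry_leg = (samp["legacy"] == "dry").to_numpy()

    mult = np.ones((len(samp), n_traits))
    mult[is_drought, :] *= drought_effect
    informative = np.zeros(n_traits, dtype=bool)
    informative[:n_informative] = True
    mult[np.ix_(is_drought & is_dry_leg, informative)] *= legacy_effect
    noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=(len(samp), n_traits))
    values = baselines[None, :] * mult * noise

    data = samp.set_index("sample_id")[
        ["legacy", "cond_water", "cond_host", "test_water"]
    ].copy()
    data["cond_group"] = data["cond_water"].astype(str) + "_" + data["cond_host"].astype(str)
    for j, name in enumerate(trait_names):
        data[name] = values[:, j]
    table = TraitTable(
        data=data,
        factor_cols=["legacy", "cond_water", "cond_host", "test_water", "cond_group"],
    )
    truth = Truth(trait_effects={
        trait_names[j]: float(legacy_effect) for j in range(n_informative)
    })
    return table, truth


def gen_icpms_run(
    n_samples: int = 45,
    n_elements: int = 23,
    drift_slope: float = 0.005,
    ref_interval: int = 9,
    seed: int = 0,
    noise_sd: float = 0.0,
    run_id: str = "run1",
    dilution_factor: float = 20.0,
    n_blanks: int = 2,
) -> tuple[ElementalRun, Truth]:
    """One ICP-MS run: reference-bracketed samples under linear drift.

    A reference record opens the run and recurs after every ``ref_interval``
    samples, with a closing reference and ``n_blanks`` blank records at the
    end. Observed intensity = true intensity x (1 + drift_slope x position)
    x exp(N(0, noise_sd)); true sample intensity encodes the true
    concentration as conc x dry_weight / dilution + blank level, so the full
    correct-subtract-normalize chain inverts the generator exactly when
    noise_sd = 0.
    """
    if ref_interval < 1:
        raise ValueError("ref_interval must be >= 1")
    rng = child_rng(seed, "icpms")
    elements = [f"el{j + 1:02d}" for j in range(n_elements)]
    conc_true = rng.lognormal(mean=np.log(50.0), sigma=0.8, size=(n_samples, n_elements))
    ref_true = rng.lognormal(mean=np.log(100.0), sigma=0.3, size=n_elements)
    blank_true = rng.lognormal(mean=np.log(0.5), sigma=0.2, size=n_elements)
    dry_weight = rng.lognormal(mean=np.log(2.0), sigma=0.1, size=n_samples)

    rows, inten = [], []

    def add(record_type: str, sample_id: str, true_vec: np.ndarray,
            dil: float = np.nan, dw: float = np.nan) -> None:
        pos = len(rows)
        drift = 1.0 + drift_slope * pos
        noise = np.exp(rng.normal(0.0, noise_sd, size=n_elements)) if noise_sd > 0 else 1.0
        rows.append({"run_id": run_id, "position": pos, "record_type": record_type,
                     "sample_id": sample_id, "dilution_factor": dil, "dry_weight_g": dw})
        inten.append(true_vec * drift * noise)

    add("reference", f"{run_id}_ref", ref_true)
    for i in range(n_samples):
        true_int = conc_true[i] * dry_weight[i] / dilution_factor + blank_true
        add("sample", f"{run_id}_smp{i + 1:03d}", true_int,
            dil=dilution_factor, dw=float(dry_weight[i]))
        if (i + 1) % ref_interval == 0 and i + 1 < n_samples:
            add("reference", f"{run_id}_ref", ref_true)
    for b in range(n_blanks):
        add("blank", f"{run_id}_blk{b + 1}", blank_true)
    add("reference", f"{run_id}_ref", ref_true)

    run = ElementalRun(
        meta=pd.DataFrame(rows),
        intensities=pd.DataFrame(inten, columns=elements),
    )
    truth = Truth(icpms_truth={
        "concentrations": pd.DataFrame(
            conc_true,
            index=pd.Index([f"{run_id}_smp{i + 1:03d}" for i in range(n_samples)],
                           name="sample_id"),
            columns=elements,
        ),
        "drift_slope": float(drift_slope),
        "ref_intensity": dict(zip(elements, map(float, ref_true))),
        "blank_intensity": dict(zip(elements, map(float, blank_true))),
    })
    return run, truth


def gen_genotypes(
    design: StudyDesign,
    n_snps: int = 5000,
    n_assoc: int = 20,
    env_slope: float = 1.0,
    missing_rate: float = 0.05,
    seed: int = 0,
    low_qual_frac: float = 0.05,
    structure_sd: float = 0.01,
    mean_depth: float = 15.0,
    n_factors: int = 12,
    factor_sd: float = 0.025,
) -> tuple[GenotypeMatrix, Truth]:
    """Pooled-read SNP dosages with precipitation-associated loci.

    Dosages model metagenome-derived allele frequencies: at each SNP the
    sample's dosage is the alternate-read fraction Binomial(DP, p) / DP with
    DP ~ Poisson(mean_depth). Null SNPs draw p from site frequencies
    jittered (logit sd ``structure_sd``) around a shared ancestral
    frequency; the first ``n_assoc`` SNPs shift the site frequency on the
    logit scale by ``env_slope`` per sd of precipitation. Sample-level
    strain-composition structure is modelled by ``n_factors`` latent
    admixture factors with per-SNP loadings of sd ``factor_sd`` on the
    frequency scale -- the genome-wide structure that the scan's PC
    correction is meant to remove. A ``low_qual_frac`` fraction of null SNPs
    receives QUAL below the standard filter so that filtering has work to
    do.
    """
    if n_assoc > n_snps:
        raise ValueError("n_assoc cannot exceed n_snps")
    if not 0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must be in [0, 0.5)")
    rng = child_rng(seed, "genotypes")
    samp = design.samples
    sample_ids = samp["sample_id"].to_numpy()
    site_of = samp["site_id"].to_numpy()
    sites = design.sites["site_id"].to_numpy()
    zp = design.sites["mean_annual_precip"].to_numpy(float)
    zp = (zp - zp.mean()) / zp.std(ddof=1)

    snp_ids = [f"snp{i + 1:05d}" for i in range(n_snps)]
    p0 = rng.uniform(0.05, 0.95, size=n_snps)
    logit0 = np.log(p0 / (1 - p0))
    site_freq = np.empty((n_snps, len(sites)))
    for s in range(len(sites)):
        shift = rng.normal(0.0, structure_sd, size=n_snps)
        lo = logit0 + shift
        lo[:n_assoc] += env_slope * zp[s]
        site_freq[:, s] = 1.0 / (1.0 + np.exp(-lo))
    site_index = {sid: i for i, sid in enumerate(sites)}
    cols = np.array([site_index[s] for s in site_of])
    freq = site_freq[:, cols]
    if n_factors > 0 and factor_sd > 0:
        loadings = rng.normal(0.0, factor_sd, size=(n_snps, n_factors))
        scores = rng.normal(0.0, 1.0, size=(n_factors, len(sample_ids)))
        freq = np.clip(freq + loadings @ scores, 0.005, 0.995)
    dp = rng.poisson(mean_depth, size=freq.shape).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        dosage = np.where(dp > 0, rng.binomial(dp.astype(int), freq) / np.maximum(dp, 1), np.nan)
    qual = rng.normal(50.0, 8.0, size=n_snps)
    n_low = int(round(low_qual_frac * (n_snps - n_assoc)))
    if n_low:
        low = n_assoc + rng.choice(n_snps - n_assoc, size=n_low, replace=False)
        qual[low] = rng.uniform(5.0, 15.0, size=n_low)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = np.nan

    idx = pd.Index(snp_ids, name="snp_id")
    g = GenotypeMatrix(
        dosage=pd.DataFrame(dosage, index=idx, columns=sample_ids),
        dp=pd.DataFrame(dp, index=idx, columns=sample_ids),
        qual=pd.Series(qual, index=idx, name="qual"),
        chrom=pd.Series(["ref1"] * n_snps, index=idx, name="chrom"),
        pos=pd.Series(np.arange(1, n_snps + 1) * 10, index=idx, name="pos"),
        env=design.precip,
    )
    truth = Truth(assoc_snps={snp_ids[i]: float(env_slope) for i in range(n_assoc)})
    return g, truth
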