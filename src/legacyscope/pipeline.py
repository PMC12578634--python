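"""End-to-end orchestration of the synthetic reproduction run.

A single YAML config drives every stage; all randomness flows from the
global seed through named child streams, and the run manifest records the
parameters, per-stage seeds and SHA-256 checksums of every output table, so
an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import biomarkers, degenes, ecostats, gea, icpms, mediation, sindex, synthgen
from ._streams import child_seed

__all__ = ["PipelineConfig", "run", "validate_inputs", "DEFAULT_STAGES"]

DEFAULT_STAGES = [
    "simulate", "icpms", "ecostats", "biomarkers", "de", "mediate", "sindex", "gea",
]


class SimulateParams(BaseModel):
    n_sites: int = 6
    n_reps: int = 8
    precip_range: tuple[float, float] = (400.0, 1000.0)
    n_taxa: int = 120
    n_markers: int = 12
    marker_slope: float = 1.0
    dispersion: float = 0.3
    zero_prob: float = 0.1
    depth: int = 50_000
    n_genes: int = 400
    set_counts: dict[str, int] = Field(
        default_factory=lambda: {"I": 20, "II": 15, "IV": 20, "VI": 10}
    )
    lfc: float = 2.0
    nb_dispersion: float = 0.1
    n_legacy_main: int = 15
    n_traits: int = 30
    legacy_effect: float = 1.2
    drought_effect: float = 0.7
    trait_noise_sd: float = 0.15
    n_icpms_samples: int = 45
    n_elements: int = 12
    drift_slope: float = 0.005
    n_snps: int = 600
    n_assoc: int = 12
    env_slope: float = 1.0
    missing_rate: float = 0.05


class AnalysisParams(BaseModel):
    min_rel_abund: float = 0.001
    min_prevalence: float = 0.20
    var_threshold: float = 0.8
    adjustment: str = "covariate"
    q_threshold: float = 0.05
    n_perm: int = 499
    n_boot: int = 500
    top_k: int = 10
    r_max: float = 0.7
    gea_n_pcs: int = 10
    gea_n_perm: int = 200


class PipelineConfig(BaseModel):
    seed: int = 0
    outdir: str = "legacyscope_run"
    stages: list[str] = Field(default_factory=lambda: list(DEFAULT_STAGES))
    simulate: SimulateParams = Field(default_factory=SimulateParams)
    analysis: AnalysisParams = Field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)
    return path


def run(config: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    unknown = set(config.stages) - set(DEFAULT_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sp, ap = config.simulate, config.analysis
    seeds = {s: child_seed(config.seed, f"stage:{s}") for s in DEFAULT_STAGES}
    manifest: dict = {
        "config": config.model_dump(), "stage_seeds": seeds, "outputs": {},
        "stages_run": [], "status": "ok",
    }
    files: list[Path] = []

    def record(stage: str) -> None:
        manifest["stages_run"].append(stage)

    try:
        stages = [s for s in DEFAULT_STAGES if s in config.stages]
        if not stages:
            _finalize(manifest, files, out)
            return manifest

        design = synthgen.gen_design(
            sp.n_sites, sp.n_reps, sp.precip_range, seed=seeds["simulate"]
        )
        table, truth_c = synthgen.gen_community(
            design, sp.n_taxa, sp.n_markers, sp.marker_slope, sp.dispersion,
            sp.zero_prob, sp.depth, seed=seeds["simulate"],
        )
        expr, truth_e = synthgen.gen_expression(
            design, sp.n_genes, sp.set_counts, sp.lfc, sp.nb_dispersion,
            n_legacy_main=sp.n_legacy_main, seed=seeds["simulate"],
        )
        traits, truth_t = synthgen.gen_traits(
            design, sp.n_traits, sp.legacy_effect, sp.drought_effect,
            sp.trait_noise_sd, seed=seeds["simulate"],
        )
        icpms_run, truth_i = synthgen.gen_icpms_run(
            sp.n_icpms_samples, sp.n_elements, sp.drift_slope,
            seed=seeds["simulate"],
        )
        geno, truth_g = synthgen.gen_genotypes(
            design, sp.n_snps, sp.n_assoc, sp.env_slope, sp.missing_rate,
            seed=seeds["simulate"],
        )
        if "simulate" in stages:
            files.append(_write(table.counts, out / "taxon_counts.tsv",
                                index_label="taxon_id"))
            files.append(_write(design.samples.set_index("sample_id"),
                                out / "metadata.tsv"))
            files.append(_write(expr.counts, out / "gene_counts.tsv",
                                index_label="gene_id"))
            files.append(_write(traits.data, out / "traits.tsv",
                                index_label="plant_id"))
            icpms_run.write_csv(out / "elemental_run.csv")
            files.append(out / "elemental_run.csv")
            gea.write_vcf(geno, out / "genotypes.vcf")
            files.append(out / "genotypes.vcf")
            truth_all = {
                "marker_taxa": truth_c.marker_taxa,
                "trait_effects": truth_t.trait_effects,
                "assoc_snps": truth_g.assoc_snps,
            }
            (out / "truth.json").write_text(json.dumps(truth_all, indent=1))
            files.append(out / "truth.json")
            record("simulate")

        profile = icpms.finalize_concentrations(icpms.correct_drift(icpms_run))
        if "icpms" in stages:
            profile.write_tsv(out / "elemental_profile.tsv")
            files.append(out / "elemental_profile.tsv")
            record("icpms")

        meta = design.samples.set_index("sample_id")
        if "ecostats" in stages:
            rel = table.relative_abundance()
            dmat = ecostats.bray_curtis(rel.T)
            perm = ecostats.permanova(
                dmat, meta, ["legacy"], n_perm=ap.n_perm,
                seed=seeds["ecostats"],
            )
            files.append(_write(perm, out / "permanova.tsv"))
            shannon = rel.apply(ecostats.shannon_effective, axis=0)
            files.append(_write(shannon.to_frame("shannon_effective"),
                                out / "alpha_diversity.tsv",
                                index_label="sample_id"))
            record("ecostats")

        if "biomarkers" in stages:
            # the soil survey measures one profile per soil sample; the demo
            # reuses the community samples by cycling the elemental profile
            conc = profile.concentrations
            reps = (len(meta) + len(conc) - 1) // len(conc)
            cyc = pd.concat([conc] * reps).iloc[:len(meta)]
            cyc.index = meta.index
            import numpy as _np
            jitter = pd.DataFrame(  # break exact duplication from cycling
                _np.random.default_rng(seeds["biomarkers"]).normal(
                    0, 1e-6, cyc.shape),
                index=cyc.index, columns=cyc.columns,
            )
            prof = type(profile)(concentrations=(cyc * (1 + jitter)).abs())
            markers = biomarkers.marker_scan(
                table, prof, design.precip, meta["porosity"],
                min_rel_abund=ap.min_rel_abund, min_prevalence=ap.min_prevalence,
                var_threshold=ap.var_threshold, adjustment=ap.adjustment,
                legacy=meta["legacy"],
            )
            files.append(_write(markers, out / "marker_taxa.tsv"))
            record("biomarkers")

        sf = degenes.size_factors(expr.counts, mode="cpm")
        de_main = degenes.nb_glm_wald(
            expr.counts, expr.design,
            ["legacy", "cond_water", "cond_host", "test_water"],
            contrast="legacy[wet]", sf=sf,
        )
        responses = degenes.drought_response_by_legacy(expr.counts, expr.design, sf=sf)
        calls = degenes.classify_interaction(responses)
        if "de" in stages:
            files.append(_write(de_main, out / "de_legacy_main.tsv",
                                index_label="gene_id"))
            files.append(_write(calls, out / "interaction_calls.tsv",
                                index_label="gene_id"))
            record("de")

        if "mediate" in stages:
            selected = mediation.select_legacy_sensitive(
                de_main, calls, q_threshold=ap.q_threshold
            )
            norm = degenes.cpm(expr.counts.loc[selected])
            dmat = ecostats.bray_curtis(norm.T)
            emb = mediation.nmds(dmat, k=2, seed=seeds["mediate"])
            tr = (expr.design["test_water"] == "drought").astype(float)
            rows = []
            for mds_axis in ("MDS1", "MDS2"):
                for trait_name in traits.trait_cols[:3]:
                    res = mediation.mediate_single(
                        traits.data[trait_name].to_numpy(float),
                        emb.scores[mds_axis].to_numpy(),
                        tr.to_numpy(), n_boot=ap.n_boot, seed=seeds["mediate"],
                    )
                    rows.append({
                        "trait": trait_name, "mediator": mds_axis,
                        "acme": res.acme, "ade": res.ade, "total": res.total,
                        "prop_mediated": res.prop_mediated,
                        "acme_lo": res.acme_ci[0], "acme_hi": res.acme_ci[1],
                        "acme_p": res.acme_p,
                    })
            files.append(_write(pd.DataFrame(rows).set_index(["trait", "mediator"]),
                                out / "mediation.tsv"))
            record("mediate")

        if "sindex" in stages:
            s_tab = sindex.s_index(traits)
            files.append(_write(s_tab.data, out / "s_index.tsv",
                                index_label="plant_id"))
            top = sindex.select_top_traits(
                s_tab, k=min(ap.top_k, len(s_tab.trait_cols)),
                r_max=ap.r_max, seed=seeds["sindex"],
            )
            (out / "top_traits.txt").write_text("\n".join(top) + "\n")
            files.append(out / "top_traits.txt")
            eff_rows = []
            for trait_name in top:
                eff = sindex.legacy_effect_model(
                    s_tab.data[trait_name], s_tab.data["legacy"],
                    s_tab.data["cond_group"],
                )
                eff_rows.append({
                    "trait": trait_name, "estimate": eff.estimate, "se": eff.se,
                    "ci_lo": eff.ci[0], "ci_hi": eff.ci[1], "p": eff.p,
                    "model": eff.model,
                })
            files.append(_write(pd.DataFrame(eff_rows).set_index("trait"),
                                out / "legacy_effects.tsv"))
            record("sindex")

        if "gea" in stages:
            filt = gea.filter_variants(geno)
            scan, thresh = gea.gea_scan(
                filt, n_pcs=min(ap.gea_n_pcs, len(filt.sample_ids) - 3),
                n_perm=ap.gea_n_perm, seed=seeds["gea"],
            )
            files.append(_write(scan, out / "gea_scan.tsv", index_label="snp_id"))
            (out / "gea_threshold.txt").write_text(f"{thresh:.10g}\n")
            files.append(out / "gea_threshold.txt")
            groups = meta["legacy"]
            diff = gea.differentiation_stats(filt, groups, n_perm=ap.n_perm,
                                             seed=seeds["gea"])
            files.append(_write(diff["fst_per_snp"].to_frame(),
                                out / "fst_per_snp.tsv", index_label="snp_id"))
            (out / "differentiation.json").write_text(json.dumps({
                "fst_global": diff["fst_global"], "phi": diff["phi"],
                "phi_p": diff["phi_p"],
            }, indent=1))
            files.append(out / "differentiation.json")
            record("gea")
    except Exception as exc:  # manifest records partial state
        manifest["status"] = f"failed: {exc}"
        _finalize(manifest, files, out)
        raise
    _finalize(manifest, files, out)
    return manifest


def _finalize(manifest: dict, files: list[Path], out: Path) -> None:
    manifest["outputs"] = {f.name: _sha256(f) for f in files if f.exists()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def validate_inputs(paths: dict[str, str | Path]) -> list[dict]:
    """Cross-check headers and IDs between counts, metadata and trait tables.

    Returns a structured error list (never raises on the first error). Known
    keys: counts, metadata, traits.
    """
    errors: list[dict] = []
    frames: dict[str, pd.DataFrame] = {}
    for key, path in paths.items():
        p = Path(path)
        if not p.exists():
            errors.append({"kind": "missing_file", "key": key, "path": str(p)})
            continue
        try:
            frames[key] = pd.read_csv(p, sep="\t", index_col=0)
        except (ValueError, pd.errors.ParserError) as exc:
            errors.append({"kind": "unreadable", "key": key, "detail": str(exc)})
    for key, df in frames.items():
        dup = df.index[df.index.duplicated()].unique().tolist()
        if dup:
            errors.append({"kind": "duplicate_ids", "key": key, "ids": dup})
    if "counts" in frames and "metadata" in frames:
        counts_samples = set(frames["counts"].columns)
        meta_samples = set(frames["metadata"].index)
        for missing in sorted(counts_samples - meta_samples):
            errors.append({"kind": "unmatched_sample", "key": "metadata",
                           "sample": missing})
    return errors
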