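"""Shared in-memory containers for the pipeline stages.

All tabular data are pandas DataFrames; the dataclasses below bundle the
matrices with the metadata they must stay aligned with, and validate the
alignment invariants on construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "AbundanceTable",
    "ExpressionMatrix",
    "TraitTable",
    "ElementalRun",
    "ElementalProfile",
    "GenotypeMatrix",
    "OrdinationResult",
    "Truth",
]

#: valid record types in an elemental run
RECORD_TYPES = ("sample", "reference", "blank")

#: columns of the long-format elemental CSV
ELEMENTAL_LONG_COLUMNS = [
    "run_id",
    "position",
    "record_type",
    "sample_id",
    "element",
    "intensity",
    "dilution_factor",
    "dry_weight_g",
]


@dataclass
class StudyDesign:
    """Sites along a precipitation gradient plus the factorial sample sheet.

    ``sites`` has columns ``site_id`` and ``mean_annual_precip`` (mm/yr);
    ``samples`` has ``sample_id``, ``site_id``, ``legacy`` (dry/wet, assigned
    from the precipitation rank of the site: bottom half dry), ``cond_water``,
    ``cond_host``, ``test_water`` and ``porosity`` (fraction in [0, 1]).
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    seed: int

    def __post_init__(self) -> None:
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design")
        unknown = set(self.samples["site_id"]) - set(self.sites["site_id"])
        if unknown:
            raise ValueError(f"samples reference unknown sites: {sorted(unknown)}")
        ranks = self.sites["mean_annual_precip"].rank(method="first")
        expect = np.where(ranks <= len(self.sites) / 2, "dry", "wet")
        site_legacy = dict(zip(self.sites["site_id"], expect))
        got = self.samples["site_id"].map(site_legacy)
        if not (got == self.samples["legacy"]).all():
            raise ValueError("legacy labels inconsistent with site precipitation ranks")
        por = self.samples["porosity"].to_numpy(float)
        if ((por < 0) | (por > 1)).any():
            raise ValueError("porosity outside [0, 1]")

    @property
    def precip(self) -> pd.Series:
        """Mean annual precipitation per sample (mm/yr), indexed by sample_id."""
        lut = dict(zip(self.sites["site_id"], self.sites["mean_annual_precip"]))
        return pd.Series(
            self.samples["site_id"].map(lut).to_numpy(float),
            index=self.samples["sample_id"].to_numpy(),
            name="mean_annual_precip",
        )

    @property
    def precip_z(self) -> pd.Series:
        """Standardized (mean 0, sd 1, ddof=1) precipitation per sample."""
        p = self.precip
        return (p - p.mean()) / p.std(ddof=1)


@dataclass
class AbundanceTable:
    """Taxa x samples non-negative counts plus per-sample metadata."""

    counts: pd.DataFrame
    metadata: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.metadata.index):
            raise ValueError("counts columns must equal metadata index (sample IDs)")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def relative_abundance(self) -> pd.DataFrame:
        tot = self.counts.sum(axis=0)
        if (tot <= 0).any():
            bad = tot.index[tot <= 0].tolist()
            raise ValueError(f"zero-sum sample columns: {bad}")
        return self.counts / tot


@dataclass
class ExpressionMatrix:
    """Genes x samples counts plus the factor design table."""

    counts: pd.DataFrame
    design: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.design.index):
            raise ValueError("counts columns must equal design index (sample IDs)")


@dataclass
class TraitTable:
    """Plants x traits with the experimental factors alongside.

    ``data`` holds both factor columns (``factor_cols``) and numeric trait
    columns (everything else), indexed by plant/sample ID.
    """

    data: pd.DataFrame
    factor_cols: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in self.factor_cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"factor columns absent from table: {missing}")

    @property
    def trait_cols(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.factor_cols]

    @property
    def traits(self) -> pd.DataFrame:
        return self.data[self.trait_cols]

    @property
    def factors(self) -> pd.DataFrame:
        return self.data[self.factor_cols]


@dataclass
class ElementalRun:
    """Ordered elemental measurement records for one (or a bridged) run.

    ``meta`` has one row per record: ``run_id``, ``position``, ``record_type``
    in {sample, reference, blank}, ``sample_id``, ``dilution_factor``,
    ``dry_weight_g``. ``intensities`` is aligned row-for-row with ``meta`` and
    has one column per element (signal units).
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.meta) != len(self.intensities):
            raise ValueError("meta and intensities must have the same length")
        bad = set(self.meta["record_type"]) - set(RECORD_TYPES)
        if bad:
            raise ValueError(f"unknown record types: {sorted(bad)}")
        for run_id, grp in self.meta.groupby("run_id", sort=False):
            pos = grp["position"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing in run {run_id!r}")
        if (self.intensities.to_numpy(float) < 0).any():
            raise ValueError("negative intensities")

    @property
    def elements(self) -> list[str]:
        return list(self.intensities.columns)

    def to_long(self) -> pd.DataFrame:
        """Long-format record table (one row per record x element)."""
        wide = pd.concat(
            [self.meta.reset_index(drop=True), self.intensities.reset_index(drop=True)],
            axis=1,
        )
        long = wide.melt(
            id_vars=["run_id", "position", "record_type", "sample_id",
                     "dilution_factor", "dry_weight_g"],
            var_name="element",
            value_name="intensity",
        )
        return long[ELEMENTAL_LONG_COLUMNS].sort_values(
            ["run_id", "position", "element"], kind="stable"
        ).reset_index(drop=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "ElementalRun":
        missing = [c for c in ELEMENTAL_LONG_COLUMNS if c not in long.columns]
        if missing:
            raise ValueError(f"long table missing columns: {missing}")
        meta = (
            long.drop_duplicates(subset=["run_id", "position"])
            [["run_id", "position", "record_type", "sample_id",
              "dilution_factor", "dry_weight_g"]]
            .sort_values(["run_id", "position"], kind="stable")
            .reset_index(drop=True)
        )
        inten = long.pivot(index=["run_id", "position"], columns="element",
                           values="intensity")
        inten = inten.loc[list(zip(meta["run_id"], meta["position"]))]
        inten = inten.reset_index(drop=True)
        inten.columns.name = None
        return cls(meta=meta, intensities=inten)

    def write_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ElementalRun":
        return cls.from_long(pd.read_csv(path))


@dataclass
class ElementalProfile:
    """Samples x elements concentrations (mass per mass dry weight)."""

    concentrations: pd.DataFrame  # samples x elements

    def __post_init__(self) -> None:
        arr = self.concentrations.to_numpy(float)
        if not np.isfinite(arr).all():
            raise ValueError("non-finite concentrations")
        if (arr < 0).any():
            raise ValueError("negative concentrations (blank floor violated)")

    def write_tsv(self, path: str | Path) -> None:
        self.concentrations.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ElementalProfile":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"))


@dataclass
class GenotypeMatrix:
    """Biallelic SNPs x samples with per-sample alternate-allele dosage.

    ``dosage`` holds values in {0, 0.5, 1} (or [0, 1]) with NaN = missing;
    ``dp`` the per-call sequencing depth; ``qual`` the per-SNP variant quality;
    ``env`` the per-sample environment value (mm/yr precipitation).
    """

    dosage: pd.DataFrame  # snps x samples
    dp: pd.DataFrame  # snps x samples
    qual: pd.Series  # per snp
    chrom: pd.Series  # per snp
    pos: pd.Series  # per snp, 1-based
    env: pd.Series | None = None  # per sample

    def __post_init__(self) -> None:
        if list(self.dosage.columns) != list(self.dp.columns):
            raise ValueError("dosage and dp sample columns differ")
        if not (list(self.dosage.index) == list(self.dp.index)
                == list(self.qual.index) == list(self.pos.index)):
            raise ValueError("SNP indexes misaligned")
        vals = self.dosage.to_numpy(float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            raise ValueError("dosage outside [0, 1]")
        if self.env is not None and list(self.env.index) != list(self.dosage.columns):
            raise ValueError("env index must equal sample columns")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosage.columns)


@dataclass
class OrdinationResult:
    """Scores plus eigenvalue bookkeeping for (constrained) ordinations."""

    scores: pd.DataFrame  # samples x axes
    eigvals: np.ndarray
    proportion_explained: np.ndarray
    #: per-term permutation statistics for constrained runs
    term_stats: pd.DataFrame | None = None
    stress: float | None = None


@dataclass
class Truth:
    """Ground-truth parameters recorded by the synthetic generators."""

    marker_taxa: dict[str, float] = field(default_factory=dict)
    de_genes: pd.DataFrame | None = None
    trait_effects: dict[str, float] = field(default_factory=dict)
    mediation_params: dict[str, float] = field(default_factory=dict)
    assoc_snps: dict[str, float] = field(default_factory=dict)
    icpms_truth: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "marker_taxa": self.marker_taxa,
            "de_genes": None if self.de_genes is None
            else self.de_genes.reset_index().to_dict(orient="list"),
            "trait_effects": self.trait_effects,
            "mediation_params": self.mediation_params,
            "assoc_snps": self.assoc_snps,
            "icpms_truth": {
                k: (v.reset_index().to_dict(orient="list")
                    if isinstance(v, pd.DataFrame) else v)
                for k, v in self.icpms_truth.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))
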