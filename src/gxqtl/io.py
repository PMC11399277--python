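"""Readers, writers and sample harmonization for the QTL pipeline.

Conventions
-----------
Variants carry 1-based positions (VCF convention); feature coordinates are
0-based half-open (BED convention). All distance computations convert
explicitly to 1-based basepairs. Missing hard-call genotypes are stored as
NaN in the dosage matrix and are never imputed in stored data; mean
imputation happens only inside regression design matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleTable",
    "GenotypeMatrix",
    "FeatureMatrix",
    "GwasSumstats",
    "read_sample_table",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_vcf",
    "read_features",
    "write_features",
    "read_sumstats",
    "write_sumstats",
    "harmonize_samples",
]

VARIANT_COLS = ["variant_id", "chrom", "pos", "ref", "alt"]
FEATURE_COLS = ["feature_id", "chrom", "start", "end", "kind"]


@dataclass
class SampleTable:
    """Per-sample exposure status, ancestry and covariates.

    ``status`` is the binary exposure (1 = smoking case, 0 = control);
    ``ancestry`` is a categorical label (e.g. AA/EA). ``covariates`` is a
    complete (no-NA) real-valued frame aligned to ``sample_id``.
    """

    sample_id: np.ndarray
    status: np.ndarray
    ancestry: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self):
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        if len(set(self.sample_id)) != len(self.sample_id):
            raise ValueError("sample ids must be unique")
        self.status = np.asarray(self.status, dtype=int)
        if not set(np.unique(self.status)) <= {0, 1}:
            raise ValueError("status must be binary 0/1 with no missing")
        self.ancestry = np.asarray(self.ancestry, dtype=object)
        if self.covariates.isna().any().any():
            raise ValueError("covariates must be complete (no NA)")
        if len(self.status) != len(self.sample_id) or len(self.covariates) != len(self.sample_id):
            raise ValueError("sample table fields must have equal length")
        self.covariates = self.covariates.set_axis(self.sample_id, axis=0)

    @property
    def n_samples(self) -> int:
        return len(self.sample_id)

    def subset(self, ids) -> "SampleTable":
        idx = pd.Index(self.sample_id).get_indexer(list(ids))
        if np.any(idx < 0):
            raise KeyError("unknown sample id(s) in subset")
        return SampleTable(
            self.sample_id[idx],
            self.status[idx],
            self.ancestry[idx],
            self.covariates.iloc[idx].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sample_id": self.sample_id, "status": self.status, "ancestry": self.ancestry}
        )
        return pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleTable":
        cov = df.drop(columns=["sample_id", "status", "ancestry"])
        return cls(df["sample_id"].to_numpy(), df["status"].to_numpy(), df["ancestry"].to_numpy(), cov)


@dataclass
class GenotypeMatrix:
    """Hard-call dosages (variants x samples) with variant metadata.

    ``dosages`` is a float array with entries in {0, 1, 2} and NaN for
    missing calls.
    """

    variants: pd.DataFrame
    sample_id: np.ndarray
    dosages: np.ndarray

    def __post_init__(self):
        missing = [c for c in VARIANT_COLS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        if (self.variants["pos"] <= 0).any():
            raise ValueError("variant positions must be strictly positive (1-based)")
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        if len(set(self.sample_id)) != len(self.sample_id):
            raise ValueError("sample ids must be unique")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.sample_id)):
            raise ValueError("dosage matrix shape must be (n_variants, n_samples)")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_id)

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency on non-missing hard calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            af = np.nanmean(self.dosages, axis=1) / 2.0
        return np.minimum(af, 1.0 - af)

    def missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def subset_samples(self, ids) -> "GenotypeMatrix":
        idx = pd.Index(self.sample_id).get_indexer(list(ids))
        if np.any(idx < 0):
            raise KeyError("unknown sample id(s)")
        return GenotypeMatrix(self.variants.copy(), self.sample_id[idx], self.dosages[:, idx])

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        idx = pd.Index(self.variants["variant_id"]).get_indexer(list(variant_ids))
        if np.any(idx < 0):
            raise KeyError("unknown variant id(s)")
        return GenotypeMatrix(
            self.variants.iloc[idx].reset_index(drop=True), self.sample_id, self.dosages[idx]
        )


@dataclass
class FeatureMatrix:
    """Quantitative features (CpG beta-values or gene counts) x samples."""

    features: pd.DataFrame
    sample_id: np.ndarray
    values: np.ndarray
    value_kind: str = "beta"  # beta | count | normalized

    def __post_init__(self):
        missing = [c for c in FEATURE_COLS if c not in self.features.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        if self.features["feature_id"].duplicated().any():
            raise ValueError("feature ids must be unique")
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.sample_id)):
            raise ValueError("value matrix shape must be (n_features, n_samples)")
        if self.value_kind == "beta":
            if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1:
                raise ValueError("beta values must lie in [0, 1]")
        elif self.value_kind == "count":
            if np.nanmin(self.values) < 0 or not np.allclose(self.values, np.round(self.values)):
                raise ValueError("counts must be non-negative integers")
        self.features = self.features.reset_index(drop=True)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def subset_samples(self, ids) -> "FeatureMatrix":
        idx = pd.Index(self.sample_id).get_indexer(list(ids))
        if np.any(idx < 0):
            raise KeyError("unknown sample id(s)")
        return FeatureMatrix(self.features.copy(), self.sample_id[idx], self.values[:, idx], self.value_kind)


@dataclass
class GwasSumstats:
    """Per-variant GWAS summary statistics for one trait."""

    trait: str
    table: pd.DataFrame  # variant_id, beta, se, p, n

    def __post_init__(self):
        required = ["variant_id", "beta", "se", "p", "n"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"sumstats missing columns: {missing}")
        if (self.table["se"] <= 0).any():
            raise ValueError("all standard errors must be > 0")
        p = self.table["p"]
        if (p <= 0).any() or (p > 1).any():
            raise ValueError("p-values must lie in (0, 1]")
        self.table = self.table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t")
    return SampleTable.from_frame(df)


def write_sample_table(table: SampleTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeMatrix:
    """Read hard-call genotypes from a VCF (GT field) or a TSV matrix.

    Multiallelic VCF records are rejected with a warning count; missing
    calls ('./.' or NA) are stored as NaN, never as 0.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_vcf(path)
    return _read_genotypes_tsv(path)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = np.array(vcf.samples, dtype=object)
    rows, meta = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types.astype(float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dos)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        meta.append((vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic record(s)")
    if not rows:
        raise ValueError(f"no biallelic variants found in {path}")
    variants = pd.DataFrame(meta, columns=VARIANT_COLS)
    return GenotypeMatrix(variants, samples, np.vstack(rows))


def _read_genotypes_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in VARIANT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"genotype TSV missing columns: {missing} ({path})")
    if len(df) == 0:
        raise ValueError(f"no variants in {path}")
    samples = np.array([c for c in df.columns if c not in VARIANT_COLS], dtype=object)
    dosages = df[samples].to_numpy(dtype=float)
    ok = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValueError(f"malformed dosage at data row {i + 1}, sample {samples[j]}: {dosages[i, j]}")
    return GenotypeMatrix(df[VARIANT_COLS].copy(), samples, dosages)


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    dose = pd.DataFrame(geno.dosages, columns=list(geno.sample_id))
    df = pd.concat([geno.variants.reset_index(drop=True), dose], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only VCF (text, uncompressed)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(geno.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, geno.sample_id)) + "\n")
        for i, row in geno.variants.iterrows():
            calls = [gt_map.get(d, "./.") if not np.isnan(d) else "./." for d in geno.dosages[i]]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_features(values_path, bed_path, value_kind: str = "beta") -> FeatureMatrix:
    """Read a feature x sample value TSV plus a BED file of coordinates."""
    vals = pd.read_csv(values_path, sep="\t")
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "feature_id", "kind"],
        dtype={"chrom": str},
    )
    features = bed[["feature_id", "chrom", "start", "end", "kind"]]
    order = pd.Index(vals["feature_id"])
    features = features.set_index("feature_id").loc[order].reset_index()
    samples = np.array([c for c in vals.columns if c != "feature_id"], dtype=object)
    return FeatureMatrix(features, samples, vals[samples].to_numpy(float), value_kind)


def write_features(fm: FeatureMatrix, values_path, bed_path) -> None:
    vals = pd.DataFrame(fm.values, columns=list(fm.sample_id))
    df = pd.concat([fm.features[["feature_id"]].reset_index(drop=True), vals], axis=1)
    df.to_csv(values_path, sep="\t", index=False)
    fm.features[["chrom", "start", "end", "feature_id", "kind"]].to_csv(
        bed_path, sep="\t", index=False, header=False
    )


def read_sumstats(path, trait: str | None = None) -> GwasSumstats:
    df = pd.read_csv(path, sep="\t")
    return GwasSumstats(trait or str(path), df)


def write_sumstats(ss: GwasSumstats, path) -> None:
    ss.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample harmonization
# ---------------------------------------------------------------------------

@dataclass
class Harmonized:
    intersection: list = field(default_factory=list)
    union: list = field(default_factory=list)

    @property
    def n_intersection(self) -> int:
        return len(self.intersection)

    @property
    def n_union(self) -> int:
        return len(self.union)


def _ids_of(obj) -> list:
    if isinstance(obj, (SampleTable, GenotypeMatrix, FeatureMatrix)):
        ids = list(obj.sample_id)
    else:
        ids = list(obj)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated sample id within one table")
    return ids


def harmonize_samples(*tables) -> Harmonized:
    """Intersect and unite sample id sets across data types.

    Accepts SampleTable / GenotypeMatrix / FeatureMatrix instances or plain
    id iterables. Ordering of the returned id lists is deterministic
    (sorted).
    """
    if len(tables) < 2:
        raise ValueError("need at least two inputs to harmonize")
    sets = [set(_ids_of(t)) for t in tables]
    inter = set.intersection(*sets)
    union = set.union(*sets)
    return Harmonized(sorted(inter), sorted(union))
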