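"""Reading and writing of genotype, phenotype and annotation data.

Genotypes are held as an individuals x variants dosage matrix (counts of the
minor allele, 0/1/2, with ``nan`` marking missing calls).  Phenotypes are a
single trait (binary 0/1 or continuous) plus optional covariates.  Annotations
carry a functional class per variant and any number of numeric deleteriousness
scores (PolyPhen-2-like probabilities, GERP-like conservation scores, binary
damaging flags).  These three tables are the inputs of every downstream
operation in this package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rarecausal")

#: recognised functional classes; anything else maps to "other" with a warning
FUNCTIONAL_CLASSES = (
    "nonsynonymous",
    "synonymous",
    "nonsense",
    "splice",
    "frameshift",
    "other",
)

#: classes treated as the functional (non-synonymous-like) stratum
FUNCTIONAL_STRATUM = ("nonsynonymous", "nonsense", "splice", "frameshift")


class GenotypeIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class GenotypeMatrix:
    """Dosage matrix for one region, with per-variant metadata.

    Attributes
    ----------
    dosages : (n, m) float array
        Minor-allele counts in {0, 1, 2}; ``nan`` marks a missing genotype.
    variant_ids : list of str
        One identifier per column, conventionally ``chrom:pos:ref:alt``.
    positions : (m,) int array
        1-based genomic coordinates.
    sample_ids : list of str
    flipped : (m,) bool array
        True where the ALT allele was the major allele and dosages were folded
        to count the minor allele instead.
    """

    dosages: np.ndarray
    variant_ids: list[str]
    positions: np.ndarray
    sample_ids: list[str]
    flipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        if self.dosages.ndim != 2:
            raise GenotypeIOError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if len(self.variant_ids) != m or len(self.positions) != m:
            raise GenotypeIOError("variant metadata length mismatch")
        if len(self.sample_ids) != n:
            raise GenotypeIOError("sample_ids length mismatch")
        if self.flipped is None:
            self.flipped = np.zeros(m, dtype=bool)
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise GenotypeIOError("dosages must be 0/1/2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant, from non-missing entries."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def impute_missing(self) -> "GenotypeMatrix":
        """Mean-impute missing dosages per variant (logged).

        Score statistics need complete columns; the per-variant mean keeps the
        allele frequency of each column unchanged.
        """
        if not np.isnan(self.dosages).any():
            return self
        d = self.dosages.copy()
        col_mean = np.nanmean(d, axis=0)
        idx = np.where(np.isnan(d))
        d[idx] = col_mean[idx[1]]
        logger.info("mean-imputed %d missing dosages", len(idx[0]))
        out = GenotypeMatrix.__new__(GenotypeMatrix)
        out.dosages = d
        out.variant_ids = list(self.variant_ids)
        out.positions = self.positions.copy()
        out.sample_ids = list(self.sample_ids)
        out.flipped = self.flipped.copy()
        return out

    def subset(self, index: np.ndarray) -> "GenotypeMatrix":
        """Column subset by integer or boolean index."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            variant_ids=[self.variant_ids[i] for i in index],
            positions=self.positions[index],
            sample_ids=list(self.sample_ids),
            flipped=self.flipped[index],
        )


@dataclass
class PhenotypeTable:
    """Per-individual trait and optional covariates."""

    y: np.ndarray
    trait_type: str  # "dichotomous" | "continuous"
    sample_ids: list[str]
    covariates: np.ndarray | None = None
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.trait_type not in ("dichotomous", "continuous"):
            raise GenotypeIOError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "dichotomous" and not np.isin(self.y, (0.0, 1.0)).all():
            raise GenotypeIOError("dichotomous trait must contain only 0/1")
        if len(self.sample_ids) != len(self.y):
            raise GenotypeIOError("sample_ids length mismatch")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != len(self.y):
                raise GenotypeIOError("covariate rows must match phenotype length")


@dataclass
class AnnotationTable:
    """Variant-level functional classes and numeric annotation scores."""

    table: pd.DataFrame  # indexed by variant_id; column "functional_class" + scores

    def __post_init__(self) -> None:
        if "functional_class" not in self.table.columns:
            raise GenotypeIOError("annotation table needs a functional_class column")
        cls = self.table["functional_class"].astype(str)
        unknown = ~cls.isin(FUNCTIONAL_CLASSES)
        if unknown.any():
            warnings.warn(
                f"{int(unknown.sum())} variants with unknown functional class "
                "mapped to 'other'",
                stacklevel=2,
            )
            cls = cls.where(~unknown, "other")
        self.table = self.table.assign(functional_class=cls)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def functional_class(self) -> pd.Series:
        return self.table["functional_class"]

    @property
    def score_names(self) -> list[str]:
        return [c for c in self.table.columns if c != "functional_class"]

    def scores(self, names: list[str], variant_ids: list[str]) -> np.ndarray:
        """Score columns aligned to ``variant_ids``; missing values -> 0.

        Synonymous/unscored variants carry a predictor value of 0 by
        convention, so missingness is imputed as 0 with a logged notice.
        """
        sub = self.table.loc[variant_ids, names].astype(float)
        n_missing = int(sub.isna().sum().sum())
        if n_missing:
            logger.info("imputed %d missing annotation scores as 0", n_missing)
        return sub.fillna(0.0).to_numpy()

    def stratum(self, variant_ids: list[str]) -> np.ndarray:
        """Stratum label per variant: True = functional (NS-like), False = synonymous."""
        cls = self.table.loc[variant_ids, "functional_class"]
        return cls.isin(FUNCTIONAL_STRATUM).to_numpy()


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, region: str | None = None, maf_policy: str = "fold_to_minor") -> GenotypeMatrix:
    """Read a diploid VCF 4.x into a :class:`GenotypeMatrix`.

    Dosages count ALT alleles per genotype; under ``fold_to_minor`` (the
    default, because all downstream statistics are stated in terms of minor
    allele counts) columns with ALT frequency > 0.5 are flipped and flagged.
    Missing genotypes become ``nan``.
    """
    if maf_policy not in ("as_alt", "fold_to_minor"):
        raise GenotypeIOError(f"unknown maf_policy {maf_policy!r}")
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise GenotypeIOError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    cols, ids, positions, flipped = [], [], [], []
    it = vcf(region) if region else vcf
    for rec in it:
        ploidy = np.asarray(rec.ploidy)
        if np.any(ploidy != 2):
            raise GenotypeIOError(
                f"non-diploid genotype at {rec.CHROM}:{rec.POS}"
            )
        # gts012: 0/1/2 = alt count, 3 = unknown
        dos = np.asarray(rec.gt_types, dtype=float)
        dos[dos == 3] = np.nan
        flip = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f_alt = np.nanmean(dos) / 2.0
        if maf_policy == "fold_to_minor" and np.isfinite(f_alt) and f_alt > 0.5:
            dos = 2.0 - dos
            flip = True
        alt = rec.ALT[0] if rec.ALT else "."
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}")
        positions.append(rec.POS)
        cols.append(dos)
        flipped.append(flip)
    if not cols:
        raise GenotypeIOError(f"no variant records in {path}")
    return GenotypeMatrix(
        dosages=np.column_stack(cols),
        variant_ids=ids,
        positions=np.asarray(positions),
        sample_ids=samples,
        flipped=np.asarray(flipped),
    )


def write_vcf(gm: GenotypeMatrix, path: str, chrom: str = "1") -> None:
    """Write dosages as a minimal uncompressed VCF 4.2 (GT only).

    Variant ids of the form ``chrom:pos:ref:alt`` supply the alleles; anything
    else is written with placeholder A/C alleles.  Folded columns are written
    on the minor-allele orientation (REF = major).
    """
    n, m = gm.dosages.shape
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(m):
            vid = gm.variant_ids[j]
            parts = vid.split(":")
            if len(parts) == 4:
                c, _, ref, alt = parts
            else:
                c, ref, alt = chrom, "A", "C"
            gts = [
                "./." if np.isnan(d) else gt_of[d] for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{c}\t{gm.positions[j]}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_tables(
    genotype_tsv: str, phenotype_tsv: str, annotation_tsv: str
) -> tuple[GenotypeMatrix, PhenotypeTable, AnnotationTable]:
    """Read aligned genotype/phenotype/annotation TSVs.

    Layout: the genotype TSV has a ``sample_id`` column plus one 0/1/2 column
    per variant; the phenotype TSV has ``sample_id``, ``phenotype`` and any
    further covariate columns; the annotation TSV has ``variant_id``,
    ``functional_class`` and score columns.  Rows are aligned by id, so file
    order does not matter.  Sample or variant ids missing from a companion
    file raise an error naming them.
    """
    geno = pd.read_csv(genotype_tsv, sep="\t", dtype={"sample_id": str})
    pheno = pd.read_csv(phenotype_tsv, sep="\t", dtype={"sample_id": str})
    annot = pd.read_csv(annotation_tsv, sep="\t", dtype={"variant_id": str})
    for df, name, col in ((geno, "genotype", "sample_id"), (pheno, "phenotype", "sample_id"), (annot, "annotation", "variant_id")):
        if col not in df.columns:
            raise GenotypeIOError(f"{name} TSV lacks a {col} column")
    geno = geno.set_index("sample_id")
    pheno = pheno.set_index("sample_id")
    annot = annot.set_index("variant_id")

    missing_pheno = sorted(set(geno.index) - set(pheno.index))
    if missing_pheno:
        raise GenotypeIOError(
            "samples present in genotypes but absent from phenotypes: "
            + ", ".join(missing_pheno)
        )
    missing_annot = sorted(set(geno.columns) - set(annot.index))
    if missing_annot:
        raise GenotypeIOError(
            "variants missing from annotation table: " + ", ".join(missing_annot)
        )
    samples = sorted(geno.index)
    variants = list(geno.columns)
    geno = geno.loc[samples]
    pheno = pheno.loc[samples]

    y = pheno["phenotype"].to_numpy(dtype=float)
    trait_type = (
        "dichotomous" if np.isin(y[~np.isnan(y)], (0.0, 1.0)).all() else "continuous"
    )
    cov_cols = [c for c in pheno.columns if c != "phenotype"]
    covariates = pheno[cov_cols].to_numpy(dtype=float) if cov_cols else None

    gm = GenotypeMatrix(
        dosages=geno.to_numpy(dtype=float),
        variant_ids=variants,
        positions=_positions_from_ids(variants),
        sample_ids=samples,
    )
    pt = PhenotypeTable(
        y=y,
        trait_type=trait_type,
        sample_ids=samples,
        covariates=covariates,
        covariate_names=cov_cols or None,
    )
    at = AnnotationTable(annot.loc[list(geno.columns) + [v for v in annot.index if v not in geno.columns]])
    return gm, pt, at


def _positions_from_ids(variant_ids: list[str]) -> np.ndarray:
    pos = []
    for i, vid in enumerate(variant_ids):
        parts = vid.split(":")
        try:
            pos.append(int(parts[1]))
        except (IndexError, ValueError):
            pos.append(i + 1)
    return np.asarray(pos, dtype=int)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "variant_id",
    "pos",
    "count_cases",
    "count_controls",
    "return_count",
    "log_or",
    "stderr",
]


def build_results_table(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    log_or: np.ndarray,
    stderr: np.ndarray,
    return_count: np.ndarray | None = None,
    annotations: AnnotationTable | None = None,
    score_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-variant report: carrier counts in cases/controls,
    return count, log OR and SE, plus annotation columns, sorted by
    descending log OR (ties by variant id)."""
    d = np.nan_to_num(gm.dosages, nan=0.0)
    if pheno.trait_type == "dichotomous":
        cases = pheno.y == 1
        count_cases = d[cases].sum(axis=0).astype(int)
        count_controls = d[~cases].sum(axis=0).astype(int)
    else:  # carrier counts are case/control specific; report totals
        count_cases = d.sum(axis=0).astype(int)
        count_controls = np.zeros(gm.n_variants, dtype=int)
    out = pd.DataFrame(
        {
            "variant_id": gm.variant_ids,
            "pos": gm.positions,
            "count_cases": count_cases,
            "count_controls": count_controls,
            "return_count": np.full(gm.n_variants, np.nan) if return_count is None else return_count,
            "log_or": np.asarray(log_or, dtype=float),
            "stderr": np.asarray(stderr, dtype=float),
        }
    )
    if annotations is not None:
        cols = score_columns or annotations.score_names
        out["functional_class"] = (
            annotations.table["functional_class"].reindex(gm.variant_ids).to_numpy()
        )
        for c in cols:
            out[c] = annotations.table[c].reindex(gm.variant_ids).to_numpy()
    out = out.sort_values(
        ["log_or", "variant_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def write_results(results: pd.DataFrame, path: str) -> None:
    """Write a results table as TSV (round-trips at printed precision)."""
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
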