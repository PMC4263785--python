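"""Synthetic cohorts with the structure of a rare-variant sequencing study.

A haplotype pool stands in for coalescent-simulated sequence data: per-site
minor allele counts follow a neutral site-frequency spectrum (P(count = i)
proportional to 1/i), so the pool is dominated by very rare variants, and
carriers are assigned uniformly (no linkage disequilibrium).  Defaults match
the study conditions used throughout this package: 10,000 haplotypes over a
1 Mb region from which 10 kb subregions are drawn, cohorts of 2000 individuals
with equal numbers of cases and controls, and disease prevalence 0.05.

Disease models M1 and M2 assign odds ratios to causal variants as a
decreasing step function of MAF, with a configurable fraction (10% or 20%) of
the MAF <= 0.05 variants causal.  Functional classes and binary deleteriousness
predictors are generated by Bayes' rule from the NS:S ratio of the region, the
assumption that 80% of causal variants are non-synonymous, and per-predictor
sensitivity/false-positive rates (B1: 0.8/0.3, B2: 0.8/0.1, plus a
non-informative 0.5/0.5 predictor).  The logistic intercept is calibrated by
bisection so the population prevalence hits its target, and case/control
cohorts are accrued by rejection sampling of random haplotype pairings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .genotype_io import AnnotationTable, GenotypeMatrix, PhenotypeTable


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Haplotype pool
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePool:
    """H x S binary haplotype matrix with site positions."""

    haplotypes: np.ndarray  # (H, S) uint8
    positions: np.ndarray  # (S,) 1-based, strictly increasing
    region_length: int
    source: str = "internal_sfs"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=int)
        if self.haplotypes.ndim != 2:
            raise SimulationError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[1] != len(self.positions):
            raise SimulationError("positions must match the number of sites")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    @property
    def maf(self) -> np.ndarray:
        f = self.frequencies
        return np.minimum(f, 1.0 - f)

    @property
    def monomorphic(self) -> np.ndarray:
        f = self.frequencies
        return (f == 0.0) | (f == 1.0)

    def variant_ids(self) -> list[str]:
        return [f"1:{p}:A:C" for p in self.positions]


def simulate_haplotypes(
    n_hap: int = 10_000,
    n_sites: int = 10_000,
    region_length: int = 1_000_000,
    sfs_exponent: float = 1.0,
    seed: int = 0,
) -> HaplotypePool:
    """Generate a haplotype pool from a neutral site-frequency spectrum.

    Per-site minor allele counts i are drawn with P(i) proportional to
    1/i**sfs_exponent for i = 1..n_hap-1, and carriers are assigned uniformly
    at random per site.  Positions are distinct uniform draws over the region.
    """
    if n_hap < 2:
        raise SimulationError("need at least 2 haplotypes")
    if n_sites > region_length:
        raise SimulationError("more sites than positions available")
    rng = np.random.default_rng(seed)
    i = np.arange(1, n_hap)
    pmf = 1.0 / i.astype(float) ** sfs_exponent
    pmf /= pmf.sum()
    counts = rng.choice(i, size=n_sites, p=pmf)
    positions = np.sort(rng.choice(region_length, size=n_sites, replace=False)) + 1
    H = np.zeros((n_hap, n_sites), dtype=np.uint8)
    for j, c in enumerate(counts):
        H[rng.permutation(n_hap)[:c], j] = 1
    return HaplotypePool(haplotypes=H, positions=positions, region_length=region_length)


def import_haplotypes(matrix: np.ndarray, positions: np.ndarray, region_length: int) -> HaplotypePool:
    """Wrap externally simulated haplotypes (e.g. coalescent output) as a pool."""
    return HaplotypePool(
        haplotypes=np.asarray(matrix), positions=np.asarray(positions),
        region_length=region_length, source="imported",
    )


def draw_region(pool: HaplotypePool, width: int = 10_000, seed: int = 0) -> HaplotypePool:
    """Contiguous positional slice of the pool (a random subregion)."""
    if width > pool.region_length:
        raise SimulationError("subregion wider than the pool region")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, pool.region_length - width + 1)) + 1
    mask = (pool.positions >= start) & (pool.positions < start + width)
    return HaplotypePool(
        haplotypes=pool.haplotypes[:, mask],
        positions=pool.positions[mask],
        region_length=pool.region_length,
        source=pool.source,
    )


# ---------------------------------------------------------------------------
# Disease and annotation models
# ---------------------------------------------------------------------------

@dataclass
class DiseaseModel:
    """MAF-dependent odds ratios for causal variants.

    ``or_bins`` maps MAF bins to odds ratios as (upper_maf, OR) pairs with
    increasing upper edges; a variant with MAF below the first edge gets the
    first OR, and so on.  The last edge doubles as the rare-variant threshold:
    only variants at or below it can be causal.
    """

    name: str
    or_bins: list[tuple[float, float]]
    causal_fraction: float = 0.2
    prevalence: float = 0.05

    def __post_init__(self) -> None:
        edges = [e for e, _ in self.or_bins]
        ors = [o for _, o in self.or_bins]
        if sorted(edges) != edges:
            raise SimulationError("or_bins edges must increase")
        if any(o < 1.0 for o in ors) or sorted(ors, reverse=True) != ors:
            raise SimulationError("odds ratios must be >= 1 and non-increasing in MAF")
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise SimulationError("causal_fraction must lie in [0, 1]")

    @property
    def rare_threshold(self) -> float:
        return self.or_bins[-1][0]

    def odds_ratio(self, maf: np.ndarray) -> np.ndarray:
        maf = np.asarray(maf, dtype=float)
        edges = np.array([e for e, _ in self.or_bins])
        ors = np.array([o for _, o in self.or_bins])
        idx = np.searchsorted(edges, maf, side="left")
        out = np.where(idx < len(ors), ors[np.minimum(idx, len(ors) - 1)], 1.0)
        return out

    @classmethod
    def M1(cls, causal_fraction: float = 0.2, prevalence: float = 0.05) -> "DiseaseModel":
        return cls("M1", [(0.001, 3.0), (0.01, 2.0), (0.05, 1.5)], causal_fraction, prevalence)

    @classmethod
    def M2(cls, causal_fraction: float = 0.2, prevalence: float = 0.05) -> "DiseaseModel":
        return cls("M2", [(0.001, 5.0), (0.01, 3.0), (0.05, 2.0)], causal_fraction, prevalence)


@dataclass
class AnnotationModel:
    """Generator of functional classes and binary deleteriousness predictors.

    ``predictors`` maps a name to (P(flag | NS, causal), P(flag | NS,
    non-causal)); synonymous variants always carry 0.  Derived population
    quantities follow from Bayes' rule given the NS:S ratio and the share of
    causal variants that are non-synonymous.
    """

    ns_s_ratio: float = 1.0
    p_ns_given_causal: float = 0.8
    predictors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"B1": (0.8, 0.3), "B2": (0.8, 0.1), "R": (0.5, 0.5)}
    )

    def derived(self, causal_fraction: float) -> dict[str, float]:
        """Bayes-rule quantities implied by the configuration.

        Returns p_ns (marginal NS share), p_ns_given_noncausal,
        p_causal_given_ns and p_causal_given_s.  Raises if the configuration
        implies a probability outside [0, 1].
        """
        c = causal_fraction
        p_ns = self.ns_s_ratio / (1.0 + self.ns_s_ratio)
        if c < 1.0:
            p_ns_nc = (p_ns - c * self.p_ns_given_causal) / (1.0 - c)
        else:
            p_ns_nc = p_ns
        out = {
            "p_ns": p_ns,
            "p_ns_given_noncausal": p_ns_nc,
            "p_causal_given_ns": (c * self.p_ns_given_causal / p_ns) if p_ns > 0 else 0.0,
            "p_causal_given_s": (
                c * (1.0 - self.p_ns_given_causal) / (1.0 - p_ns) if p_ns < 1 else 0.0
            ),
        }
        for key, v in out.items():
            if not 0.0 <= v <= 1.0:
                raise SimulationError(
                    f"inconsistent annotation model: {key} = {v:.4f} outside [0, 1]"
                )
        return out


# ---------------------------------------------------------------------------
# Causal assignment, annotations, calibration
# ---------------------------------------------------------------------------

def assign_causal_and_annotations(
    pool_slice: HaplotypePool,
    dmodel: DiseaseModel,
    amodel: AnnotationModel,
    seed: int = 0,
) -> tuple[AnnotationTable, pd.DataFrame]:
    """Draw causal flags, functional classes and predictors for a region.

    Exactly round(causal_fraction * n_rare) of the MAF <= threshold variants
    are causal.  Classes: P(NS | causal) = p_ns_given_causal, P(NS | non-
    causal) from Bayes' rule.  Binary predictors are drawn per their NS
    conditional rates (conditionally independent given causal status) and are
    0 for synonymous variants.  Returns the annotation table and a truth frame
    (causal flag, true log OR, pool MAF) indexed by variant id.
    """
    rng = np.random.default_rng(seed)
    maf = pool_slice.maf
    S = pool_slice.n_sites
    ids = pool_slice.variant_ids()
    derived = amodel.derived(dmodel.causal_fraction)

    rare = maf <= dmodel.rare_threshold
    n_causal = int(round(dmodel.causal_fraction * int(rare.sum())))
    causal = np.zeros(S, dtype=bool)
    if n_causal > 0:
        causal[rng.choice(np.flatnonzero(rare), size=n_causal, replace=False)] = True

    p_ns = np.where(causal, amodel.p_ns_given_causal, derived["p_ns_given_noncausal"])
    is_ns = rng.random(S) < p_ns

    beta = np.where(causal, np.log(dmodel.odds_ratio(maf)), 0.0)

    scores: dict[str, np.ndarray] = {}
    for name, (rate_causal, rate_noncausal) in amodel.predictors.items():
        rate = np.where(causal, rate_causal, rate_noncausal)
        flag = (rng.random(S) < rate) & is_ns
        scores[name] = flag.astype(float)

    annot = AnnotationTable(
        pd.DataFrame(
            {
                "functional_class": np.where(is_ns, "nonsynonymous", "synonymous"),
                **scores,
            },
            index=pd.Index(ids, name="variant_id"),
        )
    )
    truth = pd.DataFrame(
        {"causal": causal, "beta": beta, "maf_pool": maf},
        index=pd.Index(ids, name="variant_id"),
    )
    return annot, truth


def _pair_causal_dosages(
    pool_slice: HaplotypePool, truth: pd.DataFrame, rng: np.random.Generator, size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random haplotype pairings; returns (h1, h2, causal dosage matrix)."""
    H = pool_slice.n_haplotypes
    h1 = rng.integers(0, H, size)
    h2 = rng.integers(0, H, size)
    causal_idx = np.flatnonzero(truth["causal"].to_numpy())
    if causal_idx.size:
        hap = pool_slice.haplotypes[:, causal_idx]
        gc = hap[h1].astype(float) + hap[h2].astype(float)
    else:
        gc = np.zeros((size, 0))
    return h1, h2, gc


def calibrate_intercept(
    dmodel: DiseaseModel,
    pool_slice: HaplotypePool,
    truth: pd.DataFrame,
    mc_size: int = 200_000,
    seed: int = 0,
) -> float:
    """Intercept beta_0 such that population prevalence equals the target.

    With no causal effects this is logit(prevalence) exactly.  Otherwise the
    Monte-Carlo mean of expit(beta_0 + g' beta) over mc_size random haplotype
    pairings is matched to the target by bisection (the same genotype sample
    is reused across bisection steps, so the solve is deterministic and
    monotone; tolerance 1e-6 on the prevalence scale).
    """
    target = dmodel.prevalence
    beta = truth["beta"].to_numpy()
    beta_c = beta[truth["causal"].to_numpy()]
    if beta_c.size == 0 or np.all(beta_c == 0.0):
        return float(special.logit(target))
    rng = np.random.default_rng(seed)
    _, _, gc = _pair_causal_dosages(pool_slice, truth, rng, mc_size)
    shift = gc @ beta_c
    lo = float(special.logit(target) - 2.0 * beta_c.sum() - 1.0)
    hi = float(special.logit(target))
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        prev = float(np.mean(special.expit(mid + shift)))
        if abs(prev - target) < 1e-6:
            return mid
        if prev > target:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    annotations: AnnotationTable
    truth: pd.DataFrame  # indexed by variant id: causal, beta, maf_pool
    intercept: float
    dmodel: DiseaseModel
    amodel: AnnotationModel
    seed: int

    def causal_mask(self, variant_ids: list[str] | None = None) -> np.ndarray:
        ids = variant_ids if variant_ids is not None else self.genotypes.variant_ids
        return self.truth["causal"].reindex(ids).to_numpy(dtype=bool)

    def true_beta(self, variant_ids: list[str] | None = None) -> np.ndarray:
        ids = variant_ids if variant_ids is not None else self.genotypes.variant_ids
        return self.truth["beta"].reindex(ids).to_numpy(dtype=float)


def simulate_cohort(
    pool_slice: HaplotypePool,
    dmodel: DiseaseModel,
    amodel: AnnotationModel,
    n_cases: int = 1000,
    n_controls: int = 1000,
    seed: int = 0,
    intercept: float | None = None,
    annotations: AnnotationTable | None = None,
    truth: pd.DataFrame | None = None,
    calibration_mc_size: int = 200_000,
) -> SimulatedCohort:
    """Simulate a case-control cohort from the region.

    Individuals are random pairings of pool haplotypes (homozygous rare
    carriers arise at Hardy-Weinberg rates); affection status follows the
    logistic model with the calibrated intercept, and sampling continues until
    the requested case and control counts accrue.  Variants monomorphic in the
    accrued cohort are dropped from the genotype matrix (the annotation and
    truth tables keep all region variants).
    """
    rng = np.random.default_rng(seed)
    if annotations is None or truth is None:
        annotations, truth = assign_causal_and_annotations(
            pool_slice, dmodel, amodel, seed=int(rng.integers(2**31))
        )
    if intercept is None:
        intercept = calibrate_intercept(
            dmodel, pool_slice, truth, calibration_mc_size, seed=int(rng.integers(2**31))
        )

    need_cases, need_controls = n_cases, n_controls
    case_pairs: list[np.ndarray] = []
    control_pairs: list[np.ndarray] = []
    batch = max(4 * (n_cases + n_controls), 10_000)
    # cases are rare (prevalence ~5%), so expect ~n_cases/prevalence draws
    while need_cases > 0 or need_controls > 0:
        h1, h2, gc = _pair_causal_dosages(pool_slice, truth, rng, batch)
        beta_c = truth.loc[truth["causal"], "beta"].to_numpy()
        risk = special.expit(intercept + (gc @ beta_c if beta_c.size else 0.0))
        y = rng.random(batch) < risk
        if need_cases > 0:
            take = np.flatnonzero(y)[:need_cases]
            case_pairs.append(np.column_stack([h1[take], h2[take]]))
            need_cases -= len(take)
        if need_controls > 0:
            take = np.flatnonzero(~y)[:need_controls]
            control_pairs.append(np.column_stack([h1[take], h2[take]]))
            need_controls -= len(take)

    pairs = np.vstack(case_pairs + control_pairs)
    hap = pool_slice.haplotypes
    dosages = hap[pairs[:, 0]].astype(float) + hap[pairs[:, 1]].astype(float)
    y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    sample_ids = [f"case{i+1}" for i in range(n_cases)] + [
        f"ctrl{i+1}" for i in range(n_controls)
    ]

    poly = (dosages.sum(axis=0) > 0) & (dosages.sum(axis=0) < 2 * len(y))
    ids = pool_slice.variant_ids()
    gm = GenotypeMatrix(
        dosages=dosages[:, poly],
        variant_ids=[ids[j] for j in np.flatnonzero(poly)],
        positions=pool_slice.positions[poly],
        sample_ids=sample_ids,
    )
    pheno = PhenotypeTable(y=y, trait_type="dichotomous", sample_ids=sample_ids)
    return SimulatedCohort(
        genotypes=gm,
        phenotypes=pheno,
        annotations=annotations,
        truth=truth,
        intercept=float(intercept),
        dmodel=dmodel,
        amodel=amodel,
        seed=seed,
    )
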