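"""Haplotype pool, disease/annotation models, calibration, cohorts."""

import numpy as np
import pytest
from scipy import special, stats

import rarecausal as rc
from rarecausal.simulate import SimulationError

# printed Table-2-style scenario grid: (ns_s_ratio, causal_fraction) ->
# (p_causal_given_ns, p_causal_given_s, p_ns_given_noncausal)
SCENARIO_GRID = {
    (0.6, 0.1): (0.21, 0.03, 0.33),
    (1.0, 0.1): (0.16, 0.04, 0.47),
    (1.4, 0.1): (0.14, 0.05, 0.56),
    (0.6, 0.2): (0.42, 0.06, 0.27),
    (1.0, 0.2): (0.32, 0.08, 0.42),
    (1.4, 0.2): (0.28, 0.10, 0.53),
}


@pytest.mark.parametrize("ratio,c", sorted(SCENARIO_GRID))
def test_bayes_rule_derived_proportions(ratio, c):
    """Derived annotation proportions reproduce the scenario grid to ~2 dp and
    satisfy the exact Bayes identities."""
    am = rc.AnnotationModel(ns_s_ratio=ratio)
    d = am.derived(c)
    exp_ns, exp_s, exp_nsnc = SCENARIO_GRID[(ratio, c)]
    # two p(causal|NS) cells of the published grid are one digit off the
    # exact Bayes values (0.427 -> 0.42, 0.274 -> 0.28), hence the 7e-3 slack
    assert d["p_causal_given_ns"] == pytest.approx(exp_ns, abs=7e-3)
    assert d["p_causal_given_s"] == pytest.approx(exp_s, abs=5e-3)
    assert d["p_ns_given_noncausal"] == pytest.approx(exp_nsnc, abs=5e-3)
    # exact identities
    p_ns = ratio / (1 + ratio)
    assert d["p_causal_given_ns"] * p_ns == pytest.approx(0.8 * c, abs=1e-12)
    assert d["p_causal_given_s"] * (1 - p_ns) == pytest.approx(0.2 * c, abs=1e-12)
    total_ns = c * 0.8 + (1 - c) * d["p_ns_given_noncausal"]
    assert total_ns == pytest.approx(p_ns, abs=1e-12)


def test_bayes_degenerate_no_causal():
    am = rc.AnnotationModel(ns_s_ratio=1.4)
    d = am.derived(0.0)
    assert d["p_ns_given_noncausal"] == pytest.approx(1.4 / 2.4, abs=1e-12)


def test_inconsistent_annotation_model_raises():
    # causal fraction so high that P(NS|non-causal) would be negative
    am = rc.AnnotationModel(ns_s_ratio=0.2)
    with pytest.raises(SimulationError, match="outside"):
        am.derived(0.9)


def test_haplotype_pool_shape_and_determinism():
    pool = rc.simulate_haplotypes(n_hap=100, n_sites=50, region_length=5000, seed=5)
    assert pool.haplotypes.shape == (100, 50)
    assert set(np.unique(pool.haplotypes)) <= {0, 1}
    assert (np.diff(pool.positions) > 0).all()
    again = rc.simulate_haplotypes(n_hap=100, n_sites=50, region_length=5000, seed=5)
    np.testing.assert_array_equal(pool.haplotypes, again.haplotypes)
    np.testing.assert_array_equal(pool.positions, again.positions)


def test_sfs_log_log_slope_is_minus_one():
    pool = rc.simulate_haplotypes(n_hap=10_000, n_sites=5_000, seed=7)
    counts = pool.haplotypes.sum(axis=0)
    # histogram of allele counts over octave bins; slope of log density vs log i
    edges = np.unique(np.geomspace(1, counts.max() + 1, 12).astype(int))
    hist, _ = np.histogram(counts, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = hist > 0
    slope = np.polyfit(np.log(centers[keep]), np.log(hist[keep] / widths[keep]), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.1)


def test_draw_region_slices_and_covers(small_pool):
    widths = []
    covered = np.zeros(small_pool.n_sites, dtype=bool)
    for seed in range(40):
        region = rc.draw_region(small_pool, 10_000, seed=seed)
        assert region.positions.min() >= 1
        assert np.ptp(region.positions) <= 10_000
        covered |= np.isin(small_pool.positions, region.positions)
        widths.append(region.n_sites)
    assert covered.mean() > 0.9  # union of slices covers the region
    again = rc.draw_region(small_pool, 10_000, seed=3)
    np.testing.assert_array_equal(
        again.positions, rc.draw_region(small_pool, 10_000, seed=3).positions
    )


def test_disease_model_or_step_function():
    dm = rc.DiseaseModel.M1()
    maf = np.array([0.0005, 0.005, 0.03, 0.2])
    ors = dm.odds_ratio(maf)
    assert (np.diff(ors) <= 0).all()
    assert dm.rare_threshold == 0.05
    m2 = rc.DiseaseModel.M2()
    assert (m2.odds_ratio(maf[:3]) > ors[:3]).all()


def test_causal_assignment_counts_and_classes(small_pool):
    region = rc.draw_region(small_pool, 20_000, seed=2)
    dm = rc.DiseaseModel.M1(causal_fraction=0.2)
    am = rc.AnnotationModel(ns_s_ratio=1.0)
    annot, truth = rc.assign_causal_and_annotations(region, dm, am, seed=4)
    rare = truth["maf_pool"] <= 0.05
    assert truth["causal"].sum() == round(0.2 * rare.sum())
    assert not (truth["causal"] & ~rare).any()
    # causal variants carry the model's log odds ratio
    causal = truth[truth["causal"]]
    np.testing.assert_allclose(
        causal["beta"], np.log(dm.odds_ratio(causal["maf_pool"].to_numpy()))
    )
    # synonymous variants have zero predictors
    syn = annot.table["functional_class"] == "synonymous"
    assert (annot.table.loc[syn, ["B1", "B2", "R"]].to_numpy() == 0).all()


def test_intercept_closed_form_without_causal(small_pool):
    region = rc.draw_region(small_pool, 10_000, seed=6)
    dm = rc.DiseaseModel.M1(causal_fraction=0.0)
    am = rc.AnnotationModel()
    _, truth = rc.assign_causal_and_annotations(region, dm, am, seed=1)
    b0 = rc.calibrate_intercept(dm, region, truth, mc_size=1000, seed=0)
    assert b0 == pytest.approx(special.logit(0.05), abs=1e-12)


def test_calibrated_prevalence_and_or_monotonicity(small_pool):
    region = rc.draw_region(small_pool, 10_000, seed=8)
    dm = rc.DiseaseModel.M2(causal_fraction=0.2)
    am = rc.AnnotationModel()
    _, truth = rc.assign_causal_and_annotations(region, dm, am, seed=9)
    b0 = rc.calibrate_intercept(dm, region, truth, mc_size=100_000, seed=10)
    # fresh Monte-Carlo genotypes reproduce the target prevalence
    rng = np.random.default_rng(99)
    h1 = rng.integers(0, region.n_haplotypes, 100_000)
    h2 = rng.integers(0, region.n_haplotypes, 100_000)
    causal_idx = np.flatnonzero(truth["causal"].to_numpy())
    gc = (region.haplotypes[h1][:, causal_idx] + region.haplotypes[h2][:, causal_idx]).astype(float)
    prev = special.expit(b0 + gc @ truth["beta"].to_numpy()[causal_idx]).mean()
    assert prev == pytest.approx(0.05, abs=0.003)
    # doubling all effects strictly lowers the intercept
    truth2 = truth.copy()
    truth2["beta"] *= 2.0
    b0_stronger = rc.calibrate_intercept(dm, region, truth2, mc_size=100_000, seed=10)
    assert b0_stronger < b0


def test_cohort_counts_and_determinism(small_pool):
    region = rc.draw_region(small_pool, 10_000, seed=12)
    dm = rc.DiseaseModel.M1(causal_fraction=0.1)
    am = rc.AnnotationModel()
    cohort = rc.simulate_cohort(
        region, dm, am, n_cases=150, n_controls=100, seed=13,
        calibration_mc_size=20_000,
    )
    y = cohort.phenotypes.y
    assert (y == 1).sum() == 150 and (y == 0).sum() == 100
    d = cohort.genotypes.dosages
    assert set(np.unique(d)) <= {0.0, 1.0, 2.0}
    assert (d.sum(axis=0) > 0).all()  # cohort-monomorphic columns dropped
    again = rc.simulate_cohort(
        region, dm, am, n_cases=150, n_controls=100, seed=13,
        calibration_mc_size=20_000,
    )
    np.testing.assert_array_equal(d, again.genotypes.dosages)


def test_common_causal_effect_recovered_by_logistic_regression(small_pool):
    """The assigned OR of a not-too-rare causal variant is covered by its
    logistic-regression Wald interval in most replicates."""
    import statsmodels.api as sm

    dm = rc.DiseaseModel.M1(causal_fraction=0.2)
    am = rc.AnnotationModel()
    n_cov = 0
    n_tot = 0
    for rep in range(15):
        region = rc.draw_region(small_pool, 15_000, seed=600 + rep)
        cohort = rc.simulate_cohort(
            region, dm, am, n_cases=400, n_controls=400, seed=700 + rep,
            calibration_mc_size=20_000,
        )
        ids = cohort.genotypes.variant_ids
        causal = cohort.causal_mask(ids)
        maf = cohort.genotypes.maf
        targets = np.flatnonzero(causal & (maf >= 0.01))
        if targets.size == 0:
            continue
        j = targets[np.argmax(maf[targets])]
        X = np.column_stack(
            [np.ones(cohort.genotypes.n_individuals), cohort.genotypes.dosages[:, j]]
        )
        res = sm.Logit(cohort.phenotypes.y, X).fit(disp=0)
        true_b = cohort.true_beta(ids)[j]
        lo = res.params[1] - 1.96 * res.bse[1]
        hi = res.params[1] + 1.96 * res.bse[1]
        n_cov += lo <= true_b <= hi
        n_tot += 1
    assert n_tot >= 10
    assert n_cov / n_tot >= 0.8


def test_import_haplotypes_round_trip():
    rng = np.random.default_rng(0)
    H = (rng.random((20, 5)) < 0.2).astype(np.uint8)
    pool = rc.import_haplotypes(H, np.arange(1, 6) * 10, region_length=100)
    assert pool.source == "imported"
    np.testing.assert_array_equal(pool.haplotypes, H)
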