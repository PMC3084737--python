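"""Association statistics: crude/per-allele ORs, trend, HWE, power."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import comb

from mediassoc import (
    ConvergenceError,
    GenotypeAssociation,
    GenotypeCountTable,
    adjusted_logistic,
    allele_frequencies,
    cochran_armitage_trend,
    crude_genotype_or,
    hwe_chi2,
    per_allele_or,
    study_power,
)
from conftest import make_records


# ---------------------------------------------------------------------------
# crude genotype ORs


@pytest.mark.parametrize(
    "key,dosage,expected_or,expected_ci",
    [
        (("rs12914385", "smokers"), 2, 2.04, (1.63, 2.55)),
        (("rs12914385", "smokers"), 1, 1.45, (1.24, 1.70)),
        (("rs12914385", "never-smokers"), 1, 0.91, (0.66, 1.26)),
        (("rs12914385", "familial"), 2, 2.78, (2.05, 3.78)),
        (("rs8042374", "smokers"), 0, 0.53, (0.38, 0.74)),
        (("rs8042374", "familial"), 0, 0.40, (0.23, 0.72)),
    ],
)
def test_crude_or_reproduces_reference_tables(tables, key, dosage, expected_or, expected_ci):
    """Woolf-CI genotype ORs match the published two-decimal values."""
    ref = 2 if dosage == 0 else 0  # rs8042374 rows are printed against AA (dosage 2)
    res = crude_genotype_or(tables[key], dosage, ref)
    assert round(res.estimate, 2) == expected_or
    assert round(res.ci_low, 2) == expected_ci[0]
    assert round(res.ci_high, 2) == expected_ci[1]


def test_crude_or_null_table_is_one():
    t = GenotypeCountTable("null", (10, 10, 0), (10, 10, 0))
    res = crude_genotype_or(t, 1, 0)
    assert res.estimate == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)


def test_crude_or_inverse_under_dosage_swap(tables):
    t = tables[("rs12914385", "smokers")]
    fwd = crude_genotype_or(t, 2, 0)
    rev = crude_genotype_or(t, 0, 2)
    assert rev.estimate == pytest.approx(1.0 / fwd.estimate, rel=1e-12)
    assert rev.ci_low == pytest.approx(1.0 / fwd.ci_high, rel=1e-12)
    assert rev.ci_high == pytest.approx(1.0 / fwd.ci_low, rel=1e-12)


def test_crude_or_zero_cell_rejected_unless_corrected():
    t = GenotypeCountTable("zero", (5, 0, 3), (4, 2, 6))
    with pytest.raises(ValueError, match="zero cell"):
        crude_genotype_or(t, 1, 0)
    res = crude_genotype_or(t, 1, 0, continuity_correction=True)
    assert res.corrected
    assert res.estimate == pytest.approx((0.5 * 4.5) / (5.5 * 2.5), rel=1e-12)


def test_scaling_counts_preserves_or_and_shrinks_ci():
    t = GenotypeCountTable("base", (20, 30, 10), (25, 25, 8))
    big = GenotypeCountTable("x10", tuple(10 * c for c in t.cases), tuple(10 * c for c in t.controls))
    a, b = crude_genotype_or(t, 2, 0), crude_genotype_or(big, 2, 0)
    assert b.estimate == pytest.approx(a.estimate, rel=1e-12)
    assert (b.ci_high - b.ci_low) < (a.ci_high - a.ci_low)
    pa, pb = per_allele_or(t), per_allele_or(big)
    assert pb.estimate == pytest.approx(pa.estimate, rel=1e-6)


# ---------------------------------------------------------------------------
# per-allele (additive logistic) OR


@pytest.mark.parametrize(
    "key,expected",
    [(("rs12914385", "smokers"), 1.43), (("rs8042374", "smokers"), 1.32)],
)
def test_per_allele_or_matches_published(tables, key, expected):
    res = per_allele_or(tables[key])
    assert round(res.estimate, 2) == expected


def test_per_allele_wald_p_matches_published(tables):
    res = per_allele_or(tables[("rs12914385", "smokers")])
    assert res.p_value == pytest.approx(2.10e-11, rel=0.005)


def test_per_allele_matches_statsmodels(tables):
    import statsmodels.api as sm

    t = tables[("rs8042374", "familial")]
    y = np.array(t.cases, float)
    n = y + np.array(t.controls, float)
    X = sm.add_constant(np.arange(3.0))
    ref = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial()).fit()
    res = per_allele_or(t)
    assert math.log(res.estimate) == pytest.approx(ref.params[1], abs=1e-8)
    assert res.se_log == pytest.approx(ref.bse[1], rel=1e-6)


def test_per_allele_null_when_case_fraction_constant():
    t = GenotypeCountTable("flat", (30, 60, 15), (20, 40, 10))
    res = per_allele_or(t)
    assert res.estimate == pytest.approx(1.0, abs=1e-8)


def test_per_allele_two_group_table_equals_crude():
    t = GenotypeCountTable("two", (10, 20, 0), (30, 15, 0))
    assert per_allele_or(t).estimate == pytest.approx(
        crude_genotype_or(t, 1, 0).estimate, abs=1e-6
    )


def test_per_allele_separation_raises():
    with pytest.raises(ConvergenceError):
        per_allele_or(GenotypeCountTable("sep", (0, 0, 50), (50, 0, 0)))


# ---------------------------------------------------------------------------
# Cochran-Armitage trend


def test_trend_zero_for_identical_distributions():
    t = GenotypeCountTable("same", (4, 6, 10), (2, 3, 5))
    res = cochran_armitage_trend(t)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_trend_on_reference_table(tables):
    res = cochran_armitage_trend(tables[("rs12914385", "smokers")])
    assert 1e-12 < res.p_value < 1e-10  # published crude per-allele p is 2.1e-11
    assert res.direction > 0


def test_trend_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="weights"):
        cochran_armitage_trend(GenotypeCountTable("w", (1, 2, 3), (3, 2, 1)), weights=(1, 1, 1))
    with pytest.raises(ValueError):
        cochran_armitage_trend(GenotypeCountTable("s", (1, 2, 3), (0, 0, 0)))


def _permutation_oracle_p(cases, controls):
    """Brute-force two-sided permutation p by enumerating every assignment of
    case labels to the individual subjects (independent of the package's
    conditional-enumeration route)."""
    genotypes = []
    for g, (nc, ns) in enumerate(zip(cases, controls)):
        genotypes.extend([g] * (nc + ns))
    genotypes = np.array(genotypes)
    N, R = len(genotypes), sum(cases)
    # observed weighted case total, centred under the permutation null
    w = genotypes.astype(float)
    center = R * w.sum() / N
    u_obs = sum(g * c for g, c in enumerate(cases)) - center
    hits = total = 0
    for case_idx in itertools.combinations(range(N), R):
        u = w[list(case_idx)].sum() - center
        total += 1
        if abs(u) >= abs(u_obs) - 1e-9:
            hits += 1
    return hits / total


@pytest.mark.parametrize(
    "cases,controls",
    [
        ((3, 2, 1), (1, 2, 3)),
        ((1, 2, 3), (2, 2, 2)),
        ((2, 0, 4), (2, 3, 1)),
        ((2, 2, 2), (1, 2, 2)),
        ((4, 1, 1), (1, 2, 3)),
    ],
)
def test_trend_p_matches_exhaustive_permutation_small_tables(cases, controls):
    """On <= 12-subject tables the reported p equals the exhaustive
    label-permutation p (the test enumerates subjects directly)."""
    t = GenotypeCountTable("toy", cases, controls)
    res = cochran_armitage_trend(t)
    assert "exact" in res.flags
    assert abs(res.p_value - _permutation_oracle_p(cases, controls)) <= 0.02


def test_trend_20_subject_toy_table_exact():
    """Statistic and p for the 20-subject toy table, cross-checked against an
    independently coded enumeration over case-count configurations."""
    cases, controls = (4, 3, 3), (3, 3, 4)
    t = GenotypeCountTable("toy20", cases, controls)
    res = cochran_armitage_trend(t)
    # statistic by direct arithmetic: U^2 / Var under the hypergeometric null
    r = np.array(cases, float)
    n = r + np.array(controls, float)
    w = np.arange(3.0)
    N, R = n.sum(), r.sum()
    u = w @ r - R * (w @ n) / N
    var = R * (N - R) / (N - 1) * ((w**2 @ n) / N - ((w @ n) / N) ** 2)
    assert res.statistic == pytest.approx(u * u / var, rel=1e-12)
    # exact p by multiplicity-weighted enumeration with its own formulas
    total = comb(int(N), int(R), exact=True)
    hits = 0
    for r0 in range(int(n[0]) + 1):
        for r1 in range(int(n[1]) + 1):
            r2 = int(R) - r0 - r1
            if not 0 <= r2 <= n[2]:
                continue
            u_perm = r1 + 2 * r2 - R * (w @ n) / N
            if abs(u_perm) >= abs(u) - 1e-9:
                hits += (
                    comb(int(n[0]), r0, exact=True)
                    * comb(int(n[1]), r1, exact=True)
                    * comb(int(n[2]), r2, exact=True)
                )
    assert res.p_value == pytest.approx(hits / total, abs=1e-12)


# ---------------------------------------------------------------------------
# HWE


def test_hwe_zero_at_exact_proportions():
    res = hwe_chi2((25, 50, 25))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_hwe_reference_controls_match_hand_calculation(tables):
    obs = np.array(tables[("rs12914385", "smokers")].controls, float)
    n = obs.sum()
    q = (obs[1] + 2 * obs[2]) / (2 * n)
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    chi2_hand = float(((obs - expected) ** 2 / expected).sum())
    res = hwe_chi2(tuple(int(c) for c in obs))
    assert res.statistic == pytest.approx(chi2_hand, rel=1e-12)
    assert res.p_value > 0.05  # the control series satisfies HWE


def test_hwe_extreme_heterozygote_deficit():
    res = hwe_chi2((50, 0, 50))
    assert res.statistic == pytest.approx(100.0, rel=1e-10)  # chi2 = n for D = -pq
    assert res.p_value < 1e-3


def test_hwe_invariant_to_allele_relabelling():
    a = hwe_chi2((373, 413, 121))
    b = hwe_chi2((121, 413, 373))
    assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


def test_hwe_monomorphic_flagged():
    res = hwe_chi2((100, 0, 0))
    assert res.statistic == 0.0
    assert "monomorphic" in res.flags


# ---------------------------------------------------------------------------
# adjusted logistic on individual records


def _hwe_dosage(rng, n, raf):
    return rng.binomial(2, raf, size=n)


def test_adjusted_or_close_to_crude_with_uninformative_covariates():
    rng = np.random.default_rng(11)
    n = 8000
    g = _hwe_dosage(rng, n, 0.4)
    logit = -0.5 + 0.3 * g
    case = rng.random(n) < 1 / (1 + np.exp(-logit))
    df = make_records(
        g,
        status=np.where(case, "case", "control"),
        age=rng.uniform(45, 75, n),
        sex=np.where(rng.random(n) < 0.5, "male", "female"),
        cpd=rng.uniform(5, 35, n),
    )
    adj = adjusted_logistic(df)
    cases = tuple(int(np.sum(g[case] == d)) for d in range(3))
    ctrls = tuple(int(np.sum(g[~case] == d)) for d in range(3))
    crude = per_allele_or(GenotypeCountTable("sim", cases, ctrls))
    assert math.log(adj.estimate) == pytest.approx(math.log(crude.estimate), abs=0.05)


def test_adjusted_or_recovers_direct_effect_under_confounding():
    """CPD driven by genotype confounds the crude OR; adjustment removes it."""
    rng = np.random.default_rng(23)
    n = 20000
    g = _hwe_dosage(rng, n, 0.4)
    cpd = np.clip(rng.normal(14 + 6 * g, 4), 1, None)
    cat_effect = np.select(
        [cpd <= 10, cpd <= 20, cpd <= 30], [0.0, 0.6, 1.1], default=1.5
    )
    direct = 0.15
    logit = -2.0 + direct * g + cat_effect
    case = rng.random(n) < 1 / (1 + np.exp(-logit))
    df = make_records(
        g,
        status=np.where(case, "case", "control"),
        age=rng.uniform(45, 75, n),
        sex=np.where(rng.random(n) < 0.5, "male", "female"),
        cpd=cpd,
    )
    adj = adjusted_logistic(df)
    cases = tuple(int(np.sum(g[case] == d)) for d in range(3))
    ctrls = tuple(int(np.sum(g[~case] == d)) for d in range(3))
    crude = per_allele_or(GenotypeCountTable("conf", cases, ctrls))
    assert math.log(crude.estimate) > direct + 0.1  # visibly confounded
    assert math.log(adj.estimate) == pytest.approx(direct, abs=0.09)


def test_adjusted_logistic_rejects_constant_dosage():
    df = make_records(np.ones(50, dtype=int), cpd=np.full(50, 15.0))
    df.loc[:24, "status"] = "control"
    with pytest.raises(ValueError, match="constant"):
        adjusted_logistic(df)


def test_adjusted_logistic_drops_missing_and_reports():
    rng = np.random.default_rng(3)
    n = 400
    g = _hwe_dosage(rng, n, 0.4)
    cpd = rng.uniform(5, 30, n)
    cpd[:40] = np.nan
    df = make_records(
        g,
        status=np.where(rng.random(n) < 0.5, "case", "control"),
        age=rng.uniform(40, 70, n),
        cpd=cpd,
    )
    res = adjusted_logistic(df)
    assert res.n_used == n - 40
    assert any("dropped_missing=40" in f for f in res.flags)


# ---------------------------------------------------------------------------
# allele frequencies


@pytest.mark.parametrize(
    "key,raf_cases,raf_controls",
    [
        (("rs12914385", "smokers"), 0.45, 0.36),
        (("rs12914385", "never-smokers"), 0.35, 0.37),
        (("rs8042374", "smokers"), 0.82, 0.77),
    ],
)
def test_allele_frequencies_match_published(tables, key, raf_cases, raf_controls):
    raf = allele_frequencies(tables[key])
    assert round(raf.raf_cases, 2) == raf_cases
    assert round(raf.raf_controls, 2) == raf_controls


def test_allele_frequencies_all_homozygous():
    raf = allele_frequencies(GenotypeCountTable("hom", (0, 0, 50), (0, 0, 20)))
    assert raf.raf_cases == 1.0 and raf.raf_controls == 1.0


def test_direction_inconsistency_flagged(tables):
    """Per-allele OR below 1 with case RAF below control RAF is consistent;
    the published never-smoker row (reciprocal reported) is not, and the
    model surface flags rather than silently inverts."""
    res = GenotypeAssociation(tables[("rs12914385", "never-smokers")]).fit()
    assert res.per_allele.estimate < 1.0  # direction follows the counts
    assert "direction-inconsistent" not in res.flags
    smokers = GenotypeAssociation(tables[("rs12914385", "smokers")]).fit()
    assert "direction-inconsistent" not in smokers.flags


# ---------------------------------------------------------------------------
# power


def test_power_equals_alpha_under_null():
    assert study_power(500, 500, 0.37, 1.0, 0.05) == pytest.approx(0.05, abs=1e-9)


def test_power_monotone_in_cases():
    vals = [study_power(n, 553, 0.37, 1.3) for n in (100, 241, 500, 1000)]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_power_rejects_bad_alpha():
    with pytest.raises(ValueError):
        study_power(100, 100, 0.3, 1.3, alpha=1.5)


def test_power_agrees_with_monte_carlo():
    """Analytic non-central chi-square power vs 10,000 simulated trend tests."""
    n_cases, n_controls, p0, or_alt = 241, 553, 0.37, 1.3
    analytic = study_power(n_cases, n_controls, p0, or_alt, 0.05)
    rng = np.random.default_rng(5)
    # case genotype probabilities proportional to HWE(p0) * OR^g
    ctrl_probs = np.array([(1 - p0) ** 2, 2 * p0 * (1 - p0), p0**2])
    case_probs = ctrl_probs * or_alt ** np.arange(3)
    case_probs /= case_probs.sum()
    reps = 10_000
    r = rng.multinomial(n_cases, case_probs, size=reps).astype(float)
    s = rng.multinomial(n_controls, ctrl_probs, size=reps).astype(float)
    w = np.arange(3.0)
    n = r + s
    N, R = n.sum(axis=1), r.sum(axis=1)
    u = r @ w - R * (n @ w) / N
    var = R * (N - R) / (N - 1) * ((n @ w**2) / N - ((n @ w) / N) ** 2)
    chi2 = u**2 / var
    empirical = float(np.mean(chi2 > stats.chi2.isf(0.05, 1)))
    assert analytic == pytest.approx(empirical, abs=0.03)
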