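"""Gamete-elimination model: oracle equivalence, worked ratios, fitting."""

from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricebarrier import (
    CLASS_I,
    CLASS_II,
    CLASS_III,
    AlleleClass,
    CountsTable,
    TransmissionModel,
    chisq_gof,
    classify_cross,
    f2_genotype_freqs,
    fit_transmission,
    gamete_distribution,
    locus_marginal,
    simulate_f2_counts,
)


# ---------------------------------------------------------------------------
# Independent oracle: exact-rational enumeration of the 16 gamete pairs
# ---------------------------------------------------------------------------

def brute_force_joint(tau_m, tau_f, v, r, phase="repulsion"):
    """3x3 F2 genotype frequencies by exhaustive Fraction enumeration."""
    tau_m, tau_f, v, r = (Fraction(x).limit_denominator(10**6) for x in (tau_m, tau_f, v, r))

    def gametes(tau):
        par, rec = (1 - r) / 2, r / 2
        if phase == "repulsion":
            raw = {(1, 1): rec, (1, 0): par, (0, 1): par, (0, 0): rec}
        else:
            raw = {(1, 1): par, (1, 0): rec, (0, 1): rec, (0, 0): par}
        raw[(0, 0)] *= tau
        z = sum(raw.values())
        return {h: p / z for h, p in raw.items()}

    male, female = gametes(tau_m), gametes(tau_f)
    joint = [[Fraction(0)] * 3 for _ in range(3)]
    for (a1, a2), pm in male.items():
        for (b1, b2), pf in female.items():
            joint[2 - (a1 + b1)][2 - (a2 + b2)] += pm * pf
    joint[2][2] *= v
    z = sum(sum(row) for row in joint)
    return [[float(x / z) for x in row] for row in joint]


GRID = [
    (tm, tf, v, r)
    for tm, tf, v in product([0.0, 0.25, 0.5, 0.75, 1.0], repeat=3)
    for r in (0.0, 0.1, 0.5)
]


def test_f2_freqs_match_bruteforce_enumeration_over_grid():
    for tm, tf, v, r in GRID:
        got = np.array(f2_genotype_freqs(TransmissionModel(tm, tf, v, r)).matrix)
        want = np.array(brute_force_joint(tm, tf, v, r))
        assert np.max(np.abs(got - want)) < 1e-12, (tm, tf, v, r)


def test_coupling_phase_matches_bruteforce():
    got = np.array(f2_genotype_freqs(TransmissionModel(0.3, 0.7, 0.5, 0.1), "coupling").matrix)
    want = np.array(brute_force_joint(0.3, 0.7, 0.5, 0.1, "coupling"))
    assert np.max(np.abs(got - want)) < 1e-12


# ---------------------------------------------------------------------------
# Gamete distributions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "model,sex,expected",
    [
        (TransmissionModel(1, 1, 1, 0.5), "male", (0.25, 0.25, 0.25, 0.25)),
        (TransmissionModel(0, 1, 1, 0.5), "male", (1 / 3, 1 / 3, 1 / 3, 0.0)),
        (TransmissionModel(1, 0, 1, 0.5), "female", (1 / 3, 1 / 3, 1 / 3, 0.0)),
        (TransmissionModel(0, 1, 1, 0.0), "male", (0.0, 0.5, 0.5, 0.0)),
    ],
)
def test_gamete_distribution_worked_examples(model, sex, expected):
    got = gamete_distribution(model, sex, "repulsion").freqs
    assert got == pytest.approx(expected, abs=1e-12)


def test_gamete_distribution_rejects_bad_sex():
    with pytest.raises(ValueError):
        gamete_distribution(TransmissionModel(), "hermaphrodite")


# ---------------------------------------------------------------------------
# Marginals
# ---------------------------------------------------------------------------

def test_mendelian_limit_marginals_exact():
    joint = f2_genotype_freqs(TransmissionModel(1, 1, 1, 0.5))
    for locus in (1, 2):
        assert locus_marginal(joint, locus) == pytest.approx((0.25, 0.5, 0.25), abs=1e-15)
    # Mendelian reduction holds for any recombination fraction
    joint_r0 = f2_genotype_freqs(TransmissionModel(1, 1, 1, 0.0))
    assert locus_marginal(joint_r0, 2) == pytest.approx((0.25, 0.5, 0.25), abs=1e-15)


def test_full_elimination_marginals():
    joint = f2_genotype_freqs(TransmissionModel(0, 0, 1, 0.5))
    assert locus_marginal(joint, 2) == pytest.approx((4 / 9, 4 / 9, 1 / 9), abs=1e-12)
    # the donor's functional allele at locus 1 is preferentially transmitted:
    # parental display order puts the recurrent-parent (null) homozygote first
    assert locus_marginal(joint, 1, orientation="parental") == pytest.approx(
        (1 / 9, 4 / 9, 4 / 9), abs=1e-12
    )


def test_sex_asymmetric_elimination_marginal():
    joint = f2_genotype_freqs(TransmissionModel(0, 1, 1, 0.5))
    assert locus_marginal(joint, 2) == pytest.approx((1 / 3, 1 / 2, 1 / 6), abs=1e-12)


def test_marginals_sum_to_one_and_locus_validation():
    joint = f2_genotype_freqs(TransmissionModel(0.3, 0.8, 0.2, 0.1))
    for locus in (1, 2):
        assert sum(locus_marginal(joint, locus)) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        locus_marginal(joint, 3)


def test_locus_swap_symmetry_transposes_joint():
    # Both phases treat the two loci interchangeably (the doubly-null
    # haplotype is null at both), so swapping locus labels transposes the
    # joint matrix — which must therefore be symmetric.
    for phase in ("repulsion", "coupling"):
        for model in (TransmissionModel(0.4, 0.4, 0.6, 0.2), TransmissionModel(0.1, 0.9, 0.3, 0.35)):
            m = np.array(f2_genotype_freqs(model, phase).matrix)
            assert np.allclose(m, m.T, atol=1e-14), (phase, model)


def test_sterile_class_frequency_monotone_in_viabilities():
    def sterile(tm, tf, v):
        return f2_genotype_freqs(TransmissionModel(tm, tf, v, 0.5)).matrix[2][2]

    grid = [0.0, 0.25, 0.5, 0.75, 1.0]
    for a, b in zip(grid, grid[1:]):
        assert sterile(b, 0.5, 0.5) >= sterile(a, 0.5, 0.5) - 1e-15
        assert sterile(0.5, b, 0.5) >= sterile(0.5, a, 0.5) - 1e-15
        assert sterile(0.5, 0.5, b) >= sterile(0.5, 0.5, a) - 1e-15


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def test_chisq_gof_published_counts_vs_mendelian(published_f2_counts):
    res = chisq_gof(published_f2_counts, [1, 2, 1])
    assert res.statistic == pytest.approx(63.938, abs=0.01)
    assert res.df == 2
    assert res.p == pytest.approx(1.31e-14, rel=0.01)
    assert res.p < 0.001


def test_chisq_gof_published_counts_vs_elimination_model(published_f2_counts):
    res = chisq_gof(published_f2_counts, [4, 4, 1])
    assert res.statistic == pytest.approx(6.51, abs=0.01)
    assert res.p == pytest.approx(0.039, abs=0.001)


def test_chisq_gof_exact_fit_and_errors():
    assert chisq_gof([25, 50, 25], [1, 2, 1]).statistic == 0.0
    assert chisq_gof([25, 50, 25], [1, 2, 1]).p == 1.0
    with pytest.raises(ValueError):
        chisq_gof([1, 2, 3], [1, 0, 1])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def test_fit_mendelian_counts_gives_full_viability():
    counts = CountsTable(("W2W2", "W2G2", "G2G2"), (2500, 5000, 2500))
    fit = fit_transmission(counts, free=("tau",))
    assert fit.model.tau_m == pytest.approx(1.0, abs=0.02)


def test_fit_recovers_sex_specific_taus_up_to_exchange():
    truth = TransmissionModel(0.0, 0.2, 1.0, 0.5)
    for seed in range(3):
        counts, _ = simulate_f2_counts(10_000, truth, joint=True, seed=seed)
        fit = fit_transmission(counts, free=("tau_m", "tau_f"))
        got = sorted((fit.model.tau_m, fit.model.tau_f))
        assert got[0] == pytest.approx(0.0, abs=0.05)
        assert got[1] == pytest.approx(0.2, abs=0.05)


def test_fit_loglik_at_estimate_dominates_truth():
    truth = TransmissionModel(0.8, 0.8, 0.2, 0.5)
    for seed in range(5):
        counts, _ = simulate_f2_counts(10_000, truth, joint=True, seed=seed)
        fit = fit_transmission(counts, free=("tau", "v"))
        obs = np.array(counts.counts, float)
        from ricebarrier import expected_class_freqs

        ll_truth = float(obs @ np.log(expected_class_freqs(truth, counts.classes)))
        assert fit.log_likelihood >= ll_truth - 1e-6


def test_fit_rejects_overparameterized_marginal():
    counts = CountsTable(("W2W2", "W2G2", "G2G2"), (99, 113, 14))
    with pytest.raises(ValueError):
        fit_transmission(counts, free=("tau_m", "tau_f", "v"))


# ---------------------------------------------------------------------------
# Cross compatibility
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,verdict",
    [
        (CLASS_III, CLASS_II, "incompatible"),
        (CLASS_II, CLASS_III, "incompatible"),
        (CLASS_II, CLASS_II, "compatible"),
        (CLASS_I, CLASS_III, "compatible"),
        (CLASS_I, CLASS_II, "compatible"),
        (CLASS_I, CLASS_I, "compatible"),
        (CLASS_III, CLASS_III, "compatible"),
    ],
)
def test_cross_compatibility_truth_table(a, b, verdict):
    assert classify_cross(a, b) == verdict


@given(
    a1=st.booleans(), a2=st.booleans(), b1=st.booleans(), b2=st.booleans()
)
@settings(deadline=None, derandomize=True)
def test_classify_cross_symmetric(a1, a2, b1, b2):
    pa, pb = AlleleClass(a1, a2), AlleleClass(b1, b2)
    if not (pa.viable and pb.viable):
        with pytest.raises(ValueError):
            classify_cross(pa, pb)
        return
    assert classify_cross(pa, pb) == classify_cross(pb, pa)


def test_model_parameter_validation():
    with pytest.raises(ValueError):
        TransmissionModel(tau_m=1.2)
    with pytest.raises(ValueError):
        TransmissionModel(r=0.7)
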