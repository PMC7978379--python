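"""Allelic cell-state probabilities, observed fractions, and their agreement."""

import numpy as np
import pandas as pd
import pytest

from alleleburst import (
    InsufficientDataError,
    TwoStateKinetics,
    compare_predicted_observed,
    cross_validate,
    observed_state_fractions,
    poisson_state_comparison,
    prob_zero,
    state_probabilities,
    state_table,
)
from alleleburst.counts import AllelicCountMatrix
from alleleburst.states import STATES
from alleleburst.synthetic import PopulationSpec, generate_population


def make_pair(c57, cast, missing=None):
    c57 = np.atleast_2d(np.asarray(c57, dtype=float))
    cast = np.atleast_2d(np.asarray(cast, dtype=float))
    genes = [f"g{i}" for i in range(c57.shape[0])]
    cells = [f"c{j}" for j in range(c57.shape[1])]
    mask = np.zeros(c57.shape, dtype=bool) if missing is None else np.asarray(missing, bool)
    return (
        AllelicCountMatrix(cast, genes, cells, "CAST", mask),
        AllelicCountMatrix(c57, genes, cells, "C57", mask),
    )


class TestStateProbabilities:
    def test_symmetric_half_silence(self):
        # Beta(1,1) with k_syn solving (1-e^-s)/s = 1/2 gives P0 = 0.5 per allele
        from scipy.optimize import brentq

        s = brentq(lambda v: (1 - np.exp(-v)) / v - 0.5, 1e-6, 10)
        kin = TwoStateKinetics(1, 1, s)
        np.testing.assert_allclose(state_probabilities(kin, kin), [0.25] * 4, atol=1e-9)

    def test_product_formulas(self):
        kin_c57 = TwoStateKinetics(2, 1, 5)
        kin_cast = TwoStateKinetics(0.3, 3, 20)
        p0_c57, p0_cast = prob_zero(kin_c57), prob_zero(kin_cast)
        probs = state_probabilities(kin_c57, kin_cast)
        np.testing.assert_allclose(
            probs,
            [
                p0_c57 * p0_cast,
                (1 - p0_c57) * p0_cast,
                (1 - p0_cast) * p0_c57,
                (1 - p0_c57) * (1 - p0_cast),
            ],
            atol=1e-12,
        )
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_plug_in_quadruple(self):
        # P0_C57 = 0.2, P0_CAST = 0.5 -> (0.10, 0.40, 0.10, 0.40)
        from alleleburst.states import _probs_from_p0

        np.testing.assert_allclose(_probs_from_p0(0.2, 0.5), [0.10, 0.40, 0.10, 0.40])

    def test_both_silent(self):
        kin = TwoStateKinetics(1, 1, 0)
        np.testing.assert_allclose(state_probabilities(kin, kin), [1, 0, 0, 0])


class TestObservedFractions:
    def test_hand_enumeration(self):
        m_cast, m_c57 = make_pair(c57=[2, 0, 1], cast=[0, 0, 3])
        f = observed_state_fractions(m_cast, m_c57).iloc[0]
        assert f["f_silent"] == pytest.approx(1 / 3)
        assert f["f_mono_c57"] == pytest.approx(1 / 3)
        assert f["f_mono_cast"] == 0.0
        assert f["f_biallelic"] == pytest.approx(1 / 3)

    def test_all_silent(self):
        m_cast, m_c57 = make_pair(c57=[0, 0], cast=[0, 0])
        f = observed_state_fractions(m_cast, m_c57).iloc[0]
        assert f["f_silent"] == 1.0 and f["n_cells_used"] == 2

    def test_missing_cells_shrink_denominator(self):
        missing = np.array([[False, True, False, False]])
        m_cast, m_c57 = make_pair(c57=[1, 0, 0, 1], cast=[1, 0, 0, 0], missing=missing)
        f = observed_state_fractions(m_cast, m_c57).iloc[0]
        assert f["n_cells_used"] == 3
        assert f["f_biallelic"] == pytest.approx(1 / 3)
        assert f["f_mono_c57"] == pytest.approx(1 / 3)

    def test_fractions_sum_to_one(self, small_homogeneous):
        m_cast, m_c57, _ = small_homogeneous
        f = observed_state_fractions(m_cast, m_c57)
        sums = f[[f"f_{s}" for s in STATES]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)


class TestCompare:
    def _table(self, p, f):
        df = pd.DataFrame({f"p_{s}": p for s in STATES} | {f"f_{s}": f for s in STATES})
        return df

    def test_identity_gives_one(self):
        x = [0.1, 0.2, 0.3, 0.4, 0.5]
        rho = compare_predicted_observed(self._table(x, x))
        assert all(v == pytest.approx(1.0) for v in rho.values())

    def test_reversed_gives_minus_one(self):
        rho = compare_predicted_observed(
            self._table([0.1, 0.2, 0.3, 0.4], [0.4, 0.3, 0.2, 0.1])
        )
        assert all(v == pytest.approx(-1.0) for v in rho.values())

    def test_constant_reported_as_nan(self):
        rho = compare_predicted_observed(self._table([0.2, 0.2, 0.2], [0.1, 0.5, 0.9]))
        assert all(np.isnan(v) for v in rho.values())

    def test_too_few_genes(self):
        with pytest.raises(InsufficientDataError):
            compare_predicted_observed(self._table([0.1], [0.2]))


def test_observed_converges_to_predicted():
    # homogeneous model data: fractions approach probabilities as cells grow
    spec = PopulationSpec(n_genes=50, n_cells=5000, seed=21)
    m_cast, m_c57, truth = generate_population(spec)
    kin = truth["kinetics"]
    kin = kin.loc[kin["subpopulation"] == 0, ["gene_id", "allele", "k_on", "k_off", "k_syn"]]
    table = state_table(kin, m_cast, m_c57)
    for s in STATES:
        gap = np.abs(table[f"p_{s}"] - table[f"f_{s}"]).max()
        assert gap < 0.05, s


def test_state_table_and_compare_on_homogeneous_fixture(small_homogeneous, kinetics_long):
    m_cast, m_c57, _ = small_homogeneous
    table = state_table(kinetics_long, m_cast, m_c57)
    np.testing.assert_allclose(
        table[[f"p_{s}" for s in STATES]].sum(axis=1), 1.0, atol=1e-9
    )
    rho = compare_predicted_observed(table)
    # 400 cells of noise still leave strong rank agreement with the truth
    assert all(v > 0.85 for v in rho.values()), rho


def test_predicted_monoallelic_profile_along_kinetics():
    # as burst frequency rises at fixed burst size, monoallelic expression
    # rises then falls (silent -> mono -> biallelic); at fixed frequency the
    # burst-size response is much flatter
    bf_grid = np.logspace(-2, 1.5, 25)
    p_mono_bf = []
    for bf in bf_grid:
        kin = TwoStateKinetics(bf, 100.0 / 20.0, 100.0)  # bs = 20
        p = state_probabilities(kin, kin)
        p_mono_bf.append(p[1] + p[2])
    p_mono_bf = np.array(p_mono_bf)
    peak = int(np.argmax(p_mono_bf))
    assert 0 < peak < len(bf_grid) - 1
    assert np.all(np.diff(p_mono_bf[: peak + 1]) > -1e-12)
    assert np.all(np.diff(p_mono_bf[peak:]) < 1e-12)

    bs_grid = np.logspace(np.log10(2), 2, 25)
    p_mono_bs = []
    for bs in bs_grid:
        kin = TwoStateKinetics(1.0, 100.0 / bs, 100.0)  # bf = 1
        p = state_probabilities(kin, kin)
        p_mono_bs.append(p[1] + p[2])
    assert np.ptp(p_mono_bs) < np.ptp(p_mono_bf)


@pytest.fixture(scope="module")
def medium_population():
    spec = PopulationSpec(n_genes=40, n_cells=301, seed=33)  # odd cell count
    return generate_population(spec)


class TestCrossValidation:
    def test_held_out_close_to_full_data(self, medium_population):
        m_cast, m_c57, truth = medium_population
        kin = truth["kinetics"]
        kin = kin.loc[kin["subpopulation"] == 0, ["gene_id", "allele", "k_on", "k_off", "k_syn"]]
        full = compare_predicted_observed(state_table(kin, m_cast, m_c57))
        held = cross_validate(m_cast, m_c57, seed=5)
        for s in ("silent", "biallelic"):
            assert abs(held[s] - full[s]) < 0.1, (s, held, full)

    def test_deterministic_under_seed(self, medium_population):
        m_cast, m_c57, _ = medium_population
        assert cross_validate(m_cast, m_c57, seed=7) == cross_validate(m_cast, m_c57, seed=7)

    def test_too_few_cells(self):
        m_cast, m_c57 = make_pair(np.zeros((1, 10)), np.zeros((1, 10)))
        with pytest.raises(InsufficientDataError):
            cross_validate(m_cast, m_c57, seed=0)


class TestPoissonBaselineStates:
    def test_silent_probability_from_means(self):
        m_cast, m_c57 = make_pair(c57=[1, 1], cast=[1, 1])
        out = poisson_state_comparison(m_cast, m_c57)
        assert out["p_silent"].iloc[0] == pytest.approx(np.exp(-2), abs=1e-12)

    def test_zero_mean_is_silent(self):
        m_cast, m_c57 = make_pair(c57=[0, 0], cast=[0, 0])
        out = poisson_state_comparison(m_cast, m_c57)
        assert out["p_silent"].iloc[0] == 1.0

    def test_poisson_overestimates_biallelic_for_bursty_gene(self):
        # bursty gene: bf 0.3, bs 30
        kin = TwoStateKinetics(0.3, 100.0 / 30.0, 100.0)
        from alleleburst import sample

        rng = np.random.default_rng(17)
        c57 = sample(kin, 2000, rng)
        cast = sample(kin, 2000, rng)
        m_cast, m_c57 = make_pair(c57=c57, cast=cast)
        poisson_p_bi = poisson_state_comparison(m_cast, m_c57)["p_biallelic"].iloc[0]
        two_state_p_bi = state_probabilities(kin, kin)[3]
        assert poisson_p_bi > two_state_p_bi
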