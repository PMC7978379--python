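"""Observed/expected biallelic expression and permutation calibration."""

import numpy as np
import pandas as pd
import pytest

from alleleburst import (
    InsufficientDataError,
    InvalidParameterError,
    cell_permutation_test,
    expression_matched_control,
    gene_permutation_test,
    median_oe,
    mixing_experiment,
    oe_biallelic,
)
from alleleburst.heterogeneity import _perm_pvalue
from alleleburst.synthetic import PopulationSpec, Subpopulation, generate_population
from tests.test_states import make_pair


class TestOeBiallelic:
    def test_coexpressed_pair(self):
        m_cast, m_c57 = make_pair(c57=[1, 1, 0, 0], cast=[1, 1, 0, 0])
        rec = oe_biallelic(m_cast, m_c57).iloc[0]
        assert rec["observed"] == 0.5
        assert rec["expected"] == 0.25
        assert rec["ratio"] == 2.0

    def test_anticorrelated_pair(self):
        m_cast, m_c57 = make_pair(c57=[1, 0, 1, 0], cast=[0, 1, 0, 1])
        rec = oe_biallelic(m_cast, m_c57).iloc[0]
        assert rec["observed"] == 0.0 and rec["ratio"] == 0.0

    def test_all_biallelic(self):
        m_cast, m_c57 = make_pair(c57=[2, 1], cast=[1, 1])
        rec = oe_biallelic(m_cast, m_c57).iloc[0]
        assert rec["observed"] == rec["expected"] == rec["ratio"] == 1.0

    def test_silent_gene_flagged_undefined(self):
        m_cast, m_c57 = make_pair(c57=[0, 0], cast=[0, 0])
        rec = oe_biallelic(m_cast, m_c57).iloc[0]
        assert not rec["defined"] and np.isnan(rec["ratio"])

    def test_single_cell_rejected(self):
        m_cast, m_c57 = make_pair(c57=[[1]], cast=[[1]])
        with pytest.raises(InsufficientDataError):
            oe_biallelic(m_cast, m_c57)


class TestMedianOe:
    def test_median_of_ratios(self):
        rec = pd.DataFrame({"ratio": [1.0, 2.0, 3.0], "defined": True})
        assert median_oe(rec) == 2.0

    def test_single_gene(self):
        rec = pd.DataFrame({"ratio": [1.7], "defined": True})
        assert median_oe(rec) == 1.7

    def test_homogeneous_population_near_one(self):
        # independent alleles, one population: O ~ E per gene
        spec = PopulationSpec(n_genes=300, n_cells=500, seed=14)
        m_cast, m_c57, _ = generate_population(spec)
        med = median_oe(oe_biallelic(m_cast, m_c57))
        assert 0.95 <= med <= 1.05


class TestPermutationPvalue:
    def test_add_one_formula(self):
        null = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 20)  # 100 permutations
        assert _perm_pvalue(0.5, null, "lower") == pytest.approx(1 / 101)
        assert _perm_pvalue(10.0, null, "lower") == pytest.approx(1.0)
        assert _perm_pvalue(10.0, null, "upper") == pytest.approx(1 / 101)

    def test_bad_alternative(self):
        with pytest.raises(InvalidParameterError):
            _perm_pvalue(1.0, np.ones(3), "two-sided")


@pytest.fixture(scope="module")
def mixed_population():
    """Two equal subpopulations with disjoint active gene programs."""
    half_a = tuple(range(0, 40))
    half_b = tuple(range(40, 80))
    spec = PopulationSpec(
        n_genes=80,
        n_cells=400,
        seed=19,
        subpopulations=(
            Subpopulation(weight=0.5, multiplier=0.0, genes=half_b, target="k_syn"),
            Subpopulation(weight=0.5, multiplier=0.0, genes=half_a, target="k_syn"),
        ),
    )
    return generate_population(spec)


class TestGenePermutation:
    def test_focal_equals_universe_gives_p_near_one(self):
        spec = PopulationSpec(n_genes=100, n_cells=300, seed=23)
        m_cast, m_c57, _ = generate_population(spec)
        rec = oe_biallelic(m_cast, m_c57)
        res = gene_permutation_test(rec, list(rec.index), n_perm=200, seed=0)
        assert res.p_value > 0.5

    def test_detects_correlated_allele_genes(self):
        # positive control: copy the C57 counts onto CAST for focal genes so
        # their alleles co-occur perfectly -> high O/E, upper-tail significant
        spec = PopulationSpec(n_genes=100, n_cells=300, seed=29)
        m_cast, m_c57, _ = generate_population(spec)
        focal = m_cast.gene_ids[:10]
        m_cast.values[:10] = m_c57.values[:10]
        rec = oe_biallelic(m_cast, m_c57)
        res = gene_permutation_test(rec, focal, n_perm=500, seed=1, alternative="upper")
        assert res.p_value < 0.01
        assert res.p_value >= 1 / 501

    def test_zero_permutations_rejected(self):
        rec = pd.DataFrame({"ratio": [1.0, 2.0], "defined": True}, index=["a", "b"])
        with pytest.raises(InvalidParameterError):
            gene_permutation_test(rec, ["a"], n_perm=0)


class TestCellPermutation:
    def test_null_calibration_on_random_subsets(self):
        spec = PopulationSpec(n_genes=80, n_cells=300, seed=31)
        m_cast, m_c57, _ = generate_population(spec)
        rng = np.random.default_rng(0)
        n_nonsig = 0
        for rep in range(10):
            cells = rng.choice(300, size=40, replace=False)
            res = cell_permutation_test(m_cast, m_c57, cells, n_perm=99, seed=rep)
            if res.p_value > 0.05:
                n_nonsig += 1
        assert n_nonsig >= 8

    def test_pure_subpopulation_detected(self, mixed_population):
        m_cast, m_c57, truth = mixed_population
        # cells of subpopulation 0 form a pure cluster inside the mixture
        assignment = truth["cells"]["subpopulation"].to_numpy()
        cluster = np.nonzero(assignment == 0)[0][:50]
        res = cell_permutation_test(m_cast, m_c57, cluster, n_perm=99, seed=3)
        assert res.p_value < 0.05

    def test_zero_permutations_rejected(self, mixed_population):
        m_cast, m_c57, _ = mixed_population
        with pytest.raises(InvalidParameterError):
            cell_permutation_test(m_cast, m_c57, [0, 1, 2], n_perm=0)


class TestMixtureRatio:
    def test_fifty_fifty_mixture_doubles_ratio(self, mixed_population):
        # a gene active (both alleles) in only half the cells has O/E -> 1/w = 2
        m_cast, m_c57, _ = mixed_population
        med = median_oe(oe_biallelic(m_cast, m_c57))
        assert 1.6 <= med <= 2.4


class TestExpressionMatchedControl:
    def _records_with_gradient(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        expr = np.exp(rng.uniform(np.log(0.1), np.log(50), n))
        # O/E ratio increases with expression: a deliberate confounded gradient
        ratio = 1.0 + 0.3 * np.log10(expr) + rng.normal(0, 0.02, n)
        idx = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
        rec = pd.DataFrame({"ratio": ratio, "defined": True}, index=idx)
        return rec, pd.Series(expr, index=idx)

    def test_matched_control_removes_expression_confound(self):
        rec, expr = self._records_with_gradient()
        # every other gene among the top-expressed half: expression-skewed but
        # leaves matched candidates in every bin
        focal = list(expr.sort_values().index[-80::2])
        matched = expression_matched_control(
            rec, focal, expr, seed=1, n_controls=200, n_bins=20
        )
        unmatched = gene_permutation_test(rec, focal, n_perm=200, seed=1).null_medians
        focal_median = float(np.median(rec.loc[focal, "ratio"]))
        # matched controls sit close to the focal median; unmatched sit lower
        assert abs(np.mean(matched) - focal_median) < abs(np.mean(unmatched) - focal_median)

    def test_random_focal_set_centred(self):
        rec, expr = self._records_with_gradient(seed=5)
        rng = np.random.default_rng(2)
        focal = list(rng.choice(rec.index, size=40, replace=False))
        matched = expression_matched_control(
            rec, focal, expr, seed=3, n_controls=200, n_bins=20
        )
        assert abs(np.mean(matched) - np.median(rec["ratio"])) < 0.1

    def test_exhausted_bin_raises_with_bin_name(self):
        rec, expr = self._records_with_gradient(seed=7)
        focal = list(expr.sort_values().index[-15:])  # all genes of the top bins
        with pytest.raises(InsufficientDataError, match="bin"):
            expression_matched_control(rec, focal, expr, seed=0, n_controls=10, n_bins=20)


class TestMixing:
    def test_zero_added_is_target_median(self, mixed_population):
        m_cast, m_c57, truth = mixed_population
        assignment = truth["cells"]["subpopulation"].to_numpy()
        tgt = np.nonzero(assignment == 0)[0][:60]
        src = np.nonzero(assignment == 1)[0][:60]
        out = mixing_experiment(m_cast, m_c57, src, tgt, [0], n_boot=5, seed=0)
        assert len(out) == 1
        assert out["median_oe"].iloc[0] == median_oe(oe_biallelic(m_cast, m_c57, cells=tgt))

    def test_dissimilar_clusters_raise_median(self, mixed_population):
        m_cast, m_c57, truth = mixed_population
        assignment = truth["cells"]["subpopulation"].to_numpy()
        tgt = np.nonzero(assignment == 0)[0][:60]
        src = np.nonzero(assignment == 1)[0][:60]
        out = mixing_experiment(m_cast, m_c57, src, tgt, [0, 2, 5, 10], n_boot=10, seed=1)
        means = out.groupby("n_added")["median_oe"].mean()
        assert means.loc[10] > means.loc[0]
        assert means.is_monotonic_increasing

    def test_similar_clusters_flat(self):
        # same kinetics everywhere: adding cells from one random half to the
        # other leaves the median O/E unchanged within noise
        spec = PopulationSpec(n_genes=80, n_cells=400, seed=37)
        m_cast, m_c57, _ = generate_population(spec)
        tgt = np.arange(0, 60)
        src = np.arange(200, 300)
        out = mixing_experiment(m_cast, m_c57, src, tgt, [0, 5, 10, 20], n_boot=10, seed=2)
        means = out.groupby("n_added")["median_oe"].mean()
        base = means.loc[0]
        spread = out.groupby("n_added")["median_oe"].std().fillna(0).max()
        assert np.all(np.abs(means - base) < max(0.05, 3 * spread))

    def test_overlapping_clusters_rejected(self, mixed_population):
        m_cast, m_c57, _ = mixed_population
        with pytest.raises(InvalidParameterError):
            mixing_experiment(m_cast, m_c57, [0, 1], [1, 2], [0], seed=0)
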