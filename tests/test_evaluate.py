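import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survsig import (
    ContractError,
    ExpressionMatrix,
    GeneSet,
    PhenotypeLabels,
    auc,
    auc_sum,
    gene_correlation,
    pca_projection,
    random_signature_null,
    roc_curve,
)
from survsig.simulate import CohortSimConfig, simulate_cohort

from conftest import brute_force_auc


def _labels(outcomes):
    return PhenotypeLabels(
        {f"s{i}": ("survivor" if o else "non_survivor") for i, o in enumerate(outcomes)}
    )


def _scores(values):
    return pd.Series(values, index=[f"s{i}" for i in range(len(values))])


class TestAuc:
    def test_perfect_separation(self):
        assert auc(_scores([1, 2, 3, 4]), _labels([0, 0, 1, 1])) == 1.0

    def test_all_ties(self):
        assert auc(_scores([5, 5, 5, 5]), _labels([0, 1, 0, 1])) == 0.5

    def test_pair_counting_hand_example(self):
        # pairs: (1v3)=0, (1v2)=0, (4v3)=1, (4v2)=1 -> 2/4
        assert auc(_scores([3, 1, 2, 4]), _labels([0, 1, 0, 1])) == 0.5

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 31)
            outcomes = np.zeros(n, dtype=int)
            outcomes[: rng.integers(1, n)] = 1
            rng.shuffle(outcomes)
            if outcomes.sum() in (0, n):
                continue
            values = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            got = auc(_scores(values), _labels(outcomes))
            expected = brute_force_auc(values[outcomes == 1], values[outcomes == 0])
            assert got == pytest.approx(expected, abs=0)

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        values = rng.normal(size=50)
        outcomes = rng.integers(0, 2, size=50)
        outcomes[0], outcomes[1] = 0, 1
        assert auc(_scores(values), _labels(outcomes)) == pytest.approx(
            roc_auc_score(outcomes, values)
        )

    @given(
        values=st.lists(st.integers(min_value=-5, max_value=5), min_size=4, max_size=20),
        outcomes=st.lists(st.booleans(), min_size=4, max_size=20),
    )
    @settings(max_examples=100, deadline=None)
    def test_flip_complementarity(self, values, outcomes):
        n = min(len(values), len(outcomes))
        values, outcomes = values[:n], outcomes[:n]
        if not (0 < sum(outcomes) < n):
            return
        forward = auc(_scores([float(v) for v in values]), _labels(outcomes))
        backward = auc(_scores([-float(v) for v in values]), _labels(outcomes))
        assert forward + backward == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            auc(_scores([1, 2, 3]), _labels([1, 1, 1]))


class TestRocCurve:
    def test_perfect_curve_hits_corner(self):
        roc = roc_curve(_scores([1, 2, 3, 4]), _labels([0, 0, 1, 1]))
        corner = (roc.sensitivity == 1.0) & (roc.specificity == 1.0)
        assert corner.any()
        assert roc.auc == 1.0

    def test_single_distinct_score_is_chance(self):
        roc = roc_curve(_scores([2, 2, 2, 2]), _labels([0, 1, 0, 1]))
        assert roc.auc == pytest.approx(0.5)
        assert len(roc.thresholds) == 1

    def test_monotone_and_area_equals_auc(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(6, 40)
            outcomes = rng.integers(0, 2, size=n)
            if outcomes.sum() in (0, n):
                continue
            values = rng.integers(0, 5, size=n).astype(float)
            roc = roc_curve(_scores(values), _labels(outcomes))
            assert np.all(np.diff(roc.sensitivity) >= 0)
            assert np.all(np.diff(roc.specificity) <= 0)
            assert roc.auc == pytest.approx(auc(_scores(values), _labels(outcomes)))

    def test_labels_independent_of_scores_near_chance(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=4000)
        outcomes = rng.integers(0, 2, size=4000)
        roc = roc_curve(_scores(values), _labels(outcomes))
        assert roc.auc == pytest.approx(0.5, abs=0.03)


class TestAucSum:
    def test_worked_composites(self):
        assert auc_sum([0.89, 0.69]) == pytest.approx(1.58)
        assert auc_sum([0.97, 0.91]) == pytest.approx(1.88)

    def test_chance_baseline(self):
        assert auc_sum([0.5, 0.5]) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            auc_sum([0.5, 1.2])
        with pytest.raises(ContractError):
            auc_sum([])


def _null_world(seed=0, effect=1.5):
    planted = [f"PG{i}" for i in range(5)]
    config = CohortSimConfig(n_genes=120, n_survivors=40, n_nonsurvivors=40,
                             planted_genes=planted, effect_size=effect, seed=seed)
    matrix, labels, truth = simulate_cohort(config)
    return matrix, labels, truth


class TestRandomSignatureNull:
    def test_same_seed_identical_draws(self):
        matrix, labels, truth = _null_world()
        universe = GeneSet("genome", frozenset(matrix.gene_ids))
        kwargs = dict(cohorts=[(matrix, labels)], universe=universe, k=5,
                      n_draws=50, seed=9, observed_genes=truth.sorted_genes)
        n1 = random_signature_null(**kwargs)
        n2 = random_signature_null(**kwargs)
        np.testing.assert_array_equal(n1.draws, n2.draws)
        assert n1.empirical_p == n2.empirical_p

    def test_degenerate_universe_p_one(self):
        matrix, labels, truth = _null_world()
        universe = GeneSet("self", truth.genes)
        null = random_signature_null(
            [(matrix, labels)], universe, k=len(truth), n_draws=25, seed=1,
            observed_genes=truth.sorted_genes,
        )
        assert null.empirical_p == 1.0
        np.testing.assert_allclose(null.draws, null.observed)

    def test_planted_signature_beats_genome_null(self):
        matrix, labels, truth = _null_world(effect=1.5)
        universe = GeneSet("genome", frozenset(matrix.gene_ids))
        null = random_signature_null(
            [(matrix, labels)], universe, k=5, n_draws=200, seed=2,
            observed_genes=truth.sorted_genes,
        )
        assert null.observed > null.percentile(95)
        assert null.empirical_p < 0.05

    def test_add_one_rule_never_zero(self):
        matrix, labels, truth = _null_world()
        universe = GeneSet("genome", frozenset(matrix.gene_ids))
        null = random_signature_null(
            [(matrix, labels)], universe, k=5, n_draws=20, seed=3,
            observed_genes=truth.sorted_genes,
        )
        assert null.empirical_p >= 1.0 / 21.0

    def test_contract_errors(self):
        matrix, labels, truth = _null_world()
        tiny = GeneSet("tiny", frozenset(list(truth)[:2]))
        with pytest.raises(ContractError):
            random_signature_null([(matrix, labels)], tiny, k=5, n_draws=10, seed=0)
        genome = GeneSet("genome", frozenset(matrix.gene_ids))
        with pytest.raises(ContractError):
            random_signature_null([(matrix, labels)], genome, k=5, n_draws=0, seed=0)

    def test_per_cohort_draws_emitted(self):
        matrix, labels, truth = _null_world()
        universe = GeneSet("genome", frozenset(matrix.gene_ids))
        null = random_signature_null(
            [(matrix, labels), (matrix, labels)], universe, k=3, n_draws=10, seed=4,
            observed_genes=truth.sorted_genes,
        )
        assert null.cohort_draws.shape == (10, 2)
        np.testing.assert_allclose(null.cohort_draws.sum(axis=1), null.draws)


class TestGeneCorrelation:
    def test_trivial_cases(self):
        matrix = ExpressionMatrix.from_arrays(
            ["A", "B", "C"],
            ["s1", "s2", "s3"],
            np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 2.0, 1.0]]),
        )
        corr = gene_correlation(matrix, ["A", "B", "C"])
        assert corr.loc["A", "A"] == 1.0
        assert corr.loc["A", "B"] == pytest.approx(1.0)
        assert corr.loc["A", "C"] == pytest.approx(-1.0)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)

    def test_zero_variance_gene_flagged_nan(self, caplog):
        matrix = ExpressionMatrix.from_arrays(
            ["A", "FLAT"], ["s1", "s2", "s3"],
            np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]),
        )
        with caplog.at_level("WARNING", logger="survsig"):
            corr = gene_correlation(matrix, ["A", "FLAT"])
        assert np.isnan(corr.loc["A", "FLAT"])
        assert corr.loc["A", "A"] == 1.0

    def test_correlated_block_shows_high_correlation(self):
        config = CohortSimConfig(n_genes=10, n_survivors=200, n_nonsurvivors=200,
                                 planted_genes=["A", "B", "C"], effect_size=0.0,
                                 block_correlation=0.8, seed=5)
        matrix, _, truth = simulate_cohort(config)
        corr = gene_correlation(matrix, truth.sorted_genes)
        off = corr.to_numpy()[np.triu_indices(3, k=1)]
        assert off.min() > 0.6

    def test_too_few_samples(self, tiny_matrix):
        two = ExpressionMatrix(tiny_matrix.data.iloc[:, :2])
        with pytest.raises(ContractError):
            gene_correlation(two, ["GA"])


class TestPcaProjection:
    def test_collinear_data_one_component(self):
        t = np.linspace(0, 1, 12)
        matrix = ExpressionMatrix.from_arrays(
            ["A", "B"], [f"s{i}" for i in range(12)], np.vstack([t, 2 * t])
        )
        result = pca_projection(matrix, ["A", "B"])
        assert result.variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_noise_splits_evenly(self):
        rng = np.random.default_rng(6)
        matrix = ExpressionMatrix.from_arrays(
            ["A", "B"], [f"s{i}" for i in range(5000)], rng.normal(0, 1, (2, 5000))
        )
        result = pca_projection(matrix, ["A", "B"])
        assert result.variance_ratio[0] == pytest.approx(0.5, abs=0.05)
        assert result.variance_ratio[0] >= result.variance_ratio[1]

    def test_sign_canonicalized(self):
        rng = np.random.default_rng(7)
        matrix = ExpressionMatrix.from_arrays(
            ["A", "B", "C"], [f"s{i}" for i in range(20)], rng.normal(0, 1, (3, 20))
        )
        result = pca_projection(matrix, ["A", "B", "C"])
        for col in result.loadings.columns:
            load = result.loadings[col].to_numpy()
            assert load[np.argmax(np.abs(load))] > 0

    def test_matches_sklearn_reference(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(8)
        values = rng.normal(0, 1, (4, 25))
        matrix = ExpressionMatrix.from_arrays(
            ["A", "B", "C", "D"], [f"s{i}" for i in range(25)], values
        )
        result = pca_projection(matrix, ["A", "B", "C", "D"])
        ref = PCA(n_components=2).fit(values.T)
        np.testing.assert_allclose(
            result.variance_ratio, ref.explained_variance_ratio_, atol=1e-10
        )
        np.testing.assert_allclose(
            np.abs(result.coordinates.to_numpy()),
            np.abs(ref.transform(values.T)),
            atol=1e-8,
        )

    def test_fewer_than_two_genes_rejected(self, tiny_matrix):
        with pytest.raises(ContractError):
            pca_projection(tiny_matrix, ["GA"])
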