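"""Partitioning, bootstrap selection frequencies, overlap, and the full pipeline."""

import numpy as np
import pandas as pd
import pytest

import stabsig
from stabsig import (StabilityConfig, ValidationError, bootstrap_select,
                     make_partitions, median_coefficients, overlap_features,
                     run_stability_pipeline, top_frequency_features, truth_overlap)
from stabsig.stability import SelectionFrequencyTable


def _cfg(**kw):
    defaults = dict(n_partitions=5, alpha_grid=(0.5, 1.0), n_bootstrap=10,
                    n_lambda=20, master_seed=7)
    return StabilityConfig(**{**defaults, **kw})


class TestMakePartitions:
    def test_sizes_and_stratification(self):
        y = np.array(["R"] * 5 + ["NR"] * 5)
        parts = make_partitions(y, _cfg(n_partitions=20))
        for train, test in parts:
            assert len(train) == 7 and len(test) == 3
            n_r = (y[train] == "R").sum()
            assert n_r in (3, 4)

    def test_partition_property(self):
        y = np.array([0, 1] * 8)
        for train, test in make_partitions(y, _cfg(n_partitions=10)):
            assert len(np.intersect1d(train, test)) == 0
            assert len(np.union1d(train, test)) == len(y)

    def test_reproducible_and_seed_indexed(self):
        y = np.array([0, 1] * 10)
        a = make_partitions(y, _cfg(n_partitions=6))
        b = make_partitions(y, _cfg(n_partitions=6))
        assert all(np.array_equal(t1, t2) for (t1, _), (t2, _) in zip(a, b))
        # partitions differ from each other
        assert not np.array_equal(a[0][0], a[1][0])

    def test_class_too_small(self):
        y = np.array([0] * 10 + [1])
        with pytest.raises(ValidationError, match=">= 2"):
            make_partitions(y, _cfg())

    def test_nonbinary_rejected(self):
        with pytest.raises(ValidationError, match="binary"):
            make_partitions(np.array([0, 1, 2, 0, 1, 2]), _cfg())


class TestBootstrapSelect:
    def _data(self, rng, n=30, p=10):
        X = rng.standard_normal((n, p))
        y = (rng.random(n) < 0.5).astype(float)
        y[:2] = [0, 1]
        return X, y

    def test_zero_bootstraps(self, rng):
        X, y = self._data(rng)
        counts, values = bootstrap_select(X, y, 0.5, 0.1, n_bootstrap=0, seed=0)
        assert counts.sum() == 0 and all(not v for v in values)

    def test_perfect_feature_always_selected(self, rng):
        X, y = self._data(rng, n=40)
        X[:, 3] = y * 2 - 1
        counts, values = bootstrap_select(X, y, 0.5, 0.02, n_bootstrap=20, seed=1)
        assert counts[3] == 20
        assert len(values[3]) == 20
        assert all(v > 0 for v in values[3])

    def test_column_permutation_equivariance(self, rng):
        X, y = self._data(rng, n=40, p=8)
        counts, _ = bootstrap_select(X, y, 0.5, 0.05, n_bootstrap=15, seed=2)
        perm = rng.permutation(8)
        counts_p, _ = bootstrap_select(X[:, perm], y, 0.5, 0.05, n_bootstrap=15, seed=2)
        assert np.array_equal(counts_p, counts[perm])

    def test_counts_bounded_by_n_bootstrap(self, rng):
        X, y = self._data(rng)
        counts, _ = bootstrap_select(X, y, 1.0, 0.01, n_bootstrap=12, seed=3)
        assert counts.max() <= 12

    def test_selection_nonincreasing_in_lambda(self, rng):
        """At fixed bootstrap resamples, larger λ never selects a gene more often."""
        X, y = self._data(rng, n=50, p=12)
        X[:, 0] = y * 2 - 1 + rng.normal(0, 0.5, 50)
        ladder = [0.01, 0.03, 0.1, 0.3]
        per_lam = [bootstrap_select(X, y, 0.5, lam, n_bootstrap=20, seed=9)[0]
                   for lam in ladder]
        for lo, hi in zip(per_lam[:-1], per_lam[1:]):
            assert np.all(hi <= lo)

    def test_invalid_lambda(self, rng):
        X, y = self._data(rng)
        with pytest.raises(ValueError):
            bootstrap_select(X, y, 0.5, 0.0, n_bootstrap=5, seed=0)


class TestTopFrequencyFeatures:
    def test_simple_top_k(self):
        assert top_frequency_features({"a": 100, "b": 50, "c": 10}, 2) == ["a", "b"]

    def test_boundary_tie_by_mean_abs_coef(self):
        out = top_frequency_features({"a": 100, "b": 50, "c": 50}, 2,
                                     {"a": 1.0, "b": 0.9, "c": 0.2})
        assert out == ["a", "b"]

    def test_fewer_than_k_warns(self):
        counts = {"a": 3, "b": 2, "c": 0, "d": 0}
        with pytest.warns(UserWarning, match="only 2"):
            out = top_frequency_features(counts, 33)
        assert out == ["a", "b"]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            top_frequency_features({"a": 1}, 0)


class TestOverlapFeatures:
    def test_shared_set_both_modes(self):
        sets = {(p, a): ["x", "y"] for p in range(3) for a in (0.5, 1.0)}
        assert overlap_features(sets, "strict") == {"x", "y"}
        assert overlap_features(sets, "fraction", q=0.5) == {"x", "y"}

    def test_fraction_vs_strict(self):
        # gene "g" is in every alpha's stable set for 3 of 5 partitions (60%)
        sets = {}
        for p in range(5):
            for a in (0.5, 1.0):
                sets[(p, a)] = ["g", "h"] if p < 3 else ["h"]
        assert "g" not in overlap_features(sets, "strict")
        assert "g" in overlap_features(sets, "fraction", q=0.5)
        assert "h" in overlap_features(sets, "strict")

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            overlap_features({}, "strict")


class TestMedianCoefficients:
    def _freq(self, values):
        counts = pd.DataFrame([(0, 0.5, g, len(v)) for g, v in values.items()],
                              columns=["partition", "alpha", "gene_id", "count"])
        return SelectionFrequencyTable(counts=counts, coef_values=values,
                                       n_bootstrap=100)

    def test_odd_median(self):
        sig = median_coefficients(self._freq({"a": [0.2, 0.4, 0.9]}), {"a"})
        assert sig.weights()["a"] == pytest.approx(0.4)

    def test_even_median(self):
        sig = median_coefficients(self._freq({"a": [-0.2, -0.4]}), {"a"})
        assert sig.weights()["a"] == pytest.approx(-0.3)

    def test_never_selected_gene_rejected(self):
        with pytest.raises(ValidationError, match="never selected"):
            median_coefficients(self._freq({"a": [0.1]}), {"a", "ghost"})


class TestPipeline:
    @pytest.fixture(scope="class")
    def pipeline_inputs(self, planted_cohort):
        cm, meta, truth = planted_cohort
        cm, _ = stabsig.filter_genes(cm)
        expr = stabsig.log2_normalized(cm)
        labeled = meta[(meta["arm"] == "treated") & meta["response"].isin(["R", "NR"])]
        pos = {s: i for i, s in enumerate(expr.sample_ids)}
        X = expr.values[:, [pos[s] for s in labeled["sample_id"]]].T
        y = (labeled["response"] == "R").to_numpy(float)
        return X, y, list(expr.gene_ids), truth

    def test_planted_recovery_and_reproducibility(self, pipeline_inputs):
        X, y, genes, truth = pipeline_inputs
        cfg = _cfg(n_partitions=8, n_bootstrap=15)
        freq, sig, diag = run_stability_pipeline(X, y, genes, cfg)
        freq2, sig2, _ = run_stability_pipeline(X, y, genes, cfg)
        pd.testing.assert_frame_equal(sig.entries, sig2.entries)
        pd.testing.assert_frame_equal(freq.counts, freq2.counts)
        recall, precision = truth_overlap(set(sig.gene_ids), truth)
        assert recall >= 0.5 and precision >= 0.8
        # recovered coefficient signs match the planted directions
        for g, w in sig.weights().items():
            if g in truth.planted_pos:
                assert w > 0
            elif g in truth.planted_neg:
                assert w < 0

    def test_gene_relabeling_equivariance(self, pipeline_inputs):
        X, y, genes, _ = pipeline_inputs
        cfg = _cfg(n_partitions=3, n_bootstrap=8)
        _, sig, _ = run_stability_pipeline(X, y, genes, cfg)
        renamed = [f"x_{g}" for g in genes]
        _, sig_r, _ = run_stability_pipeline(X, y, renamed, cfg)
        assert [f"x_{g}" for g in sig.gene_ids] == sig_r.gene_ids
        assert np.allclose(sig.entries["median_coefficient"],
                           sig_r.entries["median_coefficient"])

    def test_permuted_labels_recall_collapses(self, pipeline_inputs):
        X, y, genes, truth = pipeline_inputs
        rng = np.random.default_rng(123)
        y_perm = rng.permutation(y)
        cfg = _cfg(n_partitions=8, n_bootstrap=15)
        _, sig, _ = run_stability_pipeline(X, y_perm, genes, cfg)
        recall, _ = truth_overlap(set(sig.gene_ids), truth)
        assert recall <= 0.1

    def test_recall_monotone_in_effect_size(self):
        """Mean planted-gene recall never decreases as the planted effect grows."""
        import warnings

        def recall_at(effect, seed):
            cfg = stabsig.SimulationConfig(
                n_genes=200, n_signal_pos=5, n_signal_neg=5, effect_log2fc=effect,
                placebo_progression_genes=10,
                studies={"A": stabsig.StudyDesign(n_treated_R=20, n_treated_NR=20),
                         "B": stabsig.StudyDesign(n_treated_R=20, n_treated_NR=20)},
                seed=seed)
            cm, meta, truth = stabsig.simulate_cohort(cfg)
            cm, _ = stabsig.filter_genes(cm)
            expr = stabsig.log2_normalized(cm)
            lab = meta[meta["response"].isin(["R", "NR"])]
            pos = {s: i for i, s in enumerate(expr.sample_ids)}
            X = expr.values[:, [pos[s] for s in lab["sample_id"]]].T
            y = (lab["response"] == "R").to_numpy(float)
            cfg_s = _cfg(n_partitions=8, n_bootstrap=15, n_lambda=25, master_seed=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    _, sig, _ = run_stability_pipeline(X, y, expr.gene_ids, cfg_s)
                    genes = set(sig.gene_ids)
                except ValidationError:
                    genes = set()
            return truth_overlap(genes, truth)[0]

        means = [np.mean([recall_at(e, s) for s in (11, 12, 13)])
                 for e in (0.5, 1.0, 2.0, 3.0)]
        assert all(b >= a for a, b in zip(means, means[1:]))
        assert means[-1] >= 0.8

    def test_cv_curves_cover_all_scenarios(self, pipeline_inputs):
        X, y, genes, _ = pipeline_inputs
        cfg = _cfg(n_partitions=2, alpha_grid=(0.0, 0.5, 1.0), n_bootstrap=5)
        _, _, diag = run_stability_pipeline(X, y, genes, cfg)
        curves = diag["cv_curves"]
        assert set(curves["alpha"].unique()) == {0.0, 0.5, 1.0}
        # ridge contributes diagnostics but no stable set
        assert all(a != 0.0 for _, a in diag["stable_sets"])
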