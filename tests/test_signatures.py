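"""Wilcoxon DE, Pearson correlation signatures, and signature set algebra."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from stabsig import (GeneSignature, ValidationError, combine_signatures,
                     exclude_placebo_correlated, pearson_signature, pearson_with_p,
                     top_k_signature, wilcoxon_de, wilcoxon_rank_sum)
from .conftest import as_normalized


def exact_wilcoxon_p(a, b):
    """Full-enumeration two-sided rank-sum p (tie-free data only)."""
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    ra = ranks[: len(a)].sum()
    n = len(pooled)
    mean_ra = len(a) * (n + 1) / 2.0
    observed = abs(ra - mean_ra)
    count = total = 0
    for combo in itertools.combinations(range(n), len(a)):
        total += 1
        if abs(ranks[list(combo)].sum() - mean_ra) >= observed - 1e-9:
            count += 1
    return count / total


class TestWilcoxonRankSum:
    def test_separated_groups_exact_p(self):
        _, p = wilcoxon_rank_sum([1.2, 2.3, 3.1], [0.1, 0.2, 0.3])
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        _, p = wilcoxon_rank_sum([1.2, 2.3, 3.1], [1.2, 2.3, 3.1])
        assert p == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            na, nb = rng.integers(2, 7, size=2)
            pooled = rng.permutation(rng.standard_normal(na + nb))  # tie-free
            a, b = pooled[:na], pooled[na:]
            _, p = wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(exact_wilcoxon_p(a, b), abs=1e-12)

    def test_large_groups_use_normal_approximation(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30) + 1.0
        _, p = wilcoxon_rank_sum(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, method="asymptotic").pvalue
        assert p == pytest.approx(ref)


class TestWilcoxonDE:
    def _expr(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2.0, 2.0, size=(20, 10))
        vals[0, :5] += 10.0  # strongly up in group A
        vals[1] = 0.0
        vals[1, 0] = 3.0  # detected in 1/5 of A only
        return as_normalized(vals)

    def test_detection_filter_excludes_sparse_gene(self):
        expr = self._expr()
        a = expr.sample_ids[:5]
        b = expr.sample_ids[5:]
        de = wilcoxon_de(expr, a, b, min_detect_frac=0.25)
        assert "g1" not in set(de["gene_id"])
        assert "g0" in set(de["gene_id"])

    def test_bonferroni_over_tested_only(self):
        expr = self._expr()
        de = wilcoxon_de(expr, expr.sample_ids[:5], expr.sample_ids[5:])
        n_tested = len(de)
        assert np.allclose(de["adjusted_p"],
                           np.minimum(1.0, de["p_value"] * n_tested))
        assert (de["adjusted_p"] >= de["p_value"] - 1e-15).all()
        assert (de["adjusted_p"] <= 1.0).all()

    def test_group_contract_errors(self):
        expr = self._expr()
        with pytest.raises(ValidationError, match="disjoint"):
            wilcoxon_de(expr, expr.sample_ids[:5], expr.sample_ids[4:])
        with pytest.raises(ValidationError, match=">= 2"):
            wilcoxon_de(expr, expr.sample_ids[:1], expr.sample_ids[5:])


class TestTopKSignature:
    def _de(self, n, seed=0):
        rng = np.random.default_rng(seed)
        w = rng.uniform(2.0, 6.0, size=n)
        return pd.DataFrame({
            "gene_id": [f"g{i:03d}" for i in range(n)],
            "log2_fc": rng.uniform(0.5, 3.0, size=n),
            "w_statistic": w * 10,
            "w_standardized": w,
            "p_value": rng.uniform(0.0, 1e-4, size=n),
            "adjusted_p": rng.uniform(0.0, 0.04, size=n),
        })

    def test_truncates_to_k_in_rank_order(self):
        de = self._de(60)
        sig = top_k_signature(de, "positive", k=50)
        assert len(sig) == 50
        stats = sig.entries["statistic"].to_numpy()
        assert (np.diff(np.abs(stats)) <= 1e-12).all()

    def test_fewer_than_k_warns(self):
        de = self._de(10)
        with pytest.warns(UserWarning, match="only 10"):
            sig = top_k_signature(de, "positive", k=50)
        assert len(sig) == 10

    def test_tie_broken_by_fold_change(self):
        de = pd.DataFrame({
            "gene_id": ["a", "b"], "log2_fc": [1.0, 2.0],
            "w_statistic": [30.0, 30.0], "w_standardized": [3.0, 3.0],
            "p_value": [1e-4, 1e-4], "adjusted_p": [1e-3, 1e-3]})
        sig = top_k_signature(de, "positive", k=2)
        assert sig.gene_ids == ["b", "a"]

    def test_direction_filters_sign(self):
        de = self._de(20)
        de.loc[:9, "log2_fc"] *= -1
        with pytest.warns(UserWarning):
            pos = top_k_signature(de, "positive", k=20)
            neg = top_k_signature(de, "negative", k=20)
        assert len(pos) == 10 and len(neg) == 10
        assert not set(pos.gene_ids) & set(neg.gene_ids)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            top_k_signature(self._de(5), "positive", k=0)


class TestPearson:
    def test_perfect_linearity(self):
        r, p = pearson_with_p([1, 2, 3], [2, 4, 6])
        assert r == 1.0 and p == 0.0

    def test_hand_example(self):
        r, p = pearson_with_p([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        t = 0.6 * np.sqrt(2 / (1 - 0.36))
        assert p == pytest.approx(2 * scipy.stats.t.sf(t, df=2), rel=1e-12)

    def test_matches_scipy(self, rng):
        for n in (3, 5, 30):
            x, y = rng.standard_normal((2, n))
            r, p = pearson_with_p(x, y)
            ref = scipy.stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-8)

    @given(st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3), st.floats(-10, 10))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(99)
        x, y = rng.standard_normal((2, 12))
        r0, _ = pearson_with_p(x, y)
        r1, _ = pearson_with_p(a * x + b, y)
        assert r1 == pytest.approx(np.sign(a) * r0, rel=1e-9, abs=1e-9)

    def test_null_p_uniform(self, rng):
        """Permutation-null p-values are uniform (KS check at 2,000 reps)."""
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        ps = []
        for _ in range(2000):
            _, p = pearson_with_p(x, rng.permutation(y))
            ps.append(p)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_inputs(self):
        with pytest.raises(ValidationError, match="zero variance"):
            pearson_with_p([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValidationError, match=">= 3"):
            pearson_with_p([1, 2], [1, 2])


class TestPearsonSignature:
    def test_planted_genes_recovered(self, planted_cohort):
        from stabsig import filter_genes, log2_normalized
        cm, meta, truth = planted_cohort
        cm, _ = filter_genes(cm)
        expr = log2_normalized(cm)
        treated = meta[meta["arm"] == "treated"]
        cols = [expr.sample_ids.index(s) for s in treated["sample_id"]]
        sub = as_normalized(expr.values[:, cols], expr.gene_ids,
                            list(treated["sample_id"]))
        y = treated.set_index("sample_id")["cpep_auc_pct_baseline_m6"]
        pos, neg = pearson_signature(sub, y, 0.05)
        present_pos = truth.planted_pos & set(cm.gene_ids)
        assert present_pos <= set(pos.gene_ids)
        assert not set(pos.gene_ids) & set(neg.gene_ids)

    def test_zero_threshold_empties_both(self, planted_cohort):
        from stabsig import log2_normalized
        cm, meta, _ = planted_cohort
        expr = log2_normalized(cm)
        y = meta.set_index("sample_id")["time_to_diagnosis"]
        pos, neg = pearson_signature(expr, y, 0.0)
        assert len(pos) == 0 and len(neg) == 0

    def test_null_signature_sizes(self, rng):
        """Permuted outcome: |pos| + |neg| ~ threshold * n_genes."""
        n_genes, n = 2000, 40
        expr = as_normalized(rng.standard_normal((n_genes, n)))
        y = rng.permutation(np.arange(n, dtype=float))
        pos, neg = pearson_signature(expr, y, 0.05)
        frac = (len(pos) + len(neg)) / n_genes
        se = np.sqrt(0.05 * 0.95 / n_genes)
        assert abs(frac - 0.05) < 3 * se

    def test_constant_outcome_rejected(self, rng):
        expr = as_normalized(rng.standard_normal((5, 6)))
        with pytest.raises(ValidationError, match="constant"):
            pearson_signature(expr, np.ones(6), 0.05)

    def test_ordered_by_p_then_abs_r(self, rng):
        expr = as_normalized(rng.standard_normal((100, 20)))
        y = rng.standard_normal(20)
        pos, _ = pearson_signature(expr, y, 0.5)
        p = pos.entries["p_value"].to_numpy()
        assert (np.diff(p) >= -1e-15).all()


class TestPlaceboExclusion:
    def _sig(self, genes):
        return GeneSignature(name="s", direction="positive",
                             entries=pd.DataFrame({
                                 "gene_id": genes,
                                 "statistic": np.linspace(0.9, 0.5, len(genes)),
                                 "p_value": np.linspace(0.001, 0.04, len(genes)),
                                 "adjusted_p": np.nan}))

    def test_no_placebo_signal_keeps_all(self, rng):
        sig = self._sig([f"g{i}" for i in range(5)])
        expr = as_normalized(rng.standard_normal((5, 12)))
        out = exclude_placebo_correlated(sig, expr, rng.standard_normal(12))
        assert out.gene_ids == sig.gene_ids

    def test_strong_placebo_signal_empties(self):
        sig = self._sig(["g0", "g1"])
        y = np.arange(12, dtype=float)
        vals = np.vstack([y * 2.0, -y])  # both genes perfectly track the outcome
        out = exclude_placebo_correlated(sig, as_normalized(vals), y)
        assert len(out) == 0

    def test_half_overlap_survivors(self, rng):
        sig = self._sig(["g0", "g1", "g2", "g3"])
        y = np.arange(20, dtype=float)
        vals = rng.standard_normal((4, 20))
        yc = y - y.mean()
        for i in (2, 3):  # make the non-planted genes exactly uncorrelated
            vals[i] -= yc * (vals[i] @ yc) / (yc @ yc)
        vals[0] = y + rng.normal(0, 0.1, 20)
        vals[1] = -y + rng.normal(0, 0.1, 20)
        out = exclude_placebo_correlated(sig, as_normalized(vals), y)
        assert out.gene_ids == ["g2", "g3"]


class TestCombineSignatures:
    def _sig(self, genes, direction="positive", name="x"):
        return GeneSignature(name=name, direction=direction,
                             entries=pd.DataFrame({
                                 "gene_id": genes,
                                 "statistic": np.linspace(1, 0.1, len(genes)),
                                 "p_value": np.linspace(0.001, 0.04, len(genes)),
                                 "adjusted_p": np.nan}))

    def test_idempotent(self):
        a = self._sig(["a", "b", "c"])
        assert combine_signatures(a, a).gene_ids == ["a", "b", "c"]

    def test_disjoint_empty(self):
        out = combine_signatures(self._sig(["a", "b"]), self._sig(["c", "d"]))
        assert len(out) == 0

    def test_intersection(self):
        out = combine_signatures(self._sig(["a", "b", "c"]), self._sig(["b", "c", "d"]))
        assert set(out.gene_ids) == {"b", "c"}

    def test_mean_rank_ordering(self):
        a = self._sig(["a", "b", "c"])      # ranks a=1 b=2 c=3
        b = self._sig(["c", "b", "a"])      # ranks c=1 b=2 a=3
        out = combine_signatures(a, b)       # all mean rank 2 -> lexicographic
        assert out.gene_ids == ["a", "b", "c"]

    def test_direction_mismatch(self):
        with pytest.raises(ValidationError, match="direction"):
            combine_signatures(self._sig(["a"]), self._sig(["a"], "negative"))
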