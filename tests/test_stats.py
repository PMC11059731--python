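import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kstest, spearmanr
from skbio.stats.distance import DistanceMatrix

import compng as c


def euclid_dm(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return DistanceMatrix(squareform(pdist(X)),
                          ids=[f"s{i}" for i in range(len(X))])


def brute_force_permanova(X, groups):
    """Independent oracle: enumerate every distinct relabeling and compute
    the pseudo-F from raw within-group squared distances."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    d2 = squareform(pdist(X)) ** 2
    labels = list(groups)
    levels = sorted(set(labels))
    a = len(levels)

    def f_of(lab):
        ss_t = d2[np.triu_indices(n, 1)].sum() / n
        ss_w = 0.0
        for lv in levels:
            idx = [i for i, l in enumerate(lab) if l == lv]
            sub = d2[np.ix_(idx, idx)]
            ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        with np.errstate(divide="ignore"):
            return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))

    f_obs = f_of(labels)
    perms = set(itertools.permutations(labels))
    b = sum(f_of(p) >= f_obs - 1e-12 for p in perms)
    return f_obs, b / len(perms)


class TestPseudoabundance:
    def test_paper_scale_arithmetic(self):
        assert c.pseudoabundance(75.9, 1.43e4) == pytest.approx(1.0854e4,
                                                                rel=1e-4)

    def test_identities(self):
        assert c.pseudoabundance(0.0, 123.0) == 0.0
        assert c.pseudoabundance(100.0, 55.5) == 55.5

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            c.pseudoabundance(101.0, 1.0)
        with pytest.raises(ValueError):
            c.pseudoabundance(50.0, -1.0)


class TestSpearman:
    def test_monotone_pair(self):
        res = c.spearman([1, 5, 9, 11], [2, 3, 10, 30])
        assert res.rho == 1.0

    def test_rank_formula_example(self):
        res = c.spearman([1, 2, 3], [3, 1, 2])
        assert res.rho == pytest.approx(-0.5)
        assert res.method == "exact-permutation"

    def test_exact_p_matches_direct_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        res = c.spearman(x, y)
        rhos = [spearmanr(x, p).statistic
                for p in itertools.permutations(y)]
        expect = np.mean([abs(r) >= abs(res.rho) - 1e-12 for r in rhos])
        assert res.p == pytest.approx(expect)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = c.spearman(x, y)
        ref = spearmanr(x, y)
        assert res.method == "t-approximation"
        assert res.rho == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = c.spearman(x, y)
        assert c.spearman(np.exp(x), y).rho == pytest.approx(base.rho)
        assert c.spearman(x, 3 * y - 7).rho == pytest.approx(base.rho)

    def test_constant_vector_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            res = c.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(res.rho)

    def test_pairwise_complete(self):
        res = c.spearman([1, 2, np.nan, 4], [4, 3, 9, 1])
        assert res.n == 3


class TestPermanova:
    def test_toy_exhaustive_matches_oracle(self):
        X = [0.0, 0.0, 0.0, 10.0, 10.0, 10.0]
        groups = ["a", "a", "a", "b", "b", "b"]
        res = c.permanova_oneway(euclid_dm(X), groups)
        f_ref, p_ref = brute_force_permanova(X, groups)
        assert res.method == "exhaustive" and res.n_perm == 20
        assert res.p == pytest.approx(p_ref)

    @pytest.mark.parametrize("sizes", [(3, 3), (4, 3), (4, 4), (2, 4)])
    def test_small_two_group_datasets_match_enumeration(self, sizes):
        rng = np.random.default_rng(sum(sizes))
        X = rng.normal(size=(sum(sizes), 3))
        groups = ["a"] * sizes[0] + ["b"] * sizes[1]
        res = c.permanova_oneway(euclid_dm(X), groups)
        f_ref, p_ref = brute_force_permanova(X, groups)
        assert res.method == "exhaustive"
        assert res.statistic == pytest.approx(f_ref)
        assert res.p == pytest.approx(p_ref)

    def test_statistic_matches_skbio(self):
        import skbio.stats.distance as sd
        rng = np.random.default_rng(10)
        X = rng.normal(size=(24, 4))
        groups = (["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        dm = euclid_dm(X)
        ours = c.permanova_oneway(dm, groups, n_perm=99, seed=0)
        ref = sd.permanova(dm, groups, permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"])

    def test_duplication_preserves_separation_signal(self):
        """Duplicating every sample leaves the SS_between/SS_within ratio
        unchanged; the pseudo-F differs only through its degrees of
        freedom, so F scales exactly by (2N-a)/(N-a)."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 2))
        n, a = 10, 2
        groups = ["a"] * 5 + ["b"] * 5
        f1 = c.permanova_oneway(euclid_dm(X), groups).statistic
        f2 = c.permanova_oneway(euclid_dm(np.vstack([X, X])),
                                groups * 2).statistic
        assert f2 == pytest.approx(f1 * (2 * n - a) / (n - a))

    def test_null_p_values_approximately_uniform(self):
        """On structureless data with random labels the permutation p-value
        must be close to uniform over replicates."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            X = rng.normal(size=(16, 3))
            groups = rng.permutation(["a"] * 8 + ["b"] * 8)
            res = c.permanova_oneway(euclid_dm(X), groups, n_perm=99,
                                     seed=int(rng.integers(2 ** 31)))
            ps.append(res.p)
        assert kstest(ps, "uniform").statistic < 0.12

    def test_errors(self):
        dm = euclid_dm([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="2 groups"):
            c.permanova_oneway(dm, ["a"] * 4)
        with pytest.raises(ValueError, match="fewer than 2"):
            c.permanova_oneway(dm, ["a", "a", "a", "b"])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_p_value_never_zero(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 2))
        groups = ["a"] * 6 + ["b"] * 6
        res = c.permanova_oneway(euclid_dm(X), groups, n_perm=49, seed=seed)
        assert res.p >= 1 / (res.n_perm + 1)


class TestPermdisp:
    def test_translated_copies_have_equal_dispersion(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 3))
        X = np.vstack([a, a + 5.0])
        res = c.permdisp(euclid_dm(X), ["a"] * 10 + ["b"] * 10,
                         n_perm=999, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.9

    def test_detects_inflated_dispersion(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(0, 5, (20, 3))])
        res = c.permdisp(euclid_dm(X), ["a"] * 20 + ["b"] * 20,
                         n_perm=999, seed=1)
        assert res.p <= 0.01

    def test_f_matches_hand_anova_on_toy(self):
        # 1-D points: deviations from group centroids are known exactly
        X = np.array([0.0, 2.0, 4.0, 10.0, 11.0, 12.0])
        groups = ["a"] * 3 + ["b"] * 3
        res = c.permdisp(euclid_dm(X), groups, n_perm=99, seed=0)
        z = np.array([2.0, 0.0, 2.0, 1.0, 0.0, 1.0])
        grand = z.mean()
        ss_b = sum(3 * (z[i:i + 3].mean() - grand) ** 2 for i in (0, 3))
        ss_w = sum(((z[i:i + 3] - z[i:i + 3].mean()) ** 2).sum()
                   for i in (0, 3))
        f_ref = (ss_b / 1) / (ss_w / 4)
        assert res.statistic == pytest.approx(f_ref)

    def test_statistic_matches_skbio(self):
        import skbio.stats.distance as sd
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(0, 1, (12, 4)), rng.normal(0, 3, (12, 4))])
        dm = euclid_dm(X)
        groups = ["a"] * 12 + ["b"] * 12
        ours = c.permdisp(dm, groups, n_perm=99, seed=0)
        ref = sd.permdisp(dm, groups, test="centroid", permutations=99,
                          dimensions=24)
        assert ours.statistic == pytest.approx(ref["test statistic"])


class TestConcordance:
    def test_low_noise_gives_strong_positive_rho(self, synth):
        """End-to-end regime check: FISH-like percentages generated from
        the true class compositions with <=2 percentage points of noise
        must correlate strongly with metabarcoding pseudoabundances."""
        counts, taxonomy, metadata, _ = synth
        gl = c.agglomerate(counts, taxonomy, "class")
        match = [f for f in gl.feature_ids if f.endswith(";C2")]
        rel = gl.data[match].sum(axis=1) / gl.depths() * 100
        res = c.concordance(metadata.data["GAM42a"], rel,
                            metadata.data["AAP_abs"], group="GAM42a")
        assert res.rho >= 0.7
        assert res.p < 0.001
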