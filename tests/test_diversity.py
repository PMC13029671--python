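import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from rhizonet import diversity as dv
from rhizonet import io as rio


class TestShannon:
    @pytest.mark.parametrize("counts,expected", [
        ([5, 5], np.log(2)),
        ([10], 0.0),
        ([5, 5, 10], 1.0397),   # -2*(0.25 ln 0.25) - 0.5 ln 0.5
    ])
    def test_known_values(self, counts, expected):
        assert dv.shannon(counts) == pytest.approx(expected, abs=1e-4)

    def test_uniform_is_maximal(self, rng):
        s = 7
        uniform = dv.shannon([10] * s)
        assert uniform == pytest.approx(np.log(s))
        skewed = dv.shannon(rng.integers(1, 50, s))
        assert skewed <= uniform + 1e-12

    def test_base_switch(self):
        assert dv.shannon([5, 5], base=2) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dv.shannon([0, 0])


def direct_ace(counts, rare_threshold=10):
    """Literal evaluation of the ACE formula for the oracle check."""
    c = np.asarray([x for x in counts if x > 0])
    rare = c[c <= rare_threshold]
    abund = c[c > rare_threshold]
    n_rare = rare.sum()
    f1 = (c == 1).sum()
    c_ace = 1 - f1 / n_rare
    fk = [np.sum(rare == k) for k in range(1, rare_threshold + 1)]
    gamma = max(
        (len(rare) / c_ace)
        * sum(k * (k - 1) * f for k, f in enumerate(fk, 1))
        / (n_rare * (n_rare - 1)) - 1, 0)
    return len(abund) + len(rare) / c_ace + f1 / c_ace * gamma


class TestAce:
    def test_all_abundant_equals_richness(self):
        assert dv.ace([11, 20, 300]).estimate == pytest.approx(3.0)

    def test_no_singletons_no_inflation(self):
        # F1 = 0 -> C_ACE = 1, gamma^2 = 0 -> S_abund + S_rare
        res = dv.ace([2, 3, 5, 50, 80])
        assert res.estimate == pytest.approx(5.0)
        assert not res.used_chao1_fallback

    def test_matches_direct_formula(self):
        counts = [1, 1, 2, 4, 9, 30]
        assert dv.ace(counts).estimate == pytest.approx(direct_ace(counts))

    def test_all_singletons_falls_back_to_chao1(self):
        res = dv.ace([1, 1, 1, 50])
        assert res.used_chao1_fallback
        assert res.estimate >= 4

    def test_ace_at_least_observed_when_singletons(self, rng):
        counts = rng.integers(1, 15, 12)
        counts[0] = 1
        res = dv.ace(counts)
        assert res.estimate >= len(counts) - 1e-9


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        df = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["a", "b"])
        d = dv.bray_curtis(df)
        assert d.loc["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        df = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert dv.bray_curtis(df).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_value(self):
        df = pd.DataFrame([[0.5, 0.5], [1.0, 0.0]], index=["a", "b"])
        # (|0.5-1| + |0.5-0|) / 2 = 0.5
        assert dv.bray_curtis(df).loc["a", "b"] == pytest.approx(0.5)

    def test_symmetric_zero_diagonal(self, rng):
        df = pd.DataFrame(rng.dirichlet(np.ones(5), 4))
        d = dv.bray_curtis(df).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)


class TestNmds:
    def test_collinear_points_embed_exactly(self):
        x = np.linspace(0, 1, 8)[:, None]
        D = pd.DataFrame(squareform(pdist(x)))
        res = dv.nmds(D, k=2, n_restarts=20, seed=0)
        assert res.stress < 1e-3

    def test_simplex_not_embeddable_in_2d(self):
        D = pd.DataFrame(np.ones((5, 5)) - np.eye(5))
        res = dv.nmds(D, k=2, n_restarts=10, seed=0)
        assert res.stress > 1e-3

    def test_self_recovery_of_planar_configuration(self, rng):
        X = rng.normal(size=(12, 2))
        D = pd.DataFrame(squareform(pdist(X)))
        res = dv.nmds(D, k=2, n_restarts=20, seed=0)
        assert res.stress < 0.02
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-8)

    def test_degenerate_distances_flagged(self):
        D = pd.DataFrame(np.zeros((5, 5)))
        with pytest.warns(UserWarning, match="degenerate"):
            res = dv.nmds(D, k=2)
        assert res.degenerate and res.stress == 0.0


class TestMantel:
    def _random_distance(self, rng, n):
        X = rng.normal(size=(n, 3))
        return pd.DataFrame(squareform(pdist(X)))

    def test_identity_r_one_min_p(self, rng):
        d = self._random_distance(rng, 10)
        res = dv.mantel(d, d, n_perm=99, seed=0, exact=False)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_exact_enumeration_matches_brute_force(self, rng):
        d1 = self._random_distance(rng, 4)
        d2 = self._random_distance(rng, 4)
        res = dv.mantel(d1, d2, exact=True)
        # brute force over all 24 relabelings of d2
        from scipy.stats import rankdata

        iu = np.triu_indices(4, 1)
        v1 = rankdata(d1.to_numpy()[iu])
        hits = 0
        for perm in itertools.permutations(range(4)):
            m = d2.to_numpy()[np.ix_(perm, perm)]
            r = np.corrcoef(v1, rankdata(m[iu]))[0, 1]
            hits += r >= res.r - 1e-12
        assert res.p == pytest.approx(hits / 24)

    def test_relabeling_invariance(self, rng):
        d1 = self._random_distance(rng, 5)
        d2 = self._random_distance(rng, 5)
        perm = rng.permutation(5)
        d1p = pd.DataFrame(d1.to_numpy()[np.ix_(perm, perm)])
        d2p = pd.DataFrame(d2.to_numpy()[np.ix_(perm, perm)])
        a = dv.mantel(d1, d2, exact=True)
        b = dv.mantel(d1p, d2p, exact=True)
        assert a.r == pytest.approx(b.r)
        assert a.p == pytest.approx(b.p)

    def test_against_skbio(self, rng):
        """Cross-check the sampled route against the scikit-bio Mantel."""
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        d1 = self._random_distance(rng, 12)
        d2 = pd.DataFrame(d1.to_numpy() ** 1.5 + 0.05)
        np.fill_diagonal(d2.values, 0.0)
        r_ref, p_ref, _ = skbio_mantel(DistanceMatrix(d1.to_numpy()),
                                       DistanceMatrix(d2.to_numpy()),
                                       method="spearman", permutations=999,
                                       alternative="greater")
        res = dv.mantel(d1, d2, n_perm=999, seed=1, exact=False)
        assert res.r == pytest.approx(r_ref, abs=1e-9)
        assert res.p == pytest.approx(p_ref, abs=0.02)

    def test_constant_matrix_rejected(self):
        d = pd.DataFrame(np.ones((4, 4)) - np.eye(4))
        with pytest.raises(ValueError):
            dv.mantel(d, d, exact=True)


class TestAxisEnvCorrelation:
    def _ordination(self, scores):
        coords = pd.DataFrame({"NMDS1": scores},
                              index=[f"S{i}" for i in range(len(scores))])
        return dv.OrdinationResult(coords, 0.01, True, 1)

    def test_perfect_monotone_correlations(self):
        scores = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        meta = rio.SampleMetadata(table=pd.DataFrame({
            "group": ["KC"] * 6,
            "Na": [10, 20, 30, 40, 50, 60],
            "TC": [60, 50, 40, 30, 20, 10],
        }, index=[f"S{i}" for i in range(6)]))
        out = dv.axis_env_correlation(self._ordination(scores), meta)
        na = out[out["variable"] == "Na"].iloc[0]
        tc = out[out["variable"] == "TC"].iloc[0]
        assert na["rho"] == pytest.approx(1.0)
        assert tc["rho"] == pytest.approx(-1.0)
        # exact two-sided permutation p at n=6 for a perfect ranking
        assert na["p"] == pytest.approx(2 / 720)

    def test_constant_variable_missing(self):
        meta = rio.SampleMetadata(table=pd.DataFrame({
            "group": ["KC"] * 6, "pH": [8.0] * 6,
        }, index=[f"S{i}" for i in range(6)]))
        out = dv.axis_env_correlation(
            self._ordination([1, 2, 3, 4, 5, 6]), meta)
        assert np.isnan(out.loc[out["variable"] == "pH", "rho"]).all()


def test_rarefy_uniform_depth(rng, small_otu_table):
    t = dv.rarefy(small_otu_table, seed=0)
    assert (t.library_sizes() == small_otu_table.library_sizes().min()).all()
    assert (t.counts.to_numpy() <= small_otu_table.counts.to_numpy()).all()
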