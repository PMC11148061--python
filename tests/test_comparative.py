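"""Inhibitor proximity, angular profiles, SES-Jaccard, readout comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import comb

from epiperturb import comparative


@pytest.fixture(scope="module")
def toy_scores():
    """8 inhibitors in two planted groups of 4, 100 CREs."""
    rng = np.random.default_rng(0)
    pattern_a = rng.normal(size=100) * 3
    pattern_b = rng.normal(size=100) * 3
    cols = {}
    for i in range(4):
        cols[f"A{i}"] = pattern_a + rng.normal(size=100) * 0.3
        cols[f"B{i}"] = pattern_b + rng.normal(size=100) * 0.3
    return pd.DataFrame(cols, index=[f"CRE{i}" for i in range(100)])


class TestProximity:
    def test_identical_vectors_are_mutual_neighbors_at_zero_distance(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=50)
        cols = {f"X{i}": base + rng.normal(size=50) for i in range(4)}
        cols["twin1"] = base * 2
        cols["twin2"] = base * 2
        score = pd.DataFrame(cols)
        model = comparative.proximity_fit(score, n_perm=100, seed=0)
        assert model.distances.loc["twin1", "twin2"] == pytest.approx(0.0, abs=1e-8)
        assert ("twin1", "twin2") in comparative.mutual_knn_pairs(model)

    def test_three_edges_per_vertex_by_default(self, toy_scores):
        model = comparative.proximity_fit(toy_scores, n_perm=100, seed=0)
        assert model.k == 3
        counts = pd.Series([a for a, _, _ in model.knn_edges]).value_counts()
        assert (counts == 3).all()

    def test_planted_groups_recovered(self, toy_scores):
        model = comparative.proximity_fit(toy_scores, n_perm=100, seed=0)
        d = model.distances
        within, between = [], []
        for a in d.index:
            for b in d.columns:
                if a < b:
                    (within if a[0] == b[0] else between).append(d.loc[a, b])
        assert np.mean(within) < np.mean(between)

    def test_distances_satisfy_triangle_inequality(self, toy_scores):
        d = comparative.proximity_fit(toy_scores, n_perm=100, seed=0).distances
        labels = list(d.index)
        for a in labels[:4]:
            for b in labels[:4]:
                for c in labels[:4]:
                    assert d.loc[a, c] <= d.loc[a, b] + d.loc[b, c] + 1e-9

    def test_rejects_too_few_inhibitors(self):
        score = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.raises(ValueError):
            comparative.proximity_fit(score, n_perm=100, seed=0)


class TestFamilyDistance:
    def test_planted_families_significant(self, toy_scores):
        model = comparative.proximity_fit(toy_scores, n_perm=100, seed=0)
        fam = {c: c[0] for c in toy_scores.columns}
        obs, null, p, kw_p = comparative.family_distance_test(
            model, fam, n_shuffle=500, seed=1
        )
        assert p < 0.05
        assert kw_p < 0.05
        assert obs < null.mean()

    def test_single_family_equals_all_pairs_mean(self, toy_scores):
        model = comparative.proximity_fit(toy_scores, n_perm=100, seed=0)
        fam = {c: "only" for c in toy_scores.columns}
        with pytest.raises(ValueError):
            # one family is not two families with >= 2 members
            comparative.family_distance_test(model, fam, n_shuffle=100, seed=0)

    def test_shuffle_reproducible_under_seed(self, toy_scores):
        model = comparative.proximity_fit(toy_scores, n_perm=100, seed=0)
        fam = {c: c[0] for c in toy_scores.columns}
        r1 = comparative.family_distance_test(model, fam, n_shuffle=200, seed=7)
        r2 = comparative.family_distance_test(model, fam, n_shuffle=200, seed=7)
        assert r1[0] == r2[0] and np.array_equal(r1[1], r2[1]) and r1[2] == r2[2]

    def test_all_singleton_families_rejected(self, toy_scores):
        model = comparative.proximity_fit(toy_scores, n_perm=100, seed=0)
        fam = {c: c for c in toy_scores.columns}
        with pytest.raises(ValueError):
            comparative.family_distance_test(model, fam, n_shuffle=100, seed=0)


class TestAngles:
    def _mfa_like(self, coords):
        comp = pd.DataFrame(coords, columns=["dim1", "dim2"])
        comp.index = [f"CRE{i}" for i in range(len(comp))]
        return comp

    def test_cardinal_directions_land_in_expected_bins(self):
        comp = self._mfa_like([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        calls = pd.DataFrame({"X": ["up", "up", "up"]}, index=comp.index)
        up, down = comparative.angle_frequency(comp, calls, "X")
        assert len(up.frequency) == 72
        assert up.counts[0] == 1  # 0 degrees -> first 5-degree bin
        assert up.counts[18] == 1  # 90 degrees -> bin 19 (1-based)
        assert up.counts[36] == 1  # 180 degrees
        assert down.empty

    def test_minmax_scaling_bounds(self, small_mfa, small_scores):
        inhib = small_scores.calls.columns[0]
        up, down = comparative.angle_frequency(small_mfa, small_scores.calls, inhib)
        for h in (up, down):
            assert len(h.frequency) == 72
            assert h.frequency.min() >= 0.0 and h.frequency.max() <= 1.0
            if not h.empty:
                assert h.frequency.max() == 1.0 and h.frequency.min() == 0.0

    def test_kinetic_clusters_are_angularly_coherent(self, small_screen, small_mfa):
        """CREs of one kinetic cluster concentrate in an angular sector."""
        _, _, truth = small_screen
        comp = small_mfa.compromise_scores
        theta = np.arctan2(comp["dim2"], comp["dim1"])
        clusters = truth.cluster_of[comp.index]
        for cl in clusters.unique():
            t = theta[(clusters == cl).to_numpy()]
            resultant = np.abs(np.mean(np.exp(1j * t)))
            assert resultant > 0.5  # strongly concentrated vs 0 for uniform


class TestSesJaccard:
    def test_identical_and_disjoint_sets(self):
        uni = [f"c{i}" for i in range(30)]
        st_ = comparative.ses_jaccard(uni[:5], uni[:5], uni, n_perm=200, seed=0)
        assert st_.jaccard == 1.0 and st_.ses > 0
        st2 = comparative.ses_jaccard(uni[:5], uni[5:10], uni, n_perm=200, seed=0)
        assert st2.jaccard == 0.0

    def test_null_mean_matches_hypergeometric_enumeration(self):
        # |A| = |B| = 5, universe 20: E[J] by exact overlap enumeration
        uni = [f"c{i}" for i in range(20)]
        exact = sum(
            comb(5, k) * comb(15, 5 - k) / comb(20, 5) * (k / (10 - k))
            for k in range(6)
        )
        st_ = comparative.ses_jaccard(uni[:5], uni[:5], uni, n_perm=4000, seed=3)
        assert st_.null_mean == pytest.approx(exact, abs=0.01)
        assert st_.ses > 3

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            comparative.ses_jaccard([], [], ["a", "b"], n_perm=100, seed=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 19), min_size=1, max_size=10),
        b=st.sets(st.integers(0, 19), min_size=1, max_size=10),
    )
    def test_jaccard_symmetric_and_bounded(self, a, b):
        uni = list(range(20))
        j1 = comparative.ses_jaccard(a, b, uni, n_perm=100, seed=1)
        j2 = comparative.ses_jaccard(b, a, uni, n_perm=100, seed=1)
        assert j1.jaccard == j2.jaccard
        assert 0.0 <= j1.jaccard <= 1.0


class TestReadoutCompare:
    def _pairs(self, n):
        rng = np.random.default_rng(2)
        idx = pd.MultiIndex.from_tuples(
            [(f"i{a}", f"i{b}") for a in range(n) for b in range(a + 1, n)]
        )
        return pd.Series(rng.uniform(size=len(idx)), index=idx)

    def test_identity_gives_perfect_correlation_and_increasing_quintiles(self):
        da = self._pairs(12)
        rho, q = comparative.readout_compare(da, da.copy())
        assert rho == pytest.approx(1.0)
        assert (np.diff(q["median"]) > 0).all()

    def test_permuted_readout_decorrelates(self):
        da = self._pairs(12)
        rng = np.random.default_rng(3)
        rhos = []
        for _ in range(100):
            db = pd.Series(rng.permutation(da.to_numpy()), index=da.index)
            rhos.append(comparative.readout_compare(da, db)[0])
        assert abs(np.mean(rhos)) < 0.05

    def test_594_pairs_split_into_balanced_quintiles(self):
        # 594 = C(34, 2) - {33 vehicle pairs}; any 594-long pair set works
        rng = np.random.default_rng(4)
        idx = pd.MultiIndex.from_tuples([(f"p{i}", f"q{i}") for i in range(594)])
        da = pd.Series(rng.uniform(size=594), index=idx)
        _, q = comparative.readout_compare(da, da * 2)
        assert sorted(q["n"]) == [118, 119, 119, 119, 119]
        assert q["n"].max() - q["n"].min() <= 1

    def test_mismatched_pairs_rejected(self):
        da = self._pairs(6)
        db = da.iloc[:-1]
        with pytest.raises(ValueError):
            comparative.readout_compare(da, db)
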