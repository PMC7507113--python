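"""COG matrices, classical-scaling ordination, rank-sum tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA

from sagkit.constants import COG_CATEGORIES
from sagkit.ordination import (build_cog_matrix, filter_genomes,
                               group_separation, ordinate, ranksum_test)
from _oracles import ranksum_enumeration


def _ann(gid, cats):
    return [dict(genome_id=gid, cog_category=c) for c in cats]


def _matrix(df, completeness=100.0, ssu=1500):
    from sagkit.ordination import CogMatrix
    n = len(df)
    return CogMatrix(
        values=df,
        group=pd.Series("all", index=df.index),
        completeness_pct=pd.Series(completeness, index=df.index),
        ssu_len=pd.Series(ssu, index=df.index),
    )


class TestBuildMatrix:
    def test_even_split(self):
        ann = _ann("g1", ["J"] * 10 + ["K"] * 10)
        m = build_cog_matrix(ann)
        assert m.values.loc["g1", "J"] == pytest.approx(50.0)
        assert m.values.loc["g1", "K"] == pytest.approx(50.0)
        assert m.values.loc["g1"].drop(["J", "K"]).sum() == 0.0

    def test_rows_sum_to_100(self, small_community):
        ann = [r for s in small_community.sags for r in s.annotations]
        m = build_cog_matrix(ann)
        assert np.allclose(m.values.sum(axis=1), 100.0, atol=1e-6)

    def test_empty_genome_excluded_with_warning(self):
        ann = _ann("g1", ["J"]) + [dict(genome_id="g2", cog_category=None)]
        with pytest.warns(UserWarning):
            m = build_cog_matrix(ann)
        assert list(m.values.index) == ["g1"]

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            build_cog_matrix([dict(genome_id="g", cog_category="X")])


class TestFilter:
    @pytest.mark.parametrize("comp,ssu,kept", [
        (29.9, 1500, False),
        (30.0, 1500, True),
        (80.0, 0, False),
        (80.0, 1200, True),
    ])
    def test_thresholds(self, comp, ssu, kept):
        ann = _ann("g1", ["J", "K"])
        m = build_cog_matrix(
            ann, metadata={"g1": dict(completeness_pct=comp, ssu_len=ssu)})
        f = filter_genomes(m)
        assert ("g1" in f.values.index) is kept


class TestOrdinate:
    def test_identical_rows_zero_eigenvalues(self):
        df = pd.DataFrame([[4.0] * 25] * 4, columns=list(COG_CATEGORIES),
                          index=list("abcd"))
        with pytest.warns(UserWarning):
            res = ordinate(_matrix(df), n_axes=2)
        assert np.allclose(res.eigenvalues, 0.0)

    def test_equilateral_triangle_closed_form(self):
        d = 6.0
        rows = np.zeros((3, 25))
        for i in range(3):
            rows[i, i] = d / np.sqrt(2)
        df = pd.DataFrame(rows, columns=list(COG_CATEGORIES),
                          index=list("abc"))
        res = ordinate(_matrix(df), n_axes=2)
        assert np.allclose(res.eigenvalues[:2], d * d / 2, atol=1e-9)
        D = squareform(pdist(res.coordinates))
        assert np.allclose(D[np.triu_indices(3, 1)], d, atol=1e-9)

    def test_gower_distance_reconstruction(self, small_community):
        ann = [r for s in small_community.sags for r in s.annotations]
        m = build_cog_matrix(ann)
        X = m.values.to_numpy()
        res = ordinate(m, n_axes=min(X.shape[0] - 1, 25))
        D_in = squareform(pdist(X))
        D_out = squareform(pdist(res.coordinates))
        assert np.allclose(D_in, D_out, atol=1e-6)

    def test_matches_sklearn_pca(self, small_community):
        ann = [r for s in small_community.sags for r in s.annotations]
        m = build_cog_matrix(ann)
        X = m.values.to_numpy()
        res = ordinate(m, n_axes=2)
        pca = PCA(n_components=2).fit(X)
        sk = pca.transform(X)
        for a in range(2):
            assert np.allclose(np.abs(res.coordinates[:, a]),
                               np.abs(sk[:, a]), atol=1e-6)
        assert np.allclose(res.eigenvalues[:2],
                           pca.explained_variance_ * (X.shape[0] - 1),
                           rtol=1e-9)

    def test_coordinates_centered_and_eigenvalues_sorted(self, small_community):
        ann = [r for s in small_community.sags for r in s.annotations]
        m = build_cog_matrix(ann)
        res = ordinate(m, n_axes=3)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)
        assert np.all(np.diff(res.eigenvalues[:3]) <= 1e-9)

    def test_trace_identity(self, small_community):
        ann = [r for s in small_community.sags for r in s.annotations]
        m = build_cog_matrix(ann)
        X = m.values.to_numpy()
        Xc = X - X.mean(axis=0)
        n = X.shape[0]
        res = ordinate(m, n_axes=n - 1)
        full = np.linalg.eigvalsh(Xc @ Xc.T)
        assert np.isclose(res.eigenvalues[: n - 1].sum(),
                          max(full.sum(), 0), rtol=1e-6)

    def test_hellinger_transform_option(self):
        df = pd.DataFrame(np.full((4, 25), 4.0), columns=list(COG_CATEGORIES),
                          index=list("abcd"))
        df.iloc[0, 0] += 2
        df.iloc[0, 1] -= 2
        res = ordinate(_matrix(df), n_axes=1, transform="hellinger")
        raw = ordinate(_matrix(df), n_axes=1)
        assert res.eigenvalues[0] != pytest.approx(raw.eigenvalues[0])
        with pytest.raises(ValueError):
            ordinate(_matrix(df), transform="chi2")

    def test_too_few_genomes(self):
        df = pd.DataFrame(np.eye(2, 25) * 100, columns=list(COG_CATEGORIES))
        with pytest.raises(ValueError):
            ordinate(_matrix(df))


class TestRankSum:
    def test_small_exact_example(self):
        r = ranksum_test([1, 2], [3, 4])
        assert r.statistic == 3.0
        assert r.p_value == pytest.approx(1 / 3)
        assert r.method == "exact"

    def test_identical_groups_p_one(self):
        r = ranksum_test([5, 5, 5], [5, 5, 5])
        assert r.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 10, size=int(rng.integers(2, 7))).tolist()
            y = rng.integers(0, 10, size=int(rng.integers(2, 7))).tolist()
            r = ranksum_test(x, y)
            assert r.p_value == pytest.approx(ranksum_enumeration(x, y))

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(15):
            vals = rng.permutation(100)[:13].astype(float)
            x, y = vals[:6], vals[6:]
            r = ranksum_test(x, y)
            s = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert r.p_value == pytest.approx(s.pvalue)

    def test_normal_matches_scipy_tie_corrected(self, rng):
        x = rng.integers(0, 15, size=20).astype(float)
        y = (rng.integers(0, 15, size=25) + 2).astype(float)
        r = ranksum_test(x, y)
        s = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                         use_continuity=False)
        assert r.method == "normal"
        assert r.p_value == pytest.approx(s.pvalue)

    def test_group_separation_skips_singletons(self):
        coords = np.arange(10, dtype=float).reshape(-1, 1)
        groups = ["a"] * 4 + ["b"] * 5 + ["c"]
        with pytest.warns(UserWarning):
            res = group_separation(coords, groups, axis=0)
        assert {(r.group_a, r.group_b) for r in res} == {("a", "b")}


class TestRankSumProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.integers(0, 8), min_size=2, max_size=6),
           st.lists(st.integers(0, 8), min_size=2, max_size=6))
    @settings(max_examples=40, deadline=None)
    def test_p_in_unit_interval_and_swap_symmetric(self, x, y):
        a = ranksum_test(x, y)
        b = ranksum_test(y, x)
        assert 0.0 <= a.p_value <= 1.0
        assert a.p_value == pytest.approx(b.p_value)


class TestGroupSeparationPower:
    def test_depleted_categories_separate_on_pc1(self, rng):
        """patesci-like vs standard COG profiles separate along PC1 and the
        depleted categories' loadings point away from the depleted side."""
        from sagkit.community import make_taxon_profile

        rows, groups = [], []
        for i in range(20):
            pa = make_taxon_profile("Patescibacteria", "patesci_like", 1000 + i)
            st = make_taxon_profile("Other-Bacteria", "standard", 1100 + i)
            for prof, g in ((pa, "patesci"), (st, "standard")):
                counts = rng.multinomial(500, prof.cog_distribution)
                rows.append(100.0 * counts / counts.sum())
                groups.append(g)
        df = pd.DataFrame(rows, columns=list(COG_CATEGORIES))
        res = ordinate(_matrix(df), n_axes=2)
        (r,) = group_separation(res.coordinates, groups, axis=0)
        assert r.p_value < 0.01
        # sign check: C/E/H/P loadings oppose the depleted group's side
        pc1 = res.coordinates[:, 0]
        side = np.sign(np.mean(pc1[np.array(groups) == "patesci"])
                       - np.mean(pc1[np.array(groups) == "standard"]))
        for cat in "CEHP":
            load = res.loadings[COG_CATEGORIES.index(cat), 0]
            assert np.sign(load) == -side
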