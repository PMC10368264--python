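"""Diversity indices, rarefaction, PCoA and ANOVA against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from rbcltrace.diversity import (
    anova_by_group,
    bray_curtis,
    distance_matrix,
    pcoa,
    rarefaction_curve,
    shannon,
    simpson,
    simpson_concentration,
)


class TestShannonSimpson:
    def test_uniform_closed_forms(self):
        for k in (2, 4, 7):
            v = [10] * k
            assert shannon(v) == pytest.approx(math.log(k), abs=1e-12)
            assert simpson(v) == pytest.approx(1 - 1 / k, abs=1e-12)

    def test_single_taxon_zero(self):
        assert shannon([42]) == 0.0
        assert simpson([42]) == 0.0

    def test_direct_summation_oracle(self):
        counts = (5, 3, 2)
        n = sum(counts)
        h = -sum((c / n) * math.log(c / n) for c in counts)
        d = 1 - sum((c / n) ** 2 for c in counts)
        assert shannon(counts) == pytest.approx(h, abs=1e-12)
        assert simpson(counts) == pytest.approx(d, abs=1e-12)
        assert simpson_concentration(counts) == pytest.approx(1 - d, abs=1e-12)

    def test_bounds_and_maximum_at_uniform(self, rng):
        for _ in range(20):
            v = rng.integers(1, 50, size=6)
            assert 0 <= shannon(v) <= math.log(6) + 1e-12
            assert 0 <= simpson(v) <= 1 - 1 / 6 + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_matches_skbio(self, rng):
        skbio_diversity = pytest.importorskip("skbio.diversity.alpha")
        for _ in range(5):
            v = rng.integers(1, 100, size=8)
            assert shannon(v) == pytest.approx(
                float(skbio_diversity.shannon(v, base=math.e)), abs=1e-10
            )
            assert simpson(v) == pytest.approx(float(skbio_diversity.simpson(v)), abs=1e-10)


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert bray_curtis([1, 2, 0], [0, 0, 5]) == 1.0

    def test_hand_arithmetic(self):
        assert bray_curtis((2, 0, 1), (1, 1, 0)) == pytest.approx(0.6)

    def test_mapping_alignment(self):
        assert bray_curtis({"a": 2, "c": 1}, {"a": 1, "b": 1}) == pytest.approx(0.6)

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            u = rng.integers(0, 30, size=5)
            v = rng.integers(0, 30, size=5)
            if (u + v).sum() == 0:
                continue
            d = bray_curtis(u, v)
            assert d == pytest.approx(bray_curtis(v, u))
            assert 0 <= d <= 1

    def test_matches_scipy(self, rng):
        from scipy.spatial.distance import braycurtis as scipy_bc

        for _ in range(10):
            u = rng.integers(1, 30, size=6).astype(float)
            v = rng.integers(1, 30, size=6).astype(float)
            assert bray_curtis(u, v) == pytest.approx(float(scipy_bc(u, v)), abs=1e-12)


class TestRarefaction:
    def test_full_depth_equals_observed_richness(self):
        curve = rarefaction_curve([50, 30, 20], step=100)
        n, s = curve[-1]
        assert n == 100
        assert s == pytest.approx(3.0, abs=1e-9)

    def test_depth_one(self):
        curve = rarefaction_curve([5, 5], step=100)
        assert curve[0] == (1, pytest.approx(1.0, abs=1e-12))

    def test_monte_carlo_oracle(self, rng):
        """Hypergeometric expectation vs 10,000 seeded subsampling draws."""
        counts = np.array([50, 30, 20])
        N = counts.sum()
        n = 10
        pool = np.repeat(np.arange(3), counts)
        draws = 10_000
        richness = np.empty(draws)
        for i in range(draws):
            sub = rng.choice(pool, size=n, replace=False)
            richness[i] = len(np.unique(sub))
        expected = dict(rarefaction_curve(counts, step=9))[10]
        se = richness.std(ddof=1) / np.sqrt(draws)
        assert abs(richness.mean() - expected) < 3 * se

    def test_nondecreasing_and_concave(self, rng):
        v = rng.integers(1, 40, size=8)
        curve = rarefaction_curve(v, step=25)
        values = [s for _, s in curve]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        # discrete concavity over the evenly spaced interior points
        interior = values[:-1] if curve[-1][0] != curve[-2][0] + 25 else values
        diffs = [b - a for a, b in zip(interior, interior[1:])]
        assert all(d2 <= d1 + 1e-9 for d1, d2 in zip(diffs, diffs[1:]))

    def test_matches_vegan_style_grid(self):
        curve = rarefaction_curve([120, 80], step=100)
        assert [n for n, _ in curve] == [1, 101, 200]


class TestPCoA:
    def test_equilateral_triangle(self):
        D = pd.DataFrame(
            [[0, 1, 1], [1, 0, 1], [1, 1, 0]],
            index=list("abc"),
            columns=list("abc"),
            dtype=float,
        )
        res = pcoa(D, k=2)
        coords = res.coordinates.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0, abs=1e-9)

    def test_recovers_planted_configuration(self, rng):
        """Generate plane points -> distances -> PCoA; Procrustes error < 1e-8."""
        pts = rng.normal(size=(6, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        names = [f"s{i}" for i in range(6)]
        res = pcoa(pd.DataFrame(D, index=names, columns=names), k=2)
        got = res.coordinates.to_numpy()
        D2 = np.sqrt(((got[:, None, :] - got[None, :, :]) ** 2).sum(-1))
        assert np.max(np.abs(D2 - D)) < 1e-8
        assert res.negative_eigenvalue_magnitude < 1e-9 * np.abs(D).sum()

    def test_duplicate_samples_coincide(self):
        D = pd.DataFrame(
            [[0, 0, 2], [0, 0, 2], [2, 2, 0]],
            index=list("abc"),
            columns=list("abc"),
            dtype=float,
        )
        res = pcoa(D, k=2)
        a, b = res.coordinates.loc["a"], res.coordinates.loc["b"]
        assert np.allclose(a, b, atol=1e-9)

    def test_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(5, 3))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        names = [f"s{i}" for i in range(5)]
        ours = pcoa(pd.DataFrame(D, index=names, columns=names), k=2)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D, ids=names), number_of_dimensions=2)
        ours_d = np.abs(ours.coordinates.to_numpy())
        theirs_d = np.abs(theirs.samples.to_numpy())
        assert np.allclose(ours_d, theirs_d, atol=1e-8)


class TestANOVA:
    def test_equal_group_means_f_zero(self):
        values = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 1.0, "e": 2.0, "f": 3.0}
        groups = {"a": "g1", "b": "g1", "c": "g1", "d": "g2", "e": "g2", "f": "g2"}
        f, p = anova_by_group(values, groups)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_identical_within_groups_equal_means(self):
        values = {"a": 2.0, "b": 2.0, "c": 2.0, "d": 2.0}
        groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        f, p = anova_by_group(values, groups)
        assert (f, p) == (0.0, 1.0)

    def test_first_principles_sums_of_squares_oracle(self):
        data = {"g1": [3.1, 2.9, 3.4], "g2": [4.0, 4.3, 3.8], "g3": [2.0, 2.4]}
        values, groups = {}, {}
        for g, arr in data.items():
            for i, x in enumerate(arr):
                values[f"{g}_{i}"] = x
                groups[f"{g}_{i}"] = g
        all_x = [x for arr in data.values() for x in arr]
        grand = sum(all_x) / len(all_x)
        ss_between = sum(len(a) * (sum(a) / len(a) - grand) ** 2 for a in data.values())
        ss_within = sum(sum((x - sum(a) / len(a)) ** 2 for x in a) for a in data.values())
        g, n = len(data), len(all_x)
        f_expect = (ss_between / (g - 1)) / (ss_within / (n - g))
        f, p = anova_by_group(values, groups)
        assert f == pytest.approx(f_expect, abs=1e-10)

    def test_degenerate_raises(self):
        values = {"a": 1.0, "b": 1.0, "c": 2.0, "d": 2.0}
        groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        with pytest.raises(ValueError, match="degenerate"):
            anova_by_group(values, groups)


def test_distance_matrix_properties(rng):
    table = pd.DataFrame(
        rng.integers(0, 50, size=(6, 4)),
        columns=[f"s{i}" for i in range(4)],
    )
    dm = distance_matrix(table)
    arr = dm.to_numpy()
    assert np.allclose(arr, arr.T)
    assert np.allclose(np.diag(arr), 0)
    assert ((arr >= 0) & (arr <= 1)).all()
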