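"""Trait standardization, PCoA embedding and functional dispersion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

import traitscape as tc
from traitscape.traits import fdis


def _tm(values, standardized=False, columns=None):
    values = np.atleast_2d(np.asarray(values, float))
    cols = columns or [f"t{j}" for j in range(values.shape[1])]
    idx = [f"sp{i}" for i in range(values.shape[0])]
    return tc.TraitMatrix(pd.DataFrame(values, index=idx, columns=cols), standardized)


class TestStandardize:
    def test_hand_case_unit_sample_sd(self):
        out = tc.standardize(_tm([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.values.ravel(), [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        once = tc.standardize(_tm(np.random.default_rng(0).normal(size=(10, 3))))
        twice = tc.standardize(once)
        assert np.allclose(once.values, twice.values)

    def test_constant_trait_named_in_error(self):
        with pytest.raises(ValueError, match="t1"):
            tc.standardize(_tm([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))

    def test_six_trait_pool_has_zero_mean_unit_sd(self, mini_study):
        out = tc.standardize(mini_study.traits)
        assert np.allclose(out.values.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(out.values.std(axis=0, ddof=1), 1.0, atol=1e-10)


class TestTraitDistance:
    def test_3_4_5_triangle(self):
        d = tc.trait_distance(_tm([[0.0, 0.0], [3.0, 4.0]], standardized=True))
        assert d[0, 1] == pytest.approx(5.0)

    def test_identical_species_distance_zero(self):
        d = tc.trait_distance(_tm([[1.0, 2.0], [1.0, 2.0]], standardized=True))
        assert d[0, 1] == 0.0

    def test_matches_pairwise_loop_oracle(self, traits5):
        std = tc.standardize(traits5)
        d = tc.trait_distance(std)
        v = std.values
        for i in range(5):
            for j in range(5):
                expected = np.sqrt(((v[i] - v[j]) ** 2).sum())
                assert d[i, j] == pytest.approx(expected, abs=1e-12)


class TestPcoaEmbed:
    def test_euclidean_input_reproduced_without_correction(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 2))
        d = squareform(pdist(pts))
        space = tc.pcoa_embed(d)
        emb = squareform(pdist(space.coordinates))
        assert space.correction == "none"
        assert np.allclose(emb, d, atol=1e-8)

    def test_equilateral_triangle_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        space = tc.pcoa_embed(d)
        ev = space.eigenvalues
        assert len(ev) == 2  # third axis is numerical zero, dropped
        assert ev[0] == pytest.approx(ev[1], rel=1e-8)
        emb = squareform(pdist(space.coordinates))
        assert np.allclose(emb, d, atol=1e-8)

    def test_non_euclidean_star_metric_corrected(self):
        # hub at distance 1 from three tips that are pairwise 2 apart:
        # a tree metric that cannot be embedded in Euclidean space
        d = np.full((4, 4), 2.0)
        d[0, :] = d[:, 0] = 1.0
        np.fill_diagonal(d, 0.0)
        space = tc.pcoa_embed(d, correction="cailliez")
        assert space.correction == "cailliez"
        assert space.correction_constant > 0
        emb = squareform(pdist(space.coordinates))
        off = ~np.eye(4, dtype=bool)
        # corrected distances exceed the raw ones and are reproduced exactly
        assert np.all(emb[off] >= d[off] - 1e-8)
        assert np.allclose(emb[off], d[off] + space.correction_constant, atol=1e-6)

    def test_agrees_with_skbio_on_euclidean_fixture(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(11)
        pts = rng.normal(size=(10, 3))
        d = squareform(pdist(pts))
        ours = tc.pcoa_embed(d)
        theirs = skbio_pcoa(skbio.DistanceMatrix(d), dimensions=3)
        # embeddings agree up to rotation/sign: compare pairwise distances
        d_ours = squareform(pdist(ours.coordinates))
        d_theirs = squareform(pdist(theirs.samples.to_numpy()))
        assert np.allclose(d_ours, d_theirs, atol=1e-6)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            tc.pcoa_embed(d)


def _fdis_oracle(coords, abund):
    """Naive loop implementation of the weighted-centroid formula."""
    coords = np.atleast_2d(coords)
    total = float(sum(abund))
    centroid = sum(a * x for a, x in zip(abund, coords)) / total
    return sum(a * np.sqrt(((x - centroid) ** 2).sum()) for a, x in zip(abund, coords)) / total


class TestFdis:
    def test_single_species_zero(self):
        assert fdis(np.array([[1.0, 2.0]]), np.array([7.0])) == 0.0

    def test_symmetric_pair_one_dim(self):
        assert fdis(np.array([[-1.0], [1.0]]), np.array([3.0, 3.0])) == pytest.approx(1.0)

    def test_four_species_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(4, 2))
        abund = np.array([1.0, 2.0, 3.0, 4.0])
        assert fdis(coords, abund) == pytest.approx(_fdis_oracle(coords, abund), abs=1e-12)

    def test_empty_community_is_missing(self):
        assert np.isnan(fdis(np.zeros((2, 2)), np.zeros(2)))

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_invariant_to_abundance_rescaling(self, factor):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(5, 3))
        abund = np.array([1.0, 2.0, 0.5, 4.0, 1.5])
        assert fdis(coords, abund * factor) == pytest.approx(fdis(coords, abund), rel=1e-9)

    def test_invariant_under_rotation(self):
        rng = np.random.default_rng(13)
        coords = rng.normal(size=(6, 3))
        abund = rng.uniform(0.5, 3.0, size=6)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert fdis(coords @ q, abund) == pytest.approx(fdis(coords, abund), rel=1e-10)

    def test_one_dim_equals_weighted_mean_absolute_deviation(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=7)
        a = rng.uniform(0.5, 4.0, size=7)
        wmean = np.average(x, weights=a)
        wmad = np.average(np.abs(x - wmean), weights=a)
        assert fdis(x[:, None], a) == pytest.approx(wmad, abs=1e-12)

    def test_species_at_centroid_never_increases_fdis(self):
        rng = np.random.default_rng(21)
        coords = rng.normal(size=(5, 2))
        abund = rng.uniform(0.5, 3.0, size=5)
        centroid = abund @ coords / abund.sum()
        base = fdis(coords, abund)
        for extra in (0.1, 1.0, 10.0):
            grown = fdis(
                np.vstack([coords, centroid]), np.append(abund, extra)
            )
            assert grown <= base + 1e-12


class TestDispersionMap:
    def test_monospecific_quadrats_all_zero(self):
        grid = tc.QuadratGrid(scale=10.0, n_x=2, n_y=2)
        abund = np.array([[3, 0], [0, 2], [5, 0], [0, 1]])
        comm = tc.QuadratCommunity(grid, ["a", "b"], abund)
        space = tc.TraitSpace(["a", "b"], np.array([[0.0], [1.0]]), np.array([1.0]))
        dmap = tc.dispersion_map(comm, space)
        assert np.all(dmap.fdis == 0.0)

    def test_agrees_with_per_quadrat_oracle(self, mini_study):
        comm = tc.make_grid(mini_study.census, 20.0)
        space = tc.trait_space_from_traits(mini_study.traits)
        dmap = tc.dispersion_map(comm, space)
        pos = {s: i for i, s in enumerate(space.species)}
        coords = space.coordinates[[pos[s] for s in comm.species]]
        for q in range(comm.grid.n_quadrats):
            a = comm.abundance[q].astype(float)
            if a.sum() == 0:
                assert np.isnan(dmap.fdis[q])
            else:
                assert dmap.fdis[q] == pytest.approx(_fdis_oracle(coords, a), abs=1e-10)

    def test_multivariate_differs_from_single_trait(self, mini_study):
        comm = tc.make_grid(mini_study.census, 20.0)
        multi = tc.dispersion_map(comm, tc.trait_space_from_traits(mini_study.traits))
        st_ = tc.standardize(mini_study.traits)
        single = tc.dispersion_map(comm, tc.single_trait_space(st_, "Hmax"), "Hmax")
        ok = np.isfinite(multi.fdis) & np.isfinite(single.fdis)
        assert not np.allclose(multi.fdis[ok], single.fdis[ok])

    def test_missing_species_rejected(self):
        grid = tc.QuadratGrid(scale=10.0, n_x=1, n_y=1)
        comm = tc.QuadratCommunity(grid, ["a", "zz"], np.array([[1, 1]]))
        space = tc.TraitSpace(["a", "b"], np.zeros((2, 1)), np.array([1.0]))
        with pytest.raises(ValueError, match="zz"):
            tc.dispersion_map(comm, space)
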