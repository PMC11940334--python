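"""Thresholding, affinity kernel, diffusion embedding, templates, alignment."""

import numpy as np
import pytest

import hemigrad as hg
from hemigrad.exceptions import DataError, ParameterError
from hemigrad.gradients import _orient_columns
from .conftest import random_affinity
from .oracles import (dense_diffusion_oracle, match_columns_up_to_sign,
                      random_orthogonal)


class TestThresholdProfiles:
    def test_single_profile(self):
        out = hg.threshold_profiles(np.array([5.0, 1, 4, 2, 3]), density=0.2)
        assert np.array_equal(out, [5, 0, 0, 0, 0])

    def test_density_one_is_identity(self):
        m = np.random.default_rng(0).standard_normal((6, 6))
        assert np.array_equal(hg.threshold_profiles(m, 1.0), m)

    def test_exact_count(self):
        m = np.random.default_rng(1).standard_normal((200, 200))
        out = hg.threshold_profiles(m, 0.10, exclude_diagonal=False)
        assert np.all((out != 0).sum(axis=1) == 20)

    def test_ties_break_to_smallest_index(self):
        out = hg.threshold_profiles(np.array([1.0, 3, 3, 3, 0]), density=0.4)
        assert np.array_equal(out, [0, 3, 3, 0, 0])

    def test_diagonal_never_selected(self):
        m = np.full((5, 5), 1.0)
        np.fill_diagonal(m, 100.0)
        with pytest.warns(UserWarning, match="all-equal"):
            out = hg.threshold_profiles(m, 0.2)
        assert np.all(np.diag(out) == 0)

    def test_all_equal_profile_warns(self):
        with pytest.warns(UserWarning, match="all-equal"):
            out = hg.threshold_profiles(np.ones((1, 5)), density=0.4)
        assert np.array_equal(out, [[1, 1, 0, 0, 0]])

    def test_input_unmodified_and_bad_density(self):
        m = np.arange(9.0).reshape(3, 3)
        copy = m.copy()
        hg.threshold_profiles(m, 0.5)
        assert np.array_equal(m, copy)
        for bad in (0.0, -0.2, 1.5):
            with pytest.raises(ParameterError):
                hg.threshold_profiles(m, bad)


class TestNormalizedAngleAffinity:
    def test_closed_forms(self):
        u = np.array([1.0, 2.0, -1.0, 0.5])
        v = np.array([2.0, -1.0, 0.0, 0.0])  # orthogonal to u
        X = np.vstack([u, 3 * u, -u, v])
        aff = hg.normalized_angle_affinity(X)
        assert aff[0, 1] == pytest.approx(1.0)      # identical direction
        assert aff[0, 3] == pytest.approx(0.5)      # orthogonal
        assert aff[0, 2] == pytest.approx(0.0)      # antipodal
        assert np.allclose(np.diag(aff), 1.0)
        assert np.allclose(aff, aff.T)

    def test_zero_profile_errors(self):
        X = np.ones((3, 4))
        X[2] = 0
        with pytest.raises(DataError, match="2"):
            hg.normalized_angle_affinity(X)

    def test_range(self):
        X = np.random.default_rng(2).standard_normal((20, 30))
        aff = hg.normalized_angle_affinity(X)
        assert aff.min() >= 0 and aff.max() <= 1


class TestDiffusionMap:
    def test_two_block_affinity_separates_blocks(self):
        n = 8
        aff = np.full((n, n), 0.05)
        aff[:4, :4] = 1.0
        aff[4:, 4:] = 1.0
        g = hg.diffusion_map(aff, n_components=3)
        signs = np.sign(g.coordinates[:, 0])
        assert len(set(signs[:4])) == 1 and len(set(signs[4:])) == 1
        assert signs[0] != signs[4]

    def test_eigenvalues_below_one_and_ev_sums_to_one(self):
        aff = random_affinity(10, np.random.default_rng(3))
        g = hg.diffusion_map(aff, n_components=5)
        assert np.all(g.eigenvalues < 1)
        assert np.all(np.diff(g.eigenvalues) <= 1e-12)
        assert g.explained_variance.sum() == pytest.approx(1.0)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(4)
        aff = random_affinity(6, rng)
        g = hg.diffusion_map(aff, n_components=4)
        coords, lam = dense_diffusion_oracle(aff, alpha=0.5, n_components=4)
        assert np.allclose(g.eigenvalues, lam, atol=1e-12)
        assert match_columns_up_to_sign(g.coordinates, coords) < 1e-10

    def test_disconnected_graph_errors(self):
        aff = np.zeros((6, 6))
        aff[:3, :3] = 1.0
        aff[3:, 3:] = 1.0
        with pytest.raises(DataError, match="disconnected"):
            hg.diffusion_map(aff, n_components=2)

    def test_nonzero_diffusion_time_uses_power_scaling(self):
        aff = random_affinity(8, np.random.default_rng(5))
        g0 = hg.diffusion_map(aff, diffusion_time=0, n_components=3)
        g1 = hg.diffusion_map(aff, diffusion_time=1.0, n_components=3)
        lam = g0.eigenvalues
        ratio = (lam / (1 - lam)) / lam
        assert np.allclose(g0.coordinates, g1.coordinates * ratio, atol=1e-10)

    def test_parameter_validation(self):
        aff = random_affinity(6, np.random.default_rng(6))
        with pytest.raises(ParameterError):
            hg.diffusion_map(aff, n_components=5)
        with pytest.raises(DataError):
            hg.diffusion_map(aff + 3.0, n_components=2)

    def test_relabeling_invariance(self):
        """Consistent region relabeling permutes coordinates (up to sign)."""
        rng = np.random.default_rng(7)
        block = rng.standard_normal((10, 10))
        block = 0.5 * (block + block.T)
        np.fill_diagonal(block, 0)
        g = hg.embed_block(block, n_components=3)
        perm = rng.permutation(10)
        g2 = hg.embed_block(block[np.ix_(perm, perm)], n_components=3)
        assert match_columns_up_to_sign(g2.coordinates,
                                        g.coordinates[perm]) < 1e-8


class TestTemplates:
    def test_single_subject_template_equals_its_gradient(self, small_parcellation):
        rng = np.random.default_rng(8)
        nh = 8
        sym = rng.standard_normal((nh, nh))
        sym = 0.5 * (sym + sym.T)
        np.fill_diagonal(sym, 0)
        blocks = hg.HemisphericBlocks(LL=sym, RR=sym.copy(), LR=sym.copy(),
                                      RL=sym.copy(), left_ids=np.arange(nh),
                                      right_ids=np.arange(nh, 2 * nh))
        intra, inter = hg.build_templates([blocks], n_components=3)
        own = hg.embed_block(sym, n_components=3)
        assert match_columns_up_to_sign(intra.coordinates, own.coordinates) < 1e-10

    def test_template_recovers_planted_axis(self):
        """Group-average template G1 tracks the planted first latent axis."""
        study = hg.simulate_study(n_hc=15, n_sz=1, n_sites=1, n_per_hemi=32,
                                  n_timepoints=400, seed=11)
        study.timeseries.pop(study.subjects.pop().subject_id)  # HC-only reference
        blocks = [hg.split_hemispheric(hg.compute_fc(ts), study.parcellation)
                  for ts in study.timeseries.values()]
        X = study.truth.axis_loadings
        intra, inter = hg.build_templates(blocks, sign_reference=X)
        r = np.corrcoef(intra.coordinates[:, 0], X[:, 0])[0, 1]
        assert abs(r) > 0.8
        assert r > 0  # sign convention orients along the reference

    def test_shape_mismatch_errors(self):
        b1 = hg.HemisphericBlocks(*(np.eye(4),) * 4)
        b2 = hg.HemisphericBlocks(*(np.eye(5),) * 4)
        with pytest.raises(DataError):
            hg.build_templates([b1, b2])

    def test_orient_columns(self):
        rng = np.random.default_rng(9)
        coords = rng.standard_normal((20, 3))
        ref = coords + 0.1 * rng.standard_normal((20, 3))
        out = _orient_columns(-coords, ref)
        assert np.allclose(out, coords)


class TestProcrustes:
    def _template(self, n=20, k=5, seed=0):
        coords = np.random.default_rng(seed).standard_normal((n, k))
        return hg.GradientTemplate(coordinates=coords, eigenvalues=np.ones(k),
                                   explained_variance=np.full(k, 1 / k))

    def test_identity_when_equal(self):
        t = self._template()
        g = hg.GradientSet(t.coordinates.copy(), np.ones(5), np.full(5, 0.2))
        out = hg.procrustes_align(g, t)
        assert out.aligned
        assert np.allclose(out.coordinates, t.coordinates, atol=1e-12)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        t = self._template(seed=2)
        for _ in range(5):
            R0 = random_orthogonal(5, rng)
            g = hg.GradientSet(t.coordinates @ R0, np.ones(5), np.full(5, 0.2))
            out = hg.procrustes_align(g, t)
            assert np.abs(out.coordinates - t.coordinates).max() < 1e-8

    def test_restores_sign_flip(self):
        t = self._template(seed=3)
        flipped = t.coordinates.copy()
        flipped[:, 1] *= -1
        g = hg.GradientSet(flipped, np.ones(5), np.full(5, 0.2))
        out = hg.procrustes_align(g, t)
        assert np.allclose(out.coordinates, t.coordinates, atol=1e-10)

    def test_rank_deficient_warns(self):
        t = self._template(seed=4)
        g = hg.GradientSet(np.zeros_like(t.coordinates), np.ones(5),
                           np.full(5, 0.2))
        with pytest.warns(UserWarning, match="rank-deficient"):
            hg.procrustes_align(g, t)


def test_hemispheric_symmetry_of_subject_gradients(null_study):
    """For symmetric HC subjects, aligned LL and RR gradients agree."""
    study = null_study
    blocks = {sid: hg.split_hemispheric(hg.compute_fc(ts), study.parcellation)
              for sid, ts in study.timeseries.items()}
    intra, inter = hg.build_templates(list(blocks.values()), n_components=5,
                                      sign_reference=study.truth.axis_loadings)
    hc_ids = [s.subject_id for s in study.subjects if s.group == "HC"][:6]
    corrs = []
    for sid in hc_ids:
        g = hg.subject_gradients(blocks[sid], intra, inter, n_components=5)
        for comp in range(3):
            corrs.append(np.corrcoef(g.LL.coordinates[:, comp],
                                     g.RR.coordinates[:, comp])[0, 1])
    assert np.mean(corrs) > 0.9
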