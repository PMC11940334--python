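"""Synthetic cohort generator: parcellation, phenotype, covariance, sampling."""

import numpy as np
import pytest

import hemigrad as hg
from hemigrad.exceptions import DataError, ParameterError
from hemigrad.parcellation import homotopic_pairs
from hemigrad.simulate import latent_loadings


class TestGenerateParcellation:
    def test_small_construction(self):
        p = hg.generate_parcellation(8, 2, seed=1)
        assert p.n_regions == 16
        assert p.partner_id[0] == 8  # L-first ordering
        assert p.hemisphere[0] == "L" and p.hemisphere[8] == "R"

    def test_full_atlas_network_sizes(self):
        p = hg.generate_parcellation(200, 7, seed=3)
        assert p.n_regions == 400
        left = p.network[p.left_indices]
        counts = {net: (left == net).sum() for net in p.networks}
        assert len(counts) == 7
        assert all(c in (28, 29) for c in counts.values())

    def test_below_minimum_errors(self):
        with pytest.raises(ParameterError):
            hg.generate_parcellation(4, 2, seed=1)
        with pytest.raises(ParameterError):
            hg.generate_parcellation(16, 0)

    def test_invariants_and_pairing(self, seven_net_parcellation):
        p = seven_net_parcellation
        pairs = homotopic_pairs(p)
        # involution crossing hemispheres with matching networks
        for k in range(len(pairs.left_ids)):
            i, j = pairs.left_pos[k], pairs.right_pos[k]
            assert p.hemisphere[i] == "L" and p.hemisphere[j] == "R"
            assert p.network[i] == p.network[j]

    def test_validation_rejects_broken_tables(self, small_parcellation):
        broken = small_parcellation.to_frame()
        broken.loc[0, "network"] = "DMN"  # pair now mismatched
        with pytest.raises(DataError):
            hg.ParcellationInfo(
                broken["region_id"].to_numpy(), broken["hemisphere"].to_numpy(),
                broken["partner_id"].to_numpy(), broken["network"].to_numpy())


class TestGenerateCohort:
    def test_cohort_shape(self):
        recs = hg.generate_cohort(270, 209, 8, seed=7)
        assert len(recs) == 479
        assert len({r.site for r in recs}) == 8
        groups = [r.group for r in recs]
        assert groups.count("HC") == 270 and groups.count("SZ") == 209
        ages = np.array([r.age for r in recs])
        assert ages.min() >= 18 and ages.max() <= 65
        fd = np.array([r.mean_fd for r in recs])
        assert (fd > 0.35).mean() < 0.05  # exclusions are rare by design

    def test_minimal_and_determinism(self):
        recs = hg.generate_cohort(1, 1, 1, seed=0)
        assert len(recs) == 2 and recs[0].site == recs[1].site
        a = hg.generate_cohort(10, 10, 2, seed=3)
        b = hg.generate_cohort(10, 10, 2, seed=3)
        assert all(ra == rb for ra, rb in zip(a, b))

    def test_too_many_sites(self):
        with pytest.raises(ParameterError):
            hg.generate_cohort(2, 2, 5, seed=0)

    def test_panss_only_for_patients(self):
        recs = hg.generate_cohort(5, 5, 1, seed=2)
        for r in recs:
            if r.group == "HC":
                assert r.panss_pos is None
            else:
                assert r.panss_pos >= 7


@pytest.fixture(scope="module")
def covariance_setup():
    effects = [hg.EffectSpec("DAN", 1, "intra", 0.5)]
    parc = hg.generate_parcellation(16, 7, seed=0)
    truth = hg.generate_truth(parc, effects, n_sites=1, seed=0)
    hc = hg.SubjectRecord("sub-h", "HC", 30, "F", "site1", 0.1, 0.5)
    sz = hg.SubjectRecord("sub-p", "SZ", 30, "F", "site1", 0.1, 0.5)
    return parc, truth, hc, sz


class TestTruthCovariance:
    @pytest.fixture()
    def setup(self, covariance_setup):
        return covariance_setup

    def test_hc_is_hemispherically_symmetric(self, setup):
        parc, truth, hc, _ = setup
        cov = hg.build_truth_covariance(parc, hc, truth)
        nh = len(parc.left_indices)
        # swapping each region with its partner leaves the covariance fixed
        perm = np.concatenate([np.arange(nh, 2 * nh), np.arange(nh)])
        assert np.allclose(cov, cov[np.ix_(perm, perm)])

    def test_planted_shift_confined_to_network_rows(self, setup):
        parc, truth, _, sz = setup
        cov = hg.build_truth_covariance(parc, sz, truth)
        nh = len(parc.left_indices)
        ll, rr = cov[:nh, :nh], cov[nh:, nh:]
        dan = parc.network[parc.left_indices] == "DAN"
        diff = np.abs(ll - rr) > 1e-12
        # differences appear only in DAN rows/columns
        outside = diff[np.ix_(~dan, ~dan)]
        assert not outside.any()
        assert diff[np.ix_(dan, ~dan)].any()

    def test_zero_loadings_degenerate_to_constant(self, setup):
        parc, truth, hc, _ = setup
        import dataclasses
        flat = dataclasses.replace(truth, axis_loadings=np.zeros_like(truth.axis_loadings))
        cov = hg.build_truth_covariance(parc, hc, flat)
        n = parc.n_regions
        expected = (truth.kernel_base + 1.0) * np.ones((n, n)) + truth.jitter * np.eye(n)
        assert np.allclose(cov, expected)

    def test_psd_with_strong_effects(self, setup):
        parc, _, _, sz = setup
        effects = [hg.EffectSpec("DAN", 1, "intra", -2.0),
                   hg.EffectSpec("CON", 2, "inter", 2.0)]
        truth = hg.generate_truth(parc, effects, n_sites=1, seed=0)
        cov = hg.build_truth_covariance(parc, sz, truth)
        assert np.linalg.eigvalsh(cov).min() > 0


class TestSampleTimeseries:
    def test_monte_carlo_consistency(self, small_parcellation):
        truth = hg.generate_truth(small_parcellation, n_sites=1, seed=1)
        hc = hg.SubjectRecord("sub-x", "HC", 30, "F", "site1", 0.1, 0.5)
        cov = hg.build_truth_covariance(small_parcellation, hc, truth)
        ts = hg.sample_timeseries(cov, 2000, hc, truth, seed=4)
        sample_cov = np.cov(ts)
        scale = truth.site_scale["site1"] ** 2
        r = np.corrcoef(sample_cov.ravel(), (scale * cov).ravel())[0, 1]
        assert r > 0.9

    def test_determinism_and_identity_site_effects(self, small_parcellation):
        truth = hg.generate_truth(small_parcellation, n_sites=1, seed=1)
        truth.site_location["site1"] = 0.0
        truth.site_scale["site1"] = 1.0
        hc = hg.SubjectRecord("sub-x", "HC", 30, "F", "site1", 0.1, 0.5)
        cov = hg.build_truth_covariance(small_parcellation, hc, truth)
        a = hg.sample_timeseries(cov, 100, hc, truth, seed=9)
        b = hg.sample_timeseries(cov, 100, hc, truth, seed=9)
        assert np.array_equal(a, b)
        # identity site effects leave the draw untouched
        other = hg.SubjectRecord("sub-x", "HC", 30, "F", "siteX", 0.1, 0.5)
        c = hg.sample_timeseries(cov, 100, other, truth, seed=9)
        assert np.array_equal(a, c)

    def test_short_series_warns(self, small_parcellation):
        truth = hg.generate_truth(small_parcellation, n_sites=1, seed=1)
        hc = hg.SubjectRecord("sub-x", "HC", 30, "F", "site1", 0.1, 0.5)
        cov = hg.build_truth_covariance(small_parcellation, hc, truth)
        with pytest.warns(UserWarning, match="noisy"):
            hg.sample_timeseries(cov, 10, hc, truth, seed=0)


def test_fc_error_decreases_with_timepoints(small_parcellation):
    """Longer scans bring the sample FC closer to the truth FC."""
    truth = hg.generate_truth(small_parcellation, n_sites=1, seed=2)
    hc = hg.SubjectRecord("sub-x", "HC", 30, "F", "site1", 0.1, 0.5)
    cov = hg.build_truth_covariance(small_parcellation, hc, truth)
    sd = np.sqrt(np.diag(cov))
    truth_fc = cov / np.outer(sd, sd)
    np.fill_diagonal(truth_fc, 0)
    errors = []
    for t in (100, 400, 1600):
        errs = []
        for seed in range(5):
            ts = hg.sample_timeseries(cov, t, hc, truth, seed=seed)
            r = np.corrcoef(ts)
            np.fill_diagonal(r, 0)
            errs.append(np.linalg.norm(r - truth_fc))
        errors.append(np.mean(errs))
    assert errors[0] > errors[1] > errors[2]


def test_latent_axes_are_orthogonal_with_decreasing_spread():
    X = latent_loadings(64)
    corr = np.corrcoef(X.T)
    assert np.abs(corr[np.triu_indices(3, 1)]).max() < 0.15
    sds = X.std(axis=0)
    assert sds[0] > sds[1] > sds[2]
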