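"""LDA discriminant axes, best projection values and class-code schemes."""

import numpy as np
import pytest

import phenospec as ps


def gaussian_groups(rng, centers, n=30, n_bands=1, sd=0.1):
    """1-D (or isotropic) Gaussian blobs, one per group label."""
    spectra, labels = [], []
    for g, c in centers.items():
        spectra.append(c + sd * rng.standard_normal((n, n_bands)))
        labels += [g] * n
    wl = np.linspace(400, 1000, n_bands)
    return ps.SpectrumTable(np.vstack(spectra), wl, labels)


class TestFitLDA:
    def test_univariate_two_groups_axis_is_sign_fixed_unit(self, rng):
        table = gaussian_groups(rng, {"BH": 0.0, "AS": 5.0})
        model = ps.fit_lda(table, shrinkage=0.1)
        assert model.discriminant_axes.shape == (1, 1)
        assert abs(abs(model.discriminant_axes[0, 0]) - 1.0) < 1e-12
        assert model.group_centers_1d["BH"] < model.group_centers_1d["AS"]

    def test_projected_centers_match_brute_force_means(self, cal_val):
        cal, _ = cal_val
        model = ps.fit_lda(cal)
        bpv = ps.best_projection_values(model, cal)
        for g in cal.groups:
            brute = np.mean(
                (cal.spectra[cal.group == g] - model.centering_vector)
                @ model.discriminant_axes[:, model.chosen_axis]
            )
            assert abs(model.group_centers_1d[g] - brute) < 1e-10
            assert abs(bpv[cal.group == g].mean() - brute) < 1e-10

    def test_full_shrinkage_identity_covariance_gives_mean_difference_axis(self, rng):
        """With diagonal within-scatter, the 2-group axis is the standardized
        mean-difference direction (closed form)."""
        delta = np.asarray([3.0, -1.0, 2.0, 0.5])
        base = rng.standard_normal((400, 4))
        spectra = np.vstack([base[:200], base[200:] + delta])
        table = ps.SpectrumTable(spectra, np.arange(4.0) + 400, ["BH"] * 200 + ["AS"] * 200)
        model = ps.fit_lda(table, shrinkage=1.0)
        sw_diag = np.zeros(4)
        for g in ("BH", "AS"):
            dev = table.spectra[table.group == g] - table.spectra[table.group == g].mean(0)
            sw_diag += (dev**2).sum(axis=0)
        expected = (np.diff(
            [table.spectra[table.group == g].mean(0) for g in ("BH", "AS")], axis=0
        ).ravel()) / sw_diag
        expected /= np.linalg.norm(expected)
        got = model.discriminant_axes[:, 0]
        assert min(np.linalg.norm(got - expected), np.linalg.norm(got + expected)) < 1e-8

    def test_eigenvalue_equals_between_within_bpv_variance_ratio(self, rng):
        table = gaussian_groups(rng, {"BH": 0.0, "AR": 2.0, "AS": 4.0}, n=50, n_bands=5, sd=0.3)
        model = ps.fit_lda(table, shrinkage=0.0)
        bpv = ps.best_projection_values(model, table)
        a = model.discriminant_axes[:, 0]
        sw = np.zeros((5, 5))
        sb = np.zeros((5, 5))
        mu = table.spectra.mean(0)
        for g in table.groups:
            Xg = table.spectra[table.group == g]
            dev = Xg - Xg.mean(0)
            sw += dev.T @ dev
            dm = (Xg.mean(0) - mu)[:, None]
            sb += len(Xg) * dm @ dm.T
        ratio = (a @ sb @ a) / (a @ sw @ a)
        assert abs(ratio - model.eigenvalues[0]) < 1e-8

    def test_singular_scatter_without_shrinkage_suggests_shrinkage(self, rng):
        # more bands than samples -> singular within-class scatter
        table = gaussian_groups(rng, {"BH": 0.0, "AS": 1.0}, n=4, n_bands=20, sd=0.1)
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            ps.fit_lda(table, shrinkage=0.0)


class TestBestProjectionValues:
    def test_sample_at_global_mean_projects_to_zero(self, cal_val):
        cal, _ = cal_val
        model = ps.fit_lda(cal)
        assert abs(ps.best_projection_values(model, cal.spectra.mean(0)[None, :])[0]) < 1e-10

    def test_translation_invariance(self, cal_val):
        cal, _ = cal_val
        model = ps.fit_lda(cal)
        bpv = ps.best_projection_values(model, cal)
        shifted = ps.SpectrumTable(cal.spectra + 0.37, cal.wavelengths, cal.group)
        model2 = ps.fit_lda(shifted)
        bpv2 = ps.best_projection_values(model2, shifted)
        np.testing.assert_allclose(bpv, bpv2, atol=1e-8)

    def test_band_mismatch_rejected(self, cal_val, rng):
        model = ps.fit_lda(cal_val[0])
        with pytest.raises(ValueError, match="band mismatch"):
            ps.best_projection_values(model, rng.random((3, 7)))


class TestBPVEncoding:
    def test_linear_rescale_arithmetic(self):
        bpv = np.repeat([-2.0, 1.0, 2.0], 5)
        groups = np.repeat(["BH", "AR", "AS"], 5)
        enc = ps.encode_groups_bpv(bpv, groups, "BH")
        assert enc.codes == {"BH": 0.0, "AR": 75.0, "AS": 100.0}

    def test_published_visnir_geometry_yields_0_74_100(self):
        bpv = np.repeat([0.0, 0.74, 1.0], 4)
        groups = np.repeat(["BH", "AR", "AS"], 4)
        enc = ps.encode_groups_bpv(bpv, groups, "BH")
        assert enc.codes == {"BH": 0.0, "AR": 74.0, "AS": 100.0}
        assert enc.group_order == ("BH", "AR", "AS")

    def test_sample_order_permutation_invariance(self, rng):
        bpv = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(1, 0.1, 10), rng.normal(3, 0.1, 10)])
        groups = np.asarray(["BH"] * 10 + ["AR"] * 10 + ["AS"] * 10, dtype=object)
        enc1 = ps.encode_groups_bpv(bpv, groups)
        perm = rng.permutation(30)
        enc2 = ps.encode_groups_bpv(bpv[perm], groups[perm])
        assert enc1.codes == enc2.codes

    def test_coincident_centers_rejected(self):
        bpv = np.repeat([0.0, 0.0, 1.0], 3)
        with pytest.raises(ValueError, match="degenerate"):
            ps.encode_groups_bpv(bpv, np.repeat(["BH", "AR", "AS"], 3), "BH")

    def test_affine_axis_rescale_leaves_codes_unchanged(self, rng):
        bpv = np.concatenate([rng.normal(0, 0.1, 8), rng.normal(2, 0.1, 8), rng.normal(5, 0.1, 8)])
        groups = np.repeat(["BH", "AR", "AS"], 8)
        enc1 = ps.encode_groups_bpv(bpv, groups)
        enc2 = ps.encode_groups_bpv(3.7 * bpv - 11.0, groups)
        assert enc1.codes == enc2.codes

    def test_code_order_follows_center_order(self, cal_val):
        cal, _ = cal_val
        model = ps.fit_lda(cal)
        enc = ps.encode_groups_bpv(ps.best_projection_values(model, cal), cal.group)
        by_center = tuple(sorted(enc.centers, key=enc.centers.get))
        assert enc.group_order == by_center


class TestSPRIEncoding:
    def test_three_group_visnir_order(self):
        enc = ps.encode_groups_spri(("BH", "AR", "AS"))
        assert enc.codes == {"BH": 0.0, "AR": 50.0, "AS": 100.0}

    def test_three_group_swir_order(self):
        enc = ps.encode_groups_spri(("BH", "AS", "AR"))
        assert enc.codes == {"BH": 0.0, "AS": 50.0, "AR": 100.0}

    def test_two_groups_are_endpoints(self):
        assert ps.encode_groups_spri(("BH", "AS")).codes == {"BH": 0.0, "AS": 100.0}

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ps.encode_groups_spri(("BH", "BH", "AS"))


def test_equidistant_archetypes_encode_near_0_50_100():
    """Three equally spaced group archetypes should code close to 0/50/100."""
    deviations = []
    for seed in range(20):
        arch = ps.make_archetypes("visnir", group_levels={"BH": 0.0, "AR": 0.5, "AS": 1.0})
        t = ps.simulate_spectra(arch, (60, 60, 60), ps.NoiseConfig(seed=seed))
        model = ps.fit_lda(t)
        enc = ps.encode_groups_bpv(ps.best_projection_values(model, t), t.group)
        deviations.append(abs(enc.codes["AR"] - 50.0))
        assert enc.codes["BH"] == 0.0 and enc.codes["AS"] == 100.0
    assert max(deviations) <= 5.0
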