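"""Surface references, depths, local fits, core/shell, charge density."""

import numpy as np
import pandas as pd
import pytest

from lnptitrate.spatial import (
    ChargeDensitySeries,
    DepthProfile,
    SurfaceReference,
    assign_leaflet,
    bin_profile,
    core_shell,
    density_profile,
    depth_table,
    fit_surface_charge,
    insertion_depth,
    local_fits,
    surface_charge_series,
    surface_reference,
    thickness_and_diameter,
)
from lnptitrate.titration import ghh, hh


def make_trace(rows):
    return pd.DataFrame(rows, columns=["time_ps", "particle_id", "species", "leaflet", "z_nm"])


def flat_surface(n_frames=5, up=2.0, lo=-2.0):
    rows = []
    for t in range(n_frames):
        rows.append([float(t), 900, "DSPC", "upper", up])
        rows.append([float(t), 901, "DSPC", "lower", lo])
    return make_trace(rows)


class TestSurfaceReference:
    def test_constant_positions(self):
        ref = surface_reference(flat_surface())
        assert np.all(ref.median_p_upper == 2.0)
        assert np.all(ref.median_p_lower == -2.0)

    def test_odd_count_median(self):
        rows = [[0.0, i, "DSPC", "upper", z] for i, z in enumerate([1.0, 2.0, 4.0])]
        rows += [[0.0, 9, "DSPC", "lower", -2.0]]
        ref = surface_reference(make_trace(rows))
        assert ref.median_p_upper[0] == 2.0

    def test_even_count_midpoint_convention(self):
        rows = [[0.0, i, "DSPC", "upper", z] for i, z in enumerate([1.0, 3.0])]
        rows += [[0.0, 9, "DSPC", "lower", -2.0]]
        ref = surface_reference(make_trace(rows))
        assert ref.median_p_upper[0] == 2.0

    def test_missing_leaflet_frame_skipped_with_warning(self):
        rows = [[0.0, 0, "DSPC", "upper", 2.0], [0.0, 1, "DSPC", "lower", -2.0],
                [1.0, 0, "DSPC", "upper", 2.0]]
        with pytest.warns(UserWarning, match="missing"):
            ref = surface_reference(make_trace(rows))
        assert ref.time.size == 1

    def test_upper_must_exceed_lower(self):
        with pytest.raises(ValueError):
            SurfaceReference(np.array([0.0]), np.array([-1.0]), np.array([1.0]))


class TestInsertionDepth:
    def test_zero_at_surface(self):
        assert insertion_depth(2.0, 2.0, -2.0, "upper") == 0.0

    def test_upper_below_median_is_negative(self):
        assert insertion_depth(1.0, 2.0, -2.0, "upper") == -1.0

    def test_lower_leaflet_mirror(self):
        assert insertion_depth(-1.0, 2.0, -2.0, "lower") == -1.0

    def test_leaflet_from_midplane_sign(self):
        leaf = assign_leaflet(np.array([1.0, -0.5]), 2.0, -2.0)
        assert list(leaf) == ["upper", "lower"]


class TestBinProfile:
    def test_single_bin_half_deprotonated(self):
        sites = pd.DataFrame(
            {
                "time_ps": [0.0, 0.0, 1.0, 1.0],
                "lam": [0.05, 0.95, 0.05, 0.95],
                "depth_nm": [-0.3, -0.3, -0.35, -0.3],
            }
        )
        prof = bin_profile(sites, ph=7.0)
        filled = ~np.isnan(prof.s_deprot)
        assert filled.sum() == 1
        assert prof.s_deprot[filled][0] == 0.5
        assert prof.count[filled][0] == 4

    def test_empty_bins_marked_undefined(self):
        sites = pd.DataFrame(
            {"time_ps": [0.0, 0.0], "lam": [0.05, 0.95], "depth_nm": [-1.0, 0.5]}
        )
        prof = bin_profile(sites, ph=7.0)
        assert np.isnan(prof.s_deprot).sum() > 0

    def test_no_classifiable_frames_rejected(self):
        sites = pd.DataFrame({"time_ps": [0.0], "lam": [0.5], "depth_nm": [0.0]})
        with pytest.raises(ValueError):
            bin_profile(sites, ph=7.0)


class TestLocalFits:
    @staticmethod
    def exact_profiles(pka_by_bin, n_by_bin, ph_values, sem=0.01):
        profiles = []
        centers = np.array(sorted(pka_by_bin))
        for ph in ph_values:
            s = np.array([ghh(ph, pka_by_bin[c], n_by_bin[c]) for c in centers])
            profiles.append(
                DepthProfile(
                    bin_centers=centers,
                    s_deprot=s,
                    sem=np.full(centers.size, sem),
                    count=np.full(centers.size, 50),
                    ph=ph,
                )
            )
        return profiles

    def test_exact_bins_recovered(self):
        pka = {-0.875: 6.5, -0.375: 7.0}
        n = {-0.875: 0.6, -0.375: 0.8}
        profiles = self.exact_profiles(pka, n, np.linspace(3.0, 11.0, 9))
        prof = local_fits(profiles, n_reps=300, seed=1)
        assert prof.bin_centers.size == 2
        for c, p_fit, n_fit in zip(prof.bin_centers, prof.pka_local, prof.n_local):
            assert p_fit == pytest.approx(pka[c], abs=0.02)
            assert n_fit == pytest.approx(n[c], abs=0.02)

    def test_out_of_window_bins_excluded(self):
        pka = {-1.375: 5.0, 0.375: 7.5, -0.375: 7.0}
        n = {-1.375: 1.0, 0.375: 1.0, -0.375: 1.0}
        profiles = self.exact_profiles(pka, n, np.linspace(3.0, 11.0, 9))
        prof = local_fits(profiles, n_reps=100, seed=1)
        # -1.375 lies below z_lo = -1.2 and 0.375 above z_hi = 0.2
        assert list(prof.bin_centers) == [-0.375]

    def test_bins_with_too_few_ph_levels_excluded(self):
        pka = {-0.375: 7.0}
        n = {-0.375: 1.0}
        profiles = self.exact_profiles(pka, n, [6.0, 8.0])
        prof = local_fits(profiles, min_count=3, n_reps=100, seed=1)
        assert prof.bin_centers.size == 0


def patch_like_trace():
    """Small constructed trace with known core/shell membership."""
    rows = []
    for t in (0.0, 1.0):
        rows += [[t, 900, "DSPC", "upper", 3.0], [t, 901, "DSPC", "lower", -3.0]]
        rows += [[t, 1, "ALC0315", "upper", 1.0]]    # depth -2.0 -> core
        rows += [[t, 2, "ALC0315", "upper", 2.0]]    # depth -1.0 -> shell
        rows += [[t, 3, "CHOL", "lower", -0.9]]      # depth -2.1 -> core
        rows += [[t, 4, "CHOL", "upper", 2.8]]       # depth -0.2 -> shell
        rows += [[t, 5, "WATER", "upper", 3.5]]      # above surface
    return make_trace(rows)


def mirror(trace):
    out = trace.copy()
    out["z_nm"] = -out["z_nm"]
    out["leaflet"] = out["leaflet"].map({"upper": "lower", "lower": "upper"})
    return out


class TestCoreShell:
    def test_assignment_rule_and_fractions(self):
        trace = patch_like_trace()
        ref = surface_reference(trace)
        table = core_shell(trace, ref, cutoff=1.8)
        assert table.core == pytest.approx({"ALC0315": 0.5, "CHOL": 0.5})
        assert set(table.shell) == {"ALC0315", "CHOL", "DSPC"}
        assert sum(table.core.values()) == pytest.approx(1.0)
        assert sum(table.shell.values()) == pytest.approx(1.0)
        assert table.core_water_density == 0.0

    def test_unknown_species_rejected(self):
        trace = patch_like_trace()
        trace.loc[len(trace)] = [0.0, 99, "PLASMID", "upper", 0.0]
        ref = surface_reference(patch_like_trace())
        with pytest.raises(ValueError, match="PLASMID"):
            core_shell(trace, ref)

    def test_leaflet_mirror_symmetry(self):
        """Mirroring all z about the midplane leaves the composition
        unchanged."""
        trace = patch_like_trace()
        ref = surface_reference(trace)
        mirrored = mirror(trace)
        table_a = core_shell(trace, ref)
        table_b = core_shell(mirrored, surface_reference(mirrored))
        assert table_a.core == pytest.approx(table_b.core)
        assert table_a.shell == pytest.approx(table_b.shell)


class TestSurfaceCharge:
    def test_counts_protonated_sites_in_shell(self):
        frames = []
        for ph, n_prot in ((4.0, 4), (8.0, 1)):
            rows = []
            for t in (0.0, 1.0):
                for i in range(4):
                    lam = 0.05 if i < n_prot else 0.95
                    rows.append([t, i, lam, "upper", -0.5])
            frames.append(
                (ph, pd.DataFrame(rows, columns=["time_ps", "particle_id", "lam", "leaflet", "depth_nm"]))
            )
        series = surface_charge_series(dict(frames))
        assert series.rho[0] == pytest.approx(1.0)   # low-pH reference
        assert series.rho[1] == pytest.approx(0.25)

    def test_zero_rho_max_rejected(self):
        tab = pd.DataFrame(
            {"time_ps": [0.0], "particle_id": [0], "lam": [0.95],
             "leaflet": ["upper"], "depth_nm": [-0.5]}
        )
        with pytest.raises(ValueError, match="rho_max"):
            surface_charge_series({7.0: tab})

    def test_noiseless_series_fit_is_exact(self):
        """With the true (full-protonation) normalization reference the HH
        fit returns the generator pKa to numerical precision."""
        ph = np.arange(3.17, 11.18, 1.0)
        rho = 1.0 - hh(ph, 5.47)
        series = ChargeDensitySeries(
            ph=ph, rho=rho, sem=np.full(ph.size, 1e-3), rho_max=1.0
        )
        fit = fit_surface_charge(series)
        assert fit.pka == pytest.approx(5.47, abs=1e-6)

    def test_mirror_symmetry_of_depth_binning(self):
        """Mirrored traces give identical depth tables (leaflet folding)."""
        trace = patch_like_trace()
        ref = surface_reference(trace)
        tab = depth_table(trace, ref)
        mirrored = mirror(trace)
        tab_m = depth_table(mirrored, surface_reference(mirrored))
        np.testing.assert_allclose(
            np.sort(tab.depth_nm.to_numpy()), np.sort(tab_m.depth_nm.to_numpy())
        )


class TestDensityProfile:
    def test_delta_peak_scaled_to_one(self):
        trace = flat_surface(3)
        extra = make_trace([[float(t), 5, "CHOL", "upper", 2.0] for t in range(3)])
        trace = pd.concat([trace, extra], ignore_index=True)
        ref = surface_reference(trace)
        prof = density_profile(trace, ref, ["CHOL"])
        assert prof["CHOL"].max() == 1.0
        peak_depth = prof.loc[prof["CHOL"].idxmax(), "depth_nm"]
        assert abs(peak_depth) < 0.1

    def test_every_species_max_normalized(self):
        trace = patch_like_trace()
        ref = surface_reference(trace)
        prof = density_profile(trace, ref, ["ALC0315", "CHOL", "DSPC"])
        for sp in ("ALC0315", "CHOL", "DSPC"):
            assert prof[sp].max() == 1.0


class TestThicknessAndDiameter:
    def test_constant_medians(self):
        ref = SurfaceReference(
            np.arange(5.0), np.full(5, 2.0), np.full(5, -2.0)
        )
        t, d = thickness_and_diameter(ref, equil_start=0)
        assert t == 4.0 and d == 12.0

    def test_lnp_scale_thickness_maps_into_diameter_band(self):
        ref = SurfaceReference(
            np.arange(10.0), np.full(10, 7.1), np.full(10, -7.1)
        )
        t, d = thickness_and_diameter(ref, equil_start=0)
        assert t == pytest.approx(14.2)
        assert 40.0 < d < 45.0

    def test_diameter_linear_in_thickness(self):
        ref1 = SurfaceReference(np.arange(4.0), np.full(4, 1.0), np.full(4, -1.0))
        ref2 = SurfaceReference(np.arange(4.0), np.full(4, 2.0), np.full(4, -2.0))
        _, d1 = thickness_and_diameter(ref1, equil_start=0)
        _, d2 = thickness_and_diameter(ref2, equil_start=0)
        assert d2 == pytest.approx(2.0 * d1)

    def test_unequilibrated_series_warns_and_uses_full_range(self, rng):
        n = 400
        up = np.linspace(2.0, 6.0, n)
        ref = SurfaceReference(np.arange(float(n)), up, np.full(n, -2.0))
        with pytest.warns(UserWarning, match="equilibrat"):
            t, _ = thickness_and_diameter(ref, step_frames=50)
        assert t == pytest.approx((up + 2.0).mean())
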