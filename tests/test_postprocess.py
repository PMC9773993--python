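"""Cord-frame decomposition, slice/segment statistics, DRG probes."""

import numpy as np
import pandas as pd
import pytest

import spinefield.labels as L
from spinefield.errors import AnatomyError, ComparisonError, SpinefieldError
from spinefield.montage import preset_montage
from spinefield.postprocess import (AnalysisConfig, MontageRun,
                                    compare_montages, decompose_components,
                                    drg_probe, segment_summary,
                                    segments_between, slice_profile,
                                    threshold_regions)
from spinefield.solver import FieldSolution
from spinefield.synthetic_anatomy import CordFrame, LabelGrid, Landmarks


def toy_world(nz=40):
    """9×9×nz voxel bar of CSF with a two-column WM 'cord' and GM core."""
    labels = np.full((9, 9, nz), L.CSF, np.uint8)
    labels[3, 4, :] = L.SPINAL_WM
    labels[5, 4, :] = L.SPINAL_WM
    labels[4, 4, :] = L.SPINAL_GM
    grid = LabelGrid(labels, 1.0, np.zeros(3))
    n = 5
    z = np.linspace(0, nz, n)
    pts = np.column_stack([np.full(n, 4.5), np.full(n, 4.5), z])
    t = np.tile([0.0, 0.0, 1.0], (n, 1))
    v = np.tile([0.0, -1.0, 0.0], (n, 1))
    frame = CordFrame(pts, t, v, np.cross(t, v))
    quarter = nz / 4.0
    segs = {"L2": (0.0, quarter), "L1": (quarter, 2 * quarter),
            "T12": (2 * quarter, 3 * quarter), "T11": (3 * quarter, nz)}
    lm = Landmarks(interspinous_z={}, spinous_process_z={},
                   drg_centers={("L2", "left"): np.array([7.5, 4.5, 10.0]),
                                ("L2", "right"): np.array([1.5, 4.5, 10.0])},
                   root_axes={("L2", "left"): np.array([1.0, 0.0, 0.0]),
                              ("L2", "right"): np.array([-1.0, 0.0, 0.0])},
                   segment_z_ranges=segs, cord_z_range=(0.0, float(nz)))
    return grid, frame, lm


def make_solution(grid, E):
    phi = np.where(grid.labels > 0, 0.0, np.nan)
    return FieldSolution(E=E, J=E.copy(), phi=phi, current_mA=4.0,
                         montage_name="toy", electrode_currents_mA={},
                         potential=None, grid=grid)


def masks_of(grid):
    return {"GM": grid.labels == L.SPINAL_GM,
            "WM": grid.labels == L.SPINAL_WM}


class TestDecomposition:
    def test_caudal_field_is_positive_longitudinal(self):
        grid, frame, _ = toy_world()
        E = np.zeros(grid.shape + (3,))
        E[..., 2] = -0.2  # rostral → caudal (z points rostral)
        comp = decompose_components(make_solution(grid, E), frame,
                                    masks_of(grid))
        wm = grid.labels == L.SPINAL_WM
        assert np.allclose(comp.e_long[wm], 0.2)
        assert np.allclose(comp.e_vd[wm], 0.0)
        assert np.allclose(comp.e_rl[wm], 0.0)
        assert np.allclose(comp.e_norm[wm], 0.2)

    def test_straight_frame_matches_global_axes(self, rng):
        grid, frame, _ = toy_world()
        E = rng.normal(size=grid.shape + (3,))
        comp = decompose_components(make_solution(grid, E), frame,
                                    masks_of(grid))
        m = grid.labels == L.SPINAL_WM
        assert np.allclose(comp.e_rl[m], E[..., 0][m])  # +x is left
        assert np.allclose(comp.e_vd[m], -E[..., 1][m])  # +y is dorsal
        assert np.allclose(comp.e_long[m], -E[..., 2][m])

    def test_parseval_identity(self, rng):
        grid, frame, _ = toy_world()
        E = rng.normal(size=grid.shape + (3,))
        comp = decompose_components(make_solution(grid, E), frame,
                                    masks_of(grid))
        m = ~np.isnan(comp.e_norm)
        total = (comp.e_long[m] ** 2 + comp.e_vd[m] ** 2
                 + comp.e_rl[m] ** 2)
        assert np.allclose(total, comp.e_norm[m] ** 2, rtol=1e-9)

    def test_cord_outside_frame_coverage_raises(self):
        grid, frame, _ = toy_world()
        short = CordFrame(frame.points[:3], frame.tangents[:3],
                          frame.ventral[:3], frame.left[:3])
        E = np.zeros(grid.shape + (3,))
        with pytest.raises(AnatomyError, match="coverage"):
            decompose_components(make_solution(grid, E), short,
                                 masks_of(grid))


class TestSliceProfile:
    def test_uniform_field_profile(self):
        grid, frame, _ = toy_world()
        E = np.zeros(grid.shape + (3,))
        E[..., 2] = -0.2
        comp = decompose_components(make_solution(grid, E), frame,
                                    masks_of(grid))
        prof = slice_profile(comp, AnalysisConfig(slice_thickness=1.0))
        filled = prof.dropna()
        assert np.allclose(filled["mean_e_norm"], 0.2)
        assert np.allclose(filled["mean_e_long"], 0.2)
        assert np.allclose(filled["mean_e_vd"], 0.0)

    def test_opposite_signs_cancel_in_component_not_magnitude(self):
        grid, frame, _ = toy_world()
        E = np.zeros(grid.shape + (3,))
        E[3, 4, :, 2] = -0.2  # one WM column caudal
        E[5, 4, :, 2] = +0.2  # the other rostral
        comp = decompose_components(make_solution(grid, E), frame,
                                    masks_of(grid))
        prof = slice_profile(comp, AnalysisConfig(slice_thickness=1.0))
        wm = prof[(prof.tissue == "WM") & (prof.n_voxels > 0)]
        assert np.allclose(wm["mean_e_long"], 0.0, atol=1e-12)
        assert np.allclose(wm["mean_e_norm"], 0.2)

    def test_binwise_means_consistent_with_global_mean(self, rng):
        grid, frame, _ = toy_world()
        E = rng.normal(size=grid.shape + (3,))
        comp = decompose_components(make_solution(grid, E), frame,
                                    masks_of(grid))
        prof = slice_profile(comp, AnalysisConfig(slice_thickness=2.0))
        wm = prof[(prof.tissue == "WM") & (prof.n_voxels > 0)]
        weighted = ((wm.mean_e_norm * wm.n_voxels).sum()
                    / wm.n_voxels.sum())
        mask = grid.labels == L.SPINAL_WM
        assert weighted == pytest.approx(comp.e_norm[mask].mean(), rel=1e-9)

    def test_empty_bins_flagged_not_zero_filled(self):
        grid, frame, _ = toy_world()
        grid.labels[:, :, 15:20] = L.CSF  # cut a gap in the cord
        E = np.ones(grid.shape + (3,))
        comp = decompose_components(make_solution(grid, E), frame,
                                    masks_of(grid))
        prof = slice_profile(comp, AnalysisConfig(slice_thickness=1.0))
        gap = prof[(prof.tissue == "WM")
                   & (prof.z_center > 15) & (prof.z_center < 20)]
        assert (gap.n_voxels == 0).all()
        assert gap["mean_e_norm"].isna().all()

    def test_subvoxel_slices_rejected(self):
        grid, frame, _ = toy_world()
        E = np.zeros(grid.shape + (3,))
        comp = decompose_components(make_solution(grid, E), frame,
                                    masks_of(grid))
        with pytest.raises(SpinefieldError, match="voxel"):
            slice_profile(comp, AnalysisConfig(slice_thickness=0.5))


class TestSegmentSummary:
    def _profile(self, peak_z):
        grid, frame, lm = toy_world()
        E = np.zeros(grid.shape + (3,))
        zc = grid.axis_centers(2)
        bump = 0.1 + 0.2 * np.exp(-0.5 * ((zc - peak_z) / 3.0) ** 2)
        E[..., 2] = -bump[None, None, :]
        comp = decompose_components(make_solution(grid, E), frame,
                                    masks_of(grid))
        prof = slice_profile(comp, AnalysisConfig(slice_thickness=1.0))
        return prof, lm

    def test_argmax_lands_in_peak_segment(self):
        prof, lm = self._profile(peak_z=15.0)  # inside L1's range [10, 20)
        summ = segment_summary(prof, lm)
        gm = summ[summ.tissue == "GM"].set_index("segment")
        assert gm["max_e_norm"].idxmax() == "L1"
        z0, z1 = lm.segment_z_ranges["L1"]
        assert z0 <= gm.loc["L1", "argmax_z"] <= z1

    def test_uniform_profile_gives_equal_maxima(self):
        grid, frame, lm = toy_world()
        E = np.zeros(grid.shape + (3,))
        E[..., 2] = -0.2
        comp = decompose_components(make_solution(grid, E), frame,
                                    masks_of(grid))
        prof = slice_profile(comp, AnalysisConfig(slice_thickness=1.0))
        summ = segment_summary(prof, lm)
        assert np.allclose(summ["max_e_norm"], 0.2)

    def test_norm_dominates_components(self, rng):
        grid, frame, lm = toy_world()
        E = rng.normal(size=grid.shape + (3,))
        comp = decompose_components(make_solution(grid, E), frame,
                                    masks_of(grid))
        prof = slice_profile(comp, AnalysisConfig(slice_thickness=1.0))
        summ = segment_summary(prof, lm)
        for col in ("max_abs_e_long", "max_abs_e_vd", "max_abs_e_rl"):
            assert (summ["max_e_norm"] >= summ[col] - 1e-12).all()


class TestThresholdRegions:
    @pytest.mark.parametrize("value,expect_cov", [
        (0.10, 0.0), (0.15, 1.0), (0.20, 1.0)])
    def test_threshold_inclusive(self, value, expect_cov):
        grid, frame, lm = toy_world()
        E = np.zeros(grid.shape + (3,))
        E[..., 2] = value
        comp = decompose_components(make_solution(grid, E), frame,
                                    masks_of(grid))
        mask, stats = threshold_regions(comp, AnalysisConfig(), lm)
        assert np.allclose(stats["coverage"].fillna(0.0), expect_cov)
        union = (grid.labels == L.SPINAL_WM) | (grid.labels == L.SPINAL_GM)
        assert mask.sum() == (union.sum() if expect_cov else 0)


class TestDrgProbe:
    def test_outward_field_has_positive_projection(self):
        grid, frame, lm = toy_world()
        E = np.zeros(grid.shape + (3,))
        E[..., 0] = 0.3  # +x = toward the left DRG's periphery
        rep = drg_probe(make_solution(grid, E), grid, lm,
                        AnalysisConfig(drg_probe_radius=1.5))
        rep = rep.set_index(["level", "side"])
        assert rep.loc[("L2", "left"), "projection"] == pytest.approx(0.3)
        assert rep.loc[("L2", "right"), "projection"] == pytest.approx(-0.3)
        assert rep.loc[("L2", "left"), "mean_e_norm"] == pytest.approx(0.3)

    def test_orthogonal_field_has_zero_projection(self):
        grid, frame, lm = toy_world()
        E = np.zeros(grid.shape + (3,))
        E[..., 2] = 0.3
        rep = drg_probe(make_solution(grid, E), grid, lm,
                        AnalysisConfig(drg_probe_radius=1.5))
        assert np.allclose(rep["projection"], 0.0, atol=1e-12)

    def test_empty_probe_flagged_missing(self):
        grid, frame, lm = toy_world()
        lm.drg_centers[("L2", "left")] = np.array([100.0, 100.0, 100.0])
        E = np.zeros(grid.shape + (3,))
        rep = drg_probe(make_solution(grid, E), grid, lm,
                        AnalysisConfig(drg_probe_radius=1.5))
        row = rep.set_index(["level", "side"]).loc[("L2", "left")]
        assert row["n_voxels"] == 0
        assert np.isnan(row["mean_e_norm"])


def _fake_run(name, score, digest="abc", current=4.0):
    drg = pd.DataFrame([
        {"level": "L2", "side": "left", "n_voxels": 5,
         "mean_e_norm": score, "projection": 0.1},
        {"level": "L2", "side": "right", "n_voxels": 5,
         "mean_e_norm": score / 2, "projection": -0.1}])
    summ = pd.DataFrame([{"segment": "L1", "tissue": "GM",
                          "max_e_norm": score, "max_abs_e_long": score,
                          "max_abs_e_vd": 0.0, "max_abs_e_rl": 0.0,
                          "argmax_z": 1.0, "n_slices": 3}])
    return MontageRun(name=name, summary=summ, drg_report=drg,
                      anatomy_digest=digest, current_mA=current)


class TestCompareMontages:
    def test_identical_runs_tie_broken_lexicographically(self):
        report = compare_montages(
            [_fake_run("b-montage", 0.3), _fake_run("a-montage", 0.3)],
            {"kind": "drg", "items": [("L2", "left")]})
        assert report["winner"] == "a-montage"

    def test_higher_target_field_wins(self):
        report = compare_montages(
            [_fake_run("weak", 0.2), _fake_run("strong", 0.4)],
            {"kind": "drg", "items": [("L2", "left")]})
        assert report["winner"] == "strong"
        assert report["scores"]["strong"] == pytest.approx(0.4)

    def test_segment_target(self):
        report = compare_montages(
            [_fake_run("weak", 0.2), _fake_run("strong", 0.4)],
            {"kind": "segments", "items": ["L1"], "tissue": "GM"})
        assert report["winner"] == "strong"

    def test_single_run_rejected(self):
        with pytest.raises(ComparisonError, match="two"):
            compare_montages([_fake_run("only", 0.3)],
                             {"kind": "drg", "items": [("L2", "left")]})

    def test_mismatched_anatomy_rejected(self):
        with pytest.raises(ComparisonError, match="digest"):
            compare_montages(
                [_fake_run("a", 0.3, digest="x"),
                 _fake_run("b", 0.3, digest="y")],
                {"kind": "drg", "items": [("L2", "left")]})


class TestSegmentsBetween:
    def test_default_anatomy_window(self, anatomy):
        _, _, lm = anatomy
        montage = preset_montage("T8-L2", lm)
        between = segments_between(lm, montage)
        assert {"T12", "L1", "L2", "L3", "L4", "L5"} <= set(between)
        assert "Co" not in between  # under the cathode footprint
        assert "T8" not in between  # rostral to the anode footprint
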