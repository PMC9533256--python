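"""MRT emulation and postprocessing: resampling fidelity, noise statistics,
radial profiles, cooled-area time series, NIfTI round trip."""

import numpy as np
import pytest

import braincool as bc
from conftest import radial_phantom_field


def constant_field(T=37.0):
    r = np.arange(0, 60.1, 0.5)
    z = np.arange(-30, 30.1, 1.0)
    return bc.ThermalField(mode="axisymmetric", axes=(r, z),
                           temperature=np.full((len(r), len(z)), T))


class TestSynthesize:
    def test_noiseless_stack_equals_resampled_model(self, phantom_field):
        stack = bc.synthesize_stack([phantom_field], noise_sd=0.0)
        X, Y = np.meshgrid(stack.x, stack.y, indexing="ij")
        expected = 37.0 - 5.0 * np.exp(-(X ** 2 + Y ** 2) / (2 * 15.0 ** 2))
        # linear resampling of the 0.5 mm model grid
        assert np.allclose(stack.frames[0, :, :, 1], expected, atol=5e-4)

    def test_seed_reproducibility(self, phantom_field):
        a = bc.synthesize_stack([phantom_field], noise_sd=0.5, seed=7)
        b = bc.synthesize_stack([phantom_field], noise_sd=0.5, seed=7)
        c = bc.synthesize_stack([phantom_field], noise_sd=0.5, seed=8)
        assert np.array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_acquisition_geometry_defaults(self, phantom_field):
        stack = bc.synthesize_stack([phantom_field])
        assert stack.voxel_size == (2.0, 2.0, 5.0)
        assert stack.frames.shape[3] == 3
        # artifact mask covers the 3 mm core
        X, Y = np.meshgrid(stack.x, stack.y, indexing="ij")
        assert np.array_equal(stack.artifact_mask, np.hypot(X, Y) <= 3.0 + 1e-9)

    def test_noise_standard_deviation(self):
        fld = constant_field()
        stacks = [bc.synthesize_stack([fld], noise_sd=0.5, seed=s)
                  for s in range(100)]
        samples = np.stack([s.frames[0] for s in stacks])
        sd = samples.std(axis=0).mean()
        assert sd == pytest.approx(0.5, rel=0.15)

    def test_geometry_mismatch_rejected(self, phantom_field):
        other = radial_phantom_field(r_max=40.0)
        with pytest.raises(bc.GeometryError):
            bc.synthesize_stack([phantom_field, other])


class TestPostprocess:
    def test_output_voxel_size(self, phantom_field):
        proc = bc.postprocess_stack(bc.synthesize_stack([phantom_field]))
        assert proc.voxel_size == (0.5, 0.5, 5.0)
        assert proc.processed

    def test_constant_stack_preserved(self):
        proc = bc.postprocess_stack(bc.synthesize_stack([constant_field()]))
        assert np.allclose(proc.frames, 37.0, atol=1e-9)

    def test_linear_ramp_preserved_away_from_edges(self):
        r = np.arange(0, 60.1, 0.5)
        z = np.arange(-30, 30.1, 1.0)
        # in-plane ramp via a z-uniform axisymmetric field is not linear in x,
        # so build the stack directly
        stack = bc.synthesize_stack([constant_field()])
        ramp = 30.0 + 0.1 * stack.x[:, None] + 0.05 * stack.y[None, :]
        stack.frames[0] = ramp[:, :, None]
        proc = bc.postprocess_stack(stack)
        expected = 30.0 + 0.1 * proc.x[:, None] + 0.05 * proc.y[None, :]
        interior = (slice(16, -16), slice(16, -16))
        got = proc.frames[0, :, :, 0]
        assert np.allclose(got[interior], expected[interior], atol=1e-6)

    def test_double_postprocess_raises(self, phantom_field):
        proc = bc.postprocess_stack(bc.synthesize_stack([phantom_field]))
        with pytest.raises(bc.AlreadyProcessedError):
            bc.postprocess_stack(proc)


class TestRadialProfile:
    def test_constant_stack_profile(self):
        proc = bc.postprocess_stack(bc.synthesize_stack([constant_field()]))
        prof = bc.radial_profile(proc, centroid=(0.0, 0.0))
        assert np.allclose(prof.mean, 37.0, atol=1e-9)
        assert np.allclose(prof.se, 0.0, atol=1e-9)

    def test_round_trip_recovers_generating_function(self, phantom_field):
        """model -> synthesize (noiseless) -> postprocess -> radial profile
        must recover the generating radial function."""
        proc = bc.postprocess_stack(
            bc.synthesize_stack([phantom_field], noise_sd=0.0))
        prof = bc.radial_profile(proc, centroid=(0.0, 0.0),
                                 distances=np.arange(3.5, 20.01, 0.5))
        generating = 37.0 - 5.0 * np.exp(-(prof.distances ** 2) / (2 * 15.0 ** 2))
        assert np.nanmax(np.abs(prof.mean - generating)) < 0.1

    def test_distances_inside_artifact_rejected(self, phantom_field):
        stack = bc.synthesize_stack([phantom_field])
        with pytest.raises(ValueError):
            bc.radial_profile(stack, distances=np.array([2.0, 5.0]))

    def test_missing_distances_flagged(self, phantom_field):
        stack = bc.synthesize_stack([phantom_field], in_plane_extent=32.0)
        prof = bc.radial_profile(stack, centroid=(0.0, 0.0),
                                 distances=np.array([5.0, 200.0]),
                                 bin_width=2.0)
        assert prof.missing.tolist() == [False, True]
        assert np.isnan(prof.mean[1])

    def test_se_scales_with_inverse_sqrt_voxels(self):
        """Monte-Carlo over 200 stacks: the per-ring standard error must match
        noise_sd / sqrt(n_voxels)."""
        fld = constant_field()
        sd = 0.5
        dists = np.array([5.0, 10.0, 15.0])
        se_sum = np.zeros(3)
        n_vox = None
        for s in range(200):
            st = bc.synthesize_stack([fld], noise_sd=sd, seed=3000 + s,
                                     in_plane_extent=48.0)
            p = bc.radial_profile(st, centroid=(0.0, 0.0), distances=dists,
                                  bin_width=2.0)
            se_sum += p.se
            n_vox = p.n_voxels
        ratio = (se_sum / 200) / (sd / np.sqrt(n_vox))
        assert np.all(np.abs(ratio - 1.0) < 0.2)

    def test_default_centroid_is_coldest_voxel(self, phantom_field):
        stack = bc.synthesize_stack([phantom_field])
        cx, cy = stack.min_temperature_centroid()
        assert abs(cx) <= 1.0 and abs(cy) <= 1.0


class TestCooledArea:
    def _disc_stack(self, radius=10.0, cold=30.0):
        """Stack constructed directly in processed geometry (0.5 mm in-plane)
        with a sharp cold disc."""
        n = 128
        x = (np.arange(n) - (n - 1) / 2) * 0.5
        X, Y = np.meshgrid(x, x, indexing="ij")
        img = np.where(np.hypot(X, Y) < radius, cold, 37.0)
        frames = np.tile(img[None, :, :, None], (2, 1, 1, 3))
        return bc.ThermometryStack(frames=frames, times=np.array([0.0, 7.8]),
                                   x=x, y=x, slice_z=np.array([-5., 0., 5.]),
                                   processed=True)

    def test_disc_phantom_area_at_all_thresholds(self):
        stack = self._disc_stack()
        df = bc.cooled_area_timeseries(stack)
        for _, row in df.iterrows():
            assert row["area_mm2"] == pytest.approx(np.pi * 100.0, rel=0.02)

    def test_constant_stack_zero_area(self):
        stack = self._disc_stack(cold=37.0)
        df = bc.cooled_area_timeseries(stack)
        assert (df["area_mm2"] == 0.0).all()

    def test_area_monotone_in_threshold(self, phantom_field):
        proc = bc.postprocess_stack(bc.synthesize_stack([phantom_field]))
        df = bc.cooled_area_timeseries(
            proc, thresholds={"a": 33.0, "b": 34.0, "c": 35.0})
        areas = df.set_index("stratum")["area_mm2"]
        assert areas["a"] <= areas["b"] <= areas["c"]

    def test_unprocessed_stack_rejected(self, phantom_field):
        stack = bc.synthesize_stack([phantom_field])
        with pytest.raises(ValueError):
            bc.cooled_area_timeseries(stack)


class TestNiftiRoundTrip:
    def test_save_load_preserves_stack(self, tmp_path, phantom_field):
        stack = bc.synthesize_stack([phantom_field], noise_sd=0.3, seed=5)
        path = tmp_path / "stack.nii"
        bc.save_stack(stack, path)
        back = bc.load_stack(path)
        assert np.allclose(back.frames, stack.frames, atol=1e-5)
        assert np.allclose(back.x, stack.x)
        assert np.allclose(back.times, stack.times)
        assert back.processed == stack.processed
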