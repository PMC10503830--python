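"""Digital phantom generation and forward simulators."""

import dataclasses

import numpy as np
import pytest

from qmripd.phantom import (
    AcquisitionSpec,
    NoiseSpec,
    PhantomSpec,
    RegionSpec,
    ResponseGate,
    TissueTruth,
    TreatmentEffect,
    generate_phantom,
    population_aif,
    simulate_dce,
    simulate_dwi,
    simulate_vfa,
    spec_from_dict,
    spec_to_dict,
)
from tests.conftest import small_regions


def uniform_spec(**kw):
    """No heterogeneity, no effect: maps constant within regions and visits."""
    regions = [dataclasses.replace(r, heterogeneity_sd={}) for r in small_regions()]
    defaults = dict(
        grid_shape=(16, 16, 4), regions=regions, visits=("baseline", "day1", "last"),
        effect=TreatmentEffect(multipliers={}, decay={"day1": 1.0, "last": 0.0}),
        noise=NoiseSpec(sigma_rel=0.0), seed=3,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


class TestGeneratePhantom:
    def test_identity_case_uniform_and_visit_constant(self):
        truth = generate_phantom(uniform_spec())
        t1m = truth.masks["tumor1"]
        for p in ("adc", "t1", "ktrans", "ve", "vp", "m0"):
            vals = truth.maps["baseline"][p][t1m]
            assert np.all(vals == vals[0]), f"{p} not uniform in region"
            for visit in ("day1", "last"):
                np.testing.assert_array_equal(truth.maps[visit][p],
                                              truth.maps["baseline"][p])

    def test_determinism_same_seed_bit_identical(self, small_spec):
        a = generate_phantom(small_spec)
        b = generate_phantom(small_spec)
        for visit in small_spec.visits:
            for p in a.maps[visit]:
                np.testing.assert_array_equal(a.maps[visit][p], b.maps[visit][p])

    def test_effect_arithmetic_and_full_decay(self):
        spec = uniform_spec(
            effect=TreatmentEffect(multipliers={"adc": 0.8},
                                   decay={"day1": 1.0, "last": 0.0}),
        )
        truth = generate_phantom(spec)
        tm = truth.tumor_mask
        np.testing.assert_allclose(truth.maps["day1"]["adc"][tm],
                                   0.8 * truth.maps["baseline"]["adc"][tm])
        # decay 0 at the last visit: effect fully gone
        np.testing.assert_array_equal(truth.maps["last"]["adc"][tm],
                                      truth.maps["baseline"]["adc"][tm])
        # non-tumor voxels never change
        np.testing.assert_array_equal(truth.maps["day1"]["adc"][~tm],
                                      truth.maps["baseline"]["adc"][~tm])

    def test_overlapping_regions_rejected(self):
        regions = small_regions()
        regions[1] = dataclasses.replace(regions[1], center=(5.0, 4.5, 1.5))
        with pytest.raises(ValueError, match="overlap"):
            generate_phantom(PhantomSpec(grid_shape=(16, 16, 4), regions=regions))

    def test_response_gate_defines_changed_voxel_set(self, small_spec):
        spec = dataclasses.replace(
            small_spec,
            effect=TreatmentEffect(
                multipliers={"ve": 1.4}, decay={"day1": 1.0},
                response_gate=ResponseGate("ve", 0.39, "below"),
            ),
        )
        truth = generate_phantom(spec)
        gated = truth.tumor_mask & (truth.maps["baseline"]["ve"] < 0.39)
        changed = truth.maps["day1"]["ve"] != truth.maps["baseline"]["ve"]
        np.testing.assert_array_equal(changed, gated)
        np.testing.assert_array_equal(truth.responding, gated)

    def test_truth_clipped_to_physical_bounds_with_warning(self):
        regions = small_regions()
        regions[0] = dataclasses.replace(
            regions[0], heterogeneity_sd={"ve": 3.0})  # huge spread forces clipping
        spec = PhantomSpec(grid_shape=(16, 16, 4), regions=regions, seed=0)
        with pytest.warns(UserWarning, match="clipped"):
            truth = generate_phantom(spec)
        ve = truth.maps["baseline"]["ve"]
        assert ve.min() >= 0 and ve.max() <= 1

    def test_spec_dict_round_trip(self, small_spec):
        restored = spec_from_dict(spec_to_dict(small_spec))
        a = generate_phantom(small_spec)
        b = generate_phantom(restored)
        np.testing.assert_array_equal(a.maps["day1"]["adc"], b.maps["day1"]["adc"])


class TestSimulateDwi:
    def test_closed_form_signal(self):
        truth = {"adc": np.full((4, 4, 2), 1.2e-3), "m0": np.full((4, 4, 2), 1000.0)}
        acq = AcquisitionSpec(dwi_replicates=1)
        reps = simulate_dwi(truth, acq, NoiseSpec(sigma_rel=0.0), seed=0)
        np.testing.assert_allclose(reps[0][450.0], 1000 * np.exp(-0.54))
        assert abs(reps[0][450.0].flat[0] - 582.75) < 0.01
        np.testing.assert_array_equal(reps[0][0.0], truth["m0"])

    def test_noise_mean_unbiased_gaussian(self):
        truth = {"adc": np.full((1, 1, 1), 1.2e-3), "m0": np.full((1, 1, 1), 1000.0)}
        acq = AcquisitionSpec(dwi_replicates=10_000)
        noise = NoiseSpec(model="gaussian", sigma_rel=0.05)
        reps = simulate_dwi(truth, acq, noise, seed=5)
        draws = np.array([r[450.0].flat[0] for r in reps])
        clean = 1000 * np.exp(-0.54)
        se = 50.0 / np.sqrt(len(draws))
        assert abs(draws.mean() - clean) < 3 * se

    def test_noise_sd_scaling(self):
        truth = {"adc": np.full((1, 1, 1), 1.0e-3), "m0": np.full((1, 1, 1), 1000.0)}
        acq = AcquisitionSpec(dwi_replicates=10_000)
        reps = simulate_dwi(truth, acq, NoiseSpec(sigma_rel=0.02), seed=1)
        draws = np.array([r[0.0].flat[0] for r in reps])
        assert abs(draws.std() - 20.0) / 20.0 < 0.05

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionSpec(dwi_b_values=(-10.0, 450.0))


class TestSimulateVfa:
    def test_long_tr_limit_is_m0_sin_alpha(self):
        truth = {"t1": np.full((2, 2, 1), 0.1), "m0": np.full((2, 2, 1), 500.0)}
        acq = AcquisitionSpec(vfa_flip_angles=(15.0, 30.0), vfa_tr=10.0)
        vols = simulate_vfa(truth, acq, NoiseSpec(sigma_rel=0.0), seed=0)
        for a in (15.0, 30.0):
            np.testing.assert_allclose(vols[a], 500 * np.sin(np.deg2rad(a)),
                                       rtol=1e-10)

    def test_fa_scale_equals_scaled_nominal_angles(self):
        truth = {"t1": np.full((3, 3, 2), 1.0), "m0": np.full((3, 3, 2), 1000.0)}
        acq = AcquisitionSpec()
        noise = NoiseSpec(sigma_rel=0.0)
        scaled = simulate_vfa(truth, acq, noise, seed=0, fa_scale=0.9)
        nominal_scaled = AcquisitionSpec(
            vfa_flip_angles=tuple(0.9 * a for a in acq.vfa_flip_angles))
        direct = simulate_vfa(truth, nominal_scaled, noise, seed=0)
        for a, a9 in zip(acq.vfa_flip_angles, nominal_scaled.vfa_flip_angles):
            np.testing.assert_array_equal(scaled[a], direct[a9])

    def test_nonpositive_t1_rejected(self):
        truth = {"t1": np.zeros((2, 2, 1)), "m0": np.ones((2, 2, 1))}
        with pytest.raises(ValueError):
            simulate_vfa(truth, AcquisitionSpec(), NoiseSpec(sigma_rel=0.0), seed=0)


class TestSimulateDce:
    def test_no_exchange_no_plasma_keeps_signal_flat(self, times48):
        shape = (3, 3, 2)
        truth = {"t1": np.full(shape, 1.0), "m0": np.full(shape, 1000.0),
                 "ktrans": np.zeros(shape), "ve": np.full(shape, 0.3),
                 "vp": np.zeros(shape)}
        acq = AcquisitionSpec()
        aif = population_aif(times48, 64.0)
        frames = simulate_dce(truth, aif, acq, NoiseSpec(sigma_rel=0.0), seed=0)
        assert np.ptp(frames, axis=-1).max() < 1e-9 * frames.max()

    def test_pre_injection_frames_contrast_free(self, small_spec, times48):
        truth = generate_phantom(small_spec)
        aif = population_aif(times48, 64.0)
        frames = simulate_dce(truth.maps["baseline"], aif,
                              small_spec.acquisition, NoiseSpec(sigma_rel=0.0),
                              seed=0, artery_mask=truth.region_mask("artery"))
        pre = frames[..., :8]
        assert np.ptp(pre, axis=-1).max() < 1e-9 * pre.max()

    def test_mismatched_time_grid_rejected(self, small_spec):
        truth = generate_phantom(small_spec)
        aif = population_aif(np.arange(30) * 8.0, 64.0)
        with pytest.raises(ValueError, match="time grid"):
            simulate_dce(truth.maps["baseline"], aif, small_spec.acquisition,
                         NoiseSpec(sigma_rel=0.0), seed=0)


class TestPopulationAif:
    def test_zero_before_injection_peak_at_arrival(self, times48):
        aif = population_aif(times48, 64.0)
        assert np.all(aif.cp[times48 < 64.0] == 0)
        assert aif.cp.max() == aif.cp[8]  # biexponential decays from bolus
        # dose-scaled amplitude: 0.1 mmol/kg * (3.99 + 4.78) kg/L
        np.testing.assert_allclose(aif.cp[8], 0.1 * (3.99 + 4.78), rtol=1e-12)


class TestInvariantChecks:
    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="grid_shape"):
            PhantomSpec(grid_shape=(8, 8, 2), regions=small_regions())

    def test_missing_required_region_rejected(self):
        regions = [r for r in small_regions() if r.label != "artery"]
        with pytest.raises(ValueError, match="artery"):
            PhantomSpec(grid_shape=(16, 16, 4), regions=regions)

    def test_tissue_truth_bounds_enforced(self):
        with pytest.raises(ValueError):
            TissueTruth(adc=5e-3, t1=1.0, ktrans=0.1, ve=0.3, vp=0.03)
        with pytest.raises(ValueError):
            TissueTruth(adc=1e-3, t1=1.0, ktrans=0.1, ve=0.8, vp=0.3)  # ve+vp>1
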