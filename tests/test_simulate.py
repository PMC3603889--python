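"""Patch growth, currents, envelopes and recording synthesis."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dba.anatomy import STRUCTURE_TABLE
from dba.noise import NoiseModel, generate_noise
from dba.simulate import (SilentPatchError, SimulationConfig, d_t_for_rc,
                          envelope_ratio, gaussian_timecourse, grow_patch,
                          patch_currents, simulate_recording)


class TestPatchGrowth:
    def test_uniform_grid_one_cm2_gives_100_members(self, uniform_surface_space):
        patch = grow_patch(uniform_surface_space, seed_index=465, target_extent=1.0)
        assert len(patch.member_indices) == 100
        assert patch.total_extent == pytest.approx(1.0)

    def test_target_below_element_size_gives_singleton(self, uniform_surface_space):
        patch = grow_patch(uniform_surface_space, 465, target_extent=0.005)
        assert list(patch.member_indices) == [465]

    def test_target_equal_structure_extent_takes_everything(self, uniform_surface_space):
        patch = grow_patch(uniform_surface_space, 0, target_extent=9.0)
        assert len(patch.member_indices) == 900

    def test_oversized_target_clamps_with_warning(self, small_space):
        seed = int(small_space.indices("amygdala")[0])
        with pytest.warns(UserWarning, match="clamping"):
            patch = grow_patch(small_space, seed, target_extent=50.0)
        assert len(patch.member_indices) == len(small_space.indices("amygdala"))

    def test_patch_connected_and_single_structure(self, small_space):
        seed = int(small_space.indices("hippocampus")[10])
        patch = grow_patch(small_space, seed, 3.0)
        assert set(small_space.structure_labels[patch.member_indices]) == {"hippocampus"}
        members = set(patch.member_indices.tolist())
        reached = {patch.seed_index}
        frontier = [patch.seed_index]
        while frontier:
            i = frontier.pop()
            for j in small_space.adjacency[i]:
                if int(j) in members and int(j) not in reached:
                    reached.add(int(j))
                    frontier.append(int(j))
        assert reached == members

    def test_extent_accuracy_within_one_element(self, small_space):
        for structure in ("hippocampus", "thalamus"):
            seed = int(small_space.indices(structure)[5])
            patch = grow_patch(small_space, seed, 3.0)
            kind = small_space.specs[structure].geometry_kind
            per_unit = 100.0 if kind == "surface" else 1000.0
            max_el = small_space.element_sizes[small_space.indices(structure)].max()
            assert abs(patch.total_extent * per_unit - 3.0 * per_unit) <= max_el


class TestPatchCurrents:
    @pytest.mark.parametrize("structure", sorted(STRUCTURE_TABLE))
    @pytest.mark.parametrize("size", [1.0, 5.0])
    def test_total_current_is_dmd_times_extent_times_100(self, structure, size,
                                                         uniform_surface_space):
        """Exact neural-current totals for every structure and patch size."""
        kind, dmd, _ = STRUCTURE_TABLE[structure]
        space = uniform_surface_space
        if kind == "surface":
            n = int(size * 100)          # 1 mm^2 elements
            idx = np.arange(n)
            q = patch_currents(idx, space, dmd)
        else:
            # volume dipoles carry dmd x V/10; fabricate 10 mm^3 elements
            space = _volume_space(uniform_surface_space, element_mm3=10.0)
            n = int(size * 100)
            q = patch_currents(np.arange(n), space, dmd)
        assert q.sum() == pytest.approx(dmd * size * 100.0, rel=1e-12)

    def test_hippocampus_patch_totals_forty_nam(self, small_space):
        seed = int(small_space.indices("hippocampus")[3])
        patch = grow_patch(small_space, seed, 1.0)
        max_el = small_space.element_sizes[patch.member_indices].max()
        assert abs(patch.total_current - 40.0) <= 0.4 * max_el  # dmd x slack

    def test_empty_patch_zero(self, uniform_surface_space):
        assert patch_currents(np.array([], dtype=int), uniform_surface_space, 0.4).sum() == 0

    def test_invalid_dmd(self, uniform_surface_space):
        with pytest.raises(ValueError):
            patch_currents(np.array([0]), uniform_surface_space, 0.0)


def _volume_space(template, element_mm3):
    import copy
    from dba.anatomy import StructureSpec
    space = copy.copy(template)
    space.element_sizes = np.full(template.n_sources, element_mm3)
    space.specs = {"sheet": StructureSpec("sheet", "volume", "open", "random",
                                          dmd=1.0, target_extent=9.0)}
    return space


class TestTimecourse:
    def test_unit_peak_and_fwhm(self):
        env = gaussian_timecourse(30.0, 500, 1000, 1000.0)
        assert env[500] == 1.0
        half = 15  # 15 ms at 1 kHz
        assert env[500 + half] == pytest.approx(0.5, rel=1e-9)
        assert env[500 - half] == pytest.approx(0.5, rel=1e-9)

    @given(st.floats(10.0, 80.0), st.sampled_from([250.0, 1000.0, 1250.0]))
    def test_fwhm_property(self, fwhm, rate):
        n = 4000
        env = gaussian_timecourse(fwhm, n // 2, n, rate)
        t_ms = (np.arange(n) - n // 2) / rate * 1000.0
        exact = np.exp(-4 * np.log(2) * (t_ms / fwhm) ** 2)
        assert np.allclose(env, exact)

    def test_envelope_ratio_values(self):
        assert envelope_ratio(0.0) == 1.0
        assert envelope_ratio(15.0, 30.0) == pytest.approx(0.5)
        assert envelope_ratio(60.0, 30.0) < 1e-4
        assert d_t_for_rc(0.5) == pytest.approx(15.0)

    def test_peak_outside_record_raises(self):
        with pytest.raises(ValueError):
            gaussian_timecourse(30.0, 2000, 1000, 1250.0)


class TestRecording:
    def test_noiseless_recording_is_exact_signal(self, small_space, small_gain):
        patch = grow_patch(small_space, int(small_space.indices("hippocampus")[0]), 2.0)
        rec = simulate_recording(small_gain, [patch], SimulationConfig())
        assert rec.scale == 1.0
        assert np.array_equal(rec.data, rec.clean_signal(small_gain))

    def test_energy_snr_is_exact(self, small_space, small_gain):
        patch = grow_patch(small_space, int(small_space.indices("hippocampus")[4]), 3.0)
        cfg = SimulationConfig(snr_energy=20.0)
        noise = generate_noise(NoiseModel(seed=1), small_gain.n_sensors, 0.4)
        rec = simulate_recording(small_gain, [patch], cfg, noise=noise)
        clean = rec.clean_signal(small_gain)
        ratio = (clean ** 2).sum() / (rec.noise ** 2).sum()
        assert ratio == pytest.approx(20.0, rel=1e-6)
        assert np.allclose(rec.data, clean + rec.noise)

    def test_superposition_of_patches(self, small_space, small_gain):
        p1 = grow_patch(small_space, int(small_space.indices("hippocampus")[0]), 2.0)
        p2 = grow_patch(small_space, int(small_space.indices("cortex")[50]), 3.0)
        cfg = SimulationConfig(d_t_ms=30.0)
        both = simulate_recording(small_gain, [(p1, "subcortical"), (p2, "cortical")], cfg)
        only1 = simulate_recording(small_gain, [(p1, "subcortical")], cfg)
        only2 = simulate_recording(small_gain, [(p2, "cortical")], cfg)
        assert np.abs(both.data - only1.data - only2.data).max() < 1e-12 * np.abs(both.data).max()

    def test_full_temporal_separation_at_60ms(self, small_space, small_gain):
        p1 = grow_patch(small_space, int(small_space.indices("hippocampus")[0]), 2.0)
        p2 = grow_patch(small_space, int(small_space.indices("cortex")[50]), 3.0)
        rec = simulate_recording(small_gain, [(p1, "subcortical"), (p2, "cortical")],
                                 SimulationConfig(d_t_ms=60.0))
        assert rec.r_c < 1e-4
        cortical_env = rec.envelopes[1]
        assert cortical_env[rec.subcortical_peak_sample] < 1e-4

    def test_silent_patch_with_noise_raises(self, small_space, small_gain):
        from dba.simulate import Patch
        silent = Patch(seed_index=0, member_indices=np.array([0]),
                       currents=np.array([0.0]), structure="cortex", total_extent=0.0)
        noise = generate_noise(NoiseModel(seed=0), small_gain.n_sensors, 0.4)
        with pytest.raises(SilentPatchError):
            simulate_recording(small_gain, [silent], SimulationConfig(), noise=noise)
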