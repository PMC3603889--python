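"""Experiment grid driver: determinism, composition, detection curves."""

import dataclasses

import numpy as np
import pytest

from dba.inverse import estimate_noise_cov, kernel_family
from dba.metrics import dle_g, dle_m
from dba.montecarlo import ExperimentGrid, run_grid, visual_cortex_seed
from dba.noise import NoiseModel, generate_noise
from dba.simulate import SimulationConfig, d_t_for_rc, grow_patch, simulate_recording


@pytest.fixture(scope="module")
def single_grid_result(small_space, small_gain):
    grid = ExperimentGrid(structures=("hippocampus",), patch_sizes=(3.0,),
                          noise_seeds=(0, 1), seed_stride=8)
    return grid, run_grid(grid, small_space, small_gain)


def test_grid_validation():
    with pytest.raises(ValueError):
        ExperimentGrid(structures=())
    with pytest.raises(ValueError):
        ExperimentGrid(truth="midpoint")


def test_single_cell_matches_direct_pipeline(small_space, small_gain):
    """One grid cell reproduces a hand-assembled simulation + estimate."""
    seed_idx = int(small_space.indices("hippocampus")[0])
    grid = ExperimentGrid(structures=("hippocampus",), patch_sizes=(3.0,),
                          methods=("wmne",), noise_seeds=(0,),
                          seed_stride=10 ** 6)
    res = run_grid(grid, small_space, small_gain)
    assert len(res.results) == 1
    row = res.results.iloc[0]

    nm = NoiseModel(seed=0)
    cfg = SimulationConfig(snr_energy=20.0)
    noise = generate_noise(nm, small_gain.n_sensors, cfg.record_ms / 1000.0)
    cov = estimate_noise_cov(noise[:, :250])
    kernels = kernel_family(small_gain, cov)
    patch = grow_patch(small_space, seed_idx, 3.0)
    rec = simulate_recording(small_gain, [(patch, "subcortical")],
                             dataclasses.replace(cfg, d_t_ms=60.0), noise=noise)
    est = kernels["wmne"].apply(rec.data[:, rec.subcortical_peak_sample])
    truth = small_space.positions[seed_idx]
    assert row["dle_g_cm"] == pytest.approx(dle_g(est, small_space.positions, truth))
    assert row["dle_m_cm"] == pytest.approx(dle_m(est, small_space.positions, truth))


def test_grid_deterministic(single_grid_result, small_space, small_gain):
    grid, res = single_grid_result
    res2 = run_grid(grid, small_space, small_gain)
    assert res.results.equals(res2.results)
    assert res.manifest["config_hash"] == res2.manifest["config_hash"]


def test_histograms_normalized(single_grid_result):
    _, res = single_grid_result
    h = res.dle_histogram("hippocampus", "wmne")
    for _, sub in h.groupby("patch_size"):
        assert sub["mass"].sum() == pytest.approx(1.0)


def test_mean_by_source_averages_noise_seeds(single_grid_result):
    grid, res = single_grid_result
    m = res.mean_by_source()
    n_sources = res.results["seed_index"].nunique()
    assert len(m) == n_sources * len(grid.methods)


def test_checkpoint_resume_identical(tmp_path, small_space, small_gain):
    grid = ExperimentGrid(structures=("amygdala",), patch_sizes=(1.0,),
                          noise_seeds=(0,), seed_stride=5)
    direct = run_grid(grid, small_space, small_gain)
    ck = tmp_path / "ck.tsv"
    first = run_grid(grid, small_space, small_gain, checkpoint=ck)
    resumed = run_grid(grid, small_space, small_gain, checkpoint=ck)
    for col in ("dle_g_cm", "dle_m_cm"):
        assert np.allclose(np.sort(direct.results[col]), np.sort(first.results[col]))
        assert np.allclose(np.sort(direct.results[col]), np.sort(resumed.results[col]))


def test_noiseless_sloreta_point_subgrid_zero_dle(small_space, small_gain):
    """Point-source (tiny patch), noise-free estimation through the grid's
    classical sLORETA localizes exactly."""
    from dba.inverse import NoiseCovariance, sloreta_kernel, wmne_kernel
    cov = NoiseCovariance(np.eye(small_gain.n_sensors) * 1e-26, 100, 0.0)
    ks = sloreta_kernel(wmne_kernel(small_gain, cov, w=0.0), small_gain)
    for structure in ("hippocampus", "thalamus"):
        idx = small_space.indices(structure)[::7]
        est = np.abs(ks.matrix @ small_gain.values[:, idx])
        am = est.argmax(axis=0)
        d = [dle_m(est[:, k], small_space.positions, small_space.positions[i])
             for k, i in enumerate(idx)]
        assert max(d) == 0.0
        assert (am == idx).all()


@pytest.fixture(scope="module")
def two_source_result(small_space, small_gain):
    dts = tuple(d_t_for_rc(rc) for rc in (0.25, 0.5, 0.75, 1.0))
    grid = ExperimentGrid(structures=("hippocampus",), patch_sizes=(3.0,),
                          noise_seeds=(0, 1, 2), seed_stride=4,
                          with_cortical=True, d_t_values_ms=(60.0,) + dts,
                          sloreta_unweighted=False)
    return run_grid(grid, small_space, small_gain)


def test_detection_rate_non_increasing_for_wmne(two_source_result):
    curve = two_source_result.detection_curve("wmne")
    rates = curve["detection_rate"].to_numpy()
    assert (np.diff(rates) <= 1e-12).all()


def test_detection_at_zero_rc_matches_single_source(two_source_result, small_space, small_gain):
    curve = two_source_result.detection_curve("wmne")
    rate_rc0 = curve.iloc[0]["detection_rate"]
    grid1 = ExperimentGrid(structures=("hippocampus",), patch_sizes=(3.0,),
                           noise_seeds=(0, 1, 2), seed_stride=4,
                           d_t_values_ms=(60.0,), sloreta_unweighted=False)
    single = run_grid(grid1, small_space, small_gain)
    rate_single = single.results[single.results.method == "wmne"]["detected"].mean()
    assert rate_rc0 == pytest.approx(rate_single)


def test_thalamic_ghosts_stronger_for_sloreta(two_source_result):
    """Standardizing the depth-weighted kernel inflates deep estimates and
    creates spurious thalamic maxima more often than wMNE does."""
    rc50 = lambda df: float(df.loc[np.isclose(df["r_c"], 0.5), "ghost_rate"].iloc[0])
    assert rc50(two_source_result.ghost_rate("wmne")) < \
        rc50(two_source_result.ghost_rate("sloreta"))


def test_hippocampal_share_beats_thalamic_at_rc25(two_source_result):
    sub = two_source_result.results[np.isclose(two_source_result.results["r_c"], 0.25)]
    for method, rows in sub.groupby("method"):
        assert rows["prop_hippocampus"].mean() > rows["prop_thalamus"].mean(), method


def test_larger_patches_carry_larger_currents(small_space):
    """Total current grows with patch size (the driver records extent so the
    current/error paradox stays checkable downstream)."""
    seed = int(small_space.indices("hippocampus")[8])
    totals = [grow_patch(small_space, seed, s).total_current for s in (1.0, 3.0, 5.0)]
    assert totals[0] < totals[1] < totals[2]


def test_visual_seed_is_posterior_cortex(small_space):
    i = visual_cortex_seed(small_space)
    assert small_space.structure_of(i) == "cortex"
    assert small_space.positions[i][1] < 0  # posterior (-y) side
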