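import numpy as np
import pytest
from scipy import stats

import hes1rdme as h
from hes1rdme.model import MRNA, PF, PO, PROTEIN

from conftest import small_setup


def test_all_rates_zero_gives_constant_trajectory(small_mesh):
    params, system, jumps = small_setup(
        small_mesh, k1=0, k2=0, alpha_m=0, gamma=1, alpha_p=0, mu_m=0, mu_p=0, D=0
    )
    init = h.initial_state(small_mesh, seed=5)
    traj = h.simulate_nsm(system, jumps, init, t_end=50, record_dt=1.0, seed=5)
    assert np.all(traj.totals == init.totals())


def test_identical_seed_bitwise_reproducible(small_mesh):
    params, system, jumps = small_setup(small_mesh)
    init = h.initial_state(small_mesh, seed=9)
    a = h.simulate_nsm(system, jumps, init, 120, 1.0, seed=9)
    b = h.simulate_nsm(system, jumps, init, 120, 1.0, seed=9)
    c = h.simulate_nsm(system, jumps, init, 120, 1.0, seed=10)
    assert np.array_equal(a.totals, b.totals)
    assert not np.array_equal(a.totals, c.totals)


def test_promoter_conserved_at_every_sample(wt_trajectory):
    assert np.all(wt_trajectory.pf + wt_trajectory.po == 1)
    assert np.all(wt_trajectory.totals >= 0)
    assert np.all(np.diff(wt_trajectory.times) > 0)


def test_invalid_horizon_rejected(small_mesh):
    params, system, jumps = small_setup(small_mesh)
    init = h.initial_state(small_mesh, seed=1)
    with pytest.raises(ValueError):
        h.simulate_nsm(system, jumps, init, t_end=0, record_dt=1.0, seed=1)


def test_event_counts_poisson_dispersion(small_mesh):
    """A single first-order source channel fires as a Poisson process."""
    params, system, jumps = small_setup(
        small_mesh, k1=0, k2=0, gamma=1, alpha_p=0, mu_m=0, mu_p=0, D=0
    )
    counts = []
    init = h.initial_state(small_mesh, seed=0, n_protein=0, n_mrna=0)
    for i in range(120):
        traj = h.simulate_nsm(system, jumps, init, t_end=10, record_dt=10, seed=100 + i)
        counts.append(traj.mrna[-1])
    counts = np.asarray(counts, dtype=float)
    lam = 3.00 * 10
    assert counts.mean() == pytest.approx(lam, abs=4 * np.sqrt(lam / len(counts)))
    # index of dispersion ~ 1 for a Poisson count
    assert 0.6 < counts.var(ddof=1) / counts.mean() < 1.5


def test_pure_diffusion_reaches_uniform_occupancy():
    """All molecules start in one voxel; equilibrium is volume-proportional."""
    mesh = h.build_spherical_cell_mesh(cell_radius=1.8, nucleus_radius=0.9, voxel_edge=0.6)
    params, system, jumps = small_setup(
        mesh, k1=0, k2=0, alpha_m=0, gamma=1, alpha_p=0, mu_m=0, mu_p=0
    )
    n = 1000
    init = h.SystemState(np.zeros((mesh.n_voxels, 4), dtype=np.int64))
    init.counts[0, PROTEIN] = n
    traj = h.simulate_nsm(
        system, jumps, init, t_end=200, record_dt=200, seed=42, snapshot_times=[199.5]
    )
    occupancy = traj.snapshots[0][:, PROTEIN]
    assert occupancy.sum() == n
    expected = np.full(mesh.n_voxels, n / mesh.n_voxels)
    chi2 = ((occupancy - expected) ** 2 / expected).sum()
    assert chi2 < stats.chi2.ppf(0.99, mesh.n_voxels - 1)


def test_trajectory_csv_roundtrip(wt_trajectory, tmp_path):
    p = tmp_path / "traj.csv"
    wt_trajectory.to_csv(p)
    back = h.Trajectory.from_csv(p)
    assert np.array_equal(back.totals, wt_trajectory.totals)
    np.testing.assert_allclose(back.times, wt_trajectory.times)
    assert back.seed == wt_trajectory.seed
    assert back.params["alpha_m"] == 3.00


class TestWellMixedSSA:
    def test_unrepressed_mrna_is_birth_death_process(self):
        """k1=k2=0 with a free promoter: mRNA ~ birth-death, mean alpha_m/mu_m."""
        params = h.ParameterSet(k1=0, k2=0)
        means = []
        for i in range(4):
            traj = h.ssa_wellmixed(params, volume=1767.15, t_end=1200, seed=50 + i)
            sel = traj.times >= 600
            means.append(traj.mrna[sel].mean())
        # stationary mean 3.00/0.015 = 200; SE of a 600-min time average of
        # an OU-like count process (tau = 1/mu_m ~ 67 min, var ~ 200)
        se = np.sqrt(2 * 67 / 600 * 200 / len(means))
        assert np.mean(means) == pytest.approx(200.0, abs=3 * se)

    def test_exponential_mrna_decay(self):
        params = h.ParameterSet(k1=0, k2=0, alpha_m=0, gamma=1, alpha_p=0, mu_p=0)
        vals = []
        for i in range(60):
            traj = h.ssa_wellmixed(
                params, 1767.15, init_totals=(100, 0, 1, 0), t_end=100, record_dt=50, seed=i
            )
            vals.append(traj.mrna[-1])
        expected = 100 * np.exp(-0.015 * 100)
        p_surv = np.exp(-0.015 * 100)
        se = np.sqrt(100 * p_surv * (1 - p_surv) / 60)
        assert np.mean(vals) == pytest.approx(expected, abs=4 * se)

    def test_everything_off_stays_zero(self):
        params = h.ParameterSet(k1=0, k2=0, alpha_m=0, gamma=1, alpha_p=0)
        traj = h.ssa_wellmixed(params, 1767.15, init_totals=(0, 0, 1, 0), t_end=100, seed=1)
        assert not traj.mrna.any() and not traj.protein.any()


def test_fast_diffusion_approaches_wellmixed_means(small_mesh):
    """With D scaled x100, spatial totals match the well-mixed model."""
    params, system, jumps = small_setup(small_mesh, D=6.00e-11)
    vol = small_mesh.total_volume
    # mean-field correspondence: only the cytoplasmic mRNA fraction translates
    f_cyt = small_mesh.voxel_volumes[small_mesh.cytoplasm_mask].sum() / vol
    params_mf = params.with_overrides(alpha_p=params.alpha_p * f_cyt)
    nsm, ssa = [], []
    for i in range(25):
        init = h.initial_state(small_mesh, seed=200 + i)
        t = h.simulate_nsm(system, jumps, init, 200, 5.0, seed=200 + i)
        nsm.append(t.protein[-1])
        s = h.ssa_wellmixed(params_mf, vol, init_totals=(10, 60, 1, 0), t_end=200, seed=900 + i)
        ssa.append(s.protein[-1])
    assert stats.mannwhitneyu(nsm, ssa).pvalue > 0.01
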