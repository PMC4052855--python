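"""Structure factors, Bragg/diffuse decompositions (analytic vs Monte-Carlo),
dynamic disorder gating and peak/background separation."""

import numpy as np
import pytest

from flashxtal import diffraction as Df
from flashxtal.dosimetry import PulseSpec
from flashxtal.motion import MotionModel, displacement_trajectory


class _StepMotion:
    """σ jumps from 0 to ∞ at t_off: the ideal gate."""

    def __init__(self, t_off):
        self.t_off = t_off

    def sigma_at(self, t):
        return np.where(np.asarray(t) < self.t_off, 0.0, 1e6)


class TestScatteringFactor:
    def test_neutral_carbon_forward(self):
        assert Df.scattering_factor("C", 0.0) == pytest.approx(6.0, rel=1e-3)

    def test_half_stripped(self):
        assert Df.scattering_factor("C", 0.0, bound_fraction=0.5) == \
            pytest.approx(3.0, rel=1e-3)

    def test_monotone_decreasing(self):
        q = np.linspace(0.0, 1.0, 40)
        f = Df.scattering_factor("C", q)
        assert np.all(np.diff(f) < 0)

    def test_unknown_element(self):
        with pytest.raises(KeyError):
            Df.scattering_factor("Zz", 0.1)


class TestStructureFactor:
    def test_single_atom_at_origin(self):
        q = np.array([0.3, 0.1, 0.0])
        f = Df.scattering_factor("C", np.linalg.norm(q))
        F = Df.structure_factor(np.zeros((1, 3)), [f], q)
        assert F == pytest.approx(f)

    @pytest.mark.parametrize("qd", [0.2, 0.5, 0.8, 1.3])
    def test_two_atom_interference(self, qd):
        d = 4.0
        q = np.array([qd / d, 0.0, 0.0])
        pos = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        F = Df.structure_factor(pos, [1.0, 1.0], q)
        assert abs(F) == pytest.approx(2 * abs(np.cos(np.pi * qd)), abs=1e-10)

    def test_lattice_sum_at_bragg_node(self, fig7):
        crystal = fig7[0]
        pos, els, occ = crystal.atom_positions()
        motif_pos = pos[: len(crystal.motif)]
        q = np.array([2 / 25.0, 1 / 25.0, 0.0])
        f = Df.scattering_factor("C", np.linalg.norm(q))
        F_cell = Df.structure_factor(motif_pos, f, q)
        F_crys = Df.structure_factor(pos, f, q)
        assert abs(F_crys) == pytest.approx(125 * abs(F_cell), rel=1e-9)


class TestIonizationMixtureOracle:
    @pytest.mark.parametrize("x,df_frac", [(0.25, 1.0), (0.5, 0.5), (0.8, 1.0)])
    def test_against_brute_force(self, x, df_frac):
        """Eq-level oracle: mean |F|² over seeded random ionization
        assignments must match f̄²·|L|² + n·x(1−x)·Δf² within 3 SE."""
        rng = np.random.default_rng(42)
        n = 1000
        pos = rng.uniform(0.0, 60.0, size=(n, 3))
        q = np.array([0.21, 0.07, 0.0])
        f0, df = 6.0, 6.0 * df_frac
        phases = np.exp(2j * np.pi * pos @ q)
        lattice_sum_sq = abs(phases.sum()) ** 2
        n_draws = 2000
        samples = np.empty(n_draws)
        for k in range(n_draws):
            ion = rng.random(n) < x
            f = np.where(ion, f0 - df, f0)
            samples[k] = abs((f * phases).sum()) ** 2
        mc, se = samples.mean(), samples.std(ddof=1) / np.sqrt(n_draws)
        bragg, diffuse = Df.ionization_mixture_decomposition(n, x, f0, df, lattice_sum_sq)
        assert abs(bragg + diffuse - mc) < 3 * se

    def test_limits(self):
        bragg0, diff0 = Df.ionization_mixture_decomposition(100, 0.0, 6.0, 3.0, 400.0)
        assert diff0 == 0.0 and bragg0 == pytest.approx(36.0 * 400.0)
        bragg1, diff1 = Df.ionization_mixture_decomposition(100, 1.0, 6.0, 3.0, 400.0)
        assert diff1 == 0.0 and bragg1 == pytest.approx(9.0 * 400.0)


class TestDebyeWallerOracle:
    @pytest.mark.parametrize("q,sigma", [(0.3, 0.3), (0.5, 0.25), (0.15, 0.8)])
    def test_against_brute_force(self, q, sigma):
        """Gaussian-displacement ensembles: mean |F|² vs the analytic
        Bragg·DW + diffuse split, within 3 SE."""
        rng = np.random.default_rng(7)
        n = 200
        pos = rng.uniform(0.0, 40.0, size=(n, 3))
        qvec = np.array([q, 0.0, 0.0])
        f = 4.0
        f0_sq = abs(f * np.exp(2j * np.pi * pos @ qvec).sum()) ** 2
        n_draws = 5000
        phases0 = pos @ qvec
        disp = rng.normal(0.0, sigma, size=(n_draws, n))  # only q̂-component matters
        F = (f * np.exp(2j * np.pi * (phases0[None, :] + q * disp))).sum(axis=1)
        samples = np.abs(F) ** 2
        mc, se = samples.mean(), samples.std(ddof=1) / np.sqrt(n_draws)
        bragg, diffuse = Df.debye_waller_decomposition(q, sigma, f0_sq, n, f)
        assert abs(bragg + diffuse - mc) < 3 * se

    def test_limits(self):
        bragg, diffuse = Df.debye_waller_decomposition(0.4, 0.0, 123.0, 10, 2.0)
        assert (bragg, diffuse) == (123.0, 0.0)
        bragg, diffuse = Df.debye_waller_decomposition(0.0, 5.0, 123.0, 10, 2.0)
        assert (bragg, diffuse) == (123.0, 0.0)
        # σ → ∞: everything diffuse, total n·f²
        bragg, diffuse = Df.debye_waller_decomposition(0.5, 1e3, 123.0, 10, 2.0)
        assert bragg == pytest.approx(0.0, abs=1e-200)
        assert diffuse == pytest.approx(10 * 4.0)


class TestSnapshot:
    def test_undamaged_peaks_sharp(self, fig7):
        crystal, pulse = fig7[0], fig7[1]
        grid = Df.QGrid.planar(0.25, 91, pulse.wavelength_A)
        pat = Df.snapshot_intensity(crystal, grid, pulse)
        img = pat.intensity.reshape(91, 91)
        # N⁶ lattice-sum peaks dominate the typical inter-node level
        assert img.max() / np.median(img) > 1e3

    def test_displacement_suppresses_high_q(self, small_crystal, pulse_6kev):
        nodes = np.array([[h / 25.0, 0.0, 0.0] for h in (1, 7)])
        grid = Df.QGrid(q=nodes, d_omega=1e-8, wavelength=pulse_6kev.wavelength_A)
        clean = Df.snapshot_intensity(small_crystal, grid, pulse_6kev)
        damaged = Df.snapshot_intensity(small_crystal, grid, pulse_6kev,
                                        Df.DisorderState(sigma=1.0))
        ratios = damaged.bragg / clean.bragg
        assert ratios[1] < 0.1 * ratios[0]

    def test_zero_solid_angle(self, small_crystal, pulse_6kev):
        grid = Df.QGrid(q=np.array([[0.1, 0.0, 0.0]]), d_omega=0.0,
                        wavelength=pulse_6kev.wavelength_A)
        pat = Df.snapshot_intensity(small_crystal, grid, pulse_6kev, seed=1)
        assert pat.intensity[0] == 0.0 and pat.mc_total[0] == 0.0

    def test_seeded_realization_reproducible(self, small_crystal, pulse_6kev):
        grid = Df.QGrid(q=np.array([[0.2, 0.04, 0.0]]), d_omega=1e-8,
                        wavelength=pulse_6kev.wavelength_A)
        state = Df.DisorderState(sigma=0.5, x=0.3)
        a = Df.snapshot_intensity(small_crystal, grid, pulse_6kev, state, seed=9)
        b = Df.snapshot_intensity(small_crystal, grid, pulse_6kev, state, seed=9)
        assert np.array_equal(a.mc_total, b.mc_total)


class TestPulseIntegrated:
    def test_zero_damage_equals_undamaged(self, small_crystal, pulse_6kev):
        grid = Df.QGrid.planar(0.2, 41, pulse_6kev.wavelength_A)
        snap = Df.snapshot_intensity(small_crystal, grid, pulse_6kev)
        integ = Df.pulse_integrated_pattern(small_crystal, grid, pulse_6kev,
                                            motion=None, ionization=None, n_steps=4)
        assert np.allclose(integ.intensity, snap.intensity, rtol=1e-10)

    def test_integrated_retains_high_q_peaks(self, fig7):
        crystal, pulse, disp, ion = fig7
        nodes = np.array([[h / 25.0, 0.0, 0.0] for h in (6, 7, 8)])
        grid = Df.QGrid(q=nodes, d_omega=1e-8, wavelength=pulse.wavelength_A)
        final = Df.snapshot_intensity(crystal, grid, pulse,
                                      Df.DisorderState(sigma=1.0))
        integ = Df.pulse_integrated_pattern(crystal, grid, pulse, disp, ion,
                                            n_steps=32)
        assert np.all(integ.bragg > final.bragg)

    def test_mc_matches_analytic(self, small_crystal, pulse_6kev):
        """Node-wise MC mean within 3 standard errors of Bragg + diffuse."""
        disp = displacement_trajectory(50e6, 50.0)
        nodes = np.array([
            [1 / 25.0, 0.0, 0.0], [4 / 25.0, 0.0, 0.0], [6 / 25.0, 2 / 25.0, 0.0],
            [0.13, 0.05, 0.0], [0.22, 0.0, 0.0],
        ])
        grid = Df.QGrid(q=nodes, d_omega=1e-8, wavelength=pulse_6kev.wavelength_A)
        pat = Df.pulse_integrated_pattern(small_crystal, grid, pulse_6kev, disp,
                                          None, n_steps=12, n_realizations=150,
                                          seed=2)
        z = (pat.mc_total - pat.intensity) / pat.mc_stderr
        assert np.all(np.abs(z) < 3.0)

    def test_bad_steps(self, small_crystal, pulse_6kev):
        grid = Df.QGrid(q=np.array([[0.1, 0.0, 0.0]]), d_omega=1e-8,
                        wavelength=pulse_6kev.wavelength_A)
        with pytest.raises(ValueError):
            Df.pulse_integrated_pattern(small_crystal, grid, pulse_6kev,
                                        None, None, n_steps=1)


class TestDynamicDisorder:
    def test_no_damage_is_one(self):
        assert Df.dynamic_disorder_g(0.5, 50.0, None, None) == 1.0

    def test_bounded_and_monotone_in_q(self, fig7):
        _, _, disp, ion = fig7
        qs = np.linspace(0.0, 1.0, 21)
        gs = np.array([Df.dynamic_disorder_g(q, 50.0, disp, ion) for q in qs])
        assert np.all((0.0 <= gs) & (gs <= 1.0))
        assert np.all(np.diff(gs) <= 0)
        assert gs[0] < 1.0  # ionization alone gates even at q=0

    def test_monotone_in_duration(self):
        disp = displacement_trajectory(1e9, 200.0)
        gs = [Df.dynamic_disorder_g(0.5, T, disp, None) for T in (10.0, 50.0, 200.0)]
        assert gs[0] > gs[1] > gs[2]

    def test_step_gate_limit(self):
        """With σ stepping 0→∞ at t_off and no ionization, g is exactly the
        contributing pulse fraction t_off/T."""
        T, t_off = 50.0, 20.0
        g = Df.dynamic_disorder_g(0.5, T, _StepMotion(t_off), None, n_steps=5001)
        assert g == pytest.approx(t_off / T, abs=1e-3)


@pytest.fixture(scope="module")
def damaged_pattern(small_crystal, fig7):
    _, pulse, disp, ion = fig7
    grid = Df.QGrid.planar(0.3, 226, pulse.wavelength_A)
    integ = Df.pulse_integrated_pattern(small_crystal, grid, pulse, disp, ion,
                                        n_steps=32)
    snap0 = Df.snapshot_intensity(small_crystal, grid, pulse)
    return grid, integ, snap0


class TestSeparation:
    def test_undamaged_diffuse_small(self, damaged_pattern, small_crystal):
        """With no damage the background map holds only shape-transform side
        lobes of the 27-cell crystal — well below the peaks, and negligible
        in the typical (median) inter-peak region."""
        _, _, snap0 = damaged_pattern
        _, diffuse_map = Df.separate_bragg_diffuse(snap0, small_crystal)
        peak_max = snap0.intensity.max()
        assert diffuse_map.max() <= 0.15 * peak_max
        assert np.median(diffuse_map) <= 1e-3 * peak_max

    def test_pure_diffuse_input_gives_no_peaks(self, small_crystal, pulse_6kev):
        """A structureless (flat) intensity map must yield ~zero net Bragg
        counts after background subtraction."""
        grid = Df.QGrid.planar(0.3, 226, pulse_6kev.wavelength_A)
        flat = Df.DiffractionPattern(grid=grid,
                                     bragg=np.zeros(grid.q.shape[0]),
                                     diffuse=np.full(grid.q.shape[0], 3.14))
        peaks, _ = Df.separate_bragg_diffuse(flat, small_crystal)
        assert max(abs(v) for v in peaks.values()) < 1e-9

    def test_recovers_gated_bragg(self, damaged_pattern, small_crystal, fig7):
        """Background-subtracted peak counts close the loop with g·|F₀|²."""
        _, _, disp, ion = fig7
        _, integ, snap0 = damaged_pattern
        peaks, _ = Df.separate_bragg_diffuse(integ, small_crystal)
        undamaged, _ = Df.separate_bragg_diffuse(snap0, small_crystal)
        strongest = max(undamaged.values())
        checked = 0
        for (h, k), raw in undamaged.items():
            if raw < 1e-2 * strongest:
                continue
            q = np.hypot(h / 25.0, k / 25.0)
            g = Df.dynamic_disorder_g(q, 50.0, disp, ion)
            assert peaks[(h, k)] == pytest.approx(g * raw, rel=0.05)
            checked += 1
        assert checked >= 10

    def test_coarse_grid_rejected(self, small_crystal, pulse_6kev):
        grid = Df.QGrid.planar(0.3, 41, pulse_6kev.wavelength_A)
        pat = Df.snapshot_intensity(small_crystal, grid, pulse_6kev)
        with pytest.raises(ValueError, match="coarse"):
            Df.separate_bragg_diffuse(pat, small_crystal)


class TestShapeTransform:
    def test_bragg_to_diffuse_ratio(self):
        assert Df.bragg_to_diffuse_ratio(1) == 1.0
        assert Df.bragg_to_diffuse_ratio(10) == pytest.approx(
            Df.bragg_to_diffuse_ratio(5) / 4)

    @pytest.mark.parametrize("n_side", [3, 5, 10])
    def test_peak_width_scales_inverse_n(self, n_side, fig7):
        """FWHM of the lattice-sum peak along one axis scales as 1/N."""
        crystal = Df.ToyCrystal(cell=(25.0, 25.0, 25.0), motif=fig7[0].motif[:1],
                                n_cells=(n_side, 1, 1))
        pos, _, _ = crystal.atom_positions()
        dq = np.linspace(-0.02, 0.02, 2001)
        q = np.stack([1 / 25.0 + dq, np.zeros_like(dq), np.zeros_like(dq)], axis=1)
        F = Df.structure_factor(pos, np.ones(pos.shape[0]), q)
        prof = np.abs(F) ** 2
        half = prof.max() / 2
        fwhm = dq[prof >= half][-1] - dq[prof >= half][0]
        assert fwhm == pytest.approx(0.886 / (n_side * 25.0), rel=0.05)


class TestFixture:
    def test_construction(self, fig7):
        crystal, pulse, disp, ion = fig7
        assert crystal.n_atoms == 1000
        assert crystal.cell == (25.0, 25.0, 25.0)
        assert disp.sigma_at(pulse.duration_fs) == pytest.approx(1.0, rel=1e-12)

    def test_deterministic(self, fig7):
        again = Df.build_fig7_fixture()[0]
        assert again.motif == fig7[0].motif

    def test_pdb_motif_roundtrip(self, tmp_path, fig7):
        from click.testing import CliRunner
        from flashxtal.cli import main
        res = CliRunner().invoke(main, ["fixtures", "--out-dir", str(tmp_path)])
        assert res.exit_code == 0, res.output
        sites = Df.read_motif_pdb(tmp_path / "toy_crystal_motif.pdb")
        ref = np.array([s.position for s in fig7[0].motif]) * 25.0
        got = np.array([s.position for s in sites])
        assert np.allclose(got, ref, atol=2e-3)
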