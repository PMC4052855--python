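"""Diffraction of small crystals under evolving ionization and displacement.

The measured pattern is I(q) = I₀·r_e²·ΔΩ·|F(q)|² with
F(q) = Σᵢ fᵢ(q)·exp(2πi q·xᵢ) and |q| = 2 sinθ/λ (= 1/d).  Ensemble
averaging over random, independent per-atom disorder splits the expected
intensity into a Bragg part (the average structure) and a diffuse part (the
variance), computed here both analytically and by seeded Monte-Carlo
realizations so the two can be checked against each other:

* random ionization of a fraction x with scattering-factor change Δf —
  Bragg carries f̄ = f₀ − xΔf, diffuse adds n·x(1−x)·Δf² with no q
  dependence beyond the f(q) envelope;
* Gaussian displacements of per-axis RMS σ — the Debye–Waller factor
  exp(−4π²q²σ²) gates the Bragg term and routes the loss into diffuse;
* over a pulse, the Bragg counts are modulated by the dynamic disorder
  function g(q,T) = (1/T)∫ w(t)²·exp(−4π²q²σ(t)²) dt.

Ionized atoms scatter in proportion to their remaining bound electrons
(a low-q approximation; the shape change of the hollow-atom form factor
matters only beyond ~1.7 Å resolution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .constants import R_E_CM, UM2_TO_CM2, wavelength_A
from .dosimetry import PulseSpec
from .ionization import IonizationTrajectory
from .motion import DisplacementTrajectory

__all__ = [
    "AtomSite",
    "ToyCrystal",
    "QGrid",
    "DisorderState",
    "DiffractionPattern",
    "scattering_factor",
    "structure_factor",
    "snapshot_intensity",
    "pulse_integrated_pattern",
    "ionization_mixture_decomposition",
    "debye_waller_decomposition",
    "dynamic_disorder_g",
    "bragg_to_diffuse_ratio",
    "separate_bragg_diffuse",
    "build_fig7_fixture",
    "read_motif_pdb",
]


@dataclass(frozen=True)
class AtomSite:
    """One atom: Cartesian (or fractional, per the crystal flag) position in Å."""

    position: tuple[float, float, float]
    element: str = "C"
    occupancy: float = 1.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")


@dataclass(frozen=True)
class ToyCrystal:
    """Orthorhombic toy crystal: a repeated motif on an N₁×N₂×N₃ lattice."""

    cell: tuple[float, float, float]
    motif: tuple[AtomSite, ...]
    n_cells: tuple[int, int, int] = (1, 1, 1)
    fractional: bool = True

    def __post_init__(self):
        if any(c <= 0 for c in self.cell):
            raise ValueError("cell lengths must be positive")
        if any(n < 1 for n in self.n_cells):
            raise ValueError("n_cells must be ≥ 1")
        object.__setattr__(self, "motif", tuple(self.motif))

    @property
    def n_atoms(self) -> int:
        return len(self.motif) * int(np.prod(self.n_cells))

    def atom_positions(self) -> tuple[np.ndarray, list[str], np.ndarray]:
        """All atom positions (n,3) in Å plus per-atom elements/occupancies."""
        cell = np.asarray(self.cell)
        motif_xyz = np.array([s.position for s in self.motif], dtype=float)
        if self.fractional:
            motif_xyz = motif_xyz * cell
        n1, n2, n3 = self.n_cells
        shifts = np.array(
            [(i, j, k) for i in range(n1) for j in range(n2) for k in range(n3)],
            dtype=float,
        ) * cell
        pos = (shifts[:, None, :] + motif_xyz[None, :, :]).reshape(-1, 3)
        elements = [s.element for s in self.motif] * len(shifts)
        occ = np.tile([s.occupancy for s in self.motif], len(shifts))
        return pos, elements, occ


@dataclass(frozen=True)
class QGrid:
    """Scattering vectors (Å⁻¹, convention |q| = 2 sinθ/λ = 1/d) with the
    per-node detector solid angle and the probing wavelength."""

    q: np.ndarray                      # (M, 3)
    d_omega: float                     # sr per node
    wavelength: float                  # Å
    shape: tuple[int, int] | None = None   # set for planar grids
    plane_axes: tuple[int, int] = (0, 1)

    def __post_init__(self):
        q = np.atleast_2d(np.asarray(self.q, dtype=float))
        object.__setattr__(self, "q", q)
        if self.d_omega < 0:
            raise ValueError("solid angle must be non-negative")
        qmag = np.linalg.norm(q, axis=1)
        if np.any(qmag > 2.0 / self.wavelength + 1e-12):
            raise ValueError("grid contains Ewald-inaccessible |q| > 2/λ")

    @property
    def qmag(self) -> np.ndarray:
        return np.linalg.norm(self.q, axis=1)

    @classmethod
    def planar(cls, qmax: float, n: int, wavelength: float,
               d_omega: float = 1e-8, plane_axes: tuple[int, int] = (0, 1)) -> "QGrid":
        """Square planar section through the origin of reciprocal space."""
        ax = np.linspace(-qmax, qmax, n)
        g1, g2 = np.meshgrid(ax, ax, indexing="ij")
        q = np.zeros((n * n, 3))
        q[:, plane_axes[0]] = g1.ravel()
        q[:, plane_axes[1]] = g2.ravel()
        return cls(q=q, d_omega=d_omega, wavelength=wavelength,
                   shape=(n, n), plane_axes=plane_axes)

    @property
    def axis(self) -> np.ndarray:
        if self.shape is None:
            raise ValueError("not a planar grid")
        n = self.shape[0]
        qmax = np.max(np.abs(self.q))
        return np.linspace(-qmax, qmax, n)

    @classmethod
    def volume(cls, q_lo: float, q_hi: float, n: int, wavelength: float,
               d_omega: float = 1e-8) -> "QGrid":
        """Uniform 3D box grid [q_lo, q_hi)³ — representative sampling of
        reciprocal space (endpoint excluded so sums over whole reciprocal
        cells are unbiased)."""
        ax = np.linspace(q_lo, q_hi, n, endpoint=False)
        g = np.meshgrid(ax, ax, ax, indexing="ij")
        q = np.stack([a.ravel() for a in g], axis=1)
        return cls(q=q, d_omega=d_omega, wavelength=wavelength)


@dataclass(frozen=True)
class DisorderState:
    """Instantaneous disorder: per-axis RMS displacement σ (Å), ionized
    fraction x, and the ionized-atom scattering deficit Δf as a fraction of
    the neutral f (1.0 = fully stripped)."""

    sigma: float = 0.0
    x: float = 0.0
    delta_f_frac: float = 1.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0.0 <= self.x <= 1.0:
            raise ValueError("ionized fraction must be in [0, 1]")
        if not 0.0 <= self.delta_f_frac <= 1.0:
            raise ValueError("delta_f_frac must be in [0, 1]")


@dataclass
class DiffractionPattern:
    """Expected intensities (photons per node) split into Bragg and diffuse.

    ``intensity`` is always ``bragg + diffuse``; seeded Monte-Carlo output,
    when requested, lives in ``mc_total``/``mc_stderr``.
    """

    grid: QGrid
    bragg: np.ndarray
    diffuse: np.ndarray
    mc_total: np.ndarray | None = None
    mc_stderr: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def intensity(self) -> np.ndarray:
        return self.bragg + self.diffuse


def scattering_factor(element: str, q: np.ndarray | float,
                      bound_fraction: float = 1.0) -> np.ndarray | float:
    """Atomic scattering factor (electrons) at |q| = 1/d, scaled by the
    remaining bound-electron fraction."""
    if not 0.0 <= bound_fraction <= 1.0:
        raise ValueError("bound_fraction must be in [0, 1]")
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise KeyError(f"unknown element {element!r}")
    it92 = el.it92
    qa = np.asarray(q, dtype=float)
    if np.any(qa < 0):
        raise ValueError("q must be non-negative")
    stol2 = (qa / 2.0) ** 2
    f = np.vectorize(it92.calculate_sf)(stol2) * bound_fraction
    return float(f) if np.isscalar(q) else f


def structure_factor(positions: np.ndarray, f_values: np.ndarray,
                     q: np.ndarray) -> complex | np.ndarray:
    """F(q) = Σᵢ fᵢ·exp(2πi q·xᵢ); q one 3-vector or (M,3)."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    f = np.broadcast_to(np.asarray(f_values, dtype=float), (pos.shape[0],))
    qa = np.asarray(q, dtype=float)
    single = qa.ndim == 1
    qa = np.atleast_2d(qa)
    out = np.empty(qa.shape[0], dtype=complex)
    chunk = max(1, int(4e6 // max(pos.shape[0], 1)))
    for i in range(0, qa.shape[0], chunk):
        phases = np.exp(2j * np.pi * (qa[i:i + chunk] @ pos.T))
        out[i:i + chunk] = phases @ f
    return out[0] if single else out


def _prefactor(pulse: PulseSpec, d_omega: float) -> float:
    """Expected photons per node per unit |F|²."""
    photons_per_cm2 = pulse.photons_per_um2 / UM2_TO_CM2
    return photons_per_cm2 * R_E_CM**2 * d_omega


def _per_atom_f(grid: QGrid, elements: list[str], occ: np.ndarray) -> np.ndarray:
    """(M, n) scattering factors per q-node per atom (neutral)."""
    qmag = grid.qmag
    uniq = sorted(set(elements))
    f_by_el = {el: scattering_factor(el, qmag) for el in uniq}
    f = np.stack([f_by_el[el] for el in elements], axis=1)
    return f * occ[None, :]


def ionization_mixture_decomposition(n: int, x: float, f0, delta_f,
                                     lattice_sum_sq) -> tuple:
    """Bragg/diffuse split for a binary randomly-ionized population.

    Bragg uses the average factor f̄ = f₀ − x·Δf on the coherent lattice sum;
    the diffuse level is n·x(1−x)·Δf², flat in q apart from the Δf(q) envelope.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must be in [0, 1]")
    f0 = np.asarray(f0, dtype=float)
    delta_f = np.asarray(delta_f, dtype=float)
    fbar = f0 - x * delta_f
    bragg = fbar**2 * np.asarray(lattice_sum_sq, dtype=float)
    diffuse = n * x * (1.0 - x) * delta_f**2
    return bragg, np.broadcast_to(diffuse, bragg.shape).copy()


def debye_waller_decomposition(q, sigma: float, f0_sq, n: int, f) -> tuple:
    """Bragg/diffuse split for isotropic Gaussian displacements.

    Bragg = |F₀|²·exp(−4π²q²σ²); diffuse = n·f²·(1 − exp(−4π²q²σ²)): intensity
    lost from the lattice sum reappears as single-atom diffuse scattering.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    q = np.asarray(q, dtype=float)
    dw = np.exp(-4.0 * np.pi**2 * q**2 * sigma**2)
    bragg = np.asarray(f0_sq, dtype=float) * dw
    diffuse = n * np.asarray(f, dtype=float) ** 2 * (1.0 - dw)
    return bragg, diffuse


def _coherent_f0sq(grid: QGrid, pos: np.ndarray, f_atoms: np.ndarray) -> np.ndarray:
    """|F₀(q)|² of the undamaged structure on the grid."""
    out = np.empty(grid.q.shape[0])
    chunk = max(1, int(4e6 // max(pos.shape[0], 1)))
    for i in range(0, grid.q.shape[0], chunk):
        phases = np.exp(2j * np.pi * (grid.q[i:i + chunk] @ pos.T))
        out[i:i + chunk] = np.abs(np.sum(phases * f_atoms[i:i + chunk], axis=1)) ** 2
    return out


def _expected_components(grid: QGrid, f_atoms: np.ndarray, f0sq: np.ndarray,
                         state: DisorderState) -> tuple[np.ndarray, np.ndarray]:
    """Expected (bragg, diffuse) |F|² components for one disorder state.

    The ionized fraction is uniform across atoms, so the coherent term is
    the undamaged |F₀|² scaled by the mean-factor and Debye–Waller weights;
    the incoherent (diffuse) term is the per-atom variance Σ(⟨f²⟩ − f̄²D²).
    """
    qmag = grid.qmag
    dw_int = np.exp(-4.0 * np.pi**2 * qmag**2 * state.sigma**2)
    mean_scale = 1.0 - state.x * state.delta_f_frac
    bragg = f0sq * mean_scale**2 * dw_int
    msq_scale = (1.0 - state.x) + state.x * (1.0 - state.delta_f_frac) ** 2
    sum_f2 = np.sum(f_atoms**2, axis=1)
    diffuse = sum_f2 * msq_scale - sum_f2 * mean_scale**2 * dw_int
    return bragg, diffuse


def _mc_realization(grid: QGrid, pos: np.ndarray, f_atoms: np.ndarray,
                    state: DisorderState, rng: np.random.Generator) -> np.ndarray:
    """|F|² for one random draw of displacements and ionization states."""
    n = pos.shape[0]
    disp = rng.normal(0.0, state.sigma, size=(n, 3)) if state.sigma > 0 else 0.0
    ionized = rng.random(n) < state.x
    scale = np.where(ionized, 1.0 - state.delta_f_frac, 1.0)
    p = pos + disp
    out = np.empty(grid.q.shape[0])
    chunk = max(1, int(4e6 // max(n, 1)))
    for i in range(0, grid.q.shape[0], chunk):
        phases = np.exp(2j * np.pi * (grid.q[i:i + chunk] @ p.T))
        out[i:i + chunk] = np.abs(
            np.sum(phases * (f_atoms[i:i + chunk] * scale[None, :]), axis=1)
        ) ** 2
    return out


def snapshot_intensity(crystal: ToyCrystal, grid: QGrid, pulse: PulseSpec,
                       state: DisorderState | None = None,
                       seed: int | None = None) -> DiffractionPattern:
    """Instantaneous pattern under a fixed disorder state.

    ``bragg``/``diffuse`` are the analytic expectations; with a seed, one
    Monte-Carlo realization is drawn into ``mc_total`` (bit-reproducible).
    """
    state = state or DisorderState()
    pos, elements, occ = crystal.atom_positions()
    f_atoms = _per_atom_f(grid, elements, occ)
    pref = _prefactor(pulse, grid.d_omega)
    f0sq = _coherent_f0sq(grid, pos, f_atoms)
    bragg, diffuse = _expected_components(grid, f_atoms, f0sq, state)
    mc = None
    if seed is not None:
        rng = np.random.default_rng(seed)
        mc = pref * _mc_realization(grid, pos, f_atoms, state, rng)
    return DiffractionPattern(
        grid=grid, bragg=pref * bragg, diffuse=pref * diffuse, mc_total=mc,
        meta={"kind": "snapshot", "sigma": state.sigma, "x": state.x, "seed": seed},
    )


def pulse_integrated_pattern(crystal: ToyCrystal, grid: QGrid, pulse: PulseSpec,
                             motion: DisplacementTrajectory | None,
                             ionization: IonizationTrajectory | None,
                             n_steps: int = 32, n_realizations: int = 0,
                             seed: int = 0) -> DiffractionPattern:
    """Time-average of snapshot patterns over the (flat-top) pulse.

    Disorder at each midpoint time t: σ(t) from the displacement trajectory
    and a binary neutral/stripped ionization mixture with x(t) = 1 − w(t), so
    the mean scattering factor is f₀·w(t) and the Bragg term reproduces the
    dynamic disorder function g(q,T).  Displacements and ionization states
    are drawn independently per time step and realization.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be ≥ 2")
    T = pulse.duration_fs
    t_mid = (np.arange(n_steps) + 0.5) * T / n_steps
    pos, elements, occ = crystal.atom_positions()
    f_atoms = _per_atom_f(grid, elements, occ)
    pref = _prefactor(pulse, grid.d_omega)

    states = []
    for t in t_mid:
        sigma = float(motion.sigma_at(t)) if motion is not None else 0.0
        w = float(ionization.w_at(t)) if ionization is not None else 1.0
        states.append(DisorderState(sigma=sigma, x=1.0 - w, delta_f_frac=1.0))

    f0sq = _coherent_f0sq(grid, pos, f_atoms)
    bragg = np.zeros(grid.q.shape[0])
    diffuse = np.zeros(grid.q.shape[0])
    for st in states:
        b, d = _expected_components(grid, f_atoms, f0sq, st)
        bragg += b / n_steps
        diffuse += d / n_steps

    mc_mean = mc_err = None
    if n_realizations > 0:
        seeds = np.random.SeedSequence(seed).spawn(n_realizations)
        samples = np.empty((n_realizations, grid.q.shape[0]))
        for r, ss in enumerate(seeds):
            rng = np.random.default_rng(ss)
            acc = np.zeros(grid.q.shape[0])
            for st in states:
                acc += _mc_realization(grid, pos, f_atoms, st, rng)
            samples[r] = acc / n_steps
        mc_mean = pref * samples.mean(axis=0)
        mc_err = pref * samples.std(axis=0, ddof=1) / np.sqrt(n_realizations)

    return DiffractionPattern(
        grid=grid, bragg=pref * bragg, diffuse=pref * diffuse,
        mc_total=mc_mean, mc_stderr=mc_err,
        meta={"kind": "pulse_integrated", "n_steps": n_steps,
              "n_realizations": n_realizations, "seed": seed,
              "duration_fs": T},
    )


def dynamic_disorder_g(q: float, duration_fs: float,
                       motion: DisplacementTrajectory | None,
                       ionization: IonizationTrajectory | None,
                       n_steps: int = 512) -> float:
    """g(q,T) = (1/T)∫₀ᵀ w(t)²·exp(−4π²q²σ(t)²) dt ∈ [0, 1].

    The pulse fraction effectively contributing to Bragg diffraction at
    scattering vector q, gated by displacement and by ionization.
    """
    if q < 0 or duration_fs <= 0:
        raise ValueError("q must be ≥ 0 and duration > 0")
    t = np.linspace(0.0, duration_fs, n_steps)
    sigma = motion.sigma_at(t) if motion is not None else np.zeros_like(t)
    w = ionization.w_at(t) if ionization is not None else np.ones_like(t)
    integrand = w**2 * np.exp(-4.0 * np.pi**2 * q**2 * sigma**2)
    return float(np.trapezoid(integrand, t) / duration_fs)


def bragg_to_diffuse_ratio(n_cells_wide: int) -> float:
    """Area ratio of a Bragg peak to the reciprocal unit cell: 1/N²."""
    if n_cells_wide < 1:
        raise ValueError("N must be ≥ 1")
    return 1.0 / n_cells_wide**2


def separate_bragg_diffuse(pattern: DiffractionPattern, crystal: ToyCrystal,
                           use_mc: bool = False) -> tuple[dict, np.ndarray]:
    """Background-subtract Bragg peaks from a planar pattern.

    Integrates counts in a box of half-width 1/(N·a) around each predicted
    reciprocal-lattice node, subtracting the median of a surrounding annulus;
    returns ({(h, k): net counts}, diffuse map with peak boxes filled by the
    local background).  Requires ≥ 5 grid nodes per 1/(N·a) peak period.
    """
    grid = pattern.grid
    if grid.shape is None:
        raise ValueError("separation requires a planar grid")
    n = grid.shape[0]
    axis = grid.axis
    dq = axis[1] - axis[0]
    ia, ib = grid.plane_axes
    cell = (crystal.cell[ia], crystal.cell[ib])
    n_wide = (crystal.n_cells[ia], crystal.n_cells[ib])
    peak_width = 1.0 / (min(n_wide) * max(cell))
    if peak_width / dq < 5.0:
        raise ValueError(
            f"grid spacing {dq:.2e} too coarse to resolve peak width {peak_width:.2e}; "
            "need ≥ 5 nodes per 1/(N·a)"
        )
    img = (pattern.mc_total if use_mc else pattern.intensity).reshape(n, n)
    diffuse_map = img.copy()
    half_w = max(2, int(round(1.0 / (n_wide[0] * cell[0]) / dq)))
    qmax = axis[-1]
    peaks = {}
    hmax = int(np.floor(qmax * cell[0]))
    kmax = int(np.floor(qmax * cell[1]))
    for h in range(-hmax, hmax + 1):
        for k in range(-kmax, kmax + 1):
            qh, qk = h / cell[0], k / cell[1]
            i = int(round((qh - axis[0]) / dq))
            j = int(round((qk - axis[0]) / dq))
            if not (half_w <= i < n - half_w and half_w <= j < n - half_w):
                continue
            box = img[i - half_w:i + half_w + 1, j - half_w:j + half_w + 1]
            aw = 2 * half_w
            lo_i, hi_i = max(0, i - aw), min(n, i + aw + 1)
            lo_j, hi_j = max(0, j - aw), min(n, j + aw + 1)
            annulus = img[lo_i:hi_i, lo_j:hi_j].copy()
            ci, cj = i - lo_i, j - lo_j
            annulus[max(0, ci - half_w):ci + half_w + 1,
                    max(0, cj - half_w):cj + half_w + 1] = np.nan
            bg = np.nanmedian(annulus)
            peaks[(h, k)] = float(box.sum() - bg * box.size)
            diffuse_map[i - half_w:i + half_w + 1, j - half_w:j + half_w + 1] = bg
    return peaks, diffuse_map


def build_fig7_fixture(duration_fs: float = 50.0, dose_rate_gy_fs: float = 50e6,
                       energy_ev: float = 6000.0):
    """Deterministic toy-crystal explosion scenario.

    A 5×5×5 crystal of 25 Å cubic cells, each holding 8 carbon pseudo-atoms
    at fixed (seeded) fractional positions — 1000 atoms total — exposed to a
    flat-top pulse whose displacement trajectory reaches a per-axis RMS of
    exactly 1 Å at the end of the pulse.  Returns (crystal, pulse, motion
    trajectory, ionization trajectory).
    """
    from . import dosimetry
    from .ionization import ionization_trajectory
    from .materials import builtin_material
    from .motion import MotionModel, displacement_trajectory

    rng = np.random.default_rng(7)
    motif = tuple(
        AtomSite(position=tuple(p), element="C")
        for p in rng.uniform(0.05, 0.95, size=(8, 3)).round(4)
    )
    crystal = ToyCrystal(cell=(25.0, 25.0, 25.0), motif=motif, n_cells=(5, 5, 5))
    comp = builtin_material("avg_protein")
    photons = dosimetry.photons_for_dose(dose_rate_gy_fs * duration_fs, comp, energy_ev)
    pulse = PulseSpec(energy_ev=energy_ev, photons_per_um2=photons,
                      duration_fs=duration_fs)
    model = MotionModel()  # calibrated: sigma(50 fs, 50 MGy/fs) = 1 Å
    motion = displacement_trajectory(dose_rate_gy_fs, duration_fs, model)
    ion = ionization_trajectory(dose_rate_gy_fs, duration_fs, comp)
    return crystal, pulse, motion, ion


def read_motif_pdb(path) -> tuple[AtomSite, ...]:
    """Read ATOM/HETATM records as a Cartesian motif (occupancy/B ignored)."""
    st = gemmi.read_structure(str(path))
    sites = []
    ignored_meta = False
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.occ != 1.0 or atom.b_iso not in (0.0, 20.0):
                        ignored_meta = True
                    sites.append(AtomSite(
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        element=atom.element.name,
                    ))
        break  # first model only
    if ignored_meta:
        warnings.warn("occupancies/B factors in motif file are ignored", stacklevel=2)
    if not sites:
        raise ValueError(f"no atoms found in {path}")
    return tuple(sites)
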