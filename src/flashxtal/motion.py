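"""X-ray-driven atomic displacement: diffusion-law trajectories and gating.

In the dense plasma formed during an intense pulse the RMS ion displacement
grows super-diffusively,

    σ(t) = C · R^α · t^β,

with R the dose rate.  Plasma simulations give α = 1/2, β = 3/2 (the
default, preset ``sec3b``); an alternative exponent set with σ ∝ R^(1/3) and
turn-off time ∝ R^(−1/4) (preset ``sec5``) is used by the wavelength-scaling
analysis.  σ here is the per-axis (1D) RMS displacement that enters the
Debye–Waller factor exp(−4π²q²σ²); the 3D RMS is √3·σ.

The amplitude C is calibrated so σ = 1 Å at the end of a 50 fs pulse at
50 MGy/fs (the toy-crystal explosion scenario used for the pattern
simulations in :mod:`flashxtal.diffraction`).

Bragg diffraction at scattering vector q is gated when σ reaches the
low-pass cutoff 1/(2πq) — the turn-off time — or when the sample ionizes to
transparency, whichever is earlier.  Dose rate times that gate time is the
maximum effective dose, which grows as R^(2/3) in the motion-gated regime.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ionization import transparency_time

__all__ = [
    "MotionModel",
    "DisplacementTrajectory",
    "motion_preset",
    "displacement_trajectory",
    "turnoff_time",
    "effective_dose",
    "correlated_motion_observable",
]

# calibration scenario: sigma = 1 Å after 50 fs at 50 MGy/fs
_CAL_SIGMA_A = 1.0
_CAL_T_FS = 50.0
_CAL_R_GY_FS = 50e6


def _calibrated_amplitude(alpha: float, beta: float) -> float:
    return _CAL_SIGMA_A / (_CAL_R_GY_FS ** alpha * _CAL_T_FS ** beta)


@dataclass(frozen=True)
class MotionModel:
    """Power-law displacement model σ = C·R^α·t^β (R in Gy/fs, t in fs, σ in Å)."""

    alpha: float = 0.5
    beta: float = 1.5
    amplitude: float | None = None   # Å·(Gy/fs)^(−α)·fs^(−β); None → calibrated
    n_dim: int = 3

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("exponents must be positive")
        if self.amplitude is None:
            object.__setattr__(self, "amplitude",
                               _calibrated_amplitude(self.alpha, self.beta))
        elif self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    def sigma(self, dose_rate_gy_fs: float, t_fs: np.ndarray | float):
        """Per-axis RMS displacement in Å."""
        return self.amplitude * dose_rate_gy_fs ** self.alpha \
            * np.asarray(t_fs, dtype=float) ** self.beta

    def diffusion_coefficient(self, dose_rate_gy_fs: float, t_fs):
        """Effective D_c(t) (Å²/fs): the per-axis variance obeys the
        time-dependent diffusion law σ² = 2·∫₀ᵗ D_c(t′) dt′."""
        t = np.asarray(t_fs, dtype=float)
        return self.amplitude ** 2 * dose_rate_gy_fs ** (2 * self.alpha) \
            * self.beta * t ** (2 * self.beta - 1)


_PRESETS = {
    # plasma-simulation exponents: sigma ~ t^{3/2} (I0/T)^{1/2}
    "sec3b": dict(alpha=0.5, beta=1.5),
    # wavelength-scaling exponents: sigma ~ R^{1/3}, turn-off ~ R^{-1/4}
    "sec5": dict(alpha=1.0 / 3.0, beta=4.0 / 3.0),
}


def motion_preset(name: str) -> MotionModel:
    """Named exponent presets: ``sec3b`` (default physics) or ``sec5``."""
    try:
        return MotionModel(**_PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None


@dataclass(frozen=True)
class DisplacementTrajectory:
    t_fs: np.ndarray
    sigma: np.ndarray            # Å, per-axis RMS
    dose_rate_gy_fs: float
    model: MotionModel

    def sigma_at(self, t) -> np.ndarray:
        return self.model.sigma(self.dose_rate_gy_fs, t)


def displacement_trajectory(dose_rate_gy_fs: float, duration_fs: float,
                            model: MotionModel | None = None,
                            n_steps: int = 256) -> DisplacementTrajectory:
    """σ(t) on a uniform grid over [0, T]; exactly the model power law."""
    if dose_rate_gy_fs < 0 or duration_fs <= 0:
        raise ValueError("dose rate must be ≥ 0 and duration > 0")
    model = model or MotionModel()
    t = np.linspace(0.0, duration_fs, n_steps)
    return DisplacementTrajectory(
        t_fs=t, sigma=model.sigma(dose_rate_gy_fs, t),
        dose_rate_gy_fs=dose_rate_gy_fs, model=model,
    )


def turnoff_time(q_inv_A: float, dose_rate_gy_fs: float,
                 model: MotionModel | None = None) -> float:
    """Time (fs) at which σ reaches the cutoff 1/(2πq) for resolution 1/q.

    Closed form t_off = [1/(2πq·C·R^α)]^{1/β}; decreasing in both q and R.
    """
    if q_inv_A <= 0 or dose_rate_gy_fs <= 0:
        raise ValueError("q and dose rate must be positive")
    model = model or MotionModel()
    sigma_c = 1.0 / (2.0 * np.pi * q_inv_A)
    return (sigma_c / (model.amplitude * dose_rate_gy_fs ** model.alpha)) ** (1.0 / model.beta)


def effective_dose(dose_rate_gy_fs: float, q_inv_A: float,
                   model: MotionModel | None = None) -> float:
    """Maximum effective dose R × min(turn-off time, transparency time), Gy.

    Motion-gated at moderate dose rates (slope 2/3 in log R), ionization-gated
    at the highest rates (slope 1/3).
    """
    t_gate = min(turnoff_time(q_inv_A, dose_rate_gy_fs, model),
                 transparency_time(dose_rate_gy_fs))
    return dose_rate_gy_fs * t_gate


def correlated_motion_observable(speed_A_fs: float, dose_rate_gy_fs: float,
                                 t_fs: float, model: MotionModel | None = None) -> bool:
    """Whether a correlated (directed) motion at the given speed outruns the
    diffusive Bragg gating: its displacement must exceed 2π times the RMS
    displacement at the same time (≈ six times faster than diffusion)."""
    model = model or MotionModel()
    return speed_A_fs * t_fs > 2.0 * np.pi * model.sigma(dose_rate_gy_fs, t_fs)
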