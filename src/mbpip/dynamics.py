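"""NVE molecular dynamics and velocity-autocorrelation power spectra.

Initialization follows the classical-oscillator correspondence: the total
internal energy above the minimum is <E> = (3N - 6) kT, velocities are
Maxwell-Boltzmann draws with the center-of-mass momentum and the total
angular momentum projected out (simulations are run for zero total angular
momentum) and then rescaled to the target kinetic energy.  Integration is
velocity Verlet.  Spectra are the time-averaged Fourier transform of the
(mass-weighted) Cartesian velocity autocorrelation function, computed by the
periodogram route (squared-magnitude FFT of the tapered velocities, summed
over atoms and components, averaged over trajectories).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_units import (
    AU_TIME_PER_FS,
    KB_HARTREE_PER_K,
    Structure,
    ValidationError,
)

__all__ = [
    "MDState",
    "Trajectory",
    "PowerSpectrum",
    "ATOMIC_MASSES_AMU",
    "masses_au",
    "target_energy",
    "init_velocities",
    "run_nve",
    "power_spectrum",
]

# standard atomic weights (amu); 1 amu in electron masses
ATOMIC_MASSES_AMU = {"H": 1.008, "C": 12.011, "O": 15.999, "N": 14.007}
AMU_TO_AU = 1822.888486209

# speed of light in cm per atomic time unit: converts FFT cycles/au_time -> cm^-1
_C_CM_PER_S = 2.99792458e10
_AU_TIME_S = 1e-15 / AU_TIME_PER_FS


def masses_au(structure: Structure) -> np.ndarray:
    try:
        return np.array([ATOMIC_MASSES_AMU[e] for e in structure.elements]) * AMU_TO_AU
    except KeyError as exc:
        raise ValidationError(f"no mass tabulated for element {exc}") from None


@dataclass
class MDState:
    structure: Structure
    velocities: np.ndarray  # (N, 3), bohr / au_time
    masses: np.ndarray  # (N,), electron masses

    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.masses[:, None] * self.velocities**2))

    def linear_momentum(self) -> np.ndarray:
        return np.sum(self.masses[:, None] * self.velocities, axis=0)

    def angular_momentum(self) -> np.ndarray:
        x = self.structure.coords - self.center_of_mass()
        return np.sum(np.cross(x, self.masses[:, None] * self.velocities), axis=0)

    def center_of_mass(self) -> np.ndarray:
        return np.sum(self.masses[:, None] * self.structure.coords, axis=0) / self.masses.sum()


def target_energy(structure: Structure, temperature: float) -> float:
    """Internal energy <E> = (3N - 6) kT (hartree) for a nonlinear molecule."""
    n = structure.n_atoms
    if n < 3:
        raise ValidationError("the (3N - 6) oscillator count needs N >= 3")
    if temperature < 0:
        raise ValidationError("temperature must be >= 0")
    return (3 * n - 6) * KB_HARTREE_PER_K * temperature


def init_velocities(structure: Structure, temperature: float, seed: int) -> MDState:
    """Maxwell-Boltzmann velocities with zero COM momentum and zero angular
    momentum, rescaled so the kinetic energy equals (3N - 6) kT."""
    if temperature < 0:
        raise ValidationError("temperature must be >= 0")
    m = masses_au(structure)
    rng = np.random.default_rng(seed)
    v = rng.normal(0.0, 1.0, (structure.n_atoms, 3)) / np.sqrt(m)[:, None]
    state = MDState(structure.copy(), v, m)
    # remove COM drift
    v -= state.linear_momentum() / m.sum()
    # remove rigid rotation: omega = I^-1 L, v -= omega x r
    x = structure.coords - state.center_of_mass()
    L = np.sum(np.cross(x, m[:, None] * v), axis=0)
    inertia = np.einsum("i,ij,ik->jk", m, x, x)
    inertia = np.trace(inertia) * np.eye(3) - inertia
    omega = np.linalg.solve(inertia, L)
    v -= np.cross(omega, x)
    # rescale to the target internal energy
    etarget = target_energy(structure, temperature)
    ke = state.kinetic_energy()
    if etarget > 0 and ke > 0:
        v *= np.sqrt(etarget / ke)
    elif etarget == 0:
        v[:] = 0.0
    return state


@dataclass
class Trajectory:
    times: np.ndarray  # au
    positions: np.ndarray  # (frames, N, 3) bohr
    velocities: np.ndarray  # (frames, N, 3)
    kinetic: np.ndarray
    potential: np.ndarray
    dt: float  # au
    masses: np.ndarray = None
    elements: tuple = ()

    @property
    def total_energy(self) -> np.ndarray:
        return self.kinetic + self.potential

    @property
    def n_frames(self) -> int:
        return len(self.times)


def run_nve(
    potential,
    state: MDState,
    dt: float = 5.0,
    n_equil: int = 10_000,
    n_prod: int = 22_500,
    record_stride: int = 1,
    divergence_factor: float = 100.0,
) -> Trajectory:
    """Velocity-Verlet NVE integration; only production frames are stored.

    Aborts with a diagnostic if the total energy grows beyond
    ``divergence_factor`` times its initial spread from the potential minimum.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    s = state.structure
    x = s.coords.copy()
    v = state.velocities.copy()
    m = state.masses[:, None]
    e_pot, g = potential.energy_and_gradient(s.with_coords(x))
    a = -g / m
    e_total0 = e_pot + 0.5 * float(np.sum(m * v * v))
    scale = max(abs(e_total0), 1e-6)

    n_rec = (n_prod + record_stride - 1) // record_stride
    times = np.empty(n_rec)
    positions = np.empty((n_rec, s.n_atoms, 3))
    velocities = np.empty((n_rec, s.n_atoms, 3))
    kin = np.empty(n_rec)
    pot = np.empty(n_rec)

    rec = 0
    for step in range(n_equil + n_prod):
        x = x + v * dt + 0.5 * a * dt * dt
        e_pot, g = potential.energy_and_gradient(s.with_coords(x))
        a_new = -g / m
        v = v + 0.5 * (a + a_new) * dt
        a = a_new
        ke = 0.5 * float(np.sum(m * v * v))
        if not np.isfinite(e_pot) or abs(e_pot + ke - e_total0) > divergence_factor * scale:
            raise FloatingPointError(
                f"NVE integration diverged at step {step}: "
                f"E_total = {e_pot + ke!r} vs initial {e_total0!r}"
            )
        if step >= n_equil and (step - n_equil) % record_stride == 0:
            times[rec] = (step + 1) * dt
            positions[rec] = x
            velocities[rec] = v
            kin[rec] = ke
            pot[rec] = e_pot
            rec += 1
    return Trajectory(
        times=times[:rec], positions=positions[:rec], velocities=velocities[:rec],
        kinetic=kin[:rec], potential=pot[:rec], dt=dt * record_stride,
        masses=state.masses, elements=s.elements,
    )


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray  # cm^-1
    intensity: np.ndarray  # >= 0, arbitrary units
    n_trajectories_averaged: int

    def peak_frequency(self) -> float:
        return float(self.frequencies[np.argmax(self.intensity)])


def power_spectrum(
    trajectories: list[Trajectory],
    window: str = "hann",
    mass_weighted: bool = True,
    zero_pad: int = 2,
) -> PowerSpectrum:
    """Average periodogram of the Cartesian velocities over trajectories.

    By the Wiener-Khinchin theorem the squared-magnitude Fourier transform of
    the tapered velocity series equals the Fourier transform of its time-
    averaged autocorrelation; summing over atoms and Cartesian components
    (optionally mass-weighted) and averaging over trajectories gives a
    non-negative vibrational density of states on a cm^-1 grid.
    """
    if not trajectories:
        raise ValidationError("need at least one trajectory")
    dt = trajectories[0].dt
    nf = trajectories[0].n_frames
    for t in trajectories[1:]:
        if abs(t.dt - dt) > 1e-12 or t.n_frames != nf:
            raise ValidationError("trajectories must share dt and length")
    if window == "hann":
        taper = np.hanning(nf)
    elif window in (None, "none", "rect"):
        taper = np.ones(nf)
    else:
        raise ValidationError(f"unknown window {window!r}")
    npad = int(zero_pad) * nf
    spectra = []
    for t in trajectories:
        v = t.velocities
        if mass_weighted and t.masses is not None:
            v = v * np.sqrt(t.masses)[None, :, None]
        V = np.fft.rfft(v * taper[:, None, None], n=npad, axis=0)
        spectra.append(np.sum(np.abs(V) ** 2, axis=(1, 2)))
    intensity = np.mean(spectra, axis=0)
    freq_cm = np.fft.rfftfreq(npad, d=dt * _AU_TIME_S) / _C_CM_PER_S
    return PowerSpectrum(freq_cm, intensity, len(trajectories))
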