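"""Delta-machine-learning correction of a low-level many-body PIP surface.

The corrected potential is the sum of two surfaces,

    V_corrected = V_low + Delta V,

where V_low is a many-body PIP model fit to cheap reference energies and
Delta V is a second, much smaller many-body PIP fit to the differences
between expensive and cheap energies of a modest set of configurations.
Because the energy-difference surface spans a far smaller range than the
raw high-level surface, a compact polynomial basis fits it to high
precision.

The correction training set is assembled from three sources mirroring the
reference protocol: frames strided out of NVE trajectories started at
stationary points of the low-level surface, Gaussian coordinate
displacements of those stationary points, and random picks from the
low-level training pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dynamics import init_velocities, run_nve
from .fitting import FitResult, fit_least_squares
from .io_units import Dataset, Structure, ValidationError
from .mb_potential import InteractionSpec, MBPIPModel

__all__ = [
    "DeltaStack",
    "DeltaSamplingPlan",
    "EnergyPairs",
    "assemble_delta_training_set",
    "fit_delta",
    "stacked_energy",
]


@dataclass
class DeltaStack:
    """A low-level model plus its correction, evaluated as their exact sum."""

    v_ll: MBPIPModel
    delta: MBPIPModel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.v_ll.alphabet != self.delta.alphabet:
            raise ValidationError("low-level and correction models must share the alphabet")

    def energy(self, structure: Structure, exact_invariance: bool = True) -> float:
        return self.v_ll.energy(structure, exact_invariance) + self.delta.energy(
            structure, exact_invariance
        )

    def gradient(self, structure: Structure) -> np.ndarray:
        return self.v_ll.gradient(structure) + self.delta.gradient(structure)

    def energy_and_gradient(self, structure: Structure) -> tuple[float, np.ndarray]:
        e1, g1 = self.v_ll.energy_and_gradient(structure)
        e2, g2 = self.delta.energy_and_gradient(structure)
        return e1 + e2, g1 + g2


def stacked_energy(stack: DeltaStack, structure: Structure) -> float:
    """Energy of the corrected surface: exactly v_ll + delta."""
    return stack.energy(structure)


@dataclass
class DeltaSamplingPlan:
    """Counts and knobs of the three-source correction-set protocol."""

    stationary_points: list[Structure]
    frames_per_trajectory: int = 151
    displaced_per_point: int = 51
    displacement_sigma: float = 0.05 * 1.8897259886  # 0.05 A in bohr
    n_random_picks: int = 2544
    seed: int = 0
    # MD knobs (the reference protocol leaves these open; they are logged)
    temperature: float = 300.0
    dt: float = 5.0
    stride: int = 10
    n_equil: int = 200

    @property
    def total(self) -> int:
        return (
            len(self.stationary_points)
            * (self.frames_per_trajectory + self.displaced_per_point)
            + self.n_random_picks
        )


def assemble_delta_training_set(
    plan: DeltaSamplingPlan,
    low_model,
    source_dataset: Dataset | None = None,
) -> Dataset:
    """Collect correction-training configurations per the three-source plan.

    Frames are tagged ``md`` / ``displacement`` / ``random_pick`` and labelled
    with low-model energies (random picks keep their source labels).
    Deterministic for a given plan seed.
    """
    if (plan.frames_per_trajectory or plan.displaced_per_point) and not plan.stationary_points:
        raise ValidationError("MD/displacement sampling needs stationary points")
    if plan.n_random_picks and (source_dataset is None or len(source_dataset) < plan.n_random_picks):
        raise ValidationError(
            f"cannot pick {plan.n_random_picks} frames from a source of "
            f"{0 if source_dataset is None else len(source_dataset)}"
        )
    rng = np.random.default_rng(plan.seed)
    out = Dataset()
    for k, sp in enumerate(plan.stationary_points):
        if plan.frames_per_trajectory > 0:
            state = init_velocities(sp, plan.temperature, seed=int(rng.integers(2**31)))
            n_prod = plan.frames_per_trajectory * plan.stride
            traj = run_nve(low_model, state, dt=plan.dt, n_equil=plan.n_equil,
                           n_prod=n_prod, record_stride=plan.stride)
            for i in range(plan.frames_per_trajectory):
                f = sp.with_coords(traj.positions[i], provenance_tag="md")
                f.label_energy = float(traj.potential[i])
                out.frames.append(f)
        if plan.displaced_per_point > 0:
            disp = rng.normal(0.0, plan.displacement_sigma,
                              (plan.displaced_per_point, sp.n_atoms, 3))
            for i in range(plan.displaced_per_point):
                f = sp.with_coords(sp.coords + disp[i], provenance_tag="displacement")
                f.label_energy = low_model.energy(f) if hasattr(low_model, "energy") else None
                out.frames.append(f)
    if plan.n_random_picks:
        picks = rng.choice(len(source_dataset), size=plan.n_random_picks, replace=False)
        for i in picks:
            f = source_dataset[int(i)].copy()
            f.provenance_tag = "random_pick"
            out.frames.append(f)
    return out


@dataclass
class EnergyPairs:
    """Configurations with both a high-level and a low-level energy label."""

    frames: list[Structure]
    e_high: np.ndarray  # hartree
    e_low: np.ndarray  # hartree

    def __post_init__(self):
        self.e_high = np.asarray(self.e_high, dtype=float)
        self.e_low = np.asarray(self.e_low, dtype=float)
        if not (len(self.frames) == len(self.e_high) == len(self.e_low)):
            raise ValidationError("frames, e_high and e_low must have equal lengths")
        if np.any(~np.isfinite(self.e_high)) or np.any(~np.isfinite(self.e_low)):
            raise ValidationError("energy labels must be finite (missing label?)")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def differences(self) -> np.ndarray:
        return self.e_high - self.e_low

    @property
    def span_high(self) -> float:
        return float(self.e_high.max() - self.e_high.min())

    @property
    def span_difference(self) -> float:
        d = self.differences
        return float(d.max() - d.min())

    @classmethod
    def from_datasets(cls, high: Dataset, low: Dataset) -> "EnergyPairs":
        if len(high) != len(low):
            raise ValidationError("high and low datasets must pair frame by frame")
        return cls(list(high.frames), high.energies, low.energies)

    @classmethod
    def read_table(cls, path: str | Path, frames: Sequence[Structure]) -> "EnergyPairs":
        """Flat text table: frame-index  E_high  E_low (hartree)."""
        eh, el, fr = [], [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            idx, h, l = line.split()[:3]
            fr.append(frames[int(idx)])
            eh.append(float(h))
            el.append(float(l))
        return cls(fr, np.array(eh), np.array(el))


def fit_delta(
    specs: Sequence[InteractionSpec],
    pairs: EnergyPairs,
    weights: np.ndarray | None = None,
    alphabet=("C", "H"),
    rcond: float | None = None,
) -> FitResult:
    """Least-squares fit of a correction surface to (E_high - E_low).

    The fitted model's metadata records the span of the difference data next
    to the span of the raw high-level data — the compactness that makes the
    correction cheap to learn.
    """
    diff = pairs.differences
    ds = Dataset([f.with_coords(f.coords, label_energy=float(d))
                  for f, d in zip(pairs.frames, diff)])
    result = fit_least_squares(specs, ds, weights=weights, one_body=False,
                               alphabet=alphabet, rcond=rcond)
    result.model.metadata.update(
        role="delta_correction",
        span_difference_hartree=pairs.span_difference,
        span_high_hartree=pairs.span_high,
        n_pairs=len(pairs),
    )
    return result
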