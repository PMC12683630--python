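"""Local geometry optimization and hairpin-linear gap scans.

Works with any potential object exposing ``energy(structure) -> float`` and
``energy_and_gradient(structure) -> (float, (N,3) array)`` in atomic units:
a fitted many-body PIP model, a delta-corrected stack, or the toy reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .io_units import HARTREE_PER_KCALMOL, Structure, ValidationError
from .synthetic import build_chain

__all__ = ["MinimizeResult", "GapScanResult", "minimize", "gap", "scan_chain_lengths"]

DEFAULT_GTOL = 1e-6  # hartree/bohr, max gradient component


@dataclass
class MinimizeResult:
    """Outcome of a local minimization (never silently partial)."""

    structure: Structure
    energy: float  # hartree
    grad_max: float  # hartree/bohr, max |component|
    converged: bool
    n_iterations: int
    message: str = ""


def minimize(
    potential,
    start: Structure,
    gtol: float = DEFAULT_GTOL,
    max_iterations: int = 5000,
    max_displacement: float | None = None,
) -> MinimizeResult:
    """Quasi-Newton (L-BFGS with line search) minimization in Cartesians.

    Converged means the largest gradient component is below *gtol*.  A
    non-converged run is returned with ``converged=False``; downstream gap
    evaluation refuses such inputs.

    ``max_displacement`` (bohr, per coordinate) restricts the search to a box
    around the starting geometry.  Fitted polynomial surfaces are only
    trustworthy inside their sampled region; the bound keeps a *local*
    optimization from wandering into extrapolation holes.
    """
    e0 = potential.energy(start)
    if not np.isfinite(e0):
        raise ValidationError("starting energy is not finite")

    def fun(x):
        e, g = potential.energy_and_gradient(start.with_coords(x.reshape(-1, 3)))
        return e, g.ravel()

    x = start.coords.ravel().copy()
    bounds = None
    if max_displacement is not None:
        x0 = start.coords.ravel()
        bounds = list(zip(x0 - max_displacement, x0 + max_displacement))
    total_iter = 0
    result = None
    for _ in range(3):  # L-BFGS occasionally stops on ftol; restart sharpens
        res = _scipy_minimize(
            fun, x, jac=True, method="L-BFGS-B", bounds=bounds,
            options=dict(maxiter=max_iterations, gtol=gtol * 0.1, ftol=1e-16),
        )
        x = res.x
        total_iter += res.nit
        e, g = fun(x)
        gmax = float(np.abs(g).max())
        result = MinimizeResult(
            structure=start.with_coords(x.reshape(-1, 3)),
            energy=float(e), grad_max=gmax,
            converged=gmax < gtol, n_iterations=total_iter,
            message=str(res.message),
        )
        if result.converged:
            break
    return result


def gap(
    potential,
    linear_min: Structure,
    hairpin_min: Structure,
    gtol: float = DEFAULT_GTOL,
) -> float:
    """E(hairpin) - E(linear) in kcal/mol for two converged minima."""
    for name, s in (("linear", linear_min), ("hairpin", hairpin_min)):
        g = potential.energy_and_gradient(s)[1]
        if np.abs(g).max() >= gtol:
            raise ValidationError(
                f"{name} structure is not a converged minimum "
                f"(max |grad| = {np.abs(g).max():.2e} >= {gtol:.2e} hartree/bohr)"
            )
    de = potential.energy(hairpin_min) - potential.energy(linear_min)
    return de / HARTREE_PER_KCALMOL


@dataclass
class GapScanResult:
    """Hairpin-linear gaps (kcal/mol) per chain length and per potential."""

    chain_lengths: list[int]
    potential_ids: list[str]
    gaps: dict[str, list[float | None]]  # potential_id -> per-n gap (None: failed)
    converged: dict[str, list[bool]]
    energies: dict[str, list[tuple[float, float] | None]] = field(default_factory=dict)
    start_structures: dict = field(default_factory=dict)

    def crossover(self, potential_id: str) -> int | None:
        """Smallest chain length whose gap is negative (hairpin favored)."""
        for n, g in zip(self.chain_lengths, self.gaps[potential_id]):
            if g is not None and g < 0:
                return n
        return None

    def as_table(self) -> str:
        lines = ["n\tpotential\tE_linear_h\tE_hairpin_h\tgap_kcal\tconverged"]
        for pid in self.potential_ids:
            for i, n in enumerate(self.chain_lengths):
                g = self.gaps[pid][i]
                ee = self.energies.get(pid, [None] * len(self.chain_lengths))[i]
                el, eh = ("nan", "nan") if ee is None else (repr(ee[0]), repr(ee[1]))
                lines.append(
                    f"{n}\t{pid}\t{el}\t{eh}\t"
                    f"{'nan' if g is None else f'{g:.6f}'}\t{self.converged[pid][i]}"
                )
        return "\n".join(lines)


def scan_chain_lengths(
    potentials: dict[str, object] | list,
    n_range,
    gtol: float = DEFAULT_GTOL,
    max_iterations: int = 5000,
    max_displacement: float | None = None,
) -> GapScanResult:
    """Minimize linear and hairpin templates and tabulate gaps per length.

    *potentials* maps an identifier to a potential object.  A failed or
    unconverged minimization is recorded for its cell; it never aborts the
    scan.  Starting template structures are kept in the result because gaps
    are sensitive to the starting geometry.
    """
    if not isinstance(potentials, dict):
        potentials = {f"model{i}": p for i, p in enumerate(potentials)}
    n_list = sorted(int(n) for n in n_range)
    result = GapScanResult(
        chain_lengths=n_list,
        potential_ids=list(potentials),
        gaps={pid: [] for pid in potentials},
        converged={pid: [] for pid in potentials},
        energies={pid: [] for pid in potentials},
    )
    for n in n_list:
        lin = build_chain(n, "linear")
        hp = build_chain(n, "hairpin")
        result.start_structures[n] = (lin, hp)
        for pid, pot in potentials.items():
            try:
                rl = minimize(pot, lin, gtol=gtol, max_iterations=max_iterations,
                              max_displacement=max_displacement)
                rh = minimize(pot, hp, gtol=gtol, max_iterations=max_iterations,
                              max_displacement=max_displacement)
                ok = rl.converged and rh.converged
                result.converged[pid].append(ok)
                if ok:
                    result.gaps[pid].append(
                        (rh.energy - rl.energy) / HARTREE_PER_KCALMOL
                    )
                    result.energies[pid].append((rl.energy, rh.energy))
                else:
                    result.gaps[pid].append(None)
                    result.energies[pid].append(None)
            except (ValidationError, FloatingPointError) as exc:
                result.converged[pid].append(False)
                result.gaps[pid].append(None)
                result.energies[pid].append(None)
    return result
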