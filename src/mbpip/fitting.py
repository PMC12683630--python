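"""Linear least-squares fitting of the many-body PIP coefficients.

All coefficients (every composition type, every order, plus optional
per-element one-body constants) are determined in one overdetermined linear
solve against total energies — the "at once" strategy.  The solver is the
rank-revealing SVD route of :func:`numpy.linalg.lstsq`: a rank-deficient
design matrix yields the minimum-norm solution together with a warning and a
condition diagnostic, never a silent failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_units import Dataset, Structure, ValidationError, HARTREE_PER_CM1
from .mb_potential import InteractionSpec, MBPIPModel, _tuple_table, _switch

__all__ = ["FitResult", "design_matrix", "fit_least_squares", "report_per_atom"]

SHORT_DISTANCE_WARNING_BOHR = 0.5


@dataclass
class FitResult:
    """A fitted model with its training-set residual statistics (hartree)."""

    model: MBPIPModel
    rmse: float
    rmse_per_atom: float
    max_abs_residual: float
    n_train: int
    condition_diagnostic: float
    residuals: np.ndarray = field(repr=False, default=None)

    def summary(self, energy_unit_scale: float = 1.0 / HARTREE_PER_CM1,
                unit_name: str = "cm-1") -> str:
        return (
            f"n_train={self.n_train}  n_coeff={self.model.n_coefficients}  "
            f"rmse={self.rmse * energy_unit_scale:.4g} {unit_name}  "
            f"per-atom={self.rmse_per_atom * energy_unit_scale:.4g} {unit_name}  "
            f"max|res|={self.max_abs_residual * energy_unit_scale:.4g} {unit_name}  "
            f"cond={self.condition_diagnostic:.3g}"
        )


def _frame_row(structure: Structure, specs: Sequence[InteractionSpec],
               alphabet, D=None) -> np.ndarray:
    """One design-matrix row: summed basis values per coefficient column."""
    if D is None:
        D = structure.distance_matrix()
    segments = []
    for spec in specs:
        basis = spec.basis()
        T, rows, cols = _tuple_table(tuple(structure.elements), spec.composition,
                                     tuple(alphabet))
        if T.shape[0] == 0:
            segments.append(np.zeros(basis.n_functions))
            continue
        R = D[rows, cols]
        maxdist = R.max(axis=1)
        keep = maxdist <= spec.cutoff
        if not np.any(keep):
            segments.append(np.zeros(basis.n_functions))
            continue
        R = R[keep]
        if R.min() < SHORT_DISTANCE_WARNING_BOHR:
            warnings.warn(
                f"training distance {R.min():.3f} bohr < {SHORT_DISTANCE_WARNING_BOHR} "
                "bohr: Morse variables saturate near r=0", stacklevel=3)
        with np.errstate(divide="ignore"):
            M = np.exp((-R / spec.lam) @ basis._Ef.T)
        B = M @ basis._G.T  # (m, n_functions)
        s, _ = _switch(maxdist[keep], spec.cutoff, spec.switch_width)
        segments.append(s @ B)
    return np.concatenate(segments)


def design_matrix(specs: Sequence[InteractionSpec], dataset: Dataset,
                  alphabet=("C", "H"), one_body: bool = False) -> np.ndarray:
    """Design matrix (frames x coefficients); column order follows the specs.

    With ``one_body`` two extra trailing columns hold the per-element atom
    counts.
    """
    if len(dataset) == 0:
        raise ValidationError("cannot build a design matrix from an empty dataset")
    rows = []
    for f in dataset:
        f.validate_alphabet(alphabet)
        row = _frame_row(f, specs, alphabet)
        if one_body:
            counts = [float(f.elements.count(e)) for e in alphabet]
            row = np.concatenate([row, counts])
        rows.append(row)
    return np.vstack(rows)


def fit_least_squares(
    specs: Sequence[InteractionSpec],
    dataset: Dataset,
    weights: np.ndarray | None = None,
    one_body: bool = False,
    alphabet=("C", "H"),
    metadata: dict | None = None,
    rcond: float | None = None,
) -> FitResult:
    """Solve for every coefficient at once by weighted linear least squares.

    Without one-body offsets the training energies are shifted so that the
    dataset minimum is zero and a single reference constant (the basis has no
    constant term) is solved alongside the coefficients; shift plus constant
    are restored by the fitted model's ``energy_offset``.

    ``rcond`` is the relative singular-value cutoff of the rank-revealing
    solver; directions below it are discarded (minimum-norm completion),
    which stabilizes near-degenerate bases against sampling noise.
    """
    dataset.require_labels()
    E = dataset.energies
    if np.any(~np.isfinite(E)):
        raise ValidationError("training energies contain NaN/inf")
    A0 = design_matrix(specs, dataset, alphabet=alphabet, one_body=one_body)
    shift = 0.0
    if not one_body:
        shift = float(E.min())
        # reference constant column (an intercept): the basis has no constant
        # term, so the energy zero is a fitted scalar, not an assumption
        A0 = np.concatenate([A0, np.ones((A0.shape[0], 1))], axis=1)
    A = A0
    b = E - shift
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        if w.shape != (len(dataset),):
            raise ValidationError("need one weight per frame")
        A = A * w[:, None]
        b = b * w
    n_coeff = A.shape[1]
    if len(dataset) < n_coeff:
        warnings.warn(
            f"underdetermined fit: {len(dataset)} frames for {n_coeff} coefficients "
            "(minimum-norm solution)", stacklevel=2)
    coef, _, rank, sv = np.linalg.lstsq(A, b, rcond=rcond)
    cond = float(sv[0] / sv[rank - 1]) if rank > 0 else np.inf
    if rank < n_coeff:
        warnings.warn(
            f"rank-deficient design matrix (rank {rank} < {n_coeff}); "
            "returning the minimum-norm solution", stacklevel=2)
        cond = np.inf if sv[-1] == 0 else float(sv[0] / sv[sv > 0].min())

    # split the solution back into per-spec vectors (+ one-body tail)
    sizes = [spec.basis().n_functions for spec in specs]
    split = np.split(coef[: sum(sizes)], np.cumsum(sizes)[:-1])
    ob = None
    offset = shift
    if one_body:
        ob = {e: float(c) for e, c in zip(alphabet, coef[sum(sizes):])}
    else:
        offset = shift + float(coef[-1])
    model = MBPIPModel(
        specs=list(specs), coefficients=list(split), one_body=ob,
        energy_offset=offset, alphabet=tuple(alphabet),
        metadata={"energy_shift": shift, "n_train": len(dataset),
                  **(metadata or {})},
    )
    pred = A0 @ coef + shift
    res = pred - E
    rmse = float(np.sqrt(np.mean(res**2)))
    n_atoms = dataset[0].n_atoms
    result = FitResult(
        model=model, rmse=rmse, rmse_per_atom=report_per_atom(rmse, n_atoms),
        max_abs_residual=float(np.max(np.abs(res))), n_train=len(dataset),
        condition_diagnostic=cond, residuals=res,
    )
    model.metadata["fit"] = {
        "rmse_hartree": result.rmse,
        "rmse_per_atom_hartree": result.rmse_per_atom,
        "max_abs_residual_hartree": result.max_abs_residual,
        "condition_diagnostic": cond,
    }
    return result


def report_per_atom(rmse: float, n_atoms: int) -> float:
    """Per-atom error convention: rmse divided by the atom count."""
    if n_atoms <= 0:
        raise ValidationError("n_atoms must be positive")
    return rmse / n_atoms
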