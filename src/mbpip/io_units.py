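"""Geometry containers, multi-frame XYZ input/output, and the unit system.

Everything inside the package works in Hartree atomic units (hartree, bohr,
atomic time unit); user-facing files default to angstrom coordinates.  All
conversion factors are CODATA values taken from :mod:`scipy.constants`, so
round trips are exact to floating-point precision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.constants import physical_constants, N_A

__all__ = [
    "Structure",
    "Dataset",
    "UnitQuantity",
    "convert",
    "conversion_factor",
    "read_xyz",
    "write_xyz",
    "ValidationError",
    "ParseError",
    "DimensionError",
    "BOHR_PER_ANGSTROM",
    "HARTREE_PER_KCALMOL",
    "HARTREE_PER_CM1",
    "AU_TIME_PER_FS",
    "KB_HARTREE_PER_K",
]


class ValidationError(ValueError):
    """Input violates a documented contract (bad element, missing label, ...)."""


class ParseError(ValueError):
    """A file could not be interpreted in the declared format."""


class DimensionError(ValueError):
    """Unit conversion requested across incompatible dimensions."""


# ----------------------------------------------------------------------------
# unit system
# ----------------------------------------------------------------------------

_HARTREE_J = physical_constants["Hartree energy"][0]
_BOHR_M = physical_constants["Bohr radius"][0]
_AU_TIME_S = physical_constants["atomic unit of time"][0]

BOHR_PER_ANGSTROM = 1e-10 / _BOHR_M
HARTREE_PER_KCALMOL = 4184.0 / (_HARTREE_J * N_A)
# E = h c nu~:   1 cm^-1 expressed in hartree
HARTREE_PER_CM1 = 100.0 / physical_constants["hartree-inverse meter relationship"][0]
HARTREE_PER_EV = 1.0 / physical_constants["Hartree energy in eV"][0]
AU_TIME_PER_FS = 1e-15 / _AU_TIME_S
KB_HARTREE_PER_K = physical_constants["Boltzmann constant"][0] / _HARTREE_J

# unit -> (dimension, factor converting *to* the internal unit of that dimension)
_UNITS: dict[str, tuple[str, float]] = {
    "hartree": ("energy", 1.0),
    "cm-1": ("energy", HARTREE_PER_CM1),
    "kcal/mol": ("energy", HARTREE_PER_KCALMOL),
    "eV": ("energy", HARTREE_PER_EV),
    "angstrom": ("length", BOHR_PER_ANGSTROM),
    "bohr": ("length", 1.0),
    "fs": ("time", AU_TIME_PER_FS),
    "au_time": ("time", 1.0),
    "K": ("temperature", 1.0),
}

_UNIT_ALIASES = {
    "cm−1": "cm-1",
    "cm^-1": "cm-1",
    "wavenumber": "cm-1",
    "a": "angstrom",
    "ang": "angstrom",
    "angstroem": "angstrom",
    "ev": "eV",
    "au": "au_time",
    "kelvin": "K",
}


def _canonical_unit(unit: str) -> str:
    u = unit.strip()
    if u in _UNITS:
        return u
    low = u.lower()
    if low in _UNITS:
        return low
    if low in _UNIT_ALIASES:
        return _UNIT_ALIASES[low]
    if u in _UNIT_ALIASES:
        return _UNIT_ALIASES[u]
    raise DimensionError(f"unknown unit {unit!r}; known units: {sorted(_UNITS)}")


def conversion_factor(from_unit: str, to_unit: str) -> float:
    """Multiplicative factor taking a value in *from_unit* to *to_unit*."""
    fu, tu = _canonical_unit(from_unit), _canonical_unit(to_unit)
    dim_f, fac_f = _UNITS[fu]
    dim_t, fac_t = _UNITS[tu]
    if dim_f != dim_t:
        raise DimensionError(f"cannot convert {from_unit!r} ({dim_f}) to {to_unit!r} ({dim_t})")
    if fu == tu:
        return 1.0
    return fac_f / fac_t


@dataclass(frozen=True)
class UnitQuantity:
    """A scalar tagged with one of the units the package understands."""

    value: float
    unit: str

    def to(self, unit: str) -> "UnitQuantity":
        return UnitQuantity(self.value * conversion_factor(self.unit, unit), _canonical_unit(unit))


def convert(q: UnitQuantity, to_unit: str) -> UnitQuantity:
    """Convert *q* to *to_unit* (exact multiplicative CODATA factors)."""
    return q.to(to_unit)


# ----------------------------------------------------------------------------
# structures and datasets
# ----------------------------------------------------------------------------

DEFAULT_ALPHABET = ("C", "H")


@dataclass
class Structure:
    """One configuration: element symbols plus Cartesian coordinates in bohr.

    ``bonds`` (index pairs) is optional topology carried along by the chain
    builder so that perturbed copies of a template keep their bond graph.
    """

    elements: tuple[str, ...]
    coords: np.ndarray  # (N, 3), bohr
    label_energy: float | None = None  # hartree
    provenance_tag: str = ""
    bonds: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        self.elements = tuple(self.elements)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match {len(self.elements)} elements"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def formula(self) -> str:
        counts: dict[str, int] = {}
        for e in self.elements:
            counts[e] = counts.get(e, 0) + 1
        return "".join(f"{e}{counts[e]}" for e in sorted(counts))

    def validate_alphabet(self, alphabet: Sequence[str] = DEFAULT_ALPHABET) -> None:
        bad = sorted(set(self.elements) - set(alphabet))
        if bad:
            raise ValidationError(f"elements {bad} outside the declared alphabet {tuple(alphabet)}")

    def with_coords(self, coords: np.ndarray, **changes) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float), **changes)

    def copy(self) -> "Structure":
        return replace(self, coords=self.coords.copy())

    def distance_matrix(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt(np.sum(d * d, axis=-1))


@dataclass
class Dataset:
    """An ordered collection of labelled frames."""

    frames: list[Structure] = field(default_factory=list)
    units_declared: tuple[str, str] = ("angstrom", "hartree")  # (length, energy) of the source

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Dataset(self.frames[i], self.units_declared)
        return self.frames[i]

    @property
    def energies(self) -> np.ndarray:
        self.require_labels()
        return np.array([f.label_energy for f in self.frames], dtype=float)

    def require_labels(self) -> None:
        missing = [i for i, f in enumerate(self.frames) if f.label_energy is None]
        if missing:
            raise ValidationError(f"frames {missing[:5]}... lack energy labels")

    def extend(self, other: Iterable[Structure]) -> None:
        self.frames.extend(other)

    def deduplicate(self, coord_tol: float = 1e-8, energy_tol: float = 1e-10) -> "Dataset":
        """Drop frames identical to an earlier one within the declared tolerances.

        Two frames match when every atom moved less than *coord_tol* bohr and the
        labels differ by less than *energy_tol* hartree.
        """
        kept: list[Structure] = []
        for f in self.frames:
            dup = False
            for g in kept:
                if g.elements != f.elements:
                    continue
                if np.max(np.abs(g.coords - f.coords)) >= coord_tol:
                    continue
                ea, eb = f.label_energy, g.label_energy
                if (ea is None) != (eb is None):
                    continue
                if ea is not None and abs(ea - eb) >= energy_tol:
                    continue
                dup = True
                break
            if not dup:
                kept.append(f)
        return Dataset(kept, self.units_declared)


# ----------------------------------------------------------------------------
# multi-frame XYZ
# ----------------------------------------------------------------------------

# "Energy= -1.234"  /  "energy: -1.234"  anywhere on the comment line
_ENERGY_RE = re.compile(r"energy\s*[=:]\s*([-+]?[0-9]*\.?[0-9]+(?:[eEdD][-+]?[0-9]+)?)", re.IGNORECASE)


def read_xyz(
    path: str | Path,
    units: tuple[str, str] = ("angstrom", "hartree"),
    alphabet: Sequence[str] | None = DEFAULT_ALPHABET,
) -> Dataset:
    """Read a (possibly multi-frame) XYZ file.

    *units* declares (length, energy) units of the file; coordinates and any
    per-frame ``Energy=`` comment values are converted to bohr / hartree.
    """
    length_fac = conversion_factor(units[0], "bohr")
    energy_fac = conversion_factor(units[1], "hartree")
    text = Path(path).read_text().splitlines()
    frames: list[Structure] = []
    i = 0
    frame_idx = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        try:
            natoms = int(text[i].strip())
        except ValueError as exc:
            raise ParseError(f"frame {frame_idx}: expected an atom count on line {i + 1}, "
                             f"got {text[i]!r}") from exc
        if i + 1 + natoms >= len(text) + 1 and natoms > 0 and i + 1 + natoms > len(text):
            raise ParseError(f"frame {frame_idx}: file truncated ({natoms} atoms declared)")
        comment = text[i + 1] if i + 1 < len(text) else ""
        m = _ENERGY_RE.search(comment)
        energy = None
        if m:
            energy = float(m.group(1).replace("D", "E").replace("d", "e")) * energy_fac
        elements: list[str] = []
        coords = np.empty((natoms, 3))
        for j in range(natoms):
            line = text[i + 2 + j]
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"frame {frame_idx}: malformed atom line {i + 3 + j}: {line!r}")
            elements.append(parts[0])
            coords[j] = [float(p) for p in parts[1:4]]
        s = Structure(tuple(elements), coords * length_fac, label_energy=energy)
        if alphabet is not None:
            s.validate_alphabet(alphabet)
        frames.append(s)
        i += 2 + natoms
        frame_idx += 1
    return Dataset(frames, units_declared=tuple(units))


def write_xyz(
    dataset: Dataset | Sequence[Structure],
    path: str | Path,
    units: tuple[str, str] = ("angstrom", "hartree"),
) -> Path:
    """Write frames as multi-frame XYZ with ``Energy=`` comment labels."""
    frames = list(dataset.frames if isinstance(dataset, Dataset) else dataset)
    if not frames:
        raise ValidationError("refusing to write an empty dataset")
    length_fac = conversion_factor("bohr", units[0])
    energy_fac = conversion_factor("hartree", units[1])
    lines: list[str] = []
    for f in frames:
        lines.append(str(f.n_atoms))
        comment = f"Energy= {f.label_energy * energy_fac!r}" if f.label_energy is not None else ""
        if f.provenance_tag:
            comment = (comment + f" tag={f.provenance_tag}").strip()
        lines.append(comment)
        xyz = f.coords * length_fac
        for e, (x, y, z) in zip(f.elements, xyz):
            lines.append(f"{e:2s} {x: .12f} {y: .12f} {z: .12f}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def write_energy_table(dataset: Dataset, path: str | Path, energy_unit: str = "hartree") -> Path:
    """Flat whitespace table (frame index, energy) for plotting."""
    fac = conversion_factor("hartree", energy_unit)
    lines = [f"# frame  energy[{energy_unit}]"]
    for i, f in enumerate(dataset):
        e = "nan" if f.label_energy is None else repr(f.label_energy * fac)
        lines.append(f"{i} {e}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
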