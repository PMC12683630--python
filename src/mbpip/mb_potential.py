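"""Assembly of the many-body PIP potential.

The total energy of a configuration is expanded over its atoms:

    V = sum_i V1b(i) + sum_{i<j} V2b(i,j) + sum_{i<j<k} V3b(i,j,k)
        + sum_{i<j<k<l} V4b(i,j,k,l)

Each n-body term is typed by the element composition of the tuple (CC, CH,
HH; CCC, CCH, CHH, HHH; CCCC ... HHHH) and expressed as a linear combination
of PIP basis functions in Morse variables y = exp(-r/lambda) of the tuple's
internuclear distances.  Tuples whose largest internal distance exceeds the
per-type range cutoff are dropped; an optional cosine switching window makes
that selection smooth for dynamics.

Permutation invariance of the total energy is exact (bitwise): per-tuple
basis values are computed with value-sorted products and orbit sums, and the
per-tuple contributions are accumulated in value-sorted order, so relabelling
like atoms cannot change even the floating-point round-off.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_units import Structure, ValidationError, DEFAULT_ALPHABET
from .pip_basis import (
    ConfigurationError,
    PIPBasis,
    generate_basis,
    symmetry_for_composition,
)

__all__ = [
    "InteractionSpec",
    "MBPIPModel",
    "enumerate_tuples",
    "morse",
    "default_interaction_specs",
    "DEFAULT_LAMBDA_BOHR",
    "DEFAULT_CUTOFFS_BOHR",
]

DEFAULT_LAMBDA_BOHR = 2.0
# range cutoffs per interaction order, bohr (user hyperparameters; these are
# package defaults chosen to keep 3-b/4-b tuple counts local)
DEFAULT_CUTOFFS_BOHR = {2: np.inf, 3: 10.0, 4: 8.0}
SCHEMA_VERSION = 1


def morse(r, lam: float):
    """Morse variable y = exp(-r/lambda); y in (0, 1], decreasing in r."""
    if lam <= 0:
        raise ConfigurationError(f"Morse range parameter must be positive, got {lam}")
    return np.exp(-np.asarray(r, dtype=float) / lam)


@dataclass(frozen=True)
class InteractionSpec:
    """One typed n-body interaction: composition, range and basis settings."""

    composition: str  # element string in alphabet order, e.g. "CCH"
    lam: float = DEFAULT_LAMBDA_BOHR  # Morse range parameter, bohr
    cutoff: float = np.inf  # max intra-tuple distance, bohr
    max_degree: int = 5
    connected: bool = True
    switch_width: float = 0.0  # bohr; 0 = hard cutoff
    alphabet: tuple[str, str] = DEFAULT_ALPHABET

    def __post_init__(self):
        if self.lam <= 0:
            raise ConfigurationError("lambda must be > 0")
        if self.cutoff <= 0:
            raise ConfigurationError("cutoff must be > 0")
        sym, counts = symmetry_for_composition(self.composition, self.alphabet)
        canonical = self.alphabet[0] * counts[0] + self.alphabet[1] * counts[1]
        if self.composition != canonical:
            raise ConfigurationError(
                f"composition {self.composition!r} must be written in alphabet order "
                f"as {canonical!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return symmetry_for_composition(self.composition, self.alphabet)[1]

    @property
    def symmetry(self):
        return symmetry_for_composition(self.composition, self.alphabet)[0]

    @property
    def order(self) -> int:
        return len(self.composition)

    def basis(self) -> PIPBasis:
        return generate_basis(self.symmetry, self.max_degree, self.connected)


def default_interaction_specs(
    orders: dict[int, int] = {2: 6, 3: 7, 4: 5},
    lam: float | dict[int, float] = DEFAULT_LAMBDA_BOHR,
    cutoffs: dict[int, float] | None = None,
    alphabet: tuple[str, str] = DEFAULT_ALPHABET,
    connected: bool = True,
    switch_width: float = 0.0,
) -> list[InteractionSpec]:
    """The full two-element type list at the given per-order polynomial caps.

    With the reference orders {2: 6, 3: 7, 4: 5} the eleven compositions carry
    383 linear coefficients in total.
    """
    cutoffs = dict(DEFAULT_CUTOFFS_BOHR) | (cutoffs or {})
    a, b = alphabet
    comps_by_order = {
        2: [a * 2, a + b, b * 2],
        3: [a * 3, a * 2 + b, a + b * 2, b * 3],
        4: [a * 4, a * 3 + b, a * 2 + b * 2, a + b * 3, b * 4],
    }
    specs = []
    for n, deg in sorted(orders.items()):
        for comp in comps_by_order[n]:
            lam_n = lam[n] if isinstance(lam, dict) else lam
            specs.append(InteractionSpec(comp, lam=lam_n, cutoff=cutoffs[n],
                                         max_degree=deg, connected=connected,
                                         switch_width=switch_width, alphabet=alphabet))
    return specs


# ----------------------------------------------------------------------------
# tuple enumeration
# ----------------------------------------------------------------------------


@lru_cache(maxsize=256)
def _tuple_table(elements: tuple[str, ...], composition: str, alphabet: tuple[str, str]):
    """Index tuples matching *composition* (cutoff-free) plus edge gather arrays.

    Returns (T, rows, cols) where T is (m, n) atom indices in canonical slot
    order (like atoms sorted by index) and rows/cols are (m, n_edges) atom
    indices for the canonical edge order (like-like edges first, then cross).
    """
    sym, (na, nb) = symmetry_for_composition(composition, alphabet)
    idx_a = [i for i, e in enumerate(elements) if e == alphabet[0]]
    idx_b = [i for i, e in enumerate(elements) if e == alphabet[1]]
    combos_a = list(itertools.combinations(idx_a, na))
    combos_b = list(itertools.combinations(idx_b, nb))
    if not combos_a or not combos_b:
        T = np.empty((0, na + nb), dtype=np.int64)
    else:
        A = np.array(combos_a, dtype=np.int64).reshape(len(combos_a), na)
        B = np.array(combos_b, dtype=np.int64).reshape(len(combos_b), nb)
        T = np.concatenate(
            [np.repeat(A, len(B), axis=0), np.tile(B, (len(A), 1))], axis=1
        )
    edges = _edges_for_shape(na, nb)
    rows = T[:, [i for i, _ in edges]]
    cols = T[:, [j for _, j in edges]]
    return T, rows, cols


def _edges_for_shape(na: int, nb: int):
    n = na + nb
    like_a = [(i, j) for i in range(na) for j in range(i + 1, na)]
    like_b = [(i, j) for i in range(na, n) for j in range(i + 1, n)]
    cross = [(i, j) for i in range(na) for j in range(na, n)]
    return tuple(like_a + like_b + cross)


def enumerate_tuples(
    structure: Structure,
    composition: str,
    cutoff: float = np.inf,
    alphabet: tuple[str, str] = DEFAULT_ALPHABET,
) -> list[tuple[int, ...]]:
    """All atom-index tuples matching *composition* within the range cutoff.

    Each unordered tuple appears once, like atoms sorted by index, group of
    the first alphabet element first (consistent with the basis slot order).
    """
    structure.validate_alphabet(alphabet)
    T, rows, cols = _tuple_table(tuple(structure.elements), composition, tuple(alphabet))
    if T.shape[0] == 0:
        return []
    if np.isinf(cutoff):
        return [tuple(t) for t in T]
    D = structure.distance_matrix()
    maxdist = D[rows, cols].max(axis=1) if rows.shape[1] else np.zeros(T.shape[0])
    keep = maxdist <= cutoff
    return [tuple(t) for t in T[keep]]


def _switch(maxdist: np.ndarray, cutoff: float, width: float) -> tuple[np.ndarray, np.ndarray]:
    """Cosine ramp 1 -> 0 over [cutoff - width, cutoff]; returns (s, ds/dmax)."""
    s = np.ones_like(maxdist)
    ds = np.zeros_like(maxdist)
    if width <= 0 or np.isinf(cutoff):
        return s, ds
    x = (maxdist - (cutoff - width)) / width
    ramp = (x > 0) & (x < 1)
    s[ramp] = 0.5 * (1.0 + np.cos(np.pi * x[ramp]))
    ds[ramp] = -0.5 * np.pi * np.sin(np.pi * x[ramp]) / width
    s[x >= 1] = 0.0
    return s, ds


# ----------------------------------------------------------------------------
# the model
# ----------------------------------------------------------------------------


@dataclass
class MBPIPModel:
    """A fitted many-body PIP potential (energies in hartree, lengths in bohr)."""

    specs: list[InteractionSpec]
    coefficients: list[np.ndarray]
    one_body: dict[str, float] | None = None
    energy_offset: float = 0.0
    alphabet: tuple[str, str] = DEFAULT_ALPHABET
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = [np.asarray(c, dtype=float) for c in self.coefficients]
        if len(self.coefficients) != len(self.specs):
            raise ConfigurationError("one coefficient vector per interaction spec required")
        for spec, c in zip(self.specs, self.coefficients):
            nb = spec.basis().n_functions
            if c.shape != (nb,):
                raise ConfigurationError(
                    f"{spec.composition}: coefficient vector length {c.shape} != basis size {nb}"
                )
        self.last_eval_stats: dict = {}

    @property
    def n_coefficients(self) -> int:
        return int(sum(len(c) for c in self.coefficients))

    # -- evaluation ----------------------------------------------------------

    def _tuple_data(self, structure: Structure, spec: InteractionSpec, D: np.ndarray):
        T, rows, cols = _tuple_table(tuple(structure.elements), spec.composition,
                                     tuple(self.alphabet))
        if T.shape[0] == 0:
            return None
        R = D[rows, cols]  # (m, n_edges)
        maxdist = R.max(axis=1)
        keep = maxdist <= spec.cutoff
        if not np.any(keep):
            return None
        return T[keep], rows[keep], cols[keep], R[keep], maxdist[keep]

    def energy(self, structure: Structure, exact_invariance: bool = True) -> float:
        """Total potential energy (hartree).

        ``exact_invariance=True`` (default) accumulates every per-tuple
        contribution in value-sorted order so like-atom relabelling is a
        bitwise no-op; the fast path is used by the fitter/optimizer/MD.
        """
        structure.validate_alphabet(self.alphabet)
        D = structure.distance_matrix()
        contribs: list[np.ndarray] = []
        stats = {}
        for spec, c in zip(self.specs, self.coefficients):
            data = self._tuple_data(structure, spec, D)
            stats[spec.composition] = 0 if data is None else data[0].shape[0]
            if data is None or len(c) == 0:
                continue
            _, _, _, R, maxdist = data
            Y = np.exp(-R / spec.lam)
            B = spec.basis().evaluate_many(Y, exact_invariance=exact_invariance)
            v = B @ c
            s, _ = _switch(maxdist, spec.cutoff, spec.switch_width)
            contribs.append(v * s)
        self.last_eval_stats = {"tuples": stats, "n_tuples": int(sum(stats.values()))}
        total = 0.0
        if contribs:
            allv = np.concatenate(contribs)
            allv = np.sort(allv)
            total = float(np.sum(allv))
        if self.one_body:
            for e in self.alphabet:
                total += self.one_body.get(e, 0.0) * structure.elements.count(e)
        return total + self.energy_offset

    def gradient(self, structure: Structure) -> np.ndarray:
        """Analytic Cartesian gradient dV/dx, shape (N, 3), hartree/bohr."""
        return self.energy_and_gradient(structure)[1]

    def energy_and_gradient(self, structure: Structure) -> tuple[float, np.ndarray]:
        """Fast-path energy and analytic gradient (shared tuple evaluation)."""
        structure.validate_alphabet(self.alphabet)
        x = structure.coords
        D = structure.distance_matrix()
        grad = np.zeros_like(x)
        total = self.energy_offset
        stats = {}
        if self.one_body:
            for e in self.alphabet:
                total += self.one_body.get(e, 0.0) * structure.elements.count(e)
        for spec, c in zip(self.specs, self.coefficients):
            data = self._tuple_data(structure, spec, D)
            stats[spec.composition] = 0 if data is None else data[0].shape[0]
            if data is None or len(c) == 0:
                continue
            _, rows, cols, R, maxdist = data
            basis = spec.basis()
            with np.errstate(divide="ignore"):
                M = np.exp((-R / spec.lam) @ basis._Ef.T)  # member monomials (m, n_members)
            w = basis.member_weights(c)
            v = M @ w  # per-tuple energies
            s, ds = _switch(maxdist, spec.cutoff, spec.switch_width)
            total += float(np.sum(v * s))
            # dV/dr for each edge variable: -(1/lam) sum_members w m E_{.,v}
            dVdr = -((M * w[None, :]) @ basis._Ef) / spec.lam  # (m, n_edges)
            dVdr *= s[:, None]
            if spec.switch_width > 0 and not np.isinf(spec.cutoff):
                # switch derivative acts along the current max edge of each tuple
                argmax = np.argmax(R, axis=1)
                dVdr[np.arange(len(v)), argmax] += v * ds
            vec = x[rows] - x[cols]  # (m, n_edges, 3)
            unit = vec / R[:, :, None]
            contrib = dVdr[:, :, None] * unit
            np.add.at(grad, rows.ravel(), contrib.reshape(-1, 3))
            np.add.at(grad, cols.ravel(), -contrib.reshape(-1, 3))
        self.last_eval_stats = {"tuples": stats, "n_tuples": int(sum(stats.values()))}
        return total, grad

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "element_alphabet": list(self.alphabet),
            "specs": [
                {
                    "composition": s.composition,
                    "lambda_bohr": s.lam,
                    "cutoff_bohr": None if np.isinf(s.cutoff) else s.cutoff,
                    "max_degree": s.max_degree,
                    "connected": s.connected,
                    "switch_width_bohr": s.switch_width,
                    "basis": s.basis().serialize(),
                }
                for s in self.specs
            ],
            "coefficients": [list(map(float, c)) for c in self.coefficients],
            "one_body": self.one_body,
            "energy_offset": self.energy_offset,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MBPIPModel":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValidationError(f"unsupported model schema {d.get('schema_version')!r}")
        alphabet = tuple(d["element_alphabet"])
        specs = [
            InteractionSpec(
                s["composition"],
                lam=s["lambda_bohr"],
                cutoff=np.inf if s["cutoff_bohr"] is None else s["cutoff_bohr"],
                max_degree=s["max_degree"],
                connected=s["connected"],
                switch_width=s.get("switch_width_bohr", 0.0),
                alphabet=alphabet,
            )
            for s in d["specs"]
        ]
        return cls(
            specs=specs,
            coefficients=[np.array(c, dtype=float) for c in d["coefficients"]],
            one_body=d.get("one_body"),
            energy_offset=d.get("energy_offset", 0.0),
            alphabet=alphabet,
            metadata=d.get("metadata", {}),
        )

    def save(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))
        return Path(path)

    @classmethod
    def load(cls, path: str | Path) -> "MBPIPModel":
        return cls.from_dict(json.loads(Path(path).read_text()))
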