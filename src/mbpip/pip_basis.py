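"""Permutationally invariant polynomial (PIP) bases in transformed distances.

A tuple of n atoms (n = 2..4) drawn from a two-element alphabet carries
n(n-1)/2 internuclear-distance variables.  Permuting like atoms permutes
those variable slots; a PIP basis is a list of symmetrized monomials (orbit
sums) that are exactly invariant under that induced permutation group.  Six
symmetry types cover every composition of a two-element molecule:

=========  ========  ===========  ==========================================
type       n atoms   n variables  group acting on the variable slots
=========  ========  ===========  ==========================================
PAIR       2         1            trivial
A3         3         3            S3 on the three edges
A2B        3         3            swap of the two cross edges
A4         4         6            S4 on the six edges of K4
A3B        4         6            simultaneous S3 on (3 like, 3 cross) edges
A2B2       4         6            S2 x S2 on (1, 1, 4 cross) edges
=========  ========  ===========  ==========================================

Two basis conventions are supported.  With ``connected=True`` (the default,
and the convention the many-body model uses) only monomials whose
positive-exponent edge graph connects *all* atoms of the tuple are kept, so
every basis function is a genuine n-body interaction that vanishes whenever
the tuple fragments.  With ``connected=False`` all invariants appear; that
mode is the one whose per-degree counts match the Molien/Burnside counting
oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np

from .io_units import ValidationError

__all__ = [
    "SymmetryType",
    "SymmetrizedMonomial",
    "PIPBasis",
    "SYMMETRY_TYPES",
    "get_symmetry",
    "symmetry_for_composition",
    "generate_basis",
    "evaluate",
    "jacobian",
    "invariant_count_oracle",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """A model/basis specification is internally inconsistent."""


# ----------------------------------------------------------------------------
# symmetry types
# ----------------------------------------------------------------------------


def _edge_list(na: int, nb: int) -> list[tuple[int, int]]:
    """Canonical slot-edge order: like edges of group A, of group B, then cross."""
    n = na + nb
    like_a = [(i, j) for i in range(na) for j in range(i + 1, na)]
    like_b = [(i, j) for i in range(na, n) for j in range(i + 1, n)]
    cross = [(i, j) for i in range(na) for j in range(na, n)]
    return like_a + like_b + cross


def _slot_group(na: int, nb: int) -> tuple[tuple[int, ...], ...]:
    """Permutations of the edge slots induced by permuting like atoms."""
    edges = _edge_list(na, nb)
    eidx = {e: k for k, e in enumerate(edges)}
    perms = set()
    for pa in itertools.permutations(range(na)):
        for pb in itertools.permutations(range(na, na + nb)):
            amap = {**dict(zip(range(na), pa)), **dict(zip(range(na, na + nb), pb))}
            perm = tuple(
                eidx[(min(amap[i], amap[j]), max(amap[i], amap[j]))] for (i, j) in edges
            )
            perms.add(perm)
    return tuple(sorted(perms))


@dataclass(frozen=True)
class SymmetryType:
    """A permutational symmetry class for one atom-tuple composition shape."""

    name: str
    shape: tuple[int, int]  # (n like atoms of kind A, n of kind B), representative
    edges: tuple[tuple[int, int], ...]
    group: tuple[tuple[int, ...], ...]

    @property
    def n_atoms(self) -> int:
        return sum(self.shape)

    @property
    def n_variables(self) -> int:
        return len(self.edges)

    def __repr__(self) -> str:  # compact in error messages
        return f"SymmetryType({self.name})"


def _make_type(name: str, na: int, nb: int) -> SymmetryType:
    return SymmetryType(name, (na, nb), tuple(_edge_list(na, nb)), _slot_group(na, nb))


SYMMETRY_TYPES: dict[str, SymmetryType] = {
    "PAIR": _make_type("PAIR", 1, 1),
    "A3": _make_type("A3", 3, 0),
    "A2B": _make_type("A2B", 2, 1),
    "A4": _make_type("A4", 4, 0),
    "A3B": _make_type("A3B", 3, 1),
    "A2B2": _make_type("A2B2", 2, 2),
}

_SHAPE_TO_NAME = {
    (2, 0): "PAIR", (1, 1): "PAIR", (0, 2): "PAIR",
    (3, 0): "A3", (0, 3): "A3",
    (2, 1): "A2B", (1, 2): "A2B",
    (4, 0): "A4", (0, 4): "A4",
    (3, 1): "A3B", (1, 3): "A3B",
    (2, 2): "A2B2",
}


def get_symmetry(name: str) -> SymmetryType:
    try:
        return SYMMETRY_TYPES[name.upper()]
    except KeyError:
        raise ConfigurationError(
            f"unsupported symmetry type {name!r}; supported: {sorted(SYMMETRY_TYPES)}"
        ) from None


def symmetry_for_composition(
    composition: Sequence[str], alphabet: Sequence[str] = ("C", "H")
) -> tuple[SymmetryType, tuple[int, int]]:
    """Symmetry type and (n_first, n_second) element counts for a composition.

    ``composition`` is e.g. ``"CCH"``; counts follow the alphabet order.
    """
    if len(alphabet) != 2:
        raise ConfigurationError("the typing scheme covers exactly two elements")
    counts = (
        sum(1 for e in composition if e == alphabet[0]),
        sum(1 for e in composition if e == alphabet[1]),
    )
    if counts[0] + counts[1] != len(composition):
        raise ValidationError(f"composition {composition!r} has elements outside {alphabet}")
    try:
        return get_symmetry(_SHAPE_TO_NAME[counts]), counts
    except KeyError:
        raise ConfigurationError(
            f"composition {composition!r} has size {len(composition)}, supported sizes are 2-4"
        ) from None


# ----------------------------------------------------------------------------
# basis generation
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class SymmetrizedMonomial:
    """One orbit of exponent vectors sharing a coefficient (an orbit sum)."""

    orbit: tuple[tuple[int, ...], ...]  # sorted exponent vectors
    degree: int

    @property
    def representative(self) -> tuple[int, ...]:
        return self.orbit[0]


def _monomials_of_degree(n_vars: int, degree: int) -> Iterator[tuple[int, ...]]:
    if n_vars == 1:
        yield (degree,)
        return
    for k in range(degree + 1):
        for rest in _monomials_of_degree(n_vars - 1, degree - k):
            yield (k,) + rest


def _is_connected(exponents: tuple[int, ...], edges, n_atoms: int) -> bool:
    # union-find over atoms through positive-exponent edges
    parent = list(range(n_atoms))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    touched = 0
    for v, e in enumerate(exponents):
        if e > 0:
            a, b = edges[v]
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    roots = {find(a) for a in range(n_atoms)}
    return len(roots) == 1


class PIPBasis:
    """An ordered, evaluated-ready PIP basis for one symmetry type.

    Functions are ordered by (degree, lexicographically smallest exponent
    vector of the orbit), which keeps serialized models deterministic.
    """

    def __init__(self, symmetry: SymmetryType, max_degree: int,
                 functions: Sequence[SymmetrizedMonomial], connected: bool):
        self.symmetry = symmetry
        self.max_degree = max_degree
        self.functions = tuple(functions)
        self.connected = connected
        self._prepare_arrays()

    def _prepare_arrays(self) -> None:
        nv = self.symmetry.n_variables
        members: list[tuple[int, ...]] = []
        orbit_slices: list[tuple[int, int]] = []
        for f in self.functions:
            start = len(members)
            members.extend(f.orbit)
            orbit_slices.append((start, len(members)))
        self._E = np.array(members, dtype=np.int64).reshape(len(members), nv)
        self._Ef = self._E.astype(float)
        self._orbit_slices = orbit_slices
        n_funcs = len(self.functions)
        max_orbit = max((b - a for a, b in orbit_slices), default=1)
        # pad index into a member-value array extended by one zero slot
        pad = np.full((n_funcs, max_orbit), len(members), dtype=np.int64)
        for k, (a, b) in enumerate(orbit_slices):
            pad[k, : b - a] = np.arange(a, b)
        self._pad = pad
        # orbit-sum aggregation matrix (n_funcs x n_members)
        G = np.zeros((n_funcs, len(members)))
        for k, (a, b) in enumerate(orbit_slices):
            G[k, a:b] = 1.0
        self._G = G

    # -- introspection -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.functions)

    @property
    def n_functions(self) -> int:
        return len(self.functions)

    @property
    def n_members(self) -> int:
        return self._E.shape[0]

    @property
    def variable_order(self) -> tuple[tuple[int, int], ...]:
        """Slot convention: like-like edges first, then cross edges."""
        return self.symmetry.edges

    def degrees(self) -> np.ndarray:
        return np.array([f.degree for f in self.functions])

    # -- evaluation ----------------------------------------------------------

    def evaluate_many(self, Y: np.ndarray, exact_invariance: bool = True,
                      chunk: int = 2048) -> np.ndarray:
        """Basis values at many variable vectors, shape (n_points, n_functions).

        With ``exact_invariance`` each monomial is a product of its factors in
        value-sorted order and each orbit is summed in value-sorted order, so
        the result is bitwise identical under any group permutation of the
        variables.  The fast path (``exact_invariance=False``) evaluates
        monomials as exp(E . log y) and is invariant only to round-off; it
        requires y > 0 (true for Morse variables).
        """
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[1] != self.symmetry.n_variables:
            raise ValidationError(
                f"{self.symmetry.name} basis expects {self.symmetry.n_variables} variables, "
                f"got {Y.shape[1]}"
            )
        out = np.empty((Y.shape[0], self.n_functions))
        for lo in range(0, Y.shape[0], chunk):
            yb = Y[lo : lo + chunk]
            if exact_invariance:
                F = np.where(self._E[None, :, :] > 0,
                             np.power(yb[:, None, :], self._E[None, :, :]), 1.0)
                F.sort(axis=2)
                mv = np.prod(F, axis=2)
            else:
                with np.errstate(divide="ignore"):
                    L = np.log(yb)
                mv = np.exp(L @ self._Ef.T)
            padded = np.concatenate([mv, np.zeros((mv.shape[0], 1))], axis=1)[:, self._pad]
            padded.sort(axis=2)
            out[lo : lo + chunk] = padded.sum(axis=2)
        return out

    def evaluate(self, y: np.ndarray) -> np.ndarray:
        """Basis values at one variable vector (exactly permutation invariant)."""
        return self.evaluate_many(np.asarray(y, dtype=float)[None, :])[0]

    def jacobian(self, y: np.ndarray) -> np.ndarray:
        """Exact partials, shape (n_functions, n_variables)."""
        y = np.asarray(y, dtype=float)
        nv = self.symmetry.n_variables
        if y.shape != (nv,):
            raise ValidationError(f"expected a length-{nv} variable vector, got shape {y.shape}")
        maxdeg = int(self._E.max())
        # P[v, k] = y_v**k
        P = np.vander(y, maxdeg + 1, increasing=True)  # (nv, maxdeg+1)
        J = np.zeros((self.n_functions, nv))
        for k, (a, b) in enumerate(self._orbit_slices):
            for m in range(a, b):
                e = self._E[m]
                for v in range(nv):
                    if e[v] == 0:
                        continue
                    term = float(e[v])
                    for w in range(nv):
                        term *= P[w, e[w] - (1 if w == v else 0)]
                    J[k, v] += term
        return J

    # gradient helper used by the many-body model: for coefficient-weighted
    # sums the member weights are G^T c and
    # d(sum_m c_m p_m)/dy_v = sum_members w E_{.,v} monomial / y_v.
    def member_weights(self, coefficients: np.ndarray) -> np.ndarray:
        return self._G.T @ np.asarray(coefficients, dtype=float)

    def serialize(self) -> dict:
        return {
            "symmetry": self.symmetry.name,
            "max_degree": self.max_degree,
            "connected": self.connected,
            "n_functions": self.n_functions,
        }


def generate_basis(symmetry: SymmetryType | str, max_degree: int,
                   connected: bool = True) -> PIPBasis:
    """All symmetrized monomials of total degree 1..max_degree.

    No constant term is included.  Distinct orbits have disjoint monomial
    support, so the functions are linearly independent by construction.
    """
    if isinstance(symmetry, str):
        symmetry = get_symmetry(symmetry)
    if max_degree < 1:
        raise ConfigurationError("max_degree must be >= 1")
    return PIPBasis(symmetry, max_degree,
                    _generate_functions(symmetry, max_degree, connected), connected)


@lru_cache(maxsize=None)
def _generate_functions(symmetry: SymmetryType, max_degree: int,
                        connected: bool) -> tuple[SymmetrizedMonomial, ...]:
    nv = symmetry.n_variables
    funcs: list[SymmetrizedMonomial] = []
    seen: set[tuple[int, ...]] = set()
    for d in range(1, max_degree + 1):
        reps: list[SymmetrizedMonomial] = []
        for m in _monomials_of_degree(nv, d):
            if m in seen:
                continue
            orbit = sorted({tuple(m[g[v]] for v in range(nv)) for g in symmetry.group})
            seen.update(orbit)
            if connected and not _is_connected(m, symmetry.edges, symmetry.n_atoms):
                continue
            reps.append(SymmetrizedMonomial(tuple(orbit), d))
        reps.sort(key=lambda f: f.representative)
        funcs.extend(reps)
    return tuple(funcs)


def evaluate(basis: PIPBasis, y: np.ndarray) -> np.ndarray:
    """Functional form of :meth:`PIPBasis.evaluate`."""
    return basis.evaluate(y)


def jacobian(basis: PIPBasis, y: np.ndarray) -> np.ndarray:
    """Functional form of :meth:`PIPBasis.jacobian`."""
    return basis.jacobian(y)


# ----------------------------------------------------------------------------
# counting oracle
# ----------------------------------------------------------------------------


def invariant_count_oracle(symmetry: SymmetryType | str, degree: int) -> int:
    """Number of linearly independent invariants of exactly *degree*.

    Burnside/Molien averaging: for each group element the monomials it fixes
    are those with exponents constant on its cycles, counted by the truncated
    series prod_cycles 1/(1 - x^len).  This is independent of the orbit
    enumeration used by :func:`generate_basis` (connected=False mode).
    """
    if isinstance(symmetry, str):
        symmetry = get_symmetry(symmetry)
    if degree < 0:
        raise ConfigurationError("degree must be >= 0")
    total = 0
    for g in symmetry.group:
        series = np.zeros(degree + 1)
        series[0] = 1.0
        for clen in _cycle_lengths(g):
            geom = np.zeros(degree + 1)
            geom[::clen] = 1.0  # 1 + x^c + x^2c + ...
            series = np.convolve(series, geom)[: degree + 1]
        total += series[degree]
    count = total / len(symmetry.group)
    rounded = int(round(count))
    assert abs(count - rounded) < 1e-9, "Burnside average must be an integer"
    return rounded


def _cycle_lengths(perm: tuple[int, ...]) -> list[int]:
    seen = [False] * len(perm)
    out = []
    for start in range(len(perm)):
        if seen[start]:
            continue
        length = 0
        x = start
        while not seen[x]:
            seen[x] = True
            x = perm[x]
            length += 1
        out.append(length)
    return out
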