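"""Alkane-like chain builder and a fully specified two-level toy potential.

The toy reference emulates the physics that motivates delta-corrections on
real alkane surfaces: a "low" level with bonds, angles, backbone torsions
and a short-range repulsive core but *no* dispersion, and a "high" level
that adds an attractive, damped r^-6 dispersion over atom pairs at least
three bonds apart.  The repulsive r^-12 core is shared by both levels, so
the difference high - low is exactly the dispersion sum — the only driver
of chain folding — and hairpin stabilization grows with chain length on the
high surface only, while the core makes folding cost energy on the low
surface.  (Without the shared core an attractive-only nonbonded term lets
chains collapse onto themselves under minimization, which is unusable as a
conformational testbed.)  All constants are frozen fixtures chosen for
qualitative realism, not fitted to anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .io_units import (
    BOHR_PER_ANGSTROM,
    HARTREE_PER_KCALMOL,
    Dataset,
    Structure,
    ValidationError,
)

__all__ = [
    "ChainBuilderParams",
    "ToyPotentialSpec",
    "ToyPotential",
    "build_chain",
    "toy_energy",
    "perturb",
    "label_dataset",
    "make_toy_dataset",
    "TOY_CONSTANTS",
]

_A = BOHR_PER_ANGSTROM  # angstrom -> bohr
_K = HARTREE_PER_KCALMOL  # kcal/mol -> hartree

TETRAHEDRAL = float(np.arccos(-1.0 / 3.0))

# frozen toy-potential fixture constants (converted to atomic units)
TOY_CONSTANTS = {
    "k_bond": 300.0 * _K / _A**2,          # hartree/bohr^2
    "r0": {"CC": 1.54 * _A, "CH": 1.09 * _A},
    "k_angle": 60.0 * _K,                   # hartree/rad^2
    "theta0": TETRAHEDRAL,
    "v3": 3.0 * _K,                         # backbone torsion barrier
    "c6": {"CC": 1200.0 * _K * _A**6, "CH": 330.0 * _K * _A**6, "HH": 90.0 * _K * _A**6},
    "d_damp": 1.2 * _A,
    "min_bond_separation": 3,               # nonbonded terms act on pairs >= 3 bonds apart
    # contact distances for the r^-12 core shared by BOTH levels; C12 = C6 rm^6 / 2
    # puts the pair minimum near rm with LJ-like well depths of ~0.1 kcal/mol
    "rmin": {"CC": 4.0 * _A, "CH": 3.4 * _A, "HH": 2.9 * _A},
}

# hairpin turn template (degrees): the gauche-gauche-anti-gauche-gauche
# adjacent-reentry fold, the standard tight U-turn motif for alkane chains.
# All-gauche four-dihedral turns kink the chain without folding it back.
HAIRPIN_TURN = (60.0, 60.0, 180.0, 60.0, 60.0)


@dataclass(frozen=True)
class ChainBuilderParams:
    """Geometry template parameters for C_n H_{2n+2} chains."""

    n_carbons: int
    conformation: str = "linear"  # or "hairpin"
    r_cc: float = 1.54 * _A
    r_ch: float = 1.09 * _A
    angle: float = TETRAHEDRAL


def _place_nerf(a, b, c, bond, angle, dihedral):
    """Place atom d with |d-c|=bond, angle(d,c,b)=angle, dihedral(d,c,b,a)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:  # collinear reference: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_chain(
    n_carbons: int,
    conformation: str = "linear",
    params: ChainBuilderParams | None = None,
    backbone_dihedrals=None,
) -> Structure:
    """Deterministic C_n H_{2n+2} template geometry with its bond graph.

    Linear chains use all-anti (180 deg) backbone dihedrals; hairpins insert
    the gauche-rich U-turn of :data:`HAIRPIN_TURN` mid-chain (requires n >= 8).
    ``backbone_dihedrals`` (degrees, length n-3) overrides the template's
    dihedral list, e.g. for gauche-defect conformers or partially folded
    chains.
    """
    if params is None:
        params = ChainBuilderParams(n_carbons, conformation)
    n = n_carbons
    if n < 2:
        raise ValidationError("need at least two carbons")
    if conformation not in ("linear", "hairpin"):
        raise ValidationError(f"unknown conformation {conformation!r}")
    if conformation == "hairpin" and n < 8 and backbone_dihedrals is None:
        raise ValidationError("the hairpin turn template requires n >= 8")

    n_dihedrals = n - 3
    dihedrals = np.full(max(n_dihedrals, 0), 180.0)
    if backbone_dihedrals is not None:
        if len(backbone_dihedrals) != n_dihedrals:
            raise ValidationError(f"need {n_dihedrals} backbone dihedrals, "
                                  f"got {len(backbone_dihedrals)}")
        dihedrals[:] = backbone_dihedrals
    elif conformation == "hairpin":
        start = max(0, (n_dihedrals - len(HAIRPIN_TURN)) // 2)
        dihedrals[start : start + len(HAIRPIN_TURN)] = HAIRPIN_TURN

    rcc, rch, ang = params.r_cc, params.r_ch, params.angle
    carbons = np.zeros((n, 3))
    carbons[1] = [rcc, 0.0, 0.0]
    if n > 2:
        carbons[2] = _place_nerf(
            carbons[0] + np.array([0.0, 1.0, 0.0]), carbons[0], carbons[1],
            rcc, ang, np.deg2rad(0.0),
        )
    for i in range(3, n):
        carbons[i] = _place_nerf(
            carbons[i - 3], carbons[i - 2], carbons[i - 1],
            rcc, ang, np.deg2rad(dihedrals[i - 3]),
        )

    elements: list[str] = ["C"] * n
    coords: list[np.ndarray] = list(carbons)
    bonds: list[tuple[int, int]] = [(i, i + 1) for i in range(n - 1)]

    def add_h(pos, carbon_idx):
        elements.append("H")
        coords.append(pos)
        bonds.append((carbon_idx, len(coords) - 1))

    half_hch = 0.5 * TETRAHEDRAL
    for i in range(n):
        nbrs = [j for j in (i - 1, i + 1) if 0 <= j < n]
        if len(nbrs) == 2:  # CH2: two hydrogens out of the C-C-C plane
            u1 = carbons[nbrs[0]] - carbons[i]
            u2 = carbons[nbrs[1]] - carbons[i]
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            bis = -(u1 + u2)
            bis /= np.linalg.norm(bis)
            perp = np.cross(u1, u2)
            perp /= np.linalg.norm(perp)
            for sgn in (+1.0, -1.0):
                direction = np.cos(half_hch) * bis + sgn * np.sin(half_hch) * perp
                add_h(carbons[i] + rch * direction, i)
        else:  # terminal CH3, staggered with respect to the next-next carbon
            j = nbrs[0]
            k = j + (j - i)  # carbon two bonds away, if it exists
            if 0 <= k < n:
                ref = carbons[k]
            else:  # ethane: arbitrary fixed reference
                ref = carbons[j] + np.array([0.0, 1.0, 0.0])
            for phi in (180.0, 60.0, -60.0):
                add_h(_place_nerf(ref, carbons[j], carbons[i], rch, ang, np.deg2rad(phi)), i)

    s = Structure(
        tuple(elements), np.array(coords), bonds=tuple(bonds),
        provenance_tag=f"builder:{conformation}:C{n}",
    )
    dmin = _min_distance(s)
    if dmin < 0.9 * _A:
        raise ValidationError(
            f"template clash: minimum interatomic distance {dmin / _A:.3f} A < 0.9 A"
        )
    return s


def _min_distance(s: Structure) -> float:
    D = s.distance_matrix()
    return float(D[np.triu_indices(s.n_atoms, 1)].min())


# ----------------------------------------------------------------------------
# toy potential
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyPotentialSpec:
    """Level selector for the toy surface: 'low' omits dispersion."""

    level: str = "high"

    def __post_init__(self):
        if self.level not in ("high", "low"):
            raise ValidationError("level must be 'high' or 'low'")


@lru_cache(maxsize=64)
def _topology(elements: tuple[str, ...], bonds: tuple[tuple[int, int], ...]):
    """Bond/angle/backbone-torsion/dispersion-pair lists for one bond graph."""
    n = len(elements)
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)

    bond_ij = np.array(bonds, dtype=np.int64)
    bond_r0 = np.array(
        [TOY_CONSTANTS["r0"]["CC" if elements[a] == elements[b] == "C" else "CH"]
         for a, b in bonds]
    )

    angles = []
    for j in range(n):
        nb = sorted(adj[j])
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                angles.append((nb[x], j, nb[y]))
    angles = np.array(angles, dtype=np.int64).reshape(-1, 3)

    # backbone torsions: consecutive quadruples along the carbon chain
    carbons = [i for i, e in enumerate(elements) if e == "C"]
    cadj = {i: [j for j in adj[i] if elements[j] == "C"] for i in carbons}
    torsions = []
    ends = [i for i in carbons if len(cadj[i]) == 1]
    if len(carbons) >= 4 and ends:
        path = [min(ends)]
        prev = -1
        while True:
            nxt = [j for j in cadj[path[-1]] if j != prev]
            if not nxt:
                break
            prev = path[-1]
            path.append(nxt[0])
        for i in range(len(path) - 3):
            torsions.append(tuple(path[i : i + 4]))
    torsions = np.array(torsions, dtype=np.int64).reshape(-1, 4)

    # dispersion pairs: bond-graph distance >= 3
    data = np.ones(len(bonds))
    graph = csr_matrix((data, (bond_ij[:, 0], bond_ij[:, 1])), shape=(n, n))
    hops = shortest_path(graph, method="D", directed=False, unweighted=True)
    pairs = []
    c6 = []
    c12 = []
    for i in range(n):
        for j in range(i + 1, n):
            if hops[i, j] >= TOY_CONSTANTS["min_bond_separation"]:
                pairs.append((i, j))
                key = "".join(sorted(elements[i] + elements[j]))
                key = "CC" if key == "CC" else "HH" if key == "HH" else "CH"
                c6.append(TOY_CONSTANTS["c6"][key])
                c12.append(0.5 * TOY_CONSTANTS["c6"][key] * TOY_CONSTANTS["rmin"][key] ** 6)
    pairs = np.array(pairs, dtype=np.int64).reshape(-1, 2)
    return bond_ij, bond_r0, angles, torsions, pairs, np.array(c6), np.array(c12)


class ToyPotential:
    """Analytic toy surface with energies in hartree and lengths in bohr.

    Requires structures that carry a bond graph (the chain builder attaches
    one, and perturbed copies inherit it).
    """

    def __init__(self, level: str = "high"):
        self.spec = ToyPotentialSpec(level)

    @property
    def level(self) -> str:
        return self.spec.level

    def _topo(self, structure: Structure):
        if structure.bonds is None:
            raise ValidationError("toy potential needs a structure with a bond graph")
        return _topology(tuple(structure.elements), tuple(structure.bonds))

    def energy(self, structure: Structure) -> float:
        return self.energy_and_gradient(structure)[0]

    def gradient(self, structure: Structure) -> np.ndarray:
        return self.energy_and_gradient(structure)[1]

    def dispersion_energy(self, structure: Structure) -> float:
        """The damped r^-6 sum alone (== high minus low, exactly)."""
        _, _, _, _, pairs, c6, _ = self._topo(structure)
        if len(pairs) == 0:
            return 0.0
        x = structure.coords
        d = x[pairs[:, 0]] - x[pairs[:, 1]]
        r2 = np.sum(d * d, axis=1)
        r6 = r2 * r2 * r2
        return float(np.sum(-c6 / (r6 + TOY_CONSTANTS["d_damp"] ** 6)))

    def energy_and_gradient(self, structure: Structure) -> tuple[float, np.ndarray]:
        bond_ij, bond_r0, angles, torsions, pairs, c6, c12 = self._topo(structure)
        x = structure.coords
        grad = np.zeros_like(x)
        e = 0.0

        # bonds: k (r - r0)^2
        d = x[bond_ij[:, 0]] - x[bond_ij[:, 1]]
        r = np.linalg.norm(d, axis=1)
        dr = r - bond_r0
        kb = TOY_CONSTANTS["k_bond"]
        e += float(np.sum(kb * dr * dr))
        f = (2.0 * kb * dr / r)[:, None] * d
        np.add.at(grad, bond_ij[:, 0], f)
        np.add.at(grad, bond_ij[:, 1], -f)

        # angles: k (theta - theta0)^2
        if len(angles):
            u = x[angles[:, 0]] - x[angles[:, 1]]
            v = x[angles[:, 2]] - x[angles[:, 1]]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            cos = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
            sin = np.sqrt(np.clip(1.0 - cos * cos, 1e-16, None))
            theta = np.arccos(cos)
            ka = TOY_CONSTANTS["k_angle"]
            dtheta = theta - TOY_CONSTANTS["theta0"]
            e += float(np.sum(ka * dtheta * dtheta))
            dEdt = 2.0 * ka * dtheta
            gi = (dEdt / (nu * sin))[:, None] * (cos[:, None] * uh - vh)
            gk = (dEdt / (nv * sin))[:, None] * (cos[:, None] * vh - uh)
            np.add.at(grad, angles[:, 0], gi)
            np.add.at(grad, angles[:, 2], gk)
            np.add.at(grad, angles[:, 1], -(gi + gk))

        # backbone torsions: (V3/2)(1 + cos 3 phi)
        if len(torsions):
            b1 = x[torsions[:, 1]] - x[torsions[:, 0]]
            b2 = x[torsions[:, 2]] - x[torsions[:, 1]]
            b3 = x[torsions[:, 3]] - x[torsions[:, 2]]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            phi = np.arctan2(
                np.sum(np.cross(n1, n2) * (b2 / nb2[:, None]), axis=1),
                np.sum(n1 * n2, axis=1),
            )
            v3 = TOY_CONSTANTS["v3"]
            e += float(np.sum(0.5 * v3 * (1.0 + np.cos(3.0 * phi))))
            dEdphi = -1.5 * v3 * np.sin(3.0 * phi)
            sq1 = np.sum(n1 * n1, axis=1)
            sq2 = np.sum(n2 * n2, axis=1)
            gi = (-nb2 / sq1)[:, None] * n1
            gl = (nb2 / sq2)[:, None] * n2
            p12 = np.sum(b1 * b2, axis=1) / (nb2 * nb2)
            p32 = np.sum(b3 * b2, axis=1) / (nb2 * nb2)
            gj = -(1.0 + p12)[:, None] * gi + p32[:, None] * gl
            gk = p12[:, None] * gi - (1.0 + p32)[:, None] * gl
            for col, g in zip(range(4), (gi, gj, gk, gl)):
                np.add.at(grad, torsions[:, col], dEdphi[:, None] * g)

        # nonbonded pairs: repulsive core C12/r^12 on BOTH levels (so that the
        # high-low difference stays exactly the dispersion sum), plus the
        # damped dispersion -C6/(r^6 + d^6) on the high level only
        if len(pairs):
            dvec = x[pairs[:, 0]] - x[pairs[:, 1]]
            r2 = np.sum(dvec * dvec, axis=1)
            r6 = r2 * r2 * r2
            r12 = r6 * r6
            e += float(np.sum(c12 / r12))
            coef = -12.0 * c12 / (r12 * r2)  # = (dE/dr)/r for the core
            if self.spec.level == "high":
                denom = r6 + TOY_CONSTANTS["d_damp"] ** 6
                e += float(np.sum(-c6 / denom))
                coef = coef + 6.0 * c6 * r2 * r2 / (denom * denom)
            f = coef[:, None] * dvec
            np.add.at(grad, pairs[:, 0], f)
            np.add.at(grad, pairs[:, 1], -f)

        return e, grad


def toy_energy(spec: ToyPotentialSpec | str, structure: Structure) -> float:
    """Energy of *structure* on the requested toy level."""
    level = spec if isinstance(spec, str) else spec.level
    return ToyPotential(level).energy(structure)


# ----------------------------------------------------------------------------
# sampling helpers
# ----------------------------------------------------------------------------


def perturb(structure: Structure, sigma: float, n: int, seed: int) -> Dataset:
    """n copies with i.i.d. Gaussian Cartesian displacements (sigma in bohr)."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    frames = [
        structure.with_coords(
            structure.coords + rng.normal(0.0, sigma, structure.coords.shape)
            if sigma > 0 else structure.coords.copy(),
            provenance_tag="displacement",
        )
        for _ in range(n)
    ]
    return Dataset(frames)


def label_dataset(dataset: Dataset, potential) -> Dataset:
    """Attach potential energies as frame labels (in place; returns dataset)."""
    for f in dataset.frames:
        f.label_energy = potential.energy(f)
    return dataset


def make_toy_dataset(
    n_carbons: int,
    level: str = "high",
    n_frames: int = 100,
    sigma: float = 0.05 * _A,
    seed: int = 0,
    conformations: tuple[str, ...] = ("linear",),
) -> Dataset:
    """Labelled toy dataset: perturbed copies of template conformers."""
    pot = ToyPotential(level)
    out = Dataset()
    for k, conf in enumerate(conformations):
        base = build_chain(n_carbons, conf)
        out.extend(perturb(base, sigma, n_frames, seed + k).frames)
    return label_dataset(out, pot)
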