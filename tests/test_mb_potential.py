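import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mbpip.io_units import Structure, ValidationError
from mbpip.mb_potential import (
    InteractionSpec,
    MBPIPModel,
    default_interaction_specs,
    enumerate_tuples,
    morse,
)
from mbpip.pip_basis import ConfigurationError


class TestEnumerateTuples:
    def test_c14h30_pair_count(self, rng):
        s = Structure(tuple(["C"] * 14 + ["H"] * 30), rng.normal(0, 5, (44, 3)))
        total = sum(len(enumerate_tuples(s, c)) for c in ("CC", "CH", "HH"))
        assert total == math.comb(44, 2) == 946

    def test_zero_cutoff_empty(self, rng):
        s = Structure(("C", "C", "H"), rng.normal(0, 2, (3, 3)))
        assert enumerate_tuples(s, "CC", cutoff=1e-12) == []

    def test_methane_chh_brute_force(self, rng):
        s = Structure(("C", "H", "H", "H", "H"), rng.normal(0, 2, (5, 3)))
        got = enumerate_tuples(s, "CHH")
        assert len(got) == math.comb(4, 2)
        # canonical order: carbon slot first, hydrogens sorted
        for t in got:
            assert s.elements[t[0]] == "C" and t[1] < t[2]

    @pytest.mark.parametrize("n_c,n_h,order", [(3, 5, 3), (2, 4, 4)])
    def test_total_tuple_count_formula(self, rng, n_c, n_h, order):
        """Summed over compositions of one order, counts equal C(N, n)."""
        els = tuple(["C"] * n_c + ["H"] * n_h)
        s = Structure(els, rng.normal(0, 4, (len(els), 3)))
        comps = {3: ("CCC", "CCH", "CHH", "HHH"),
                 4: ("CCCC", "CCCH", "CCHH", "CHHH", "HHHH")}[order]
        total = sum(len(enumerate_tuples(s, c)) for c in comps)
        assert total == math.comb(len(els), order)

    def test_cutoff_filters_by_max_internal_distance(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [5, 0, 0.0]])
        s = Structure(("C", "C", "C"), coords)
        assert len(enumerate_tuples(s, "CCC", cutoff=10.0)) == 1
        assert len(enumerate_tuples(s, "CCC", cutoff=2.0)) == 0
        assert len(enumerate_tuples(s, "CC", cutoff=2.0)) == 1


class TestMorse:
    def test_closed_form_points(self):
        assert morse(0.0, 2.0) == 1.0
        assert morse(2.0, 2.0) == pytest.approx(np.exp(-1.0))
        assert morse(1e6, 2.0) == pytest.approx(0.0, abs=1e-300)

    def test_monotone_decreasing(self):
        r = np.linspace(0, 10, 50)
        y = morse(r, 1.7)
        assert np.all(np.diff(y) < 0) and np.all((y > 0) & (y <= 1))

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ConfigurationError):
            morse(1.0, 0.0)
        with pytest.raises(ConfigurationError):
            InteractionSpec("CC", lam=-1.0)


class TestEnergy:
    def test_zero_coefficients_zero_energy(self, random_structure):
        specs = default_interaction_specs(orders={2: 3, 3: 2, 4: 2})
        m = MBPIPModel(specs, [np.zeros(s.basis().n_functions) for s in specs])
        assert m.energy(random_structure) == 0.0
        assert np.all(m.gradient(random_structure) == 0.0)

    def test_diatomic_closed_form(self):
        spec = InteractionSpec("CH", lam=2.0, max_degree=4)
        c = np.array([0.3, -0.2, 0.05, 0.01])
        m = MBPIPModel([spec], [c])
        r = 2.7
        s = Structure(("C", "H"), np.array([[0, 0, 0], [r, 0, 0.0]]))
        y = np.exp(-r / 2.0)
        assert m.energy(s) == pytest.approx(sum(ck * y ** (k + 1) for k, ck in enumerate(c)))

    def test_like_atom_swap_is_bitwise_noop(self, random_small_model, random_structure):
        e0 = random_small_model.energy(random_structure)
        perm = [0, 1, 2, 5, 4, 3, 7, 6]  # swap H pairs
        swapped = Structure(
            tuple(random_structure.elements[i] for i in perm),
            random_structure.coords[perm],
        )
        assert random_small_model.energy(swapped) == e0

    def test_rigid_motion_invariance(self, random_small_model, random_structure, rng):
        e0 = random_small_model.energy(random_structure)
        for k in range(5):
            R = Rotation.random(random_state=k).as_matrix()
            t = rng.normal(0, 10, 3)
            moved = random_structure.with_coords(random_structure.coords @ R.T + t)
            assert abs(random_small_model.energy(moved) - e0) < 1e-10

    def test_alphabet_violation_rejected(self, random_small_model):
        s = Structure(("N", "H"), np.array([[0, 0, 0], [1, 0, 0.0]]))
        with pytest.raises(ValidationError):
            random_small_model.energy(s)

    def test_one_body_offsets_count_atoms(self, random_structure):
        specs = default_interaction_specs(orders={2: 2})
        m = MBPIPModel(specs, [np.zeros(2)] * 3, one_body={"C": 0.5, "H": -0.25})
        assert m.energy(random_structure) == pytest.approx(3 * 0.5 - 5 * 0.25)


class TestGradient:
    def test_matches_finite_differences(self, random_small_model, random_structure):
        e, g = random_small_model.energy_and_gradient(random_structure)
        h = 1e-5
        x = random_structure.coords
        for i, k in [(0, 0), (3, 1), (7, 2), (4, 0)]:
            xp, xm = x.copy(), x.copy()
            xp[i, k] += h
            xm[i, k] -= h
            fd = (
                random_small_model.energy_and_gradient(random_structure.with_coords(xp))[0]
                - random_small_model.energy_and_gradient(random_structure.with_coords(xm))[0]
            ) / (2 * h)
            assert g[i, k] == pytest.approx(fd, rel=1e-6, abs=1e-10)

    def test_translation_invariance_zero_net_force(self, random_small_model, random_structure):
        g = random_small_model.gradient(random_structure)
        assert np.abs(g.sum(axis=0)).max() < 1e-10

    def test_net_torque_vanishes(self, random_small_model, random_structure):
        g = random_small_model.gradient(random_structure)
        torque = np.cross(random_structure.coords, -g).sum(axis=0)
        assert np.abs(torque).max() < 1e-10

    def test_cost_scales_with_surviving_tuples(self, rng):
        """Operation-count contract: evaluation touches exactly the tuples
        inside the cutoff, so the instrumented count drops with the cutoff."""
        spec_wide = InteractionSpec("CC", cutoff=np.inf, max_degree=3)
        spec_narrow = InteractionSpec("CC", cutoff=3.0, max_degree=3)
        coords = np.arange(6)[:, None] * np.array([2.0, 0, 0])
        s = Structure(("C",) * 6, coords)
        m1 = MBPIPModel([spec_wide], [np.ones(3)])
        m1.energy(s)
        wide = m1.last_eval_stats["n_tuples"]
        m2 = MBPIPModel([spec_narrow], [np.ones(3)])
        m2.energy(s)
        narrow = m2.last_eval_stats["n_tuples"]
        assert wide == 15 and narrow == 5  # only nearest-neighbour pairs survive


class TestSerialization:
    def test_bit_exact_round_trip(self, random_small_model, random_structure, tmp_path):
        p = tmp_path / "model.json"
        random_small_model.save(p)
        again = MBPIPModel.load(p)
        assert again.energy(random_structure) == random_small_model.energy(random_structure)
        for a, b in zip(again.coefficients, random_small_model.coefficients):
            np.testing.assert_array_equal(a, b)

    def test_schema_version_checked(self, random_small_model, tmp_path):
        d = random_small_model.to_dict()
        d["schema_version"] = 99
        with pytest.raises(ValidationError):
            MBPIPModel.from_dict(d)

    def test_coefficient_length_validated(self):
        spec = InteractionSpec("CC", max_degree=4)
        with pytest.raises(ConfigurationError):
            MBPIPModel([spec], [np.zeros(3)])


def test_smooth_switch_continuity():
    """With a switching window the pair energy ramps to zero at the cutoff."""
    spec = InteractionSpec("CC", lam=2.0, cutoff=6.0, max_degree=2, switch_width=1.0)
    m = MBPIPModel([spec], [np.array([1.0, 0.5])])

    def e(r):
        return m.energy(Structure(("C", "C"), np.array([[0, 0, 0], [r, 0, 0.0]])))

    assert e(4.9) == pytest.approx(np.exp(-4.9 / 2) + 0.5 * np.exp(-4.9), rel=1e-12)
    assert abs(e(5.999)) < 1e-3  # nearly off at the cutoff
    assert e(6.01) == 0.0
    mid = e(5.5)
    assert 0 < mid < e(5.0)
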