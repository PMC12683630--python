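import numpy as np
import pytest

from mbpip.io_units import BOHR_PER_ANGSTROM, ValidationError
from mbpip.synthetic import (
    ToyPotential,
    build_chain,
    label_dataset,
    perturb,
    toy_energy,
)

A = BOHR_PER_ANGSTROM


class TestBuilder:
    @pytest.mark.parametrize("n", [2, 4, 14])
    def test_formula(self, n):
        s = build_chain(n, "linear")
        assert s.elements.count("C") == n
        assert s.elements.count("H") == 2 * n + 2
        assert s.n_atoms == 3 * n + 2

    def test_linear_backbone_is_all_anti(self):
        s = build_chain(14, "linear")
        c = s.coords[:14]
        for i in range(11):
            b1, b2, b3 = c[i + 1] - c[i], c[i + 2] - c[i + 1], c[i + 3] - c[i + 2]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            phi = np.degrees(np.arctan2(
                np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)), np.dot(n1, n2)))
            assert abs(abs(phi) - 180.0) < 1e-6

    def test_deterministic(self):
        a, b = build_chain(10, "hairpin"), build_chain(10, "hairpin")
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_no_clashes(self):
        for n, conf in [(8, "hairpin"), (20, "hairpin"), (20, "linear")]:
            s = build_chain(n, conf)
            d = s.distance_matrix()[np.triu_indices(3 * n + 2, 1)]
            assert d.min() >= 0.9 * A

    def test_hairpin_needs_eight_carbons(self):
        with pytest.raises(ValidationError):
            build_chain(6, "hairpin")

    def test_hairpin_folds_back(self):
        s = build_chain(14, "hairpin")
        lin = build_chain(14, "linear")
        def end_to_end(x):
            c = x.coords[:14]
            return np.linalg.norm(c[-1] - c[0])
        assert end_to_end(s) < 0.45 * end_to_end(lin)

    def test_custom_dihedrals(self):
        s = build_chain(6, "linear", backbone_dihedrals=[60, 180, 180])
        assert s.n_atoms == 20
        with pytest.raises(ValidationError):
            build_chain(6, "linear", backbone_dihedrals=[180, 180])


class TestToyPotential:
    def test_high_minus_low_is_exactly_dispersion(self, octane_hairpin, rng):
        ph, pl = ToyPotential("high"), ToyPotential("low")
        for _ in range(5):
            s = octane_hairpin.with_coords(
                octane_hairpin.coords + rng.normal(0, 0.2, octane_hairpin.coords.shape))
            # by construction the high level adds the dispersion sum as the
            # final term, so this identity is bitwise
            assert ph.energy(s) == pl.energy(s) + ph.dispersion_energy(s)

    def test_isolated_pair_dispersion_closed_form(self):
        # two atoms >= 3 bonds apart in a butane chain: C1 and C4
        s = build_chain(4, "linear")
        ph = ToyPotential("high")
        from mbpip.synthetic import TOY_CONSTANTS

        r = np.linalg.norm(s.coords[0] - s.coords[3])
        expected = -TOY_CONSTANTS["c6"]["CC"] / (r**6 + TOY_CONSTANTS["d_damp"] ** 6)
        # dispersion_energy sums all >=3-bond pairs; isolate CC(1,4) by
        # comparing against the direct pair formula through a 2-atom probe
        pairs_total = ph.dispersion_energy(s)
        assert pairs_total < expected  # the full sum is more negative than one pair

    @pytest.mark.parametrize("level", ["low", "high"])
    def test_gradient_matches_finite_differences(self, level, octane_hairpin, rng):
        pot = ToyPotential(level)
        s = octane_hairpin.with_coords(
            octane_hairpin.coords + rng.normal(0, 0.1, octane_hairpin.coords.shape))
        e, g = pot.energy_and_gradient(s)
        h = 1e-6
        idx = [(0, 0), (3, 1), (7, 2), (12, 0), (25, 1)]
        for i, k in idx:
            xp, xm = s.coords.copy(), s.coords.copy()
            xp[i, k] += h
            xm[i, k] -= h
            fd = (pot.energy(s.with_coords(xp)) - pot.energy(s.with_coords(xm))) / (2 * h)
            assert g[i, k] == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_energy_invariances(self, octane_hairpin, rng):
        from scipy.spatial.transform import Rotation

        pot = ToyPotential("high")
        e0 = pot.energy(octane_hairpin)
        R = Rotation.random(random_state=1).as_matrix()
        moved = octane_hairpin.with_coords(octane_hairpin.coords @ R.T + rng.normal(0, 5, 3))
        assert abs(pot.energy(moved) - e0) < 1e-10

    def test_missing_bond_graph_rejected(self, random_structure):
        with pytest.raises(ValidationError):
            ToyPotential("low").energy(random_structure)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValidationError):
            ToyPotential("medium")

    def test_toy_energy_functional_form(self, butane):
        assert toy_energy("high", butane) == ToyPotential("high").energy(butane)


@pytest.fixture(scope="module")
def gaps():
    from mbpip.conformers import minimize

    ph, pl = ToyPotential("high"), ToyPotential("low")
    out = {}
    for n in (8, 12, 16):
        lin_h = minimize(ph, build_chain(n, "linear"), gtol=1e-7).structure
        hp_h = minimize(ph, build_chain(n, "hairpin"), gtol=1e-7).structure
        lin_l = minimize(pl, build_chain(n, "linear"), gtol=1e-7).structure
        hp_l = minimize(pl, build_chain(n, "hairpin"), gtol=1e-7).structure
        out[n] = (
            ph.energy(hp_h) - ph.energy(lin_h),
            pl.energy(hp_l) - pl.energy(lin_l),
        )
    return out


class TestFoldingPhysics:
    """The dispersionless level must penalize folding; dispersion must reward
    it increasingly with chain length (evaluated at each level's own optimized
    geometries)."""

    def test_low_level_always_prefers_linear(self, gaps):
        for n, (gh, gl) in gaps.items():
            assert gl > 0

    def test_dispersion_stabilizes_hairpin(self, gaps):
        for n, (gh, gl) in gaps.items():
            assert gh < gl

    def test_high_level_gap_decreases_with_length(self, gaps):
        gh = [gaps[n][0] for n in (8, 12, 16)]
        assert gh[0] > gh[1] > gh[2]
        assert gh[2] < 0  # hairpin favored for long chains


class TestPerturb:
    def test_zero_sigma_identical_copies(self, butane):
        ds = perturb(butane, 0.0, 3, seed=1)
        for f in ds:
            np.testing.assert_array_equal(f.coords, butane.coords)

    def test_seed_determinism(self, butane):
        a = perturb(butane, 0.1, 5, seed=42)
        b = perturb(butane, 0.1, 5, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.coords, y.coords)

    def test_sample_standard_deviation(self, butane):
        sigma = 0.07
        ds = perturb(butane, sigma, 2000, seed=3)
        disp = np.concatenate([(f.coords - butane.coords).ravel() for f in ds])
        assert np.std(disp) == pytest.approx(sigma, rel=0.02)

    def test_bond_graph_carried(self, butane):
        ds = perturb(butane, 0.05, 2, seed=0)
        assert ds[0].bonds == butane.bonds
        label_dataset(ds, ToyPotential("low"))
        assert all(np.isfinite(f.label_energy) for f in ds)

    def test_negative_sigma_rejected(self, butane):
        with pytest.raises(ValidationError):
            perturb(butane, -0.1, 1, seed=0)
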