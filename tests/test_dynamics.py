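import numpy as np
import pytest

from mbpip.dynamics import (
    AMU_TO_AU,
    MDState,
    Trajectory,
    init_velocities,
    masses_au,
    power_spectrum,
    run_nve,
    target_energy,
)
from mbpip.io_units import KB_HARTREE_PER_K, Structure, ValidationError
from mbpip.synthetic import ToyPotential, build_chain


class ZeroForce:
    def energy_and_gradient(self, s):
        return 0.0, np.zeros_like(s.coords)

    def energy(self, s):
        return 0.0


class Harmonic1D:
    """Two atoms coupled by V = 1/2 k (r - r0)^2."""

    def __init__(self, k=0.2, r0=2.0):
        self.k, self.r0 = k, r0

    def energy_and_gradient(self, s):
        v = s.coords[1] - s.coords[0]
        r = np.linalg.norm(v)
        g = np.zeros_like(s.coords)
        de = self.k * (r - self.r0)
        g[1] = de * v / r
        g[0] = -g[1]
        return 0.5 * self.k * (r - self.r0) ** 2, g

    def energy(self, s):
        return self.energy_and_gradient(s)[0]


class TestTargetEnergy:
    def test_c14h30_factor_is_126(self):
        s = build_chain(14, "linear")
        t = 300.0
        assert target_energy(s, t) == pytest.approx(126 * KB_HARTREE_PER_K * t, rel=1e-12)

    def test_zero_temperature(self, butane):
        assert target_energy(butane, 0.0) == 0.0

    def test_triatomic_has_three_modes(self):
        s = Structure(("C", "H", "H"), np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0.0]]))
        assert target_energy(s, 100.0) == pytest.approx(3 * KB_HARTREE_PER_K * 100.0)

    def test_diatomic_rejected(self):
        s = Structure(("C", "H"), np.array([[0, 0, 0], [2, 0, 0.0]]))
        with pytest.raises(ValidationError):
            target_energy(s, 10.0)


class TestInitVelocities:
    def test_momenta_projected_out(self, butane):
        st = init_velocities(butane, 300.0, seed=4)
        assert np.abs(st.linear_momentum()).max() < 1e-10
        assert np.abs(st.angular_momentum()).max() < 1e-10

    def test_kinetic_energy_matches_target(self, butane):
        st = init_velocities(butane, 250.0, seed=4)
        assert st.kinetic_energy() == pytest.approx(target_energy(butane, 250.0), rel=1e-10)

    def test_seed_determinism(self, butane):
        a = init_velocities(butane, 300.0, seed=11)
        b = init_velocities(butane, 300.0, seed=11)
        np.testing.assert_array_equal(a.velocities, b.velocities)

    def test_negative_temperature_rejected(self, butane):
        with pytest.raises(ValidationError):
            init_velocities(butane, -1.0, seed=0)


class TestRunNVE:
    def test_zero_force_free_flight(self, butane):
        st = init_velocities(butane, 50.0, seed=2)
        traj = run_nve(ZeroForce(), st, dt=5.0, n_equil=0, n_prod=100)
        expected = butane.coords + st.velocities * traj.times[-1]
        np.testing.assert_allclose(traj.positions[-1], expected, atol=1e-10)

    def test_harmonic_period_within_a_tenth_percent(self):
        k, r0 = 0.2, 2.0
        m = 12.011 * AMU_TO_AU
        mu = m / 2
        s = Structure(("C", "C"), np.array([[0, 0, 0], [r0 + 0.1, 0, 0.0]]))
        state = MDState(s, np.zeros((2, 3)), np.full(2, m))
        period = 2 * np.pi * np.sqrt(mu / k)
        dt = 1.0
        traj = run_nve(Harmonic1D(k, r0), state, dt=dt, n_equil=0,
                       n_prod=int(20 * period / dt))
        r = np.linalg.norm(traj.positions[:, 1] - traj.positions[:, 0], axis=1)
        # measure the period from zero crossings of (r - r0)
        x = r - r0
        crossings = []
        for i in range(len(x) - 1):
            if x[i] < 0 <= x[i + 1]:
                frac = -x[i] / (x[i + 1] - x[i])
                crossings.append(traj.times[i] + frac * dt)
        measured = np.mean(np.diff(crossings))
        assert measured == pytest.approx(period, rel=1e-3)

    def test_divergence_aborts_with_diagnostic(self, butane):
        st = init_velocities(butane, 300.0, seed=1)
        with pytest.raises(FloatingPointError):
            run_nve(ToyPotential("low"), st, dt=500.0, n_equil=0, n_prod=500)

    def test_only_production_frames_recorded(self, butane):
        st = init_velocities(butane, 10.0, seed=1)
        traj = run_nve(ZeroForce(), st, dt=5.0, n_equil=7, n_prod=13)
        assert traj.n_frames == 13

    def test_nonpositive_dt_rejected(self, butane):
        st = init_velocities(butane, 10.0, seed=1)
        with pytest.raises(ValidationError):
            run_nve(ZeroForce(), st, dt=0.0, n_equil=0, n_prod=1)


def _cosine_trajectory(nu_cm, n_frames=4096, dt=5.0):
    """Synthetic 1-atom trajectory with v_x = cos(2 pi nu t)."""
    from mbpip.dynamics import _AU_TIME_S, _C_CM_PER_S

    nu_au = nu_cm * _C_CM_PER_S * _AU_TIME_S  # cycles per au time
    t = np.arange(n_frames) * dt
    v = np.zeros((n_frames, 1, 3))
    v[:, 0, 0] = np.cos(2 * np.pi * nu_au * t)
    return Trajectory(times=t, positions=np.zeros_like(v), velocities=v,
                      kinetic=np.zeros(n_frames), potential=np.zeros(n_frames),
                      dt=dt, masses=np.array([1.0 / AMU_TO_AU]), elements=("H",))


class TestPowerSpectrum:
    def test_zero_velocities_zero_spectrum(self):
        t = _cosine_trajectory(1000.0)
        t.velocities = np.zeros_like(t.velocities)
        ps = power_spectrum([t])
        assert np.all(ps.intensity == 0.0)

    @pytest.mark.parametrize("nu", [500.0, 1500.0, 2900.0])
    def test_cosine_peaks_at_injected_frequency(self, nu):
        ps = power_spectrum([_cosine_trajectory(nu)])
        bin_width = ps.frequencies[1] - ps.frequencies[0]
        assert abs(ps.peak_frequency() - nu) <= bin_width

    def test_intensity_nonnegative(self, butane):
        st = init_velocities(butane, 100.0, seed=3)
        traj = run_nve(ToyPotential("low"), st, dt=5.0, n_equil=50, n_prod=256)
        ps = power_spectrum([traj])
        assert np.all(ps.intensity >= 0.0)

    def test_averaging_linearity(self):
        trajs = [_cosine_trajectory(800.0 + 100 * k) for k in range(5)]
        mean_of_each = np.mean([power_spectrum([t]).intensity for t in trajs], axis=0)
        ps = power_spectrum(trajs)
        np.testing.assert_allclose(ps.intensity, mean_of_each, rtol=1e-12)
        assert ps.n_trajectories_averaged == 5

    def test_parseval_consistency(self, butane):
        """The integrated spectrum equals the windowed mass-weighted kinetic
        energy content (Parseval), far inside the 1% proportionality margin."""
        st = init_velocities(butane, 200.0, seed=5)
        traj = run_nve(ToyPotential("low"), st, dt=5.0, n_equil=200, n_prod=512)
        ps = power_spectrum([traj], window="hann", mass_weighted=True, zero_pad=2)
        npad = 2 * traj.n_frames
        # real-signal symmetry: doubled interior bins minus DC/Nyquist
        integrated = 2 * np.sum(ps.intensity) - ps.intensity[0] - ps.intensity[-1]
        taper = np.hanning(traj.n_frames)
        v = traj.velocities * np.sqrt(traj.masses)[None, :, None]
        expected = npad * np.sum((v * taper[:, None, None]) ** 2)
        assert integrated == pytest.approx(expected, rel=1e-8)

    def test_mismatched_dt_rejected(self):
        a, b = _cosine_trajectory(500.0), _cosine_trajectory(500.0, dt=4.0)
        with pytest.raises(ValidationError):
            power_spectrum([a, b])


def test_masses_require_known_elements():
    s = Structure(("C", "H"), np.array([[0, 0, 0], [2, 0, 0.0]]))
    assert masses_au(s)[0] == pytest.approx(12.011 * AMU_TO_AU)
    with pytest.raises(ValidationError):
        masses_au(Structure(("Xx",), np.zeros((1, 3)), ), )
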