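"""Model containers, spectral-density observables, partition and discretization."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from excitonmash.model import (
    ContinuousComponent,
    DiscreteMode,
    ExcitonSystem,
    ModelValidationError,
    SpectralDensity,
    build_dynamical_bath,
    discretize_continuous,
    load_model,
    max_exciton_gap,
    partition_bath,
    reorg_fraction,
    reorganization_density,
    total_reorganization,
    write_model,
)
from excitonmash.units import CM_TO_RADFS, thermal_energy_cm


def simple_system(eps=(0.0, 100.0), J=50.0):
    n = len(eps)
    coup = np.zeros((n, n))
    coup[0, 1] = coup[1, 0] = J
    return ExcitonSystem(site_energies=np.array(eps), couplings=coup)


class TestModelIO:
    def test_round_trip_identity(self, tmp_path, dimer_sd):
        system = simple_system()
        path = tmp_path / "model.json"
        write_model(path, system, dimer_sd, meta={"temperature_K": 300})
        system2, sd2 = load_model(path)
        assert system2.n_sites == 2
        np.testing.assert_allclose(system2.site_energies, system.site_energies)
        np.testing.assert_allclose(system2.couplings, system.couplings)
        assert len(sd2.discrete) == len(dimer_sd.discrete)
        assert sd2.continuous[0].lam == dimer_sd.continuous[0].lam
        # writing again reproduces the file byte for byte
        path2 = tmp_path / "model2.json"
        write_model(path2, system2, sd2, meta={"temperature_K": 300})
        assert path.read_bytes() == path2.read_bytes()

    def test_negative_frequency_rejected(self, tmp_path):
        doc = {
            "system": {"energies_cm1": [0.0, 100.0],
                       "couplings_cm1": [[0.0, 50.0], [50.0, 0.0]]},
            "bath": {"discrete": [{"omega_cm1": -5.0, "huang_rhys": 0.1}]},
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelValidationError):
            load_model(path)

    def test_asymmetric_couplings_rejected(self, tmp_path):
        doc = {
            "system": {"energies_cm1": [0.0, 100.0],
                       "couplings_cm1": [[0.0, 50.0], [49.0, 0.0]]},
            "bath": {},
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelValidationError):
            load_model(path)

    def test_group_index_out_of_range(self):
        with pytest.raises(ModelValidationError):
            ExcitonSystem(
                site_energies=np.zeros(2),
                couplings=np.zeros((2, 2)),
                groups={"bad": (0, 5)},
            )


class TestReorganizationDensity:
    def test_empty_bath_is_zero(self):
        sd = SpectralDensity()
        grid = np.linspace(1.0, 100.0, 50)
        assert np.all(reorganization_density(sd, grid) == 0.0)

    def test_single_mode_integral_recovers_lambda(self):
        sd = SpectralDensity(discrete=(DiscreteMode(1000.0, 0.5),))
        grid = np.linspace(0.5, 5000.0, 40000)
        lam = np.trapezoid(reorganization_density(sd, grid, 10.0), grid)
        assert lam == pytest.approx(500.0, rel=0.005)

    def test_peak_near_mode_frequency(self):
        sd = SpectralDensity(discrete=(DiscreteMode(1000.0, 0.5),))
        grid = np.linspace(0.5, 2000.0, 20000)
        curve = reorganization_density(sd, grid, 10.0)
        assert abs(grid[np.argmax(curve)] - 1000.0) < 10.0

    def test_empty_grid_rejected(self, dimer_sd):
        with pytest.raises(ValueError):
            reorganization_density(dimer_sd, np.array([]))


class TestTotalReorganization:
    def test_single_mode(self):
        sd = SpectralDensity(discrete=(DiscreteMode(1000.0, 0.5),))
        assert total_reorganization(sd) == pytest.approx(500.0)

    def test_empty(self):
        assert total_reorganization(SpectralDensity()) == 0.0

    def test_additivity(self):
        sd = SpectralDensity(
            discrete=(DiscreteMode(100.0, 1.0), DiscreteMode(100.0, 1.0)),
            continuous=(ContinuousComponent("debye", lam=35.0, omega_c=50.0),),
        )
        assert total_reorganization(sd) == pytest.approx(235.0)


class TestMaxExcitonGap:
    def test_dimer_closed_form(self):
        system = simple_system(eps=(0.0, 100.0), J=50.0)
        assert max_exciton_gap(system) == pytest.approx(
            np.sqrt(100.0**2 + 4 * 50.0**2))

    def test_uncoupled_dimer(self):
        system = simple_system(eps=(0.0, 123.0), J=0.0)
        assert max_exciton_gap(system) == pytest.approx(123.0)

    def test_single_site_rejected(self):
        system = ExcitonSystem(site_energies=np.zeros(1),
                               couplings=np.zeros((1, 1)))
        with pytest.raises(ValueError):
            max_exciton_gap(system)

    @given(shift=st.floats(-1e4, 1e4), seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_shift_and_permutation_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        n = 4
        eps = rng.uniform(-500, 500, n)
        J = rng.uniform(-100, 100, (n, n))
        J = 0.5 * (J + J.T)
        np.fill_diagonal(J, 0.0)
        system = ExcitonSystem(site_energies=eps, couplings=J)
        gap = max_exciton_gap(system)
        shifted = ExcitonSystem(site_energies=eps + shift, couplings=J)
        assert max_exciton_gap(shifted) == pytest.approx(gap, rel=1e-9, abs=1e-6)
        perm = rng.permutation(n)
        permuted = ExcitonSystem(site_energies=eps[perm],
                                 couplings=J[np.ix_(perm, perm)])
        assert max_exciton_gap(permuted) == pytest.approx(gap, rel=1e-9)


class TestPartition:
    @pytest.mark.parametrize(
        "freq, expected",
        [(100.0, "low"), (300.0, "high"), (1488.0, "high"), (1600.0, "nonresonant")],
    )
    def test_mode_routing(self, freq, expected):
        sd = SpectralDensity(discrete=(DiscreteMode(freq, 0.1),))
        part = partition_bath(sd, 300.0, 1488.0)
        assert len(getattr(part, expected)) == 1

    def test_continuous_always_low(self, dimer_sd):
        part = partition_bath(dimer_sd, 300.0, 1488.0)
        assert len(part.continuous) == 1

    @given(freqs=st.lists(st.floats(1.0, 3000.0), min_size=1, max_size=12))
    @settings(max_examples=30, deadline=None)
    def test_partition_exhaustive_exclusive(self, freqs):
        sd = SpectralDensity(discrete=tuple(DiscreteMode(f, 0.1) for f in freqs))
        part = partition_bath(sd, 300.0, 1488.0)
        assert len(part.low) + len(part.high) + len(part.nonresonant) == len(freqs)


class TestReorgFraction:
    def test_two_mode_split(self):
        kT = thermal_energy_cm(300.0)
        sd = SpectralDensity(discrete=(
            DiscreteMode(0.5 * kT, 90.0 / (0.5 * kT)),   # lambda = 90, low
            DiscreteMode(2.0 * kT, 10.0 / (2.0 * kT)),   # lambda = 10, high
        ))
        assert reorg_fraction(sd, 300.0, 1488.0) == pytest.approx(0.10)

    def test_all_below_thermal(self):
        sd = SpectralDensity(discrete=(DiscreteMode(50.0, 1.0),))
        assert reorg_fraction(sd, 300.0, 1488.0) == 0.0

    def test_zero_denominator_raises(self):
        sd = SpectralDensity(discrete=(DiscreteMode(2000.0, 1.0),))
        with pytest.raises(ZeroDivisionError):
            reorg_fraction(sd, 300.0, 1488.0)

    def test_bounded_unit_interval(self, dimer_sd):
        frac = reorg_fraction(dimer_sd, 300.0, 1488.0)
        assert 0.0 <= frac <= 1.0


class TestDiscretization:
    @pytest.mark.parametrize("n", [1, 7, 50])
    def test_reorganization_preserved(self, debye, n):
        modes = discretize_continuous(debye, n)
        lam = sum(m.reorganization for m in modes)
        assert lam == pytest.approx(100.0 * 0.999, rel=1e-3)

    def test_single_mode_at_median(self, debye):
        (mode,) = discretize_continuous(debye, 1)
        median = debye.inverse_cumulative(0.999 / 2)
        assert mode.frequency == pytest.approx(float(median))

    def test_correlation_function_matches_quadrature(self, debye):
        """n=200 discretization reproduces the bath correlation function.

        The classical site-energy autocorrelation is (up to 2 kT)
        C(t) = sum_k lambda_k cos(w_k t) discretized versus the direct
        quadrature of the continuous density.  Agreement is to 1% of C(0)
        while the correlation is alive; once C(t) has decayed, the
        discrete sum fluctuates within its dephasing noise floor
        ~ lambda/sqrt(2 n).
        """
        n = 200
        modes = discretize_continuous(debye, n)
        w = np.array([m.frequency for m in modes])
        lam = np.array([m.reorganization for m in modes])
        t = np.linspace(0.0, 1000.0, 60)  # fs
        disc = (lam[None, :] * np.cos(CM_TO_RADFS * w[None, :] * t[:, None])).sum(1)
        grid = np.geomspace(1e-3, 3e5, 400000)
        rho = debye.reorg_density(grid)
        cont = np.trapezoid(
            rho[None, :] * np.cos(CM_TO_RADFS * grid[None, :] * t[:, None]),
            grid, axis=1)
        c0 = cont[0]
        # The broad top slices of the slowly decaying Debye tail limit the
        # short-time accuracy to ~2% of C(0) at n=200; at long times the
        # discrete sum fluctuates within its dephasing noise floor.
        alive = t <= 400.0  # several solvent correlation times
        assert np.max(np.abs(disc - cont)[alive]) < 0.02 * c0
        floor = debye.lam / np.sqrt(2 * n)
        assert np.max(np.abs(disc - cont)) < 1.5 * floor

    def test_total_reorg_close_to_continuous(self, dimer_sd):
        bath = build_dynamical_bath(dimer_sd, 300.0, 1488.0, n_solvent_modes=40)
        assert bath.total_reorganization == pytest.approx(
            total_reorganization(dimer_sd), rel=2e-3)

    def test_kappa_consistent_with_reorganization(self):
        # minimum of eps + kappa q + 1/2 Omega^2 q^2 lies at depth -lambda
        from excitonmash.model import DiscretizedBath

        bath = DiscretizedBath(frequencies=np.array([1000.0]),
                               couplings=np.array([np.sqrt(0.5)]))
        kappa = bath.coupling_coefficients[0]
        omega = CM_TO_RADFS * 1000.0
        depth = -kappa**2 / (2 * omega**2)
        assert depth / CM_TO_RADFS == pytest.approx(-500.0)
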