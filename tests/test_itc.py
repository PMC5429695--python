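"""Single-site ITC model, simulation, fitting, and thermodynamic identities."""

import numpy as np
import pytest

from cohdoc.errors import ParseError, ProtocolError
from cohdoc.itc import (
    DEFAULT_TEMPERATURE,
    R_KCAL,
    ItcDataset,
    ItcProtocol,
    ThermoParams,
    derive_thermodynamics,
    fit_single_site,
    gibbs_from_enthalpy_entropy,
    model_heats,
    protocol_for_c_value,
    read_itc,
    simulate_titration,
    totals_after_injections,
    write_itc,
)

from oracles import bisection_titration_heats

WT_PARAMS = ThermoParams(n=1.0, Ka=1.18e8, dH=-50.68)


class TestModelHeats:
    def test_zero_enthalpy_returns_only_the_offset(self):
        params = ThermoParams(n=1.0, Ka=1e7, dH=0.0, q_offset=0.7)
        protocol = protocol_for_c_value(params)
        heats = model_heats(protocol, params)
        assert np.allclose(heats, 0.7)

    def test_stoichiometric_limit_binds_all_injected_titrant(self):
        """At Ka -> inf the early bound amount equals the injected amount."""
        params = ThermoParams(n=1.0, Ka=1e15, dH=-50.0)
        protocol = ItcProtocol(
            cell_conc=1e-5, syringe_conc=1.5e-4,
            injection_volumes=(10e-6,) * 10,
        )
        Mt, Lt = totals_after_injections(protocol)
        from cohdoc.itc import bound_concentration

        B = bound_concentration(params.Ka, params.n, Mt, Lt)
        early = slice(0, 5)  # far from saturation: all titrant is bound
        assert np.allclose(B[early], Lt[early], rtol=1e-3)

    def test_matches_bisection_equilibrium_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            params = ThermoParams(
                n=rng.uniform(0.5, 2.0),
                Ka=10 ** rng.uniform(5, 9),
                dH=rng.uniform(-80, -10),
                q_offset=rng.uniform(-0.5, 0.5),
            )
            protocol = ItcProtocol(
                cell_conc=10 ** rng.uniform(-6, -4),
                syringe_conc=10 ** rng.uniform(-5, -3),
                injection_volumes=tuple(rng.uniform(5e-6, 15e-6, size=20)),
            )
            ours = model_heats(protocol, params)
            oracle = bisection_titration_heats(
                protocol.cell_volume, protocol.cell_conc, protocol.syringe_conc,
                protocol.injection_volumes, params.n, params.Ka, params.dH,
                params.q_offset,
            )
            scale = np.abs(oracle).max()
            assert np.abs(ours - oracle).max() <= 1e-6 * scale

    def test_heat_conservation_at_saturation(self):
        params = ThermoParams(n=1.0, Ka=1e8, dH=-50.0)
        protocol = protocol_for_c_value(params, c_value=100, syringe_ratio=25)
        heats = model_heats(protocol, params)
        Mt, Lt = totals_after_injections(protocol)
        expected_total = (
            params.n * min(Mt[-1], Lt[-1] / params.n) * params.dH
            * protocol.cell_volume * 1e9
        )
        # compensated sum (the differential heats include the displaced-volume
        # correction, so compare against the final cumulative heat)
        from cohdoc.itc import bound_concentration

        B = bound_concentration(params.Ka, params.n, Mt, Lt)
        Q_final = B[-1] * params.dH * protocol.cell_volume * 1e9
        assert Q_final == pytest.approx(expected_total, rel=0.02)

    def test_overfilled_cell_rejected(self):
        with pytest.raises(ProtocolError, match="volume"):
            ItcProtocol(injection_volumes=(200e-6,) * 10)


class TestSimulation:
    def test_zero_noise_equals_model(self):
        protocol = protocol_for_c_value(WT_PARAMS)
        ds = simulate_titration(protocol, WT_PARAMS, noise_sd=0.0)
        assert np.array_equal(ds.heats, model_heats(protocol, WT_PARAMS))

    def test_same_seed_reproduces_dataset(self):
        protocol = protocol_for_c_value(WT_PARAMS)
        a = simulate_titration(protocol, WT_PARAMS, noise_sd=0.5, seed=11)
        b = simulate_titration(protocol, WT_PARAMS, noise_sd=0.5, seed=11)
        assert np.array_equal(a.heats, b.heats)

    def test_noise_is_unbiased_with_expected_spread(self):
        protocol = protocol_for_c_value(WT_PARAMS, n_injections=10)
        clean = model_heats(protocol, WT_PARAMS)
        rng_means = []
        n_rep = 2000
        for seed in range(n_rep):
            ds = simulate_titration(protocol, WT_PARAMS, noise_sd=1.0, seed=seed)
            rng_means.append((ds.heats - clean).mean())
        rng_means = np.array(rng_means)
        assert abs(rng_means.mean()) < 5.0 / np.sqrt(n_rep * 10)
        assert rng_means.std() == pytest.approx(1.0 / np.sqrt(10), rel=0.1)

    def test_negative_noise_rejected(self):
        protocol = protocol_for_c_value(WT_PARAMS)
        with pytest.raises(ValueError):
            simulate_titration(protocol, WT_PARAMS, noise_sd=-1.0)


class TestFit:
    def test_noiseless_recovery_is_essentially_exact(self):
        protocol = protocol_for_c_value(WT_PARAMS)
        ds = simulate_titration(protocol, WT_PARAMS, noise_sd=0.0)
        fit = fit_single_site(ds)
        assert fit.converged
        assert fit.params.Ka == pytest.approx(WT_PARAMS.Ka, rel=1e-4)
        assert fit.params.dH == pytest.approx(WT_PARAMS.dH, rel=1e-4)
        assert fit.params.n == pytest.approx(1.0, abs=1e-4)

    def test_fit_is_idempotent_from_its_own_optimum(self):
        protocol = protocol_for_c_value(WT_PARAMS)
        ds = simulate_titration(protocol, WT_PARAMS, noise_sd=0.3, seed=3)
        first = fit_single_site(ds)
        again = fit_single_site(ds, init=first.params)
        assert again.params.Ka == pytest.approx(first.params.Ka, rel=1e-6)
        assert again.params.n == pytest.approx(first.params.n, rel=1e-6)
        assert again.params.dH == pytest.approx(first.params.dH, rel=1e-6)

    def test_thermodynamic_identity_holds_exactly(self):
        protocol = protocol_for_c_value(WT_PARAMS)
        ds = simulate_titration(protocol, WT_PARAMS, noise_sd=0.5, seed=5)
        fit = fit_single_site(ds)
        assert fit.dG == pytest.approx(
            -R_KCAL * protocol.temperature * np.log(fit.params.Ka), abs=1e-12
        )
        assert fit.TdS == pytest.approx(fit.params.dH - fit.dG, abs=1e-12)

    def test_too_few_injections_rejected(self):
        params = ThermoParams()
        protocol = ItcProtocol(injection_volumes=(10e-6,) * 3)
        ds = ItcDataset(protocol, np.zeros(3))
        with pytest.raises(ProtocolError, match="6 injections"):
            fit_single_site(ds)

    def test_standard_errors_reported(self):
        protocol = protocol_for_c_value(WT_PARAMS)
        ds = simulate_titration(protocol, WT_PARAMS, noise_sd=0.5, seed=9)
        fit = fit_single_site(ds)
        assert fit.params.Ka_se > 0
        assert fit.params.n_se > 0


class TestDerivedThermodynamics:
    def test_unit_association_constant_gives_zero_free_energy(self):
        dG, TdS = derive_thermodynamics(Ka=1.0, dH=-30.0, T=308.0)
        assert dG == pytest.approx(0.0, abs=1e-12)
        assert TdS == pytest.approx(-30.0)

    def test_rt_at_308K(self):
        assert R_KCAL * 308.0 == pytest.approx(0.6121, abs=1e-4)

    def test_gibbs_identity_helper(self):
        assert gibbs_from_enthalpy_entropy(-61.19, -50.82) == pytest.approx(-10.37)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            derive_thermodynamics(Ka=0.0, dH=-10.0)
        with pytest.raises(ValueError):
            derive_thermodynamics(Ka=1e7, dH=-10.0, T=-5.0)


class TestDelimitedFormat:
    def test_round_trip_preserves_heats_and_protocol(self, tmp_path):
        protocol = protocol_for_c_value(WT_PARAMS)
        ds = simulate_titration(protocol, WT_PARAMS, noise_sd=0.5, seed=2)
        path = tmp_path / "titration.tsv"
        write_itc(ds, path)
        back = read_itc(path)
        assert np.allclose(back.heats, ds.heats, atol=1e-6)
        assert back.protocol.cell_conc == pytest.approx(protocol.cell_conc)
        assert back.protocol.n_injections == 28

    def test_missing_column_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("injection_index\tvolume_uL\n1\t10\n")
        with pytest.raises(ParseError, match="missing required columns"):
            read_itc(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ParseError):
            read_itc(path)

    def test_default_protocol_emulates_28_injections(self):
        protocol = ItcProtocol()
        assert protocol.n_injections == 28
        assert protocol.injection_volumes[0] == pytest.approx(10e-6)
        assert protocol.injection_spacing == pytest.approx(220.0)
        assert protocol.temperature == pytest.approx(DEFAULT_TEMPERATURE)
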