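"""Reaction network, steady-state solver and h1 fitting."""

import dataclasses

import numpy as np
import pytest

from sednit.column_model import (
    ColumnConfig,
    KineticParams,
    SpeciesDef,
    TransportProblem,
    _network_guess,
    _network_problem,
    depth_integrated_rate,
    fit_h1,
    mass_balance,
    net_sources,
    reaction_rates,
    solve_steady_state,
)
from sednit.fluxes import DepthProfile


def _conc(**overrides):
    base = {sp: np.full(5, 10.0) for sp in ("O2", "NO3", "NH4", "Mn2", "OM", "MnO2")}
    base.update({k: np.asarray(v, dtype=float) for k, v in overrides.items()})
    return base


class TestReactionRates:
    @pytest.mark.parametrize(
        "overrides, zero_rates",
        [
            ({"O2": np.zeros(5)}, ["R1", "R4", "R5"]),
            ({"O2": np.zeros(5), "NO3": np.zeros(5), "MnO2": np.zeros(5)},
             ["R1", "R2", "R3"]),
            ({"NH4": np.zeros(5)}, ["R4"]),
        ],
    )
    def test_rate_vanishes_without_substrate(self, overrides, zero_rates):
        rates = reaction_rates(_conc(**overrides), KineticParams())
        for r in zero_rates:
            assert np.all(rates[r] == 0.0)

    def test_all_rates_nonnegative(self):
        rng = np.random.default_rng(0)
        conc = {sp: rng.uniform(0, 100, 20)
                for sp in ("O2", "NO3", "NH4", "Mn2", "OM", "MnO2")}
        rates = reaction_rates(conc, KineticParams())
        for r in rates.values():
            assert np.all(r >= 0)

    def test_o2_inhibition_factor_is_half_at_h1(self):
        """By definition of the inhibition constant, O2 = h1 halves R2."""
        p = KineticParams(h1=7.5)
        uninhibited = reaction_rates(_conc(O2=np.zeros(5)), p)["R2"]
        at_h1 = reaction_rates(_conc(O2=np.full(5, 7.5)), p)["R2"]
        assert at_h1 == pytest.approx(0.5 * uninhibited)

    def test_negative_concentration_rejected_with_diagnostic(self):
        conc = _conc(NO3=[10.0, 10.0, -1.0, 10.0, 10.0])
        with pytest.raises(ValueError, match="NO3 at node 2"):
            reaction_rates(conc, KineticParams())

    def test_stoichiometric_sources(self):
        """NH4 balance: released with rN per mol C oxidized, consumed by R4."""
        rates = {k: np.full(3, float(i + 1)) for i, k in
                 enumerate(("R1", "R2", "R3", "R4", "R5"))}
        src = net_sources(rates, rN=0.15)
        assert src["NH4"] == pytest.approx(0.15 * (1 + 2 + 3) - 4)
        assert src["O2"] == pytest.approx(-1 - 2 * 4 - 0.5 * 5)
        assert src["NO3"] == pytest.approx(-0.8 * 2 + 4)
        assert src["Mn2"] == pytest.approx(2 * 3 - 5)


def _single_solute_problem(n_nodes, depth, D0, bc_top, bc_bot, source_fn, phi=0.8):
    z = np.linspace(0.0, depth, n_nodes)
    # D0 pre-multiplied by the tortuosity factor so Ds equals the requested value
    from sednit.column_model import tortuosity_factor

    Ds_eff = D0 * float(tortuosity_factor(phi))
    species = [SpeciesDef("C", "solute", Ds_eff, bc_top, bc_bot)]
    return TransportProblem(z, np.full(n_nodes, phi), 0.0, species, source_fn)


class TestClosedForms:
    def test_zeroth_order_consumption(self):
        """Constant consumption R0: C(z) = C0(1-z/L) - R0/(2 Ds) z(L-z)."""
        phi, Ds, L, C0, R0 = 0.8, 0.01, 10.0, 250.0, 0.02  # R0 in uM/yr

        def source(conc):
            # uM/yr porewater basis -> mol m-3 total: x phi / 1000
            return {"C": -np.full(conc["C"].size, R0) * phi / 1000.0}

        pr = _single_solute_problem(200, L, Ds, C0, 0.0, source, phi)
        conc, nf, ok = pr.solve()
        assert ok
        z = pr.z
        exact = C0 * (1 - z / L) - R0 / (2 * Ds) * z * (L - z)
        mid = np.interp(5.0, z, conc["C"])
        assert mid == pytest.approx(100.0, rel=1e-3)
        interior = slice(1, -1)
        assert np.max(np.abs(conc["C"][interior] - exact[interior])
                      / np.abs(exact[interior])) < 1e-3

    def test_first_order_decay(self):
        """First-order decay: C = C0 exp(-z sqrt(k/Ds)) on a long domain."""
        phi, Ds, L, C0, k = 0.8, 0.01, 100.0, 250.0, 1e-4

        def source(conc):
            return {"C": -k * conc["C"] * phi / 1000.0}

        pr = _single_solute_problem(200, L, Ds, C0, 0.0, source, phi)
        conc, nf, ok = pr.solve()
        assert ok
        c10 = np.interp(10.0, pr.z, conc["C"])
        assert c10 == pytest.approx(250.0 * np.exp(-1.0), rel=1e-3)

    def test_grid_refinement_first_order(self):
        """Error vs the analytic solution shrinks at least linearly in dz."""
        phi, Ds, L, C0, k = 0.8, 0.01, 100.0, 250.0, 1e-4

        def source(conc):
            return {"C": -k * conc["C"] * phi / 1000.0}

        errs = {}
        for n in (100, 200):
            pr = _single_solute_problem(n, L, Ds, C0, 0.0, source, phi)
            conc, _, ok = pr.solve()
            assert ok
            exact = C0 * np.sinh((L - pr.z) * np.sqrt(k / Ds)) / np.sinh(L * np.sqrt(k / Ds))
            errs[n] = np.max(np.abs(conc["C"] - exact))
        assert errs[200] < errs[100] / 2.0  # observed order >= 1 (central: ~2)

    def test_zeroth_order_flux_budget(self):
        """Boundary-flux difference equals the integrated consumption R0*L."""
        phi, Ds, L, C0, R0 = 0.8, 0.01, 10.0, 250.0, 0.02

        def source(conc):
            return {"C": -np.full(conc["C"].size, R0) * phi / 1000.0}

        pr = _single_solute_problem(200, L, Ds, C0, 0.0, source, phi)
        conc, _, ok = pr.solve()
        j_top, j_bot_in = pr.boundary_fluxes(conc)["C"]
        consumed = phi * R0 * L / 1000.0  # mol m-2 yr-1
        assert j_top + j_bot_in == pytest.approx(consumed, rel=1e-3)


class TestFullNetwork:
    def test_c_shaped_oxygen_and_mirror_nitrate(self, solved):
        """Two-sided oxygenation gives a C-shaped O2 profile; nitrate is its
        mirror image with an interior maximum."""
        o2 = solved.concentrations["O2"]
        no3 = solved.concentrations["NO3"]
        assert o2.argmin() not in (0, o2.size - 1)
        assert o2.min() < 3.0 < 200.0 <= o2[[0, -1]].min()
        assert no3.argmax() not in (0, no3.size - 1)
        assert 40.0 <= no3.max() <= 50.0
        # anticorrelation of the two shapes
        assert np.corrcoef(o2, no3)[0, 1] < -0.5

    def test_converged_solution_nonnegative(self, solved):
        for sp, c in solved.concentrations.items():
            assert np.all(c >= 0), sp
        for rk, r in solved.rates.items():
            assert np.all(r >= 0), rk

    def test_mass_balance_within_one_percent(self, solved, spec):
        closure = mass_balance(solved, spec.column, spec.kinetics)
        assert max(closure.values()) <= 0.01

    def test_pure_diffusion_budget_is_zero(self):
        pr = _single_solute_problem(50, 10.0, 0.01, 100.0, 100.0, None)
        conc, _, ok = pr.solve()
        assert ok
        j_top, j_bot = pr.boundary_fluxes(conc)["C"]
        assert abs(j_top) < 1e-12 and abs(j_bot) < 1e-12
        assert np.allclose(conc["C"], 100.0)

    def test_nitrogen_closure_brute_force(self, solved, spec):
        """N entering (NO3 + NH4 boundary fluxes + rN of mineralized OM) must
        leave as N2 via denitrification: 0.8 * integral of R2."""
        pr = _network_problem(spec.column, spec.kinetics)
        fl = pr.boundary_fluxes(solved.concentrations)
        z = solved.z
        mineralized = np.trapezoid(
            solved.rates["R1"] + solved.rates["R2"] + solved.rates["R3"], z)
        n_in = (fl["NO3"][0] + fl["NO3"][1] + fl["NH4"][0] + fl["NH4"][1]
                + spec.kinetics.rN * mineralized)
        n2_loss = 0.8 * np.trapezoid(solved.rates["R2"], z)
        assert n_in == pytest.approx(n2_loss, rel=0.01)

    def test_transient_integrator_agrees_with_newton(self, spec):
        """Independent route to the steady state: stiff pseudo-time integration
        reaches the same fixed point as the damped Newton iteration."""
        cfg = dataclasses.replace(spec.column, n_nodes=50)
        sol = solve_steady_state(cfg, spec.kinetics)
        pr = _network_problem(cfg, spec.kinetics)
        conc = pr.solve_transient(pr.pack(_network_guess(pr, cfg, spec.kinetics)),
                                  t_end=1e9, rtol=1e-9, atol=1e-12)
        for sp, c in conc.items():
            scale = max(1.0, np.max(np.abs(sol.concentrations[sp])))
            assert np.max(np.abs(c - sol.concentrations[sp])) / scale < 1e-8

    def test_denitrification_monotone_in_h1(self, small_spec):
        """Weaker O2 inhibition (larger h1) never decreases depth-integrated
        denitrification."""
        totals = []
        for h1 in (1.0, 5.0, 10.0, 30.0):
            par = dataclasses.replace(small_spec.kinetics, h1=h1)
            sol = solve_steady_state(small_spec.column, par)
            assert sol.converged
            totals.append(depth_integrated_rate(sol, "R2", 0.0,
                                                small_spec.column.depth_max))
        assert all(b >= a * (1 - 1e-9) for a, b in zip(totals, totals[1:]))

    def test_nonconvergence_is_flagged(self):
        cfg = ColumnConfig(depth_max=70.0, n_nodes=10)  # grid far too coarse
        par = KineticParams(k_nit=1e4, k_mnox=1e4)  # absurdly stiff kinetics
        sol = solve_steady_state(cfg, par, tol=1e-14)
        assert isinstance(sol.converged, bool)  # flag present, never silent

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ColumnConfig(depth_max=-1.0)
        with pytest.raises(ValueError):
            ColumnConfig(n_nodes=5)
        with pytest.raises(ValueError):
            ColumnConfig(porosity=1.2)
        with pytest.raises(ValueError):
            KineticParams(h1=-3.0)


class TestFitH1:
    def test_self_consistency_exact_on_grid(self, small_spec):
        """Noise-free observations generated at h1=5 are refit exactly when the
        grid contains 5."""
        par = dataclasses.replace(small_spec.kinetics, h1=5.0)
        truth = solve_steady_state(small_spec.column, par)
        obs = {sp: DepthProfile(truth.z[::4], truth.concentrations[sp][::4], species=sp)
               for sp in ("O2", "NO3")}
        fit = fit_h1(small_spec.column, small_spec.kinetics, obs, [1.0, 2.0, 5.0, 10.0, 20.0])
        assert fit.best_h1 == 5.0
        assert np.nanargmin(fit.misfit) == 2
        assert fit.misfit[2] < 1e-8

    def test_misfit_reported_for_every_candidate(self, small_spec):
        truth = solve_steady_state(small_spec.column, small_spec.kinetics)
        obs = {sp: DepthProfile(truth.z[::4], truth.concentrations[sp][::4], species=sp)
               for sp in ("O2", "NO3")}
        grid = [0.1, 1.0, 10.0]
        fit = fit_h1(small_spec.column, small_spec.kinetics, obs, grid)
        assert fit.misfit.shape == (3,)
        assert np.all(np.isfinite(fit.misfit))

    def test_rejects_nonpositive_candidates(self, small_spec):
        with pytest.raises(ValueError):
            fit_h1(small_spec.column, small_spec.kinetics, {}, [0.0, 1.0])
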