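"""1-D steady-state early-diagenesis model of nitrogen cycling in a sediment
column oxygenated from above (bottom seawater) and below (oxic basement fluid).

Six species are tracked: two solids advected with burial (organic matter OM and
MnO2, in mol per m³ of total sediment) and four porewater solutes diffusing
through the tortuous pore network (O2, NO3, NH4, Mn2+, in µM).  Five reactions
link them — three primary organic-matter oxidation pathways and two secondary
re-oxidation reactions:

    R1  aerobic respiration        OM + O2            -> CO2 (+ rN NH4)
    R2  heterotrophic denitrif.    OM + 4/5 NO3       -> 2/5 N2 (+ rN NH4)
    R3  manganese reduction        OM + 2 MnO2        -> 2 Mn2+ (+ rN NH4)
    R4  nitrification              NH4 + 2 O2         -> NO3
    R5  Mn2+ oxidation             Mn2+ + 1/2 O2      -> MnO2

Primary rates follow first-order organic-matter decay modulated by Monod
limitation on the electron acceptor and hyperbolic inhibition by the more
favourable acceptors (O2 inhibits denitrification with constant ``h1``, O2 and
NO3 inhibit Mn reduction with ``h2``/``h3``).  Secondary rates are bimolecular.
The steady state of the advection-diffusion-reaction equations is found by
damped Newton iteration on a finite-difference discretization (central
differences for diffusion, second-order upwind for burial advection of solids).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from ._bandsolve import ConvergenceError, newton_banded, pseudo_transient

SOLUTES: tuple[str, ...] = ("O2", "NO3", "NH4", "Mn2")
SOLIDS: tuple[str, ...] = ("OM", "MnO2")
SPECIES: tuple[str, ...] = SOLUTES + SOLIDS
RATES: tuple[str, ...] = ("R1", "R2", "R3", "R4", "R5")

#: 1 µM = 1e-3 mol m⁻³; multiply mol m⁻³ yr⁻¹ sources by this to get µM-basis.
UM_PER_MOL_M3 = 1000.0

#: Free-solution diffusion coefficients at ~1.5 °C, m² yr⁻¹ (config-overridable
#: placeholders in the usual infinite-dilution range for cold seawater).
DEFAULT_D0: dict[str, float] = {"O2": 0.0372, "NO3": 0.0306, "NH4": 0.0318, "Mn2": 0.0104}


def tortuosity_factor(porosity: np.ndarray | float) -> np.ndarray | float:
    """θ² = 1 − ln(φ²); sediment diffusivity is Ds = D0/θ²."""
    return 1.0 - np.log(np.asarray(porosity, dtype=float) ** 2)


@dataclass(frozen=True)
class KineticParams:
    """Rate constants for the five-reaction network.

    Units: ``k_OM`` 1/yr; half-saturations ``K_O2``/``K_NO3`` and inhibition
    constants ``h1``/``h2``/``h3`` in µM; ``K_MnO2`` in mol m⁻³; the bimolecular
    constants ``k_nit``/``k_mnox`` in 1/(µM·yr); ``rN`` mol N per mol C in
    organic matter (Redfield 16/106 by default).
    """

    k_OM: float = 2.0e-7
    K_O2: float = 3.0
    K_NO3: float = 500.0
    h1: float = 10.0
    K_MnO2: float = 5.0
    h2: float = 5.0
    h3: float = 5.0
    k_nit: float = 1e-2
    k_mnox: float = 1e-2
    rN: float = 16.0 / 106.0

    def __post_init__(self) -> None:
        for name in ("k_OM", "K_O2", "K_NO3", "h1", "K_MnO2", "h2", "h3", "k_nit", "k_mnox", "rN"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"kinetic parameter {name} must be strictly positive, got {v}")


@dataclass
class ColumnConfig:
    """Geometry, transport properties and boundary conditions of one column.

    Solute boundary conditions are Dirichlet concentrations (µM) at the
    sediment-water interface (``bc_top``) and the sediment-basement interface
    (``bc_bot``).  Solids enter with a prescribed burial flux at the top
    (mol m⁻² yr⁻¹) and obey a zero-gradient condition at the base.
    """

    depth_max: float = 70.0
    n_nodes: int = 200
    porosity: float | np.ndarray = 0.75
    temperature: float = 1.5
    burial_velocity: float | None = None  # m/yr; default depth_max / 8 Myr
    D0: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_D0))
    bc_top: dict[str, float] = field(
        default_factory=lambda: {"O2": 250.0, "NO3": 21.0, "NH4": 0.0, "Mn2": 0.0}
    )
    bc_bot: dict[str, float] = field(
        default_factory=lambda: {"O2": 200.0, "NO3": 21.1, "NH4": 0.0, "Mn2": 0.0}
    )
    om_flux_top: float = 6.5e-4  # mol C m⁻² yr⁻¹
    mno2_flux_top: float = 2.0e-6  # mol Mn m⁻² yr⁻¹
    solute_advection: bool = False

    def __post_init__(self) -> None:
        if self.depth_max <= 0:
            raise ValueError("depth_max must be positive")
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be at least 10")
        phi = np.asarray(self.porosity, dtype=float)
        if np.any(phi <= 0) or np.any(phi >= 1):
            raise ValueError("porosity must lie strictly between 0 and 1")
        for bc in (self.bc_top, self.bc_bot):
            for sp, v in bc.items():
                if v < 0:
                    raise ValueError(f"Dirichlet value for {sp} must be >= 0, got {v}")

    @property
    def burial(self) -> float:
        if self.burial_velocity is not None:
            return self.burial_velocity
        return self.depth_max / 8.0e6

    def grid(self) -> np.ndarray:
        return np.linspace(0.0, self.depth_max, self.n_nodes)

    def porosity_profile(self) -> np.ndarray:
        phi = np.asarray(self.porosity, dtype=float)
        if phi.ndim == 0:
            return np.full(self.n_nodes, float(phi))
        if phi.size != self.n_nodes:
            raise ValueError("porosity array length must equal n_nodes")
        return phi


@dataclass
class SolutionField:
    """Converged (or flagged) steady state: concentrations and rates per node.

    Solutes in µM, solids in mol m⁻³ total sediment, rates R1..R5 in
    mol m⁻³ total sediment yr⁻¹.
    """

    z: np.ndarray
    concentrations: dict[str, np.ndarray]
    rates: dict[str, np.ndarray]
    converged: bool
    residual_norm: float

    def to_frame(self):
        import pandas as pd

        data = {"depth_m": self.z}
        data.update({sp: self.concentrations[sp] for sp in SPECIES if sp in self.concentrations})
        data.update(self.rates)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Reaction network
# ---------------------------------------------------------------------------

#: Width of the smooth positivity clamp used inside the solver.  Monod and
#: bimolecular factors are evaluated on max(c, 0) smoothed over this width so
#: the Newton residual stays differentiable when an iterate grazes zero; 1e-9
#: is far below any concentration of interest (µM / mol m⁻³ scales).
SMOOTH_CLIP = 1e-9


def _smooth_pos(c: np.ndarray, eps: float) -> np.ndarray:
    return 0.5 * (c + np.hypot(c, eps)) if eps > 0 else np.maximum(c, 0.0)


def reaction_rates(
    concentrations: Mapping[str, np.ndarray],
    params: KineticParams,
    porosity: np.ndarray | float = 0.75,
    validate: bool = True,
    smooth_eps: float = 0.0,
) -> dict[str, np.ndarray]:
    """Volumetric rates R1..R5 in mol m⁻³ total sediment yr⁻¹.

    Secondary (bimolecular) rates are computed on the porewater µM basis and
    converted to the total-sediment basis with the porosity.  Each rate is zero
    whenever any of its substrates is zero.
    """
    if validate:
        for sp, arr in concentrations.items():
            arr = np.atleast_1d(np.asarray(arr, dtype=float))
            bad = np.flatnonzero(arr < 0)
            if bad.size:
                raise ValueError(
                    f"negative concentration for species {sp} at node {bad[0]} "
                    f"(value {arr[bad[0]]:g})"
                )
    c = {sp: _smooth_pos(np.atleast_1d(np.asarray(concentrations[sp], dtype=float)), smooth_eps)
         for sp in SPECIES}
    phi = np.asarray(porosity, dtype=float)
    p = params
    r1 = p.k_OM * c["OM"] * c["O2"] / (p.K_O2 + c["O2"])
    r2 = (p.k_OM * c["OM"] * c["NO3"] / (p.K_NO3 + c["NO3"]) * p.h1 / (p.h1 + c["O2"]))
    r3 = (p.k_OM * c["OM"] * c["MnO2"] / (p.K_MnO2 + c["MnO2"])
          * p.h2 / (p.h2 + c["O2"]) * p.h3 / (p.h3 + c["NO3"]))
    r4 = p.k_nit * c["NH4"] * c["O2"] * phi / UM_PER_MOL_M3
    r5 = p.k_mnox * c["Mn2"] * c["O2"] * phi / UM_PER_MOL_M3
    return {"R1": r1, "R2": r2, "R3": r3, "R4": r4, "R5": r5}


def stoichiometry(rN: float) -> dict[str, dict[str, float]]:
    """Mol of species per mol of reaction turnover (negative = consumed)."""
    return {
        "O2": {"R1": -1.0, "R4": -2.0, "R5": -0.5},
        "NO3": {"R2": -0.8, "R4": +1.0},
        "NH4": {"R1": rN, "R2": rN, "R3": rN, "R4": -1.0},
        "Mn2": {"R3": +2.0, "R5": -1.0},
        "OM": {"R1": -1.0, "R2": -1.0, "R3": -1.0},
        "MnO2": {"R3": -2.0, "R5": +1.0},
    }


def net_sources(rates: Mapping[str, np.ndarray], rN: float) -> dict[str, np.ndarray]:
    """Net production per species, mol m⁻³ total sediment yr⁻¹.

    Stoichiometry per mol C oxidized (R1-R3) / per mol substrate (R4, R5):
    R1 consumes 1 O2; R2 consumes 4/5 NO3; R3 consumes 2 MnO2 and releases
    2 Mn2+; each OM pathway releases rN NH4; R4 consumes 1 NH4 + 2 O2 and
    produces 1 NO3; R5 consumes 1 Mn2+ + 1/2 O2 and produces 1 MnO2.
    """
    r1, r2, r3, r4, r5 = (rates[k] for k in RATES)
    return {
        "O2": -r1 - 2.0 * r4 - 0.5 * r5,
        "NO3": -0.8 * r2 + r4,
        "NH4": rN * (r1 + r2 + r3) - r4,
        "Mn2": 2.0 * r3 - r5,
        "OM": -(r1 + r2 + r3),
        "MnO2": -2.0 * r3 + r5,
    }


# ---------------------------------------------------------------------------
# Generic 1-D transport problem
# ---------------------------------------------------------------------------

@dataclass
class SpeciesDef:
    """One transported species for :class:`TransportProblem`.

    ``phase='solute'``: Dirichlet top/bottom concentrations, diffusion D0/θ².
    ``phase='solid'``: prescribed advective flux at the top (``bc_top``,
    mol m⁻² yr⁻¹), zero-gradient base; advection only.
    """

    name: str
    phase: str
    D0: float = 0.0
    bc_top: float = 0.0
    bc_bot: float = 0.0


class TransportProblem:
    """Finite-difference steady-state advection-diffusion-reaction problem.

    ``source_fn(conc) -> {name: array}`` must return net production in
    mol m⁻³ total sediment yr⁻¹ on the same grid (solute sources are converted
    to the µM basis internally).  This generic core is also usable for single-
    species benchmark problems with analytic solutions.
    """

    def __init__(
        self,
        z: np.ndarray,
        porosity: np.ndarray,
        burial_velocity: float,
        species: Sequence[SpeciesDef],
        source_fn: Callable[[dict[str, np.ndarray]], Mapping[str, np.ndarray]] | None,
        solute_advection: bool = False,
    ) -> None:
        self.z = np.asarray(z, dtype=float)
        self.n = self.z.size
        self.dz = float(self.z[1] - self.z[0])
        if not np.allclose(np.diff(self.z), self.dz):
            raise ValueError("grid must be uniform")
        self.phi = np.asarray(porosity, dtype=float)
        self.v = float(burial_velocity)
        self.species = list(species)
        self.ns = len(self.species)
        self.source_fn = source_fn
        self.solute_advection = solute_advection

        theta2 = tortuosity_factor(self.phi)
        self._phiD = {}
        self._faceD = {}
        for sp in self.species:
            if sp.phase == "solute":
                pd_ = self.phi * sp.D0 / theta2
                self._phiD[sp.name] = pd_
                self._faceD[sp.name] = 0.5 * (pd_[1:] + pd_[:-1])

        # per-species magnitude scales for residual normalization and FD steps
        self.typ = np.empty(self.ns)
        self.res_scale = np.empty(self.ns)
        for k, sp in enumerate(self.species):
            if sp.phase == "solute":
                t = max(abs(sp.bc_top), abs(sp.bc_bot), 1.0)
                self.typ[k] = t
                self.res_scale[k] = np.max(self._phiD[sp.name]) / self.dz**2 * t
            else:
                t = max(abs(sp.bc_top) / max(self.v, 1e-30), 1e-6)
                self.typ[k] = t
                self.res_scale[k] = self.v / self.dz * t
        # bandwidths for interleaved (node-major) unknown ordering
        self.lower = 2 * self.ns
        self.upper = 2 * self.ns - 1

    # -- helpers -----------------------------------------------------------
    def pack(self, conc: Mapping[str, np.ndarray]) -> np.ndarray:
        u = np.empty((self.n, self.ns))
        for k, sp in enumerate(self.species):
            u[:, k] = conc[sp.name]
        return u.ravel()

    def unpack(self, u: np.ndarray) -> dict[str, np.ndarray]:
        u2 = u.reshape(self.n, self.ns)
        return {sp.name: u2[:, k] for k, sp in enumerate(self.species)}

    def typ_vector(self) -> np.ndarray:
        return np.tile(self.typ, self.n)

    # -- residual ----------------------------------------------------------
    def residual(self, u: np.ndarray, transient: bool = False) -> np.ndarray:
        """Scaled residual (O(1) per equation).  ``transient=True`` flips the
        boundary-row sign so that ``du/dτ = residual`` relaxes toward the BC."""
        u2 = u.reshape(self.n, self.ns)
        conc = {sp.name: u2[:, k] for k, sp in enumerate(self.species)}
        src = self.source_fn(conc) if self.source_fn is not None else {}
        f = np.zeros_like(u2)
        dz = self.dz
        bc_sign = -1.0 if transient else 1.0
        for k, sp in enumerate(self.species):
            c = u2[:, k]
            s = np.asarray(src.get(sp.name, 0.0))
            if sp.phase == "solute":
                face = self._faceD[sp.name]
                interior = (face[1:] * (c[2:] - c[1:-1]) - face[:-1] * (c[1:-1] - c[:-2])) / dz**2
                if np.ndim(s):
                    interior = interior + UM_PER_MOL_M3 * s[1:-1]
                if self.solute_advection:
                    phivc = self.phi * self.v * c
                    interior = interior - (phivc[1:-1] - phivc[:-2]) / dz
                f[1:-1, k] = interior / self.res_scale[k]
                f[0, k] = bc_sign * (c[0] - sp.bc_top) / self.typ[k]
                f[-1, k] = bc_sign * (c[-1] - sp.bc_bot) / self.typ[k]
            else:
                v = self.v
                sv = s if np.ndim(s) else np.zeros(self.n)
                f[0, k] = bc_sign * (v * c[0] - sp.bc_top) / (v * self.typ[k])
                f[1, k] = (-v * (c[1] - c[0]) / dz + sv[1]) / self.res_scale[k]
                f[2:, k] = (-v * (3.0 * c[2:] - 4.0 * c[1:-1] + c[:-2]) / (2.0 * dz)
                            + sv[2:]) / self.res_scale[k]
        out = f.ravel()
        if not np.all(np.isfinite(out)):
            bad = int(np.flatnonzero(~np.isfinite(out))[0])
            node, k = divmod(bad, self.ns)
            raise ConvergenceError(
                f"non-finite residual for species {self.species[k].name} at node {node}"
            )
        return out

    # -- solvers -----------------------------------------------------------
    def solve(
        self,
        u0: np.ndarray | None = None,
        tol: float = 1e-10,
        max_iter: int = 80,
    ) -> tuple[dict[str, np.ndarray], float, bool]:
        if u0 is None:
            u0 = self.pack(self.default_guess())
        typ = self.typ_vector()
        u, nf, ok = newton_banded(self.residual, u0, self.lower, self.upper, typ,
                                  tol=tol, max_iter=max_iter)
        if not ok:
            u, nf, ok = pseudo_transient(self.residual, u, self.lower, self.upper, typ, tol=tol)
        return self.unpack(u), nf, ok

    def solve_transient(
        self,
        u0: np.ndarray | None = None,
        t_end: float = 1e7,
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ) -> dict[str, np.ndarray]:
        """Integrate the relaxational system ``du/dτ = residual(u)`` to large
        pseudo-time with a stiff (BDF) integrator — an alternative route to the
        steady state used to cross-check the Newton solver."""
        from scipy.integrate import solve_ivp
        from scipy.sparse import lil_matrix

        if u0 is None:
            u0 = self.pack(self.default_guess())
        n = u0.size
        sparsity = lil_matrix((n, n))
        for j in range(n):
            lo, hi = max(0, j - self.upper), min(n, j + self.lower + 1)
            sparsity[lo:hi, j] = 1
        sol = solve_ivp(
            lambda t, y: self.residual(y, transient=True),
            (0.0, t_end),
            u0,
            method="BDF",
            rtol=rtol,
            atol=atol,
            jac_sparsity=sparsity.tocsr(),
        )
        if not sol.success:
            raise ConvergenceError(f"transient integration failed: {sol.message}")
        return self.unpack(sol.y[:, -1])

    def default_guess(self) -> dict[str, np.ndarray]:
        guess = {}
        zfrac = (self.z - self.z[0]) / (self.z[-1] - self.z[0])
        for sp in self.species:
            if sp.phase == "solute":
                guess[sp.name] = sp.bc_top + (sp.bc_bot - sp.bc_top) * zfrac
            else:
                guess[sp.name] = np.full(self.n, sp.bc_top / max(self.v, 1e-30))
        return guess

    # -- diagnostics -------------------------------------------------------
    def boundary_fluxes(self, conc: Mapping[str, np.ndarray]) -> dict[str, tuple[float, float]]:
        """Influx at the top and at the bottom boundary, mol m⁻² yr⁻¹, positive
        into the domain.  Solute gradients use second-order one-sided stencils."""
        dz = self.dz
        out = {}
        for sp in self.species:
            c = np.asarray(conc[sp.name], dtype=float)
            if sp.phase == "solute":
                pd_ = self._phiD[sp.name]
                g_top = (-3.0 * c[0] + 4.0 * c[1] - c[2]) / (2.0 * dz)
                g_bot = (3.0 * c[-1] - 4.0 * c[-2] + c[-3]) / (2.0 * dz)
                j_top = -pd_[0] * g_top / UM_PER_MOL_M3  # mol m-2 yr-1, + down
                j_bot = -pd_[-1] * g_bot / UM_PER_MOL_M3
                out[sp.name] = (j_top, -j_bot)
            else:
                out[sp.name] = (sp.bc_top, -self.v * c[-1])
        return out


# ---------------------------------------------------------------------------
# Full-network front end
# ---------------------------------------------------------------------------

def _network_problem(config: ColumnConfig, params: KineticParams) -> TransportProblem:
    phi = config.porosity_profile()
    specs = []
    for name in SOLUTES:
        specs.append(SpeciesDef(name, "solute", config.D0[name],
                                config.bc_top[name], config.bc_bot[name]))
    specs.append(SpeciesDef("OM", "solid", bc_top=config.om_flux_top))
    specs.append(SpeciesDef("MnO2", "solid", bc_top=config.mno2_flux_top))

    def source(conc: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        rates = reaction_rates(conc, params, phi, validate=False, smooth_eps=SMOOTH_CLIP)
        return net_sources(rates, params.rN)

    return TransportProblem(config.grid(), phi, config.burial, specs, source,
                            solute_advection=config.solute_advection)


def _network_guess(problem: TransportProblem, config: ColumnConfig,
                   params: KineticParams) -> dict[str, np.ndarray]:
    guess = problem.default_guess()
    v = config.burial
    # solids: pure advection-decay estimate ignoring Monod limitation
    guess["OM"] = (config.om_flux_top / v) * np.exp(-params.k_OM * problem.z / v)
    guess["MnO2"] = np.full(problem.n, config.mno2_flux_top / v)
    guess["NH4"] = np.full(problem.n, 1e-3)
    guess["Mn2"] = np.full(problem.n, 1e-6)
    guess["NH4"][0] = config.bc_top["NH4"]
    guess["NH4"][-1] = config.bc_bot["NH4"]
    guess["Mn2"][0] = config.bc_top["Mn2"]
    guess["Mn2"][-1] = config.bc_bot["Mn2"]
    return guess


def solve_steady_state(
    config: ColumnConfig,
    params: KineticParams,
    initial: Mapping[str, np.ndarray] | None = None,
    tol: float = 1e-10,
) -> SolutionField:
    """Solve the six-species network to steady state.

    Non-convergence is flagged on the returned :class:`SolutionField`, never
    silently ignored; NaNs in the residual raise with a node/species
    diagnostic.
    """
    problem = _network_problem(config, params)
    guess = dict(initial) if initial is not None else _network_guess(problem, config, params)
    conc, nf, ok = problem.solve(problem.pack(guess), tol=tol)
    if not ok:
        # homotopy on the organic-matter load: ramp the top flux up from a
        # quarter of its value, warm-starting each stage from the previous one
        conc = guess
        for frac in (0.25, 0.5, 0.75, 1.0):
            cfg_f = replace(config, om_flux_top=config.om_flux_top * frac,
                            mno2_flux_top=config.mno2_flux_top * frac)
            prob_f = _network_problem(cfg_f, params)
            conc, nf, ok = prob_f.solve(prob_f.pack(conc), tol=tol)
        problem = prob_f
    # converged solutions may carry O(tol)-level negative excursions; clip them
    for sp in SPECIES:
        c = conc[sp]
        tiny = -1e-8 * max(1.0, np.max(np.abs(c)))
        c[(c < 0) & (c > tiny)] = 0.0
    phi = config.porosity_profile()
    rates = reaction_rates(conc, params, phi, validate=False)
    return SolutionField(problem.z, conc, rates, ok, nf)


def mass_balance(solution: SolutionField, config: ColumnConfig,
                 params: KineticParams) -> dict[str, float]:
    """Normalized steady-state closure residual per species.

    Compares boundary influxes (one-sided second-order gradients for solutes;
    prescribed top flux and advective export for solids) with the
    depth-integrated net consumption (trapezoid), normalized by the largest
    flux magnitude.  Values well below 1 indicate a closed budget.
    """
    problem = _network_problem(config, params)
    fluxes = problem.boundary_fluxes(solution.concentrations)
    src = net_sources(solution.rates, params.rN)
    out = {}
    for sp in SPECIES:
        j_top, j_bot = fluxes[sp]
        produced = float(np.trapezoid(src[sp], solution.z))
        residual = j_top + j_bot + produced
        # species that cycle internally (e.g. NH4 produced by mineralization
        # and consumed by nitrification in near-balance at every depth) are
        # judged against their gross turnover, not the vanishing net term
        gross = 0.0
        for rk, nu in stoichiometry(params.rN)[sp].items():
            gross = max(gross, abs(nu) * float(np.trapezoid(solution.rates[rk], solution.z)))
        scale = max(abs(j_top), abs(j_bot), gross, 1e-30)
        out[sp] = abs(residual) / scale
    return out


# ---------------------------------------------------------------------------
# h1 sensitivity fit
# ---------------------------------------------------------------------------

@dataclass
class H1FitResult:
    best_h1: float
    h1_grid: np.ndarray
    misfit: np.ndarray  # NaN where the candidate failed to converge
    best_solution: SolutionField

    @property
    def at_grid_edge(self) -> bool:
        finite = np.isfinite(self.misfit)
        idx = int(np.nanargmin(np.where(finite, self.misfit, np.inf)))
        return idx in (0, len(self.h1_grid) - 1)


def profile_misfit(solution: SolutionField, observed: Mapping[str, "object"]) -> float:
    """Range-normalized RMSE over observed depths, species weighted equally.

    ``observed`` maps species name to an object with ``depth`` and ``value``
    arrays (a :class:`sednit.fluxes.DepthProfile` fits).
    """
    terms = []
    for sp, prof in observed.items():
        model = np.interp(prof.depth, solution.z, solution.concentrations[sp])
        rng = float(np.max(prof.value) - np.min(prof.value))
        if rng <= 0:
            rng = max(float(np.max(prof.value)), 1.0)
        rmse = float(np.sqrt(np.mean((model - prof.value) ** 2)))
        terms.append(rmse / rng)
    return float(np.mean(terms))


def fit_h1(
    config: ColumnConfig,
    params: KineticParams,
    observed: Mapping[str, "object"],
    h1_grid: Sequence[float],
    tol: float = 1e-10,
) -> H1FitResult:
    """Grid-search the denitrification O2-inhibition constant against observed
    profiles (typically O2 and NO3).  Candidates that fail to converge are
    recorded as NaN misfit; an error is raised only if all fail."""
    h1_grid = np.asarray(sorted(h1_grid), dtype=float)
    if np.any(h1_grid <= 0):
        raise ValueError("h1 candidates must be positive")
    misfit = np.full(h1_grid.size, np.nan)
    best: tuple[float, float, SolutionField] | None = None
    warm: Mapping[str, np.ndarray] | None = None
    for i, h1 in enumerate(h1_grid):
        p = replace(params, h1=float(h1))
        try:
            sol = solve_steady_state(config, p, initial=warm, tol=tol)
        except ConvergenceError:
            continue
        if not sol.converged:
            continue
        warm = sol.concentrations
        misfit[i] = profile_misfit(sol, observed)
        if best is None or misfit[i] < best[1]:
            best = (float(h1), float(misfit[i]), sol)
    if best is None:
        raise ConvergenceError("no h1 candidate converged")
    return H1FitResult(best[0], h1_grid, misfit, best[2])


def depth_integrated_rate(solution: SolutionField, rate: str,
                          z_top: float, z_bot: float) -> float:
    """∫ rate dz over [z_top, z_bot], mol m⁻² yr⁻¹, on a refined sub-grid."""
    if z_bot <= z_top:
        return 0.0
    zz = np.linspace(z_top, z_bot, 200)
    rr = np.interp(zz, solution.z, solution.rates[rate])
    return float(np.trapezoid(rr, zz))
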