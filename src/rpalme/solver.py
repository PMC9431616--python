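"""Growth solving: mu-parameterized LP assembly, feasibility, bisection
to the maximal growth rate, parsimonious fluxes and flux ranges.

The ME coupling terms make enzyme demand proportional to mu * v, so the
full problem is bilinear in (mu, v).  Fixing mu instantiates every coupled
coefficient and pins the biomass-dilution flux, leaving a pure LP; the
maximal growth rate is then the largest mu at which that LP is feasible,
located by bisection (with a guard scan for the monotone-feasibility
assumption and a linear-scan fallback).  Parsimonious FBA (minimize the
total absolute flux at fixed mu) selects the enzymatically cheapest of the
alternate optima, which is what makes isozyme choices well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import MEModel, ModelError

__all__ = [
    "LPProblem",
    "GrowthSolution",
    "SolverError",
    "assemble_lp",
    "is_feasible",
    "max_growth",
    "pfba_fluxes",
    "flux_range",
    "steady_state_residual",
    "DEFAULT_MU_TOL",
]

DEFAULT_MU_TOL = 1e-4  # day^-1
RESIDUAL_TOL = 1e-6


class SolverError(RuntimeError):
    """LP backend failure that is *not* plain infeasibility."""


@dataclass
class LPProblem:
    """A mu-instantiated linear program over reaction fluxes."""

    mu: float
    reaction_ids: list[str]
    species_ids: list[str]
    A_eq: np.ndarray
    b_eq: np.ndarray
    A_ub: np.ndarray  # (k, n); empty k allowed
    b_ub: np.ndarray
    bounds: list[tuple[float, float]]

    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    def column(self, reaction_id: str) -> int:
        return self.reaction_ids.index(reaction_id)


@dataclass
class GrowthSolution:
    mu: float
    status: str  # "optimal" | "infeasible"
    fluxes: dict[str, float] = field(default_factory=dict)
    total_flux: float = float("nan")
    residual: float = float("nan")


def _resolve_exchange(model: MEModel, key: str) -> str:
    sub_ex = model.annotations.get("substrate_exchanges", {})
    if key in sub_ex:
        return sub_ex[key]
    if key in model.reactions:
        return key
    raise ModelError(f"unknown substrate or exchange reaction {key!r}")


def assemble_lp(model: MEModel, mu: float,
                uptake_bounds: dict[str, float] | None = None,
                pinned_fluxes: dict[str, float] | None = None,
                pinned_sums: dict[str, tuple[dict[str, float], float]] | None = None,
                ) -> LPProblem:
    """Instantiate the steady-state LP at growth rate ``mu``.

    ``uptake_bounds`` maps substrate names (or exchange reaction ids) to a
    maximal uptake magnitude ``u`` (the exchange lower bound becomes -u).
    ``pinned_fluxes`` fixes individual reactions (lb = ub = value);
    ``pinned_sums`` adds equality rows ``sum coeffs*v == value`` under a
    name.  All mu-coupled usage coefficients are multiplied by ``mu`` and
    the biomass-dilution flux is pinned to ``mu``.
    """
    if mu < 0:
        raise ModelError("growth rate must be non-negative")
    rids = list(model.reactions)
    sids = list(model.metabolites)
    ridx = {r: j for j, r in enumerate(rids)}
    sidx = {s: i for i, s in enumerate(sids)}

    A_eq = np.zeros((len(sids), len(rids)))
    for j, rid in enumerate(rids):
        rxn = model.reactions[rid]
        for sid, coef in rxn.stoichiometry.items():
            A_eq[sidx[sid], j] += coef
        for sid, per_mu in rxn.mu_coupled_terms.items():
            A_eq[sidx[sid], j] += per_mu * mu
    b_eq = np.zeros(len(sids))

    bounds = [(model.reactions[r].lower_bound, model.reactions[r].upper_bound)
              for r in rids]
    if uptake_bounds:
        for key, u in uptake_bounds.items():
            if u < 0:
                raise ModelError(f"uptake bound for {key} must be non-negative")
            j = ridx[_resolve_exchange(model, key)]
            bounds[j] = (-u, bounds[j][1])
    if model.biomass_dilution_id is not None:
        bounds[ridx[model.biomass_dilution_id]] = (mu, mu)
    if pinned_fluxes:
        for rid, val in pinned_fluxes.items():
            bounds[ridx[rid]] = (val, val)

    ub_rows: list[np.ndarray] = []
    ub_rhs: list[float] = []
    eq_rows: list[np.ndarray] = []
    eq_rhs: list[float] = []
    for con in model.extra_constraints:
        row = np.zeros(len(rids))
        for rid, c in con.coeffs.items():
            row[ridx[rid]] += c
        rhs = con.rhs_const + con.rhs_mu * mu
        if con.sense == "==":
            eq_rows.append(row)
            eq_rhs.append(rhs)
        elif con.sense == ">=":
            ub_rows.append(-row)
            ub_rhs.append(-rhs)
        elif con.sense == "<=":
            ub_rows.append(row)
            ub_rhs.append(rhs)
        else:
            raise ModelError(f"bad constraint sense {con.sense!r}")
    if pinned_sums:
        for _, (coeffs, value) in pinned_sums.items():
            row = np.zeros(len(rids))
            for rid, c in coeffs.items():
                row[ridx[rid]] += c
            eq_rows.append(row)
            eq_rhs.append(value)
    if eq_rows:
        A_eq = np.vstack([A_eq] + eq_rows)
        b_eq = np.concatenate([b_eq, np.asarray(eq_rhs)])
    A_ub = np.vstack(ub_rows) if ub_rows else np.zeros((0, len(rids)))
    b_ub = np.asarray(ub_rhs) if ub_rhs else np.zeros(0)

    return LPProblem(mu=mu, reaction_ids=rids, species_ids=sids,
                     A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds)


def _split(lp: LPProblem):
    """Split v = v+ - v- so the total absolute flux is a linear objective."""
    n = lp.n
    bounds_p = [(max(lo, 0.0), max(hi, 0.0)) for lo, hi in lp.bounds]
    bounds_m = [(max(-hi, 0.0), max(-lo, 0.0)) for lo, hi in lp.bounds]
    A_eq = np.hstack([lp.A_eq, -lp.A_eq])
    A_ub = np.hstack([lp.A_ub, -lp.A_ub]) if lp.A_ub.size else np.zeros((0, 2 * n))
    return A_eq, A_ub, bounds_p + bounds_m


def _run(c, A_ub, b_ub, A_eq, b_eq, bounds):
    res = linprog(c, A_ub=A_ub if A_ub.size else None,
                  b_ub=b_ub if b_ub.size else None,
                  A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status not in (0, 2):
        raise SolverError(f"LP backend failed (status {res.status}): {res.message}")
    return res


def _lp_feasible(lp: LPProblem) -> bool:
    res = _run(np.zeros(lp.n), lp.A_ub, lp.b_ub, lp.A_eq, lp.b_eq, lp.bounds)
    return res.status == 0


def is_feasible(model: MEModel, mu: float,
                uptake_bounds: dict[str, float] | None = None, **kw) -> bool:
    """True iff the mu-pinned LP admits a feasible flux vector."""
    return _lp_feasible(assemble_lp(model, mu, uptake_bounds, **kw))


def steady_state_residual(model: MEModel, mu: float, fluxes: dict[str, float],
                          uptake_bounds: dict[str, float] | None = None) -> float:
    """Max absolute species-balance violation of a flux vector."""
    lp = assemble_lp(model, mu, uptake_bounds)
    v = np.array([fluxes.get(r, 0.0) for r in lp.reaction_ids])
    n_species = len(lp.species_ids)
    return float(np.max(np.abs(lp.A_eq[:n_species] @ v))) if n_species else 0.0


def pfba_fluxes(model: MEModel, mu: float,
                uptake_bounds: dict[str, float] | None = None,
                **kw) -> GrowthSolution:
    """Parsimonious fluxes: minimize sum |v| subject to the mu-pinned LP.

    Reports the solver's vertex among alternate optima; use
    :func:`flux_range` for claims about individual fluxes.
    """
    lp = assemble_lp(model, mu, uptake_bounds, **kw)
    A_eq, A_ub, bounds = _split(lp)
    res = _run(np.ones(2 * lp.n), A_ub, lp.b_ub, A_eq, lp.b_eq, bounds)
    if res.status == 2:
        return GrowthSolution(mu=mu, status="infeasible")
    v = res.x[: lp.n] - res.x[lp.n:]
    fluxes = dict(zip(lp.reaction_ids, v))
    n_species = len(lp.species_ids)
    resid = float(np.max(np.abs(lp.A_eq[:n_species] @ v)))
    return GrowthSolution(mu=mu, status="optimal", fluxes=fluxes,
                          total_flux=float(res.fun), residual=resid)


def _carbon_upper_bound(model: MEModel, uptake_bounds: dict[str, float] | None) -> float:
    """Analytic growth bound from carbon balance: carbon consumed by the
    dilution reaction cannot exceed carbon entering through uptakes (CO2
    exchange is secretion-only in models built here)."""
    if model.biomass_dilution_id is None:
        raise ModelError("model has no biomass-dilution reaction")
    dil = model.reactions[model.biomass_dilution_id]
    c_dil = sum(-coef * model.metabolites[sid].formula.get("C", 0.0)
                for sid, coef in dil.stoichiometry.items() if coef < 0)
    if c_dil <= 0:
        return 10.0
    c_in = 0.0
    for key, u in (uptake_bounds or {}).items():
        rid = _resolve_exchange(model, key)
        for sid, coef in model.reactions[rid].stoichiometry.items():
            c_in += u * abs(coef) * model.metabolites[sid].formula.get("C", 0.0)
    for rid, rxn in model.reactions.items():
        if rxn.rclass == "exchange" and rxn.lower_bound < 0:
            if uptake_bounds and rid in {_resolve_exchange(model, k) for k in uptake_bounds}:
                continue
            for sid, coef in rxn.stoichiometry.items():
                c_in += -rxn.lower_bound * abs(coef) * model.metabolites[sid].formula.get("C", 0.0)
    return c_in / c_dil


def max_growth(model: MEModel, uptake_bounds: dict[str, float] | None = None,
               tol: float = DEFAULT_MU_TOL, mu_upper: float | None = None,
               guard_points: int = 10, **kw) -> GrowthSolution:
    """Maximal feasible growth rate by bisection over LP feasibility.

    Returns mu* with ``is_feasible(mu*)`` and ``not is_feasible(mu* + tol)``
    (up to bracketing).  The upper bracket defaults to twice the analytic
    carbon-balance bound.  Monotone feasibility in mu is validated with a
    coarse guard scan; on violation the scan falls back to a fine linear
    scan at step ``tol``.
    """
    if tol <= 0:
        raise ModelError("tolerance must be positive")

    def feasible(mu: float) -> bool:
        return is_feasible(model, mu, uptake_bounds, **kw)

    if not feasible(0.0):
        raise ModelError("model infeasible even at mu = 0; check exchange bounds")

    hi = mu_upper if mu_upper is not None else max(2.0 * _carbon_upper_bound(model, uptake_bounds), 1e-2)
    for _ in range(8):
        if not feasible(hi):
            break
        hi *= 2.0
    else:
        raise ModelError("could not bracket the maximal growth rate (unbounded?)")

    # Guard scan: feasibility should flip from True to False exactly once.
    grid = np.linspace(0.0, hi, guard_points + 1)
    flags = [feasible(m) for m in grid]
    if sorted(flags, reverse=True) != flags:
        # Non-monotone window detected; fall back to an exhaustive scan.
        mu = 0.0
        best = 0.0
        while mu <= hi:
            if feasible(mu):
                best = mu
            mu += tol
        return pfba_fluxes(model, best, uptake_bounds, **kw)

    lo = max((m for m, f in zip(grid, flags) if f), default=0.0)
    hi = min((m for m, f in zip(grid, flags) if not f), default=hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return pfba_fluxes(model, lo, uptake_bounds, **kw)


def flux_range(model: MEModel, mu: float, reaction_id: str,
               uptake_bounds: dict[str, float] | None = None,
               pin_total_flux: float | None = None,
               **kw) -> tuple[float, float]:
    """(min, max) flux of one reaction over the mu-pinned polytope,
    optionally restricted to (near-)parsimonious solutions by capping the
    total absolute flux at ``pin_total_flux``."""
    lp = assemble_lp(model, mu, uptake_bounds, **kw)
    if reaction_id not in lp.reaction_ids:
        raise ModelError(f"unknown reaction {reaction_id}")
    j = lp.column(reaction_id)
    A_eq, A_ub, bounds = _split(lp)
    b_ub = lp.b_ub
    if pin_total_flux is not None:
        cap = np.ones((1, 2 * lp.n))
        A_ub = np.vstack([A_ub, cap]) if A_ub.size else cap
        b_ub = np.concatenate([b_ub, [pin_total_flux * (1.0 + 1e-9) + 1e-9]])
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(2 * lp.n)
        c[j] = sign
        c[lp.n + j] = -sign
        res = _run(c, A_ub, b_ub, A_eq, lp.b_eq, bounds)
        if res.status == 2:
            raise ModelError(f"infeasible at mu={mu}; cannot compute flux range")
        out.append(sign * res.fun)
    return out[0], out[1]
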