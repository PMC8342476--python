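"""Optimal resource allocation: maximize assimilation over nitrogen
fractions, the LET proportion and the energy partition.

The decision vector has seven coordinates: two free nitrogen fractions
(``n_Etot``, ``n_C4``; the thylakoid fraction is the simplex residual), the
LET proportion ``p`` and four free energy fractions (the C4-pool fraction
is the residual of the five-pool simplex).  The assimilation surface has
ridges where the binding limitation switches, so a multistart local search
(SLSQP from a deterministic scrambled-Sobol sequence over the feasible
region) is used, with an exhaustive grid search available as an
independent oracle for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .assimilation import SimulationContext
from .errors import PhotoallocError
from .light import EnergyPartition
from .nitrogen import Allocation
from .params import Environment, SpeciesParams, StoichiometryConstants

_PENALTY = 1e4


@dataclass(frozen=True)
class OptimizerSettings:
    n_starts: int = 20
    seed: int = 0
    maxiter: int = 200
    ftol: float = 1e-10
    polish: bool = True


@dataclass(frozen=True)
class OptimizationResult:
    alloc: Allocation
    partition: EnergyPartition
    A_star: float
    converged: bool
    n_restarts_used: int
    best_start: int
    constraint_violation: float

    def as_dict(self) -> dict:
        return {
            "alloc": self.alloc.as_dict(),
            "partition": self.partition.as_dict(),
            "A_star": self.A_star,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "best_start": self.best_start,
            "constraint_violation": self.constraint_violation,
        }


def _effective_bounds(species: SpeciesParams, constants: StoichiometryConstants):
    b = species.allocation_bounds
    p_min = constants.p_min()
    p_lb = max(b["p"][0], p_min + 1e-9)
    p_ub = b["p"][1]
    if p_lb > p_ub:
        raise PhotoallocError(
            "infeasible p bounds: the thylakoid composition requires "
            f"p >= {p_min:.4f}"
        )
    return b["n_Etot"], b["n_C4"], b["n_Jmax"], (p_lb, p_ub)


def _clip(x: float, lo: float, hi: float) -> float:
    return min(max(x, lo), hi)


class _Problem:
    """Shared state for the penalized objective over the 7-vector."""

    def __init__(self, ctx: SimulationContext):
        self.ctx = ctx
        self.be, self.bc, self.bj, self.bp = _effective_bounds(
            ctx.species, ctx.constants
        )

    def unpack(self, x) -> tuple[Allocation, EnergyPartition] | None:
        n_etot, n_c4, p, f1, f2, f3, f4 = (float(v) for v in x)
        n_jmax = 1.0 - n_etot - n_c4
        f5 = 1.0 - (f1 + f2 + f3 + f4)
        if (
            n_jmax < self.bj[0] - 1e-9
            or n_jmax > self.bj[1] + 1e-9
            or f5 < -1e-9
        ):
            return None
        n_jmax = _clip(n_jmax, 0.0, 1.0)
        n_etot = _clip(n_etot, 0.0, 1.0 - n_jmax)
        n_c4 = 1.0 - n_etot - n_jmax
        f5 = max(f5, 0.0)
        total = f1 + f2 + f3 + f4 + f5
        alloc = Allocation(n_Etot=n_etot, n_C4=n_c4, n_Jmax=n_jmax, p=p)
        partition = EnergyPartition(
            cb_mesophyll=f1 / total,
            cb_bundle_sheath=f2 / total,
            pr_mesophyll=f3 / total,
            pr_bundle_sheath=f4 / total,
            c4_cycle=f5 / total,
        )
        return alloc, partition

    def violation(self, x) -> float:
        n_etot, n_c4, _, f1, f2, f3, f4 = (float(v) for v in x)
        n_jmax = 1.0 - n_etot - n_c4
        f5 = 1.0 - (f1 + f2 + f3 + f4)
        v = 0.0
        v = max(v, self.bj[0] - n_jmax, n_jmax - self.bj[1], -f5)
        return max(v, 0.0)

    def objective(self, x) -> float:
        unpacked = self.unpack(x)
        if unpacked is None:
            return _PENALTY * (1.0 + self.violation(x))
        alloc, partition = unpacked
        try:
            result = self.ctx.evaluate(alloc, partition)
        except PhotoallocError:
            return _PENALTY
        return -result.A

    def bounds(self):
        return [
            self.be,
            self.bc,
            self.bp,
            (0.0, 1.0),
            (0.0, 1.0),
            (0.0, 1.0),
            (0.0, 1.0),
        ]

    def constraints(self):
        lbj, ubj = self.bj
        return [
            {"type": "ineq", "fun": lambda x: 1.0 - x[0] - x[1] - lbj},
            {"type": "ineq", "fun": lambda x: ubj - (1.0 - x[0] - x[1])},
            {"type": "ineq", "fun": lambda x: 1.0 - x[3] - x[4] - x[5] - x[6]},
        ]

    def starts(self, n: int, seed: int) -> np.ndarray:
        """Deterministic low-discrepancy starting points, repaired to the
        feasible region."""
        sampler = qmc.Sobol(d=8, scramble=True, seed=seed)
        n = max(n, 1)
        u = sampler.random(2 ** math.ceil(math.log2(n)))[:n]
        return np.array([self._repair(row) for row in u])

    def _repair(self, u) -> list[float]:
        (le, ue), (lc, uc), (lj, uj) = self.be, self.bc, self.bj
        a = le + u[0] * (ue - le)
        b = lc + u[1] * (uc - lc)
        nj = 1.0 - a - b
        if nj < lj:
            excess = lj - nj
            slack = (a - le) + (b - lc)
            if slack > 0:
                a -= excess * (a - le) / slack
                b -= excess * (b - lc) / slack
        elif nj > uj:
            deficit = nj - uj
            room = (ue - a) + (uc - b)
            if room > 0:
                a += deficit * (ue - a) / room
                b += deficit * (uc - b) / room
        a, b = _clip(a, le, ue), _clip(b, lc, uc)
        p = self.bp[0] + u[2] * (self.bp[1] - self.bp[0])
        # exponential spacings map the unit cube onto the 5-simplex
        e = [-math.log(max(v, 1e-12)) for v in u[3:8]]
        total = sum(e)
        f = [v / total for v in e]
        return [a, b, p, f[0], f[1], f[2], f[3]]


def _project_partition(
    alloc: Allocation, partition: EnergyPartition
) -> EnergyPartition:
    """Zero the C4 energy pool when the allocation carries no C4 enzymes.

    With ``n_C4 = 0`` the C4 pool has no demand, so any energy assigned to
    it is wasted; removing it (renormalizing the rest) never lowers the
    assimilation rate and makes the reported optimum unambiguous.
    """
    if alloc.n_C4 > 0.0 or partition.c4_cycle == 0.0:
        return partition
    rest = 1.0 - partition.c4_cycle
    if rest <= 0.0:
        return EnergyPartition(1.0, 0.0, 0.0, 0.0, 0.0)
    return EnergyPartition(
        cb_mesophyll=partition.cb_mesophyll / rest,
        cb_bundle_sheath=partition.cb_bundle_sheath / rest,
        pr_mesophyll=partition.pr_mesophyll / rest,
        pr_bundle_sheath=partition.pr_bundle_sheath / rest,
        c4_cycle=0.0,
    )


def _run_local(problem: _Problem, x0, settings: OptimizerSettings):
    return minimize(
        problem.objective,
        x0,
        method="SLSQP",
        bounds=problem.bounds(),
        constraints=problem.constraints(),
        options={"maxiter": settings.maxiter, "ftol": settings.ftol},
    )


def optimize_allocation(
    species: SpeciesParams,
    env: Environment,
    settings: OptimizerSettings | None = None,
    constants: StoichiometryConstants | None = None,
    tparams: dict | None = None,
) -> OptimizationResult:
    """Find the allocation and energy partition maximizing assimilation.

    Multistart SLSQP with deterministic seeding; the best local optimum is
    polished once more and returned together with the recomputed objective
    and the residual constraint violation.
    """
    settings = settings or OptimizerSettings()
    ctx = SimulationContext(species, env, constants, tparams)
    problem = _Problem(ctx)
    starts = problem.starts(settings.n_starts, settings.seed)
    best = None
    best_idx = -1
    for idx, x0 in enumerate(starts):
        res = _run_local(problem, x0, settings)
        if problem.unpack(res.x) is None:
            continue
        if best is None or res.fun < best.fun:
            best, best_idx = res, idx
    if best is None:
        raise PhotoallocError(
            "no feasible start: check the allocation bounds of "
            f"{species.label!r}"
        )
    if settings.polish:
        polished = _run_local(
            problem, best.x, replace(settings, ftol=1e-12, maxiter=500)
        )
        if polished.fun < best.fun and problem.unpack(polished.x) is not None:
            best = polished
    alloc, partition = problem.unpack(best.x)
    candidate = _project_partition(alloc, partition)
    if candidate is not partition:
        if ctx.evaluate(alloc, candidate).A >= -best.fun - 1e-12:
            partition = candidate
    result = ctx.evaluate(alloc, partition)
    return OptimizationResult(
        alloc=alloc,
        partition=partition,
        A_star=result.A,
        converged=bool(best.success),
        n_restarts_used=len(starts),
        best_start=best_idx,
        constraint_violation=problem.violation(best.x),
    )


def _simplex_compositions(n_parts: int, total: int):
    """All integer compositions of ``total`` into ``n_parts`` parts."""
    if n_parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for tail in _simplex_compositions(n_parts - 1, total - head):
            yield (head,) + tail


def grid_oracle(
    species: SpeciesParams,
    env: Environment,
    resolution: int = 9,
    energy_resolution: int = 4,
    constants: StoichiometryConstants | None = None,
    tparams: dict | None = None,
) -> OptimizationResult:
    """Exhaustive grid search over the feasible region (test oracle).

    Nitrogen fractions and ``p`` are gridded at ``resolution`` points per
    axis (simplex-filtered); energy fractions at integer compositions of
    ``energy_resolution``.  Guaranteed within grid spacing of the optimum
    of the evaluated surface, at exhaustive-search cost.
    """
    if resolution < 2:
        raise PhotoallocError("resolution must be at least 2 points per axis")
    ctx = SimulationContext(species, env, constants, tparams)
    problem = _Problem(ctx)
    (le, ue), (lc, uc), (lj, uj) = problem.be, problem.bc, problem.bj
    p_lb, p_ub = problem.bp
    e_grid = np.linspace(le, ue, resolution)
    c_grid = np.unique(np.linspace(lc, uc, resolution))
    p_grid = np.linspace(p_lb, p_ub, resolution)
    fractions = [
        tuple(k / energy_resolution for k in combo)
        for combo in _simplex_compositions(5, energy_resolution)
    ]
    best_a = -math.inf
    best_point = None
    n_evaluated = 0
    for a in e_grid:
        for b in c_grid:
            nj = 1.0 - a - b
            if nj < lj - 1e-12 or nj > uj + 1e-12:
                continue
            alloc_fracs = (a, b, _clip(nj, 0.0, 1.0))
            for p in p_grid:
                alloc = Allocation(
                    n_Etot=alloc_fracs[0],
                    n_C4=alloc_fracs[1],
                    n_Jmax=alloc_fracs[2],
                    p=float(p),
                )
                for f in fractions:
                    partition = EnergyPartition(*f)
                    try:
                        result = ctx.evaluate(alloc, partition)
                    except PhotoallocError:
                        continue
                    n_evaluated += 1
                    if result.A > best_a:
                        best_a = result.A
                        best_point = (alloc, partition)
    if best_point is None:
        raise PhotoallocError("no feasible grid point")
    alloc, partition = best_point
    return OptimizationResult(
        alloc=alloc,
        partition=partition,
        A_star=best_a,
        converged=True,
        n_restarts_used=n_evaluated,
        best_start=0,
        constraint_violation=0.0,
    )


def optimize_energy_given_nitrogen(
    alloc: Allocation,
    species: SpeciesParams,
    env_measurement: Environment,
    settings: OptimizerSettings | None = None,
    constants: StoichiometryConstants | None = None,
    tparams: dict | None = None,
    vary_p: bool = True,
) -> OptimizationResult:
    """Re-optimize the energy partition (and optionally ``p``) only.

    The nitrogen pools stay frozen at ``alloc``; this implements the
    alternative plasticity model in which energy allocation, but not
    protein abundance, adjusts to a new (measurement) environment.
    """
    settings = settings or OptimizerSettings(n_starts=8)
    ctx = SimulationContext(species, env_measurement, constants, tparams)
    problem = _Problem(ctx)
    p_bounds = problem.bp if vary_p else (alloc.p, alloc.p)

    def objective(y) -> float:
        x = [alloc.n_Etot, alloc.n_C4, y[0], y[1], y[2], y[3], y[4]]
        return problem.objective(x)

    sampler = qmc.Sobol(d=6, scramble=True, seed=settings.seed)
    n_starts = max(settings.n_starts, 1)
    u = sampler.random(2 ** math.ceil(math.log2(n_starts)))[:n_starts]
    best = None
    for row in u:
        e = [-math.log(max(v, 1e-12)) for v in row[1:6]]
        total = sum(e)
        y0 = [
            p_bounds[0] + row[0] * (p_bounds[1] - p_bounds[0]),
            e[0] / total,
            e[1] / total,
            e[2] / total,
            e[3] / total,
        ]
        res = minimize(
            objective,
            y0,
            method="SLSQP",
            bounds=[p_bounds] + [(0.0, 1.0)] * 4,
            constraints=[
                {"type": "ineq", "fun": lambda y: 1.0 - y[1] - y[2] - y[3] - y[4]}
            ],
            options={"maxiter": settings.maxiter, "ftol": settings.ftol},
        )
        if best is None or res.fun < best.fun:
            best = res
    x = [alloc.n_Etot, alloc.n_C4, *best.x]
    unpacked = problem.unpack(x)
    if unpacked is None:
        raise PhotoallocError("energy re-optimization left the feasible region")
    new_alloc, partition = unpacked
    candidate = _project_partition(new_alloc, partition)
    if candidate is not partition:
        if ctx.evaluate(new_alloc, candidate).A >= -best.fun - 1e-12:
            partition = candidate
    result = ctx.evaluate(new_alloc, partition)
    return OptimizationResult(
        alloc=new_alloc,
        partition=partition,
        A_star=result.A,
        converged=bool(best.success),
        n_restarts_used=len(u),
        best_start=0,
        constraint_violation=problem.violation(x),
    )
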