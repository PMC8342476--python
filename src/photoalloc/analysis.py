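"""Scenario analysis: required nitrogen re-allocation, residual-based
scenario comparison, environment-grid inference and response curves.

The required nitrogen re-allocation delta_n between two optimal allocations
is the summed absolute difference of the three nitrogen fractions; it
quantifies how much protein nitrogen a plant would have to move between
pools to re-adapt from one environment to another.  The environment scan
optimizes resource allocation over a grid of candidate environments and
scores each cell by the mean squared residual between model predictions
and measurements, the residuals expressed as fractions of the experimental
means; the argmin cell is the inferred best-explaining environment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .assimilation import SimulationContext, simulate
from .errors import PhotoallocError, ValidationError
from .light import EnergyPartition
from .nitrogen import Allocation, capacities
from .optimizer import OptimizerSettings, optimize_allocation
from .params import (
    Environment,
    MeasurementTable,
    SpeciesParams,
    StoichiometryConstants,
)

logger = logging.getLogger(__name__)

_POOLS = ("n_Etot", "n_C4", "n_Jmax")


@dataclass(frozen=True)
class DeltaNResult:
    delta_n: float
    per_pool: dict
    scenario_evo: str | None = None
    scenario_growth: str | None = None


@dataclass(frozen=True)
class ScanResult:
    surface: pd.DataFrame  # columns I, T, C_m, error
    argmin: dict  # {"I": ..., "T": ..., "C_m": ..., "error": ...}
    residuals_at_argmin: pd.DataFrame


def delta_n(evo: Allocation, growth: Allocation) -> DeltaNResult:
    """Total nitrogen fraction to re-allocate between the three pools.

    ``delta_n = sum_i |n_i_evo - n_i_growth|`` over Rubisco, C4-cycle and
    thylakoid pools; the LET proportion ``p`` is not a nitrogen pool and
    is excluded.  Bounded by [0, 2], symmetric in its arguments.
    """
    per_pool = {
        pool: abs(getattr(evo, pool) - getattr(growth, pool)) for pool in _POOLS
    }
    return DeltaNResult(
        delta_n=sum(per_pool.values()),
        per_pool=per_pool,
        scenario_evo=evo.scenario,
        scenario_growth=growth.scenario,
    )


def normalized_squared_residuals(
    pred: MeasurementTable, meas: MeasurementTable
) -> pd.DataFrame:
    """Squared residuals normalized to fractions of the experimental means.

    Rows are matched on ``(curve_id, x_kind, x, quantity)``; each residual
    is ``((pred - meas) / mean(meas over the quantity's rows))**2``, making
    the score invariant to rescaling any one quantity.
    """
    keys = ["curve_id", "x_kind", "x", "quantity"]
    merged = pred.df.merge(
        meas.df, on=keys, suffixes=("_pred", "_meas"), how="outer", indicator=True
    )
    if (merged["_merge"] != "both").any():
        raise ValidationError("prediction and measurement rows do not match")
    out = merged[keys].copy()
    means = merged.groupby("quantity")["value_meas"].transform("mean")
    if (means == 0).any():
        raise ValidationError("zero experimental mean: cannot normalize")
    out["residual"] = ((merged["value_pred"] - merged["value_meas"]) / means) ** 2
    return out


def compare_scenarios(
    residuals_evo, residuals_growth, delta_pairs=None
) -> dict:
    """Statistical comparison of two scenarios' residual distributions.

    Two-sided Wilcoxon rank-sum test on the residuals (exact distribution
    for combined sample sizes up to 20 without ties, otherwise the normal
    approximation with continuity correction).  If ``delta_pairs`` is given
    as an iterable of (delta_n_A, delta_n_B) pairs, a two-sided sign test
    on the paired differences is appended.
    """
    a = np.asarray(residuals_evo, dtype=float)
    b = np.asarray(residuals_growth, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least two residuals per scenario")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    test = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    report = {
        "wilcoxon_p": float(test.pvalue),
        "wilcoxon_method": method,
        "median_evo": float(np.median(a)),
        "median_growth": float(np.median(b)),
        "n_evo": int(a.size),
        "n_growth": int(b.size),
    }
    if delta_pairs is not None:
        pairs = [(float(x), float(y)) for x, y in delta_pairs]
        diffs = [x - y for x, y in pairs if x != y]
        n_pos = sum(d > 0 for d in diffs)
        report["sign_test_p"] = float(
            stats.binomtest(n_pos, len(diffs), 0.5).pvalue
        ) if diffs else 1.0
        report["sign_test_n"] = len(diffs)
    return report


def predicted_quantities(
    species: SpeciesParams,
    env: Environment,
    alloc: Allocation,
    partition: EnergyPartition,
    constants: StoichiometryConstants | None = None,
    tparams: dict | None = None,
) -> dict:
    """Model predictions for the measurable quantity vocabulary.

    Nitrogen pools are absolute investments (umol N m-2); chlorophyll,
    PSII and cytochrome f are leaf-area contents (umol m-2); A is the net
    assimilation rate.
    """
    c = constants or StoichiometryConstants()
    caps = capacities(alloc, env, species, c)
    result = simulate(species, env, alloc, partition, c, tparams)
    comp = caps.composition
    return {
        "A": result.A,
        "Chl": caps.Chl,
        "PSII": comp.PSII * caps.Chl / 1000.0 if caps.Chl > 0 else 0.0,
        "cyt_f": (comp.cyt_LET + comp.cyt_CET) * caps.Chl / 1000.0,
        "Rubisco_N": alloc.n_Etot * caps.N_ps,
        "C4_N": alloc.n_C4 * caps.N_ps,
        "thylakoid_N": alloc.n_Jmax * caps.N_ps,
    }


def response_curves(
    species: SpeciesParams,
    env: Environment,
    alloc: Allocation,
    partition: EnergyPartition,
    sweep_kind: str,
    values,
    constants: StoichiometryConstants | None = None,
    tparams: dict | None = None,
    curve_id: str = "model",
) -> MeasurementTable:
    """A-Ci, A-T or A-N response curves at a fixed allocation.

    The allocation is deliberately not re-optimized along the sweep:
    protein re-allocation takes hours to days, far longer than a
    gas-exchange measurement.  For the Ci sweep the mesophyll CO2 is
    derived from the intercellular value through the Cm/Ci ratio.
    """
    c = constants or StoichiometryConstants()
    if sweep_kind not in {"Ci", "T", "N"}:
        raise ValidationError("sweep kind must be one of Ci, T, N")
    records = []
    for x in values:
        if sweep_kind == "Ci":
            env_x = replace(env, C_m=float(x) * c.cm_over_ci, C_a=None)
        elif sweep_kind == "T":
            env_x = replace(env, T=float(x))
        else:
            env_x = replace(env, N_t=float(x))
        a = simulate(species, env_x, alloc, partition, c, tparams).A
        records.append(
            {
                "curve_id": curve_id,
                "x_kind": sweep_kind,
                "x": float(x),
                "quantity": "A",
                "value": a,
                "se": 0.0,
                "n": 1,
            }
        )
    return MeasurementTable.from_records(records)


def synthetic_measurements(
    species: SpeciesParams,
    env: Environment,
    alloc: Allocation,
    partition: EnergyPartition,
    noise_sd: float,
    seed: int,
    quantities: tuple | None = None,
    constants: StoichiometryConstants | None = None,
    tparams: dict | None = None,
    curve_id: str = "synthetic",
) -> MeasurementTable:
    """Model predictions perturbed by multiplicative Gaussian noise.

    Emulates pool-measurement data (chlorophyll, photosystem II,
    cytochrome f, nitrogen pools, assimilation): each value is multiplied
    by ``1 + eps`` with ``eps ~ N(0, noise_sd**2)``, reproducibly seeded.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    preds = predicted_quantities(species, env, alloc, partition, constants, tparams)
    if quantities is not None:
        preds = {q: preds[q] for q in quantities}
    rng = np.random.default_rng(seed)
    records = []
    for name, value in preds.items():
        noisy = value * (1.0 + rng.normal(0.0, noise_sd)) if noise_sd else value
        records.append(
            {
                "curve_id": curve_id,
                "x_kind": "none",
                "x": 0.0,
                "quantity": name,
                "value": noisy,
                "se": noise_sd * abs(value),
                "n": 1,
            }
        )
    return MeasurementTable.from_records(records)


def environment_scan(
    species: SpeciesParams,
    measured: MeasurementTable,
    grid: dict,
    env_template: Environment | None = None,
    settings: OptimizerSettings | None = None,
    constants: StoichiometryConstants | None = None,
    tparams: dict | None = None,
    measurement_env: Environment | None = None,
) -> ScanResult:
    """Infer the environment that best explains the measurements.

    For every cell of the (I, T, C_m) grid, resource allocation is
    optimized for that cell's environment (O2 and leaf nitrogen held fixed
    from ``env_template``), the measured quantities are predicted, and the
    cell is scored by the mean normalized squared residual.  If
    ``measurement_env`` is given, predictions are evaluated there (the
    acclimation scenario: allocation from the candidate environment,
    physiology at the measurement conditions); otherwise at the cell
    environment itself.  Cells where the optimizer fails score NaN and are
    excluded from the argmin.
    """
    for axis in ("I", "T", "C_m"):
        if axis not in grid or len(grid[axis]) == 0:
            raise ValidationError(f"grid axis {axis!r} missing or empty")
    template = env_template or Environment(I=1000.0, T=25.0, C_m=100.0)
    settings = settings or OptimizerSettings(n_starts=6)
    quantities = tuple(sorted(set(measured.df["quantity"])))
    rows = []
    best = None
    for i_val in grid["I"]:
        for t_val in grid["T"]:
            for cm_val in grid["C_m"]:
                env = replace(
                    template,
                    I=float(i_val),
                    T=float(t_val),
                    C_m=float(cm_val),
                    C_a=None,
                )
                try:
                    opt = optimize_allocation(
                        species, env, settings, constants, tparams
                    )
                    pred_env = measurement_env or env
                    pred = synthetic_measurements(
                        species,
                        pred_env,
                        opt.alloc,
                        opt.partition,
                        noise_sd=0.0,
                        seed=0,
                        quantities=quantities,
                        constants=constants,
                        tparams=tparams,
                        curve_id=str(measured.df["curve_id"].iloc[0]),
                    )
                    res = normalized_squared_residuals(pred, measured)
                    error = float(res["residual"].mean())
                except PhotoallocError as exc:
                    logger.warning(
                        "optimizer failed at I=%s T=%s C_m=%s: %s",
                        i_val,
                        t_val,
                        cm_val,
                        exc,
                    )
                    error, res = math.nan, None
                rows.append(
                    {
                        "I": float(i_val),
                        "T": float(t_val),
                        "C_m": float(cm_val),
                        "error": error,
                    }
                )
                if not math.isnan(error) and (
                    best is None or error < best[0]
                ):
                    best = (error, rows[-1], res)
    if best is None:
        raise PhotoallocError("all scan cells failed")
    surface = pd.DataFrame.from_records(rows)
    argmin = dict(best[1])
    return ScanResult(
        surface=surface, argmin=argmin, residuals_at_argmin=best[2]
    )
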