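"""delta_n, residual scoring, scenario statistics, curves and the scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from photoalloc import (
    Allocation,
    EnergyPartition,
    Environment,
    MeasurementTable,
    OptimizerSettings,
    ValidationError,
    compare_scenarios,
    delta_n,
    environment_scan,
    normalized_squared_residuals,
    optimize_allocation,
    predicted_quantities,
    response_curves,
    synthetic_measurements,
)


def _alloc(e, c, p=0.8):
    return Allocation(e, c, 1.0 - e - c, p)


def test_delta_n_examples():
    assert delta_n(_alloc(0.5, 0.1), _alloc(0.5, 0.1)).delta_n == 0.0
    r = delta_n(_alloc(0.5, 0.1), _alloc(0.4, 0.2))
    assert r.delta_n == pytest.approx(0.2)
    assert r.per_pool == pytest.approx(
        {"n_Etot": 0.1, "n_C4": 0.1, "n_Jmax": 0.0}
    )


@settings(deadline=None, max_examples=50)
@given(
    a=st.tuples(st.floats(0, 1), st.floats(0, 1)).filter(lambda t: sum(t) <= 1),
    b=st.tuples(st.floats(0, 1), st.floats(0, 1)).filter(lambda t: sum(t) <= 1),
)
def test_delta_n_symmetry_and_bounds(a, b):
    x, y = _alloc(*a), _alloc(*b)
    fwd, rev = delta_n(x, y), delta_n(y, x)
    assert fwd.delta_n == rev.delta_n
    assert 0.0 <= fwd.delta_n <= 2.0
    # p is not a nitrogen pool and must not contribute
    x2 = Allocation(x.n_Etot, x.n_C4, x.n_Jmax, 0.5)
    assert delta_n(x2, y).delta_n == fwd.delta_n


def _table(values, quantity="A"):
    return MeasurementTable.from_records(
        [
            {
                "curve_id": "c",
                "x_kind": "Ci",
                "x": float(i),
                "quantity": quantity,
                "value": float(v),
                "se": 0.0,
                "n": 1,
            }
            for i, v in enumerate(values)
        ]
    )


def test_residuals_examples_and_scale_invariance():
    assert (
        normalized_squared_residuals(_table([1, 3]), _table([1, 3]))["residual"]
        == 0.0
    ).all()
    r = normalized_squared_residuals(_table([2, 2]), _table([1, 3]))["residual"]
    assert list(r) == pytest.approx([0.25, 0.25])
    r_scaled = normalized_squared_residuals(
        _table([20, 20]), _table([10, 30])
    )["residual"]
    assert list(r_scaled) == pytest.approx(list(r))


def test_residuals_reject_mismatch_and_zero_mean():
    with pytest.raises(ValidationError):
        normalized_squared_residuals(_table([1, 2, 3]), _table([1, 2]))
    with pytest.raises(ValidationError):
        normalized_squared_residuals(_table([1, -1]), _table([1, -1]))


def test_residuals_normalize_per_quantity():
    pred = MeasurementTable(
        pd.concat([_table([2, 2], "A").df, _table([300], "Chl").df])
    )
    meas = MeasurementTable(
        pd.concat([_table([1, 3], "A").df, _table([400], "Chl").df])
    )
    r = normalized_squared_residuals(pred, meas)
    by_q = dict(zip(r["quantity"], r["residual"]))
    del by_q  # two A rows share the A mean; Chl has its own
    r_a = r[r["quantity"] == "A"]["residual"]
    assert list(r_a) == pytest.approx([0.25, 0.25])
    r_chl = r[r["quantity"] == "Chl"]["residual"]
    assert list(r_chl) == pytest.approx([(100 / 400) ** 2])


def test_compare_scenarios_statistics():
    report = compare_scenarios([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
    assert report["wilcoxon_method"] == "exact"
    assert report["wilcoxon_p"] == pytest.approx(0.1)  # 2 / C(6,3)
    same = compare_scenarios([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert same["wilcoxon_p"] == pytest.approx(1.0)
    pairs = [(0.3, 0.1)] * 15  # 15/15 concordant pairs
    report = compare_scenarios([1.0, 2.0], [3.0, 4.0], delta_pairs=pairs)
    assert report["sign_test_p"] == pytest.approx(2 * 0.5**15)
    with pytest.raises(ValidationError):
        compare_scenarios([1.0], [2.0, 3.0])


def test_response_curves_shapes(c3, c4, c4_alloc, c4_partition):
    env = Environment(I=1000.0, T=25.0, C_m=150.0, N_t=130.0)
    alloc = Allocation(0.45, 0.0, 0.55, 0.9)
    part = EnergyPartition(0.7, 0.0, 0.3, 0.0, 0.0)
    aci = response_curves(c3, env, alloc, part, "Ci", np.linspace(50, 600, 12))
    values = list(aci.df["value"])
    assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))
    an = response_curves(c3, env, alloc, part, "N", [0.0, 60.0, 130.0])
    assert an.df["value"].iloc[0] == 0.0  # through the origin
    at = response_curves(
        c4, env, c4_alloc, c4_partition, "T", np.arange(10.0, 46.0, 2.5)
    )
    v = list(at.df["value"])
    peak = max(range(len(v)), key=v.__getitem__)
    assert 0 < peak < len(v) - 1  # single interior optimum temperature
    assert all(b >= a - 1e-9 for a, b in zip(v[: peak + 1], v[1 : peak + 1]))
    assert all(b <= a + 1e-9 for a, b in zip(v[peak:], v[peak + 1 :]))
    with pytest.raises(ValidationError):
        response_curves(c3, env, alloc, part, "O2", [200.0])


def test_synthetic_measurements_noise_model(c4, c4_alloc, c4_partition):
    env = Environment(I=1200.0, T=30.0, C_m=100.0, N_t=130.0)
    clean = synthetic_measurements(c4, env, c4_alloc, c4_partition, 0.0, 1)
    preds = predicted_quantities(c4, env, c4_alloc, c4_partition)
    for _, row in clean.df.iterrows():
        assert row["value"] == pytest.approx(preds[row["quantity"]])
    t1 = synthetic_measurements(c4, env, c4_alloc, c4_partition, 0.05, 42)
    t2 = synthetic_measurements(c4, env, c4_alloc, c4_partition, 0.05, 42)
    assert t1 == t2
    t3 = synthetic_measurements(c4, env, c4_alloc, c4_partition, 0.05, 43)
    assert not t1 == t3


def test_synthetic_noise_sd_calibration(c4, c4_alloc, c4_partition):
    """Monte-Carlo: the empirical SD of the noisy A matches noise_sd*|A|."""
    env = Environment(I=1200.0, T=30.0, C_m=100.0, N_t=130.0)
    noise_sd = 0.05
    values = [
        synthetic_measurements(
            c4, env, c4_alloc, c4_partition, noise_sd, seed, quantities=("A",)
        ).df["value"].iloc[0]
        for seed in range(1000)
    ]
    clean = predicted_quantities(c4, env, c4_alloc, c4_partition)["A"]
    assert np.std(values) == pytest.approx(noise_sd * abs(clean), rel=0.05)


def test_environment_scan_recovers_generating_cell(c4):
    """Noiseless synthetic data generated at one grid cell is scored best
    at exactly that cell."""
    grid = {"I": [600.0, 1400.0], "T": [22.0, 32.0], "C_m": [80.0, 160.0]}
    template = Environment(I=1000.0, T=25.0, C_m=100.0, O=200.0, N_t=130.0)
    settings = OptimizerSettings(n_starts=4, seed=9)
    true_env = Environment(I=1400.0, T=22.0, C_m=80.0, O=200.0, N_t=130.0)
    opt = optimize_allocation(c4, true_env, settings)
    measured = synthetic_measurements(
        c4, true_env, opt.alloc, opt.partition, 0.0, 0
    )
    result = environment_scan(c4, measured, grid, template, settings)
    assert result.argmin["I"] == 1400.0
    assert result.argmin["T"] == 22.0
    assert result.argmin["C_m"] == 80.0
    assert result.argmin["error"] == pytest.approx(0.0, abs=1e-10)
    assert len(result.surface) == 8
    assert result.surface["error"].min() == result.argmin["error"]
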