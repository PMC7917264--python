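import numpy as np
import pytest

import gclm
from gclm.data import read_panel_csv, write_panel_csv

from conftest import ar1_params


# -- PanelData / CSV ----------------------------------------------------------

def test_csv_roundtrip(tmp_path, preset_spec, panel500):
    path = tmp_path / "panel.csv"
    write_panel_csv(panel500, path)
    back = read_panel_csv(path, preset_spec)
    assert back.unit_ids == panel500.unit_ids
    assert np.allclose(back.values, panel500.values)


def test_csv_missing_column_named(tmp_path, preset_spec, panel500):
    import pandas as pd
    path = tmp_path / "panel.csv"
    write_panel_csv(panel500, path)
    df = pd.read_csv(path).drop(columns=["swb_4"])
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="swb_4"):
        read_panel_csv(path, preset_spec)


def test_csv_duplicate_units(tmp_path, preset_spec, panel500):
    import pandas as pd
    path = tmp_path / "panel.csv"
    write_panel_csv(panel500, path)
    df = pd.read_csv(path)
    df.loc[1, "unit"] = df.loc[0, "unit"]
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="duplicate"):
        read_panel_csv(path, preset_spec)


def test_csv_non_numeric_cell(tmp_path, preset_spec, panel500):
    import pandas as pd
    path = tmp_path / "panel.csv"
    write_panel_csv(panel500, path)
    df = pd.read_csv(path)
    df["income_3"] = df["income_3"].astype(object)
    df.loc[2, "income_3"] = "oops"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="income_3"):
        read_panel_csv(path, preset_spec)


def test_blank_cell_masked_n_unchanged(tmp_path, preset_spec, panel500):
    import pandas as pd
    path = tmp_path / "panel.csv"
    write_panel_csv(panel500, path)
    df = pd.read_csv(path)
    df.loc[5, "income_2"] = np.nan
    df.to_csv(path, index=False)
    back = read_panel_csv(path, preset_spec)
    assert back.n_units == panel500.n_units
    assert back.mask[5, 1, 0]
    assert back.complete_cases().n_units == panel500.n_units - 1


def test_wide_layout_occasion_major(panel500):
    Y = panel500.wide()
    # entry (t-1)*k + j must be variable j at occasion t
    assert np.allclose(Y[:, 2], panel500.values[:, 1, 0])
    assert np.allclose(Y[:, 3], panel500.values[:, 1, 1])


# -- simulation ---------------------------------------------------------------

def test_simulation_seed_reproducible(preset_spec, preset_params):
    cfg = gclm.SimulationConfig(N=50, seed=9)
    a = gclm.simulate_panel(preset_spec, preset_params, cfg)
    b = gclm.simulate_panel(preset_spec, preset_params, cfg)
    assert np.array_equal(a.values, b.values)
    c = gclm.simulate_panel(preset_spec, preset_params,
                            gclm.SimulationConfig(N=50, seed=10))
    assert not np.array_equal(a.values, c.values)


def test_simulation_rejects_bad_covariance(preset_spec, preset_params):
    import copy
    bad = copy.deepcopy(preset_params)
    bad.psi_u[2] = np.array([[1.0, 2.0], [2.0, 1.0]])   # not PSD
    with pytest.raises(ValueError, match="positive"):
        gclm.simulate_panel(preset_spec, bad, gclm.SimulationConfig(N=10, seed=0))


def test_stationary_burnin_matches_stationary_variance(ar1_spec):
    b, v = 0.6, 1.0
    params = ar1_params(ar1_spec, b=b, var=v)
    panel = gclm.simulate_panel(
        ar1_spec, params,
        gclm.SimulationConfig(N=60000, seed=3, init_mode="stationary-burnin",
                              burnin_length=200))
    target = v / (1 - b * b)
    var1 = panel.values[:, 0, 0].var()
    assert var1 == pytest.approx(target, rel=0.05)


def test_stationary_burnin_rejects_explosive(ar1_spec):
    params = ar1_params(ar1_spec, b=1.05)
    with pytest.raises(ValueError, match="spectral radius"):
        gclm.simulate_panel(ar1_spec, params,
                            gclm.SimulationConfig(N=10, seed=0,
                                                  init_mode="stationary-burnin"))


def test_stationary_burnin_rejects_time_varying(preset_spec, preset_params):
    # preset psi_u varies by occasion (co-movement correlations differ)
    with pytest.raises(ValueError, match="psi_u"):
        gclm.simulate_panel(preset_spec, preset_params,
                            gclm.SimulationConfig(N=10, seed=0,
                                                  init_mode="stationary-burnin"))


def test_preset_spec_is_valid_and_persistent(preset_spec, preset_params):
    assert not gclm.validate_spec(preset_spec)
    assert preset_params.beta[(0, 0, 1, 2)] == pytest.approx(0.97)
    # income -> swb cross effect positive, reverse near zero
    assert preset_params.beta[(1, 0, 1, 2)] > 0.2
    assert abs(preset_params.beta[(0, 1, 1, 2)]) < 0.05


def test_simulation_config_validation():
    with pytest.raises(ValueError):
        gclm.SimulationConfig(N=0)
    with pytest.raises(ValueError):
        gclm.SimulationConfig(N=5, init_mode="bogus")
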