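"""Two-stage estimation: recovery, identifiability, goodness of fit."""

import numpy as np
import pandas as pd
import pytest

from lungpk import estimation, forward, literature_prior_physiology, synthdata
from lungpk.estimation import (
    GofSummary,
    InsufficientDataError,
    NonIdentifiableError,
    goodness_of_fit,
)


@pytest.fixture(scope="module")
def noise_free(fixtures, design):
    err = synthdata.ErrorModel(plasma_cv=0.0, tissue_cv=0.0, seed=0)
    phys = fixtures["salmeterol"][1]
    return {
        name: synthdata.generate_study_data(p, phys, design, err)
        for name, (p, _) in fixtures.items()
    }


def test_systemic_recovery_two_compartment(fixtures, design, noise_free):
    """Noise-free dense plasma data returns the generating parameters."""
    p_true, _ = fixtures["salmeterol"]
    fit = estimation.fit_systemic(noise_free["salmeterol"], n_cpt=2, d=design, seed=3)
    for name, truth in [("cl", 3.86), ("v_c", 0.123), ("q_ic", 3.24), ("v_p", 3.77)]:
        assert fit.estimates[name] == pytest.approx(truth, rel=1e-3)
        assert np.isfinite(fit.cv_percent[name])
    assert fit.n_obs == 65


def test_systemic_one_compartment_fits_to_machine_precision(fixtures, design, noise_free):
    fit = estimation.fit_systemic(noise_free["indomethacin"], n_cpt=1, d=design, seed=3)
    assert fit.objective < 1e-16
    assert fit.estimates["cl"] == pytest.approx(0.0691, rel=1e-6)


def test_insufficient_plasma_data_raises(design):
    df = pd.DataFrame(
        {"drug": "x", "matrix": "plasma", "time_h": [0.5, 1.0, 2.0], "conc": [1.0, 0.8, 0.5]}
    )
    with pytest.raises(InsufficientDataError, match="at least 8"):
        estimation.fit_systemic(df, n_cpt=2, d=design)


def test_tissue_shared_recovery_all_parameters(fixtures, design, noise_free):
    """Noise-free 4-drug tissue data recovers 12 Kp and 3 flows within 1%."""
    params = {n: p for n, (p, _) in fixtures.items()}
    phys = fixtures["salmeterol"][1]
    tissue = {n: df[df["matrix"] != "plasma"] for n, df in noise_free.items()}
    fit = estimation.fit_tissue_shared(
        tissue, params, literature_prior_physiology(), design, seed=11
    )
    truth = {"q_t": phys.q_t, "q_b": phys.q_b, "q_a": phys.q_a}
    for name, (p, _) in fixtures.items():
        truth[f"kp_trachea:{name}"] = p.kp_t
        truth[f"kp_bronchi:{name}"] = p.kp_b
        truth[f"kp_alveolar:{name}"] = p.kp_a
    for name, val in truth.items():
        assert fit.estimates[name] == pytest.approx(val, rel=0.01), name


def test_single_time_point_is_non_identifiable(fixtures, design):
    p, phys = fixtures["salmeterol"]
    t = np.asarray([2.0])
    df = pd.DataFrame(
        {
            "drug": "salmeterol",
            "matrix": "trachea",
            "time_h": t,
            "conc": forward.tissue_conc(p, phys, "trachea", design, t),
        }
    )
    with pytest.raises(NonIdentifiableError, match="trachea"):
        estimation.fit_tissue_shared(
            {"salmeterol": df}, {"salmeterol": p}, literature_prior_physiology(), design
        )


def test_stage_separability_with_flows_fixed_at_truth(fixtures, design, noise_free):
    """Fixing blood flows to truth and refitting Kp alone reproduces Kp."""
    params = {"salmeterol": fixtures["salmeterol"][0]}
    phys = fixtures["salmeterol"][1]
    tissue = {"salmeterol": noise_free["salmeterol"].query("matrix != 'plasma'")}
    fit = estimation.fit_tissue_shared(
        tissue, params, phys, design, estimate_flows=False, seed=5
    )
    assert set(fit.param_names) == {
        "kp_trachea:salmeterol",
        "kp_bronchi:salmeterol",
        "kp_alveolar:salmeterol",
    }
    assert fit.estimates["kp_bronchi:salmeterol"] == pytest.approx(18.6, rel=1e-4)


def test_estimates_invariant_under_record_permutation(fixtures, design, noise_free):
    params = {n: p for n, (p, _) in fixtures.items()}
    tissue = {n: df[df["matrix"] != "plasma"] for n, df in noise_free.items()}
    shuffled = {
        n: df.sample(frac=1.0, random_state=42) for n, df in tissue.items()
    }
    prior = literature_prior_physiology()
    a = estimation.fit_tissue_shared(tissue, params, prior, design, n_starts=1, seed=2)
    b = estimation.fit_tissue_shared(shuffled, params, prior, design, n_starts=1, seed=2)
    assert a.estimates == b.estimates  # bit-identical


def test_prior_and_random_starts_reach_the_same_optimum(fixtures, design, noise_free):
    params = {n: p for n, (p, _) in fixtures.items()}
    tissue = {n: df[df["matrix"] != "plasma"] for n, df in noise_free.items()}
    prior = literature_prior_physiology()
    a = estimation.fit_tissue_shared(tissue, params, prior, design, n_starts=1, seed=0)
    b = estimation.fit_tissue_shared(tissue, params, prior, design, n_starts=5, seed=123)
    for name in a.param_names:
        assert a.estimates[name] == pytest.approx(b.estimates[name], rel=1e-6)


def test_whole_lung_comparator_describes_regional_data_worse(fixtures, design, noise_free):
    """Evaluating the single-compartment lung model against regional
    observations gives a lower R^2 than the separate-tissue model."""
    p, phys = fixtures["salmeterol"]
    tissue_obs = noise_free["salmeterol"].query("matrix != 'plasma'")
    obs = tissue_obs["conc"].to_numpy()
    pred_regional = estimation.predict_for_records(tissue_obs, p, phys, design)
    pred_whole = estimation.predict_for_records(
        tissue_obs, p, phys, design, whole_lung_for_tissues=True
    )
    r2_regional = goodness_of_fit(obs, pred_regional).r_squared
    r2_whole = goodness_of_fit(obs, pred_whole).r_squared
    assert r2_regional == pytest.approx(1.0, abs=1e-9)
    assert r2_whole < r2_regional


def test_whole_lung_fit_recovers_single_compartment_data(fixtures, design):
    """Data generated from the whole-lung model itself is fit perfectly."""
    p, phys = fixtures["linezolid"]
    t = np.asarray(design.tissue_times)
    df = pd.DataFrame(
        {
            "drug": "linezolid",
            "matrix": "whole_lung",
            "time_h": t,
            "conc": forward.tissue_conc(p, phys, "whole_lung", design, t),
        }
    )
    fit = estimation.fit_whole_lung(
        {"linezolid": df}, {"linezolid": p}, literature_prior_physiology(), design, seed=1
    )
    assert fit.estimates["kp_whole_lung:linezolid"] == pytest.approx(p.kp_lung, rel=1e-3)
    pred = forward.tissue_conc(
        p, phys, "whole_lung", design, t
    )  # refit reproduces its own data
    assert goodness_of_fit(df["conc"], pred).r_squared == pytest.approx(1.0)


@pytest.mark.parametrize(
    "obs, pred, r2, frac",
    [
        ([1.0, 2.0, 4.0], [1.0, 2.0, 4.0], 1.0, 1.0),
        ([1.0, 2.0, 4.0], [7.0 / 3] * 3, 0.0, None),
        ([1.0, 2.0, 4.0], [3.0, 6.0, 12.0], None, 0.0),
    ],
)
def test_goodness_of_fit_definitions(obs, pred, r2, frac):
    gof = goodness_of_fit(obs, pred)
    if r2 is not None:
        assert gof.r_squared == pytest.approx(r2)
    if frac is not None:
        assert gof.frac_within_twofold == frac
    assert isinstance(gof, GofSummary)


def test_goodness_of_fit_rejects_empty_input():
    with pytest.raises(ValueError):
        goodness_of_fit([], [])
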