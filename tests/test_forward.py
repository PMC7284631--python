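"""Forward model: closed-form backend against the ODE oracle and limits."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungpk import StudyDesign, forward
from lungpk.domain import ParameterError, TISSUES

TIMES = np.linspace(0.01, 4.0, 60)


@pytest.mark.parametrize("drug", ["salmeterol", "fluticasone", "linezolid", "indomethacin"])
def test_closed_form_matches_ode_oracle(fixtures, design, drug):
    """All matrices agree with full numerical integration to <1e-6 relative."""
    p, phys = fixtures[drug]
    ode = forward.ode_backend(p, phys, design, TIMES)
    for prof in ode:
        if prof.matrix == "plasma":
            cf = forward.plasma_conc(p, design, TIMES)
        else:
            cf = forward.tissue_conc(p, phys, prof.matrix, design, TIMES)
        assert np.max(np.abs(cf - prof.concs) / np.abs(prof.concs)) < 1e-6


def test_one_compartment_infusion_matches_textbook_form(fixtures, design):
    """IND plasma during infusion is (rate/CL)(1 - exp(-CL t / V_C))."""
    p, _ = fixtures["indomethacin"]
    t = np.linspace(0.05, design.infusion_duration, 10)
    expected = (design.infusion_rate / p.cl) * (1 - np.exp(-p.cl * t / p.v_c))
    assert forward.plasma_conc(p, design, t) == pytest.approx(expected, rel=1e-12)


def test_plasma_approaches_rate_over_cl_at_steady_state(fixtures):
    p, _ = fixtures["indomethacin"]
    d = StudyDesign(infusion_duration=5000.0, infusion_rate=2.0)
    css = forward.plasma_conc(p, d, [4999.0])[0]
    assert css == pytest.approx(d.infusion_rate / p.cl, rel=1e-9)


def test_tissue_to_plasma_ratio_reaches_kp_at_steady_state(fixtures):
    p, phys = fixtures["salmeterol"]
    d = StudyDesign(infusion_duration=5000.0)
    t = [4999.0]
    cp = forward.plasma_conc(p, d, t)[0]
    for tissue in TISSUES:
        ct = forward.tissue_conc(p, phys, tissue, d, t)[0]
        assert ct / cp == pytest.approx(p.tissue_kp(tissue), rel=1e-6)


def test_fast_equilibration_limit_tracks_plasma(fixtures, design):
    """Kp = 1 with large Q*fu/V makes tissue follow plasma closely."""
    p, phys = fixtures["indomethacin"]
    p = replace(p, kp_t=1.0, fu_plasma=1.0)
    phys = replace(phys, q_t=5000.0 * phys.w_t)  # k_in = 5000/h
    t = np.linspace(0.1, 4.0, 20)
    cp = forward.plasma_conc(p, design, t)
    ct = forward.tissue_conc(p, phys, "trachea", design, t)
    assert ct == pytest.approx(cp, rel=5e-3)


def test_initial_condition_and_zero_rate(fixtures, design):
    p, phys = fixtures["salmeterol"]
    assert forward.plasma_conc(p, design, [0.0])[0] == 0.0
    d0 = replace(design, infusion_rate=0.0)
    t = np.linspace(0, 4, 9)
    assert np.all(forward.plasma_conc(p, d0, t) == 0.0)
    assert np.all(forward.tissue_conc(p, phys, "bronchi", d0, t) == 0.0)


def test_continuity_at_infusion_stop(fixtures, design):
    p, phys = fixtures["salmeterol"]
    eps = 1e-9
    for f in (
        lambda t: forward.plasma_conc(p, design, t),
        lambda t: forward.tissue_conc(p, phys, "trachea", design, t),
    ):
        lo, hi = f([design.infusion_duration - eps])[0], f([design.infusion_duration + eps])[0]
        assert hi == pytest.approx(lo, rel=1e-6)


def test_input_validation(fixtures, design):
    p, phys = fixtures["salmeterol"]
    with pytest.raises(ValueError, match="non-negative"):
        forward.plasma_conc(p, design, [-0.1])
    with pytest.raises(ParameterError, match="unknown tissue"):
        forward.tissue_conc(p, phys, "liver", design, [1.0])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(alpha=st.floats(min_value=1e-3, max_value=1e3))
def test_linearity_in_infusion_rate(alpha):
    """Scaling the rate by alpha scales every concentration by alpha."""
    from lungpk import default_fixtures

    p, phys = default_fixtures()["salmeterol"]
    d1 = StudyDesign(infusion_rate=1.0)
    d2 = replace(d1, infusion_rate=alpha)
    t = np.array([0.25, 0.75, 2.0, 4.0])
    assert forward.plasma_conc(p, d2, t) == pytest.approx(alpha * forward.plasma_conc(p, d1, t))
    assert forward.tissue_conc(p, phys, "bronchi", d2, t) == pytest.approx(
        alpha * forward.tissue_conc(p, phys, "bronchi", d1, t)
    )


def test_ratio_monotone_toward_kp_during_constant_infusion(fixtures):
    p, phys = fixtures["salmeterol"]
    d = StudyDesign(infusion_duration=50.0)
    t = np.linspace(0.05, 49.0, 200)
    ratio = forward.tissue_conc(p, phys, "trachea", d, t) / forward.plasma_conc(p, d, t)
    assert np.all(np.diff(ratio) > -1e-9)
    assert np.all(ratio < p.kp_t * (1 + 1e-9))


def test_virtual_compartments_do_not_perturb_plasma(fixtures, design):
    """Plasma is identical whatever the tissue parameters are (no feedback)."""
    p, phys = fixtures["salmeterol"]
    base = forward.plasma_conc(p, design, TIMES)
    modified = replace(p, kp_t=1000.0, kp_b=0.001, kp_a=500.0)
    assert np.array_equal(forward.plasma_conc(modified, design, TIMES), base)


def test_simulate_study_layout(fixtures, design):
    p, phys = fixtures["salmeterol"]
    profiles = forward.simulate_study(p, phys, design)
    assert [prof.matrix for prof in profiles] == ["plasma", *TISSUES]
    for prof in profiles[1:]:
        assert tuple(prof.times) == design.tissue_times == (0.25, 0.75, 2.0, 4.0)
    empty = replace(design, tissue_times=())
    assert all(prof.times.size == 0 for prof in forward.simulate_study(p, phys, empty)[1:])


def test_whole_lung_defaults_to_weighted_tissue_mean(fixtures, design):
    """Without a dedicated Kp_lung the whole-lung curve is the tissue-mass-
    weighted mean of the regional curves."""
    p, phys = fixtures["salmeterol"]
    p_no_lung = replace(p, kp_lung=None)
    mix = forward.tissue_conc(p_no_lung, phys, "whole_lung", design, TIMES)
    expected = (
        phys.w_t * forward.tissue_conc(p, phys, "trachea", design, TIMES)
        + phys.w_b * forward.tissue_conc(p, phys, "bronchi", design, TIMES)
        + phys.w_a * forward.tissue_conc(p, phys, "alveolar", design, TIMES)
    ) / phys.w_lung
    assert mix == pytest.approx(expected, rel=1e-12)
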