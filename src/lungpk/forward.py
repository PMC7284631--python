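"""Forward simulation of plasma and regional lung concentrations.

The systemic model (one or two compartments, constant-rate infusion) and
the perfusion-limited tissue regions form a linear time-invariant system,
so every concentration is a sum of exponentials.  The primary backend
propagates those exponential terms in closed form: the bi-/mono-exponential
plasma forcing is convolved analytically through the first-order tissue
filter, and the finite infusion is handled by superposition,
``response(t) - response(t - T_inf)``.  This is exact and stiff-safe (the
fast salmeterol macro rate constant is ~58 1/h, which would make naive
explicit integration stiff).

Each tissue region is a *virtual* compartment driven by total plasma
concentration::

    dC_tis/dt = (Q*fu/V) * C_p(t) - (Q*fu/(V*Kp)) * C_tis

with no feedback onto plasma.  At equilibrium under a constant plasma
concentration, C_tis/C_p = Kp.  A numerical ODE backend (Radau) integrates
the full coupled system as an independent verification oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .domain import (
    DrugParameters,
    ParameterError,
    PhysiologyParameters,
    StudyDesign,
    TISSUES,
)

__all__ = [
    "SimulatedProfile",
    "plasma_conc",
    "tissue_conc",
    "plasma_profile",
    "tissue_profile",
    "simulate_study",
    "ode_backend",
]


@dataclass(frozen=True)
class SimulatedProfile:
    """A noise-free concentration-time curve for one drug and matrix."""

    drug: str
    matrix: str
    times: np.ndarray  # h
    concs: np.ndarray  # amount/L

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        concs = np.asarray(self.concs, dtype=float)
        if times.shape != concs.shape:
            raise ValueError("times and concs must have the same length")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concs", concs)


# ---------------------------------------------------------------------------
# Exponential-term algebra
# ---------------------------------------------------------------------------
# A profile is represented as a list of terms (coef, rate, power) meaning
# coef * t**power * exp(-rate * t); power > 0 only arises in the degenerate
# case where a tissue rate constant coincides with a plasma macro constant.

_Term = tuple[float, float, int]


def _eval_terms(terms: list[_Term], t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for coef, rate, power in terms:
        contrib = coef * np.exp(-rate * t)
        if power:
            contrib = contrib * t**power
        out += contrib
    return out


def _macro_constants(p: DrugParameters) -> tuple[float, float, float]:
    """Two-compartment macro rate constants (lam1 > lam2) and k21."""
    k10 = p.cl / p.v_c
    k12 = p.q_ic / p.v_c
    k21 = p.q_ic / p.v_p
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    lam1 = 0.5 * (s + disc)
    lam2 = (k10 * k21) / lam1  # product form avoids cancellation
    return lam1, lam2, k21


def _plasma_step_terms(p: DrugParameters, rate: float) -> list[_Term]:
    """Terms of C_p(t) for an infusion switched on at t=0 and never stopped."""
    if p.n_compartments == 1:
        k10 = p.cl / p.v_c
        return [(rate / p.cl, 0.0, 0), (-rate / p.cl, k10, 0)]
    lam1, lam2, k21 = _macro_constants(p)
    c1 = (lam1 - k21) / (lam1 - lam2)
    c2 = (k21 - lam2) / (lam1 - lam2)
    b = rate / p.v_c
    return [
        (rate / p.cl, 0.0, 0),  # steady-state plateau; equals b*(c1/lam1 + c2/lam2)
        (-b * c1 / lam1, lam1, 0),
        (-b * c2 / lam2, lam2, 0),
    ]


def _filter_terms(terms: list[_Term], k_in: float, k_a: float) -> list[_Term]:
    """Convolve input terms through dX/dt = k_in * u(t) - k_a * X, X(0)=0."""
    out: list[_Term] = []
    for coef, rate, power in terms:
        if power:
            raise NotImplementedError("nested degenerate convolution not required")
        if abs(k_a - rate) > 1e-9 * (k_a + rate):
            g = k_in * coef / (k_a - rate)
            out.append((g, rate, 0))
            out.append((-g, k_a, 0))
        else:  # resonant limit: integral of e^{-k s} e^{-k (t-s)} is t e^{-k t}
            out.append((k_in * coef, k_a, 1))
    return out


def _pulse(terms: list[_Term], times: np.ndarray, t_inf: float) -> np.ndarray:
    """Finite-infusion response by superposition of two step responses."""
    t = np.asarray(times, dtype=float)
    on = _eval_terms(terms, t)
    shifted = np.clip(t - t_inf, 0.0, None)
    off = _eval_terms(terms, shifted)
    # clip the ~1e-17 cancellation residue at t=0; the response is non-negative
    return np.maximum(on - np.where(t > t_inf, off, 0.0), 0.0)


def _check_times(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t


def _tissue_rates(
    p: DrugParameters, phys: PhysiologyParameters, tissue: str
) -> tuple[float, float]:
    """(k_in, k_a) for one region: influx and efflux rate constants, 1/h."""
    q = phys.tissue_flow(tissue)
    v = phys.tissue_volume(tissue)
    kp = p.tissue_kp(tissue)
    k_in = q * p.fu_plasma / v
    return k_in, k_in / kp


# ---------------------------------------------------------------------------
# Closed-form backend (primary)
# ---------------------------------------------------------------------------

def plasma_conc(p: DrugParameters, d: StudyDesign, times) -> np.ndarray:
    """Plasma concentration at the requested times, closed form."""
    t = _check_times(times)
    return _pulse(_plasma_step_terms(p, d.infusion_rate), t, d.infusion_duration)


def tissue_conc(
    p: DrugParameters, phys: PhysiologyParameters, tissue: str, d: StudyDesign, times
) -> np.ndarray:
    """Regional tissue concentration at the requested times, closed form.

    ``whole_lung`` uses the drug's single-compartment lung parameterisation
    when ``kp_lung`` is set, and otherwise falls back to the tissue-weight-
    weighted mean of the three regional profiles.
    """
    t = _check_times(times)
    if tissue not in ("trachea", "bronchi", "alveolar", "whole_lung"):
        raise ParameterError(f"unknown tissue {tissue!r}")
    if tissue == "whole_lung" and p.kp_lung is None:
        parts = [
            phys.tissue_volume(tis) * tissue_conc(p, phys, tis, d, t)
            for tis in TISSUES
        ]
        return sum(parts) / phys.w_lung
    k_in, k_a = _tissue_rates(p, phys, tissue)
    terms = _filter_terms(_plasma_step_terms(p, d.infusion_rate), k_in, k_a)
    return _pulse(terms, t, d.infusion_duration)


def plasma_profile(p: DrugParameters, d: StudyDesign, times) -> SimulatedProfile:
    t = _check_times(times)
    return SimulatedProfile(p.name, "plasma", t, plasma_conc(p, d, t))


def tissue_profile(
    p: DrugParameters, phys: PhysiologyParameters, tissue: str, d: StudyDesign, times
) -> SimulatedProfile:
    t = _check_times(times)
    return SimulatedProfile(p.name, tissue, t, tissue_conc(p, phys, tissue, d, t))


def simulate_study(
    p: DrugParameters, phys: PhysiologyParameters, d: StudyDesign
) -> list[SimulatedProfile]:
    """Noise-free profiles at the design's sampling times.

    Returns the plasma profile at ``d.plasma_times`` and the three regional
    tissue profiles at ``d.tissue_times``.
    """
    p.validate()
    phys.validate()
    d.validate()
    profiles = [plasma_profile(p, d, np.asarray(d.plasma_times, dtype=float))]
    tissue_t = np.asarray(d.tissue_times, dtype=float)
    for tissue in TISSUES:
        profiles.append(tissue_profile(p, phys, tissue, d, tissue_t))
    return profiles


# ---------------------------------------------------------------------------
# ODE backend (verification oracle)
# ---------------------------------------------------------------------------

def ode_backend(
    p: DrugParameters,
    phys: PhysiologyParameters,
    d: StudyDesign,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-13,
) -> list[SimulatedProfile]:
    """Numerically integrate the full coupled system (Radau).

    Returns profiles for plasma and the three regions (plus ``whole_lung``
    when ``kp_lung`` is set), evaluated at ``times``.  Exists to verify the
    closed-form backend; agreement is < 1e-6 relative in tests.
    """
    t = _check_times(times)
    p.validate()
    phys.validate()
    d.validate()

    matrices = ["plasma", *TISSUES]
    rates = [_tissue_rates(p, phys, tis) for tis in TISSUES]
    if p.kp_lung is not None:
        matrices.append("whole_lung")
        rates.append(_tissue_rates(p, phys, "whole_lung"))

    k10 = p.cl / p.v_c
    two_cpt = p.n_compartments == 2
    k12 = p.q_ic / p.v_c if two_cpt else 0.0
    k21 = p.q_ic / p.v_p if two_cpt else 0.0

    def rhs(_t: float, y: np.ndarray, infusion: float) -> np.ndarray:
        a_c, a_p = y[0], y[1]
        c_p = a_c / p.v_c
        dy = np.empty_like(y)
        dy[0] = infusion - k10 * a_c - k12 * a_c + k21 * a_p
        dy[1] = k12 * a_c - k21 * a_p
        for i, (k_in, k_a) in enumerate(rates):
            dy[2 + i] = k_in * c_p - k_a * y[2 + i]
        return dy

    t_end = max(float(t.max()), d.infusion_duration) if t.size else d.infusion_duration
    y0 = np.zeros(2 + len(rates))
    segments = []
    bounds = [0.0, min(d.infusion_duration, t_end)]
    if t_end > d.infusion_duration:
        bounds.append(t_end)
    y = y0
    for lo, hi, infusion in zip(
        bounds[:-1], bounds[1:], (d.infusion_rate, 0.0)
    ):
        sol = solve_ivp(
            rhs,
            (lo, hi),
            y,
            args=(infusion,),
            method="Radau",
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{lo}, {hi}]: {sol.message}")
        segments.append((lo, hi, sol.sol))
        y = sol.y[:, -1]

    states = np.empty((len(y0), t.size))
    for j, tj in enumerate(t):
        for lo, hi, interp in segments:
            if tj <= hi or (lo, hi, interp) is segments[-1]:
                states[:, j] = interp(min(tj, hi))
                break

    out = [SimulatedProfile(p.name, "plasma", t, states[0] / p.v_c)]
    for i, matrix in enumerate(matrices[1:]):
        out.append(SimulatedProfile(p.name, matrix, t, states[2 + i]))
    return out
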