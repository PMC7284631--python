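"""Two-stage parameter estimation with uncertainty and goodness of fit.

Stage 1 fits the empirical systemic disposition model (CL, V_C and, for
two-compartment drugs, Q, V_P) to the plasma concentration-time data.
Stage 2 fixes the systemic parameters and fits the tissue-specific
partition coefficients per drug together with the three regional blood
flows, which are physiological quantities and therefore shared across all
drugs and estimated simultaneously from the combined tissue data.

Numerical choices (documented in docs/methods.md):

* residuals on log-transformed concentrations (proportional-error
  weighting; the data span more than two orders of magnitude),
* parameters fitted on the log scale to enforce positivity without
  constrained optimisation,
* CV% = 100*SE/estimate with the SE from the delta method on the
  log-scale covariance (so CV% equals 100*SE(log theta)),
* multi-start (default 5 log-uniform restarts, seeded) against local
  optima; best objective wins, ties broken by first found.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import forward
from .domain import (
    DrugParameters,
    PhysiologyParameters,
    StudyDesign,
    TISSUES,
)

__all__ = [
    "FitResult",
    "GofSummary",
    "FitError",
    "InsufficientDataError",
    "NonIdentifiableError",
    "fit_systemic",
    "fit_tissue_shared",
    "fit_whole_lung",
    "goodness_of_fit",
    "predict_for_records",
]

_LOG_FLOOR = 1e-290  # guards log() against transient underflow during search


class FitError(RuntimeError):
    """Optimisation failed to converge."""


class InsufficientDataError(ValueError):
    """Fewer observations than the fit can support."""


class NonIdentifiableError(ValueError):
    """The sampling schedule cannot separate the requested parameters."""


@dataclass(frozen=True)
class FitResult:
    """Point estimates with uncertainty for one estimation stage.

    ``covariance`` is the delta-method covariance of the natural-scale
    estimates, ordered as ``param_names``.
    """

    estimates: dict[str, float]
    cv_percent: dict[str, float]
    objective: float  # sum of squared log residuals
    covariance: np.ndarray
    param_names: tuple[str, ...]
    n_obs: int


@dataclass(frozen=True)
class GofSummary:
    """Goodness of fit of predictions against observations."""

    r_squared: float  # 1 - SSR/SST; may be negative for a poor model
    frac_within_twofold: float  # share of pairs with 0.5 <= pred/obs <= 2


# ---------------------------------------------------------------------------
# Shared machinery
# ---------------------------------------------------------------------------

def _multistart(residual, x0: np.ndarray, n_starts: int, seed: int):
    rng = np.random.default_rng(seed)
    starts = [np.asarray(x0, dtype=float)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(x0 + rng.uniform(-np.log(10.0), np.log(10.0), size=len(x0)))
    best = None
    last_exc: Exception | None = None
    for start in starts:
        try:
            with np.errstate(all="ignore"):
                res = least_squares(residual, start, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception as exc:  # singular Jacobian etc. on a bad start
            last_exc = exc
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost - 1e-12:
            best = res
    if best is None:
        raise FitError(f"no start converged ({last_exc})")
    if not best.success:
        raise FitError(
            "optimisation did not converge: objective "
            f"{2 * best.cost:.6g}, gradient norm {np.linalg.norm(best.grad):.3g}"
        )
    return best


def _fit_result(res, names: tuple[str, ...], n_obs: int) -> FitResult:
    x = res.x
    resid = res.fun
    n_free = len(x)
    dof = max(n_obs - n_free, 1)
    s2 = float(resid @ resid) / dof
    jtj = res.jac.T @ res.jac
    cov_log = s2 * np.linalg.pinv(jtj)
    theta = np.exp(x)
    se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
    cov_nat = cov_log * np.outer(theta, theta)  # delta method
    return FitResult(
        estimates=dict(zip(names, theta)),
        cv_percent=dict(zip(names, 100.0 * se_log)),
        objective=float(resid @ resid),
        covariance=cov_nat,
        param_names=tuple(names),
        n_obs=n_obs,
    )


def _plasma_records(records: pd.DataFrame) -> pd.DataFrame:
    if "matrix" in records.columns:
        records = records[records["matrix"] == "plasma"]
    return records


def _check_positive(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = records["time_h"].to_numpy(dtype=float)
    c = records["conc"].to_numpy(dtype=float)
    if np.any(c <= 0):
        raise InsufficientDataError("concentrations must be strictly positive")
    if np.any(t <= 0):
        raise InsufficientDataError("observation times must be strictly positive")
    # canonical ordering makes the fit invariant to record permutation
    order = np.lexsort((c, t))
    return t[order], c[order]


# ---------------------------------------------------------------------------
# Stage 1: systemic disposition from plasma data
# ---------------------------------------------------------------------------

def fit_systemic(
    records: pd.DataFrame,
    n_cpt: int,
    d: StudyDesign,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit the one- or two-compartment infusion model to plasma data.

    ``records`` is a long-format frame with columns ``time_h`` and ``conc``
    (a ``matrix`` column, if present, is filtered to plasma rows).
    """
    if n_cpt not in (1, 2):
        raise ValueError("n_cpt must be 1 or 2")
    records = _plasma_records(records)
    t, c = _check_positive(records)
    names = ("cl", "v_c") if n_cpt == 1 else ("cl", "v_c", "q_ic", "v_p")
    if len(c) < 2 * len(names):
        raise InsufficientDataError(
            f"need at least {2 * len(names)} plasma observations for "
            f"{len(names)} parameters, got {len(c)}"
        )

    order = np.argsort(t)
    dose = d.infusion_rate * d.infusion_duration
    auc = float(np.trapezoid(c[order], t[order]))
    cl0 = dose / max(auc, 1e-12)
    vc0 = dose / max(float(c.max()), 1e-12)
    x0 = np.log([cl0, vc0] if n_cpt == 1 else [cl0, vc0, cl0, 5.0 * vc0])

    log_obs = np.log(c)

    def residual(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, -200.0, 200.0)  # keep exploratory starts finite
        cl, v_c = np.exp(x[0]), np.exp(x[1])
        if n_cpt == 2:
            q_ic, v_p = np.exp(x[2]), np.exp(x[3])
        else:
            q_ic = v_p = None
        p = DrugParameters("candidate", cl=cl, v_c=v_c, q_ic=q_ic, v_p=v_p)
        pred = forward.plasma_conc(p, d, t)
        return np.log(np.maximum(pred, _LOG_FLOOR)) - log_obs

    best = _multistart(residual, x0, n_starts, seed)
    return _fit_result(best, names, len(c))


# ---------------------------------------------------------------------------
# Stage 2: tissue affinities plus shared regional blood flows
# ---------------------------------------------------------------------------

def _check_tissue_identifiability(
    records_by_drug: dict[str, pd.DataFrame], tissues: tuple[str, ...]
) -> None:
    for tissue in tissues:
        best_n_times = 0
        seen = False
        for df in records_by_drug.values():
            sub = df[df["matrix"] == tissue]
            if len(sub):
                seen = True
                best_n_times = max(best_n_times, sub["time_h"].nunique())
        if seen and best_n_times < 2:
            raise NonIdentifiableError(
                f"{tissue}: observations at fewer than 2 distinct times; "
                "its blood flow and partition coefficient cannot be separated"
            )


def _fit_tissue_generic(
    records_by_drug: dict[str, pd.DataFrame],
    systemic_by_drug: dict[str, DrugParameters],
    phys_init: PhysiologyParameters,
    d: StudyDesign,
    tissues: tuple[str, ...],
    flow_names: dict[str, str],
    kp_field: dict[str, str],
    n_starts: int,
    seed: int,
    estimate_flows: bool = True,
) -> FitResult:
    drugs = sorted(records_by_drug)
    data: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    for drug in drugs:
        df = records_by_drug[drug]
        for tissue in tissues:
            sub = df[df["matrix"] == tissue]
            if not len(sub):
                continue
            t, c = _check_positive(sub)
            data.append((drug, tissue, t, np.log(c)))
    if not data:
        raise InsufficientDataError("no tissue observations supplied")
    if estimate_flows:  # Kp and Q trade off when a tissue has a single time
        _check_tissue_identifiability(records_by_drug, tissues)

    kp_names = [f"kp_{tissue}:{drug}" for drug, tissue, _, _ in data]
    # collapse duplicates while preserving order (one Kp per drug-tissue pair)
    kp_names = list(dict.fromkeys(kp_names))
    q_names = [flow_names[tissue] for tissue in tissues] if estimate_flows else []
    names = tuple(kp_names + q_names)

    # data-driven Kp starts: observed/predicted-plasma ratio at the latest time
    kp0: dict[str, float] = {}
    for drug, tissue, t, log_c in data:
        i_last = int(np.argmax(t))
        cp = float(forward.plasma_conc(systemic_by_drug[drug], d, t[i_last : i_last + 1])[0])
        key = f"kp_{tissue}:{drug}"
        kp0.setdefault(key, max(float(np.exp(log_c[i_last])) / max(cp, 1e-12), 1e-6))
    q0 = {flow_names[tissue]: phys_init.tissue_flow(tissue) for tissue in tissues}
    x0 = np.log([kp0[n] for n in kp_names] + [q0[n] for n in q_names])

    idx = {name: i for i, name in enumerate(names)}
    n_obs = sum(len(t) for _, _, t, _ in data)

    def residual(x: np.ndarray) -> np.ndarray:
        theta = np.exp(np.clip(x, -200.0, 200.0))
        if estimate_flows:
            kwargs = {
                flow_names[tissue]: theta[idx[flow_names[tissue]]] for tissue in tissues
            }
            phys = _replace_phys(phys_init, **kwargs)
        else:
            phys = phys_init
        out = []
        for drug, tissue, t, log_c in data:
            base = systemic_by_drug[drug]
            p = _with_kp(base, kp_field[tissue], theta[idx[f"kp_{tissue}:{drug}"]])
            pred = forward.tissue_conc(p, phys, tissue, d, t)
            out.append(np.log(np.maximum(pred, _LOG_FLOOR)) - log_c)
        return np.concatenate(out)

    best = _multistart(residual, x0, n_starts, seed)
    return _fit_result(best, names, n_obs)


def _replace_phys(phys: PhysiologyParameters, **kwargs) -> PhysiologyParameters:
    from dataclasses import replace

    return replace(phys, **kwargs)


def _with_kp(p: DrugParameters, field: str, value: float) -> DrugParameters:
    from dataclasses import replace

    return replace(p, **{field: value})


def fit_tissue_shared(
    records_by_drug: dict[str, pd.DataFrame],
    systemic_by_drug: dict[str, DrugParameters],
    phys_init: PhysiologyParameters,
    d: StudyDesign,
    n_starts: int = 5,
    seed: int = 0,
    estimate_flows: bool = True,
) -> FitResult:
    """Fit per-drug regional Kp plus the three shared blood flows.

    Free parameters: one partition coefficient per drug and region
    (``kp_<tissue>:<drug>``) plus ``q_t``, ``q_b``, ``q_a`` shared across
    all drugs.  Systemic parameters are held fixed at the supplied values.
    With ``estimate_flows=False`` the blood flows stay fixed at
    ``phys_init`` and only the partition coefficients are free.
    """
    return _fit_tissue_generic(
        records_by_drug,
        systemic_by_drug,
        phys_init,
        d,
        tissues=TISSUES,
        flow_names={"trachea": "q_t", "bronchi": "q_b", "alveolar": "q_a"},
        kp_field={"trachea": "kp_t", "bronchi": "kp_b", "alveolar": "kp_a"},
        n_starts=n_starts,
        seed=seed,
        estimate_flows=estimate_flows,
    )


def fit_whole_lung(
    records_by_drug: dict[str, pd.DataFrame],
    systemic_by_drug: dict[str, DrugParameters],
    phys_init: PhysiologyParameters,
    d: StudyDesign,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Single-compartment lung comparator: one Kp per drug, one shared flow."""
    return _fit_tissue_generic(
        records_by_drug,
        systemic_by_drug,
        phys_init,
        d,
        tissues=("whole_lung",),
        flow_names={"whole_lung": "q_lung"},
        kp_field={"whole_lung": "kp_lung"},
        n_starts=n_starts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def goodness_of_fit(obs, pred) -> GofSummary:
    """R-squared (1 - SSR/SST, may be negative) and two-fold-error fraction."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise ValueError("obs and pred must be non-empty and matched")
    ssr = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else (1.0 if ssr == 0 else -np.inf)
    ratio = pred / obs
    frac = float(np.mean((ratio >= 0.5) & (ratio <= 2.0)))
    return GofSummary(r_squared=r2, frac_within_twofold=frac)


def predict_for_records(
    records: pd.DataFrame,
    p: DrugParameters,
    phys: PhysiologyParameters,
    d: StudyDesign,
    whole_lung_for_tissues: bool = False,
) -> np.ndarray:
    """Model predictions aligned with the rows of a long-format frame.

    With ``whole_lung_for_tissues`` the single-compartment lung model's
    prediction is used for every tissue row, which is how the comparator
    model is evaluated against regional observations.
    """
    preds = np.empty(len(records), dtype=float)
    for i, (_, row) in enumerate(records.iterrows()):
        matrix = row["matrix"]
        t = np.asarray([row["time_h"]], dtype=float)
        if matrix == "plasma":
            preds[i] = forward.plasma_conc(p, d, t)[0]
        elif whole_lung_for_tissues:
            preds[i] = forward.tissue_conc(p, phys, "whole_lung", d, t)[0]
        else:
            preds[i] = forward.tissue_conc(p, phys, matrix, d, t)[0]
    return preds
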