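"""Quantities derived from fitted parameters.

Absorption rate constants and half-lives per lung region, allometric
scaling of the physiology to human, tissue unbound fractions, and the
percent-of-steady-state tissue-to-plasma ratio summaries.

The absorption half-life describes the unidirectional transfer from a
lung region back to the systemic circulation,

    k_a = Q * fu / (V * Kp),        t_half = ln(2) / k_a,

and is a measure of local retention, not a full terminal half-life: it
ignores redistribution from plasma back into the tissue.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .domain import (
    DEFAULT_BW_HUMAN,
    DEFAULT_BW_RAT,
    LN2,
    DrugParameters,
    PhysiologyParameters,
    TISSUES,
)

__all__ = [
    "absorption_rate_constant",
    "half_life",
    "scale_to_human",
    "tissue_fu",
    "percent_of_steady_state",
    "half_life_table",
    "format_duration",
]

#: allometric exponent for blood flows; volumes scale with exponent 1
FLOW_EXPONENT = 0.75


def absorption_rate_constant(
    p: DrugParameters, phys: PhysiologyParameters, tissue: str
) -> float:
    """k_a = Q*fu/(V*Kp) for one lung region, 1/h."""
    q = phys.tissue_flow(tissue)
    v = phys.tissue_volume(tissue)
    return q * p.fu_plasma / (v * p.tissue_kp(tissue))


def half_life(k_a: float) -> float:
    """Absorption half-life ln(2)/k_a, h."""
    if k_a <= 0:
        raise ValueError("absorption rate constant must be positive")
    return LN2 / k_a


def scale_to_human(
    phys: PhysiologyParameters,
    bw_rat: float = DEFAULT_BW_RAT,
    bw_human: float = DEFAULT_BW_HUMAN,
) -> PhysiologyParameters:
    """Allometric scaling of the per-kg physiology from rat to human.

    Absolute flows scale with BW^0.75 and volumes with BW^1; after body
    weight normalisation the per-kg flows change by (BW_h/BW_r)^-0.25 and
    the per-kg volumes are unchanged.  Partition coefficients are assumed
    conserved between species, so every regional absorption half-life grows
    by exactly (BW_h/BW_r)^0.25.
    """
    if bw_rat <= 0 or bw_human <= 0:
        raise ValueError("body weights must be positive")
    f = (bw_human / bw_rat) ** (FLOW_EXPONENT - 1.0)
    return replace(
        phys,
        q_t=phys.q_t * f,
        q_b=phys.q_b * f,
        q_a=phys.q_a * f,
        q_lung=phys.q_lung * f,
        bw=bw_human,
    )


def tissue_fu(fu_plasma: float, kp: float) -> float:
    """Unbound fraction in tissue, fu_plasma/Kp.

    Follows from assuming equal unbound concentrations in plasma and
    tissue at distribution equilibrium.
    """
    if fu_plasma <= 0 or kp <= 0:
        raise ValueError("inputs must be positive")
    return fu_plasma / kp


def percent_of_steady_state(
    records: pd.DataFrame, kp: float, tissue: str
) -> pd.DataFrame:
    """Observed tissue-to-plasma ratio as % of its steady-state value (Kp).

    ``records`` holds long-format rows for one drug containing the tissue
    replicates and plasma observations; each tissue time must have a
    positive plasma observation at the same time (averaged if several).
    Ratios are formed per replicate and then aggregated, returning columns
    ``time_h``, ``mean_percent``, ``sd_percent``, ``n``.
    """
    if kp <= 0:
        raise ValueError("kp must be positive")
    tis = records[records["matrix"] == tissue]
    plasma = records[records["matrix"] == "plasma"]
    if not len(tis):
        raise ValueError(f"no {tissue} observations")
    rows = []
    for t, group in tis.groupby("time_h"):
        cp = plasma.loc[plasma["time_h"] == t, "conc"]
        if not len(cp) or float(cp.mean()) <= 0:
            raise ValueError(f"no positive plasma observation at t={t} h")
        pct = 100.0 * group["conc"].to_numpy() / (float(cp.mean()) * kp)
        rows.append(
            {
                "time_h": t,
                "mean_percent": float(np.mean(pct)),
                "sd_percent": float(np.std(pct, ddof=1)) if len(pct) > 1 else 0.0,
                "n": len(pct),
            }
        )
    return pd.DataFrame(rows).sort_values("time_h", ignore_index=True)


def half_life_table(
    fixtures: dict[str, tuple[DrugParameters, PhysiologyParameters]],
    bw_human: float = DEFAULT_BW_HUMAN,
    include_whole_lung: bool = True,
) -> pd.DataFrame:
    """Rat and human absorption half-lives for every drug and region.

    Returns columns ``drug``, ``tissue``, ``t_half_rat_h``,
    ``t_half_human_h`` plus display-formatted strings.  Internal unit is
    hours; magnitude-dependent h/min/s formatting is presentation only.
    """
    rows = []
    for drug, (p, phys) in fixtures.items():
        tissues = list(TISSUES) + (
            ["whole_lung"] if include_whole_lung and p.kp_lung is not None else []
        )
        phys_h = scale_to_human(phys, bw_rat=phys.bw, bw_human=bw_human)
        for tissue in tissues:
            t_rat = half_life(absorption_rate_constant(p, phys, tissue))
            t_hum = half_life(absorption_rate_constant(p, phys_h, tissue))
            rows.append(
                {
                    "drug": drug,
                    "tissue": tissue,
                    "t_half_rat_h": t_rat,
                    "t_half_human_h": t_hum,
                    "t_half_rat": format_duration(t_rat),
                    "t_half_human": format_duration(t_hum),
                }
            )
    return pd.DataFrame(rows)


def format_duration(hours: float) -> str:
    """Format a duration in h, min, or s depending on magnitude."""
    if hours >= 1.0:
        return f"{hours:.3g} h"
    minutes = hours * 60.0
    if minutes >= 1.0:
        return f"{minutes:.3g} min"
    return f"{minutes * 60.0:.2g} s"
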