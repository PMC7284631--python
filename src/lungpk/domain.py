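"""Core data types, packaged parameter values, and validation.

Regional lung pharmacokinetics after constant-rate intravenous infusion in
the rat: four model drugs (salmeterol, fluticasone propionate, linezolid,
indomethacin) with empirical one- or two-compartment systemic disposition
and perfusion-limited distribution into three lung regions -- trachea,
bronchi, and alveolar parenchyma.  Each region is a "virtual" compartment
(no feedback onto the systemic mass balance) characterised by a
tissue-to-plasma partition coefficient ``Kp`` and a regional blood flow
that is scaled by the fraction unbound in plasma, since only unbound drug
is assumed to permeate into tissue.

All kinetic parameters are normalised to body weight (L/h/kg, L/kg).
Concentrations carry an arbitrary amount/L unit throughout: every headline
output (half-life, tissue-to-plasma ratio, fold bias) is unit-free or
time-valued, so no unit registry is maintained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "LN2",
    "TISSUES",
    "MATRICES",
    "DEFAULT_BW_RAT",
    "DEFAULT_BW_HUMAN",
    "ParameterError",
    "DrugParameters",
    "PhysiologyParameters",
    "StudyDesign",
    "ConcentrationRecord",
    "validate_parameters",
    "fu_from_free_ec50",
    "fu_from_half_life",
    "default_physiology",
    "default_fixtures",
    "literature_prior_physiology",
]

logger = logging.getLogger("lungpk")

LN2 = math.log(2.0)

#: The three separately sampled lung regions, ordered proximal to distal.
TISSUES = ("trachea", "bronchi", "alveolar")
#: All observation matrices appearing in long-format records.
MATRICES = ("plasma", "trachea", "bronchi", "alveolar", "whole_lung")

DEFAULT_BW_RAT = 0.28  # kg, mean body weight of the study animals
DEFAULT_BW_HUMAN = 70.0  # kg


class ParameterError(ValueError):
    """A parameter set violates one of its invariants."""


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ParameterError(message)


@dataclass(frozen=True)
class DrugParameters:
    """Systemic disposition and lung tissue affinity for one drug.

    ``q_ic``/``v_p`` (intercompartmental clearance and peripheral volume)
    are both present for two-compartment drugs and both absent for
    one-compartment drugs.  Partition coefficients may be left unset when
    only the systemic model is needed (e.g. during stage-1 estimation).
    """

    name: str
    cl: float  # clearance, L/h/kg
    v_c: float  # central volume, L/kg
    q_ic: float | None = None  # intercompartmental clearance, L/h/kg
    v_p: float | None = None  # peripheral volume, L/kg
    fu_plasma: float = 1.0  # fraction unbound in plasma, (0, 1]
    kp_t: float | None = None  # trachea-to-plasma partition coefficient
    kp_b: float | None = None  # bronchi-to-plasma partition coefficient
    kp_a: float | None = None  # alveolar-to-plasma partition coefficient
    kp_lung: float | None = None  # optional whole-lung partition coefficient

    @property
    def n_compartments(self) -> int:
        return 1 if self.q_ic is None else 2

    def tissue_kp(self, tissue: str) -> float:
        kp = {
            "trachea": self.kp_t,
            "bronchi": self.kp_b,
            "alveolar": self.kp_a,
            "whole_lung": self.kp_lung,
        }.get(tissue)
        if kp is None:
            raise ParameterError(
                f"{self.name}: no partition coefficient available for tissue {tissue!r}"
            )
        return kp

    def validate(self) -> "DrugParameters":
        _require(self.cl > 0, "clearance must be strictly positive")
        _require(self.v_c > 0, "central volume must be strictly positive")
        _require(
            (self.q_ic is None) == (self.v_p is None),
            "q_ic and v_p must be both present or both absent",
        )
        if self.q_ic is not None:
            _require(self.q_ic > 0, "intercompartmental clearance must be strictly positive")
            _require(self.v_p > 0, "peripheral volume must be strictly positive")
        _require(0.0 < self.fu_plasma <= 1.0, "fraction unbound must be in (0,1]")
        for label, kp in (
            ("kp_t", self.kp_t),
            ("kp_b", self.kp_b),
            ("kp_a", self.kp_a),
            ("kp_lung", self.kp_lung),
        ):
            if kp is not None:
                _require(kp > 0, f"{label} must be strictly positive")
        return self


@dataclass(frozen=True)
class PhysiologyParameters:
    """Body-weight-normalised lung tissue volumes and blood flows."""

    w_t: float  # trachea weight fraction, kg/kg
    w_b: float  # bronchi weight fraction, kg/kg
    w_a: float  # alveolar parenchyma weight fraction, kg/kg
    q_t: float  # tracheal blood flow, L/h/kg
    q_b: float  # bronchial blood flow, L/h/kg
    q_a: float  # alveolar blood flow, L/h/kg
    w_lung: float  # whole-lung weight fraction, kg/kg
    q_lung: float  # whole-lung blood flow, L/h/kg
    bw: float = DEFAULT_BW_RAT  # body weight, kg

    def tissue_volume(self, tissue: str) -> float:
        """Distribution volume of a region, L/kg (1 kg tissue == 1 L)."""
        try:
            return {
                "trachea": self.w_t,
                "bronchi": self.w_b,
                "alveolar": self.w_a,
                "whole_lung": self.w_lung,
            }[tissue]
        except KeyError:
            raise ParameterError(f"unknown tissue {tissue!r}") from None

    def tissue_flow(self, tissue: str) -> float:
        """Blood flow perfusing a region, L/h/kg."""
        try:
            return {
                "trachea": self.q_t,
                "bronchi": self.q_b,
                "alveolar": self.q_a,
                "whole_lung": self.q_lung,
            }[tissue]
        except KeyError:
            raise ParameterError(f"unknown tissue {tissue!r}") from None

    def validate(self) -> "PhysiologyParameters":
        for label, v in (
            ("w_t", self.w_t),
            ("w_b", self.w_b),
            ("w_a", self.w_a),
            ("q_t", self.q_t),
            ("q_b", self.q_b),
            ("q_a", self.q_a),
            ("w_lung", self.w_lung),
            ("q_lung", self.q_lung),
            ("bw", self.bw),
        ):
            _require(v > 0, f"{label} must be strictly positive")
        _require(
            math.isclose(self.w_t + self.w_b + self.w_a, self.w_lung, rel_tol=1e-9),
            "tissue weights must sum to lung weight",
        )
        return self


@dataclass(frozen=True)
class StudyDesign:
    """Infusion regimen and sampling schedule of one study arm.

    The infusion rate carries an arbitrary amount unit per h per kg; all
    quantities reported by the package are dose-invariant under linear PK.
    """

    infusion_duration: float = 1.0  # h
    infusion_rate: float = 1.0  # amount/h/kg
    plasma_times: tuple[float, ...] = ()
    tissue_times: tuple[float, ...] = (0.25, 0.75, 2.0, 4.0)
    tissue_replicates: int = 3
    bw: float = DEFAULT_BW_RAT  # kg

    def __post_init__(self) -> None:
        object.__setattr__(self, "plasma_times", tuple(self.plasma_times))
        object.__setattr__(self, "tissue_times", tuple(self.tissue_times))

    def validate(self) -> "StudyDesign":
        _require(self.infusion_duration > 0, "infusion duration must be positive")
        _require(self.infusion_rate >= 0, "infusion rate must be non-negative")
        for label, times in (("plasma_times", self.plasma_times), ("tissue_times", self.tissue_times)):
            _require(all(t >= 0 for t in times), f"{label} must be non-negative")
            _require(list(times) == sorted(times), f"{label} must be sorted")
        _require(self.tissue_replicates >= 1, "tissue_replicates must be >= 1")
        _require(self.bw > 0, "body weight must be positive")
        return self


@dataclass(frozen=True)
class ConcentrationRecord:
    """One long-format observation row."""

    drug: str
    matrix: str  # one of MATRICES
    time: float  # h
    conc: float  # amount/L

    def validate(self) -> "ConcentrationRecord":
        _require(self.matrix in MATRICES, f"unknown matrix {self.matrix!r}")
        _require(self.time >= 0, "time must be non-negative")
        _require(self.conc >= 0, "concentration must be non-negative")
        return self


def validate_parameters(
    p: DrugParameters, phys: PhysiologyParameters
) -> tuple[DrugParameters, PhysiologyParameters]:
    """Validate a drug/physiology pair, returning it unchanged.

    Raises :class:`ParameterError` naming the first violated invariant.
    """
    return p.validate(), phys.validate()


# ---------------------------------------------------------------------------
# Fraction-unbound derivations
# ---------------------------------------------------------------------------

def fu_from_free_ec50(ec50_total: float, ec50_free: float, kp_b: float) -> float:
    """Solve ``ec50_free = ec50_total * fu / kp_b`` for the plasma fu.

    The free EC50 in the bronchial target tissue relates to a total-tissue
    EC50 through the tissue unbound fraction fu/Kp_B.
    """
    return ec50_free * kp_b / ec50_total


def fu_from_half_life(t_half_h: float, kp: float, q: float, v: float) -> float:
    """Solve ``t_half = ln2 * V * Kp / (Q * fu)`` for the plasma fu."""
    return LN2 * v * kp / (q * t_half_h)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _load_fixture_config() -> dict:
    text = (resources.files("lungpk") / "data" / "fixtures.yaml").read_text()
    return yaml.safe_load(text)


def default_physiology() -> PhysiologyParameters:
    """Rat lung physiology used throughout: fixed tissue weights, fitted flows."""
    cfg = _load_fixture_config()["physiology"]
    return PhysiologyParameters(**cfg).validate()


def _resolve_fu(name: str, entry: Mapping, phys: PhysiologyParameters) -> float:
    anchor = entry.get("fu_anchor")
    if anchor is None:
        fu = float(entry.get("fu_plasma", 1.0))
        if entry.get("fu_assumed"):
            logger.warning(
                "%s: fraction unbound is not derivable from the packaged anchors; "
                "defaulting to fu_plasma = %.3g (supply a measured value for "
                "quantitative half-life work)",
                name,
                fu,
            )
        return fu
    if anchor["kind"] == "free_ec50":
        return fu_from_free_ec50(
            anchor["ec50_total_nm"], anchor["ec50_free_nm"], entry["kp_b"]
        )
    if anchor["kind"] == "half_life":
        tissue = anchor["tissue"]
        if "t_half_h" in anchor:
            t_half = anchor["t_half_h"]
        elif "t_half_min" in anchor:
            t_half = anchor["t_half_min"] / 60.0
        else:
            t_half = anchor["t_half_s"] / 3600.0
        kp = {"trachea": "kp_t", "bronchi": "kp_b", "alveolar": "kp_a"}[tissue]
        return fu_from_half_life(
            t_half, entry[kp], phys.tissue_flow(tissue), phys.tissue_volume(tissue)
        )
    raise ParameterError(f"{name}: unknown fu anchor kind {anchor['kind']!r}")


def default_fixtures() -> dict[str, tuple[DrugParameters, PhysiologyParameters]]:
    """The four packaged model drugs paired with the rat physiology.

    Keys: ``salmeterol``, ``fluticasone``, ``linezolid``, ``indomethacin``.
    Fraction-unbound values are resolved from the anchors recorded in the
    packaged config (see the fixtures file and docs/methods.md).
    """
    cfg = _load_fixture_config()
    phys = PhysiologyParameters(**cfg["physiology"]).validate()
    out: dict[str, tuple[DrugParameters, PhysiologyParameters]] = {}
    for name, entry in cfg["drugs"].items():
        fu = _resolve_fu(name, entry, phys)
        p = DrugParameters(
            name=name,
            cl=entry["cl"],
            v_c=entry["v_c"],
            q_ic=entry.get("q_ic"),
            v_p=entry.get("v_p"),
            fu_plasma=fu,
            kp_t=entry["kp_t"],
            kp_b=entry["kp_b"],
            kp_a=entry["kp_a"],
            kp_lung=entry.get("kp_lung"),
        ).validate()
        out[name] = (p, phys)
    return out


def literature_prior_physiology(bw: float = DEFAULT_BW_RAT) -> PhysiologyParameters:
    """Blood-flow starting values from literature physiology.

    Alveolar flow from mean rat cardiac output (15.1 L/h/kg); the
    tracheobronchial circulation as 2.1% of cardiac output, split between
    trachea and bronchi in proportion to tissue weight.  Tissue weights are
    the fixed anatomical fractions.
    """
    cardiac_output = 15.1
    q_airways = 0.021 * cardiac_output
    w_t, w_b, w_a = 0.0002, 0.0008, 0.004
    return PhysiologyParameters(
        w_t=w_t,
        w_b=w_b,
        w_a=w_a,
        q_t=q_airways * w_t / (w_t + w_b),
        q_b=q_airways * w_b / (w_t + w_b),
        q_a=cardiac_output,
        w_lung=w_t + w_b + w_a,
        q_lung=cardiac_output,
        bw=bw,
    ).validate()
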