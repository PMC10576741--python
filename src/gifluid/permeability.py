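"""Absorption clearance, effective permeability, and the villous blood-flow
rate-limiting comparison.

``CL_abs = k_abs * V_lumen`` converts a first-order absorption rate constant
into a clearance (mL/min) for the loop's distribution volume (1 mL dose).
``P_eff = CL_abs / S`` normalises by the loop mucosal surface area
(11.2 cm^2) and is reported in cm/s.

Water absorption is so fast that the mucosal (villous) blood flow, rather
than membrane permeation, can be the rate-limiting step.  Villous flow is
taken as a fixed fraction (~20%) of portal flow (32.9 mL/min/kg in rat),
scaled to the animal's mass and to the loop's share of total intestinal
length; comparing it with ``CL_abs`` classifies absorption as
blood-flow-limited when the clearance is a sizeable fraction of the flow.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ValidationError
from .kinetics import DEFAULT_S_RATIO
from .volumes import DEFAULT_SURFACE_AREA_CM2

__all__ = [
    "SECONDS_PER_MINUTE",
    "DEFAULT_Q_PORTAL_ML_MIN_KG",
    "DEFAULT_VILLOUS_FRACTION",
    "DEFAULT_BODY_MASS_KG",
    "PermeabilityResult",
    "BloodFlowComparison",
    "absorption_clearance",
    "effective_permeability",
    "permeability_for_region",
    "villous_blood_flow",
    "round_sig",
]

#: min -> s conversion for permeability reporting.
SECONDS_PER_MINUTE = 60.0

#: Portal venous blood flow in rat (mL/min/kg).
DEFAULT_Q_PORTAL_ML_MIN_KG = 32.9

#: Villous mucosal flow as a fraction of portal flow.
DEFAULT_VILLOUS_FRACTION = 0.20

#: Body mass (kg) used to scale per-kg flows to the experimental animal.
DEFAULT_BODY_MASS_KG = 0.25


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (report style)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class PermeabilityResult:
    """Clearance and permeability of fluid for one intestinal region."""

    region: str
    cl_abs_ml_per_min: float
    p_eff_cm_per_s: float
    surface_area_cm2: float
    v_lumen_ml: float

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "cl_abs_ml_per_min": self.cl_abs_ml_per_min,
            "p_eff_cm_per_s": self.p_eff_cm_per_s,
            "p_eff_1e4_cm_per_s_3sf": round_sig(self.p_eff_cm_per_s * 1e4, 3),
            "surface_area_cm2": self.surface_area_cm2,
            "v_lumen_ml": self.v_lumen_ml,
        }


@dataclass(frozen=True)
class BloodFlowComparison:
    """Villous blood flow estimate and the clearance/flow comparison."""

    q_portal_ml_per_min_per_kg: float
    villous_fraction: float
    body_mass_kg: float
    length_fraction: float
    q_villi_ml_per_min_per_kg: float
    q_villi_loop_ml_per_min: float
    cl_abs_ml_per_min: float | None = None
    cl_over_q_villi: float | None = None
    classification: str | None = None

    def to_dict(self) -> dict:
        return {
            "q_portal_ml_per_min_per_kg": self.q_portal_ml_per_min_per_kg,
            "villous_fraction": self.villous_fraction,
            "body_mass_kg": self.body_mass_kg,
            "length_fraction": self.length_fraction,
            "q_villi_ml_per_min_per_kg": self.q_villi_ml_per_min_per_kg,
            "q_villi_loop_ml_per_min": self.q_villi_loop_ml_per_min,
            "cl_abs_ml_per_min": self.cl_abs_ml_per_min,
            "cl_over_q_villi": self.cl_over_q_villi,
            "classification": self.classification,
        }


def absorption_clearance(k_abs: float, v_lumen: float = 1.0) -> float:
    """Fluid absorption clearance ``k_abs * v_lumen`` (mL/min)."""
    if not k_abs > 0:
        raise ValidationError(f"k_abs must be > 0, got {k_abs}")
    if not v_lumen > 0:
        raise ValidationError(f"v_lumen must be > 0, got {v_lumen}")
    return k_abs * v_lumen


def effective_permeability(
    cl_abs: float, s: float = DEFAULT_SURFACE_AREA_CM2
) -> float:
    """Effective permeability ``(CL_abs / S) / 60`` in cm/s.

    Full precision is returned; report writers round to 3 significant
    figures via :func:`round_sig`.
    """
    if not s > 0:
        raise ValidationError(f"surface area must be > 0, got {s}")
    return (cl_abs / s) / SECONDS_PER_MINUTE


def permeability_for_region(
    region: str,
    k_abs: float,
    v_lumen: float = 1.0,
    s: float = DEFAULT_SURFACE_AREA_CM2,
) -> PermeabilityResult:
    """Bundle CL_abs and P_eff for one region."""
    cl = absorption_clearance(k_abs, v_lumen)
    return PermeabilityResult(
        region=region,
        cl_abs_ml_per_min=cl,
        p_eff_cm_per_s=effective_permeability(cl, s),
        surface_area_cm2=s,
        v_lumen_ml=v_lumen,
    )


def villous_blood_flow(
    q_portal: float = DEFAULT_Q_PORTAL_ML_MIN_KG,
    fraction: float = DEFAULT_VILLOUS_FRACTION,
    body_mass: float = DEFAULT_BODY_MASS_KG,
    length_fraction: float = DEFAULT_S_RATIO,
    cl_abs: float | None = None,
    limited_threshold: float = 0.5,
) -> BloodFlowComparison:
    """Villous blood flow for the loop and the rate-limiting classification.

    ``Q_villi/kg = q_portal * fraction``; the loop's flow is that per-kg
    value times ``body_mass`` times the loop's share of total intestinal
    length.  When ``cl_abs`` is supplied the ratio ``CL_abs / Q_villi`` is
    formed and absorption is classified ``blood-flow-limited`` when the
    ratio reaches ``limited_threshold``, else ``permeability-limited``.
    """
    for name, val in (
        ("q_portal", q_portal), ("fraction", fraction),
        ("body_mass", body_mass), ("length_fraction", length_fraction),
    ):
        if not val > 0:
            raise ValidationError(f"{name} must be > 0, got {val}")
    for name, val in (("fraction", fraction), ("length_fraction", length_fraction)):
        if val > 1:
            raise ValidationError(f"{name} must be in (0, 1], got {val}")
    q_villi_kg = q_portal * fraction
    q_villi_loop = q_villi_kg * body_mass * length_fraction
    ratio = None
    classification = None
    if cl_abs is not None:
        ratio = cl_abs / q_villi_loop
        classification = (
            "blood-flow-limited" if ratio >= limited_threshold else "permeability-limited"
        )
    return BloodFlowComparison(
        q_portal_ml_per_min_per_kg=q_portal,
        villous_fraction=fraction,
        body_mass_kg=body_mass,
        length_fraction=length_fraction,
        q_villi_ml_per_min_per_kg=q_villi_kg,
        q_villi_loop_ml_per_min=q_villi_loop,
        cl_abs_ml_per_min=cl_abs,
        cl_over_q_villi=ratio,
        classification=classification,
    )
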