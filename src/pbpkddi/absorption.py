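"""Mechanistic oral absorption.

Five lumped gastrointestinal lumen segments (stomach, duodenum, jejunum,
ileum, colon) with a fixed luminal pH profile and first-order transit carry
solid and dissolved drug.  Formulations release drug by one of three
mechanisms: immediate (solution), an integrated Weibull profile
(tablets), or particle dissolution of monodisperse shrinking spheres
(suspensions) with optional supersaturation and first-order precipitation.
Dissolved drug permeates into the gut wall, where it is exposed to mucosal
CYP3A4 before reaching the portal vein; meals slow gastric emptying in
proportion to their caloric content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .compound import CompoundParameters, ph_solubility

SEGMENTS = ("stomach", "duodenum", "jejunum", "ileum", "colon")

#: fasted-state luminal pH per segment (configurable; the profile rises from
#: the acidic stomach to near-neutral distal segments)
SEGMENT_PH = {
    "stomach": 1.3,
    "duodenum": 6.0,
    "jejunum": 6.5,
    "ileum": 7.0,
    "colon": 6.5,
}

#: luminal water volumes, L
SEGMENT_VOLUME_L = {
    "stomach": 0.25,
    "duodenum": 0.05,
    "jejunum": 0.15,
    "ileum": 0.12,
    "colon": 0.05,
}

#: first-order transit rate constants, 1/min (fasted gastric half-emptying
#: time 15 min; ~4.3 h mean small-intestinal residence, within the reported
#: physiological 2–6 h range; ~20 h colon residence)
SEGMENT_TRANSIT_PER_MIN = {
    "stomach": math.log(2.0) / 15.0,
    "duodenum": 1.0 / 15.0,
    "jejunum": 1.0 / 90.0,
    "ileum": 1.0 / 150.0,
    "colon": 1.0 / 1200.0,
}

#: effective absorptive surface area per segment, cm² (mucosal surface with
#: villous amplification; stomach wall absorption is neglected)
SEGMENT_AREA_CM2 = {
    "stomach": 0.0,
    "duodenum": 2.0e4,
    "jejunum": 8.0e4,
    "ileum": 6.0e4,
    "colon": 5.0e3,
}


@dataclass(frozen=True)
class FormulationModel:
    """Dissolution/release description for one (compound, formulation) pair."""

    kind: str  # "iv_infusion" | "solution" | "weibull" | "particle"
    dissolution_time_t50: float = 0.0  # min, Weibull 50% dissolution time
    dissolution_shape: float = 1.0
    lag_time: float = 0.0  # min
    particle_radius: float = 0.0  # µm
    drug_density: float = 0.0  # g/cm³
    unstirred_water_layer: float = 0.0  # µm
    supersaturation_enabled: bool = False
    precipitation_half_life: float = 10.0  # min
    gastric_release_blocked: bool = False  # enteric coating
    permeability: float | None = None  # cm/min, unit-normalized at load
    segment_solubility_override: dict | None = None  # mg/mL per segment
    name: str = ""

    def __post_init__(self):
        if self.kind not in ("iv_infusion", "solution", "weibull", "particle"):
            raise ValueError(f"unknown formulation kind {self.kind!r}")
        if self.kind == "weibull":
            if self.dissolution_time_t50 <= 0 or self.dissolution_shape <= 0:
                raise ValueError("Weibull formulation needs t50 > 0 and shape > 0")
        if self.kind == "particle":
            if min(
                self.particle_radius, self.drug_density, self.unstirred_water_layer
            ) <= 0:
                raise ValueError(
                    "particle formulation needs radius, density and water layer > 0"
                )
        if self.lag_time < 0:
            raise ValueError("lag time must be >= 0")


@dataclass(frozen=True)
class MealEvent:
    time: float  # h after first dose
    energy: float  # kcal
    solid_fraction: float = 0.8

    def __post_init__(self):
        if self.energy < 0:
            raise ValueError("meal energy must be >= 0")
        if not (0.0 <= self.solid_fraction <= 1.0):
            raise ValueError("solid fraction outside [0, 1]")


@dataclass
class GILumenState:
    """State of one lumen segment (amounts in mg)."""

    segment: str
    solid_mass: float = 0.0
    dissolved_mass: float = 0.0
    ph: float = 6.5
    transit_rate: float = 0.0  # 1/min
    effective_particle_radius: float = 0.0  # µm
    volume_l: float = 0.1


def segment_state(segment: str, **kwargs) -> GILumenState:
    """Construct a segment state pre-filled with the physiological profile."""
    base = dict(
        segment=segment,
        ph=SEGMENT_PH[segment],
        transit_rate=SEGMENT_TRANSIT_PER_MIN[segment],
        volume_l=SEGMENT_VOLUME_L[segment],
    )
    base.update(kwargs)
    return GILumenState(**base)


# ---------------------------------------------------------------------------
# Weibull release

def weibull_fraction_dissolved(t: float, formulation: FormulationModel) -> float:
    """Cumulative fraction released at time ``t`` (min) after administration.

    F(t) = 1 - exp(-ln2 * ((t - lag)/t50)^shape) for t > lag, else 0, so the
    release reaches exactly 50% one dissolution time past the lag.
    """
    if t < 0:
        raise ValueError("negative time")
    if formulation.kind != "weibull":
        raise ValueError("formulation is not a Weibull release model")
    tau = t - formulation.lag_time
    if tau <= 0.0:
        return 0.0
    return 1.0 - math.exp(
        -math.log(2.0)
        * (tau / formulation.dissolution_time_t50) ** formulation.dissolution_shape
    )


def weibull_release_hazard(t: float, formulation: FormulationModel) -> float:
    """Instantaneous first-order release rate k(t) = F'(t)/(1-F(t)), 1/min.

    Lets the engine release the *remaining* solid at the Weibull hazard, which
    keeps the lumen mass balance exact even while the solid transits between
    segments.
    """
    tau = t - formulation.lag_time
    if tau <= 0.0:
        return 0.0
    t50, b = formulation.dissolution_time_t50, formulation.dissolution_shape
    return math.log(2.0) * b * tau ** (b - 1.0) / t50 ** b


# ---------------------------------------------------------------------------
# Particle dissolution / precipitation

def _diffusion_coefficient_cm2_min(molecular_weight: float) -> float:
    # aqueous diffusion from molar mass (Hayduk–Laudie-type size scaling)
    return 9.9e-5 * molecular_weight ** -0.453 * 60.0


def local_solubility(
    compound: CompoundParameters,
    segment: str,
    ph: float,
    formulation: FormulationModel | None = None,
) -> float:
    """Saturation solubility (mg/mL) in one segment, honoring any
    per-formulation override table (the delayed-release tablet carries
    adapted intestinal solubilities)."""
    if formulation is not None and formulation.segment_solubility_override:
        if segment in formulation.segment_solubility_override:
            return float(formulation.segment_solubility_override[segment])
    return ph_solubility(compound, ph)


def particle_dissolution_rate(
    state: GILumenState,
    compound: CompoundParameters,
    formulation: FormulationModel,
) -> float:
    """Dissolution rate (mg/min) of monodisperse shrinking spheres.

    Nernst–Brunner form: rate = A_total * (D/h) * (Cs - C), with the total
    surface area 3*m/(rho*r) of the remaining particles.  Zero once the solid
    is exhausted or the lumen is at (or beyond) saturation, so dissolution
    never drives the dissolved mass negative.
    """
    if formulation.kind != "particle":
        raise ValueError("formulation is not a particle dissolution model")
    if state.solid_mass <= 0.0:
        return 0.0
    r_cm = max(state.effective_particle_radius, 1e-3) * 1e-4  # µm -> cm
    h_cm = formulation.unstirred_water_layer * 1e-4
    rho = formulation.drug_density * 1000.0  # g/cm³ -> mg/cm³... (mg/mL == g/L)
    # surface area of N spheres carrying solid_mass mg at density g/cm³:
    # A [cm²] = 3 m / (rho r) with m in mg and rho in mg/cm³
    area = 3.0 * state.solid_mass / (formulation.drug_density * 1e3 * r_cm)
    d = _diffusion_coefficient_cm2_min(compound.molecular_weight)
    cs = local_solubility(compound, state.segment, state.ph, formulation)
    conc = state.dissolved_mass / (state.volume_l * 1000.0)  # mg/mL
    rate = area * d / h_cm * (cs - conc)
    return max(rate, 0.0)


def apply_precipitation(
    state: GILumenState,
    compound: CompoundParameters,
    formulation: FormulationModel,
    dt_min: float,
) -> GILumenState:
    """Move supersaturated dissolved drug back to the solid pool.

    First-order decay of the excess above local saturation with the
    formulation's precipitation half-life (``dt_min = inf`` precipitates
    instantaneously).  The precipitate is treated as soluble drug mass: it
    is added to the solid pool and the effective particle radius grows with
    the cube root of the mass gain, so it remains available for dissolution.
    Total segment mass is conserved exactly.
    """
    if not formulation.supersaturation_enabled:
        return state
    cs = local_solubility(compound, state.segment, state.ph, formulation)
    sat_mass = cs * state.volume_l * 1000.0
    excess = state.dissolved_mass - sat_mass
    if excess <= 0.0:
        return state
    k = math.log(2.0) / formulation.precipitation_half_life
    precipitated = excess if math.isinf(dt_min) else excess * (1.0 - math.exp(-k * dt_min))
    new_solid = state.solid_mass + precipitated
    radius = state.effective_particle_radius
    if state.solid_mass > 0.0 and radius > 0.0:
        radius *= (new_solid / state.solid_mass) ** (1.0 / 3.0)
    elif radius == 0.0:
        radius = formulation.particle_radius or 1.0
    return replace(
        state,
        solid_mass=new_solid,
        dissolved_mass=state.dissolved_mass - precipitated,
        effective_particle_radius=radius,
    )


def precipitation_rate(
    dissolved_mass: float,
    solubility_mg_ml: float,
    volume_l: float,
    half_life_min: float,
) -> float:
    """Instantaneous precipitation rate (mg/min) used inside the ODE system."""
    excess = dissolved_mass - solubility_mg_ml * volume_l * 1000.0
    if excess <= 0.0:
        return 0.0
    return math.log(2.0) / half_life_min * excess


# ---------------------------------------------------------------------------
# Meals

#: kcal at which the linear gastric-emptying rule reaches its floor
_MEAL_KCAL_SCALE = 1200.0
_MEAL_FLOOR = 0.1
MEAL_EFFECT_DURATION_H = 4.0


def gastric_emptying_modifier(meal: MealEvent) -> float:
    """Multiplier on the stomach transit (emptying) rate after a meal.

    Linear-in-kcal slowing: 1 at 0 kcal, decreasing to a floor of 0.1, so the
    emptying half-time increases monotonically with caloric content (a
    841 kcal high-fat meal empties markedly slower than a 200 kcal non-fat
    meal).  Only the caloric supply enters the rule; the recorded solid
    fraction of the meal does not modify it.
    """
    return max(1.0 - meal.energy / _MEAL_KCAL_SCALE, _MEAL_FLOOR)


# ---------------------------------------------------------------------------
# Permeation

def intestinal_permeation_rate(
    state: GILumenState,
    compound: CompoundParameters,
    individual=None,
    permeability_cm_min: float | None = None,
) -> float:
    """Flux of dissolved drug into the gut wall, mg/min.

    flux = permeability x segment absorptive area x dissolved concentration.
    Only dissolved drug permeates; the engine routes the flux through the
    gut-wall compartment where mucosal CYP3A4 acts before the portal vein.
    """
    perm = permeability_cm_min
    if perm is None:
        perm = compound.specific_intestinal_permeability
    if perm is None:
        raise ValueError(
            f"{compound.name}: no unit-tagged specific intestinal permeability"
        )
    if state.dissolved_mass <= 0.0:
        return 0.0
    conc = state.dissolved_mass / (state.volume_l * 1000.0)  # mg/mL
    return perm * SEGMENT_AREA_CM2[state.segment] * conc
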