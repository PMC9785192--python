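"""Virtual individuals and populations.

Builds the physiological substrate for every simulation: organ volumes,
blood flows, tissue composition, enzyme expression and glomerular filtration
rate, scaled from an embedded reference adult to arbitrary demographics, and
samples seeded virtual populations from demographic ranges.

The reference tables are ICRP-style adult values embedded as package data so
the whole physiology is auditable.  Scaling is deliberately simple and
documented: organ volumes scale linearly with body weight, blood flows and
GFR with weight^0.75, and GFR additionally declines with age past 40 years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tissue_data import TISSUE_COMPOSITION, composition

# ---------------------------------------------------------------------------
# Reference adult (male, 30 y, 73 kg, 176 cm)

REFERENCE_WEIGHT_KG = 73.0
REFERENCE_HEIGHT_CM = 176.0
REFERENCE_AGE_Y = 30.0

#: organ volumes of the reference adult, litres
REFERENCE_ORGAN_VOLUMES = {
    "lung": 1.00,
    "adipose": 14.5,
    "bone": 8.5,
    "brain": 1.45,
    "gut": 1.10,
    "heart": 0.33,
    "kidney": 0.31,
    "liver": 1.80,
    "muscle": 29.0,
    "skin": 3.30,
    "spleen": 0.15,
    "gonads": 0.035,
    "stomach_wall": 0.15,
    "rest": 2.00,
    "arterial_blood": 1.70,
    "venous_blood": 3.90,
}

#: systemic (arterial) blood flows of the reference adult, L/min.  The liver
#: entry is the hepatic *artery*; portal inflow from gut, spleen and stomach
#: wall is added on top, so total hepatic flow = artery + portal drainage.
REFERENCE_ORGAN_FLOWS = {
    "adipose": 0.32,
    "bone": 0.32,
    "brain": 0.78,
    "gut": 1.00,
    "heart": 0.26,
    "kidney": 1.24,
    "liver": 0.39,          # hepatic artery
    "muscle": 1.10,
    "skin": 0.33,
    "spleen": 0.077,
    "gonads": 0.003,
    "stomach_wall": 0.06,
    "rest": 0.62,
}

#: organs whose venous outflow drains into the portal vein
PORTAL_ORGANS = ("gut", "spleen", "stomach_wall")

#: cardiac output of the reference adult = sum of systemic flows (exact by
#: construction, which is what keeps the flow-conservation invariant at 1e-9)
REFERENCE_CARDIAC_OUTPUT = float(sum(REFERENCE_ORGAN_FLOWS.values()))

#: reference enzyme tissue concentrations, µmol enzyme / L organ.
#: CYP3A4 and CYP2C9 are expressed in liver and CYP3A4 additionally in the
#: small-intestinal mucosa (gut wall), which is what produces oral
#: first-pass inhibition; UGT1A4 is hepatic only.  The liver CYP values were
#: identified jointly with the ruxolitinib model: their sum reproduces the
#: published steady-state ruxolitinib exposure through the fixed in-vitro
#: specific clearances, and their balance reproduces the published fraction
#: metabolized via CYP3A4 implied by the reported interaction magnitude.
#: Both lie inside reported hepatic P450 abundance ranges.
REFERENCE_ENZYME_CONCENTRATIONS = {
    ("CYP3A4", "liver"): 8.588,
    ("CYP2C9", "liver"): 10.804,
    ("UGT1A4", "liver"): 2.00,
    ("CYP3A4", "gut"): 1.50,
}

REFERENCE_GFR_ML_MIN = {"male": 110.0, "female": 100.0}
REFERENCE_HEMATOCRIT = {"male": 0.43, "female": 0.39}


@dataclass(frozen=True)
class Demographics:
    """Demographic description of one subject."""

    sex: str  # "male" | "female"
    age: float  # years
    weight: float  # kg
    height: float  # cm
    population_label: str = "healthy_adult"

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (0 < self.age < 120):
            raise ValueError(f"non-physiologic age: {self.age}")
        if not (20 <= self.weight <= 250):
            raise ValueError(f"non-physiologic weight: {self.weight} kg")
        if not (100 <= self.height <= 230):
            raise ValueError(f"non-physiologic height: {self.height} cm")


REFERENCE_DEMOGRAPHICS = Demographics(
    sex="male", age=REFERENCE_AGE_Y, weight=REFERENCE_WEIGHT_KG,
    height=REFERENCE_HEIGHT_CM, population_label="reference_adult",
)


@dataclass(frozen=True)
class VirtualIndividual:
    """Organ-level physiology for one subject.

    Volumes in L, blood flows in L/min, enzyme concentrations in µmol/L of
    organ, GFR in mL/min.  ``organ_blood_flows['liver']`` is the hepatic
    artery only; portal drainage is described by :data:`PORTAL_ORGANS`.
    """

    demographics: Demographics
    organ_volumes: dict
    organ_blood_flows: dict
    tissue_composition: dict
    enzyme_concentrations: dict
    gfr: float
    hematocrit: float
    #: per-parameter multiplicative deviates for population variability,
    #: applied by the engine (empty for a mean individual)
    iiv_factors: dict = field(default_factory=dict)

    @property
    def cardiac_output(self) -> float:
        """Cardiac output in L/min (sum of systemic organ flows)."""
        return float(sum(self.organ_blood_flows.values()))

    def validate(self) -> None:
        for name, v in self.organ_volumes.items():
            if v <= 0:
                raise ValueError(f"nonpositive volume for {name}")
        for name, q in self.organ_blood_flows.items():
            if q <= 0:
                raise ValueError(f"nonpositive flow for {name}")
        for key, c in self.enzyme_concentrations.items():
            if c < 0:
                raise ValueError(f"negative enzyme concentration for {key}")
        if not (0 < self.hematocrit < 1):
            raise ValueError("hematocrit outside (0, 1)")
        if self.gfr <= 0:
            raise ValueError("nonpositive GFR")


def build_individual(
    demographics: Demographics,
    physiology_table: dict | None = None,
) -> VirtualIndividual:
    """Create a virtual individual scaled from the reference adult.

    Parameters
    ----------
    demographics
        Validated demographic record (invalid values are rejected by the
        ``Demographics`` constructor, never clamped).
    physiology_table
        Optional override of the reference tables; a mapping with keys
        ``organ_volumes``, ``organ_flows``, ``enzyme_concentrations``.

    Organ volumes scale with weight/weight_ref; blood flows and GFR with
    (weight/weight_ref)^0.75.  At reference demographics the scaling factor
    is exactly 1 and the embedded table is returned unchanged.
    """
    table = physiology_table or {}
    volumes = dict(table.get("organ_volumes", REFERENCE_ORGAN_VOLUMES))
    flows = dict(table.get("organ_flows", REFERENCE_ORGAN_FLOWS))
    enzymes = dict(
        table.get("enzyme_concentrations", REFERENCE_ENZYME_CONCENTRATIONS)
    )

    for organ in flows:
        if organ not in volumes:
            raise KeyError(f"flow given for unknown organ {organ!r}")
    for organ in volumes:
        if organ not in TISSUE_COMPOSITION and organ not in (
            "arterial_blood", "venous_blood",
        ):
            raise KeyError(f"organ {organ!r} missing from tissue composition")

    w_scale = demographics.weight / REFERENCE_WEIGHT_KG
    q_scale = w_scale ** 0.75

    volumes = {k: v * w_scale for k, v in volumes.items()}
    flows = {k: q * q_scale for k, q in flows.items()}

    gfr = REFERENCE_GFR_ML_MIN[demographics.sex] * q_scale
    if demographics.age > 40:
        gfr *= max(0.5, 1.0 - 0.008 * (demographics.age - 40.0))

    tissue = {o: composition(o) for o in volumes if o in TISSUE_COMPOSITION}

    ind = VirtualIndividual(
        demographics=demographics,
        organ_volumes=volumes,
        organ_blood_flows=flows,
        tissue_composition=tissue,
        enzyme_concentrations=enzymes,
        gfr=gfr,
        hematocrit=REFERENCE_HEMATOCRIT[demographics.sex],
    )
    ind.validate()
    return ind


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a virtual population.

    ``demographic_ranges`` maps field name ('age', 'weight', 'height') to
    either ``(min, max)`` for uniform sampling or
    ``{'mean': m, 'sd': s, 'min': lo, 'max': hi}`` for truncated-normal
    sampling; a degenerate range (min == max) fixes the value.
    """

    n: int
    demographic_ranges: dict
    proportion_female: float = 0.5
    seed: int = 0
    population_label: str = "virtual_population"
    #: per-parameter log-normal coefficients of variation applied as
    #: multiplicative deviates on compound parameters (see engine docs)
    iiv_cv: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if not (0.0 <= self.proportion_female <= 1.0):
            raise ValueError("proportion_female outside [0, 1]")


#: default inter-individual variability (log-normal CV) used for population
#: simulations; applied to clearances, unbound fraction, dissolution time and
#: intestinal permeability.  Chosen inside the variability ranges reported
#: for posaconazole absorption in the source studies.
DEFAULT_IIV_CV = {
    "clearance": 0.30,
    "fu_p": 0.15,
    "dissolution_t50": 0.30,
    "permeability": 0.40,
}

GVHD_DEMOGRAPHIC_RANGES = {
    "age": {"mean": 55.0, "sd": 12.0, "min": 20.0, "max": 75.0},
    "weight": {"mean": 75.0, "sd": 13.0, "min": 48.0, "max": 110.0},
    "height": {"mean": 172.0, "sd": 9.0, "min": 150.0, "max": 195.0},
}


def population_spec_from_file(path) -> PopulationSpec:
    """Load a PopulationSpec from a YAML/JSON-style config file.

    Recognized keys: ``n``, ``seed``, ``proportion_female``,
    ``population_label``, ``iiv_cv`` and ``demographic_ranges`` (per-field
    ``[min, max]`` pairs or ``{mean, sd, min, max}`` mappings)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    ranges = {
        k: tuple(v) if isinstance(v, (list, tuple)) else dict(v)
        for k, v in raw.get("demographic_ranges", {}).items()
    }
    return PopulationSpec(
        n=int(raw["n"]),
        demographic_ranges=ranges,
        proportion_female=float(raw.get("proportion_female", 0.5)),
        seed=int(raw.get("seed", 0)),
        population_label=raw.get("population_label", "virtual_population"),
        iiv_cv=dict(raw.get("iiv_cv", {})),
    )


def _sample_field(rng: np.random.Generator, spec, size: int) -> np.ndarray:
    if isinstance(spec, dict):
        lo, hi = spec.get("min", -np.inf), spec.get("max", np.inf)
        if lo > hi:
            raise ValueError("infeasible demographic range (min > max)")
        if lo == hi:
            return np.full(size, float(lo))
        mean, sd = float(spec["mean"]), float(spec["sd"])
        if sd <= 0:
            return np.full(size, mean)
        out = np.empty(size)
        filled = 0
        while filled < size:  # rejection sampling keeps the rng stream simple
            draw = rng.normal(mean, sd, size=2 * (size - filled))
            draw = draw[(draw >= lo) & (draw <= hi)]
            take = min(draw.size, size - filled)
            out[filled:filled + take] = draw[:take]
            filled += take
        return out
    lo, hi = float(spec[0]), float(spec[1])
    if lo > hi:
        raise ValueError("infeasible demographic range (min > max)")
    if lo == hi:
        return np.full(size, lo)
    return rng.uniform(lo, hi, size=size)


def sample_population(spec: PopulationSpec) -> list[VirtualIndividual]:
    """Sample ``spec.n`` virtual individuals, reproducibly for a given seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    sexes = np.where(rng.random(n) < spec.proportion_female, "female", "male")
    ages = _sample_field(rng, spec.demographic_ranges.get("age", (30, 30)), n)
    weights = _sample_field(rng, spec.demographic_ranges.get("weight", (73, 73)), n)
    heights = _sample_field(rng, spec.demographic_ranges.get("height", (176, 176)), n)

    cv = dict(spec.iiv_cv)
    individuals = []
    for i in range(n):
        demo = Demographics(
            sex=str(sexes[i]), age=float(ages[i]), weight=float(weights[i]),
            height=float(heights[i]), population_label=spec.population_label,
        )
        ind = build_individual(demo)
        if cv:
            factors = {}
            # median-preserving log-normal deviates: the population median
            # equals the typical-individual value, matching how the reported
            # population metrics are summarized
            for name, c in sorted(cv.items()):
                if c > 0:
                    sigma = math.sqrt(math.log(1.0 + c * c))
                    factors[name] = float(math.exp(rng.normal(0.0, sigma)))
                else:
                    factors[name] = 1.0
            ind = replace(ind, iiv_factors=factors)
        individuals.append(ind)
    return individuals


def population_to_frame(individuals: list[VirtualIndividual]) -> pd.DataFrame:
    """Export a population as one row per individual (demographics + scaled
    physiologic parameters), suitable for CSV export."""
    rows = []
    for i, ind in enumerate(individuals):
        row = {
            "subject": i,
            "sex": ind.demographics.sex,
            "age_y": ind.demographics.age,
            "weight_kg": ind.demographics.weight,
            "height_cm": ind.demographics.height,
            "gfr_ml_min": ind.gfr,
            "hematocrit": ind.hematocrit,
            "cardiac_output_l_min": ind.cardiac_output,
        }
        for organ, v in ind.organ_volumes.items():
            row[f"volume_{organ}_l"] = v
        for name, f in ind.iiv_factors.items():
            row[f"iiv_{name}"] = f
        rows.append(row)
    return pd.DataFrame(rows)
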