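"""Drug-dependent parameters and derived quantities.

Holds physicochemistry, clearance processes and interaction constants per
compound, and computes tissue-to-plasma partition coefficients (Rodgers &
Rowland or Poulin & Theil), a calculated specific intestinal permeability,
and pH-dependent solubility of ionizable drugs.

Compound parameter sets ship as YAML files under ``pbpkddi/data`` with a
per-field provenance note; all internal permeability arithmetic is in
cm/min, and file values carry an explicit unit tag (``cm/min`` or ``cm/s``)
that is converted at load time to prevent silent 60-fold errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .tissue_data import (
    BLOOD_CELL_COMPOSITION,
    PH_BLOOD_CELLS,
    PH_INTRACELLULAR,
    PH_PLASMA,
    PLASMA_COMPOSITION,
)

# ---------------------------------------------------------------------------
# Domain types

VALID_ENZYMES = ("CYP3A4", "CYP2C9", "UGT1A4", "biliary", "renal_gfr")


@dataclass(frozen=True)
class ClearanceProcess:
    """One elimination process.

    ``first_order_specific_clearance`` values are in L/µmol/min and are
    multiplied by enzyme concentration, compartment volume and local unbound
    concentration.  ``kcat`` processes carry a Michaelis constant ``km``
    (µmol/L) and are evaluated in their first-order range,
    v = (kcat/km)·[E]·V·Cu, consistent with the engine's linear-kinetics
    scope.  ``biliary`` uses a specific clearance in 1/min referenced to
    liver volume; ``renal_gfr`` is parameterized on the compound level via
    ``gfr_fraction``.
    """

    enzyme: str
    kind: str  # "first_order_specific_clearance" | "kcat"
    value: float
    km: float | None = None  # µmol/L, kcat processes only

    def __post_init__(self):
        if self.enzyme not in VALID_ENZYMES:
            raise ValueError(f"unknown enzyme/pathway {self.enzyme!r}")
        if self.value < 0:
            raise ValueError("clearance value must be >= 0")
        if self.kind == "kcat" and (self.km is None or self.km <= 0):
            raise ValueError("kcat process requires km > 0")

    @property
    def specific_clearance(self) -> float:
        """Effective first-order specific clearance in L/µmol/min."""
        if self.kind == "kcat":
            return self.value / self.km
        return self.value


@dataclass(frozen=True)
class InteractionParameters:
    target_enzyme: str
    mechanism: str  # only "competitive" is modeled
    ki: float  # µmol/L

    def __post_init__(self):
        if self.mechanism != "competitive":
            raise ValueError("only competitive inhibition is supported")
        if self.ki <= 0:
            raise ValueError("Ki must be positive")


@dataclass(frozen=True)
class SolubilityReference:
    value_mg_ml: float
    ph: float
    gain_per_charge: float = 1.0


@dataclass(frozen=True)
class CompoundParameters:
    """All drug-dependent model inputs for one compound."""

    name: str
    molecular_weight: float  # g/mol
    logp: float
    fu_p: float
    pka_list: tuple = ()  # ((value, "acid"|"base"), ...)
    solubility_reference: SolubilityReference | None = None
    specific_intestinal_permeability: float | None = None  # cm/min, normalized
    partition_method: str = "rodgers_rowland"
    permeability_method: str = "fixed"
    clearance_processes: tuple = ()
    gfr_fraction: float = 0.0
    blood_plasma_ratio: float = 1.0
    interaction_parameters: tuple = ()
    formulations: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.fu_p <= 1):
            raise ValueError("fu_p must be in (0, 1]")
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")
        if self.gfr_fraction < 0:
            raise ValueError("gfr_fraction must be >= 0")
        if self.partition_method not in ("rodgers_rowland", "poulin_theil"):
            raise ValueError(f"unsupported partition method {self.partition_method!r}")
        for v, kind in self.pka_list:
            if kind not in ("acid", "base"):
                raise ValueError(f"pKa type must be acid or base, got {kind!r}")

    def interaction_for(self, enzyme: str) -> InteractionParameters | None:
        for ip in self.interaction_parameters:
            if ip.target_enzyme == enzyme:
                return ip
        return None


# ---------------------------------------------------------------------------
# Ionization helpers

def _charged_species_ratios(pka_list, ph: float) -> list[tuple[int, float]]:
    """Concentration of each charged species relative to the neutral one.

    Returns (|charge|, ratio) pairs.  Basic pKas are taken in decreasing,
    acidic in increasing order of strength for successive protonations.
    """
    bases = sorted((v for v, k in pka_list if k == "base"), reverse=True)
    acids = sorted(v for v, k in pka_list if k == "acid")
    out = []
    acc = 0.0
    for i, pka in enumerate(bases):
        acc += pka - ph
        out.append((i + 1, 10.0 ** acc))
    acc = 0.0
    for i, pka in enumerate(acids):
        acc += ph - pka
        out.append((i + 1, 10.0 ** acc))
    return out


def _ionization_factor(pka_list, ph: float) -> float:
    """1 + sum of charged/neutral ratios ( = 1/neutral fraction )."""
    return 1.0 + sum(r for _, r in _charged_species_ratios(pka_list, ph))


# ---------------------------------------------------------------------------
# Partition coefficients

def _vegetable_oil_p(logp: float) -> float:
    """Storage-lipid (vegetable oil:water) partition coefficient from logP.

    Octanol overestimates partitioning into adipose storage lipid; the
    standard log-linear correlation log D_vo = 1.115 logP - 1.35 is used for
    the adipose neutral-lipid term in both distribution methods.
    """
    return 10.0 ** (1.115 * logp - 1.35)


def _rr_kpu(compound: CompoundParameters, comp: dict, organ: str = "") -> float:
    """Rodgers & Rowland unbound tissue:plasma partition coefficient.

    Moderate-to-strong bases (any basic pKa >= 7) bind acidic phospholipids
    (method 1, with the affinity back-calculated from blood-cell
    partitioning); neutrals, acids and weak bases bind extracellular
    protein scaled by the tissue:plasma albumin ratio (method 2).
    """
    p = 10.0 ** compound.logp
    p_nl = _vegetable_oil_p(compound.logp) if organ == "adipose" else p
    y_p = _ionization_factor(compound.pka_list, PH_PLASMA)
    y_iw = _ionization_factor(compound.pka_list, PH_INTRACELLULAR)
    lipid = lambda f_nl, f_np: (p_nl * f_nl + (0.3 * p + 0.7) * f_np)  # noqa: E731

    kpu = comp["f_ew"] + (y_iw / y_p) * comp["f_iw"] + lipid(
        comp["f_nl"], comp["f_np"]
    ) / y_p

    strong_base = any(k == "base" and v >= 7.0 for v, k in compound.pka_list)
    if strong_base:
        bc = BLOOD_CELL_COMPOSITION
        y_bc = _ionization_factor(compound.pka_list, PH_BLOOD_CELLS)
        hct = 0.43
        kpu_bc = (compound.blood_plasma_ratio - (1.0 - hct)) / (
            hct * compound.fu_p
        )
        ka_ap = (
            kpu_bc
            - (y_bc / y_p) * bc["f_iw"]
            - (p * bc["f_nl"] + (0.3 * p + 0.7) * bc["f_np"]) / y_p
        ) * y_p / (bc["ap_mg_g"] * (y_bc - 1.0))
        ka_ap = max(ka_ap, 0.0)
        kpu += ka_ap * comp["ap_mg_g"] * (y_iw - 1.0) / y_p
    else:
        # plasma reference lipid always uses octanol partitioning
        plasma_lipid = (p * PLASMA_COMPOSITION["f_nl"]
                        + (0.3 * p + 0.7) * PLASMA_COMPOSITION["f_np"])
        protein_term = max(1.0 / compound.fu_p - 1.0 - plasma_lipid / y_p, 0.0)
        kpu += protein_term * comp["alb_ratio"]
    return kpu


def _pt_kp(compound: CompoundParameters, comp: dict, organ: str) -> float:
    """Poulin & Theil tissue:plasma partition coefficient (plasma-based)."""
    p = 10.0 ** compound.logp
    f_w_t = comp["f_ew"] + comp["f_iw"]
    f_w_p = PLASMA_COMPOSITION["f_water"]
    nl_p, np_p = PLASMA_COMPOSITION["f_nl"], PLASMA_COMPOSITION["f_np"]
    if organ == "adipose":
        # only the neutral species partitions into storage (vegetable-oil-
        # like) lipid
        d = _vegetable_oil_p(compound.logp) / _ionization_factor(
            compound.pka_list, PH_PLASMA
        )
        num = d * (comp["f_nl"] + 0.3 * comp["f_np"]) + (f_w_t + 0.7 * comp["f_np"])
        den = d * (nl_p + 0.3 * np_p) + (f_w_p + 0.7 * np_p)
        return (num / den) * compound.fu_p
    fu_t = 1.0 / (1.0 + (1.0 - compound.fu_p) / compound.fu_p * 0.5)
    num = p * (comp["f_nl"] + 0.3 * comp["f_np"]) + (f_w_t + 0.7 * comp["f_np"])
    den = p * (nl_p + 0.3 * np_p) + (f_w_p + 0.7 * np_p)
    return (num / den) * compound.fu_p / fu_t


def partition_coefficients(compound: CompoundParameters, individual) -> dict:
    """Tissue:plasma partition coefficients (Kp) for every organ.

    The chosen ``partition_method`` changes only the Kp values, never the
    topology; results are deterministic and independent of organ ordering.
    """
    kps = {}
    for organ, comp in sorted(individual.tissue_composition.items()):
        if compound.partition_method == "rodgers_rowland":
            kp = _rr_kpu(compound, comp, organ) * compound.fu_p
        else:
            kp = _pt_kp(compound, comp, organ)
        if not (kp > 0):
            raise ValueError(f"nonpositive Kp computed for {organ}")
        kps[organ] = float(kp)
    return kps


# ---------------------------------------------------------------------------
# Permeability

#: coefficient of the calculated-permeability formula
#: P = PERMEABILITY_COEFF * 10**(0.9*logP) * MW**-3  [cm/min],
#: calibrated so the posaconazole inputs (MW 700.78, logP 4.30) reproduce the
#: software-calculated specific permeability of 1.81e-4 cm/min.
PERMEABILITY_COEFF = 8.4037


def calculated_specific_permeability(molecular_weight: float, logp: float) -> float:
    """Specific intestinal permeability (cm/min) from MW and lipophilicity.

    A closed-form lipophilicity/size correlation used only as an initial
    estimate; measured or optimized permeabilities override it.
    """
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    return PERMEABILITY_COEFF * 10.0 ** (0.9 * logp) * molecular_weight ** -3.0


def convert_permeability(value: float, unit: str) -> float:
    """Normalize a tagged permeability to cm/min."""
    if unit == "cm/min":
        return value
    if unit == "cm/s":
        return value * 60.0
    raise ValueError(f"permeability unit must be 'cm/min' or 'cm/s', got {unit!r}")


# ---------------------------------------------------------------------------
# Solubility

def ph_solubility(compound: CompoundParameters, ph: float) -> float:
    """Solubility (mg/mL) at a given pH.

    Henderson–Hasselbalch profile through the reference point: each charged
    species contributes its neutral-relative abundance scaled by
    ``gain_per_charge`` per unit charge, so weak bases gain solubility at
    low pH.  Continuous in pH; constant for neutral compounds.
    """
    if not (0.0 <= ph <= 14.0):
        raise ValueError("pH outside [0, 14]")
    ref = compound.solubility_reference
    if ref is None:
        raise ValueError(f"{compound.name}: no solubility reference available")
    if not compound.pka_list:
        return ref.value_mg_ml

    def factor(at_ph: float) -> float:
        return 1.0 + sum(
            ref.gain_per_charge ** z * r
            for z, r in _charged_species_ratios(compound.pka_list, at_ph)
        )

    intrinsic = ref.value_mg_ml / factor(ref.ph)
    return intrinsic * factor(ph)


# ---------------------------------------------------------------------------
# YAML loading

def _load_formulation(name: str, raw: dict):
    from .absorption import FormulationModel  # local import avoids a cycle

    return FormulationModel(
        kind=raw["kind"],
        dissolution_time_t50=raw.get("dissolution_time_t50_min", 0.0),
        dissolution_shape=raw.get("dissolution_shape", 1.0),
        lag_time=raw.get("lag_time_min", 0.0),
        particle_radius=raw.get("particle_radius_um", 0.0),
        drug_density=raw.get("drug_density_g_cm3", 0.0),
        unstirred_water_layer=raw.get("unstirred_water_layer_um", 0.0),
        supersaturation_enabled=raw.get("supersaturation_enabled", False),
        precipitation_half_life=raw.get("precipitation_half_life_min", 10.0),
        gastric_release_blocked=raw.get("gastric_release_blocked", False),
        permeability=(
            convert_permeability(
                raw["permeability"]["value"], raw["permeability"]["unit"]
            )
            if "permeability" in raw
            else None
        ),
        segment_solubility_override=raw.get("segment_solubility_override_mg_ml"),
        name=name,
    )


def compound_from_dict(raw: dict) -> CompoundParameters:
    sol = None
    if "solubility" in raw:
        s = raw["solubility"]
        sol = SolubilityReference(
            value_mg_ml=float(s["reference_value_mg_ml"]),
            ph=float(s["reference_ph"]),
            gain_per_charge=float(s.get("gain_per_charge", 1.0)),
        )
    perm = None
    if "specific_intestinal_permeability" in raw:
        p = raw["specific_intestinal_permeability"]
        perm = convert_permeability(float(p["value"]), p["unit"])
    clearances = tuple(
        ClearanceProcess(
            enzyme=c["enzyme"], kind=c["kind"], value=float(c["value"]),
            km=float(c["km"]) if "km" in c else None,
        )
        for c in raw.get("clearances", ())
    )
    interactions = tuple(
        InteractionParameters(
            target_enzyme=i["target_enzyme"], mechanism=i["mechanism"],
            ki=float(i["ki_umol_l"]),
        )
        for i in raw.get("interactions", ())
    )
    formulations = {
        fname: _load_formulation(fname, fraw)
        for fname, fraw in raw.get("formulations", {}).items()
    }
    return CompoundParameters(
        name=raw["name"],
        molecular_weight=float(raw["molecular_weight_g_mol"]),
        logp=float(raw["logp"]),
        fu_p=float(raw["fu_p"]),
        pka_list=tuple(
            (float(p["value"]), p["type"]) for p in raw.get("pka", ())
        ),
        solubility_reference=sol,
        specific_intestinal_permeability=perm,
        partition_method=raw.get("partition_method", "rodgers_rowland"),
        permeability_method=raw.get("permeability_method", "fixed"),
        clearance_processes=clearances,
        gfr_fraction=float(raw.get("gfr_fraction", 0.0)),
        blood_plasma_ratio=float(raw.get("blood_plasma_ratio", 1.0)),
        interaction_parameters=interactions,
        formulations=formulations,
        provenance=raw.get("provenance", {}),
    )


def load_compound(name_or_path: str) -> CompoundParameters:
    """Load a compound parameter file.

    ``name_or_path`` is either the name of a packaged compound
    (``posaconazole``, ``ruxolitinib``, ``midazolam``) or a filesystem path
    to a YAML file with the same schema.
    """
    packaged = {
        "posaconazole": "posaconazole.yaml",
        "ruxolitinib": "ruxolitinib.yaml",
        "midazolam": "midazolam_synthetic.yaml",
    }
    if name_or_path in packaged:
        ref = resources.files("pbpkddi.data") / packaged[name_or_path]
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(name_or_path) as fh:
            raw = yaml.safe_load(fh)
    return compound_from_dict(raw)
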