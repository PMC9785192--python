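"""Whole-body PBPK ODE engine.

Assembles and integrates the perfusion-limited ~15-organ circulation (lung,
adipose, bone, brain, gut wall, heart, kidney, liver, muscle, skin, spleen,
gonads, stomach wall, rest, arterial/venous blood) for one individual and one
or two compounds, with mechanistic oral absorption, first-order metabolism
driven by unbound tissue concentrations, glomerular filtration, biliary
excretion, dose-event handling and a full mass-balance ledger.

Metabolism uses v = CL_spec * [E]_organ * V_organ * C_unbound(organ) with the
well-stirred assumption C_unbound = fu_p * C_organ / Kp_organ; the renal term
is gfr_fraction * GFR * fu_p * C_kidney/Kp; competitive enzyme inhibition
multiplies the victim's affected specific clearance by 1/(1 + I_u/Ki) using
the perpetrator's local unbound concentration in each expressing organ.

All amounts are integrated in µmol on a minutes time base; the public
interface speaks hours and ng/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import absorption as ab
from .absorption import (
    MealEvent,
    SEGMENTS,
    FormulationModel,
    gastric_emptying_modifier,
    local_solubility,
    weibull_release_hazard,
)
from .compound import CompoundParameters
from .physiology import PORTAL_ORGANS, VirtualIndividual
from .compound import partition_coefficients

INTESTINAL = ("duodenum", "jejunum", "ileum", "colon")


# ---------------------------------------------------------------------------
# Dosing

@dataclass(frozen=True)
class DosingRegimen:
    """Dosing description for one compound.

    ``dose_times_h`` lists every administration explicitly (strictly
    increasing); the ``schedule`` label (SD/QD/BID/TID) is carried for
    bookkeeping.  ``formulation`` names an entry of the compound's
    formulation table or is a :class:`FormulationModel` directly.
    """

    compound: str
    route: str  # "iv_infusion" | "oral"
    dose: float  # mg per administration
    dose_times_h: tuple
    schedule: str = "SD"
    infusion_duration_min: float = 0.0
    formulation: object = None
    meals: tuple = ()

    def __post_init__(self):
        if self.route not in ("iv_infusion", "oral"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        times = tuple(self.dose_times_h)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("dose times must be strictly increasing")
        if self.route == "iv_infusion" and self.infusion_duration_min <= 0:
            raise ValueError("i.v. infusion needs a positive duration")

    @staticmethod
    def _times(n_per_day: int, days: int) -> tuple:
        step = 24.0 / n_per_day
        return tuple(d * 24.0 + k * step for d in range(days) for k in range(n_per_day))

    @classmethod
    def qd(cls, compound, dose, days, **kw):
        return cls(compound, kw.pop("route", "oral"), dose,
                   cls._times(1, days), "QD", **kw)

    @classmethod
    def bid(cls, compound, dose, days, **kw):
        return cls(compound, kw.pop("route", "oral"), dose,
                   cls._times(2, days), "BID", **kw)

    @classmethod
    def tid(cls, compound, dose, days, **kw):
        return cls(compound, kw.pop("route", "oral"), dose,
                   cls._times(3, days), "TID", **kw)

    @classmethod
    def single(cls, compound, dose, route="oral", at_h=0.0, **kw):
        return cls(compound, route, dose, (at_h,), "SD", **kw)


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    grid_h: float = 0.1
    #: inhibitor concentration driving the interaction: unbound concentration
    #: in the expressing tissue ("tissue_unbound") or unbound venous plasma
    inhibitor_driver: str = "tissue_unbound"


@dataclass(frozen=True)
class PKMetrics:
    """Noncompartmental summary of one profile over one interval."""

    cmax: float  # ng/mL
    tmax: float  # h
    auc_last: float  # ng·h/mL
    ctrough: float  # ng/mL
    interval: tuple

    def __post_init__(self):
        if not (self.cmax + 1e-12 >= self.ctrough >= 0):
            raise ValueError("inconsistent Cmax/Ctrough")
        if self.auc_last < 0:
            raise ValueError("negative AUC")


def nca(result: "SimulationResult", compound: str, interval: tuple) -> PKMetrics:
    """Noncompartmental metrics (Cmax, tmax, AUC_last by linear trapezoid,
    and the end-of-interval trough) on the simulation output grid."""
    t0, t1 = float(interval[0]), float(interval[1])
    t = result.time_h
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9 or t1 <= t0:
        raise ValueError("interval outside the simulated time grid")
    c = result.plasma_concentration[compound]
    mask = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    tt, cc = t[mask], c[mask]
    if tt.size < 2:
        raise ValueError("empty interval")
    imax = int(np.argmax(cc))
    return PKMetrics(
        cmax=float(cc[imax]),
        tmax=float(tt[imax]),
        auc_last=float(np.trapezoid(cc, tt)),
        ctrough=float(cc[-1]),
        interval=(t0, t1),
    )


# ---------------------------------------------------------------------------
# Result container

@dataclass
class SimulationResult:
    """Concentration-time output plus the mass-balance ledger.

    ``plasma_concentration`` maps compound name to venous-plasma ng/mL on
    ``time_h``; ``compartment_amounts`` maps compound to a DataFrame of µmol
    per compartment over time; ``cumulative_eliminated`` maps compound to a
    DataFrame of µmol eliminated per pathway.
    """

    time_h: np.ndarray
    plasma_concentration: dict
    compartment_amounts: dict
    cumulative_eliminated: dict
    mass_balance_residual: float
    doses_mg: dict

    def nca(self, compound: str, interval: tuple) -> PKMetrics:
        return nca(self, compound, interval)

    def to_frame(self) -> pd.DataFrame:
        """Long-format concentration table (compound, time_h, conc_ng_ml)."""
        frames = []
        for name, conc in self.plasma_concentration.items():
            frames.append(pd.DataFrame({
                "compound": name, "time_h": self.time_h, "conc_ng_ml": conc,
            }))
        return pd.concat(frames, ignore_index=True)

    def plot(self, ax=None, log=False):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, conc in self.plasma_concentration.items():
            ax.plot(self.time_h, conc, label=name)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("plasma concentration (ng/mL)")
        if log:
            ax.set_yscale("log")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# Internal per-compound block

class _Block:
    """Precomputed structure for one compound in the joint state vector."""

    def __init__(self, compound: CompoundParameters, regimen: DosingRegimen,
                 individual: VirtualIndividual, offset: int):
        self.compound = compound
        self.regimen = regimen
        self.offset = offset
        iiv = individual.iiv_factors

        self.organs = [o for o in individual.organ_volumes
                       if o not in ("arterial_blood", "venous_blood")]
        if "lung" not in self.organs or "liver" not in self.organs:
            raise ValueError("physiology must include lung and liver")
        self.kp = partition_coefficients(compound, individual)
        self.fu = min(compound.fu_p * iiv.get("fu_p", 1.0), 1.0)
        self.mw = compound.molecular_weight

        # ---- state layout ----------------------------------------------
        names = ["venous", "arterial"] + list(self.organs)
        self.oral = regimen.route == "oral"
        form = regimen.formulation
        if isinstance(form, str) or form is None:
            key = form
            if key is None and not self.oral:
                form = compound.formulations.get(
                    "iv", FormulationModel(kind="iv_infusion", name="iv")
                )
            else:
                if key is None:
                    if not compound.formulations:
                        raise KeyError(
                            f"{compound.name}: no packaged formulation for "
                            "oral dosing"
                        )
                    key = next(iter(compound.formulations))
                try:
                    form = compound.formulations[key]
                except KeyError:
                    raise KeyError(
                        f"{compound.name}: formulation {key!r} not packaged"
                    ) from None
        self.formulation: FormulationModel = form
        if self.oral and form.kind == "iv_infusion":
            raise ValueError("oral regimen with an i.v. formulation")

        if self.oral:
            names += [f"solid_{s}" for s in SEGMENTS]
            names += [f"dissolved_{s}" for s in SEGMENTS]
        pathways = []
        for proc in compound.clearance_processes:
            if proc.enzyme == "biliary":
                pathways.append("biliary")
            else:
                pathways.append(f"met_{proc.enzyme}")
        if compound.gfr_fraction > 0:
            pathways.append("renal")
        if self.oral:
            pathways.append("fecal")
        self.pathways = pathways
        names += [f"elim_{p}" for p in pathways]
        self.state_names = names
        self.n = len(names)
        self.ix = {nm: i for i, nm in enumerate(names)}

        # ---- distribution matrix ---------------------------------------
        n = self.n
        m = np.zeros((n, n))
        vol = individual.organ_volumes
        q = dict(individual.organ_blood_flows)
        co = individual.cardiac_output
        i_ven, i_art = self.ix["venous"], self.ix["arterial"]
        v_ven, v_art = vol["venous_blood"], vol["arterial_blood"]

        # venous -> lung -> arterial
        i_lung = self.ix["lung"]
        k_lung_out = co / (vol["lung"] * self.kp["lung"])
        m[i_lung, i_ven] += co / v_ven
        m[i_ven, i_ven] -= co / v_ven
        m[i_art, i_lung] += k_lung_out
        m[i_lung, i_lung] -= k_lung_out

        q_liver_total = q["liver"] + sum(q[o] for o in PORTAL_ORGANS if o in q)
        for organ in self.organs:
            if organ == "lung":
                continue
            i_o = self.ix[organ]
            m[i_o, i_art] += q[organ] / v_art
            m[i_art, i_art] -= q[organ] / v_art
            q_out = q_liver_total if organ == "liver" else q[organ]
            k_out = q_out / (vol[organ] * self.kp[organ])
            m[i_o, i_o] -= k_out
            dest = self.ix["liver"] if organ in PORTAL_ORGANS else i_ven
            m[dest, i_o] += k_out

        # ---- elimination -----------------------------------------------
        cl_iiv = iiv.get("clearance", 1.0)
        enz = individual.enzyme_concentrations
        self._cyp3a4_entries = []  # (organ index, pathway row, base 1/min coeff)
        for proc in compound.clearance_processes:
            if proc.enzyme == "biliary":
                i_o = self.ix["liver"]
                coeff = proc.value * cl_iiv * self.fu / self.kp["liver"]
                row = self.ix["elim_biliary"]
                m[i_o, i_o] -= coeff
                m[row, i_o] += coeff
                continue
            expressed = [(o, c) for (e, o), c in enz.items() if e == proc.enzyme]
            if not expressed:
                raise ValueError(
                    f"{compound.name}: enzyme {proc.enzyme} not expressed in "
                    "this individual"
                )
            row = self.ix[f"elim_met_{proc.enzyme}"]
            for organ, e_conc in expressed:
                i_o = self.ix[organ]
                coeff = (proc.specific_clearance * cl_iiv * e_conc
                         * self.fu / self.kp[organ])
                m[i_o, i_o] -= coeff
                m[row, i_o] += coeff
                if proc.enzyme == "CYP3A4":
                    self._cyp3a4_entries.append((i_o, row, coeff))
        if compound.gfr_fraction > 0:
            i_k = self.ix["kidney"]
            gfr_l_min = individual.gfr / 1000.0
            coeff = (compound.gfr_fraction * gfr_l_min * self.fu
                     / (vol["kidney"] * self.kp["kidney"]))
            row = self.ix["elim_renal"]
            m[i_k, i_k] -= coeff
            m[row, i_k] += coeff

        # ---- GI transit & absorption -----------------------------------
        if self.oral:
            perm = self.formulation.permeability
            if perm is None:
                perm = compound.specific_intestinal_permeability
            if perm is None:
                raise ValueError(
                    f"{compound.name}: no unit-tagged permeability for oral dosing"
                )
            perm *= iiv.get("permeability", 1.0)
            self.permeability = perm
            i_gut = self.ix["gut"]
            i_fec = self.ix["elim_fecal"]
            self._stomach_entries = []
            for phase in ("solid", "dissolved"):
                for s, nxt in zip(SEGMENTS, SEGMENTS[1:] + (None,)):
                    i_s = self.ix[f"{phase}_{s}"]
                    k_t = ab.SEGMENT_TRANSIT_PER_MIN[s]
                    dest = self.ix[f"{phase}_{nxt}"] if nxt else i_fec
                    m[i_s, i_s] -= k_t
                    m[dest, i_s] += k_t
                    if s == "stomach":
                        self._stomach_entries.append((i_s, dest, k_t))
                if phase == "dissolved":
                    for s in INTESTINAL:
                        i_s = self.ix[f"dissolved_{s}"]
                        k_abs = (perm * ab.SEGMENT_AREA_CM2[s]
                                 / (ab.SEGMENT_VOLUME_L[s] * 1000.0))
                        m[i_s, i_s] -= k_abs
                        m[i_gut, i_s] += k_abs
            # per-segment saturation solubility, µmol
            self.sat_umol = {}
            for s in SEGMENTS:
                if compound.solubility_reference is None:
                    self.sat_umol[s] = math.inf
                else:
                    cs = local_solubility(compound, s, ab.SEGMENT_PH[s],
                                          self.formulation)
                    self.sat_umol[s] = (cs * ab.SEGMENT_VOLUME_L[s] * 1000.0
                                        * 1000.0 / self.mw)
            t50_iiv = iiv.get("dissolution_t50", 1.0)
            if self.formulation.kind == "weibull" and t50_iiv != 1.0:
                self.formulation = replace(
                    self.formulation,
                    dissolution_time_t50=self.formulation.dissolution_time_t50
                    * t50_iiv,
                )
        self.matrix = m
        self.dose_umol = regimen.dose * 1000.0 / self.mw
        self.dose_times_min = tuple(t * 60.0 for t in regimen.dose_times_h)

    # -- dose application at an event time ------------------------------
    def apply_dose(self, y: np.ndarray) -> None:
        if self.dose_umol == 0.0:
            return
        o = self.offset
        if not self.oral:
            return  # infusion handled continuously
        form = self.formulation
        if form.kind == "solution":
            y[o + self.ix["dissolved_stomach"]] += self.dose_umol
        else:
            y[o + self.ix["solid_stomach"]] += self.dose_umol

    def administered_umol(self, t_min: float, t_end_min: float = math.inf
                          ) -> float:
        """Cumulative dose delivered by ``t_min``; doses scheduled at or
        beyond the simulation end are never applied and never counted."""
        total = 0.0
        rate, dur = self._infusion_rate_dur()
        for td in self.dose_times_min:
            if td >= t_end_min - 1e-9:
                continue
            if self.oral:
                if td <= t_min + 1e-9:
                    total += self.dose_umol
            else:
                total += rate * min(max(t_min - td, 0.0), dur)
        return total

    def _infusion_rate_dur(self):
        if self.oral or self.dose_umol == 0.0:
            return 0.0, 0.0
        dur = self.regimen.infusion_duration_min
        return self.dose_umol / dur, dur


def _meal_windows(regimen: DosingRegimen):
    wins = []
    for meal in regimen.meals:
        t0 = meal.time * 60.0
        wins.append((t0, t0 + ab.MEAL_EFFECT_DURATION_H * 60.0,
                     gastric_emptying_modifier(meal)))
    return wins


# ---------------------------------------------------------------------------
# Model

class PBPKModel:
    """Assembled whole-body model for one individual and one or two compounds.

    Parameters
    ----------
    individual
        A :class:`~pbpkddi.physiology.VirtualIndividual`.
    compounds, regimens
        Matching sequences of one or two compounds and their regimens.
    interaction
        If True, competitive inhibition couples the compounds: the compound
        carrying interaction parameters (the perpetrator) multiplies the
        other's affected specific clearance by 1/(1 + I_u/Ki) in every organ
        expressing the target enzyme.
    """

    def __init__(self, individual, compounds, regimens, interaction=False,
                 settings: SolverSettings | None = None,
                 external_inhibition=None):
        if isinstance(compounds, CompoundParameters):
            compounds = [compounds]
            regimens = [regimens]
        compounds, regimens = list(compounds), list(regimens)
        if len(compounds) != len(regimens) or not 1 <= len(compounds) <= 2:
            raise ValueError("need one or two compounds with matching regimens")
        self.individual = individual
        self.settings = settings or SolverSettings()
        self.blocks: list[_Block] = []
        off = 0
        for cp, reg in zip(compounds, regimens):
            if reg.compound != cp.name:
                raise ValueError("regimen/compound name mismatch")
            blk = _Block(cp, reg, individual, off)
            self.blocks.append(blk)
            off += blk.n
        self.n_states = off

        # external inhibition: (ki, t_min_grid, {organ: I_u µmol/L array})
        # drives the single victim with a precomputed perpetrator trajectory
        self.external_inhibition = external_inhibition
        if external_inhibition is not None and len(self.blocks) != 1:
            raise ValueError("external inhibition applies to a single victim")

        self.interaction = None
        if interaction:
            if len(self.blocks) != 2:
                raise ValueError("interaction requires two compounds")
            perp = vict = None
            for a, b in (self.blocks, self.blocks[::-1]):
                ip = a.compound.interaction_for("CYP3A4")
                if ip is not None and any(
                    p.enzyme == "CYP3A4" for p in b.compound.clearance_processes
                ):
                    perp, vict, ki = a, b, ip.ki
            if perp is None:
                raise ValueError(
                    "interaction enabled but no perpetrator Ki matches a "
                    "victim CYP3A4 clearance"
                )
            self.interaction = (perp, vict, ki)

    # ------------------------------------------------------------------
    @property
    def state_dimension(self) -> int:
        return self.n_states

    def state_names(self) -> list:
        out = []
        for blk in self.blocks:
            out += [f"{blk.compound.name}:{nm}" for nm in blk.state_names]
        return out

    # ------------------------------------------------------------------
    def _breakpoints(self, t_end_min: float) -> np.ndarray:
        pts = {0.0, t_end_min}
        for blk in self.blocks:
            for td in blk.dose_times_min:
                if td < t_end_min:
                    pts.add(td)
                    if not blk.oral:
                        pts.add(min(td + blk.regimen.infusion_duration_min,
                                    t_end_min))
            for t0, t1, _ in _meal_windows(blk.regimen):
                for t in (t0, t1):
                    if 0 < t < t_end_min:
                        pts.add(t)
        return np.array(sorted(pts))

    def _piece_matrix(self, t_mid: float) -> np.ndarray:
        """Joint linear matrix for the piece containing t_mid (meal factors
        applied to gastric emptying)."""
        m = np.zeros((self.n_states, self.n_states))
        for blk in self.blocks:
            o = blk.offset
            mb = blk.matrix
            m[o:o + blk.n, o:o + blk.n] = mb
            if blk.oral:
                fac = 1.0
                for t0, t1, f in _meal_windows(blk.regimen):
                    if t0 <= t_mid < t1:
                        fac = min(fac, f)
                if fac != 1.0:
                    for i_s, dest, k_t in blk._stomach_entries:
                        m[o + i_s, o + i_s] += k_t * (1.0 - fac)
                        m[o + dest, o + i_s] -= k_t * (1.0 - fac)
        return m

    def _infusion_vector(self, t_mid: float) -> np.ndarray:
        b = np.zeros(self.n_states)
        for blk in self.blocks:
            if blk.oral:
                continue
            rate, dur = blk._infusion_rate_dur()
            for td in blk.dose_times_min:
                if td <= t_mid < td + dur:
                    b[blk.offset + blk.ix["venous"]] += rate
        return b

    def _inhibition_factors(self, y: np.ndarray) -> dict:
        """Per-organ multiplier on the victim's CYP3A4 clearance."""
        perp, _, ki = self.interaction
        driver = self.settings.inhibitor_driver
        out = {}
        for i_o, _, _ in self.interaction[1]._cyp3a4_entries:
            organ = self.interaction[1].state_names[i_o]
            if driver == "plasma_unbound":
                iu = (perp.fu * y[perp.offset + perp.ix["venous"]]
                      / self.individual.organ_volumes["venous_blood"])
            else:
                vol = self.individual.organ_volumes[organ]
                iu = (perp.fu * y[perp.offset + perp.ix[organ]]
                      / (vol * perp.kp[organ]))
            out[i_o] = 1.0 / (1.0 + max(iu, 0.0) / ki)
        return out

    def _rhs(self, m_piece: np.ndarray, b_inf: np.ndarray):
        blocks = self.blocks
        interaction = self.interaction
        external = self.external_inhibition

        def rhs(t, y):
            dy = m_piece @ y + b_inf
            for blk in blocks:
                if blk.oral:
                    self._gi_nonlinear(blk, t, y, dy)
            if interaction is not None:
                perp, vict, ki = interaction
                facs = self._inhibition_factors(y)
                vo = vict.offset
                for i_o, row, coeff in vict._cyp3a4_entries:
                    delta = coeff * (facs[i_o] - 1.0) * y[vo + i_o]
                    dy[vo + i_o] -= delta
                    dy[vo + row] += delta
            elif external is not None:
                ki, tgrid, iu_map = external
                vict = blocks[0]
                for i_o, row, coeff in vict._cyp3a4_entries:
                    organ = vict.state_names[i_o]
                    iu = np.interp(t, tgrid, iu_map[organ])
                    fac = 1.0 / (1.0 + max(iu, 0.0) / ki)
                    delta = coeff * (fac - 1.0) * y[i_o]
                    dy[i_o] -= delta
                    dy[row] += delta
            return dy

        return rhs

    def _gi_nonlinear(self, blk: _Block, t: float, y: np.ndarray,
                      dy: np.ndarray) -> None:
        form = blk.formulation
        o = blk.offset
        if form.kind == "solution":
            return
        if form.kind == "weibull":
            t_last = None
            for td in blk.dose_times_min:
                if td <= t + 1e-9:
                    t_last = td
            if t_last is None:
                return
            k = weibull_release_hazard(t - t_last, form)
            if k <= 0.0:
                return
            for s in SEGMENTS:
                if s == "stomach" and form.gastric_release_blocked:
                    continue
                i_sol = o + blk.ix[f"solid_{s}"]
                solid = y[i_sol]
                if solid <= 0.0:
                    continue
                sat = blk.sat_umol[s]
                f_sat = 1.0
                if math.isfinite(sat) and sat > 0:
                    f_sat = min(max(1.0 - y[o + blk.ix[f"dissolved_{s}"]] / sat,
                                    0.0), 1.0)
                rate = k * solid * f_sat
                dy[i_sol] -= rate
                dy[o + blk.ix[f"dissolved_{s}"]] += rate
            return
        # particle dissolution with optional supersaturation/precipitation.
        # At fixed particle number the effective radius follows the solid
        # mass as r = r0 (m/m_dose)^(1/3) — the same cube-root rule that
        # grows the particles when precipitate is added to the solid pool —
        # so the radius is carried algebraically rather than as a state.
        mw = blk.mw
        m_ref = max(blk.dose_umol, 1e-9)
        for s in SEGMENTS:
            i_sol = o + blk.ix[f"solid_{s}"]
            i_dis = o + blk.ix[f"dissolved_{s}"]
            solid_umol = max(y[i_sol], 0.0)
            frac = min(max(solid_umol / m_ref, 1e-6), 1.0)
            radius = form.particle_radius * frac ** (1.0 / 3.0)
            state = ab.segment_state(
                s,
                solid_mass=solid_umol * mw / 1000.0,  # µmol -> mg
                dissolved_mass=max(y[i_dis], 0.0) * mw / 1000.0,
                effective_particle_radius=radius,
            )
            rate_mg = ab.particle_dissolution_rate(state, blk.compound, form)
            rate = rate_mg * 1000.0 / mw
            net_solid = -rate
            if form.supersaturation_enabled:
                cs = local_solubility(blk.compound, s, ab.SEGMENT_PH[s], form)
                p_mg = ab.precipitation_rate(
                    state.dissolved_mass, cs, state.volume_l,
                    form.precipitation_half_life,
                )
                p_rate = p_mg * 1000.0 / mw
                net_solid += p_rate
                rate -= p_rate
            dy[i_sol] += net_solid
            dy[i_dis] += rate

    # ------------------------------------------------------------------
    def simulate(self, duration_h: float, grid_h: float | None = None,
                 ) -> SimulationResult:
        """Integrate the system over ``duration_h`` hours.

        Integration is restarted at every dose/infusion/meal event and the
        output grid includes all event times.  Raises if the solver fails or
        the mass-balance residual exceeds 1e-6.
        """
        if not np.isfinite(duration_h) or duration_h <= 0:
            raise ValueError("finite positive duration required")
        st = self.settings
        grid = grid_h if grid_h is not None else st.grid_h
        t_end = duration_h * 60.0
        bps = self._breakpoints(t_end)
        t_eval = np.unique(np.concatenate([
            np.arange(0.0, t_end + 1e-9, grid * 60.0), bps,
        ]))
        t_eval = t_eval[(t_eval >= 0) & (t_eval <= t_end + 1e-9)]

        y = np.zeros(self.n_states)
        out = np.empty((t_eval.size, self.n_states))
        written = 0
        for a, b in zip(bps, bps[1:]):
            for blk in self.blocks:
                if any(abs(td - a) < 1e-9 for td in blk.dose_times_min):
                    blk.apply_dose(y)
            mask = (t_eval >= a - 1e-9) & (t_eval <= b + 1e-9)
            seg_t = t_eval[mask]
            mid = 0.5 * (a + b)
            rhs = self._rhs(self._piece_matrix(mid), self._infusion_vector(mid))
            sol = solve_ivp(rhs, (a, b), y, method=st.method, t_eval=seg_t,
                            rtol=st.rtol, atol=st.atol)
            if not sol.success:
                raise RuntimeError(f"solver failure in [{a}, {b}] min: "
                                   f"{sol.message}")
            # segments share their boundary point; overwrite it
            start = written if written == 0 else written - 1
            out[start:start + sol.y.shape[1]] = sol.y.T
            written = start + sol.y.shape[1]
            y = sol.y[:, -1].copy()
        assert written == t_eval.size

        return self._package(t_eval, out)

    def _package(self, t_min: np.ndarray, states: np.ndarray) -> SimulationResult:
        time_h = t_min / 60.0
        v_ven = self.individual.organ_volumes["venous_blood"]
        plasma, amounts, elim, doses = {}, {}, {}, {}
        residual = 0.0
        for blk in self.blocks:
            o = blk.offset
            ys = states[:, o:o + blk.n]
            name = blk.compound.name
            plasma[name] = np.maximum(ys[:, blk.ix["venous"]] / v_ven, 0.0) * blk.mw
            amounts[name] = pd.DataFrame(ys, columns=blk.state_names,
                                         index=time_h)
            elim[name] = amounts[name][[f"elim_{p}" for p in blk.pathways]]
            doses[name] = blk.regimen.dose
            given = np.array([blk.administered_umol(t, t_min[-1]) for t in t_min])
            body_cols = [i for i, nm in enumerate(blk.state_names)
                         if not nm.startswith("radius_")]
            total = ys[:, body_cols].sum(axis=1)
            scale = np.maximum(given, blk.dose_umol if blk.dose_umol > 0 else 1.0)
            if blk.dose_umol > 0:
                residual = max(residual,
                               float(np.max(np.abs(total - given) / scale)))
        if residual > 1e-6:
            raise RuntimeError(
                f"mass-balance residual {residual:.2e} exceeds 1e-6"
            )
        return SimulationResult(
            time_h=time_h,
            plasma_concentration=plasma,
            compartment_amounts=amounts,
            cumulative_eliminated=elim,
            mass_balance_residual=residual,
            doses_mg=doses,
        )


def assemble_model(individual, compounds, regimens, interaction=False,
                   settings=None) -> PBPKModel:
    """Functional alias for :class:`PBPKModel`."""
    return PBPKModel(individual, compounds, regimens, interaction, settings)


# ---------------------------------------------------------------------------
# Generic piecewise integrator (also used for reduced test systems)

def integrate_piecewise(rhs, y0, breakpoints, t_eval, rtol=1e-8, atol=1e-10,
                        method="LSODA", events=None):
    """Integrate ``rhs`` restarting at every breakpoint.

    ``events`` maps a breakpoint time to a state-modifying callable applied
    on arrival (dose boluses).  Returns the states on ``t_eval``.
    This is the same restart discipline the whole-body model uses, exposed
    so that reduced systems (e.g. a one-compartment model) can exercise the
    identical integration machinery.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    y = np.array(y0, dtype=float)
    out = np.empty((t_eval.size, y.size))
    written = 0
    bps = sorted(set(breakpoints))
    for a, b in zip(bps, bps[1:]):
        if events:
            for te, fn in events.items():
                if abs(te - a) < 1e-12:
                    y = np.asarray(fn(y), dtype=float)
        mask = (t_eval >= a - 1e-12) & (t_eval <= b + 1e-12)
        sol = solve_ivp(rhs, (a, b), y, method=method, t_eval=t_eval[mask],
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(sol.message)
        start = written if written == 0 else written - 1
        out[start:start + sol.y.shape[1]] = sol.y.T
        written = start + sol.y.shape[1]
        y = sol.y[:, -1].copy()
    return out
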