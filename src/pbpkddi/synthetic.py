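"""Synthetic concentration–time datasets with known ground truth.

Two dataset classes cover everything the evaluation and estimation layers
consume: dense study-design profiles (fixed nominal sampling times, log-normal
residual error, per-subject parameter variability) and sparse
clinical-routine TDM samples at steady state with dose-time uncertainty —
the recorded time-since-dose differs from the true one by a jitter draw, so
the datasets embed realistic timing error.  Ground-truth parameters travel
with every dataset for recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import DosingRegimen, PBPKModel, SolverSettings
from .evaluation import ObservedDataset
from .physiology import (
    DEFAULT_IIV_CV,
    GVHD_DEMOGRAPHIC_RANGES,
    PopulationSpec,
    sample_population,
)


@dataclass(frozen=True)
class StudyDesign:
    """Dense-profile study design.

    ``residual_sd_log10`` is the SD of the multiplicative residual error on
    the log10 scale (0.1 ≈ 26% CV); ``iiv_cv`` maps parameter names to
    log-normal coefficients of variation applied per subject.
    """

    compound: str
    regimen: DosingRegimen
    n_subjects: int
    sampling_times: tuple  # h since first dose
    residual_sd_log10: float = 0.1
    iiv_cv: dict = field(default_factory=lambda: dict(DEFAULT_IIV_CV))
    demographic_ranges: dict = field(
        default_factory=lambda: dict(GVHD_DEMOGRAPHIC_RANGES)
    )
    seed: int = 0

    def __post_init__(self):
        if self.residual_sd_log10 < 0:
            raise ValueError("residual SD must be >= 0")
        if any(cv < 0 for cv in self.iiv_cv.values()):
            raise ValueError("IIV CVs must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")


@dataclass(frozen=True)
class TDMDesign(StudyDesign):
    """Sparse therapeutic-drug-monitoring design at steady state."""

    samples_per_patient: tuple = (8, 9)
    dose_time_jitter_sd_h: float = 0.5
    perpetrator_cotiming_assumed: bool = True
    perpetrator: object = None  # (CompoundParameters, DosingRegimen) or None
    sampling_day: int = 10

    def __post_init__(self):
        super().__post_init__()
        if self.dose_time_jitter_sd_h < 0:
            raise ValueError("jitter must be >= 0")


def _simulate_subject(compound, regimen, individual, horizon_h, grid_h,
                      settings, perpetrator=None):
    if perpetrator is None:
        model = PBPKModel(individual, compound, regimen, settings=settings)
    else:
        perp_compound, perp_regimen = perpetrator
        model = PBPKModel(individual, [perp_compound, compound],
                          [perp_regimen, regimen], interaction=True,
                          settings=settings)
    return model.simulate(horizon_h, grid_h=grid_h)


def generate_study_dataset(design: StudyDesign, compound,
                           settings: SolverSettings | None = None,
                           grid_h: float = 0.1) -> list[ObservedDataset]:
    """Simulate a dense study: per subject, draw an individual with
    parameter variability, run the model, read off the nominal sampling
    times and multiply by log-normal residual noise.

    With zero residual SD and zero CVs the dataset equals the deterministic
    model prediction exactly; identical seeds give identical datasets.
    """
    settings = settings or SolverSettings(rtol=1e-6, atol=1e-9)
    t_samp = np.asarray(design.sampling_times, dtype=float)
    horizon = max(float(np.max(t_samp)), max(design.regimen.dose_times_h) + 1.0)
    pop = sample_population(PopulationSpec(
        n=design.n_subjects, demographic_ranges=design.demographic_ranges,
        seed=design.seed, iiv_cv=design.iiv_cv,
        population_label=f"study_{design.compound}",
    ))
    rng = np.random.default_rng(design.seed + 1)
    datasets = []
    for i, ind in enumerate(pop):
        res = _simulate_subject(compound, design.regimen, ind, horizon,
                                grid_h, settings)
        pred = np.interp(t_samp, res.time_h,
                         res.plasma_concentration[compound.name])
        noise = rng.normal(0.0, design.residual_sd_log10, size=t_samp.size)
        conc = pred * 10.0 ** noise if design.residual_sd_log10 > 0 else pred
        datasets.append(ObservedDataset(
            dataset_id=f"study_{design.compound}_{design.seed}",
            subject_id=f"S{i:03d}",
            compound=design.compound,
            times=t_samp,
            concentrations=conc,
            dosing_context=design.regimen,
            covariates={
                "truth": {
                    "iiv_factors": dict(ind.iiv_factors),
                    "weight_kg": ind.demographics.weight,
                    "noise_free": pred.tolist(),
                },
            },
        ))
    return datasets


def _draw_time_since_dose(rng, tau_h: float) -> float:
    # uniform over the interval with extra mass near trough, matching
    # clinical-routine sampling that clusters before the next dose
    if rng.random() < 0.5:
        return float(rng.uniform(0.0, tau_h))
    return float(rng.triangular(0.5 * tau_h, tau_h, tau_h))


def generate_tdm_dataset(design: TDMDesign, compound,
                         settings: SolverSettings | None = None,
                         grid_h: float = 0.1) -> list[ObservedDataset]:
    """Simulate sparse clinical-routine TDM sampling at steady state.

    Concentrations are read at the *true* sampling times while the recorded
    times carry the dose-time jitter, so the reported time-since-dose is
    biased exactly the way patient-reported intake times are.  When a
    perpetrator is attached and co-timing is assumed, it is dosed at the
    victim's dose times.
    """
    settings = settings or SolverSettings(rtol=1e-6, atol=1e-9)
    reg = design.regimen
    times = reg.dose_times_h
    tau = times[1] - times[0] if len(times) > 1 else 24.0
    day_start = (design.sampling_day - 1) * 24.0
    anchor = next((t for t in times if t >= day_start - 1e-9), times[-1])
    horizon = anchor + tau

    pop = sample_population(PopulationSpec(
        n=design.n_subjects, demographic_ranges=design.demographic_ranges,
        seed=design.seed, iiv_cv=design.iiv_cv,
        population_label=f"tdm_{design.compound}",
    ))
    rng = np.random.default_rng(design.seed + 1)
    lo, hi = design.samples_per_patient
    datasets = []
    for i, ind in enumerate(pop):
        res = _simulate_subject(compound, reg, ind, horizon, grid_h, settings,
                                perpetrator=design.perpetrator
                                if design.perpetrator_cotiming_assumed
                                or design.perpetrator is None
                                else design.perpetrator)
        n_samp = int(rng.integers(lo, hi + 1))
        tsd_true = np.array([_draw_time_since_dose(rng, tau)
                             for _ in range(n_samp)])
        jitter = rng.normal(0.0, design.dose_time_jitter_sd_h, size=n_samp)
        t_true = anchor + np.sort(tsd_true)
        pred = np.interp(t_true, res.time_h,
                         res.plasma_concentration[compound.name])
        noise = rng.normal(0.0, design.residual_sd_log10, size=n_samp)
        conc = pred * 10.0 ** noise if design.residual_sd_log10 > 0 else pred
        recorded = np.maximum(t_true - anchor + jitter, 0.0)
        datasets.append(ObservedDataset(
            dataset_id=f"tdm_{design.compound}_{design.seed}",
            subject_id=f"P{i:03d}",
            compound=design.compound,
            times=recorded + anchor,
            concentrations=conc,
            dosing_context=reg,
            covariates={
                "truth": {
                    "true_times_h": t_true.tolist(),
                    "time_since_dose_true_h": (t_true - anchor).tolist(),
                    "iiv_factors": dict(ind.iiv_factors),
                    "noise_free": pred.tolist(),
                },
                "steady_state_assumed": True,
                "perpetrator_cotiming_assumed":
                    design.perpetrator_cotiming_assumed,
            },
        ))
    return datasets
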