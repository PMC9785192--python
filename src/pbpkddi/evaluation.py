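"""Model-performance statistics, prediction intervals and sensitivity.

Implements the accuracy/precision metrics used to judge PBPK model fits —
per-point prediction error PE, its mean MPE and absolute mean MAPE, the mean
relative deviation MRD = 10^sqrt(mean(Δlog10²)), the fraction of predictions
within 2-fold of the observations — together with population prediction
intervals with observed-coverage computation and a local (one-at-a-time)
sensitivity analysis on log-spaced parameter multipliers.

Below-LLOQ observations are excluded from all statistics and from coverage
numerators and denominators; the 2-fold boundary is inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

OBSERVED_CSV_COLUMNS = [
    "dataset_id", "subject_id", "compound", "time_h", "conc_ng_ml",
    "dose_mg", "route", "formulation", "below_lloq",
]


@dataclass
class ObservedDataset:
    """Concentration–time observations with their dosing context.

    ``times`` are hours since the reference (first) dose; ``lloq`` is the
    assay lower limit of quantification in ng/mL.  Concentrations at or
    below LLOQ stay in the container but are flagged and excluded from the
    evaluation statistics.
    """

    dataset_id: str
    subject_id: str
    compound: str
    times: np.ndarray
    concentrations: np.ndarray
    lloq: float = 0.0
    dosing_context: object = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must be paired")
        if np.any(self.times < 0):
            raise ValueError("negative observation time")
        if np.any(self.concentrations < 0):
            raise ValueError("negative concentration")

    @property
    def quantifiable(self) -> np.ndarray:
        return self.concentrations > self.lloq

    def to_frame(self) -> pd.DataFrame:
        ctx = self.dosing_context
        regs = ctx if isinstance(ctx, (tuple, list)) else (ctx,)
        reg = regs[0]
        return pd.DataFrame({
            "dataset_id": self.dataset_id,
            "subject_id": self.subject_id,
            "compound": self.compound,
            "time_h": self.times,
            "conc_ng_ml": self.concentrations,
            "dose_mg": getattr(reg, "dose", np.nan),
            "route": getattr(reg, "route", ""),
            "formulation": str(getattr(reg, "formulation", "")),
            "below_lloq": ~self.quantifiable,
        })


def datasets_to_csv(datasets, path) -> None:
    pd.concat([d.to_frame() for d in datasets], ignore_index=True).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Accuracy / precision metrics

def prediction_error(c_pred, c_obs) -> np.ndarray:
    """Per-point prediction error in percent, (pred - obs)/obs * 100."""
    c_pred = np.atleast_1d(np.asarray(c_pred, dtype=float))
    c_obs = np.atleast_1d(np.asarray(c_obs, dtype=float))
    if c_pred.size == 0:
        raise ValueError("empty input")
    if np.any(c_obs <= 0):
        raise ValueError("observed concentrations must be positive "
                         "(exclude below-LLOQ points first)")
    return (c_pred - c_obs) / c_obs * 100.0


def mpe(pe_values) -> float:
    """Mean (signed) prediction error, percent."""
    pe_values = np.asarray(pe_values, dtype=float)
    if pe_values.size == 0:
        raise ValueError("empty input")
    return float(np.mean(pe_values))


def mape(pe_values) -> float:
    """Mean absolute prediction error, percent."""
    pe_values = np.asarray(pe_values, dtype=float)
    if pe_values.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(pe_values)))


def mrd(c_pred, c_obs) -> float:
    """Mean relative deviation, 10^sqrt(mean((log10 pred - log10 obs)^2)).

    Equals 1 for a perfect fit and 2 when predictions deviate on average by
    a factor of two on the log scale; values <= 2 are conventionally
    considered adequate.
    """
    c_pred = np.atleast_1d(np.asarray(c_pred, dtype=float))
    c_obs = np.atleast_1d(np.asarray(c_obs, dtype=float))
    if c_pred.size == 0:
        raise ValueError("empty input")
    if np.any(c_pred <= 0) or np.any(c_obs <= 0):
        raise ValueError("nonpositive concentration in MRD input")
    x = math.sqrt(float(np.mean((np.log10(c_pred) - np.log10(c_obs)) ** 2)))
    return 10.0 ** x


def twofold_fraction(c_pred, c_obs=None) -> float:
    """Fraction of prediction/observation ratios within [0.5, 2.0], bounds
    inclusive.  Accepts either paired arrays or precomputed ratios."""
    if c_obs is None:
        ratios = np.atleast_1d(np.asarray(c_pred, dtype=float))
    else:
        c_pred = np.atleast_1d(np.asarray(c_pred, dtype=float))
        c_obs = np.atleast_1d(np.asarray(c_obs, dtype=float))
        if np.any(c_obs <= 0):
            raise ValueError("observed concentrations must be positive")
        ratios = c_pred / c_obs
    if ratios.size == 0:
        raise ValueError("empty input")
    if np.any(ratios <= 0):
        raise ValueError("nonpositive ratio")
    return float(np.mean((ratios >= 0.5) & (ratios <= 2.0)))


@dataclass
class EvaluationReport:
    """All fit statistics for one prediction/observation pairing."""

    pe_values: np.ndarray
    mpe: float
    mape: float
    mrd: float
    fraction_within_twofold: float
    n: int
    n_excluded_lloq: int = 0
    metric_ratios: pd.DataFrame | None = None

    def summary(self) -> str:
        out = [
            f"n = {self.n} observations "
            f"({self.n_excluded_lloq} excluded below LLOQ)",
            f"MPE  {self.mpe:8.2f} %",
            f"MAPE {self.mape:8.2f} %",
            f"MRD  {self.mrd:8.3f}  ({'<= 2, adequate' if self.mrd <= 2 else '> 2'})",
            f"within 2-fold {100 * self.fraction_within_twofold:6.2f} %",
        ]
        return "\n".join(out)

    def to_dict(self) -> dict:
        return {
            "n": self.n, "mpe_percent": self.mpe, "mape_percent": self.mape,
            "mrd": self.mrd,
            "fraction_within_twofold": self.fraction_within_twofold,
            "n_excluded_lloq": self.n_excluded_lloq,
        }


def evaluate_predictions(c_pred, c_obs, lloq: float = 0.0) -> EvaluationReport:
    """Full accuracy report for paired predicted/observed concentrations."""
    c_pred = np.atleast_1d(np.asarray(c_pred, dtype=float))
    c_obs = np.atleast_1d(np.asarray(c_obs, dtype=float))
    keep = c_obs > lloq
    n_excl = int(np.sum(~keep))
    c_pred, c_obs = c_pred[keep], c_obs[keep]
    if c_pred.size == 0:
        raise ValueError("no quantifiable observations")
    pe = prediction_error(c_pred, c_obs)
    return EvaluationReport(
        pe_values=pe, mpe=mpe(pe), mape=mape(pe), mrd=mrd(c_pred, c_obs),
        fraction_within_twofold=twofold_fraction(c_pred, c_obs),
        n=int(c_pred.size), n_excluded_lloq=n_excl,
    )


def evaluate_datasets(pairs) -> tuple[EvaluationReport, pd.DataFrame]:
    """Pooled report plus a per-dataset table.

    ``pairs`` is a sequence of (dataset_id, c_pred, c_obs).  Whether 2-fold
    statistics should be pooled or averaged per study is ambiguous in
    common practice, so both are reported: the pooled report and per-dataset
    rows.
    """
    all_pred, all_obs, rows = [], [], []
    for ds_id, c_pred, c_obs in pairs:
        rep = evaluate_predictions(c_pred, c_obs)
        rows.append({"dataset_id": ds_id, **rep.to_dict()})
        all_pred.append(np.asarray(c_pred, dtype=float))
        all_obs.append(np.asarray(c_obs, dtype=float))
    pooled = evaluate_predictions(np.concatenate(all_pred),
                                  np.concatenate(all_obs))
    return pooled, pd.DataFrame(rows)


def gof_scatter_frame(pairs) -> pd.DataFrame:
    """Goodness-of-fit scatter data (predicted vs observed, per dataset)
    ready for CSV export and plotting.

    ``pairs`` as in :func:`evaluate_datasets`; adds the prediction/observation
    ratio and a within-2-fold flag per point.
    """
    rows = []
    for ds_id, c_pred, c_obs in pairs:
        c_pred = np.atleast_1d(np.asarray(c_pred, dtype=float))
        c_obs = np.atleast_1d(np.asarray(c_obs, dtype=float))
        ratio = c_pred / c_obs
        rows.append(pd.DataFrame({
            "dataset_id": ds_id,
            "observed_ng_ml": c_obs,
            "predicted_ng_ml": c_pred,
            "ratio": ratio,
            "within_twofold": (ratio >= 0.5) & (ratio <= 2.0),
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Prediction intervals

def prediction_interval(time_h, profiles, level=(0.05, 0.95)) -> pd.DataFrame:
    """Pointwise empirical quantile band of population profiles.

    ``profiles`` has one row per subject and one column per time point; at
    least 20 subjects are required for stable quantiles.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 20:
        raise ValueError("need a (subjects x times) array with >= 20 subjects")
    lo, hi = level
    return pd.DataFrame({
        "time_h": np.asarray(time_h, dtype=float),
        "lower": np.quantile(profiles, lo, axis=0),
        "median": np.quantile(profiles, 0.5, axis=0),
        "upper": np.quantile(profiles, hi, axis=0),
    })


def coverage(observed_times, observed_concs, band: pd.DataFrame,
             lloq: float = 0.0) -> float:
    """Fraction of quantifiable observations inside the band at their
    sampling times (band linearly interpolated in time)."""
    t = np.asarray(observed_times, dtype=float)
    c = np.asarray(observed_concs, dtype=float)
    keep = c > lloq
    t, c = t[keep], c[keep]
    if t.size == 0:
        raise ValueError("no quantifiable observations")
    tb = band["time_h"].to_numpy()
    if np.any(t < tb[0] - 1e-9) or np.any(t > tb[-1] + 1e-9):
        raise ValueError("observation time outside the simulated horizon")
    lo = np.interp(t, tb, band["lower"].to_numpy())
    hi = np.interp(t, tb, band["upper"].to_numpy())
    return float(np.mean((c >= lo) & (c <= hi)))


# ---------------------------------------------------------------------------
# Local sensitivity analysis

@dataclass
class SensitivityResult:
    parameter: str
    relative_sensitivity_auc: float
    relative_sensitivity_cmax: float
    variation_range: float
    steps: int
    table: pd.DataFrame | None = None


def perturb_compound(compound, parameter: str, factor: float):
    """Return a copy of ``compound`` with one named parameter multiplied.

    Supported names: ``logp``, ``fu_p``, ``gfr_fraction``,
    ``clearance.<ENZYME>``, ``formulation.<name>.dissolution_t50``,
    ``formulation.<name>.permeability``.
    """
    if parameter == "logp":
        return dc_replace(compound, logp=compound.logp * factor)
    if parameter == "fu_p":
        return dc_replace(compound, fu_p=min(compound.fu_p * factor, 1.0))
    if parameter == "gfr_fraction":
        return dc_replace(compound, gfr_fraction=compound.gfr_fraction * factor)
    if parameter.startswith("clearance."):
        enzyme = parameter.split(".", 1)[1]
        procs = tuple(
            dc_replace(p, value=p.value * factor) if p.enzyme == enzyme else p
            for p in compound.clearance_processes
        )
        if procs == compound.clearance_processes and not any(
            p.enzyme == enzyme for p in compound.clearance_processes
        ):
            raise KeyError(f"no clearance process for {enzyme}")
        return dc_replace(compound, clearance_processes=procs)
    if parameter.startswith("formulation."):
        _, fname, attr = parameter.split(".", 2)
        form = compound.formulations[fname]
        if attr == "dissolution_t50":
            form = dc_replace(form,
                              dissolution_time_t50=form.dissolution_time_t50
                              * factor)
        elif attr == "permeability":
            form = dc_replace(form, permeability=form.permeability * factor)
        else:
            raise KeyError(f"unsupported formulation attribute {attr}")
        forms = dict(compound.formulations)
        forms[fname] = form
        return dc_replace(compound, formulations=forms)
    raise KeyError(f"unsupported parameter {parameter!r}")


def local_sensitivity(metric_fn, parameter: str, variation_range: float = 10.0,
                      steps: int = 9) -> SensitivityResult:
    """One-at-a-time sensitivity of AUC_last and Cmax to one parameter.

    ``metric_fn(parameter, factor)`` must return an object with ``auc_last``
    and ``cmax`` attributes for the model with the named parameter multiplied
    by ``factor``.  Simulations run at log-spaced multipliers spanning
    [1/variation_range, variation_range] in at most ``steps`` points
    (including the base point), and the relative sensitivity
    S = (ΔM/M)/(Δp/p) is computed at the base point by central difference
    from the nearest neighbors.  Per-point simulation failures are recorded
    in the table and excluded.
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    if variation_range <= 1:
        raise ValueError("variation range must exceed 1")
    half = max((steps - 1) // 2, 1)
    exps = np.linspace(-1.0, 1.0, 2 * half + 1)
    factors = variation_range ** exps

    rows = []
    for fac in factors:
        try:
            m = metric_fn(parameter, float(fac))
            rows.append({"factor": float(fac), "auc_last": m.auc_last,
                         "cmax": m.cmax, "error": ""})
        except Exception as exc:  # recorded per point, never silently dropped
            rows.append({"factor": float(fac), "auc_last": np.nan,
                         "cmax": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows)
    ok = table[table["error"] == ""].reset_index(drop=True)
    base_idx = (ok["factor"] - 1.0).abs().idxmin()
    if not math.isclose(ok.loc[base_idx, "factor"], 1.0, rel_tol=1e-9):
        raise RuntimeError("base simulation failed")
    below = ok[ok["factor"] < 1.0 - 1e-12]
    above = ok[ok["factor"] > 1.0 + 1e-12]
    if below.empty or above.empty:
        raise RuntimeError("no successful perturbations around the base point")
    lo = below.iloc[-1]
    hi = above.iloc[0]
    base = ok.loc[base_idx]

    def rel_s(col):
        dm = (hi[col] - lo[col]) / base[col]
        dp = (hi["factor"] - lo["factor"]) / 1.0
        return float(dm / dp)

    return SensitivityResult(
        parameter=parameter,
        relative_sensitivity_auc=rel_s("auc_last"),
        relative_sensitivity_cmax=rel_s("cmax"),
        variation_range=variation_range,
        steps=len(factors),
        table=table,
    )
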