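"""Noncompartmental analysis and model-evaluation statistics.

Implements the exposure metrics (AUC_last by linear trapezoid, Cmax/Tmax,
average steady-state concentration), the prediction-error family (PE, MPE,
MAPE), the mean relative deviation MRD = 10^sqrt(mean(log10 ratio)^2)
(root-mean-square convention; values <= 2 indicate adequate performance),
fold-deviation fractions for goodness-of-fit, DDI exposure ratios, and a
deterministic least-squares parameter-fitting helper used by the recovery
tests.

Observed concentrations that are zero or below quantification are excluded
from the error statistics (exclusion count reported in the evaluation
report); the fold boundary is inclusive (p/o exactly 2 counts as within
2-fold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .params import RangeError

__all__ = [
    "ObservedProfile",
    "EvaluationReport",
    "SteadyStateError",
    "auc_last",
    "cmax_tmax",
    "css_average",
    "prediction_errors",
    "mrd",
    "ddi_ratios",
    "fold_fractions",
    "evaluate_profiles",
    "FitResult",
    "fit_parameters",
]


class SteadyStateError(RuntimeError):
    """Steady state could not be established from the simulated horizon."""


@dataclass(frozen=True)
class ObservedProfile:
    """A concentration-time profile with study metadata."""

    study_id: str
    arm: str
    times_h: np.ndarray
    conc_ng_ml: np.ndarray
    dose_mg: float
    formulation: str = "tablet"

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.conc_ng_ml, dtype=float)
        if t.size < 2:
            raise RangeError("times_h", t, "profile needs at least 2 points")
        if t.size != c.size:
            raise RangeError("profile", (t.size, c.size), "times and conc must align")
        if np.any(np.diff(t) <= 0):
            raise RangeError("times_h", t, "must be strictly increasing")
        if np.any(c < 0):
            raise RangeError("conc_ng_ml", c, "must be >= 0")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "conc_ng_ml", c)


@dataclass(frozen=True)
class EvaluationReport:
    """Model-evaluation summary for one predicted-vs-observed comparison."""

    pe_percent: np.ndarray
    mpe_percent: float
    mape_percent: float
    mrd: float
    frac_within_2fold: float
    frac_within_1p25fold: float
    auc_ratio_pred_obs: float
    cmax_ratio_pred_obs: float
    n_points: int
    n_excluded: int

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("mpe_percent", "mape_percent", "mrd", "frac_within_2fold",
              "frac_within_1p25fold", "auc_ratio_pred_obs",
              "cmax_ratio_pred_obs", "n_points", "n_excluded")}
        d["pe_percent"] = [float(x) for x in self.pe_percent]
        return d


def _times_conc(profile) -> tuple[np.ndarray, np.ndarray]:
    """Accept ObservedProfile, simulation results or (times, conc) pairs."""
    if isinstance(profile, ObservedProfile):
        return profile.times_h, profile.conc_ng_ml
    if hasattr(profile, "times") and hasattr(profile, "conc_plasma_ng_ml"):
        return np.asarray(profile.times), np.asarray(profile.conc_plasma_ng_ml)
    t, c = profile
    return np.asarray(t, dtype=float), np.asarray(c, dtype=float)


def auc_last(times, conc=None):
    """Area under the curve from the first to the last point, linear
    trapezoidal rule (ng*h/mL for ng/mL input)."""
    if conc is None:
        times, conc = _times_conc(times)
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times.size < 2:
        raise RangeError("times", times, "AUC needs at least 2 points")
    if np.any(np.diff(times) <= 0):
        raise RangeError("times", times, "must be strictly increasing")
    return float(np.trapezoid(conc, times))


def cmax_tmax(profile) -> tuple[float, float]:
    """Peak concentration and its time; ties resolved to the earliest."""
    t, c = _times_conc(profile)
    k = int(np.argmax(c))   # argmax returns the first maximum
    return float(c[k]), float(t[k])


def css_average(result, tau: float, min_intervals: int = 5,
                tolerance: float = 0.01) -> float:
    """Average steady-state concentration, AUC_tau / tau over the last
    dosing interval.

    Requires at least ``min_intervals`` complete intervals in the simulated
    horizon and a detected steady state (successive-interval AUC change
    below ``tolerance``); otherwise raises :class:`SteadyStateError` with a
    diagnostic.
    """
    t, c = _times_conc(result)
    if not tau > 0:
        raise RangeError("tau", tau, "must be > 0")
    t_end = t[-1]
    n_int = int(np.floor((t_end - t[0]) / tau + 1e-9))
    if n_int < min_intervals:
        raise SteadyStateError(
            f"only {n_int} complete intervals simulated, need >= {min_intervals}")

    def interval_auc(k_back: int) -> float:
        hi = t_end - k_back * tau
        lo = hi - tau
        grid = np.linspace(lo, hi, 201)
        return float(np.trapezoid(np.interp(grid, t, c), grid))

    auc_last_int = interval_auc(0)
    auc_prev_int = interval_auc(1)
    if auc_prev_int <= 0:
        raise SteadyStateError("no exposure in the penultimate interval")
    change = abs(auc_last_int - auc_prev_int) / auc_prev_int
    if change > tolerance:
        raise SteadyStateError(
            f"steady state not reached: successive-interval AUC change "
            f"{change:.2%} exceeds {tolerance:.0%}")
    return auc_last_int / tau


def prediction_errors(pred, obs) -> tuple[np.ndarray, float, float]:
    """Percent prediction errors and their mean / mean-absolute summaries.

    PE_i = (pred_i - obs_i)/obs_i * 100%; MPE = mean(PE); MAPE = mean(|PE|).
    Pairs with nonpositive observed values are excluded (BLQ policy).
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise RangeError("pred/obs", (pred.shape, obs.shape), "must have equal length")
    keep = obs > 0
    if not np.any(keep):
        raise RangeError("obs", obs, "no positive observed concentrations")
    pe = (pred[keep] - obs[keep]) / obs[keep] * 100.0
    return pe, float(np.mean(pe)), float(np.mean(np.abs(pe)))


def mrd(pred, obs) -> float:
    """Mean relative deviation: 10^sqrt(mean((log10 pred - log10 obs)^2)).

    Symmetric in pred/obs and invariant to common rescaling; 1 means perfect
    agreement, values <= 2 are conventionally adequate.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise RangeError("pred/obs", (pred.shape, obs.shape), "must have equal length")
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise RangeError("pred/obs", None, "MRD requires strictly positive values")
    x = np.sqrt(np.mean((np.log10(pred) - np.log10(obs)) ** 2))
    return float(10.0 ** x)


def ddi_ratios(with_perpetrator, alone) -> tuple[float, float]:
    """DDI exposure ratios: (AUC_last ratio, Cmax ratio), perpetrator arm
    over control arm."""
    auc_ddi = auc_last(with_perpetrator)
    auc_ctrl = auc_last(alone)
    cmax_ddi, _ = cmax_tmax(with_perpetrator)
    cmax_ctrl, _ = cmax_tmax(alone)
    if auc_ctrl <= 0 or cmax_ctrl <= 0:
        raise RangeError("alone profile", (auc_ctrl, cmax_ctrl),
                         "control exposure must be positive")
    return auc_ddi / auc_ctrl, cmax_ddi / cmax_ctrl


def fold_fractions(pred, obs, thresholds=(2.0, 1.25)) -> tuple[float, ...]:
    """Fractions of points within each fold threshold (inclusive bound)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise RangeError("pred/obs", None, "fold fractions require positive values")
    fold = np.maximum(pred / obs, obs / pred)
    return tuple(float(np.mean(fold <= thr)) for thr in thresholds)


def evaluate_profiles(predicted, observed: ObservedProfile) -> EvaluationReport:
    """Full evaluation of a predicted curve against an observed profile.

    The predicted curve is linearly interpolated onto the observed sampling
    times; nonpositive observed points are excluded from PE/MRD/fold
    statistics (count reported).
    """
    pt, pc = _times_conc(predicted)
    obs_t, obs_c = observed.times_h, observed.conc_ng_ml
    pred_at_obs = np.interp(obs_t, pt, pc)
    keep = (obs_c > 0) & (pred_at_obs > 0)
    n_excluded = int(np.sum(~keep))
    if keep.sum() < 2:
        raise RangeError("observed", observed.study_id,
                         "fewer than 2 usable (positive) points")
    pe, mpe, mape = prediction_errors(pred_at_obs[keep], obs_c[keep])
    rel_dev = mrd(pred_at_obs[keep], obs_c[keep])
    f2, f125 = fold_fractions(pred_at_obs[keep], obs_c[keep])
    auc_ratio = auc_last(pt, pc) / auc_last(obs_t, obs_c)
    cmax_ratio = cmax_tmax((pt, pc))[0] / cmax_tmax((obs_t, obs_c))[0]
    return EvaluationReport(
        pe_percent=pe, mpe_percent=mpe, mape_percent=mape, mrd=rel_dev,
        frac_within_2fold=f2, frac_within_1p25fold=f125,
        auc_ratio_pred_obs=auc_ratio, cmax_ratio_pred_obs=cmax_ratio,
        n_points=int(keep.sum()), n_excluded=n_excluded)


@dataclass
class FitResult:
    estimates: dict[str, float]
    objective: float
    success: bool
    message: str
    n_evaluations: int


def fit_parameters(profiles, predict, names, bounds, start,
                   method: str = "powell", xtol: float = 1e-4) -> FitResult:
    """Least-squares parameter estimation on the log-concentration scale.

    ``predict(params: dict) -> list[np.ndarray]`` must return predicted
    concentrations aligned with each profile's sampling times.  Minimizes
    sum over profiles of sum((log10 pred - log10 obs)^2) with a
    derivative-free bounded local optimizer — Powell by default, or a
    bounded Brent scalar search (``method='bounded'``) for single-parameter
    problems, which needs far fewer model evaluations.  Deterministic for a
    given start point.  Points where either value is nonpositive are
    excluded from the objective.
    """
    if isinstance(profiles, ObservedProfile):
        profiles = [profiles]
    names = list(names)
    start = np.asarray([start[n] if isinstance(start, dict) else start[i]
                        for i, n in enumerate(names)], dtype=float)
    lo = np.array([bounds[n][0] if isinstance(bounds, dict) else bounds[i][0]
                   for i, n in enumerate(names)])
    hi = np.array([bounds[n][1] if isinstance(bounds, dict) else bounds[i][1]
                   for i, n in enumerate(names)])
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise RangeError("bounds", (lo, hi), "must be finite")
    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        params = dict(zip(names, x))
        preds = predict(params)
        total = 0.0
        for prof, pred in zip(profiles, preds):
            obs = prof.conc_ng_ml
            pred = np.asarray(pred, dtype=float)
            keep = (obs > 0) & (pred > 0)
            total += float(np.sum((np.log10(pred[keep]) - np.log10(obs[keep])) ** 2))
        return total

    if method == "bounded":
        if len(names) != 1:
            raise RangeError("method", method,
                             "'bounded' applies to single-parameter fits only")
        res = optimize.minimize_scalar(
            lambda x: objective(np.array([x])), bounds=(lo[0], hi[0]),
            method="bounded", options={"xatol": xtol * max(abs(start[0]), 1.0)})
        return FitResult(estimates={names[0]: float(res.x)},
                         objective=float(res.fun), success=bool(res.success),
                         message=str(getattr(res, "message", "")),
                         n_evaluations=n_eval)
    if method != "powell":
        raise RangeError("method", method, "must be 'powell' or 'bounded'")
    res = optimize.minimize(objective, start, method="Powell",
                            bounds=list(zip(lo, hi)),
                            options={"xtol": xtol, "ftol": 1e-8})
    return FitResult(estimates=dict(zip(names, map(float, res.x))),
                     objective=float(res.fun), success=bool(res.success),
                     message=str(res.message), n_evaluations=n_eval)
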