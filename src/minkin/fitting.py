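"""Least-squares estimation of mineralization kinetics and model selection.

Fitting follows the conventional workflow for degradation-kinetics
endpoint derivation: replicate means per sampling time are fitted by
bounded nonlinear least squares, goodness of fit is summarized by the
minimum error percentage at which a chi-square test would accept the fit,
and the model with the smallest error percentage is selected (error levels
below 15% conventionally denote an acceptable fit).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
from scipy.stats import chi2 as chi2_dist

from .models import (
    MODEL_PARAM_NAMES,
    DtEstimate,
    KineticParameters,
    ModelId,
    dt_x_closed_form,
    model_curve,
)

__all__ = [
    "FitError",
    "ModelSelectionError",
    "FitResult",
    "chi2_error_percent",
    "fit_model",
    "select_model",
    "fit_all",
    "FitOutcome",
]

#: Error percentage below which a fit is conventionally "good".
CHI2_GOOD_FIT_THRESHOLD = 15.0

#: Tie margin (percentage points of chi2 error) for preferring parsimony.
SELECTION_TIE_MARGIN = 0.1

_RATE_LIKE = ("k1", "k2", "alpha", "beta")  # bound-activity checked on these

_BOUNDS = {
    "k1": (1e-8, 10.0),
    "k2": (1e-8, 10.0),
    "alpha": (1e-3, 50.0),
    "beta": (1e-3, 1e5),
    "tb": (1e-3, 1e5),  # tightened to the sampling window at fit time
    "m_max": (1e-6, 100.0),
}


class FitError(RuntimeError):
    """A curve cannot be fitted (e.g. too few distinct timepoints)."""


class ModelSelectionError(RuntimeError):
    """No converged fit is available to select from."""


@dataclass
class FitResult:
    """Outcome of fitting one kinetic model to one mineralization curve."""

    params: KineticParameters
    dt50: DtEstimate
    dt90: DtEstimate
    chi2_error_pct: float
    ssr: float
    n_obs: int
    n_params: int
    mean_observed: float
    residuals: np.ndarray
    extent_observed: float
    converged: bool
    n_starts_tried: int
    seed: Optional[int] = None
    poor_fit: bool = field(init=False)

    def __post_init__(self) -> None:
        self.poor_fit = not (self.chi2_error_pct < CHI2_GOOD_FIT_THRESHOLD)


def chi2_error_percent(
    observed: Sequence[float], predicted: Sequence[float], n_params: int
) -> float:
    """Minimum error level (percent) at which a chi-square test passes.

    ``err% = (100 / mean(O)) * sqrt(SSR / chi2_crit(m - p, 0.95))`` — the
    smallest relative measurement error for which the scaled squared
    residuals do not exceed the upper 5% chi-square quantile on
    ``m - p`` degrees of freedom.  Invariant under a common rescaling of
    observed and predicted values.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have the same length")
    m = observed.size
    df = m - n_params
    if df <= 0:
        raise ValueError(f"need more observations ({m}) than parameters ({n_params})")
    mean_obs = observed.mean()
    if mean_obs <= 0:
        raise ValueError("mean of observations must be positive")
    ssr = float(np.sum((observed - predicted) ** 2))
    crit = chi2_dist.ppf(0.95, df)
    return 100.0 / mean_obs * math.sqrt(ssr / crit)


def _initial_guesses(
    model_id: ModelId, times: np.ndarray, obs: np.ndarray, fix_mmax: bool
) -> dict:
    """Data-driven starting values: plateau from the curve maximum, k1 from
    a log-linear regression of the early rise, schedule-based tb/beta."""
    m_max0 = 100.0 if fix_mmax else float(np.clip(obs.max() * 1.05, 1.0, 100.0))
    pos = (times > 0) & (obs > 0) & (obs < 0.95 * m_max0)
    if pos.any():
        y = -np.log1p(-np.clip(obs[pos] / m_max0, 0.0, 0.999999))
        k10 = float(np.sum(y * times[pos]) / np.sum(times[pos] ** 2))
        k10 = float(np.clip(k10, 1e-6, 1.0))
    else:
        k10 = 1e-4
    interior = times[times > 0]
    guesses = {"m_max": m_max0}
    if model_id is ModelId.SFO:
        guesses["k1"] = k10
    elif model_id is ModelId.FOMC:
        guesses["alpha"] = 1.0
        guesses["beta"] = float(np.median(interior)) if interior.size else 10.0
    else:
        guesses["k1"] = k10
        guesses["k2"] = k10 / 10.0
        mid = times[len(times) // 2]
        guesses["tb"] = float(mid) if mid > 0 else float(times[-1] / 2)
    return guesses


def _make_lmfit_params(
    model_id: ModelId, start: dict, times: np.ndarray, fix_mmax: bool
) -> lmfit.Parameters:
    pars = lmfit.Parameters()
    for name in MODEL_PARAM_NAMES[model_id]:
        lo, hi = _BOUNDS[name]
        if name == "tb":
            lo = max(float(times[times > 0].min()) * 0.5, 1e-3)
            hi = float(times.max())
        pars.add(name, value=float(np.clip(start[name], lo, hi)), min=lo, max=hi)
    lo, hi = _BOUNDS["m_max"]
    pars.add(
        "m_max",
        value=float(np.clip(start["m_max"], lo, hi)),
        min=lo,
        max=hi,
        vary=not fix_mmax,
    )
    return pars


def _params_from_lmfit(model_id: ModelId, pars: lmfit.Parameters) -> KineticParameters:
    kwargs = {name: float(pars[name].value) for name in MODEL_PARAM_NAMES[model_id]}
    return KineticParameters(model_id=model_id, m_max=float(pars["m_max"].value), **kwargs)


def fit_model(
    curve,
    model_id: ModelId | str,
    *,
    seed: Optional[int] = None,
    n_starts: int = 10,
    fix_mmax: bool = False,
    basis: str = "applied",
    pooled_replicates: bool = False,
) -> FitResult:
    """Fit one kinetic model to a mineralization curve.

    Observations are replicate means per sampling time by default
    (``pooled_replicates=True`` fits every replicate point instead).
    ``n_starts`` seeded multi-starts jitter the data-driven initial guess
    by ±50% to guard the local optimizer against poor basins; the best SSR
    is kept.  A fit is ``converged`` when the optimizer met its tolerance
    and no rate/shape parameter sits on a bound.

    Raises :class:`FitError` when the curve has fewer than
    ``n_free_params + 2`` distinct timepoints.
    """
    model_id = ModelId(model_id)
    if pooled_replicates:
        times, obs = curve.pooled_observations()
    else:
        times, obs = curve.replicate_mean()
    times = np.asarray(times, dtype=float)
    obs = np.asarray(obs, dtype=float)

    n_free = len(MODEL_PARAM_NAMES[model_id]) + (0 if fix_mmax else 1)
    if np.unique(times).size < n_free + 2:
        raise FitError(
            f"{model_id.value} needs at least {n_free + 2} distinct timepoints, "
            f"got {np.unique(times).size}"
        )

    start = _initial_guesses(model_id, times, obs, fix_mmax)
    rng = np.random.default_rng(seed)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        return model_curve(times, _params_from_lmfit(model_id, pars)) - obs

    starts = [dict(start)]
    if model_id is ModelId.HS:
        # single-phase start: lets HS reach the nested SFO solution
        starts.append({**start, "k2": start["k1"]})
    while len(starts) < n_starts:
        jittered = {
            k: v * rng.uniform(0.5, 1.5) if k != "m_max" else v
            for k, v in start.items()
        }
        starts.append(jittered)

    best = None
    for guess in starts[:n_starts]:
        pars = _make_lmfit_params(model_id, guess, times, fix_mmax)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = lmfit.minimize(
                    residual,
                    pars,
                    method="least_squares",
                    calc_covar=False,
                    ftol=1e-10,
                    xtol=1e-10,
                    gtol=1e-10,
                    max_nfev=1000,
                )
        except Exception:
            continue
        ssr = float(np.sum(np.asarray(res.residual) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, res)
    if best is None:
        raise FitError(f"optimizer failed for {model_id.value} on all starts")
    ssr, res = best

    fitted = _params_from_lmfit(model_id, res.params)
    predicted = model_curve(times, fitted)
    residuals = obs - predicted

    on_bound = False
    for name in MODEL_PARAM_NAMES[model_id]:
        if name in _RATE_LIKE:
            p = res.params[name]
            span = p.max - p.min
            if (p.value - p.min) <= 1e-8 * span or (p.max - p.value) <= 1e-10 * span:
                on_bound = True
    converged = bool(res.success) and not on_bound

    mean_obs = float(obs.mean())
    if mean_obs > 0:
        chi2_err = chi2_error_percent(obs, predicted, n_free)
    else:
        chi2_err = math.nan
        converged = False

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dt50 = dt_x_closed_form(fitted, 50.0, basis=basis)
        dt90 = dt_x_closed_form(fitted, 90.0, basis=basis)

    return FitResult(
        params=fitted,
        dt50=dt50,
        dt90=dt90,
        chi2_error_pct=chi2_err,
        ssr=ssr,
        n_obs=int(obs.size),
        n_params=n_free,
        mean_observed=mean_obs,
        residuals=residuals,
        extent_observed=float(obs[np.argmax(times)]),
        converged=converged,
        n_starts_tried=min(len(starts), n_starts),
        seed=seed,
    )


def select_model(fits: Sequence[FitResult]) -> FitResult:
    """Pick the best fit: smallest chi-square error among converged fits.

    Fits whose errors are within 0.1 percentage points of the minimum are
    tie-broken toward fewer free parameters.  The returned fit keeps its
    ``poor_fit`` flag when even the best error is at or above 15%.
    """
    if not fits:
        raise ModelSelectionError("no fits supplied")
    converged = [f for f in fits if f.converged and math.isfinite(f.chi2_error_pct)]
    if not converged:
        raise ModelSelectionError("no converged fit to select from")
    best_err = min(f.chi2_error_pct for f in converged)
    candidates = [
        f for f in converged if f.chi2_error_pct <= best_err + SELECTION_TIE_MARGIN
    ]
    return min(candidates, key=lambda f: (f.n_params, f.chi2_error_pct))


@dataclass
class FitOutcome:
    """Per-curve record from a batch fit: the selected model plus all fits."""

    soil: str
    treatment: str
    selected: Optional[FitResult]
    fits: dict
    error: Optional[str] = None


def fit_all(
    curves,
    *,
    seed: Optional[int] = None,
    models: Sequence[ModelId] = (ModelId.SFO, ModelId.FOMC, ModelId.HS),
    **fit_kwargs,
) -> list[FitOutcome]:
    """Fit every supplied curve with every model and select the best.

    Per-curve failures are recorded on the outcome (``error``) and the
    batch continues.  Child seeds are derived deterministically from
    ``seed`` and the curve's position, so a rerun reproduces every fit.
    """
    outcomes: list[FitOutcome] = []
    for i, curve in enumerate(curves):
        child_seed = None if seed is None else int(
            np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)
        )
        fits: dict = {}
        errors: list[str] = []
        for model_id in models:
            try:
                fits[ModelId(model_id)] = fit_model(
                    curve, model_id, seed=child_seed, **fit_kwargs
                )
            except FitError as exc:
                errors.append(f"{ModelId(model_id).value}: {exc}")
        try:
            selected = select_model(list(fits.values()))
            error = None
        except ModelSelectionError as exc:
            selected = None
            error = "; ".join(errors) or str(exc)
        outcomes.append(
            FitOutcome(
                soil=curve.soil,
                treatment=curve.treatment,
                selected=selected,
                fits=fits,
                error=error,
            )
        )
    return outcomes
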