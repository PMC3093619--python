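"""The 2AFC analysis chain: aggregation, Weibull fits, PSEs, dB, bootstrap.

Trials are aggregated per probe intensity level into compound-choice counts,
a Weibull psychometric function

    P(compound) = lapse/2 + (1 - lapse) * (1 - exp(-(x / alpha)^beta))

is fit by maximising the binomial likelihood over (alpha, beta) with the
lapse fixed (estimating a lapse from 200 trials is unstable; 0.01 by
default, configurable), and the PSE is the intensity at which the fitted
curve crosses 50%.  With the symmetric lapse term this crossing has the
closed form ``alpha * ln(2)^(1/beta)``.

Because each staircase was run with the compound adaptor in the left and
the right hemi-field, the two per-side PSEs are averaged, which cancels any
fixed side bias.  Effects are reported as the shift of that averaged PSE
from the point of veridical equality; plaid effects are additionally
expressed in decibels, ``db = 20 * log10(C_adapt / C)`` with ``C`` the
reference probe contrast and ``C_adapt`` the matching contrast.

Confidence intervals come from a within-subject bootstrap: each resample
redraws every side's trials with replacement (at the original count),
refits both psychometric functions, and averages the resulting PSE pair;
the 95% CI is the 2.5/97.5 percentile band of the resampled means
(5000 resamples in the published-scale analysis).  Resamples whose fits
fail are dropped and counted; more than 20% failures flags the CI as
unreliable.

Probe intensities must be positive for the Weibull: plaid probes are raw
Michelson contrasts, and contour probe angles are mapped to the positive
"curvature" coordinate 180 - angle (degrees of deviation from a straight
contour), an invertible relabelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "ResponseTable",
    "PsychometricFit",
    "PSEEstimate",
    "AdaptationEffect",
    "aggregate",
    "fit_weibull",
    "pse_from_fit",
    "side_averaged_pse",
    "to_db",
    "from_db",
    "bootstrap_ci",
    "adaptation_effect",
    "analyze_trials",
    "angle_to_curvature",
    "curvature_to_angle",
]

DEFAULT_LAPSE = 0.01
_LOG_BETA_BOUNDS = (math.log(0.2), math.log(80.0))
_P_FLOOR = 1e-9


@dataclass
class ResponseTable:
    """Compound-choice counts per unique probe intensity, sorted ascending."""

    intensity: np.ndarray
    n_compound: np.ndarray
    n_total: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.n_compound > self.n_total) or np.any(self.n_compound < 0):
            raise ValueError("counts must satisfy 0 <= n_compound <= n_total")
        if np.any(np.diff(self.intensity) <= 0):
            raise ValueError("intensities must be sorted and unique")

    @property
    def total_trials(self) -> int:
        return int(self.n_total.sum())


@dataclass
class PsychometricFit:
    """Fitted Weibull parameters (lapse held fixed)."""

    alpha: float
    beta: float
    lapse: float
    converged: bool
    n_trials: int

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        w = 1.0 - np.exp(-((np.asarray(x, dtype=float) / self.alpha) ** self.beta))
        return self.lapse / 2.0 + (1.0 - self.lapse) * w


@dataclass
class PSEEstimate:
    """Side-averaged PSE with optional bootstrap confidence interval.

    All values are on the (positive) intensity axis; shifts from veridical
    equality are derived downstream.  ``partial`` marks estimates where only
    one side could be fit.
    """

    pse_left: float
    pse_right: float
    pse_mean: float
    ci95: tuple[float, float] | None = None
    n_bootstrap: int = 0
    n_failed_resamples: int = 0
    partial: bool = False
    ci_unreliable: bool = False


@dataclass
class AdaptationEffect:
    """PSE shift from veridical equality, with the dB form for plaids."""

    shift: float
    units: str  # "contrast" or "degrees"
    C: float
    C_adapt: float
    db: float | None = None


def aggregate(trials: pd.DataFrame, side: str | None = None) -> ResponseTable:
    """Count compound choices per unique test intensity.

    ``side`` restricts to trials with the compound adaptor in that
    hemi-field ('left' or 'right'); None aggregates everything.  The total
    count is preserved exactly.
    """
    sub = trials if side is None else trials[trials["compound_side"] == side]
    if len(sub) == 0:
        raise ValueError(f"no trials for side {side!r}")
    grouped = (
        sub.assign(is_compound=(sub["response"] == "compound").astype(int))
        .groupby("intensity", sort=True)["is_compound"]
        .agg(["sum", "count"])
    )
    return ResponseTable(
        intensity=grouped.index.to_numpy(dtype=float),
        n_compound=grouped["sum"].to_numpy(dtype=int),
        n_total=grouped["count"].to_numpy(dtype=int),
    )


def _nll_and_grad(theta, x, n, y, lapse):
    la, lb = theta
    beta = math.exp(lb)
    u = np.log(x) - la
    t = np.exp(np.clip(beta * u, -700.0, 700.0))
    et = np.exp(-t)
    p = lapse / 2.0 + (1.0 - lapse) * (1.0 - et)
    p = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
    nll = -(y * np.log(p) + (n - y) * np.log1p(-p)).sum()
    dldp = -(y / p - (n - y) / (1.0 - p))
    dpdt = (1.0 - lapse) * et
    common = dldp * dpdt
    g_la = float((common * (-beta * t)).sum())
    g_lb = float((common * (beta * u * t)).sum())
    return nll, np.array([g_la, g_lb])


def _ls_objective(theta, x, n, y, lapse):
    la, lb = theta
    beta = math.exp(lb)
    t = np.exp(np.clip(beta * (np.log(x) - la), -700.0, 700.0))
    p = lapse / 2.0 + (1.0 - lapse) * (1.0 - np.exp(-t))
    return float(((p - y / n) ** 2).sum())


def _fit_counts(
    x: np.ndarray,
    n: np.ndarray,
    y: np.ndarray,
    lapse: float,
    method: str = "mle",
) -> PsychometricFit:
    """Core fitter on aggregated counts; x must be positive."""
    n_trials = int(n.sum())
    if len(x) < 3:
        return PsychometricFit(float("nan"), float("nan"), lapse, False, n_trials)
    if np.any(x <= 0):
        raise ValueError("probe intensities must be positive for the Weibull")
    total_y = int(y.sum())
    if total_y == 0 or total_y == n_trials:
        # all-identical responses: the likelihood has no interior optimum
        return PsychometricFit(float("nan"), float("nan"), lapse, False, n_trials)

    # initial scale: empirical 50% crossing, start slope beta = 3
    prop = y / n
    beta0 = 3.0
    cross = np.nonzero(np.diff(np.sign(prop - 0.5)) != 0)[0]
    if len(cross):
        i = cross[0]
        x0, x1, p0, p1 = x[i], x[i + 1], prop[i], prop[i + 1]
        x50 = x0 + (0.5 - p0) / (p1 - p0) * (x1 - x0) if p1 != p0 else x0
    else:
        x50 = float(np.median(x))
    alpha0 = max(x50, 1e-9) / math.log(2.0) ** (1.0 / beta0)

    span = float(x[-1] - x[0])
    alpha_lo = max(x[0] - span, x[0] * 1e-3, 1e-9)
    alpha_hi = x[-1] + max(span, x[-1])
    theta0 = np.array(
        [math.log(np.clip(alpha0, alpha_lo, alpha_hi)), math.log(beta0)]
    )
    bounds = [(math.log(alpha_lo), math.log(alpha_hi)), _LOG_BETA_BOUNDS]

    if method == "mle":
        res = minimize(
            _nll_and_grad,
            theta0,
            args=(x, n, y, lapse),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12},
        )
    elif method == "ls":
        res = minimize(
            _ls_objective,
            theta0,
            args=(x, n, y, lapse),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200},
        )
    else:
        raise ValueError(f"unknown fit method {method!r}")
    alpha, beta = math.exp(res.x[0]), math.exp(res.x[1])
    return PsychometricFit(alpha, beta, lapse, bool(res.success), n_trials)


def fit_weibull(
    table: ResponseTable, lapse: float = DEFAULT_LAPSE, method: str = "mle"
) -> PsychometricFit:
    """Fit the Weibull psychometric function to a response table.

    ``method`` is ``"mle"`` (binomial maximum likelihood, the default -
    trials per level weight the fit naturally) or ``"ls"`` (least squares
    on the proportions, kept as a cross-check).
    """
    return _fit_counts(table.intensity, table.n_total, table.n_compound, lapse, method)


def pse_from_fit(fit: PsychometricFit) -> float:
    """Intensity at which the fitted curve crosses 50%.

    With the symmetric lapse term the crossing is ``alpha * ln(2)^(1/beta)``
    for any fixed lapse < 1.
    """
    if not fit.converged or not np.isfinite(fit.alpha):
        raise ValueError("cannot extract a PSE from a non-converged fit")
    pse = fit.alpha * math.log(2.0) ** (1.0 / fit.beta)
    if not np.isfinite(pse) or pse <= 0:
        raise ValueError("fitted curve has no usable 50% crossing")
    return pse


def side_averaged_pse(
    left_trials: pd.DataFrame,
    right_trials: pd.DataFrame,
    lapse: float = DEFAULT_LAPSE,
    method: str = "mle",
) -> PSEEstimate:
    """Point estimate: mean of the left- and right-compound PSEs.

    A fixed side bias moves the two per-side PSEs by equal and opposite
    amounts, so their arithmetic mean is bias-free.  If one side cannot be
    fit the estimate falls back to the other side and is marked partial.
    """
    pses: dict[str, float] = {}
    for name, tbl in (("left", left_trials), ("right", right_trials)):
        try:
            pses[name] = pse_from_fit(fit_weibull(aggregate(tbl), lapse, method))
        except ValueError:
            pses[name] = float("nan")
    left, right = pses["left"], pses["right"]
    usable = [v for v in (left, right) if np.isfinite(v)]
    if not usable:
        raise ValueError("neither side produced a usable psychometric fit")
    return PSEEstimate(
        pse_left=left,
        pse_right=right,
        pse_mean=float(np.mean(usable)),
        partial=len(usable) < 2,
    )


def to_db(c_adapt: float, c: float) -> float:
    """Decibel form of a contrast match: ``20 * log10(C_adapt / C)``."""
    if c_adapt <= 0 or c <= 0:
        raise ValueError("contrasts must be positive")
    return 20.0 * math.log10(c_adapt / c)


def from_db(db: float, c: float) -> float:
    """Inverse of :func:`to_db`: the matching contrast ``C * 10^(db/20)``."""
    if c <= 0:
        raise ValueError("reference contrast must be positive")
    return c * 10.0 ** (db / 20.0)


def _side_arrays(trials: pd.DataFrame):
    intensity = trials["intensity"].to_numpy(dtype=float)
    resp = (trials["response"] == "compound").to_numpy(dtype=float)
    # canonical trial order, so the resampling stream - and therefore the
    # CI - is invariant to the row order of the input table
    order = np.lexsort((resp, intensity))
    intensity, resp = intensity[order], resp[order]
    levels, level_idx = np.unique(intensity, return_inverse=True)
    return levels, level_idx, resp


def bootstrap_ci(
    left_trials: pd.DataFrame,
    right_trials: pd.DataFrame,
    n_resamples: int = 5000,
    rng: np.random.Generator | None = None,
    lapse: float = DEFAULT_LAPSE,
    method: str = "mle",
) -> PSEEstimate:
    """Within-subject bootstrap of the side-averaged PSE.

    Each resample draws, per side, N trials with replacement (N = that
    side's original trial count), refits both Weibulls and averages the PSE
    pair; the CI is the 2.5/97.5 percentile band of the resampled means.
    Resamples with a failed fit on either side are dropped and counted;
    more than 20% failures marks the CI unreliable.
    """
    if rng is None:
        rng = np.random.default_rng()
    point = side_averaged_pse(left_trials, right_trials, lapse, method)
    sides = [_side_arrays(left_trials), _side_arrays(right_trials)]
    means = np.empty(n_resamples)
    n_ok = 0
    n_failed = 0
    for _ in range(n_resamples):
        pair = []
        for levels, level_idx, resp in sides:
            nt = len(level_idx)
            idx = rng.integers(0, nt, nt)
            cnt = np.bincount(level_idx[idx], minlength=len(levels))
            hits = np.bincount(
                level_idx[idx], weights=resp[idx], minlength=len(levels)
            )
            keep = cnt > 0
            fit = _fit_counts(levels[keep], cnt[keep], hits[keep], lapse, method)
            try:
                pair.append(pse_from_fit(fit))
            except ValueError:
                break
        if len(pair) == 2:
            means[n_ok] = 0.5 * (pair[0] + pair[1])
            n_ok += 1
        else:
            n_failed += 1
    if n_ok == 0:
        raise ValueError("every bootstrap resample failed to fit")
    lo, hi = np.percentile(means[:n_ok], [2.5, 97.5])
    return PSEEstimate(
        pse_left=point.pse_left,
        pse_right=point.pse_right,
        pse_mean=point.pse_mean,
        ci95=(float(lo), float(hi)),
        n_bootstrap=n_resamples,
        n_failed_resamples=n_failed,
        partial=point.partial,
        ci_unreliable=n_failed > 0.2 * n_resamples,
    )


def adaptation_effect(
    estimate: PSEEstimate, reference: float, units: str
) -> AdaptationEffect:
    """Express a PSE estimate as a shift from veridical equality.

    Positive shifts mean stronger adaptation on the compound side (more
    intensity was needed there to match the reference).  For contrast
    (plaid) data the decibel form is attached.
    """
    shift = estimate.pse_mean - reference
    db = to_db(estimate.pse_mean, reference) if units == "contrast" else None
    return AdaptationEffect(
        shift=shift, units=units, C=reference, C_adapt=estimate.pse_mean, db=db
    )


def angle_to_curvature(angle_deg: float) -> float:
    """Map a contour probe angle to the positive curvature coordinate
    (degrees of deviation from a straight, 180-deg contour)."""
    return 180.0 - angle_deg


def curvature_to_angle(curvature_deg: float) -> float:
    """Inverse of :func:`angle_to_curvature`."""
    return 180.0 - curvature_deg


def analyze_trials(
    trials: pd.DataFrame,
    reference: float,
    units: str,
    n_resamples: int = 5000,
    rng: np.random.Generator | None = None,
    lapse: float = DEFAULT_LAPSE,
    method: str = "mle",
) -> dict:
    """Full per-condition analysis of one trial table; returns a flat row.

    The table must carry both compound sides.  The returned mapping holds
    the per-side PSEs, the side-averaged shift (with CI in shift units),
    the dB value for contrast data, and bookkeeping counts.
    """
    left = trials[trials["compound_side"] == "left"]
    right = trials[trials["compound_side"] == "right"]
    est = bootstrap_ci(left, right, n_resamples, rng, lapse, method)
    eff = adaptation_effect(est, reference, units)
    lo, hi = est.ci95
    return {
        "pse_left": est.pse_left,
        "pse_right": est.pse_right,
        "pse_mean": est.pse_mean,
        "shift": eff.shift,
        "db": eff.db,
        "ci_lo": lo - reference,
        "ci_hi": hi - reference,
        "n_trials": int(len(trials)),
        "n_failed_resamples": est.n_failed_resamples,
        "ci_unreliable": est.ci_unreliable,
    }
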