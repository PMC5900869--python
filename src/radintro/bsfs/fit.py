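"""Maximum-likelihood fitting, profile support intervals and model comparison.

Free parameters are optimised on a log10 scale with a bounded Nelder-Mead
simplex, restarted from seeded Latin-hypercube points.  Profile support
curves follow the standard convention: the 95% interval is the parameter
range within 1.92 log-likelihood units (chi2_1 / 2) of the profile maximum,
with endpoints interpolated linearly between grid points and flagged as
open when they run off the evaluated grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .data import BsfsData
from .engine import DEFAULT_KMAX, log_likelihood
from .params import IMParams, MODELS, MODEL_DIRECTION, model_params

#: default log10 search bounds per parameter; chosen to bracket values
#: plausible for RAD-scale blocks by well over an order of magnitude while
#: keeping the stiffest corner of the state space integrable quickly
DEFAULT_BOUNDS = {
    "theta_anc": (1e-3, 10.0),
    "nu": (0.02, 20.0),
    "T": (0.02, 20.0),
    "M": (1e-4, 10.0),
}

CI_DROP = 1.92  # chi2(1) 95% / 2

_FREE = {"div2": ("theta_anc", "nu", "T"),
         "IM_u_to_r": ("theta_anc", "nu", "T", "M"),
         "IM_r_to_u": ("theta_anc", "nu", "T", "M")}


@dataclass
class FitResult:
    model: str
    params: IMParams
    loglik: float
    kmax: tuple = DEFAULT_KMAX
    trace: list = field(default_factory=list)
    n_blocks: int = 0
    data_fingerprint: int = 0
    profiles: dict = field(default_factory=dict)

    def free_names(self):
        return _FREE[self.model]


def _data_fingerprint(data: BsfsData) -> int:
    a = np.ascontiguousarray(np.sort(data.configs, axis=0))
    return hash(a.tobytes()) & 0x7FFFFFFF


def _objective(model, data, kmax):
    names = _FREE[model]

    def negll(logx):
        vals = dict(zip(names, 10.0 ** np.asarray(logx)))
        p = model_params(model, **vals)
        return -log_likelihood(p, data, kmax)

    return names, negll


def fit_model(data: BsfsData, model: str, *, kmax=DEFAULT_KMAX,
              bounds: dict | None = None, n_restarts: int = 5,
              seed: int = 0, starts=None, maxiter: int = 400) -> FitResult:
    """Maximise the conditional block likelihood for one model."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    data = data.drop_monomorphic() if data.n_monomorphic else data
    names, negll = _objective(model, data, kmax)
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.log10([bnds[n][0] for n in names])
    hi = np.log10([bnds[n][1] for n in names])

    if starts is None:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        pts = sampler.random(max(1, n_restarts))
        starts = lo + pts * (hi - lo)
    starts = np.atleast_2d(starts)

    best = None
    trace = []
    for x0 in starts:
        res = optimize.minimize(
            negll, x0, method="Nelder-Mead",
            bounds=optimize.Bounds(lo, hi),
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-7})
        trace.append({"start": 10.0 ** x0, "fun": float(res.fun),
                      "nfev": int(res.nfev), "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all restarts failed for model {model}: {trace}")

    vals = dict(zip(names, 10.0 ** best.x))
    params = model_params(model, **vals)
    return FitResult(model=model, params=params, loglik=-float(best.fun),
                     kmax=tuple(kmax), trace=trace, n_blocks=data.n_blocks,
                     data_fingerprint=_data_fingerprint(data))


@dataclass
class ProfileCI:
    param: str
    grid: np.ndarray
    profile_loglik: np.ndarray
    mle: float
    max_loglik: float
    lower: float
    upper: float
    lower_open: bool = False
    upper_open: bool = False

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def profile_ci(data: BsfsData, fit: FitResult, param: str, *,
               grid=None, n_grid: int = 11, span: float = 4.0,
               seed: int = 0, maxiter: int = 200) -> ProfileCI:
    """Discretised marginal support curve and 95% support interval.

    ``grid`` defaults to ``n_grid`` log-spaced points spanning a factor of
    ``span`` either side of the MLE (clipped to the search bounds).  The
    other free parameters are re-maximised at every grid point, warm-started
    from the joint MLE and the previous point.
    """
    names = list(fit.free_names())
    if param not in names:
        raise ValueError(f"{param!r} is not a free parameter of {fit.model}")
    mle_val = getattr(fit.params, param)
    if grid is None:
        b = DEFAULT_BOUNDS[param]
        gmin = max(mle_val / span, b[0])
        gmax = min(mle_val * span, b[1])
        grid = np.geomspace(gmin, gmax, n_grid)
        grid = np.unique(np.append(grid, mle_val))
    grid = np.asarray(grid, dtype=float)

    others = [n for n in names if n != param]
    mle_free = np.log10([getattr(fit.params, n) for n in others])
    bnds = DEFAULT_BOUNDS
    lo = np.log10([bnds[n][0] for n in others])
    hi = np.log10([bnds[n][1] for n in others])

    def negll_at(value, logx):
        vals = dict(zip(others, 10.0 ** np.asarray(logx)))
        vals[param] = value
        p = model_params(fit.model, **vals)
        return -log_likelihood(p, data, fit.kmax)

    def prof(value, x0):
        """Profile log-likelihood at one fixed value of ``param``."""
        if not others:
            return -negll_at(value, []), x0
        res = optimize.minimize(
            lambda lx: negll_at(value, lx), x0,
            method="Nelder-Mead", bounds=optimize.Bounds(lo, hi),
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-7})
        return -res.fun, res.x

    curve = np.empty(len(grid))
    warm_x = {}
    # sweep outward from the MLE so warm starts stay close
    order = np.argsort(np.abs(np.log(grid / mle_val)))
    prev_x = mle_free
    for gi in order:
        curve[gi], prev_x = prof(grid[gi], prev_x)
        warm_x[gi] = prev_x

    ref = max(curve.max(), fit.loglik)
    thr = ref - CI_DROP
    above = curve >= thr

    def _cross(i_out, i_in):
        """Bisect for the value where the profile crosses the threshold
        (linear interpolation on a coarse log grid is badly biased toward
        the MLE, so the crossing is located with the real objective)."""
        x_out, x_in = np.log(grid[i_out]), np.log(grid[i_in])
        y_out, y_in = curve[i_out], curve[i_in]
        x0 = warm_x[i_in]
        for _ in range(30):
            if abs(x_out - x_in) < 0.01:
                break
            x_mid = 0.5 * (x_out + x_in)
            y_mid, x0 = prof(float(np.exp(x_mid)), x0)
            if y_mid >= thr:
                x_in, y_in = x_mid, y_mid
            else:
                x_out, y_out = x_mid, y_mid
        # final linear interpolation inside the narrowed bracket
        if y_in == y_out:
            return float(np.exp(x_in))
        frac = (thr - y_out) / (y_in - y_out)
        return float(np.exp(x_out + frac * (x_in - x_out)))

    idx = np.flatnonzero(above)
    if len(idx) == 0:  # grid missed the peak region entirely
        lower, upper = mle_val, mle_val
        lo_open = up_open = True
    else:
        if idx[0] == 0:
            lower, lo_open = float(grid[0]), True
        else:
            lower, lo_open = _cross(idx[0] - 1, idx[0]), False
        if idx[-1] == len(grid) - 1:
            upper, up_open = float(grid[-1]), True
        else:
            upper, up_open = _cross(idx[-1] + 1, idx[-1]), False

    ci = ProfileCI(param=param, grid=grid, profile_loglik=curve,
                   mle=mle_val, max_loglik=ref, lower=lower, upper=upper,
                   lower_open=lo_open, upper_open=up_open)
    fit.profiles[param] = ci
    return ci


def compare_models(fits) -> list[dict]:
    """Delta log-likelihood table; models with delta < -2 fit significantly
    worse than the best model."""
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    fps = {f.data_fingerprint for f in fits}
    if len(fps) != 1:
        raise ValueError("fits were computed on different data sets")
    best = max(f.loglik for f in fits)
    return [{"model": f.model, "loglik": f.loglik,
             "delta_lnL": f.loglik - best,
             "significantly_worse": (f.loglik - best) < -2.0}
            for f in fits]
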