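"""Hill-curve fitting of fluorescence dose-response data.

Estimates promoter cooperativity and induction parameters from
(concentration, response) observations by nonlinear least squares of

    F(s) = F0 + Fmax * s^n / (K^n + s^n)

with multi-start initialisation over log-spaced midpoints and a small set
of cooperativities, so the optimiser does not get trapped by a bad single
guess on sigmoidal data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import lmfit

from .errors import NoInductionError

__all__ = ["HillFitResult", "fit_hill", "hill_curve"]

#: multi-start cooperativity guesses
_N_STARTS = (0.5, 1.0, 2.0, 4.0)

#: bounds keeping fits on truncated curves from running away
N_BOUNDS = (0.2, 10.0)


def hill_curve(s, F0: float, Fmax: float, K: float, n: float):
    """Evaluate F0 + Fmax * s^n / (K^n + s^n) elementwise (s >= 0)."""
    s = np.asarray(s, float)
    out = np.full(s.shape, float(F0))
    pos = s > 0
    sn = (s[pos] / K) ** n
    out[pos] = F0 + Fmax * sn / (1.0 + sn)
    return out


@dataclass(frozen=True)
class HillFitResult:
    """Converged Hill fit with per-parameter standard errors."""

    F0: float
    Fmax: float
    K: float
    n: float
    rss: float
    stderr: dict
    converged: bool
    n_obs: int

    def predict(self, s):
        return hill_curve(s, self.F0, self.Fmax, self.K, self.n)


def _residual(params, s, y, w):
    model = hill_curve(s, params["F0"].value, params["Fmax"].value,
                       params["K"].value, params["n"].value)
    r = model - y
    return r * w if w is not None else r


def fit_hill(concentrations, responses, weights=None) -> HillFitResult:
    """Least-squares Hill fit of response vs concentration.

    Requires at least 5 distinct positive concentrations; zero-concentration
    points are used (they constrain the baseline F0), not dropped.  Raises
    :class:`NoInductionError` when the response span is indistinguishable
    from replicate noise (span below 3x the pooled standard deviation at
    repeated concentrations, or no span at all).
    """
    s = np.asarray(list(concentrations), float)
    y = np.asarray(list(responses), float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("concentrations and responses must be 1-D and aligned")
    if np.any(s < 0) or np.any(y < 0):
        raise ValueError("concentrations and responses must be nonnegative")
    pos = np.unique(s[s > 0])
    if len(pos) < 5:
        raise ValueError("need at least 5 distinct positive concentrations")
    w = None
    if weights is not None:
        w = np.asarray(list(weights), float)
        if w.shape != y.shape or np.any(w < 0):
            raise ValueError("weights must be nonnegative and aligned to responses")

    span = float(y.max() - y.min())
    noise = _replicate_sd(s, y)
    if span == 0.0 or (noise > 0 and span < 3.0 * noise):
        raise NoInductionError(
            f"response span {span:.4g} is below 3x replicate noise {noise:.4g}; "
            "no induction detectable"
        )

    k_lo, k_hi = pos.min() / 10.0, pos.max() * 10.0
    k_starts = np.geomspace(pos.min(), pos.max(), 4)
    f0_guess = float(np.median(y[s == s.min()]))
    fmax_guess = max(span, 1e-12)

    best = None
    for k0 in k_starts:
        for n0 in _N_STARTS:
            p = lmfit.Parameters()
            p.add("F0", value=f0_guess, min=0.0)
            p.add("Fmax", value=fmax_guess, min=0.0)
            p.add("K", value=float(k0), min=k_lo, max=k_hi)
            p.add("n", value=float(n0), min=N_BOUNDS[0], max=N_BOUNDS[1])
            try:
                res = lmfit.minimize(_residual, p, args=(s, y, w), method="leastsq")
            except Exception:
                continue
            if not res.success:
                continue
            rss = float(np.sum(np.asarray(res.residual) ** 2))
            if best is None or rss < best[0]:
                best = (rss, res)

    if best is None:
        return HillFitResult(math.nan, math.nan, math.nan, math.nan,
                             math.nan, {}, converged=False, n_obs=len(y))
    rss, res = best
    vals = {k: float(res.params[k].value) for k in ("F0", "Fmax", "K", "n")}
    errs = {
        k: (float(res.params[k].stderr) if res.params[k].stderr is not None else math.nan)
        for k in ("F0", "Fmax", "K", "n")
    }
    return HillFitResult(vals["F0"], vals["Fmax"], vals["K"], vals["n"],
                         rss, errs, converged=True, n_obs=len(y))


def _replicate_sd(s: np.ndarray, y: np.ndarray) -> float:
    """Pooled sample standard deviation over repeated concentrations."""
    sds, dfs = [], []
    for v in np.unique(s):
        grp = y[s == v]
        if len(grp) > 1:
            sds.append(np.var(grp, ddof=1))
            dfs.append(len(grp) - 1)
    if not sds:
        return 0.0
    return float(np.sqrt(np.average(sds, weights=dfs)))
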