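"""Supporting statistics: random-intercept LMM, t-tests, beta modes, correlation.

The mixed model tests whether completion depends quadratically on the coded
luminance level (1-9): ``proportion ~ level + level^2 + (1 | subject)``.
Estimation is maximum likelihood (not REML) so that likelihood-ratio tests
between the quadratic and linear models are valid.  For a random-intercept
model the marginal covariance is block diagonal, ``V_i = sigma^2 I +
tau^2 J`` per subject, so the profile likelihood over the variance ratio
``theta = tau^2 / sigma^2`` has a closed form via the Woodbury identity and
the whole fit reduces to a one-dimensional optimization.

Also here: paired/one-sample t-tests with the d_z effect-size convention
(mean difference over SD of differences), beta-distribution MLE with a
closed-form mode for summarizing bounded proportions, and Pearson
correlation.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stimuli import CENTER_LUMINANCE_LEVELS

__all__ = [
    "LmmFit",
    "TTestResult",
    "BetaFitResult",
    "fit_quadratic_lmm",
    "lr_test",
    "quadratic_peak",
    "t_test",
    "beta_mode",
    "pearson_correlation",
]

Sidedness = Literal["two", "greater", "less"]


@dataclass(frozen=True)
class LmmFit:
    """ML fit of a random-intercept (optionally quadratic) regression."""

    beta0: float
    beta1: float
    beta2: float | None
    sigma_subject: float
    sigma_resid: float
    loglik: float
    includes_quadratic: bool
    n_obs: int
    n_subjects: int
    n_params: int
    data_fingerprint: str

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "sigma_subject": self.sigma_subject,
            "sigma_resid": self.sigma_resid,
            "loglik": self.loglik,
            "includes_quadratic": self.includes_quadratic,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
        }


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    mean_diff: float
    ci95: tuple[float, float]
    sidedness: Sidedness
    n: int

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "cohens_d": self.cohens_d,
            "mean_diff": self.mean_diff,
            "ci95": list(self.ci95),
            "sidedness": self.sidedness,
            "n": self.n,
        }


@dataclass(frozen=True)
class BetaFitResult:
    a: float
    b: float
    mode: float
    n: int

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "mode": self.mode, "n": self.n}


# ---------------------------------------------------------------------------
# random-intercept mixed model


def _fingerprint(y: np.ndarray, groups: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(y, dtype=float).tobytes())
    h.update("|".join(map(str, groups)).encode())
    return h.hexdigest()[:16]


def _profile_negloglik(theta: float, Xg: list, yg: list):
    """Negative profile log-likelihood over beta and sigma^2 at fixed theta.

    With V_i = I + theta J (J the all-ones matrix), Woodbury gives
    V_i^{-1} = I - theta / (1 + n_i theta) J and log|V_i| = log(1 + n_i theta).
    """
    p = Xg[0].shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    n_total = 0
    for X, y in zip(Xg, yg):
        ni = y.size
        c = theta / (1.0 + ni * theta)
        Xs, ys = X.sum(axis=0), y.sum()
        XtVX += X.T @ X - c * np.outer(Xs, Xs)
        XtVy += X.T @ y - c * Xs * ys
        yty += y @ y - c * ys * ys
        logdet += math.log1p(ni * theta)
        n_total += ni
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(yty - beta @ XtVy, 1e-300)  # generalized RSS; guard exact fits
    sigma2 = rss / n_total
    ll = -0.5 * (n_total * math.log(2 * math.pi * sigma2) + logdet + n_total)
    return -ll, beta, sigma2


def fit_quadratic_lmm(
    table: pd.DataFrame,
    include_quadratic: bool = True,
    subject_col: str = "subject_id",
    level_col: str = "coded_level",
    response_col: str = "proportion_completion",
) -> LmmFit:
    """ML fit of ``response ~ level (+ level^2) + (1 | subject)``.

    ``table`` holds one row per subject x level with the completion
    proportion as response.  Requires >= 2 subjects (the random intercept is
    unidentifiable from one) and >= 3 distinct levels.
    """
    df = table[[subject_col, level_col, response_col]].dropna()
    y = df[response_col].to_numpy(dtype=float)
    x = df[level_col].to_numpy(dtype=float)
    groups = df[subject_col].to_numpy()
    if np.unique(groups).size < 2:
        raise ValueError("random intercept unidentifiable with a single subject")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct levels")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    if np.ptp(y) == 0:
        warnings.warn("constant response: degenerate variance", RuntimeWarning)

    cols = [np.ones_like(x), x] + ([x**2] if include_quadratic else [])
    X = np.column_stack(cols)
    Xg, yg = [], []
    for g in pd.unique(groups):
        m = groups == g
        Xg.append(X[m])
        yg.append(y[m])

    # profile over theta = tau^2 / sigma^2 on a log grid + local refinement
    def obj(log_theta: float) -> float:
        return _profile_negloglik(math.exp(log_theta), Xg, yg)[0]

    grid = np.linspace(-12, 6, 37)
    vals = [obj(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        obj, bounds=(g0 - 1.0, g0 + 1.0), method="bounded",
        options={"xatol": 1e-8},
    )
    nll_theta, beta, sigma2 = _profile_negloglik(math.exp(res.x), Xg, yg)
    nll0, beta0_, sigma2_0 = _profile_negloglik(0.0, Xg, yg)  # boundary theta = 0
    if nll0 <= nll_theta:
        theta, nll, beta, sigma2 = 0.0, nll0, beta0_, sigma2_0
    else:
        theta, nll = math.exp(res.x), nll_theta

    n_params = X.shape[1] + 2  # fixed effects + two variance components
    return LmmFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]) if include_quadratic else None,
        sigma_subject=float(math.sqrt(theta * sigma2)),
        sigma_resid=float(math.sqrt(sigma2)),
        loglik=float(-nll),
        includes_quadratic=include_quadratic,
        n_obs=y.size,
        n_subjects=int(np.unique(groups).size),
        n_params=n_params,
        data_fingerprint=_fingerprint(y, groups),
    )


def lr_test(full: LmmFit, reduced: LmmFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits on identical data.

    Returns ``(chi2, df, p)`` with ``chi2 = max(0, 2 (ll_full - ll_reduced))``
    and df the parameter-count difference.
    """
    if not (full.includes_quadratic and not reduced.includes_quadratic):
        raise ValueError("expected a quadratic full model and a linear reduced model")
    if full.data_fingerprint != reduced.data_fingerprint:
        raise ValueError("fits were not computed on identical data")
    df = full.n_params - reduced.n_params
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, df, p


def quadratic_peak(
    fit: LmmFit,
    level_to_luminance: Sequence[float] = CENTER_LUMINANCE_LEVELS,
) -> float:
    """Peak of the fitted quadratic, mapped to cd/m^2.

    The vertex of the coded-level parabola, ``x* = -beta1 / (2 beta2)``, is
    converted to luminance by linear interpolation of log10 luminance
    between adjacent coded levels (the level list is approximately
    log-spaced); values outside the level range clamp to the end levels.
    Requires a concave fit (beta2 < 0).
    """
    if fit.beta2 is None:
        raise ValueError("fit has no quadratic term")
    if fit.beta2 >= 0:
        raise ValueError(f"beta2 = {fit.beta2} >= 0: no interior peak")
    x_star = -fit.beta1 / (2.0 * fit.beta2)
    levels = np.arange(1, len(level_to_luminance) + 1, dtype=float)
    logl = np.log10(np.asarray(level_to_luminance, dtype=float))
    return float(10.0 ** np.interp(x_star, levels, logl))


# ---------------------------------------------------------------------------
# t-tests


def t_test(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    sidedness: Sidedness = "two",
    mu0: float = 0.0,
) -> TTestResult:
    """One-sample (or paired, when ``y`` is given) t-test.

    Paired data are reduced to differences ``x - y``; the test is then the
    one-sample test of the differences against ``mu0``.  Cohen's d uses the
    d_z convention, ``(mean - mu0) / sd``.  The 95% CI of the mean
    (difference) is always two-sided, regardless of the test's sidedness.
    """
    if sidedness not in ("two", "greater", "less"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    d = np.asarray(x, dtype=float)
    if y is not None:
        ya = np.asarray(y, dtype=float)
        if ya.shape != d.shape:
            raise ValueError("paired samples must have equal length")
        d = d - ya
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == mu0:
            t = 0.0
        else:
            warnings.warn("zero variance with nonzero mean: t is infinite",
                          RuntimeWarning)
            t = math.copysign(math.inf, mean - mu0)
        se = 0.0
    else:
        se = sd / math.sqrt(n)
        t = (mean - mu0) / se

    if sidedness == "two":
        p = 2.0 * float(stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    elif sidedness == "greater":
        p = float(stats.t.sf(t, df)) if math.isfinite(t) else (0.0 if t > 0 else 1.0)
    else:
        p = float(stats.t.cdf(t, df)) if math.isfinite(t) else (0.0 if t < 0 else 1.0)
    if t == 0.0 and sd == 0.0:
        p = 1.0

    half = float(stats.t.ppf(0.975, df)) * se
    cohens_d = (mean - mu0) / sd if sd > 0 else (0.0 if mean == mu0 else math.inf)
    return TTestResult(
        t=float(t), df=df, p=min(p, 1.0), cohens_d=float(cohens_d),
        mean_diff=mean, ci95=(mean - half, mean + half),
        sidedness=sidedness, n=n,
    )


# ---------------------------------------------------------------------------
# beta-distribution mode


def beta_mode(proportions: Sequence[float]) -> BetaFitResult:
    """Beta MLE of a sample of proportions, summarized by the density mode.

    Exact 0/1 observations are first pulled inside the open interval with the
    standard shrink transform ``p' = (p (n - 1) + 0.5) / n``, which keeps the
    beta likelihood finite.  Shapes are fit by ML; the mode is
    ``(a - 1) / (a + b - 2)`` for a, b > 1 and otherwise the boundary where
    the density diverges.
    """
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or p.size < 3:
        raise ValueError("need a 1-D sample of at least 3 proportions")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("proportions must lie in [0, 1]")
    n = p.size
    p = (p * (n - 1) + 0.5) / n
    if np.ptp(p) == 0:
        raise ValueError("degenerate sample: all values identical")
    a, b, _, _ = stats.beta.fit(p, floc=0.0, fscale=1.0)
    if a > 1 and b > 1:
        mode = (a - 1.0) / (a + b - 2.0)
    elif a <= 1 and b > 1:
        mode = 0.0
    elif b <= 1 and a > 1:
        mode = 1.0
    else:  # both <= 1: density diverges at both ends; report the heavier one
        mode = 0.0 if a <= b else 1.0
    return BetaFitResult(a=float(a), b=float(b), mode=float(mode), n=n)


# ---------------------------------------------------------------------------
# correlation


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-distributed p (n-2 df)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 3:
        raise ValueError("need equal-length 1-D samples with n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)
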