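"""Piecewise-linear completion models and BIC-based model comparison.

Two competing accounts of how afterimage completion depends on the center
patch's log-luminance L:

* transparency model — completion is maximal (a plateau at M) over the
  interval [B1, B2] consistent with a layered interpretation, and falls off
  linearly on either side with slopes s1 (left) and s2 (right)::

      C(L) = M - s1 * (B1 - L)   for L < B1
      C(L) = M                   for B1 <= L <= B2
      C(L) = M - s2 * (L - B2)   for L > B2

* equiluminance model — the same shape with a degenerate plateau, peaking at
  the single point E where center and points are equiluminant (B1 = B2 = E).

The breakpoints are fixed physical constants (transparency bounds in
log10 cd/m^2), so both models are linear in the free parameters (M, s1, s2)
and the constrained least-squares problem is convex: bounded linear least
squares finds the global optimum deterministically, with no need for
multi-start heuristics.  Fits are scored by a Gaussian BIC and compared via
Schwarz weights (normalized exp(-BIC/2), interpretable as posterior model
probabilities under equal priors).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import lsq_linear

__all__ = [
    "TRANSPARENCY_LOWER_CDM2",
    "TRANSPARENCY_UPPER_CDM2",
    "PiecewiseModelSpec",
    "PiecewiseParams",
    "PiecewiseModelFit",
    "ModelComparison",
    "UnderdeterminedError",
    "IncomparableFitsError",
    "eval_completion_model",
    "fit_completion_model",
    "gaussian_bic",
    "schwarz_weights",
    "compare_models",
    "kass_raftery_label",
]

#: Default breakpoints on the luminance scale (cd/m^2): the transparency
#: bounds of the standard stimulus (84 cd/m^2 points on 169 cd/m^2 ground).
TRANSPARENCY_LOWER_CDM2 = 41.7
TRANSPARENCY_UPPER_CDM2 = 84.0

ModelKind = Literal["transparency", "equiluminance"]


class UnderdeterminedError(ValueError):
    """Fewer data points than free parameters."""


class IncomparableFitsError(ValueError):
    """Fits being compared were not computed on identical data."""


@dataclass(frozen=True)
class PiecewiseModelSpec:
    """Model kind plus fixed breakpoints in log10 cd/m^2."""

    kind: ModelKind
    b1: float
    b2: float

    def __post_init__(self) -> None:
        if self.kind not in ("transparency", "equiluminance"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.b1 > self.b2:
            raise ValueError("b1 must not exceed b2")
        if self.kind == "equiluminance" and self.b1 != self.b2:
            raise ValueError("equiluminance model requires b1 == b2")

    @classmethod
    def transparency(
        cls,
        b1_cdm2: float = TRANSPARENCY_LOWER_CDM2,
        b2_cdm2: float = TRANSPARENCY_UPPER_CDM2,
    ) -> "PiecewiseModelSpec":
        return cls("transparency", math.log10(b1_cdm2), math.log10(b2_cdm2))

    @classmethod
    def equiluminance(cls, e_cdm2: float = TRANSPARENCY_UPPER_CDM2) -> "PiecewiseModelSpec":
        e = math.log10(e_cdm2)
        return cls("equiluminance", e, e)


@dataclass(frozen=True)
class PiecewiseParams:
    """Free parameters: plateau height M and the two descending slopes."""

    m: float
    s1: float
    s2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"m={self.m} outside [0, 1]")
        if self.s1 < 0 or self.s2 < 0:
            raise ValueError("slopes must be non-negative")


@dataclass(frozen=True)
class PiecewiseModelFit:
    spec: PiecewiseModelSpec
    params: PiecewiseParams
    sse: float
    n: int
    k: int
    loglik: float
    bic: float

    def predict(self, l: np.ndarray | float) -> np.ndarray | float:
        return eval_completion_model(self.spec, self.params, l)

    def to_dict(self) -> dict:
        return {
            "kind": self.spec.kind,
            "b1_log10": self.spec.b1,
            "b2_log10": self.spec.b2,
            "m": self.params.m,
            "s1": self.params.s1,
            "s2": self.params.s2,
            "sse": self.sse,
            "n": self.n,
            "k": self.k,
            "loglik": self.loglik,
            "bic": self.bic,
        }


@dataclass(frozen=True)
class ModelComparison:
    """BIC comparison of competing fits, ordered as supplied."""

    kinds: tuple[str, ...]
    bics: tuple[float, ...]
    delta_bic: float
    weights: tuple[float, ...]
    best_index: int
    evidence_ratio: float
    evidence_label: str

    @property
    def best_kind(self) -> str:
        return self.kinds[self.best_index]

    def to_dict(self) -> dict:
        return {
            "kinds": list(self.kinds),
            "bics": list(self.bics),
            "delta_bic": self.delta_bic,
            "weights": list(self.weights),
            "best": self.best_kind,
            "evidence_ratio": self.evidence_ratio,
            "evidence_label": self.evidence_label,
        }


def _design_matrix(l: np.ndarray, spec: PiecewiseModelSpec) -> np.ndarray:
    # C = M - s1*relu(B1 - L) - s2*relu(L - B2): linear in (M, s1, s2)
    return np.column_stack(
        [
            np.ones_like(l),
            -np.clip(spec.b1 - l, 0.0, None),
            -np.clip(l - spec.b2, 0.0, None),
        ]
    )


def eval_completion_model(
    spec: PiecewiseModelSpec, params: PiecewiseParams, l: np.ndarray | float
) -> np.ndarray | float:
    """Predicted completion proportion at log10-luminance ``l``.

    The output is not clipped to [0, 1]; extreme luminances may yield
    negative predictions, which is a concern for data generation, not for
    the model itself.
    """
    arr = np.asarray(l, dtype=float)
    out = _design_matrix(np.atleast_1d(arr), spec) @ np.array(
        [params.m, params.s1, params.s2]
    )
    return float(out[0]) if arr.ndim == 0 else out


def fit_completion_model(
    xs: Sequence[float], ys: Sequence[float], spec: PiecewiseModelSpec
) -> PiecewiseModelFit:
    """Least-squares fit of a piecewise completion model.

    ``xs`` are log10 luminances, ``ys`` proportions.  The SSE is minimized
    over the box 0 <= M <= 1, s1 >= 0, s2 >= 0 by bounded linear least
    squares (the objective is convex given fixed breakpoints, so this is the
    global optimum).  The Gaussian log-likelihood uses the MLE variance
    sigma^2 = SSE / n; k = 3 free parameters are charged to BIC.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be 1-D sequences of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    k = 3
    n = x.size
    if n <= k:
        raise UnderdeterminedError(f"need more than {k} points, got {n}")

    A = _design_matrix(x, spec)
    res = lsq_linear(A, y, bounds=([0.0, 0.0, 0.0], [1.0, np.inf, np.inf]))
    params = PiecewiseParams(m=float(np.clip(res.x[0], 0, 1)),
                             s1=float(max(res.x[1], 0.0)),
                             s2=float(max(res.x[2], 0.0)))
    resid = y - A @ res.x
    sse = float(resid @ resid)
    if sse > 0:
        sigma2 = sse / n
        loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    else:
        loglik = math.inf
    bic = gaussian_bic(sse, n, k)
    return PiecewiseModelFit(spec=spec, params=params, sse=sse, n=n, k=k,
                             loglik=loglik, bic=bic)


def gaussian_bic(sse: float, n: int, k: int) -> float:
    """Full-form Gaussian BIC: ``n ln(sse/n) + n (ln 2pi + 1) + k ln n``.

    This is ``-2 loglik + k ln n`` at the MLE variance.  For two models with
    equal k and n the difference reduces to ``n ln(sse_A / sse_B)``, so the
    constant terms never affect a comparison.  The residual variance is not
    charged as a parameter; since k is identical across the models compared
    here, that choice cannot change any BIC difference or weight.
    """
    if n <= 0 or k < 1:
        raise ValueError("need n > 0 and k >= 1")
    if sse < 0:
        raise ValueError("sse must be non-negative")
    if sse == 0:
        warnings.warn("zero residual: degenerate fit, BIC -> -inf", RuntimeWarning)
        return -math.inf
    return n * math.log(sse / n) + n * (math.log(2 * math.pi) + 1.0) + k * math.log(n)


def schwarz_weights(bics: Sequence[float]) -> np.ndarray:
    """Schwarz weights: ``exp(-dBIC_i/2)`` normalized to sum 1.

    Under equal model priors these approximate posterior model probabilities.
    Invariant to adding a constant to every BIC.
    """
    b = np.asarray(bics, dtype=float)
    if b.size < 2:
        raise ValueError("need at least two BIC values")
    if not np.isfinite(b).all():
        raise ValueError("all BIC values must be finite")
    rel = np.exp(-0.5 * (b - b.min()))
    return rel / rel.sum()


def kass_raftery_label(delta_bic: float) -> str:
    """Conventional evidence category for a BIC difference."""
    if delta_bic < 0:
        raise ValueError("delta_bic must be non-negative")
    if delta_bic < 2:
        return "barely worth mentioning"
    if delta_bic < 6:
        return "positive"
    if delta_bic < 10:
        return "strong"
    return "very strong"


def compare_models(fits: Sequence[PiecewiseModelFit]) -> ModelComparison:
    """Compare >= 2 fits of the same data by BIC and Schwarz weights.

    ``delta_bic`` is best-vs-runner-up; the evidence ratio is the weight
    ratio of the same pair.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise IncomparableFitsError(f"fits cover different data sizes: {sorted(ns)}")
    bics = np.array([f.bic for f in fits])
    w = schwarz_weights(bics)
    order = np.argsort(bics, kind="stable")
    best, second = int(order[0]), int(order[1])
    delta = float(bics[second] - bics[best])
    ratio = float(w[best] / w[second]) if w[second] > 0 else math.inf
    return ModelComparison(
        kinds=tuple(f.spec.kind for f in fits),
        bics=tuple(float(b) for b in bics),
        delta_bic=delta,
        weights=tuple(float(x) for x in w),
        best_index=best,
        evidence_ratio=ratio,
        evidence_label=kass_raftery_label(delta),
    )
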