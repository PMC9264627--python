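"""Concordance-vs-SNP-count saturation curves and their model fits.

The amount of phylogenetic signal in an alignment scales with its number of
segregating sites.  To characterise that relationship, SNP columns are drawn
in a single seeded random permutation whose prefixes define *nested* subsets
of increasing size; a tree is estimated from each subset and its concordance
with a reference phylogeny recorded.  The resulting curve is summarised by a
saturating model fitted by least squares — either

* logarithmic:  y = a + b * ln(x), or
* logistic:     y = 1 / (1 + exp(-(a + b * x))),

with the family chosen by k-fold cross-validation on summed squared held-out
error.  The logistic family is ordinary logistic regression — a linear
predictor in the raw SNP count.  A saturation curve that keeps rising on the
log scale is concave in x, which a raw-x sigmoid fits poorly; the CV contest
between the two families is therefore a real test of curve shape rather than
a comparison of two reparameterizations of the same covariate.  The fitted model can then be inverted for the SNP count at a target
concordance (e.g. 80%) or evaluated at a given SNP count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit, logit

from .alignment import Alignment
from .estimate import Estimator
from .trees import concordance

logger = logging.getLogger(__name__)

__all__ = [
    "CurvePoint",
    "ConcordanceCurve",
    "ModelFit",
    "subsample_curve",
    "fit_model",
    "cross_validate_select",
    "invert_for_target",
    "predict_at",
]

FAMILIES = ("logarithmic", "logistic")


@dataclass(frozen=True)
class CurvePoint:
    size: int
    concordance: float | None  # None: tree estimation failed at this size


@dataclass
class ConcordanceCurve:
    """(snp_count, concordance) points from nested seeded subsampling."""

    points: list[CurvePoint]
    category: str = ""
    seed: int = 0
    nested: bool = True

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Valid points only (failed estimations dropped)."""
        ok = [(p.size, p.concordance) for p in self.points
              if p.concordance is not None]
        if not ok:
            return np.array([]), np.array([])
        x, y = zip(*ok)
        return np.asarray(x, dtype=float), np.asarray(y, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "size": [p.size for p in self.points],
            "concordance": [p.concordance for p in self.points],
            "seed": self.seed,
            "category": self.category,
        })


@dataclass
class ModelFit:
    """A fitted saturation model.

    ``coefficients`` is (a, b) with the meaning fixed by ``family``:
    logarithmic y = a + b ln x; logistic y = expit(a + b x).
    """

    family: str
    coefficients: tuple[float, float]
    sse: float
    cv_error: float | None = None

    @property
    def a(self) -> float:
        return self.coefficients[0]

    @property
    def b(self) -> float:
        return self.coefficients[1]

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "a": self.a,
            "b": self.b,
            "sse": self.sse,
            "cv_error": self.cv_error,
        }


def subsample_curve(
    snps: Alignment,
    sizes: Sequence[int],
    seed: int,
    estimator: Estimator,
    reference,
    category: str = "",
    nested: bool = True,
) -> ConcordanceCurve:
    """Estimate concordance at increasing SNP-subset sizes.

    A single seeded permutation of the SNP columns defines nested subsets
    (the size-s subset is the first s columns of the permutation), so larger
    subsets always contain smaller ones and the curve endpoint at the full
    column count reproduces the full-matrix concordance.  With
    ``nested=False`` each size is an independent seeded draw instead.
    Sizes at which tree estimation fails (e.g. a pair of taxa with no shared
    called column at 1 SNP) are recorded as missing points.
    """
    sizes = [int(s) for s in sizes]
    if any(s <= 0 for s in sizes):
        raise ValueError("sizes must be positive")
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly increasing")
    if sizes[-1] > snps.length:
        raise ValueError(
            f"largest size {sizes[-1]} exceeds available SNP columns "
            f"({snps.length})"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(snps.length)
    points: list[CurvePoint] = []
    for s in sizes:
        if nested:
            cols = np.sort(perm[:s])
        else:
            cols = np.sort(rng.permutation(snps.length)[:s])
        sub = snps.take_columns(cols)
        try:
            tree = estimator(sub)
            value = concordance(reference, tree).concordance
        except ValueError as exc:
            logger.info("size %d: estimation failed (%s)", s, exc)
            value = None
        points.append(CurvePoint(size=s, concordance=value))
    return ConcordanceCurve(points=points, category=category, seed=seed,
                            nested=nested)


def _as_xy(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, ConcordanceCurve):
        return curve.xy()
    x, y = curve
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def _fit_logarithmic(lx: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    design = np.column_stack([np.ones_like(lx), lx])
    (a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(a), float(b)


def _fit_logistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # start from the linear fit on the logit scale (y clipped off {0,1})
    yc = np.clip(y, 1e-3, 1 - 1e-3)
    a0, b0 = _fit_logarithmic(x, logit(yc))

    def f(x_, a, b):
        return expit(a + b * x_)

    try:
        (a, b), _ = curve_fit(f, x, y, p0=(a0, b0), maxfev=10000)
    except RuntimeError:
        a, b = a0, b0
    return float(a), float(b)


def _predict(family: str, a: float, b: float, x: np.ndarray) -> np.ndarray:
    if family == "logarithmic":
        return a + b * np.log(x)
    return expit(a + b * x)


def fit_model(curve, family: str) -> ModelFit:
    """Least-squares fit of one model family to a concordance curve."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    x, y = _as_xy(curve)
    if len(x) < 3:
        raise ValueError("need >= 3 valid points to fit")
    if np.any(x < 1):
        raise ValueError("snp counts must be >= 1")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate curve: all sizes equal")
    if family == "logarithmic":
        a, b = _fit_logarithmic(np.log(x), y)
    else:
        a, b = _fit_logistic(x, y)
    resid = y - _predict(family, a, b, x)
    return ModelFit(family=family, coefficients=(a, b),
                    sse=float(np.sum(resid ** 2)))


def cross_validate_select(
    curve,
    families: Sequence[str] = FAMILIES,
    k: int = 5,
    seed: int = 0,
) -> ModelFit:
    """k-fold cross-validated family selection, refit on all data.

    The points are split into k near-equal folds by a seeded permutation;
    each family is fitted on the complement of every fold and scored by the
    summed squared error of its held-out predictions.  The family with the
    smallest total error wins (ties resolve in the order given, so
    logarithmic wins an exact tie under the default ordering) and is refitted
    on the complete curve; the winning total is stored as ``cv_error``.
    """
    x, y = _as_xy(curve)
    n = len(x)
    if k > n:
        raise ValueError(f"k={k} exceeds number of points ({n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    totals: dict[str, float] = {}
    for family in families:
        total = 0.0
        for fold in folds:
            train = np.setdiff1d(perm, fold)
            try:
                fit = fit_model((x[train], y[train]), family)
            except ValueError:
                total = np.inf
                break
            pred = _predict(family, fit.a, fit.b, x[fold])
            total += float(np.sum((y[fold] - pred) ** 2))
        totals[family] = total
    best = min(families, key=lambda f: totals[f])
    result = fit_model((x, y), best)
    result.cv_error = totals[best]
    return result


def invert_for_target(fit: ModelFit, target: float) -> float:
    """SNP count at which the fitted model reaches a target concordance."""
    if not 0.0 < target < 1.0:
        raise ValueError("target must be in (0, 1)")
    if fit.b <= 0:
        raise ValueError(
            "model is not increasing in SNP count (b <= 0); "
            "cannot invert toward higher concordance"
        )
    if fit.family == "logarithmic":
        return float(np.exp((target - fit.a) / fit.b))
    return float((logit(target) - fit.a) / fit.b)


def predict_at(fit: ModelFit, snp_count: float) -> float:
    """Model-predicted concordance at a given SNP count.

    The logistic model is bounded in (0, 1) by construction; a logarithmic
    prediction outside [0, 1] is reported as-is with a warning.
    """
    if snp_count < 1:
        raise ValueError("snp_count must be >= 1")
    value = float(_predict(fit.family, fit.a, fit.b,
                           np.asarray([snp_count], dtype=float))[0])
    if fit.family == "logarithmic" and not 0.0 <= value <= 1.0:
        warnings.warn(
            f"logarithmic prediction {value:.3f} outside [0, 1] "
            f"at x={snp_count}", stacklevel=2,
        )
    return value
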