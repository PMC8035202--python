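"""Interpretation of an identified feature: the channel-space axis that
explains view-dependent response changes, and weighted-average images of the
captured stimulus sub-regions.

With a single response variable as the second view, canonical correlation
degenerates to a regression direction; the axis is therefore computed as the
ridge-regularized regression direction between the flattened sub-region
vectors and the responses (regularization strength chosen by efficient
leave-one-out cross-validation), unit-normalized and sign-fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize
from sklearn.linear_model import RidgeCV

from .selection import pearson_r_p
from .types import ChannelStack, MatchResult

__all__ = [
    "CcaAxis",
    "capture_subregion",
    "extract_axis",
    "weighted_average_subregions",
]


def capture_subregion(
    stimulus: ChannelStack, match: MatchResult, target_shape: tuple[int, int]
) -> np.ndarray:
    """Cut the matched sub-region out of a stimulus stack and resample it
    (bilinear, per channel) to the candidate grid ``target_shape``."""
    th, tw = target_shape
    h = max(1, round(th * match.best_scale))
    w = max(1, round(tw * match.best_scale))
    r0, c0 = match.best_offset
    sub = stimulus.data[:, r0 : r0 + h, c0 : c0 + w]
    if sub.shape[1:] != (h, w):
        raise ValueError("match window outside the stimulus")
    if (h, w) == (th, tw):
        return sub.copy()
    moved = np.moveaxis(sub, 0, -1)
    out = resize(moved, (th, tw), order=1, preserve_range=True, anti_aliasing=False)
    return np.maximum(np.moveaxis(out, -1, 0), 0.0)


@dataclass
class CcaAxis:
    """Unit-norm axis in the candidate's (7, h, w) channel space."""

    a_V: np.ndarray  # shape (7, h, w), unit Frobenius norm
    projection_curve: np.ndarray  # inner products, one per stimulus
    curve_correlation: float
    curve_p: float
    ridge_lambda: float

    @property
    def flat(self) -> np.ndarray:
        return self.a_V.ravel()


def extract_axis(
    subregions: Sequence[np.ndarray],
    responses: Sequence[float],
    lambdas: Optional[Sequence[float]] = None,
) -> CcaAxis:
    """Extract the single channel-space axis explaining response changes.

    ``subregions`` are (7, h, w) arrays on a common grid (see
    :func:`capture_subregion`); ``responses`` the per-stimulus responses.
    The axis is the ridge regression direction of responses on flattened
    sub-regions, unit-normalized, with the sign fixed so the loading of
    largest magnitude is positive. The projection curve holds the raw inner
    products between each sub-region and the axis.
    """
    subregions = list(subregions)
    if len(subregions) < 2:
        raise ValueError("need at least 2 stimuli")
    shape = subregions[0].shape
    if any(s.shape != shape for s in subregions):
        raise ValueError("sub-regions must share one shape")
    y = np.asarray(responses, dtype=float)
    if y.size != len(subregions):
        raise ValueError("one response per sub-region required")
    if np.std(y) == 0:
        raise ValueError("zero-variance responses")
    X = np.stack([s.ravel() for s in subregions])
    if lambdas is None:
        lambdas = np.logspace(-6, 3, 19)
    ridge = RidgeCV(alphas=np.asarray(lambdas), fit_intercept=True)
    ridge.fit(X, y)
    coef = np.asarray(ridge.coef_, dtype=float)
    norm = np.linalg.norm(coef)
    if norm == 0:
        raise ValueError("degenerate axis: zero regression direction")
    a = coef / norm
    if a[np.argmax(np.abs(a))] < 0:
        a = -a
    proj = X @ a
    r, p = pearson_r_p(proj, y)
    return CcaAxis(
        a_V=a.reshape(shape),
        projection_curve=proj,
        curve_correlation=r,
        curve_p=p,
        ridge_lambda=float(ridge.alpha_),
    )


def weighted_average_subregions(
    subregions: Sequence[np.ndarray], weights: Sequence[float]
) -> ChannelStack:
    """Weighted average of captured sub-regions on the common grid,
    ``sum_i w_i sub_i / sum_i w_i``. Weights must be non-negative with at
    least one positive entry; they conventionally default to the predicted
    responses."""
    subregions = list(subregions)
    w = np.asarray(weights, dtype=float)
    if w.size != len(subregions):
        raise ValueError("one weight per sub-region required")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero weights")
    acc = np.zeros_like(subregions[0], dtype=float)
    for wi, sub in zip(w, subregions):
        acc += wi * sub
    return ChannelStack(acc / total)
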