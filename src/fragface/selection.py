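"""Feature identification by dual (global/local) correlation screening.

Every candidate in the fragment bank is turned into a predicted-response
vector over the identification stimuli (view-uncontrolled faces plus
non-face objects; the view-controlled faces are deliberately withheld).
A candidate survives the screen if both its global correlation (all
stimuli) and its local correlation (faces only) with the neural responses
are significant at alpha = 0.05; among the survivors the candidate with the
highest global correlation becomes the site's identified visual feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .model import (
    ModelConfig,
    bank_min_distances,
    calibrate_sigma2,
    min_over_positions_scales,
    responses01_from_distances,
)
from .types import ChannelStack, FeatureCandidate, MatchResult, ResponseTable

__all__ = [
    "SelectionResult",
    "dual_correlation",
    "select_feature",
    "select_from_distances",
    "deduplicate_features",
    "FeatureSelector",
    "pearson_r_p",
    "pearson_rows_r_p",
]


def pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided t-approximation on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, _p_from_r(r, x.size)


def _p_from_r(r, n: int):
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df)


def pearson_rows_r_p(R: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r and p between each row of ``R`` and ``y``.

    Rows with zero variance get r = nan, p = 1.
    """
    R = np.asarray(R, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    Rc = R - R.mean(axis=1, keepdims=True)
    rnorm = np.linalg.norm(Rc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Rc @ yc) / (rnorm * ynorm)
    bad = (rnorm == 0) | (ynorm == 0)
    r = np.where(bad, np.nan, r)
    p = np.where(bad, 1.0, _p_from_r(np.nan_to_num(r), n))
    return r, p


def _permutation_p(x: np.ndarray, y: np.ndarray, n_perm: int, rng) -> float:
    """Two-sided permutation p-value for Pearson r (verification mode)."""
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    count = 0
    for _ in range(n_perm):
        r = abs(np.corrcoef(x, rng.permutation(y))[0, 1])
        if r >= r_obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def dual_correlation(
    predicted,
    neural,
    face_ids: Sequence[str],
    all_ids: Sequence[str],
    method: str = "t",
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float, float, float]:
    """(r_global, p_global, r_local, p_local).

    ``predicted`` and ``neural`` are indexable by stimulus id (pandas
    Series). The global correlation is over ``all_ids`` (faces plus
    non-face objects), the local one over ``face_ids`` only.
    ``method='permutation'`` replaces the parametric p with a shuffle test.
    """
    face_ids, all_ids = list(face_ids), list(all_ids)
    if not set(face_ids) <= set(all_ids):
        raise ValueError("face_ids must be a subset of all_ids")
    if len(face_ids) < 3:
        raise ValueError("need at least 3 face stimuli")
    pg = np.asarray([predicted[s] for s in all_ids], dtype=float)
    ng = np.asarray([neural[s] for s in all_ids], dtype=float)
    pl = np.asarray([predicted[s] for s in face_ids], dtype=float)
    nl = np.asarray([neural[s] for s in face_ids], dtype=float)
    r_g, p_g = pearson_r_p(pg, ng)
    r_l, p_l = pearson_r_p(pl, nl)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        p_g = _permutation_p(pg, ng, n_perm, rng)
        p_l = _permutation_p(pl, nl, n_perm, rng)
    elif method != "t":
        raise ValueError("method must be 't' or 'permutation'")
    return r_g, p_g, r_l, p_l


@dataclass
class SelectionResult:
    """A site's identified visual feature and its screening statistics."""

    site_id: str
    candidate_id: str
    candidate: FeatureCandidate
    rbf_sigma2: float
    r_global: float
    p_global: float
    r_local: float
    p_local: float
    runner_up_ids: list[str]
    per_stimulus_matches: Optional[dict[str, MatchResult]] = None


def select_from_distances(
    bank: Sequence[FeatureCandidate],
    D2: np.ndarray,
    stim_ids: Sequence[str],
    neural_means,
    face_ids: Sequence[str],
    config: ModelConfig,
    alpha_sig: float = 0.05,
    site_id: str = "site",
) -> Optional[SelectionResult]:
    """Core selection given a precomputed (candidates x stimuli) distance
    matrix whose columns are ordered as ``stim_ids``.

    Returns None ("no feature") when no candidate passes the joint screen.
    """
    stim_ids = list(stim_ids)
    face_set = set(face_ids)
    face_mask = np.array([s in face_set for s in stim_ids])
    if face_mask.sum() < 3 or (~face_mask).sum() < 1:
        raise ValueError("need >= 3 faces and >= 1 non-face among stimuli")
    y = np.asarray([neural_means[s] for s in stim_ids], dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant neural vector")

    if config.rbf_sigma2 is not None:
        sigma2 = np.full(len(bank), float(config.rbf_sigma2))
    else:
        sigma2 = calibrate_sigma2(D2)
    R = responses01_from_distances(D2, sigma2)
    r_g, p_g = pearson_rows_r_p(R, y)
    if np.std(y[face_mask]) == 0:
        raise ValueError("constant neural vector on faces")
    r_l, p_l = pearson_rows_r_p(R[:, face_mask], y[face_mask])

    # a feature must *positively* explain the responses on both subsets:
    # an anti-matching template is not a candidate feature
    significant = (p_g < alpha_sig) & (p_l < alpha_sig)
    significant &= np.isfinite(r_g) & np.isfinite(r_l)
    significant &= (r_g > 0) & (r_l > 0)
    if not significant.any():
        return None

    # highest r_global; ties by higher r_local, then lexically lower id
    idx = [int(i) for i in np.flatnonzero(significant)]
    idx.sort(key=lambda i: (-r_g[i], -r_l[i], bank[i].candidate_id))
    best = idx[0]
    runner_ups = [bank[i].candidate_id for i in idx[1:6]]
    return SelectionResult(
        site_id=site_id,
        candidate_id=bank[best].candidate_id,
        candidate=bank[best],
        rbf_sigma2=float(sigma2[best]),
        r_global=float(r_g[best]),
        p_global=float(p_g[best]),
        r_local=float(r_l[best]),
        p_local=float(p_l[best]),
        runner_up_ids=runner_ups,
    )


def select_feature(
    bank: Sequence[FeatureCandidate],
    neural: ResponseTable,
    stacks: dict[str, ChannelStack],
    config: ModelConfig = ModelConfig(),
    alpha_sig: float = 0.05,
    with_matches: bool = True,
) -> Optional[SelectionResult]:
    """Identify the visual feature of one site.

    Screens every candidate by its dual correlation with the trial-averaged
    neural responses over the identification stimuli (view-uncontrolled
    faces + non-face objects) and selects the jointly significant candidate
    with the highest global correlation. Returns None when no candidate
    passes (an explicit "no feature" outcome).
    """
    if len(bank) == 0:
        raise ValueError("empty candidate bank")
    stim_ids = neural.screening_ids()
    D2 = bank_min_distances(bank, [stacks[s] for s in stim_ids], config)
    result = select_from_distances(
        bank,
        D2,
        stim_ids,
        neural.trial_means(),
        neural.uncontrolled_face_ids(),
        config,
        alpha_sig,
        site_id=neural.site_id,
    )
    if result is not None and with_matches:
        cfg = ModelConfig(
            alpha=config.alpha,
            rbf_sigma2=result.rbf_sigma2,
            scale_range_b=config.scale_range_b,
            normalize=config.normalize,
        )
        result.per_stimulus_matches = {
            s: min_over_positions_scales(result.candidate, stacks[s], cfg)
            for s in stim_ids
        }
    return result


def deduplicate_features(
    selections: Sequence[SelectionResult],
) -> tuple[list[SelectionResult], dict[str, int]]:
    """Collapse selections sharing one candidate into unique feature axes.

    Returns the list of unique axes (first selection per candidate id, in
    first-appearance order) and a site -> axis-index map.
    """
    axes: list[SelectionResult] = []
    index_of: dict[str, int] = {}
    site_map: dict[str, int] = {}
    for sel in selections:
        if sel.candidate_id not in index_of:
            index_of[sel.candidate_id] = len(axes)
            axes.append(sel)
        site_map[sel.site_id] = index_of[sel.candidate_id]
    return axes, site_map


class FeatureSelector(BaseEstimator):
    """Sklearn-style wrapper around :func:`select_feature`.

    ``fit(stacks_by_id, neural_table)`` stores ``selection_`` (or None);
    ``predict(stacks)`` returns the selected feature's RBF responses.
    """

    def __init__(
        self,
        bank: Sequence[FeatureCandidate],
        config: ModelConfig | None = None,
        alpha_sig: float = 0.05,
    ):
        self.bank = bank
        self.config = config
        self.alpha_sig = alpha_sig

    def fit(self, X: dict[str, ChannelStack], y: ResponseTable):
        cfg = self.config if self.config is not None else ModelConfig()
        self.selection_ = select_feature(
            self.bank, y, X, cfg, self.alpha_sig, with_matches=False
        )
        return self

    def predict(self, X: Sequence[ChannelStack]) -> np.ndarray:
        if not hasattr(self, "selection_"):
            raise RuntimeError("call fit before predict")
        if self.selection_ is None:
            raise RuntimeError("no feature was identified for this site")
        cfg = self.config if self.config is not None else ModelConfig()
        D2 = bank_min_distances([self.selection_.candidate], list(X), cfg)
        return responses01_from_distances(D2, np.array([self.selection_.rbf_sigma2]))[0]
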