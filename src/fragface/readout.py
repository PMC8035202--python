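"""Population-level identity readout in the feature space.

Each de-duplicated identified feature defines one axis of a feature space;
every view-controlled face is a point whose coordinates are the features'
predicted responses. For each target identity a projection vector w is fit
by ordinary least squares on a +-1 target indicator (features standardized
first), separability is scored by ROC AUC in its Mann-Whitney pair-counting
form, generalization by a leave-one-view-out identification test, and
sparseness by incremental-AUC and view-specificity curves over the top-|w|
features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .model import ModelConfig, bank_min_distances, responses01_from_distances
from .selection import SelectionResult
from .types import ChannelStack

__all__ = [
    "build_feature_space",
    "fit_projection",
    "auc_separability",
    "leave_one_view_out",
    "leave_one_view_out_rate",
    "incremental_auc",
    "view_specificity",
    "IdentityReadout",
    "ReadoutResult",
]


def build_feature_space(
    axes: Sequence[SelectionResult],
    view_stacks: dict[str, ChannelStack],
    stimulus_ids: Sequence[str],
    config: ModelConfig = ModelConfig(),
) -> pd.DataFrame:
    """Predicted-response matrix (stimuli x axes).

    Entry (s, f) is axis f's RBF response to stimulus s; columns are ordered
    by axis candidate id order as given.
    """
    if len(axes) == 0:
        raise ValueError("need at least one axis")
    stimulus_ids = list(stimulus_ids)
    stacks = [view_stacks[s] for s in stimulus_ids]
    cols = {}
    for sel in axes:
        D2 = bank_min_distances([sel.candidate], stacks, config)
        cols[sel.candidate_id] = responses01_from_distances(
            D2, np.array([sel.rbf_sigma2])
        )[0]
    return pd.DataFrame(cols, index=pd.Index(stimulus_ids, name="stimulus_id"))


def _standardize(F: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = F.mean(axis=0)
    sd = F.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (F - mu) / sd_safe, mu, sd_safe


def fit_projection(features: np.ndarray, target_mask: np.ndarray) -> np.ndarray:
    """OLS projection vector separating target from non-target faces.

    Regresses a +-1 target indicator on the intercept-augmented,
    standardized feature matrix; the minimum-norm solution is used when the
    design is rank deficient. Returns w (no intercept) in original column
    order; w applies to standardized features.
    """
    F = np.asarray(features, dtype=float)
    t = np.asarray(target_mask, dtype=bool)
    if F.ndim != 2 or t.size != F.shape[0]:
        raise ValueError("features must be (n, p) with one target flag per row")
    if t.sum() < 1 or (~t).sum() < 1:
        raise ValueError("need both target and non-target rows")
    Fs, _, _ = _standardize(F)
    y = np.where(t, 1.0, -1.0)
    X = np.column_stack([np.ones(F.shape[0]), Fs])
    sol, *_ = np.linalg.lstsq(X, y, rcond=None)
    return sol[1:]


def auc_separability(target_scores, nontarget_scores) -> float:
    """AUC as the fraction of correctly ordered (target, non-target) pairs,
    ties counted 0.5 (the Mann-Whitney formulation)."""
    t = np.asarray(target_scores, dtype=float)
    n = np.asarray(nontarget_scores, dtype=float)
    if t.size == 0 or n.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([t, n]))
    u = ranks[: t.size].sum() - t.size * (t.size + 1) / 2.0
    return float(u / (t.size * n.size))


def _order_by_weight(w: np.ndarray) -> np.ndarray:
    """Axis indices by descending |w|, ties broken by lower axis index."""
    return np.lexsort((np.arange(w.size), -np.abs(w)))


def incremental_auc(
    features_std: np.ndarray, target_mask: np.ndarray, w: np.ndarray
) -> list[float]:
    """AUC of the restricted combination over the top-k |w| axes, k=1..p.

    The last entry (k = p) equals the full-space AUC by construction.
    """
    order = _order_by_weight(np.asarray(w, dtype=float))
    t = np.asarray(target_mask, dtype=bool)
    out = []
    for k in range(1, order.size + 1):
        top = order[:k]
        scores = features_std[:, top] @ w[top]
        out.append(auc_separability(scores[t], scores[~t]))
    return out


def view_specificity(
    features_std: np.ndarray, target_mask: np.ndarray, w: np.ndarray, k: int
) -> float:
    """Unnormalized view specificity at k: the ratio of the variance of the
    target faces' top-k projections to the variance over all faces. Low
    values mean the target's projections barely move across views."""
    order = _order_by_weight(np.asarray(w, dtype=float))
    if not 1 <= k <= order.size:
        raise ValueError("k out of range")
    top = order[:k]
    scores = features_std[:, top] @ w[top]
    t = np.asarray(target_mask, dtype=bool)
    var_all = float(np.var(scores))
    if var_all == 0:
        raise ValueError("zero all-face variance")
    return float(np.var(scores[t])) / var_all


def view_specificity_curve(
    features_std: np.ndarray, target_mask: np.ndarray, w: np.ndarray
) -> list[float]:
    """View-specificity over k, normalized so the value at k = p is 1.0.

    When the target's full-space projections have zero variance (perfect
    view invariance) the normalization is undefined and the unnormalized
    all-zero curve is returned instead.
    """
    p = np.asarray(w).size
    raw = [view_specificity(features_std, target_mask, w, k) for k in range(1, p + 1)]
    last = raw[-1]
    if last == 0:
        return raw
    return [v / last for v in raw]


def leave_one_view_out(
    F: pd.DataFrame,
    identities: pd.Series,
    views: pd.Series,
    target_identity: str,
    view_held_out: int,
) -> bool:
    """One leave-one-view-out identification trial.

    w is fit on all identities' remaining six views (standardization
    computed on the training rows); the trial is a hit iff the target's
    held-out face attains the strict maximum projection among all
    identities' held-out faces (ties count as misses).
    """
    test_mask = (views == view_held_out).to_numpy()
    if not test_mask.any():
        raise ValueError(f"view {view_held_out} missing")
    train_mask = ~test_mask
    Ftr = F.to_numpy(dtype=float)[train_mask]
    Fte = F.to_numpy(dtype=float)[test_mask]
    ids_tr = identities.to_numpy()[train_mask]
    ids_te = identities.to_numpy()[test_mask]
    if target_identity not in ids_te:
        raise ValueError("target has no held-out face")
    _, mu, sd = _standardize(Ftr)
    w = fit_projection(Ftr, ids_tr == target_identity)
    proj = ((Fte - mu) / sd) @ w
    target_proj = proj[ids_te == target_identity]
    other_proj = proj[ids_te != target_identity]
    return bool(np.all(target_proj > other_proj.max()))


def leave_one_view_out_rate(
    F: pd.DataFrame, identities: pd.Series, views: pd.Series
) -> tuple[float, pd.DataFrame]:
    """Identification rate over every (identity, view) pair, with the
    per-pair hit table. Chance level is 1/n_identities."""
    hits = []
    for ident in pd.unique(identities):
        for view in sorted(pd.unique(views)):
            hit = leave_one_view_out(F, identities, views, ident, int(view))
            hits.append({"identity_id": ident, "view_deg": int(view), "hit": hit})
    table = pd.DataFrame(hits)
    return float(table["hit"].mean()), table


@dataclass
class ReadoutResult:
    identity_id: str
    w: np.ndarray
    auc: float
    incremental_auc: list[float]
    view_specificity: list[float]
    per_view_hits: dict[int, bool]


class IdentityReadout(BaseEstimator):
    """Per-identity linear readout over the feature space.

    ``fit(F, identities, views=...)`` fits one projection vector per
    identity on the full space and computes AUC, incremental-AUC and
    view-specificity curves; ``results_`` holds one :class:`ReadoutResult`
    per identity, ``mean_auc_`` the average separability, and
    ``k_at_mean_auc(level)`` the smallest number of features whose mean
    incremental AUC reaches the level.
    """

    def __init__(self, run_leave_one_view_out: bool = True):
        self.run_leave_one_view_out = run_leave_one_view_out

    def fit(self, F: pd.DataFrame, identities: pd.Series, views: Optional[pd.Series] = None):
        Fmat = F.to_numpy(dtype=float)
        Fs, _, _ = _standardize(Fmat)
        idents = pd.Series(identities).reset_index(drop=True)
        self.axis_ids_ = list(F.columns)
        self.results_ = []
        for ident in pd.unique(idents):
            mask = (idents == ident).to_numpy()
            w = fit_projection(Fmat, mask)
            scores = Fs @ w
            auc = auc_separability(scores[mask], scores[~mask])
            inc = incremental_auc(Fs, mask, w)
            spec = view_specificity_curve(Fs, mask, w)
            self.results_.append(
                ReadoutResult(
                    identity_id=str(ident),
                    w=w,
                    auc=auc,
                    incremental_auc=inc,
                    view_specificity=spec,
                    per_view_hits={},
                )
            )
        self.auc_ = np.array([r.auc for r in self.results_])
        self.mean_auc_ = float(self.auc_.mean())
        if self.run_leave_one_view_out:
            if views is None:
                raise ValueError("views required for the leave-one-view-out test")
            vser = pd.Series(views).reset_index(drop=True)
            rate, table = leave_one_view_out_rate(F, idents, vser)
            self.loo_rate_ = rate
            self.loo_table_ = table
            for r in self.results_:
                sub = table[table["identity_id"] == r.identity_id]
                r.per_view_hits = dict(zip(sub["view_deg"], sub["hit"]))
        return self

    def k_at_mean_auc(self, level: float = 0.9) -> Optional[int]:
        """Smallest k with mean-over-identities incremental AUC >= level."""
        curves = np.array([r.incremental_auc for r in self.results_])
        mean_curve = curves.mean(axis=0)
        hit = np.flatnonzero(mean_curve >= level)
        return int(hit[0]) + 1 if hit.size else None
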