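"""Validation of identified features: cross-validation and tuning prediction.

Two checks mirror how the encoding model is validated. First, a two-fold
cross-validation on the identification stimuli (view-uncontrolled faces and
non-face objects): features are selected on one half and their correlation
with neural responses is evaluated on the held-out half. Second — the
generalization test — a feature identified *without* any view-controlled
stimulus is used to predict the neural responses across the 7 x n_identities
view-controlled faces, giving a view-tuning predictability r (Pearson, on
within-identity z-scored values, one pair per identity x view) and an
identity-tuning Spearman rho on view-averaged responses.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelConfig, bank_min_distances, responses01_from_distances
from .selection import (
    SelectionResult,
    dual_correlation,
    select_from_distances,
)
from .types import ChannelStack, FeatureCandidate, ResponseTable

__all__ = [
    "CrossValReport",
    "ViewTuningReport",
    "IdentityTuningReport",
    "crossval_two_fold",
    "predict_view_tuning",
    "predict_identity_tuning",
    "spearman_rho_p",
]


@dataclass
class CrossValReport:
    site_id: str
    fold_cc_global: list[Optional[float]]
    fold_cc_local: list[Optional[float]]
    cc_global_test: Optional[float]
    cc_local_test: Optional[float]
    n_per_fold: int


def _stratified_halves(
    face_ids: list[str], nonface_ids: list[str], rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Random equal split, stratified by category."""
    halves: tuple[list[str], list[str]] = ([], [])
    for ids in (face_ids, nonface_ids):
        ids = list(ids)
        perm = rng.permutation(len(ids))
        half = len(ids) // 2
        halves[0].extend(ids[i] for i in perm[:half])
        halves[1].extend(ids[i] for i in perm[half:])
    return halves


def crossval_two_fold(
    bank: Sequence[FeatureCandidate],
    neural: ResponseTable,
    stacks: dict[str, ChannelStack],
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
    alpha_sig: float = 0.05,
    D2: Optional[np.ndarray] = None,
    stim_ids: Optional[list[str]] = None,
) -> CrossValReport:
    """Two-fold cross-validation of feature identification for one site.

    The identification stimuli are split into equal halves stratified by
    category; a feature is selected on each training half (including its
    per-candidate RBF calibration) and its dual correlation is evaluated on
    the held-out half. A fold whose selection returns "no feature" is
    reported as missing, not imputed. ``D2`` / ``stim_ids`` may carry a
    precomputed bank-distance matrix to avoid recomputation.
    """
    if stim_ids is None:
        stim_ids = neural.screening_ids()
    if D2 is None:
        D2 = bank_min_distances(bank, [stacks[s] for s in stim_ids], config)
    col = {s: j for j, s in enumerate(stim_ids)}
    means = neural.trial_means()
    face_set = set(neural.uncontrolled_face_ids())
    faces = [s for s in stim_ids if s in face_set]
    nonfaces = [s for s in stim_ids if s not in face_set]
    rng = np.random.default_rng(seed)
    half_a, half_b = _stratified_halves(faces, nonfaces, rng)

    fold_g: list[Optional[float]] = []
    fold_l: list[Optional[float]] = []
    for train, test in ((half_a, half_b), (half_b, half_a)):
        sel = select_from_distances(
            bank,
            D2[:, [col[s] for s in train]],
            train,
            means,
            face_set,
            config,
            alpha_sig,
            site_id=neural.site_id,
        )
        if sel is None:
            fold_g.append(None)
            fold_l.append(None)
            continue
        ci = next(i for i, c in enumerate(bank) if c.candidate_id == sel.candidate_id)
        pred = responses01_from_distances(
            D2[ci : ci + 1, [col[s] for s in test]], np.array([sel.rbf_sigma2])
        )[0]
        pred_by_id = pd.Series(pred, index=test)
        test_faces = [s for s in test if s in face_set]
        r_g, _, r_l, _ = dual_correlation(pred_by_id, means, test_faces, test)
        fold_g.append(r_g)
        fold_l.append(r_l)

    done_g = [v for v in fold_g if v is not None]
    done_l = [v for v in fold_l if v is not None]
    return CrossValReport(
        site_id=neural.site_id,
        fold_cc_global=fold_g,
        fold_cc_local=fold_l,
        cc_global_test=float(np.mean(done_g)) if done_g else None,
        cc_local_test=float(np.mean(done_l)) if done_l else None,
        n_per_fold=len(half_a),
    )


@dataclass
class ViewTuningReport:
    r: float
    p: float
    n: int
    views: list[int]
    predicted_curve_mean: np.ndarray
    predicted_curve_sd: np.ndarray
    neural_curve_mean: np.ndarray
    neural_curve_sd: np.ndarray


def _pivot_by_identity_view(values, meta: pd.DataFrame) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "identity": meta["identity_id"],
            "view": meta["view_deg"].astype(int),
            "resp": [values[s] for s in meta.index],
        }
    )
    return frame.pivot_table(index="identity", columns="view", values="resp").sort_index(
        axis=1
    )


def _zscore_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-score (population sd); returns (z, keep mask); rows with
    zero variance are masked out."""
    sd = mat.std(axis=1)
    keep = sd > 0
    z = np.zeros_like(mat)
    z[keep] = (mat[keep] - mat[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return z, keep


def predicted_view_responses(
    selection: SelectionResult,
    view_stacks: dict[str, ChannelStack],
    meta: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
) -> pd.Series:
    """Predicted responses of a selected feature to the view-controlled
    stimuli, using the RBF width fixed during identification."""
    ids = list(meta.index)
    D2 = bank_min_distances(
        [selection.candidate], [view_stacks[s] for s in ids], config
    )
    pred = responses01_from_distances(D2, np.array([selection.rbf_sigma2]))[0]
    return pd.Series(pred, index=ids)


def predict_view_tuning(
    selection: SelectionResult,
    view_stacks: dict[str, ChannelStack],
    neural: ResponseTable,
    config: ModelConfig = ModelConfig(),
    predicted: Optional[pd.Series] = None,
) -> ViewTuningReport:
    """Correlate predicted and neural view tuning on view-controlled faces.

    Both response sets are z-scored within identity (population sd); the
    predictability r is the Pearson correlation over all (identity, view)
    pairs — n = 7 x n_identities — and per-view mean/sd curves are emitted
    for plotting. Identities with zero variance in either set are dropped.
    """
    meta = neural.meta.loc[neural.view_controlled_ids()]
    if meta.empty:
        raise ValueError("no view-controlled stimuli")
    if predicted is None:
        predicted = predicted_view_responses(selection, view_stacks, meta, config)
    if float(np.std(predicted.to_numpy())) == 0:
        raise ValueError("degenerate: constant predicted responses")
    pred_piv = _pivot_by_identity_view(predicted, meta)
    neur_piv = _pivot_by_identity_view(neural.trial_means(), meta)
    views = [int(v) for v in pred_piv.columns]

    zp, keep_p = _zscore_rows(pred_piv.to_numpy(dtype=float))
    zn, keep_n = _zscore_rows(neur_piv.to_numpy(dtype=float))
    keep = keep_p & keep_n
    if keep.sum() < 1:
        raise ValueError("no identity with variance in both curves")
    zp, zn = zp[keep], zn[keep]
    x, y = zp.ravel(), zn.ravel()
    r = float(np.corrcoef(x, y)[0, 1])
    df = x.size - 2
    t = r * math.sqrt(df / max(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(abs(t), df)
    return ViewTuningReport(
        r=r,
        p=float(p),
        n=int(x.size),
        views=views,
        predicted_curve_mean=zp.mean(axis=0),
        predicted_curve_sd=zp.std(axis=0),
        neural_curve_mean=zn.mean(axis=0),
        neural_curve_sd=zn.std(axis=0),
    )


@dataclass
class IdentityTuningReport:
    rho: float
    p: float
    n: int
    predicted_by_identity: pd.Series
    neural_by_identity: pd.Series


def spearman_rho_p(
    x: np.ndarray, y: np.ndarray, exact_below: int = 9
) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties).

    The p-value uses the t-approximation; for n below ``exact_below`` an
    exact permutation p is computed by full enumeration.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    n = x.size
    if n < exact_below:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
            if r >= obs - 1e-12:
                count += 1
            total += 1
        p = count / total
    return float(rho), float(p)


def predict_identity_tuning(
    selection: SelectionResult,
    view_stacks: dict[str, ChannelStack],
    neural: ResponseTable,
    config: ModelConfig = ModelConfig(),
    predicted: Optional[pd.Series] = None,
) -> IdentityTuningReport:
    """Spearman correlation between predicted and neural identity tuning,
    both averaged across the 7 views per identity."""
    meta = neural.meta.loc[neural.view_controlled_ids()]
    if meta.empty:
        raise ValueError("no view-controlled stimuli")
    if predicted is None:
        predicted = predicted_view_responses(selection, view_stacks, meta, config)
    pred_piv = _pivot_by_identity_view(predicted, meta)
    neur_piv = _pivot_by_identity_view(neural.trial_means(), meta)
    pred_means = pred_piv.mean(axis=1)
    neur_means = neur_piv.mean(axis=1)
    rho, p = spearman_rho_p(pred_means.to_numpy(), neur_means.to_numpy())
    return IdentityTuningReport(
        rho=rho,
        p=p,
        n=int(len(pred_means)),
        predicted_by_identity=pred_means,
        neural_by_identity=neur_means,
    )
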