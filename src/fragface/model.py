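"""Template-matching response model (layers 3-4 of the shallow network).

A candidate fragment is slid over a stimulus ChannelStack; at each offset the
alpha-weighted squared Euclidean distance between the candidate and the
stimulus sub-region is computed. The global minimum over offsets (position
invariance) and over a small set of candidate rescalings (scale invariance)
is mapped through a Gaussian radial basis function to a response in (0, 1],
and optionally rescaled to spike rates by a two-point affine map anchored at
the face and non-face means of a neural response table.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize
from sklearn.base import BaseEstimator

from .types import ChannelStack, FeatureCandidate, MatchResult, ModelConfig

__all__ = [
    "distance_map",
    "min_over_positions_scales",
    "rbf_response",
    "rescale_to_spikes",
    "calibrate_sigma2",
    "bank_min_distances",
    "responses01_from_distances",
    "FragmentResponseModel",
]


def _rescale_candidate(data: np.ndarray, b: float) -> np.ndarray:
    """Bilinearly resample a (7, h, w) candidate by factor ``b``."""
    if b == 1.0:
        return data
    h, w = data.shape[1:]
    nh, nw = max(1, round(h * b)), max(1, round(w * b))
    moved = np.moveaxis(data, 0, -1)  # (h, w, 7): channels untouched
    out = resize(
        moved, (nh, nw), order=1, preserve_range=True, anti_aliasing=False
    )
    return np.maximum(np.moveaxis(out, -1, 0), 0.0)


def _weighted_distance_map(
    cand_data: np.ndarray,
    stim_data: np.ndarray,
    weights: np.ndarray,
    normalize: bool,
) -> np.ndarray:
    ch, h, w = cand_data.shape
    H, W = stim_data.shape[1:]
    if h > H or w > W:
        raise ValueError("candidate larger than stimulus")
    windows = sliding_window_view(stim_data, (h, w), axis=(1, 2))
    diff = windows - cand_data[:, None, None, :, :]
    d2 = np.einsum("cijhw,c->ij", diff * diff, weights)
    if normalize:
        d2 = d2 / (h * w)
    return d2


def distance_map(
    candidate: FeatureCandidate,
    stimulus: ChannelStack,
    alpha: float = 0.5,
    normalize: bool = True,
) -> np.ndarray:
    """Alpha-weighted squared-distance map at scale 1.0.

    Entry (i, j) is ``alpha * sum_orient + (1 - alpha) * sum_color`` of
    squared channel differences between the candidate and the stimulus
    window at offset (i, j), divided by the number of spatial cells when
    ``normalize`` is on. Only valid offsets are scanned (no padding).
    """
    cfg = ModelConfig(alpha=alpha, normalize=normalize)
    return _weighted_distance_map(
        candidate.stack.data, stimulus.data, cfg.channel_weights, normalize
    )


def min_over_positions_scales(
    candidate: FeatureCandidate,
    stimulus: ChannelStack,
    config: ModelConfig,
) -> MatchResult:
    """Global-minimum pooling over offsets and candidate scales.

    Ties are broken deterministically: the earliest scale in
    ``config.scale_range_b`` wins, then the row-major first offset.
    """
    weights = config.channel_weights
    best: Optional[tuple[float, tuple[int, int], float, int]] = None
    for si, b in enumerate(config.scale_range_b):
        scaled = _rescale_candidate(candidate.stack.data, b)
        h, w = scaled.shape[1:]
        H, W = stimulus.shape
        if h > H or w > W:
            continue
        d2 = _weighted_distance_map(scaled, stimulus.data, weights, config.normalize)
        idx = int(np.argmin(d2))
        off = np.unravel_index(idx, d2.shape)
        val = float(d2[off])
        if best is None or val < best[0]:
            best = (val, (int(off[0]), int(off[1])), b, si)
    if best is None:
        raise ValueError("no feasible scale: candidate exceeds stimulus everywhere")
    d2_min, offset, scale, si = best
    resp = (
        rbf_response(d2_min, config.rbf_sigma2)
        if config.rbf_sigma2 is not None
        else None
    )
    return MatchResult(
        d2_min=d2_min,
        best_offset=offset,
        best_scale=scale,
        scale_index=si,
        response01=resp,
    )


def rbf_response(d2, rbf_sigma2: float):
    """Gaussian radial basis readout ``exp(-d2 / (2 sigma^2))``.

    Maps [0, inf) onto (0, 1]; equals 1 at d2 = 0 and is strictly
    decreasing. Accepts scalars or arrays.
    """
    if rbf_sigma2 is None or rbf_sigma2 <= 0:
        raise ValueError("rbf_sigma2 must be positive")
    d2 = np.asarray(d2, dtype=float)
    if np.any(d2 < 0):
        raise ValueError("squared distance must be non-negative")
    out = np.exp(-d2 / (2.0 * rbf_sigma2))
    return float(out) if out.ndim == 0 else out


def rescale_to_spikes(
    responses01: "np.ndarray | Sequence[float]",
    stimulus_ids: Sequence[str],
    face_ids: Sequence[str],
    nonface_ids: Sequence[str],
    neural_means,
) -> np.ndarray:
    """Affinely map [0, 1] responses to spike rates.

    The unique affine map sending the predicted face mean to the neural face
    mean and the predicted non-face mean to the neural non-face mean is
    applied to all stimuli. ``neural_means`` is indexable by stimulus id
    (e.g. a pandas Series of trial-averaged rates).
    """
    face_ids, nonface_ids = list(face_ids), list(nonface_ids)
    if not face_ids or not nonface_ids:
        raise ValueError("both id sets must be non-empty")
    responses01 = np.asarray(responses01, dtype=float)
    pos = {s: i for i, s in enumerate(stimulus_ids)}
    pf = float(np.mean([responses01[pos[s]] for s in face_ids]))
    pn = float(np.mean([responses01[pos[s]] for s in nonface_ids]))
    if pf == pn:
        raise ValueError("degenerate rescaling: equal predicted means")
    nf = float(np.mean([neural_means[s] for s in face_ids]))
    nn = float(np.mean([neural_means[s] for s in nonface_ids]))
    slope = (nf - nn) / (pf - pn)
    return (responses01 - pn) * slope + nn


def calibrate_sigma2(d2_min: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Per-candidate RBF width: median minimum squared distance over a
    calibration stimulus set. ``d2_min`` has shape (n_candidates, n_stimuli)
    or (n_stimuli,)."""
    d2_min = np.asarray(d2_min, dtype=float)
    med = np.median(d2_min, axis=-1)
    return np.maximum(med, floor)


def bank_min_distances(
    bank: Sequence[FeatureCandidate],
    stacks: Sequence[ChannelStack],
    config: ModelConfig,
) -> np.ndarray:
    """Minimum squared distance of every candidate to every stimulus.

    Vectorized equivalent of calling :func:`min_over_positions_scales` for
    each (candidate, stimulus) pair and keeping ``d2_min``; candidates are
    grouped by scaled shape so the offset scan becomes one matrix product
    per group. Returns an array of shape (n_candidates, n_stimuli).
    """
    if len(bank) == 0 or len(stacks) == 0:
        raise ValueError("bank and stimuli must be non-empty")
    shapes = {s.shape for s in stacks}
    if len(shapes) > 1:
        raise ValueError("all stimuli must share one pooled shape")
    weights = config.channel_weights
    sw = np.sqrt(weights)
    stim = np.stack([s.data for s in stacks])  # (n, 7, H, W)
    stim_w = stim * sw[None, :, None, None]
    n, _, H, W = stim_w.shape

    groups: dict[tuple[int, int], list[tuple[int, np.ndarray]]] = {}
    for ci, cand in enumerate(bank):
        for b in config.scale_range_b:
            scaled = _rescale_candidate(cand.stack.data, b)
            h, w = scaled.shape[1:]
            if h > H or w > W:
                continue
            groups.setdefault((h, w), []).append(
                (ci, (scaled * sw[:, None, None]).ravel())
            )
    if not groups:
        raise ValueError("no feasible scale for any candidate")

    D2 = np.full((len(bank), n), np.inf)
    for (h, w), entries in groups.items():
        win = sliding_window_view(stim_w, (h, w), axis=(2, 3))  # (n,7,nh,nw,h,w)
        win = np.moveaxis(win, 1, 3)  # (n, nh, nw, 7, h, w)
        noff = win.shape[1] * win.shape[2]
        X = win.reshape(n * noff, -1)
        X2 = np.einsum("ij,ij->i", X, X)
        C = np.stack([v for _, v in entries])
        C2 = np.einsum("ij,ij->i", C, C)
        d2 = X2[:, None] + C2[None, :] - 2.0 * (X @ C.T)
        np.maximum(d2, 0.0, out=d2)
        if config.normalize:
            d2 /= h * w
        d2 = d2.reshape(n, noff, len(entries)).min(axis=1)  # (n, k)
        for k, (ci, _) in enumerate(entries):
            np.minimum(D2[ci], d2[:, k], out=D2[ci])
    if not np.all(np.isfinite(D2)):
        raise ValueError("some candidate exceeds the stimuli at every scale")
    return D2


def responses01_from_distances(d2_min: np.ndarray, sigma2) -> np.ndarray:
    """RBF responses for a (n_candidates, n_stimuli) distance matrix with a
    per-candidate (or scalar) sigma^2."""
    d2_min = np.asarray(d2_min, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if sigma2.ndim == 1:
        sigma2 = sigma2[:, None]
    return np.exp(-d2_min / (2.0 * sigma2))


class FragmentResponseModel(BaseEstimator):
    """Sklearn-style predictor for one candidate fragment.

    ``fit`` calibrates the RBF width on a calibration stimulus set (median
    minimum squared distance) unless the config pins it; ``predict`` returns
    responses in (0, 1].
    """

    def __init__(self, candidate: FeatureCandidate, config: ModelConfig | None = None):
        self.candidate = candidate
        self.config = config

    def _config(self) -> ModelConfig:
        return self.config if self.config is not None else ModelConfig()

    def fit(self, X: Sequence[ChannelStack], y=None):
        cfg = self._config()
        if cfg.rbf_sigma2 is not None:
            self.sigma2_ = float(cfg.rbf_sigma2)
        else:
            d2 = bank_min_distances([self.candidate], X, cfg)[0]
            self.sigma2_ = float(calibrate_sigma2(d2))
        return self

    def match(self, stimulus: ChannelStack) -> MatchResult:
        cfg = self._config()
        cfg = ModelConfig(
            alpha=cfg.alpha,
            rbf_sigma2=getattr(self, "sigma2_", cfg.rbf_sigma2),
            scale_range_b=cfg.scale_range_b,
            normalize=cfg.normalize,
        )
        return min_over_positions_scales(self.candidate, stimulus, cfg)

    def predict(self, X: Sequence[ChannelStack]) -> np.ndarray:
        if not hasattr(self, "sigma2_"):
            raise RuntimeError("call fit before predict")
        cfg = self._config()
        d2 = bank_min_distances([self.candidate], X, cfg)[0]
        return rbf_response(d2, self.sigma2_)
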