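"""Shared domain containers for the fragment-based face-column analysis.

The analysis represents every image (stimulus or fragment) in a common
"V1/V2-level" space: a 7-channel map holding local orientation energy at
0/45/90/135 degrees followed by max-pooled red, green and blue intensity.
Channel order is fixed and is part of the on-disk format.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

#: Fixed channel order of every ChannelStack.
CHANNEL_NAMES = ("ori0", "ori45", "ori90", "ori135", "red", "green", "blue")

#: Edge orientations (degrees from horizontal) of the four orientation channels.
ORIENTATIONS_DEG = (0, 45, 90, 135)

#: The seven controlled facial views, left profile to right profile.
VIEWS_DEG = (-90, -60, -30, 0, 30, 60, 90)

#: Allowed fragment side lengths, in pooled cells.
FRAGMENT_SIZE_MIN = 8
FRAGMENT_SIZE_MAX = 20

FACE_CATEGORIES = ("monkey_face", "human_face")
CATEGORIES = FACE_CATEGORIES + ("nonface",)


@dataclass(frozen=True)
class ChannelStack:
    """A 7-channel local-orientation + color map of an image or fragment.

    Parameters
    ----------
    data
        Array of shape ``(7, H, W)``; orientation channels first
        (0, 45, 90, 135 degrees), then red, green, blue. All values are
        non-negative.
    grid_stride_px
        Size of one pooled cell in source-image pixels.
    """

    data: np.ndarray
    grid_stride_px: int = 10

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or data.shape[0] != len(CHANNEL_NAMES):
            raise ValueError(f"expected (7, H, W) data, got shape {data.shape}")
        if data.shape[1] < 1 or data.shape[2] < 1:
            raise ValueError("spatial size must be at least 1x1")
        if np.min(data) < -1e-9:
            raise ValueError("channel values must be non-negative")
        if self.grid_stride_px < 1:
            raise ValueError("grid_stride_px must be positive")
        object.__setattr__(self, "data", np.maximum(data, 0.0))

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (H, W) of the pooled grid."""
        return self.data.shape[1], self.data.shape[2]

    def window(self, row0: int, col0: int, height: int, width: int) -> "ChannelStack":
        """Cut a half-open sub-window ``[row0:row0+height, col0:col0+width]``."""
        h, w = self.shape
        if row0 < 0 or col0 < 0 or row0 + height > h or col0 + width > w:
            raise ValueError("window outside the stack")
        return ChannelStack(
            self.data[:, row0 : row0 + height, col0 : col0 + width].copy(),
            self.grid_stride_px,
        )


@dataclass(frozen=True)
class FeatureCandidate:
    """A fragment's ChannelStack plus provenance.

    ``source_window`` is ``(row0, col0, height, width)`` in pooled coordinates
    of the source image's stack, 0-based and half-open.
    """

    candidate_id: str
    stack: ChannelStack
    source_image_id: str
    source_window: tuple[int, int, int, int]
    scale_range_b: tuple[float, ...] = (0.8, 1.0, 1.25)

    def __post_init__(self) -> None:
        h, w = self.stack.shape
        if not (FRAGMENT_SIZE_MIN <= h <= FRAGMENT_SIZE_MAX) or not (
            FRAGMENT_SIZE_MIN <= w <= FRAGMENT_SIZE_MAX
        ):
            raise ValueError(
                f"fragment size {h}x{w} outside "
                f"[{FRAGMENT_SIZE_MIN}, {FRAGMENT_SIZE_MAX}]"
            )
        if 1.0 not in self.scale_range_b:
            raise ValueError("scale_range_b must contain 1.0")
        if any(b <= 0 for b in self.scale_range_b):
            raise ValueError("scales must be positive")
        object.__setattr__(self, "scale_range_b", tuple(self.scale_range_b))


@dataclass
class ModelConfig:
    """Configuration of the template-matching response model (layers 3-4).

    alpha
        Orientation-versus-color weight in the squared distance,
        ``alpha * sum_orient + (1 - alpha) * sum_color``. ``alpha=1.0``
        ignores the color channels entirely.
    rbf_sigma2
        Width of the radial basis function. ``None`` means "calibrate per
        candidate as the median of its minimum squared distances over a
        calibration stimulus set".
    scale_range_b
        Candidate rescaling factors searched for scale invariance; must
        contain 1.0.
    normalize
        If True (default) squared distances are divided by the number of
        spatial cells compared, making candidates of different sizes
        comparable.
    """

    alpha: float = 0.5
    rbf_sigma2: Optional[float] = None
    scale_range_b: tuple[float, ...] = (0.8, 1.0, 1.25)
    normalize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.rbf_sigma2 is not None and self.rbf_sigma2 <= 0:
            raise ValueError("rbf_sigma2 must be positive")
        if len(self.scale_range_b) == 0 or 1.0 not in self.scale_range_b:
            raise ValueError("scale_range_b must be non-empty and contain 1.0")
        self.scale_range_b = tuple(self.scale_range_b)

    @property
    def channel_weights(self) -> np.ndarray:
        """Per-channel weights: alpha on the 4 orientations, 1-alpha on RGB."""
        return np.array([self.alpha] * 4 + [1.0 - self.alpha] * 3, dtype=float)


@dataclass(frozen=True)
class MatchResult:
    """Best template match of one candidate against one stimulus."""

    d2_min: float
    best_offset: tuple[int, int]
    best_scale: float
    scale_index: int
    response01: Optional[float] = None


@dataclass(frozen=True)
class StimulusSpec:
    """Metadata of one stimulus image."""

    stimulus_id: str
    category: str
    identity_id: Optional[str] = None
    view_deg: Optional[int] = None
    image_size_px: int = 200

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.view_deg is not None and self.view_deg not in VIEWS_DEG:
            raise ValueError(f"view_deg must be one of {VIEWS_DEG}")
        if self.image_size_px <= 0:
            raise ValueError("image_size_px must be positive")

    @property
    def is_face(self) -> bool:
        return self.category in FACE_CATEGORIES

    @property
    def is_view_controlled(self) -> bool:
        return self.view_deg is not None


@dataclass
class ResponseTable:
    """Trial-resolved columnar responses of one recording site.

    trials
        Long-format frame with columns ``stimulus_id``, ``trial`` (1-based),
        ``response`` (spikes/s).
    meta
        Frame indexed by ``stimulus_id`` with columns ``category``,
        ``identity_id``, ``view_deg``.
    """

    site_id: str
    trials: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"stimulus_id", "trial", "response"}
        if not required.issubset(self.trials.columns):
            raise ValueError(f"trials must have columns {sorted(required)}")
        missing = set(self.trials["stimulus_id"]) - set(self.meta.index)
        if missing:
            raise ValueError(f"stimuli missing from meta: {sorted(missing)[:5]}")

    def trial_means(self) -> pd.Series:
        """Trial-averaged response per stimulus, ordered as ``meta``."""
        means = self.trials.groupby("stimulus_id")["response"].mean()
        return means.reindex(self.meta.index)

    def n_trials(self) -> int:
        return int(self.trials.groupby("stimulus_id")["trial"].count().min())

    # -- stimulus subsets ---------------------------------------------------
    def face_ids(self) -> list[str]:
        """All face stimuli (view-controlled and uncontrolled)."""
        m = self.meta
        return list(m.index[m["category"].isin(FACE_CATEGORIES)])

    def nonface_ids(self) -> list[str]:
        return list(self.meta.index[self.meta["category"] == "nonface"])

    def view_controlled_ids(self) -> list[str]:
        return list(self.meta.index[self.meta["view_deg"].notna()])

    def uncontrolled_face_ids(self) -> list[str]:
        m = self.meta
        mask = m["category"].isin(FACE_CATEGORIES) & m["view_deg"].isna()
        return list(m.index[mask])

    def screening_ids(self) -> list[str]:
        """Stimuli used for feature identification: view-uncontrolled faces
        plus non-face objects (view-controlled faces are held out)."""
        return self.uncontrolled_face_ids() + self.nonface_ids()


@dataclass
class GroundTruthColumn:
    """Synthetic stand-in for a recorded face column.

    The column's noiseless rate is the affine map of the planted candidate's
    RBF response: ``nonface_gain`` is the extrapolated baseline at response
    0 and ``face_gain`` the rate at a perfect match (response 1); i.i.d.
    Gaussian trial noise is added and negative trial rates are clipped at
    zero. A strongly negative baseline yields thresholded rates — near-zero
    responses to non-preferred objects — as observed in face columns.
    """

    site_id: str
    planted_candidate: FeatureCandidate
    noise_sd: float = 3.0
    n_trials: int = 10
    face_gain: float = 20.0
    nonface_gain: float = -18.0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2 for an even/odd split")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
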