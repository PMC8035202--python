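"""Synthetic stimuli and ground-truth columnar responses.

The renderer is parametric-geometric (filled ellipses and polygons), not a
morphable 3-D model: views are emulated by horizontal displacement of the
facial features (an odd, smooth function of view angle) plus self-occlusion
of the far-side eye beyond +-60 degrees, so that a fragment cut from one
view genuinely matches that view best. Identity is carried by geometry
(face aspect, eye separation, hairline, mouth) and by view-invariant skin,
hair and mouth colors.

Columnar responses are generated by the package's own forward model from a
planted candidate fragment: the RBF response in (0, 1] is mapped affinely to
spike rates (non-face gain at 0, face gain at 1) and i.i.d. Gaussian trial
noise is added, with negative rates clipped at zero.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .model import bank_min_distances, calibrate_sigma2, responses01_from_distances
from .types import (
    ChannelStack,
    FeatureCandidate,
    GroundTruthColumn,
    ModelConfig,
    ResponseTable,
    StimulusSpec,
    VIEWS_DEG,
)

__all__ = [
    "FaceParams",
    "ObjectParams",
    "StimulusSetConfig",
    "substream",
    "sample_identity_params",
    "sample_object_params",
    "render_face",
    "render_nonface",
    "build_stimulus_set",
    "simulate_responses",
]


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG substream derived from one master seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# parameter records


@dataclass(frozen=True)
class FaceParams:
    """Identity-defining face geometry (fractions of image size) and colors."""

    skin_rgb: tuple[float, float, float] = (0.82, 0.62, 0.48)
    hair_rgb: tuple[float, float, float] = (0.15, 0.10, 0.06)
    mouth_rgb: tuple[float, float, float] = (0.55, 0.22, 0.20)
    face_halfwidth: float = 0.30
    face_halfheight: float = 0.40
    hairline_frac: float = 0.30  # fraction of face height occupied by hair
    eye_sep: float = 0.115  # half-distance between eye centers
    eye_radius: float = 0.028
    eye_y: float = -0.08  # vertical offset of eyes from center
    mouth_width: float = 0.12
    mouth_height: float = 0.022
    mouth_y: float = 0.21
    nose_len: float = 0.05
    nose_width: float = 0.022
    feature_shift: float = 0.16  # horizontal feature excursion at +-90 deg
    shading: float = 0.8  # lateral self-shadow strength at the profiles


@dataclass(frozen=True)
class ObjectParams:
    """Non-face object description: textured blob, grating, or silhouette."""

    kind: str = "blob"  # one of {blob, grating, silhouette}
    color_rgb: tuple[float, float, float] = (0.3, 0.5, 0.7)
    orientation_deg: float = 0.0  # gratings: stripe (edge) orientation
    frequency: float = 0.05  # gratings: cycles per pixel
    radius: float = 0.28  # blobs: mean radius fraction
    wobble: float = 0.18  # blobs: radial modulation amplitude
    lobes: int = 5  # blobs: number of radial lobes
    phase: float = 0.0
    aspect: float = 0.6  # silhouettes: width/height of the body


def sample_identity_params(rng: np.random.Generator) -> FaceParams:
    """Draw one identity. Colors and geometry vary enough that identities
    are visually distinct but remain plausible faces."""
    skin_base = rng.uniform(0.55, 0.9)
    skin = (
        skin_base,
        skin_base * rng.uniform(0.68, 0.85),
        skin_base * rng.uniform(0.5, 0.7),
    )
    hair_base = rng.uniform(0.05, 0.75)
    hair = (
        hair_base,
        hair_base * rng.uniform(0.55, 1.0),
        hair_base * rng.uniform(0.3, 0.9),
    )
    return FaceParams(
        skin_rgb=tuple(round(v, 4) for v in skin),
        hair_rgb=tuple(round(v, 4) for v in hair),
        mouth_rgb=(rng.uniform(0.45, 0.65), rng.uniform(0.15, 0.3), rng.uniform(0.15, 0.3)),
        face_halfwidth=rng.uniform(0.26, 0.34),
        face_halfheight=rng.uniform(0.36, 0.44),
        hairline_frac=rng.uniform(0.2, 0.38),
        eye_sep=rng.uniform(0.095, 0.14),
        eye_radius=rng.uniform(0.022, 0.034),
        eye_y=rng.uniform(-0.11, -0.05),
        mouth_width=rng.uniform(0.09, 0.16),
        mouth_height=rng.uniform(0.016, 0.03),
        mouth_y=rng.uniform(0.17, 0.24),
        nose_len=rng.uniform(0.04, 0.06),
        nose_width=rng.uniform(0.016, 0.028),
        feature_shift=rng.uniform(0.13, 0.19),
    )


def sample_object_params(rng: np.random.Generator) -> ObjectParams:
    kind = rng.choice(["blob", "grating", "silhouette"])
    color = tuple(np.round(rng.uniform(0.1, 0.9, size=3), 4))
    return ObjectParams(
        kind=str(kind),
        color_rgb=color,
        orientation_deg=float(rng.choice([0, 45, 90, 135])),
        frequency=float(rng.uniform(0.02, 0.08)),
        radius=float(rng.uniform(0.2, 0.35)),
        wobble=float(rng.uniform(0.05, 0.25)),
        lobes=int(rng.integers(3, 8)),
        phase=float(rng.uniform(0, 2 * math.pi)),
        aspect=float(rng.uniform(0.4, 0.9)),
    )


# ---------------------------------------------------------------------------
# renderers

_BG_GRAY = 0.45
_NOISE_SD = 0.01


def _canvas(size_px: int) -> np.ndarray:
    return np.full((size_px, size_px, 3), _BG_GRAY, dtype=float)


def _paint(img: np.ndarray, rr: np.ndarray, cc: np.ndarray, color) -> np.ndarray:
    mask = np.zeros(img.shape[:2], dtype=bool)
    mask[rr, cc] = True
    img[mask] = color
    return mask


def _finish(img: np.ndarray, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    img = img + rng.normal(0.0, _NOISE_SD, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def render_face(
    identity_params: FaceParams,
    view_deg: int,
    size_px: int = 200,
    seed: int = 0,
    return_masks: bool = False,
):
    """Render one face at one of the 7 controlled views.

    Deterministic given (identity_params, view_deg, seed); the seed only
    drives a faint pixel-noise field. Rendering -view is the mirror image of
    +view up to that noise field.
    """
    if view_deg not in VIEWS_DEG:
        raise ValueError(f"view_deg must be one of {VIEWS_DEG}")
    if size_px <= 0:
        raise ValueError("size_px must be positive")
    p = identity_params
    S = size_px
    img = _canvas(S)
    cy = cx = (S - 1) / 2.0
    v = math.radians(view_deg)
    s, c = math.sin(v), math.cos(v)
    dx = p.feature_shift * S * s  # horizontal feature excursion (odd in view)

    masks: dict[str, np.ndarray] = {}

    # head: narrows toward the profiles
    a_w = p.face_halfwidth * S * (0.72 + 0.28 * abs(c))
    a_h = p.face_halfheight * S
    rr, cc = draw_ellipse(cy, cx, a_h, a_w, shape=img.shape[:2])
    masks["head"] = _paint(img, rr, cc, p.skin_rgb)

    # hair: the top part of the head above the identity's hairline
    hair_rows = int(round(2 * a_h * p.hairline_frac))
    hairline_y = cy - a_h + hair_rows
    hair_mask = masks["head"] & (np.arange(S)[:, None] < hairline_y)
    img[hair_mask] = p.hair_rgb
    masks["hair"] = hair_mask

    # eyes: displaced by the view, far-side eye occluded beyond +-60 deg
    eye_y = cy + p.eye_y * S
    eye_r = p.eye_radius * S
    eye_mask = np.zeros(img.shape[:2], dtype=bool)
    if abs(view_deg) > 60:
        eye_xs = [cx + dx]
    else:
        eye_xs = [cx + dx - p.eye_sep * S * c, cx + dx + p.eye_sep * S * c]
    for ex in eye_xs:
        rr, cc = draw_ellipse(eye_y, ex, eye_r, eye_r * 1.3, shape=img.shape[:2])
        eye_mask |= _paint(img, rr, cc, (0.08, 0.06, 0.05))
    masks["eyes"] = eye_mask

    # nose: a slightly darker skin wedge, shifted more than the eyes
    nose_x = cx + 1.2 * dx
    rr, cc = draw_ellipse(
        cy + 0.04 * S,
        nose_x,
        p.nose_len * S,
        max(1.0, p.nose_width * S * (0.55 + 0.45 * abs(c))),
        shape=img.shape[:2],
    )
    nose_color = tuple(0.8 * np.asarray(p.skin_rgb))
    masks["nose"] = _paint(img, rr, cc, nose_color)

    # mouth: foreshortened toward the profiles
    rr, cc = draw_ellipse(
        cy + p.mouth_y * S,
        cx + dx,
        max(1.0, p.mouth_height * S),
        max(1.0, p.mouth_width * S * (0.4 + 0.6 * abs(c))),
        shape=img.shape[:2],
    )
    masks["mouth"] = _paint(img, rr, cc, p.mouth_rgb)

    # lateral self-shadow: turning the head darkens the receding side.
    # The gradient is odd in the view angle (mirror-consistent) and is an
    # identity-independent view signature that survives position-invariant
    # matching downstream.
    if s != 0.0 and p.shading > 0.0:
        xs = (np.arange(S) - cx) / max(a_w, 1.0)
        gradient = 1.0 - p.shading * abs(s) * np.clip(-np.sign(s) * xs, 0.0, 1.5)
        img[masks["head"]] *= np.repeat(
            gradient[None, :], S, axis=0
        )[masks["head"], None]

    img = _finish(img, seed)
    if return_masks:
        return img, masks
    return img


def render_nonface(
    object_params: ObjectParams, size_px: int = 200, seed: int = 0
) -> np.ndarray:
    """Render a non-face object: textured blob, grating, or a household-
    object silhouette. No face-configural (eyes-above-mouth) layout is
    drawn."""
    if size_px <= 0:
        raise ValueError("size_px must be positive")
    p = object_params
    S = size_px
    img = _canvas(S)
    cy = cx = (S - 1) / 2.0
    if p.kind == "grating":
        yy, xx = np.mgrid[0:S, 0:S].astype(float)
        normal = math.radians((p.orientation_deg + 90.0) % 180.0)
        proj = (xx - cx) * math.cos(normal) + (yy - cy) * math.sin(normal)
        g = 0.5 + 0.45 * np.sin(2 * math.pi * p.frequency * proj + p.phase)
        for ch in range(3):
            img[:, :, ch] = g * p.color_rgb[ch] + (1 - g) * _BG_GRAY * 0.5
    elif p.kind == "blob":
        theta = np.linspace(0, 2 * math.pi, 120, endpoint=False)
        r = p.radius * S * (1 + p.wobble * np.sin(p.lobes * theta + p.phase))
        rr, cc = draw_polygon(
            cy + r * np.sin(theta), cx + r * np.cos(theta), shape=img.shape[:2]
        )
        _paint(img, rr, cc, p.color_rgb)
    elif p.kind == "silhouette":
        # a box with a lid: two stacked rectangles
        half_h = 0.30 * S
        half_w = p.aspect * half_h
        rr, cc = draw_polygon(
            [cy - half_h * 0.4, cy - half_h * 0.4, cy + half_h, cy + half_h],
            [cx - half_w, cx + half_w, cx + half_w, cx - half_w],
            shape=img.shape[:2],
        )
        _paint(img, rr, cc, p.color_rgb)
        lid = tuple(np.clip(np.asarray(p.color_rgb) * 0.6, 0, 1))
        rr, cc = draw_polygon(
            [cy - half_h, cy - half_h, cy - half_h * 0.4, cy - half_h * 0.4],
            [cx - half_w * 1.15, cx + half_w * 1.15, cx + half_w * 1.15, cx - half_w * 1.15],
            shape=img.shape[:2],
        )
        _paint(img, rr, cc, lid)
    else:
        raise ValueError(f"unknown object kind {p.kind!r}")
    return _finish(img, seed)


# ---------------------------------------------------------------------------
# stimulus sets


@dataclass
class StimulusSetConfig:
    """Counts and geometry of a synthetic stimulus set.

    Defaults are the desk-scale study conditions (8 identities x 7 views,
    40 view-uncontrolled faces, 60 non-face objects); ``paper_scale`` gives
    the full published counts (41 identities -> 287 view-controlled, 532
    uncontrolled faces, 690 non-face objects, 1509 stimuli in total).
    """

    n_identities: int = 8
    n_uncontrolled: int = 40
    n_nonface: int = 60
    monkey_fraction: float = 0.125
    size_px: int = 200

    def __post_init__(self) -> None:
        if self.n_identities <= 0 or self.n_uncontrolled < 0 or self.n_nonface < 0:
            raise ValueError("counts must be positive")
        if self.size_px <= 0:
            raise ValueError("size_px must be positive")

    @classmethod
    def paper_scale(cls) -> "StimulusSetConfig":
        return cls(
            n_identities=41,
            n_uncontrolled=532,
            n_nonface=690,
            monkey_fraction=5 / 41,
        )


def build_stimulus_set(
    config: StimulusSetConfig, master_seed: int = 0
) -> tuple[list[StimulusSpec], dict[str, np.ndarray]]:
    """Render the full stimulus set.

    Returns the ordered list of StimulusSpec plus a dict mapping stimulus id
    to its RGB image. The view-controlled subset has exactly
    ``7 * n_identities`` members; view-uncontrolled faces are fresh
    identities rendered at a pose sampled uniformly from the 7 views but
    recorded with no view label.
    """
    rng_id = substream(master_seed, "identities")
    rng_unc = substream(master_seed, "uncontrolled")
    rng_obj = substream(master_seed, "objects")
    specs: list[StimulusSpec] = []
    images: dict[str, np.ndarray] = {}
    n_monkey = int(round(config.monkey_fraction * config.n_identities))

    for i in range(config.n_identities):
        params = sample_identity_params(rng_id)
        category = "monkey_face" if i < n_monkey else "human_face"
        ident = f"id{i:03d}"
        for view in VIEWS_DEG:
            sid = f"vc_{ident}_{view:+04d}"
            specs.append(
                StimulusSpec(sid, category, ident, view, config.size_px)
            )
            images[sid] = render_face(
                params, view, config.size_px, seed=master_seed * 1000 + i
            )

    for j in range(config.n_uncontrolled):
        params = sample_identity_params(rng_unc)
        pose = int(rng_unc.choice(VIEWS_DEG))
        category = "monkey_face" if rng_unc.random() < config.monkey_fraction else "human_face"
        sid = f"uf_{j:04d}"
        specs.append(StimulusSpec(sid, category, None, None, config.size_px))
        images[sid] = render_face(
            params, pose, config.size_px, seed=master_seed * 2000 + j
        )

    for k in range(config.n_nonface):
        params = sample_object_params(rng_obj)
        sid = f"nf_{k:04d}"
        specs.append(StimulusSpec(sid, "nonface", None, None, config.size_px))
        images[sid] = render_nonface(params, config.size_px, seed=master_seed * 3000 + k)

    return specs, images


def specs_to_meta(specs: Sequence[StimulusSpec]) -> pd.DataFrame:
    """Stimulus-metadata frame indexed by stimulus id."""
    return pd.DataFrame(
        {
            "category": [s.category for s in specs],
            "identity_id": [s.identity_id for s in specs],
            "view_deg": [s.view_deg for s in specs],
        },
        index=pd.Index([s.stimulus_id for s in specs], name="stimulus_id"),
    )


# ---------------------------------------------------------------------------
# forward-model response simulation


def simulate_responses(
    column: GroundTruthColumn,
    specs: Sequence[StimulusSpec],
    stacks: dict[str, ChannelStack],
    seed: int,
    config: Optional[ModelConfig] = None,
    response01: Optional[np.ndarray] = None,
) -> ResponseTable:
    """Simulate trial-resolved responses of one synthetic column.

    The noiseless rate for stimulus s is
    ``nonface_gain + (face_gain - nonface_gain) * r01(s)`` where r01 is the
    forward-model RBF response of the planted candidate; each trial adds
    i.i.d. Gaussian noise (sd ``column.noise_sd``) and clips negative rates
    at zero. Precomputed ``response01`` (ordered as ``specs``) may be
    injected to avoid recomputing the forward model.
    """
    cfg = config or ModelConfig()
    ids = [s.stimulus_id for s in specs]
    if response01 is None:
        stack_list = [stacks[i] for i in ids]
        d2 = bank_min_distances([column.planted_candidate], stack_list, cfg)[0]
        sigma2 = cfg.rbf_sigma2 if cfg.rbf_sigma2 is not None else calibrate_sigma2(d2)
        response01 = responses01_from_distances(d2[None, :], np.atleast_1d(sigma2))[0]
    response01 = np.asarray(response01, dtype=float)
    rate = column.nonface_gain + (column.face_gain - column.nonface_gain) * response01

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=(column.n_trials, len(ids)))
    trials_mat = np.maximum(rate[None, :] + column.noise_sd * noise, 0.0)
    if column.noise_sd == 0:
        trials_mat = np.tile(np.maximum(rate, 0.0), (column.n_trials, 1))

    trials = pd.DataFrame(
        {
            "stimulus_id": np.repeat(ids, column.n_trials),
            "trial": np.tile(np.arange(1, column.n_trials + 1), len(ids)),
            "response": trials_mat.T.ravel(),
        }
    )
    return ResponseTable(column.site_id, trials, specs_to_meta(specs))
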