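"""Site screening: repeatability, face selectivity, and tuning ANOVA.

A recording site enters the fragment analysis only if its responses are
(1) repeatable — split-half correlation between even- and odd-trial means,
Spearman-Brown corrected, above 0.5; (2) face selective — FSI above 1/3,
i.e. at least a 2:1 face/non-face response ratio; and, for the view
analyses, (3) significantly view tuned (one-way ANOVA across the 7 views,
p < 1e-6, identities as replicates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import ResponseTable

__all__ = [
    "ScreeningThresholds",
    "ScreeningReport",
    "repeatability",
    "face_selectivity_index",
    "tuning_anova",
    "zscore_view_curve",
    "screen_site",
]


@dataclass(frozen=True)
class ScreeningThresholds:
    repeatability: float = 0.5
    fsi: float = 1.0 / 3.0
    anova_p: float = 1e-6

    def __post_init__(self) -> None:
        if not -1.0 <= self.repeatability <= 1.0:
            raise ValueError("repeatability threshold must lie in [-1, 1]")
        if not 0.0 < self.anova_p <= 1.0:
            raise ValueError("anova_p threshold must lie in (0, 1]")


@dataclass
class ScreeningReport:
    site_id: str
    repeatability_sb: float
    fsi: float
    view_anova_p: Optional[float]
    identity_anova_p: Optional[float]
    reliable: bool
    face_selective: bool
    view_tuned: bool
    identity_tuned: bool

    @property
    def passes_view_cascade(self) -> bool:
        return self.reliable and self.face_selective and self.view_tuned


def repeatability(table: ResponseTable) -> float:
    """Split-half repeatability with Spearman-Brown correction.

    Pearson correlation across stimuli between odd-trial means (trials
    1, 3, ...) and even-trial means, corrected to full length as
    ``2 r / (1 + r)``.
    """
    t = table.trials
    if table.n_trials() < 2:
        raise ValueError("need at least 2 trials per stimulus")
    odd = t[t["trial"] % 2 == 1].groupby("stimulus_id")["response"].mean()
    even = t[t["trial"] % 2 == 0].groupby("stimulus_id")["response"].mean()
    ids = table.meta.index
    if len(ids) < 3:
        raise ValueError("need at least 3 stimuli")
    x = odd.reindex(ids).to_numpy()
    y = even.reindex(ids).to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant response vector: correlation undefined")
    r_raw = float(np.corrcoef(x, y)[0, 1])
    if r_raw == -1.0:
        raise ValueError("split-half correlation of -1: correction undefined")
    return 2.0 * r_raw / (1.0 + r_raw)


def face_selectivity_index(table: ResponseTable) -> float:
    """FSI = (F - N) / (F + N) on trial-averaged responses, with the mean
    responses baseline-clipped at 0 before the ratio."""
    means = table.trial_means()
    face_ids, nonface_ids = table.face_ids(), table.nonface_ids()
    if not face_ids or not nonface_ids:
        raise ValueError("need both face and non-face stimuli")
    f = max(float(means.loc[face_ids].mean()), 0.0)
    n = max(float(means.loc[nonface_ids].mean()), 0.0)
    if f + n <= 0:
        raise ValueError("non-positive denominator after clipping")
    return (f - n) / (f + n)


def tuning_anova(table: ResponseTable, grouping: str = "view") -> tuple[float, float]:
    """One-way ANOVA over the view-controlled set.

    ``grouping='view'`` groups the trial-averaged responses into the 7 view
    groups with identities as replicates; ``grouping='identity'`` groups by
    identity with views as replicates. Returns (F, p).
    """
    if grouping not in ("view", "identity"):
        raise ValueError("grouping must be 'view' or 'identity'")
    means = table.trial_means()
    meta = table.meta.loc[table.view_controlled_ids()]
    if meta.empty:
        raise ValueError("no view-controlled stimuli")
    key = "view_deg" if grouping == "view" else "identity_id"
    groups = [
        means.loc[idx.index].to_numpy() for _, idx in meta.groupby(key, dropna=False)
    ]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 replicates")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def zscore_view_curve(
    table: ResponseTable,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Z-scored view tuning curve.

    Each identity's 7-view trial-averaged vector is z-scored (mean 0, sd 1
    across its views, population sd); the per-view mean and sd across
    identities are returned, along with the ids of identities dropped for
    zero within-identity variance.
    """
    means = table.trial_means()
    meta = table.meta.loc[table.view_controlled_ids()]
    pivot = (
        pd.DataFrame(
            {
                "identity": meta["identity_id"],
                "view": meta["view_deg"],
                "resp": means.loc[meta.index],
            }
        )
        .pivot_table(index="identity", columns="view", values="resp")
        .sort_index(axis=1)
    )
    if pivot.isna().any().any():
        raise ValueError("every identity needs all views")
    vals = pivot.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    degenerate = [str(i) for i, s in zip(pivot.index, sd) if s == 0]
    keep = sd > 0
    z = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    if z.shape[0] == 0:
        n_views = vals.shape[1]
        return np.zeros(n_views), np.zeros(n_views), degenerate
    return z.mean(axis=0), z.std(axis=0), degenerate


def screen_site(
    table: ResponseTable, thresholds: ScreeningThresholds = ScreeningThresholds()
) -> ScreeningReport:
    """Run the full screening cascade for one site.

    ANOVA p-values are None when the site has no view-controlled stimuli
    with enough replicates (the corresponding flags are then False).
    """
    rep = repeatability(table)
    fsi = face_selectivity_index(table)
    view_p = identity_p = None
    try:
        _, view_p = tuning_anova(table, "view")
        _, identity_p = tuning_anova(table, "identity")
    except ValueError:
        pass
    return ScreeningReport(
        site_id=table.site_id,
        repeatability_sb=rep,
        fsi=fsi,
        view_anova_p=view_p,
        identity_anova_p=identity_p,
        reliable=rep > thresholds.repeatability,
        face_selective=fsi > thresholds.fsi,
        view_tuned=view_p is not None and view_p < thresholds.anova_p,
        identity_tuned=identity_p is not None and identity_p < thresholds.anova_p,
    )
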