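"""End-to-end pipeline: synthesize -> preprocess -> screen -> select ->
validate -> interpret -> readout, driven by one YAML config.

Every stage is a pure function of (inputs, config, master seed); re-running
with the same config writes bit-identical reports. Each stage appends its
outputs to a run directory and the final manifest records the config hash,
seed, package version and SHA-256 of every written file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .axes import capture_subregion, extract_axis, weighted_average_subregions
from .experiments import (
    BankResponses,
    StimulusBundle,
    compute_bank_responses,
    make_bundle,
    make_fragment_bank,
)
from .io import (
    save_bank,
    save_image_png,
    save_response_tables,
    save_stacks,
    write_stimulus_manifest,
)
from .model import ModelConfig, min_over_positions_scales
from .readout import IdentityReadout, build_feature_space
from .screening import ScreeningThresholds, screen_site
from .selection import deduplicate_features, select_from_distances
from .synth import StimulusSetConfig, simulate_responses, substream
from .tuning import (
    crossval_two_fold,
    predict_identity_tuning,
    predict_view_tuning,
    predicted_view_responses,
)
from .types import GroundTruthColumn, ResponseTable

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("fragface.pipeline")

STAGES = (
    "synth",
    "preprocess",
    "screen",
    "select",
    "validate",
    "interpret",
    "readout",
)


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    master_seed: int = 0
    # stimulus set
    n_identities: int = 4
    n_uncontrolled: int = 12
    n_nonface: int = 14
    size_px: int = 100
    # front end
    gabor_frequency: float = 0.25
    gabor_sigma: float = 1.8
    pool_window: int = 10
    pool_stride: int = 10
    # response model
    alpha: float = 0.5
    scale_range_b: tuple[float, ...] = (0.8, 1.0, 1.25)
    normalize: bool = True
    # fragment bank
    bank_size: int = 80
    fragment_sizes: tuple[int, ...] = (8,)
    fragment_stride: int = 1
    # simulated columns
    n_planted_columns: int = 3
    n_noise_columns: int = 1
    noise_sd: float = 3.0
    n_trials: int = 10
    face_gain: float = 20.0
    nonface_gain: float = -18.0
    # screening / selection thresholds (the published values)
    repeatability_threshold: float = 0.5
    fsi_threshold: float = 1.0 / 3.0
    anova_p_threshold: float = 1e-6
    alpha_sig: float = 0.05
    save_pngs: bool = True

    def __post_init__(self) -> None:
        self.thresholds = ScreeningThresholds(
            repeatability=self.repeatability_threshold,
            fsi=self.fsi_threshold,
            anova_p=self.anova_p_threshold,
        )
        if not 0 < self.alpha_sig < 1:
            raise ValueError("alpha_sig must lie in (0, 1)")
        self.model_config = ModelConfig(
            alpha=self.alpha,
            scale_range_b=tuple(self.scale_range_b),
            normalize=self.normalize,
        )
        self.stimulus_config = StimulusSetConfig(
            n_identities=self.n_identities,
            n_uncontrolled=self.n_uncontrolled,
            n_nonface=self.n_nonface,
            size_px=self.size_px,
        )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("scale_range_b", "fragment_sizes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "out_dir"
        }
        dump = yaml.safe_dump(
            {k: list(v) if isinstance(v, tuple) else v for k, v in payload.items()},
            sort_keys=True,
        )
        return hashlib.sha256(dump.encode()).hexdigest()[:16]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Mutable in-memory state threaded through the stages."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outputs: list[str] = []
        self.bundle: Optional[StimulusBundle] = None
        self.bank = None
        self.responses: Optional[BankResponses] = None
        self.tables: list[ResponseTable] = []
        self.reports = None
        self.selections: dict[str, object] = {}
        self.validation = None

    def path(self, name: str) -> str:
        p = os.path.join(self.config.out_dir, name)
        os.makedirs(os.path.dirname(p), exist_ok=True)
        self.outputs.append(p)
        return p


def _stage_synth(run: _Run) -> None:
    cfg = run.config
    run.bundle = make_bundle(
        cfg.master_seed,
        cfg.stimulus_config,
        bank_params={"frequency": cfg.gabor_frequency, "sigma": cfg.gabor_sigma},
    )
    if cfg.save_pngs:
        img_dir = os.path.join(cfg.out_dir, "stimuli")
        os.makedirs(img_dir, exist_ok=True)
        for sid, img in run.bundle.images.items():
            save_image_png(run.path(os.path.join("stimuli", f"{sid}.png")), img)
    write_stimulus_manifest(
        run.path("stimulus_manifest.csv"), run.bundle.specs, "stimuli"
    )


def _stage_preprocess(run: _Run) -> None:
    cfg = run.config
    save_stacks(run.path("stacks.h5"), run.bundle.stacks)
    run.bank = make_fragment_bank(
        run.bundle,
        n_candidates=cfg.bank_size,
        sizes=cfg.fragment_sizes,
        stride=cfg.fragment_stride,
        seed=cfg.master_seed,
        scale_range_b=cfg.scale_range_b,
    )
    save_bank(run.path("bank.h5"), run.bank)
    run.responses = compute_bank_responses(run.bundle, run.bank, cfg.model_config)

    # simulate ground-truth columns: planted (face-derived fragment) + noise
    rng = substream(cfg.master_seed, "columns")
    face_sources = [
        i
        for i, c in enumerate(run.bank)
        if not c.source_image_id.startswith("nf_")
    ]
    run.tables = []
    for i in range(cfg.n_planted_columns):
        planted = int(face_sources[rng.integers(len(face_sources))])
        col = GroundTruthColumn(
            site_id=f"planted{i:02d}",
            planted_candidate=run.bank[planted],
            noise_sd=cfg.noise_sd,
            n_trials=cfg.n_trials,
            face_gain=cfg.face_gain,
            nonface_gain=cfg.nonface_gain,
        )
        run.tables.append(
            simulate_responses(
                col,
                run.bundle.specs,
                run.bundle.stacks,
                seed=int(rng.integers(2**31 - 1)),
                config=cfg.model_config,
            )
        )
    flat_gain = 0.5 * (cfg.face_gain + cfg.nonface_gain)
    for i in range(cfg.n_noise_columns):
        planted = int(rng.integers(len(run.bank)))
        col = GroundTruthColumn(
            site_id=f"noise{i:02d}",
            planted_candidate=run.bank[planted],
            noise_sd=cfg.noise_sd,
            n_trials=cfg.n_trials,
            face_gain=flat_gain,
            nonface_gain=flat_gain,
        )
        run.tables.append(
            simulate_responses(
                col,
                run.bundle.specs,
                run.bundle.stacks,
                seed=int(rng.integers(2**31 - 1)),
                config=cfg.model_config,
            )
        )
    save_response_tables(run.path("responses.csv"), run.tables)


def _stage_screen(run: _Run) -> None:
    run.reports = [screen_site(t, run.config.thresholds) for t in run.tables]
    frame = pd.DataFrame([dataclasses.asdict(r) for r in run.reports])
    frame.to_csv(run.path("screening_report.csv"), index=False)


def _stage_select(run: _Run) -> None:
    cfg = run.config
    resp = run.responses
    rows = []
    run.selections = {}
    for table, report in zip(run.tables, run.reports):
        if not (report.reliable and report.face_selective):
            continue
        sel = select_from_distances(
            run.bank,
            resp.d2_screen,
            resp.screening_ids,
            table.trial_means(),
            set(table.uncontrolled_face_ids()),
            cfg.model_config,
            alpha_sig=cfg.alpha_sig,
            site_id=table.site_id,
        )
        if sel is None:
            rows.append({"site_id": table.site_id, "candidate_id": ""})
            continue
        run.selections[table.site_id] = sel
        rows.append(
            {
                "site_id": table.site_id,
                "candidate_id": sel.candidate_id,
                "r_global": sel.r_global,
                "p_global": sel.p_global,
                "r_local": sel.r_local,
                "p_local": sel.p_local,
                "rbf_sigma2": sel.rbf_sigma2,
                "runner_up_ids": ";".join(sel.runner_up_ids),
            }
        )
    pd.DataFrame(rows).to_csv(run.path("selection.csv"), index=False)


def _stage_validate(run: _Run) -> None:
    cfg = run.config
    rows = []
    curve_rows = []
    for table in run.tables:
        sel = run.selections.get(table.site_id)
        if sel is None:
            continue
        cv = crossval_two_fold(
            run.bank,
            table,
            run.bundle.stacks,
            cfg.model_config,
            seed=cfg.master_seed,
            alpha_sig=cfg.alpha_sig,
            D2=run.responses.d2_screen,
            stim_ids=run.responses.screening_ids,
        )
        row = {
            "site_id": table.site_id,
            "cc_global_test": cv.cc_global_test,
            "cc_local_test": cv.cc_local_test,
            "n_per_fold": cv.n_per_fold,
        }
        try:
            vt = predict_view_tuning(sel, run.bundle.stacks, table, cfg.model_config)
            it = predict_identity_tuning(
                sel, run.bundle.stacks, table, cfg.model_config
            )
            row.update(
                view_predictability_r=vt.r,
                view_predictability_p=vt.p,
                view_n=vt.n,
                identity_spearman_rho=it.rho,
                identity_spearman_p=it.p,
                identity_n=it.n,
            )
            for view, pm, ps, nm, ns in zip(
                vt.views,
                vt.predicted_curve_mean,
                vt.predicted_curve_sd,
                vt.neural_curve_mean,
                vt.neural_curve_sd,
            ):
                curve_rows.append(
                    {
                        "site_id": table.site_id,
                        "view_deg": view,
                        "predicted_mean": pm,
                        "predicted_sd": ps,
                        "neural_mean": nm,
                        "neural_sd": ns,
                    }
                )
        except ValueError as exc:
            row["view_predictability_r"] = None
            log.warning("site %s: tuning prediction skipped (%s)", table.site_id, exc)
        rows.append(row)
    run.validation = pd.DataFrame(rows)
    run.validation.to_csv(run.path("validation.csv"), index=False)
    pd.DataFrame(curve_rows).to_csv(run.path("tuning_curves.csv"), index=False)


def _stage_interpret(run: _Run) -> None:
    cfg = run.config
    import h5py

    path = run.path("axes.h5")
    with h5py.File(path, "w") as f:
        for site_id, sel in run.selections.items():
            meta = run.bundle.meta.loc[run.bundle.view_ids]
            if meta.empty:
                continue
            mcfg = ModelConfig(
                alpha=cfg.alpha,
                rbf_sigma2=sel.rbf_sigma2,
                scale_range_b=cfg.scale_range_b,
                normalize=cfg.normalize,
            )
            shape = sel.candidate.stack.shape
            subs, resp = [], []
            for sid in meta.index:
                m = min_over_positions_scales(
                    sel.candidate, run.bundle.stacks[sid], mcfg
                )
                subs.append(
                    capture_subregion(run.bundle.stacks[sid], m, shape)
                )
                resp.append(m.response01)
            axis = extract_axis(subs, resp)
            avg = weighted_average_subregions(subs, resp)
            g = f.create_group(site_id)
            g.create_dataset("a_V", data=axis.a_V, track_times=False)
            g.create_dataset(
                "projection_curve", data=axis.projection_curve, track_times=False
            )
            g.create_dataset(
                "weighted_average", data=avg.data, track_times=False
            )
            g.attrs["curve_correlation"] = axis.curve_correlation
            g.attrs["ridge_lambda"] = axis.ridge_lambda
            if cfg.save_pngs:
                from .viz import plot_channel_panels

                plot_channel_panels(
                    axis.a_V,
                    run.path(os.path.join("panels", f"{site_id}_axis.png")),
                    title=f"{site_id} view axis",
                )
                plot_channel_panels(
                    avg.data,
                    run.path(os.path.join("panels", f"{site_id}_avg.png")),
                    title=f"{site_id} weighted average sub-region",
                )


def _stage_readout(run: _Run) -> None:
    cfg = run.config
    selections = list(run.selections.values())
    meta = run.bundle.meta.loc[run.bundle.view_ids]
    if not selections or meta.empty:
        pd.DataFrame().to_csv(run.path("readout_report.csv"), index=False)
        return
    axes, site_map = deduplicate_features(selections)
    F = build_feature_space(axes, run.bundle.stacks, list(meta.index), cfg.model_config)
    F.to_csv(run.path("feature_space.csv"))
    pd.DataFrame(
        [{"site_id": s, "axis_index": a} for s, a in sorted(site_map.items())]
    ).to_csv(run.path("site_axis_map.csv"), index=False)
    readout = IdentityReadout().fit(
        F, meta["identity_id"], views=meta["view_deg"].astype(int)
    )
    rows = []
    curve_rows = []
    for r in readout.results_:
        rows.append(
            {
                "identity_id": r.identity_id,
                "auc": r.auc,
                "n_view_hits": sum(r.per_view_hits.values()),
            }
        )
        for k, (a, v) in enumerate(zip(r.incremental_auc, r.view_specificity), 1):
            curve_rows.append(
                {
                    "identity_id": r.identity_id,
                    "k": k,
                    "incremental_auc": a,
                    "view_specificity": v,
                }
            )
    report = pd.DataFrame(rows)
    report.attrs["mean_auc"] = readout.mean_auc_
    report.to_csv(run.path("readout_report.csv"), index=False)
    pd.DataFrame(curve_rows).to_csv(run.path("readout_curves.csv"), index=False)
    summary = {
        "mean_auc": readout.mean_auc_,
        "loo_rate": readout.loo_rate_,
        "chance": 1.0 / meta["identity_id"].nunique(),
        "n_axes": F.shape[1],
        "k_at_mean_auc_0.9": readout.k_at_mean_auc(0.9),
    }
    with open(run.path("readout_summary.json"), "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)


_STAGE_FN = {
    "synth": _stage_synth,
    "preprocess": _stage_preprocess,
    "screen": _stage_screen,
    "select": _stage_select,
    "validate": _stage_validate,
    "interpret": _stage_interpret,
    "readout": _stage_readout,
}


def run_pipeline(config: PipelineConfig, until: str = "readout") -> dict:
    """Execute the pipeline in dependency order up to stage ``until``.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; stages are {STAGES}")
    os.makedirs(config.out_dir, exist_ok=True)
    run = _Run(config)
    for stage in STAGES[: STAGES.index(until) + 1]:
        log.info("stage %s", stage)
        try:
            _STAGE_FN[stage](run)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "version": __version__,
        "until": until,
        "outputs": {
            os.path.relpath(p, config.out_dir): _sha256(p)
            for p in sorted(set(run.outputs))
            if os.path.isfile(p)
        },
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest
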