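"""End-to-end pipeline: simulate -> cilia -> stats -> DE -> transfer.

A :class:`RunConfig` names an output directory, one explicit seed per
stochastic stage, and the analysis settings.  :func:`run_pipeline`
executes the stages in order, writes every artifact under the output
directory, and finishes with a ``manifest.json`` recording inputs,
seeds, package version and a SHA-256 hash of every written file.  All
outputs are deterministic: rerunning with the same configuration
reproduces every file byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cilia, io, longitudinal, synthetic, transfer
from .expression import fit_linear_de, select_signature

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

STAGES = ("simulate", "cilia", "stats", "de", "transfer")
REQUIRED_SEEDS = ("video", "longitudinal", "expression", "classifier")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    out_dir: str
    seeds: dict = field(default_factory=dict)
    stages: tuple[str, ...] = STAGES
    band: tuple[float, float] = (2.0, 14.0)
    snr_threshold: float = 15.0
    fps: float = 30.0
    q_cut: float = 0.05
    de_variance_mode: str = "pooled"  # for the small-n paired in vitro cohort
    rf_folds: int = 50
    rf_trees: int = 100
    rf_features_per_split: int = 10
    # synthetic-demo problem sizes (kept small; the generators scale freely)
    video_size: int = 40
    video_frames: int = 256
    n_transcripts: int = 300
    n_signature: int = 40
    discordant_fraction: float = 0.14

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        missing = [k for k in REQUIRED_SEEDS if k not in self.seeds]
        if missing:
            raise ValueError(f"config is missing seeds for stochastic stages: {missing}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    state: dict = {}

    def record(path: Path) -> None:
        written.append(path)

    for stage in config.stages:
        try:
            _STAGE_FUNCS[stage](config, out, state, record)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "alismoke",
        "version": __version__,
        "stages": list(config.stages),
        "seeds": dict(config.seeds),
        "config": {
            k: v for k, v in asdict(config).items() if k not in ("seeds", "stages", "out_dir")
        },
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
    }
    manifest_path = out / "manifest.json"
    _write_json(manifest, manifest_path)
    logger.info("pipeline complete: %d artifacts in %s", len(written), out)
    return manifest


def _stage_simulate(config: RunConfig, out: Path, state: dict, record) -> None:
    n = config.video_size
    mask = np.zeros((n, n), dtype=bool)
    side = max(4, n // 3)
    mask[2 : 2 + side, 2 : 2 + side] = True
    video_spec = synthetic.CiliaVideoSpec(
        height=n,
        width=n,
        n_frames=config.video_frames,
        fps=config.fps,
        regions=(synthetic.CiliaRegion(mask=mask, frequency=8.0, amplitude=10.0, phase_jitter_sd=0.3),),
        noise_sd=2.0,
        seed=config.seeds["video"],
    )
    stack, truth = synthetic.generate_cilia_video(video_spec)
    record(io.write_video(stack, out / "video.tif"))
    record(out / "video.json")

    long_spec = synthetic.LongitudinalSpec(
        n_subjects_per_group=3,
        mean_curves={
            ("HC", "Air"): (400.0, 500.0, 560.0, 580.0),
            ("HC", "CS"): (320.0, 360.0, 380.0, 390.0),
            ("COPD", "Air"): (390.0, 480.0, 540.0, 560.0),
            ("COPD", "CS"): (310.0, 350.0, 360.0, 370.0),
        },
        subject_sd=40.0,
        residual_sd=25.0,
        within_subject_correlation=0.5,
        endpoint="teer",
        seed=config.seeds["longitudinal"],
    )
    endpoints = synthetic.generate_longitudinal(long_spec)
    io.write_endpoints(endpoints, out / "endpoints.csv")
    record(out / "endpoints.csv")

    expr_spec = synthetic.TwoCohortExpressionSpec(
        n_transcripts=config.n_transcripts,
        n_signature=config.n_signature,
        discordant_fraction=config.discordant_fraction,
        seed=config.seeds["expression"],
    )
    invitro, invivo, truth_table = synthetic.generate_two_cohort_expression(expr_spec)
    io.write_expression(invitro, out / "invitro.tsv", out / "invitro_meta.tsv")
    io.write_expression(invivo, out / "invivo.tsv", out / "invivo_meta.tsv")
    truth_table.to_csv(out / "expression_truth.tsv", sep="\t")
    for name in ("invitro.tsv", "invitro_meta.tsv", "invivo.tsv", "invivo_meta.tsv", "expression_truth.tsv"):
        record(out / name)
    state.update(stack=stack, endpoints=endpoints, invitro=invitro, invivo=invivo)


def _stage_cilia(config: RunConfig, out: Path, state: dict, record) -> None:
    stack = state.get("stack") or io.read_video(out / "video.tif")
    sconf = cilia.SpectralConfig(
        band_low=config.band[0], band_high=config.band[1], snr_threshold=config.snr_threshold
    )
    fmap = cilia.compute_frequency_map(stack, sconf)
    summary = cilia.summarize_cilia(fmap)
    record(io.write_frequency_map(fmap, out / "frequency_map.tif"))
    record(out / "frequency_map.json")
    _write_json(
        {
            "active_area_pct": summary.active_area_pct,
            "mean_cbf": None if np.isnan(summary.mean_cbf) else summary.mean_cbf,
            "n_active": summary.n_active,
            "n_analyzed": summary.n_analyzed,
        },
        out / "cilia_summary.json",
    )
    record(out / "cilia_summary.json")
    rgb, _ = cilia.render_false_color(fmap)
    from PIL import Image

    Image.fromarray(rgb).save(out / "frequency_map.png")
    record(out / "frequency_map.png")


def _stage_stats(config: RunConfig, out: Path, state: dict, record) -> None:
    endpoints = state.get("endpoints")
    if endpoints is None:
        endpoints = io.read_endpoints(out / "endpoints.csv")
    log_endpoints = {
        name for name, spec in longitudinal.DIRECTION_REGISTRY.items() if spec.transform == "log"
    }
    aucs = longitudinal.auc_table(endpoints, log_endpoints=log_endpoints)
    aucs.to_csv(out / "adjusted_auc.csv", index=False)
    record(out / "adjusted_auc.csv")
    contrasts = {}
    for endpoint, sub in aucs.groupby("endpoint"):
        fit = longitudinal.fit_repeated_measures(sub)
        for group in sorted(sub["group"].unique()):
            spec = longitudinal.hypothesis_for(endpoint, group)
            result = longitudinal.test_one_sided(fit, spec)
            contrasts[f"{endpoint}:{group}"] = {
                "estimate": result.estimate,
                "standard_error": result.standard_error,
                "df": result.df,
                "t": result.t_statistic,
                "p_one_sided": result.p_one_sided,
                "direction": result.direction,
            }
    _write_json(contrasts, out / "contrasts.json")
    record(out / "contrasts.json")


def _stage_de(config: RunConfig, out: Path, state: dict, record) -> None:
    invitro = state.get("invitro") or io.read_expression(out / "invitro.tsv", out / "invitro_meta.tsv")
    invivo = state.get("invivo") or io.read_expression(out / "invivo.tsv", out / "invivo_meta.tsv")
    # pooled variance for the 3-donor paired design; per-transcript variance
    # has essentially no power at 2 residual df
    de_iv = fit_linear_de(invitro, contrast=("smoke", "air"), variance_mode=config.de_variance_mode)
    de_vv = fit_linear_de(invivo, contrast=("smoker", "nonsmoker"))
    for name, de in (("de_invitro", de_iv), ("de_invivo", de_vv)):
        de.table.to_csv(out / f"{name}.tsv", sep="\t", index_label="transcript")
        record(out / f"{name}.tsv")
    signature = select_signature(de_iv, q_cut=config.q_cut)
    signature.to_csv(out / "signature.tsv", sep="\t", index_label="transcript")
    record(out / "signature.tsv")
    state.update(de_invitro=de_iv, de_invivo=de_vv, signature=signature)


def _stage_transfer(config: RunConfig, out: Path, state: dict, record) -> None:
    import pandas as pd

    invitro = state.get("invitro") or io.read_expression(out / "invitro.tsv", out / "invitro_meta.tsv")
    invivo = state.get("invivo") or io.read_expression(out / "invivo.tsv", out / "invivo_meta.tsv")
    de_iv = state.get("de_invitro")
    de_vv = state.get("de_invivo")
    if de_iv is None or de_vv is None:
        raise ValueError("transfer stage requires the de stage in the same run")

    joined, clustering = transfer.join_and_cluster(
        de_iv, de_vv, invitro, invivo, q_cut=config.q_cut, dataset_names=("invitro", "invivo")
    )
    joined.values.to_csv(out / "joined_normalized.tsv", sep="\t", index_label="transcript")
    record(out / "joined_normalized.tsv")
    if clustering is not None:
        (out / "joined_columns.nwk").write_text(clustering.to_newick())
        record(out / "joined_columns.nwk")

    signature = list(state["signature"].index)
    signature = [t for t in signature if t in invivo.values.index]
    norm_vv = transfer.minmax_normalize(invivo, dataset="invivo")
    labels = invivo.aligned_metadata()["condition"]
    k_remove = min(10, max(1, len(signature) - 1))
    full, reduced = transfer.ablate_and_reclassify(
        norm_vv,
        labels,
        signature,
        k_remove=k_remove,
        folds=config.rf_folds,
        n_trees=config.rf_trees,
        features_per_split=config.rf_features_per_split,
        seed=config.seeds["classifier"],
    )
    pd.DataFrame(full.roc_points, columns=["fpr", "tpr"]).to_csv(out / "roc_full.csv", index=False)
    record(out / "roc_full.csv")
    _write_json(
        {
            "full": {"auc": full.auc, "confusion_matrix": full.confusion_matrix.tolist(),
                     "cv_scheme": full.cv_scheme},
            "reduced": {"auc": reduced.auc, "confusion_matrix": reduced.confusion_matrix.tolist(),
                        "removed": sorted(set(full.features) - set(reduced.features))},
            "n_trees": full.n_trees,
            "features_per_split": full.features_per_split,
            "seed": full.seed,
        },
        out / "classification.json",
    )
    record(out / "classification.json")

    overlap = transfer.direction_overlap(de_iv, de_vv, q_cut=config.q_cut)
    _write_json(
        {
            "n_only_invitro": overlap.n_only_a,
            "n_only_invivo": overlap.n_only_b,
            "n_shared": overlap.n_shared,
            "n_consistent": overlap.n_consistent,
            "consistent_fraction": overlap.consistent_fraction,
        },
        out / "overlap.json",
    )
    record(out / "overlap.json")
    overlap.scatter_pairs.to_csv(out / "overlap_scatter.csv", index_label="transcript")
    record(out / "overlap_scatter.csv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cilia": _stage_cilia,
    "stats": _stage_stats,
    "de": _stage_de,
    "transfer": _stage_transfer,
}
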