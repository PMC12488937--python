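"""End-to-end quality-determination pipeline.

measure -> screen -> cluster -> cutpoint -> compose -> report.  The
pipeline accepts either a directory of brightfield images or an existing
per-organoid feature table, screens the nine morphological parameters
against the expert rating, clusters the selected features with k-means,
derives per-feature Youden cutpoints, classifies by the winning feature
(Feret diameter by default) and, when expression inputs are present,
estimates cell-type composition and its cohort statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    agreement_metrics,
    elbow_wss,
    kmeans_cluster,
    map_clusters_to_labels,
    zscore_normalize,
)
from .composition import cohort_composition_stats, estimate_fractions
from .cutpoint import classify_by_threshold, cutpoint_for_feature
from .errors import ConfigurationError
from .morphometry import FEATURE_COLUMNS, measure_image
from .screen import screen_features

logger = logging.getLogger("organoid_qc")

__all__ = ["PipelineConfig", "QCReport", "run_quality_pipeline", "write_report", "load_pipeline_config"]


@dataclass
class PipelineConfig:
    features_csv: str | None = None  # per-organoid feature table, or
    images_dir: str | None = None  # a directory of brightfield TIFF/PNG
    pixel_size_um: float = 12.0
    label_col: str = "expert_label"
    p_cut: float = 1e-5
    r_cut: float = 0.5
    k_max: int = 15
    n_start: int = 20
    seed: int = 111
    cutpoint_feature: str = "feret_um"
    expression_csv: str | None = None  # genes x samples
    signature_csv: str | None = None  # genes x cell types
    exclude_genes: str | None = None  # one gene id per line
    out_dir: str = "organoid_qc_out"

    def validate(self) -> None:
        if self.features_csv is None and self.images_dir is None:
            raise ConfigurationError("either features_csv or images_dir is required")
        for attr in ("features_csv", "images_dir", "expression_csv", "signature_csv", "exclude_genes"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{attr} does not exist: {path}")


@dataclass
class QCReport:
    config: dict
    screen: pd.DataFrame
    selected_features: list
    elbow: dict
    cluster_agreement: dict
    cutpoints: list  # per-feature dicts, best first
    threshold_classification: dict
    composition_stats: dict | None
    features: pd.DataFrame
    clusters: pd.DataFrame
    fractions: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def payload(self) -> dict:
        """JSON-serializable core of the report (excludes the CSV tables)."""
        return {
            "config": self.config,
            "screen": self.screen.to_dict(orient="records"),
            "selected_features": list(self.selected_features),
            "elbow": self.elbow,
            "cluster_agreement": self.cluster_agreement,
            "cutpoints": self.cutpoints,
            "threshold_classification": self.threshold_classification,
            "composition_stats": self.composition_stats,
            "provenance": self.provenance,
        }


def _hash_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _load_features(config: PipelineConfig) -> pd.DataFrame:
    if config.features_csv is not None:
        logger.info("features table %s (sha %s)", config.features_csv, _hash_file(config.features_csv))
        return pd.read_csv(config.features_csv)
    rows = []
    img_dir = Path(config.images_dir)
    paths = sorted(list(img_dir.glob("*.tif")) + list(img_dir.glob("*.tiff")) + list(img_dir.glob("*.png")))
    if not paths:
        raise ConfigurationError(f"no TIFF/PNG images in {img_dir}")
    import imageio.v3 as iio

    for path in paths:
        organoid_id = path.stem
        line_id = organoid_id.rsplit("_org", 1)[0] if "_org" in organoid_id else ""
        rec = measure_image(iio.imread(path), config.pixel_size_um, organoid_id, line_id)
        rows.append(rec.as_dict())
    logger.info("measured %d images from %s", len(rows), img_dir)
    return pd.DataFrame(rows)


def run_quality_pipeline(config: PipelineConfig, labels: pd.Series | None = None) -> QCReport:
    """Execute all stages; composition is skipped without expression inputs.

    ``labels`` may inject expert labels for image-based runs where the
    table has no label column (indexed like the measured table).
    """
    config.validate()
    logging.basicConfig(level=logging.INFO)

    table = _load_features(config)
    if labels is not None:
        table = table.copy()
        table[config.label_col] = np.asarray(labels)
    if config.label_col not in table.columns:
        raise ConfigurationError(f"label column {config.label_col!r} missing")

    # stage: screen
    screen_res = screen_features(
        table, label_col=config.label_col, p_cut=config.p_cut, r_cut=config.r_cut
    )
    selected = screen_res.selected
    logger.info("screen selected %s", selected)
    cluster_feats = selected if len(selected) >= 2 else [
        f for f in FEATURE_COLUMNS if f in table.columns
    ]

    # stage: cluster
    Z = zscore_normalize(table, cluster_feats)
    elbow = elbow_wss(Z, k_max=config.k_max, n_start=config.n_start, seed=config.seed)
    assign = kmeans_cluster(Z, k=2, n_start=config.n_start, seed=config.seed)
    mapped = map_clusters_to_labels(assign, table[config.label_col], table.get("feret_um"))
    km_agree = agreement_metrics(mapped.mapped_label, table[config.label_col])
    logger.info("k-means (k=%d chosen): PPV=%.3f NPV=%.3f", elbow.chosen_k,
                km_agree.ppv or float("nan"), km_agree.npv or float("nan"))

    # stage: cutpoint (all screened features; winner reported separately)
    cutpoints = []
    for feat in (selected or cluster_feats):
        cutpoints.append(cutpoint_for_feature(table, feat, config.label_col).as_dict())
    cutpoints.sort(key=lambda c: -c["youden_j"])
    win = cutpoint_for_feature(table, config.cutpoint_feature, config.label_col)
    calls, agree = classify_by_threshold(
        table[config.cutpoint_feature], win.optimal_threshold, win.direction,
        table[config.label_col],
    )
    logger.info("%s cutpoint %.1f (J=%.3f): PPV=%.3f NPV=%.3f", win.feature,
                win.optimal_threshold, win.youden_j,
                agree.ppv or float("nan"), agree.npv or float("nan"))

    clusters_df = pd.DataFrame(
        {
            "organoid_id": table.get("organoid_id", pd.RangeIndex(len(table)).astype(str)),
            "expert_label": table[config.label_col],
            "kmeans_cluster": mapped.cluster_id,
            "kmeans_label": mapped.mapped_label,
            "threshold_label": calls,
        }
    )

    # stage: composition (optional)
    comp_stats = None
    fractions = None
    if config.expression_csv and config.signature_csv:
        bulk = pd.read_csv(config.expression_csv, index_col=0).T  # to samples x genes
        signature = pd.read_csv(config.signature_csv, index_col=0)
        exclusion = []
        if config.exclude_genes:
            exclusion = Path(config.exclude_genes).read_text().split()
        est = estimate_fractions(bulk, signature, exclusion)
        fractions = est.fractions
        # any frac_* columns already in the table (e.g. synthetic ground
        # truth) are set aside; downstream stats use the estimates
        plain = table.drop(columns=[c for c in table.columns if c.startswith("frac_")])
        merged = plain.set_index("organoid_id").join(
            est.fractions.add_prefix("frac_"), how="inner"
        ).reset_index()
        groupings = {"expert": config.label_col}
        merged = merged.merge(clusters_df[["organoid_id", "kmeans_label", "threshold_label"]],
                              on="organoid_id")
        groupings.update({"cluster": "kmeans_label", "feret": "threshold_label"})
        stats = cohort_composition_stats(merged, groupings=groupings)
        comp_stats = {
            "per_line_cv_pct": stats.per_line_cv.round(4).to_dict(),
            "median_line_cv_pct": stats.median_line_cv,
            "cv_of_line_means_pct": stats.cv_of_line_means,
            "group_tests": stats.group_tests,
            "correlations": stats.correlations,
        }
        logger.info("composition: median per-line CV %.2f%%, CV of line means %.2f%%",
                    stats.median_line_cv, stats.cv_of_line_means)

    provenance = {
        "organoid_qc_version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest()[:16],
    }
    return QCReport(
        config=asdict(config),
        screen=screen_res.table,
        selected_features=selected,
        elbow={"k": elbow.k_values.tolist(), "wss": elbow.wss.tolist(), "chosen_k": elbow.chosen_k},
        cluster_agreement=km_agree.as_dict(),
        cutpoints=cutpoints,
        threshold_classification=win.as_dict(),
        composition_stats=comp_stats,
        features=table,
        clusters=clusters_df,
        fractions=fractions,
        provenance=provenance,
    )


def write_report(report: QCReport, out_dir: str | Path) -> Path:
    """Write report.json plus the CSV bundle and a run log summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report.payload(), fh, indent=2, default=_json_default)
    report.features.to_csv(out / "features.csv", index=False)
    report.clusters.to_csv(out / "clusters.csv", index=False)
    with open(out / "cutpoint.json", "w") as fh:
        json.dump(report.threshold_classification, fh, indent=2, default=_json_default)
    if report.fractions is not None:
        report.fractions.to_csv(out / "fractions.csv")
    if report.composition_stats is not None:
        with open(out / "stats.json", "w") as fh:
            json.dump(report.composition_stats, fh, indent=2, default=_json_default)
    with open(out / "run.log", "w") as fh:
        fh.write(_summary_text(report))
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _summary_text(report: QCReport) -> str:
    lines = [
        f"organoid-qc {report.provenance.get('organoid_qc_version', '?')} report",
        f"selected features: {', '.join(report.selected_features) or '(none)'}",
        f"elbow chosen k: {report.elbow['chosen_k']}",
        f"k-means agreement: {report.cluster_agreement}",
        f"threshold classification: {report.threshold_classification}",
    ]
    if report.composition_stats:
        lines.append(
            "composition: median per-line MC CV "
            f"{report.composition_stats['median_line_cv_pct']:.2f}%, "
            f"CV of line means {report.composition_stats['cv_of_line_means_pct']:.2f}%"
        )
    return "\n".join(lines) + "\n"


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a flat key = value pipeline configuration file."""
    raw = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        raw[key.strip()] = val.strip()
    defaults = PipelineConfig()
    kwargs: dict = {}
    for key, val in raw.items():
        if not hasattr(defaults, key):
            raise ConfigurationError(f"unknown config key {key!r}")
        default = getattr(defaults, key)
        if isinstance(default, bool):
            kwargs[key] = val.lower() in ("1", "true", "yes")
        elif isinstance(default, int) and not isinstance(default, bool):
            kwargs[key] = int(val)
        elif isinstance(default, float):
            kwargs[key] = float(val)
        else:
            kwargs[key] = val or None
    return PipelineConfig(**kwargs)
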