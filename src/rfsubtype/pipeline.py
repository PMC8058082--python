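"""End-to-end orchestration: simulate -> subtype -> validate -> report.

``run_all`` executes the full analysis in a run directory with
deterministic per-stage seeds derived from a single global seed by fixed
offsets, and writes a manifest with the configuration and SHA-256
checksums of every numeric artifact so that reruns are verifiable
byte for byte. ``render_report`` re-renders the human-readable bundle from
stored artifacts without recomputation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rfsubtype import __version__
from rfsubtype.forest import score_external
from rfsubtype.markers import CONTRASTS, classify_contrast, compare_marker_panels, group_vector, marker_direction_tests
from rfsubtype.profiling import profile_subtypes
from rfsubtype.subtypes import discover_subtypes
from rfsubtype.synthetic import CLASS_BIOMARKER, AUX_CLASSES, CohortConfig, config_from_dict, generate_cohort, read_cohort, write_cohort

#: fixed per-stage seed offsets (stages can be rerun in isolation)
STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "subtype": 101,
    "classify": 211,
}

DEFAULT_CLASSES = (CLASS_BIOMARKER,) + AUX_CLASSES


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    n_trees: int = 4000
    k: int = 2
    drop_fraction: float = 0.1
    auc_tolerance: float = 0.005
    alpha_family: float = 1e-4
    alpha_marker: float = 0.05
    topk: int = 5
    proximity_mode: str = "all_trees"
    min_features: int = 5
    contrasts: tuple = CONTRASTS
    feature_classes: tuple = DEFAULT_CLASSES
    pooled: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_prefix: str | None = None  # read instead of simulating

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                if f.name == "cohort":
                    v = config_from_dict(v)
                elif f.name == "contrasts":
                    v = tuple(tuple(c) for c in v)
                elif isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrasts"] = [list(c) for c in self.contrasts]
        d["feature_classes"] = list(self.feature_classes)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(msg: str, log_path: Path | None = None) -> None:
    line = f"[rfsubtype] {msg}"
    print(line, file=sys.stderr)
    if log_path is not None:
        with open(log_path, "a") as fh:
            fh.write(line + "\n")


def run_all(config: RunConfig, out_dir: str) -> Path:
    """Execute every analysis stage; abort with the stage name on failure."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    artifacts: list[Path] = []
    stage = "setup"
    t0 = time.time()
    try:
        # --- simulate or load -------------------------------------------------
        stage = "simulate"
        if config.cohort_prefix is not None:
            cohort = read_cohort(config.cohort_prefix)
        else:
            cc = dataclasses.replace(config.cohort, seed=config.seed + STAGE_SEED_OFFSETS["simulate"])
            cohort = generate_cohort(cc)
        artifacts += [Path(p) for p in write_cohort(cohort, str(out / "cohort"))]
        _log(f"simulate: {len(cohort.subjects)} subjects, {cohort.values.shape[1]} features", log_path)

        # --- subtype discovery ------------------------------------------------
        stage = "subtype"
        result = discover_subtypes(
            cohort,
            n_trees=config.n_trees,
            seed=config.seed + STAGE_SEED_OFFSETS["subtype"],
            k=config.k,
            proximity_mode=config.proximity_mode,
        )
        sub_df = pd.DataFrame(
            {
                "subtype": result.labels,
                "silhouette": result.silhouettes.loc[result.labels.index],
            }
        )
        sub_df.index.name = "subject_id"
        sub_df.to_csv(out / "subtypes.csv")
        result.embedding.to_csv(out / "embedding.csv", index_label="subject_id")
        sil_df = result.silhouettes.to_frame()
        sil_df.index.name = "subject_id"
        sil_df.to_csv(out / "silhouettes.csv")
        cluster_sizes = result.labels.value_counts().sort_index()
        artifacts += [out / "subtypes.csv", out / "embedding.csv", out / "silhouettes.csv"]
        _log(f"subtype: sizes {cluster_sizes.to_dict()}, cost {result.total_cost:.3f}", log_path)

        # --- external validation scoring --------------------------------------
        stage = "external_validation"
        val = cohort.subset(role="validation")
        ext = {}
        if len(val.subjects):
            scores, roc = score_external(
                result.forest,
                val.values[result.forest.feature_ids],
                (val.subjects["group"] == "case").astype(int).to_numpy(),
            )
            ext = {"auc": roc.auc, "n": int(len(scores))}
            pd.DataFrame({"score": scores}).to_csv(out / "external_scores.csv", index_label="subject_id")
            artifacts.append(out / "external_scores.csv")
            _log(f"external validation AUC {roc.auc:.3f}", log_path)

        # --- clinical profiling -----------------------------------------------
        stage = "profile"
        report, pca, aux_table = profile_subtypes(cohort, result, alpha_family=config.alpha_family)
        report.table.to_csv(out / "summary_scale_comparisons.csv", index_label="variable")
        pca.loadings.to_csv(out / "pca_loadings.csv", index_label="variable")
        aux_table.to_csv(out / "subtype_characteristics.csv", index_label="variable")
        artifacts += [
            out / "summary_scale_comparisons.csv",
            out / "pca_loadings.csv",
            out / "subtype_characteristics.csv",
        ]
        _log(f"profile: PC1 fraction {report.table.attrs['pc1_variance_fraction']:.3f}", log_path)

        # --- per-class classification with shaving ----------------------------
        stage = "classify"
        groups = group_vector(cohort, result)
        disc = cohort.subset(role="discovery")
        auc_rows = []
        reports = {}
        class_list = list(config.feature_classes) + (["pooled"] if config.pooled else [])
        for ci, contrast in enumerate(config.contrasts):
            for fj, fclass in enumerate(class_list):
                rep = classify_contrast(
                    disc, groups, tuple(contrast),
                    feature_class=fclass,
                    n_trees=config.n_trees,
                    seed=config.seed + STAGE_SEED_OFFSETS["classify"] + 17 * ci + fj,
                    drop_fraction=config.drop_fraction,
                    min_features=config.min_features,
                    auc_tolerance=config.auc_tolerance,
                )
                reports[(tuple(contrast), fclass)] = rep
                auc_rows.append(
                    {
                        "contrast": f"{contrast[0]}_vs_{contrast[1]}",
                        "feature_class": fclass,
                        "auc": rep.auc,
                        "n_markers": rep.n_markers,
                    }
                )
                rep.trace.to_frame().to_csv(
                    out / f"shaving_{contrast[0]}_vs_{contrast[1]}_{fclass}.csv", index=False
                )
                artifacts.append(out / f"shaving_{contrast[0]}_vs_{contrast[1]}_{fclass}.csv")
        auc_matrix = pd.DataFrame(auc_rows).pivot(index="contrast", columns="feature_class", values="auc")
        auc_matrix.to_csv(out / "auc_matrix.csv")
        pd.DataFrame(auc_rows).to_csv(out / "classification_reports.csv", index=False)
        artifacts += [out / "auc_matrix.csv", out / "classification_reports.csv"]
        _log(f"classify: {len(auc_rows)} contrast x class models", log_path)

        # --- marker direction tests -------------------------------------------
        stage = "marker_tests"
        markers_by_contrast = {}
        for contrast in config.contrasts:
            rep = reports.get((tuple(contrast), CLASS_BIOMARKER))
            if rep is not None:
                markers_by_contrast[tuple(contrast)] = rep.importance_ranks[: config.topk]
        if markers_by_contrast:
            direction = marker_direction_tests(
                disc, groups, markers_by_contrast, alpha_fwer=config.alpha_marker
            )
            direction.to_csv(out / "marker_directions.csv", index=False)
            artifacts.append(out / "marker_directions.csv")
            _log(
                f"marker tests: m={direction.attrs['n_tests']}, "
                f"threshold {direction.attrs['threshold']:.6g}",
                log_path,
            )
        else:
            direction = None

        # --- panel comparison by CCA ------------------------------------------
        stage = "panel_cca"
        cca_summary = None
        rep_severe = reports.get((("S2", "HC"), CLASS_BIOMARKER))
        rep_case = reports.get((("case", "HC"), CLASS_BIOMARKER))
        if rep_severe is not None and rep_case is not None:
            pa, pb = rep_severe.importance_ranks, rep_case.importance_ranks
            if set(pa) - set(pb) and set(pb) - set(pa):
                res = compare_marker_panels(disc.values, pa, pb)
                cca_summary = {
                    "correlations": [float(c) for c in res.correlations],
                    "n_panel_a": len(set(pa) - set(pb)),
                    "n_panel_b": len(set(pb) - set(pa)),
                }
                with open(out / "panel_cca.json", "w") as fh:
                    json.dump(cca_summary, fh, indent=2, sort_keys=True)
                artifacts.append(out / "panel_cca.json")
                _log(f"panel CCA: {cca_summary['correlations']}", log_path)

        # --- manifest + summary ------------------------------------------------
        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "stage_seed_offsets": STAGE_SEED_OFFSETS,
            "checksums": {p.name: _sha256(p) for p in sorted(set(artifacts))},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

        summary = {
            "subtype_sizes": {str(k): int(v) for k, v in cluster_sizes.items()},
            "cluster_mean_silhouettes": result.cluster_mean_silhouettes,
            "external_validation": ext,
            "pc1_variance_fraction": report.table.attrs["pc1_variance_fraction"],
            "pc1_mean_ratio_s2_s1": report.table.attrs.get("pc1_mean_ratio_s2_s1"),
            "auc_matrix": {r["contrast"] + "/" + r["feature_class"]: r["auc"] for r in auc_rows},
            "panel_cca": cca_summary,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        _log(f"done in {time.time() - t0:.1f}s", log_path)
        return out
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


REPORT_SECTIONS = (
    ("Subtype assignments", "subtypes.csv"),
    ("Per-class AUC matrix", "auc_matrix.csv"),
    ("Summary-scale comparisons", "summary_scale_comparisons.csv"),
    ("Marker direction calls", "marker_directions.csv"),
)


def render_report(run_dir: str) -> Path:
    """Render report.md from stored artifacts; no recomputation, idempotent."""
    run = Path(run_dir)
    manifest_path = run / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"incomplete run: missing {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    missing = [n for n in manifest["checksums"] if not (run / n).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run: missing artifacts {missing}")
    stale = [n for n, h in manifest["checksums"].items() if _sha256(run / n) != h]
    if stale:
        raise RuntimeError(f"artifacts changed since the run: {stale}")

    lines = ["# Pipeline report", "", f"Package version {manifest['package_version']}.", ""]
    summary = json.loads((run / "summary.json").read_text()) if (run / "summary.json").exists() else {}
    if summary:
        lines += ["## Headline numbers", "", "```json", json.dumps(summary, indent=2, sort_keys=True), "```", ""]
    for title, name in REPORT_SECTIONS:
        path = run / name
        if not path.exists():
            continue
        df = pd.read_csv(path)
        lines += [f"## {title}", "", "```", df.head(40).to_string(index=False), "```", ""]
    text = "\n".join(lines)
    out = run / "report.md"
    out.write_text(text)
    return out
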