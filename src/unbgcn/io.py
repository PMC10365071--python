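"""Readers, writers, run configuration and the end-to-end pipeline.

On-disk cohort layout (all plain text)::

    <cohort>/
      thickness/<subject>.tsv            roi_id  vertex_id  thickness_mm
      thickness_followup/<subject>.tsv   (optional, same structure)
      phenotypes.csv                     subject,age,gender,apoe4_count,amyloid
      labels.csv                         subject,label
      manifest.json                      generative settings + seed

``run_pipeline`` ties the stages together: simulate/load -> GLM adjustment ->
atrophy patterns -> UNB features -> phenotype graph -> transductive GCN
cross-validation -> attention ROI ranking -> longitudinal statistics, and
writes every artifact (UNB CSVs, adjacency MTX, checkpoint JSON, metrics,
attention ranking, stats, log) under the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from . import atlas
from .biomarker import ThicknessDataset, longitudinal_unb_matrices
from .cohort import CohortConfig, SyntheticCohort, cohort_manifest, generate_cohort
from .gcn import (
    ModelConfig,
    cross_validate,
    model_to_dict,
    rank_roi_attention,
    train,
)
from .popgraph import EdgeSpec, PopulationGraph, build_adjacency
from .stats import C_DEFAULT, min_sample_size, paired_test, roc_auc

logger = logging.getLogger("unbgcn")


class PipelineStageError(RuntimeError):
    """Wraps an exception with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# cohort directory I/O
# ---------------------------------------------------------------------------


def _write_thickness(ds: ThicknessDataset, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    roi_col = np.repeat(ds.roi_names, ds.vertex_counts)
    vid_col = np.concatenate([np.arange(c) for c in ds.vertex_counts])
    for i, subject in enumerate(ds.subjects):
        df = pd.DataFrame(
            {"roi_id": roi_col, "vertex_id": vid_col, "thickness_mm": ds.values[i]}
        )
        df.to_csv(directory / f"{subject}.tsv", sep="\t", index=False,
                  float_format="%.17g")


def write_cohort(cohort: SyntheticCohort, path: str | Path) -> Path:
    """Write a cohort to the documented directory layout; returns the path."""
    path = Path(path)
    _write_thickness(cohort.thickness, path / "thickness")
    if cohort.thickness_followup is not None:
        _write_thickness(cohort.thickness_followup, path / "thickness_followup")
    phen = cohort.phenotypes.copy()
    phen["amyloid"] = cohort.amyloid_status.loc[phen["subject"]].to_numpy()
    phen.to_csv(path / "phenotypes.csv", index=False, float_format="%.17g")
    cohort.labels.rename_axis("subject").reset_index().to_csv(
        path / "labels.csv", index=False
    )
    manifest = {
        "config": cohort_manifest(cohort.config) if cohort.config else None,
        "affected_rois": cohort.affected_rois.tolist(),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_thickness_dir(path: str | Path, atlas_mode: bool = False) -> ThicknessDataset:
    """Read per-subject TSVs, validating a shared (ROI, vertex) structure.

    With ``atlas_mode`` the ROI names must be exactly the 34 left-hemisphere
    Desikan-Killiany regions.
    """
    path = Path(path)
    files = sorted(path.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no thickness TSV files under {path}")
    structure = None
    subjects, rows = [], []
    for f in files:
        subject = f.stem
        df = pd.read_csv(f, sep="\t", float_precision="round_trip")
        for col in ("roi_id", "vertex_id", "thickness_mm"):
            if col not in df.columns:
                raise ValueError(f"subject {subject!r}: missing column {col!r}")
        # preserve file order of ROIs; sizes per ROI
        roi_names = list(dict.fromkeys(df["roi_id"]))
        counts = df.groupby("roi_id", sort=False).size()
        this = [(r, int(counts[r])) for r in roi_names]
        if structure is None:
            structure = this
        elif this != structure:
            theirs = dict(this)
            ours = dict(structure)
            for roi in ours:
                if roi not in theirs:
                    raise ValueError(f"subject {subject!r}: missing ROI {roi!r}")
                if theirs[roi] != ours[roi]:
                    raise ValueError(
                        f"subject {subject!r}: ROI {roi!r} has {theirs[roi]} "
                        f"vertices, expected {ours[roi]}"
                    )
            extra = [r for r in theirs if r not in ours]
            raise ValueError(f"subject {subject!r}: unexpected ROI(s) {extra}")
        subjects.append(subject)
        rows.append(df["thickness_mm"].to_numpy(dtype=float))
    roi_names = [r for r, _ in structure]
    if atlas_mode:
        atlas.validate_roi_names(roi_names)
    return ThicknessDataset(
        subjects=subjects,
        roi_names=roi_names,
        vertex_counts=np.array([c for _, c in structure]),
        values=np.vstack(rows),
    )


def read_cohort(path: str | Path, atlas_mode: bool = False) -> SyntheticCohort:
    """Read a cohort directory back into memory (inverse of write_cohort)."""
    path = Path(path)
    thickness = read_thickness_dir(path / "thickness", atlas_mode=atlas_mode)
    followup = None
    if (path / "thickness_followup").is_dir():
        followup = read_thickness_dir(path / "thickness_followup", atlas_mode=atlas_mode)
    phen = pd.read_csv(path / "phenotypes.csv", float_precision="round_trip")
    labels_df = pd.read_csv(path / "labels.csv")
    labels = pd.Series(
        labels_df["label"].to_numpy(), index=labels_df["subject"], name="label"
    )
    amyloid = pd.Series(
        phen["amyloid"].to_numpy() if "amyloid" in phen else "+",
        index=phen["subject"],
        name="amyloid",
    )
    manifest = {}
    if (path / "manifest.json").exists():
        manifest = json.loads((path / "manifest.json").read_text())
    affected = np.asarray(manifest.get("affected_rois", []), dtype=int)
    cfg = manifest.get("config")
    if cfg is not None:
        cfg["vertices_per_roi"] = (
            tuple(cfg["vertices_per_roi"])
            if isinstance(cfg["vertices_per_roi"], list)
            else cfg["vertices_per_roi"]
        )
        cfg["longitudinal_decline"] = tuple(cfg["longitudinal_decline"])
        cfg = CohortConfig(**cfg)
    return SyntheticCohort(
        thickness=thickness,
        thickness_followup=followup,
        phenotypes=phen.drop(columns=["amyloid"], errors="ignore"),
        labels=labels.loc[thickness.subjects],
        amyloid_status=amyloid.loc[thickness.subjects],
        affected_rois=affected,
        config=cfg,
    )


def write_adjacency(W: np.ndarray, path: str | Path) -> None:
    mmwrite(str(path), csr_matrix(W))


def read_adjacency(path: str | Path) -> np.ndarray:
    return np.asarray(mmread(str(path)).todense())


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    output_dir: str = "unbgcn_run"
    simulate: bool = True
    cohort_dir: str | None = None        # load mode
    atlas_mode: bool = True
    task: str = "AD_vs_CU"               # or "AD_vs_MCI"
    theta: float = 2.0
    n_repeats: int = 10
    test_fraction: float = 0.1
    power_constant: float = C_DEFAULT
    n_bootstrap: int = 2000
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["cohort"] = cohort_manifest(self.cohort)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        cfg = d.pop("cohort")
        cfg["vertices_per_roi"] = (
            tuple(cfg["vertices_per_roi"])
            if isinstance(cfg["vertices_per_roi"], list)
            else cfg["vertices_per_roi"]
        )
        cfg["longitudinal_decline"] = tuple(cfg["longitudinal_decline"])
        d["cohort"] = CohortConfig(**cfg)
        d["model"] = ModelConfig(**d["model"])
        return cls(**d)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all artifacts; returns a summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    (out / "config.json").write_text(config.to_json())

    try:
        with _stage("cohort"):
            if config.simulate:
                cohort = generate_cohort(
                    dataclasses.replace(config.cohort, seed=config.seed)
                )
            else:
                if config.cohort_dir is None or not Path(config.cohort_dir).exists():
                    raise FileNotFoundError("cohort_dir missing in load mode")
                cohort = read_cohort(config.cohort_dir, atlas_mode=config.atlas_mode)
            if config.atlas_mode:
                atlas.validate_roi_names(cohort.thickness.roi_names)
            logger.info(
                "cohort: %d subjects, %d ROIs, label counts %s",
                cohort.thickness.n_subjects,
                cohort.thickness.n_rois,
                cohort.labels.value_counts().to_dict(),
            )

        with _stage("unb"):
            ad = cohort.group_subjects("AD")
            cu = cohort.group_subjects("CU")
            followup = cohort.thickness_followup or cohort.thickness
            unb_base, unb_fu = longitudinal_unb_matrices(
                cohort.thickness, followup, cohort.phenotypes, ad, cu
            )
            unb_base.rename_axis("subject").to_csv(out / "unb_baseline.csv")
            unb_fu.rename_axis("subject").to_csv(out / "unb_followup.csv")
            logger.info("UNB matrix: %s", unb_base.shape)

        with _stage("graph"):
            g1, g2 = config.task.split("_vs_")
            task_subjects = [s for s in cohort.subjects if cohort.labels[s] in (g1, g2)]
            phen = (
                cohort.phenotypes.set_index("subject").loc[task_subjects].reset_index()
            )
            spec = EdgeSpec.default(theta=config.theta)
            W = build_adjacency(phen, spec)
            write_adjacency(W, out / "adjacency.mtx")
            X = unb_fu.loc[task_subjects].to_numpy()
            y = cohort.labels.loc[task_subjects].to_numpy()

        with _stage("train"):
            model_cfg = dataclasses.replace(config.model, seed=config.seed)
            cv = cross_validate(
                X,
                phen,
                y,
                model_cfg,
                edge_spec=spec,
                n_repeats=config.n_repeats,
                test_fraction=config.test_fraction,
                positive_class=g1,
            )
            table = cv["per_split"].copy()
            table.loc["mean"] = cv["mean"]
            table.loc["sd"] = cv["sd"]
            table.to_csv(out / "metrics.csv")
            logger.info("CV mean: %s", cv["mean"].to_dict())

            classes = sorted(set(y))
            enc = np.array([classes.index(v) for v in y])
            full_graph = PopulationGraph(
                X=X,
                W=W,
                labels=enc,
                train_mask=np.ones(len(y), dtype=bool),
                test_mask=np.zeros(len(y), dtype=bool),
                phenotypes=phen,
            )
            final = train(full_graph, model_cfg)
            for e in range(0, len(final.history), 20):
                logger.info("epoch %d loss %.6f", e, final.history[e])
            (out / "checkpoint.json").write_text(
                json.dumps(model_to_dict(final), sort_keys=True)
            )

        with _stage("attention"):
            if model_cfg.attention_enabled:
                ranking = rank_roi_attention(final, X, list(unb_fu.columns))
                ranking.to_csv(out / "attention.csv", index=False)

        with _stage("stats"):
            stats_rows = []
            total_base = unb_base.sum(axis=1)
            total_fu = unb_fu.sum(axis=1)
            for grp in ("AD", "MCI", "CU"):
                subs = cohort.group_subjects(grp)
                if len(subs) < 2:
                    continue
                b = total_base.loc[subs].to_numpy()
                f = total_fu.loc[subs].to_numpy()
                p, d = paired_test(b, f)
                n_min = min_sample_size(b, f, C=config.power_constant)
                stats_rows.append(
                    {
                        "group": grp,
                        "n": len(subs),
                        "mean_change": float((f - b).mean()),
                        "p_paired": p,
                        "cohens_d": d,
                        "min_sample_size": n_min,
                    }
                )
            stats_df = pd.DataFrame(stats_rows)
            roc = None
            if ad and cu:
                scores = total_fu.loc[ad + cu].to_numpy()
                lab = np.array([1] * len(ad) + [0] * len(cu))
                roc = roc_auc(
                    scores, lab, n_boot=config.n_bootstrap, seed=config.seed
                )
            stats_df.to_csv(out / "stats.csv", index=False)
            sidecar = {
                "seed": config.seed,
                "power_constant": config.power_constant,
                "n_bootstrap": config.n_bootstrap,
                "auc_total_unb_ad_cu": None if roc is None else roc["auc"],
                "auc_ci": None if roc is None else list(roc["ci"]),
            }
            (out / "stats.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    finally:
        logger.removeHandler(handler)
        handler.close()

    return {
        "output_dir": str(out),
        "cv_mean": cv["mean"].to_dict(),
        "cv_sd": cv["sd"].to_dict(),
        "stats": stats_df,
        "auc": None if roc is None else roc["auc"],
        "auc_ci": None if roc is None else roc["ci"],
        "unb_baseline": unb_base,
        "unb_followup": unb_fu,
        "model": final,
    }
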