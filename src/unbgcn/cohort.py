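"""Synthetic cohorts with the statistical structure the biomarker assumes.

No public dataset ships with this package, so every downstream stage is
exercised on simulated cohorts that emulate the relevant properties of
FreeSurfer-processed structural MRI: vertex-wise cortical thickness on the
34 left-hemisphere Desikan-Killiany regions, group-level atrophy on a subset
of "affected" regions (AD > MCI > 0), linear age and gender covariate
effects, subject-level heterogeneity, measurement noise, and a 24-month
follow-up with group-specific global thinning.

Defaults mirror an amyloid-positive longitudinal cohort of 84 AD, 102 MCI
and 132 CU subjects; see the methods note for the rationale behind the
effect magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .atlas import DESIKAN_KILLIANY_LH
from .biomarker import ThicknessDataset
from .popgraph import PopulationGraph


@dataclass
class CohortConfig:
    """Generative parameters of a synthetic cohort (all thickness in mm)."""

    n_ad: int = 84
    n_mci: int = 102
    n_cu: int = 132
    n_rois: int = 34
    vertices_per_roi: int | tuple[int, ...] = 100
    atrophy_effect_ad: float = 0.30    # thinning on affected ROIs
    atrophy_effect_mci: float = 0.15
    age_slope: float = -0.01           # mm per year
    gender_offset: float = 0.05        # additive for the second gender level
    noise_sd: float = 0.20             # vertex-level measurement noise
    subject_sd: float = 0.05           # per-subject global thickness offset
    longitudinal_decline: tuple[float, float, float] = (0.10, 0.05, 0.02)  # AD, MCI, CU mm/24mo
    decline_sd: float = 0.06           # between-subject SD of the 24-month decline
    affected_roi_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ad", "n_mci", "n_cu", "n_rois"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be nonnegative")
        if self.decline_sd < 0:
            raise ValueError("decline_sd must be nonnegative")
        if not 0.0 <= self.affected_roi_fraction <= 1.0:
            raise ValueError("affected_roi_fraction must be in [0, 1]")
        if np.isscalar(self.vertices_per_roi):
            if int(self.vertices_per_roi) < 1:
                raise ValueError("vertices_per_roi must be >= 1")
        elif len(self.vertices_per_roi) != self.n_rois:
            raise ValueError("vertices_per_roi list length must equal n_rois")

    def vertex_counts(self) -> np.ndarray:
        if np.isscalar(self.vertices_per_roi):
            return np.full(self.n_rois, int(self.vertices_per_roi))
        return np.asarray(self.vertices_per_roi, dtype=int)

    def roi_names(self) -> list[str]:
        if self.n_rois == 34:
            return list(DESIKAN_KILLIANY_LH)
        return [f"roi_{k:02d}" for k in range(self.n_rois)]


@dataclass
class SyntheticCohort:
    """A generated cohort: baseline + 24-month thickness, phenotypes, labels."""

    thickness: ThicknessDataset
    thickness_followup: ThicknessDataset
    phenotypes: pd.DataFrame  # subject, age, gender, apoe4_count
    labels: pd.Series         # AD / MCI / CU, indexed by subject
    amyloid_status: pd.Series
    affected_rois: np.ndarray
    config: CohortConfig = field(repr=False, default=None)

    @property
    def subjects(self) -> list[str]:
        return self.thickness.subjects

    def group_subjects(self, group: str) -> list[str]:
        return [s for s in self.subjects if self.labels[s] == group]


_GROUPS = ("AD", "MCI", "CU")
_APOE_P = {  # e4 allele-count probabilities by group, enriched in AD
    "AD": (0.30, 0.50, 0.20),
    "MCI": (0.45, 0.40, 0.15),
    "CU": (0.60, 0.35, 0.05),
}


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort; identical config + seed gives bit-identical output.

    Per subject s in group g, the thickness at vertex v is

        base(v) + age_slope*(age_s - mean age) + gender_offset*1[male]
        - effect_g * 1[v in affected ROI] + subject_offset_s + noise

    and the follow-up subtracts a per-subject global 24-month decline
    (group mean plus between-subject heterogeneity ``decline_sd``) and
    redraws the measurement noise (same subject offset: heterogeneity is a
    trait, noise is per-scan).
    """
    rng = np.random.default_rng(config.seed)
    counts = config.vertex_counts()
    total = int(counts.sum())
    roi_of_vertex = np.repeat(np.arange(config.n_rois), counts)

    # fixed anatomy, shared across subjects (vertex correspondence)
    roi_base = 2.5 + 0.2 * rng.standard_normal(config.n_rois)
    vertex_base = roi_base[roi_of_vertex] + 0.1 * rng.standard_normal(total)

    n_aff = int(round(config.affected_roi_fraction * config.n_rois))
    affected = np.sort(rng.choice(config.n_rois, size=n_aff, replace=False))
    affected_mask = np.isin(roi_of_vertex, affected).astype(float)

    n = config.n_ad + config.n_mci + config.n_cu
    groups = np.repeat(_GROUPS, (config.n_ad, config.n_mci, config.n_cu))
    subjects = [f"sub-{i:04d}" for i in range(n)]

    ages = np.clip(rng.normal(74.0, 6.0, size=n), 55.0, 90.0)
    genders = rng.choice(["F", "M"], size=n)
    apoe = np.array(
        [rng.choice(3, p=_APOE_P[g]) for g in groups], dtype=int
    )
    effect = np.select(
        [groups == "AD", groups == "MCI"],
        [config.atrophy_effect_ad, config.atrophy_effect_mci],
        default=0.0,
    )
    decline = np.select(
        [groups == "AD", groups == "MCI"],
        [config.longitudinal_decline[0], config.longitudinal_decline[1]],
        default=config.longitudinal_decline[2],
    )
    subj_offset = config.subject_sd * rng.standard_normal(n)
    decline = decline + config.decline_sd * rng.standard_normal(n)

    fixed = (
        vertex_base[None, :]
        + config.age_slope * (ages - ages.mean())[:, None]
        + config.gender_offset * (genders == "M")[:, None]
        - effect[:, None] * affected_mask[None, :]
        + subj_offset[:, None]
    )
    baseline = fixed + config.noise_sd * rng.standard_normal((n, total))
    followup = (
        fixed - decline[:, None] + config.noise_sd * rng.standard_normal((n, total))
    )

    mk = dict(
        roi_names=config.roi_names(),
        vertex_counts=counts,
    )
    phen = pd.DataFrame(
        {"subject": subjects, "age": ages, "gender": genders, "apoe4_count": apoe}
    )
    labels = pd.Series(groups, index=subjects, name="label")
    amyloid = pd.Series(
        np.where(groups == "CU", "-", "+"), index=subjects, name="amyloid"
    )
    return SyntheticCohort(
        thickness=ThicknessDataset(subjects=subjects, values=baseline, **mk),
        thickness_followup=ThicknessDataset(subjects=subjects, values=followup, **mk),
        phenotypes=phen,
        labels=labels,
        amyloid_status=amyloid,
        affected_rois=affected,
        config=config,
    )


def planted_feature_graph(
    n_per_class: int,
    separation: float,
    seed: int,
    n_features: int = 34,
    informative_features: int | None = None,
    test_fraction: float = 0.3,
) -> PopulationGraph:
    """Two-class Gaussian node features on a phenotype-similarity graph.

    Class mean vectors are `separation` apart in Euclidean norm with unit
    isotropic covariance; by default the shift is spread evenly over all
    features, or concentrated on the first ``informative_features`` columns.
    Phenotypes are drawn so that within-class phenotype similarity exceeds
    between-class similarity on average, but only weakly (through a mildly
    class-enriched APOE distribution; ages and genders are class
    independent): the class signal lives in the node features, and with
    ``separation = 0`` the graph alone cannot recover the labels.  Masks are
    a stratified split with ``test_fraction`` held out.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    labels = np.repeat([0, 1], n_per_class)

    shift = np.zeros(n_features)
    k = informative_features if informative_features is not None else n_features
    shift[:k] = separation / np.sqrt(k)
    X = rng.standard_normal((n, n_features)) + labels[:, None] * shift[None, :]

    ages = rng.uniform(55.0, 90.0, size=n)
    genders = rng.choice(["F", "M"], size=n)
    apoe = np.array(
        [
            rng.choice(3, p=(0.5, 0.35, 0.15) if y == 0 else (0.35, 0.35, 0.3))
            for y in labels
        ]
    )
    phen = pd.DataFrame({"age": ages, "gender": genders, "apoe4_count": apoe})

    from .popgraph import EdgeSpec, build_adjacency

    W = build_adjacency(phen, EdgeSpec.default())

    n_test = max(1, int(round(test_fraction * n_per_class)))
    test = np.zeros(n, dtype=bool)
    for c in (0, 1):
        idx = rng.permutation(np.flatnonzero(labels == c))
        test[idx[:n_test]] = True
    return PopulationGraph(
        X=X,
        W=W,
        labels=labels,
        train_mask=~test,
        test_mask=test,
        phenotypes=phen,
        feature_names=[f"f{i:02d}" for i in range(n_features)],
        class_names=["class0", "class1"],
        subjects=[f"node-{i:03d}" for i in range(n)],
    )


def cohort_manifest(config: CohortConfig) -> dict:
    """JSON-serializable record of the generative settings."""
    d = asdict(config)
    if not np.isscalar(d["vertices_per_roi"]):
        d["vertices_per_roi"] = list(map(int, d["vertices_per_roi"]))
    d["longitudinal_decline"] = list(map(float, d["longitudinal_decline"]))
    return d
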