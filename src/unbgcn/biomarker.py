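"""Univariate neurodegeneration biomarker (UNB) from vertex-wise cortical thickness.

The biomarker quantifies, per anatomical region, how similar an individual's
cortical-thinning pattern is to the average pattern of an amyloid-positive
AD group.  The pipeline is:

1. Adjust vertex-wise thickness for age and gender with a per-vertex
   ordinary-least-squares model (diagnostic group, when present, is kept in
   the design so group differences are not regressed away).
2. Compute a vertex-wise *group* atrophy pattern: a two-sample t statistic
   (AD minus cognitively-unimpaired reference), mapped to z-scores.
3. Compute a vertex-wise *individual* atrophy pattern: a one-vs-reference
   t statistic against the CU reference mean, mapped to z-scores.
4. Per ROI k with m_k vertices, the biomarker is the inner product of the
   two z-maps divided by 100:

       UNB_k = (sum_i Z_group,k,i * Z_indiv,k,i) / 100

Cortical thinning makes both z-maps negative at affected vertices, so a
more AD-like individual scores a *larger* (more positive) UNB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

UNB_SCALE = 100.0  # fixed divisor of the ROI inner product


class DegenerateDesignError(ValueError):
    """Raised when the covariate design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ThicknessDataset:
    """Vertex-wise cortical thickness for a set of subjects.

    ``values`` has shape ``(n_subjects, total_vertices)``; vertices are laid
    out ROI-by-ROI in the order of ``roi_names`` with ``vertex_counts[k]``
    vertices for ROI k.  All subjects share this vertex correspondence.
    """

    subjects: list[str]
    roi_names: list[str]
    vertex_counts: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.vertex_counts = np.asarray(self.vertex_counts, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x vertices)")
        if self.values.shape[0] != len(self.subjects):
            raise ValueError("row count does not match number of subjects")
        if self.values.shape[1] != int(self.vertex_counts.sum()):
            raise ValueError("column count does not match total vertex count")
        if len(self.roi_names) != len(self.vertex_counts):
            raise ValueError("roi_names and vertex_counts lengths differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("thickness values must be finite")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def total_vertices(self) -> int:
        return int(self.vertex_counts.sum())

    def roi_slices(self) -> list[slice]:
        edges = np.concatenate([[0], np.cumsum(self.vertex_counts)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def roi_of_vertex(self) -> np.ndarray:
        """ROI index for every vertex column."""
        return np.repeat(np.arange(self.n_rois), self.vertex_counts)

    def subset(self, subjects: list[str]) -> "ThicknessDataset":
        idx = [self.subjects.index(s) for s in subjects]
        return ThicknessDataset(
            subjects=list(subjects),
            roi_names=list(self.roi_names),
            vertex_counts=self.vertex_counts.copy(),
            values=self.values[idx].copy(),
        )

    def same_structure(self, other: "ThicknessDataset") -> bool:
        return (
            self.roi_names == other.roi_names
            and np.array_equal(self.vertex_counts, other.vertex_counts)
        )


@dataclass
class AtrophyPattern:
    """Vertex-wise z-score map; ``kind`` is ``"group"`` or ``"individual"``."""

    roi_names: list[str]
    vertex_counts: np.ndarray
    z: np.ndarray
    kind: str
    df: float

    def __post_init__(self) -> None:
        self.vertex_counts = np.asarray(self.vertex_counts, dtype=int)
        self.z = np.asarray(self.z, dtype=float)
        if self.kind not in ("group", "individual"):
            raise ValueError("kind must be 'group' or 'individual'")
        if self.z.shape != (int(self.vertex_counts.sum()),):
            raise ValueError("z length does not match vertex structure")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z-scores must be finite")

    def roi_slices(self) -> list[slice]:
        edges = np.concatenate([[0], np.cumsum(self.vertex_counts)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def same_structure(self, other: "AtrophyPattern") -> bool:
        return (
            self.roi_names == other.roi_names
            and np.array_equal(self.vertex_counts, other.vertex_counts)
        )


@dataclass
class UNBVector:
    """Per-ROI biomarker scores for one subject."""

    subject: str
    roi_names: list[str]
    unb: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.unb = np.asarray(self.unb, dtype=float)
        if self.unb.shape != (len(self.roi_names),):
            raise ValueError("unb length must equal number of ROIs")
        if not np.all(np.isfinite(self.unb)):
            raise ValueError("UNB values must be finite")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _align_covariates(cov: pd.DataFrame, thickness: ThicknessDataset) -> pd.DataFrame:
    cov = cov.copy()
    if "subject" in cov.columns:
        cov = cov.set_index("subject").loc[thickness.subjects].reset_index()
    if len(cov) != thickness.n_subjects:
        raise ValueError("covariate table does not cover every subject")
    for c in ("age", "gender"):
        if cov[c].isna().any():
            raise ValueError(f"missing values in covariate '{c}'")
    return cov


@dataclass
class GLMAdjuster:
    """Per-vertex age/gender nuisance model, fit once and applicable anywhere.

    Stores the fitted age slope and gender-dummy coefficients per vertex,
    centered at the fitting sample's covariate means, so applying the model
    returns thickness evaluated at those mean covariates.
    """

    beta_age: np.ndarray
    gender_levels: list[str]
    beta_gender: np.ndarray  # (n_levels, V)
    age_center: float
    gender_center: np.ndarray  # (n_levels,)

    @classmethod
    def fit(
        cls,
        thickness: ThicknessDataset,
        covariates: pd.DataFrame,
        include_group: bool = False,
    ) -> "GLMAdjuster":
        cov = _align_covariates(covariates, thickness)
        if len(cov) < 3:
            raise ValueError("need at least 3 subjects to fit the GLM")
        cols = [np.ones(len(cov))]
        names = ["intercept"]
        age = cov["age"].to_numpy(dtype=float)
        cols.append(age - age.mean())
        names.append("age")
        gdum = pd.get_dummies(cov["gender"], drop_first=True)
        g_center = []
        for c in gdum.columns:
            g = gdum[c].to_numpy(dtype=float)
            cols.append(g - g.mean())
            names.append(f"gender[{c}]")
            g_center.append(g.mean())
        if include_group and "group" in cov.columns:
            for c in pd.get_dummies(cov["group"], drop_first=True).columns:
                g = pd.get_dummies(cov["group"], drop_first=True)[c].to_numpy(dtype=float)
                cols.append(g - g.mean())
                names.append(f"group[{c}]")
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1] or len(gdum.columns) == 0:
            raise DegenerateDesignError(
                "covariate design is rank deficient (e.g. a single gender present)"
            )
        beta, *_ = np.linalg.lstsq(X, thickness.values, rcond=None)
        levels = list(gdum.columns)
        return cls(
            beta_age=beta[names.index("age")],
            gender_levels=levels,
            beta_gender=np.vstack(
                [beta[names.index(f"gender[{c}]")] for c in levels]
            ),
            age_center=float(age.mean()),
            gender_center=np.asarray(g_center),
        )

    def apply(
        self, thickness: ThicknessDataset, covariates: pd.DataFrame
    ) -> ThicknessDataset:
        """Subtract the fitted age/gender contributions from *thickness*."""
        cov = _align_covariates(covariates, thickness)
        age_c = cov["age"].to_numpy(dtype=float) - self.age_center
        nuisance = np.outer(age_c, self.beta_age)
        gdum = pd.get_dummies(cov["gender"], drop_first=False)
        for i, level in enumerate(self.gender_levels):
            col = (
                gdum[level].to_numpy(dtype=float)
                if level in gdum.columns
                else np.zeros(len(cov))
            )
            nuisance += np.outer(col - self.gender_center[i], self.beta_gender[i])
        return ThicknessDataset(
            subjects=list(thickness.subjects),
            roi_names=list(thickness.roi_names),
            vertex_counts=thickness.vertex_counts.copy(),
            values=thickness.values - nuisance,
        )


def adjust_glm(
    thickness: ThicknessDataset,
    covariates: pd.DataFrame,
    fit_subjects: list[str] | None = None,
) -> ThicknessDataset:
    """Remove age and gender effects from thickness at every vertex.

    A per-vertex OLS model of thickness on centered age and gender (and, when
    a ``group`` column is present, group dummies, which are retained rather
    than removed) is fitted and the age/gender contributions are subtracted.
    Because the covariates are centered on the fitting sample, the output is
    thickness evaluated at the sample-mean age/gender — the intercept and any
    group effect survive.

    Parameters
    ----------
    thickness
        Dataset to adjust; rows must match ``covariates`` (indexed by the
        ``subject`` column or aligned by order).
    covariates
        Columns ``age`` (years), ``gender`` (categorical), optional ``group``.
    fit_subjects
        If given, coefficients are estimated on this subset only (e.g. the
        CU reference group) and then applied to every subject, with age and
        gender centered at the fitting subset's means.
    """
    cov = _align_covariates(covariates, thickness)
    if fit_subjects is None:
        adjuster = GLMAdjuster.fit(thickness, cov, include_group="group" in cov.columns)
    else:
        sub = thickness.subset(fit_subjects)
        sub_cov = cov.set_index("subject").loc[fit_subjects].reset_index() \
            if "subject" in cov.columns else cov.iloc[
                [thickness.subjects.index(s) for s in fit_subjects]
            ]
        adjuster = GLMAdjuster.fit(sub, sub_cov, include_group=False)
    return adjuster.apply(thickness, cov)


def t_to_z(t: np.ndarray | float, df: float) -> np.ndarray | float:
    """Map Student-t scores to standard-normal z-scores.

    z = Phi^{-1}(F_t(t; df)) — the probit of the t CDF.  Monotone, exact, and
    sign preserving; evaluated through the survival function on the positive
    branch for numerical stability at large |t|.
    """
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t scores must be finite")
    z = np.where(
        t_arr <= 0,
        sps.norm.ppf(sps.t.cdf(t_arr, df)),
        -sps.norm.ppf(sps.t.sf(t_arr, df)),
    )
    return z if np.ndim(t) else float(z)


def group_atrophy_pattern(ad: ThicknessDataset, cu: ThicknessDataset) -> AtrophyPattern:
    """Two-sample vertex-wise atrophy pattern, direction AD minus CU.

    Pooled-variance two-sample t at every vertex, df = n_AD + n_CU - 2, then
    the t->z probit map.  Negative z means the AD group is thinner there.
    """
    if not ad.same_structure(cu):
        raise ValueError("AD and CU datasets have different (ROI, vertex) structure")
    n1, n2 = ad.n_subjects, cu.n_subjects
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    m1 = ad.values.mean(axis=0)
    m2 = cu.values.mean(axis=0)
    v1 = ad.values.var(axis=0, ddof=1)
    v2 = cu.values.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    bad = np.flatnonzero(sp2 <= 0)
    if bad.size:
        raise ZeroDivisionError(f"zero pooled variance at vertex index {bad[0]}")
    df = n1 + n2 - 2
    t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return AtrophyPattern(
        roi_names=list(ad.roi_names),
        vertex_counts=ad.vertex_counts.copy(),
        z=np.asarray(t_to_z(t, df)),
        kind="group",
        df=float(df),
    )


def individual_atrophy_pattern(
    subject_values: np.ndarray, cu_reference: ThicknessDataset
) -> AtrophyPattern:
    """One-vs-reference atrophy pattern for a single subject.

    t_i = (x_i - mean_CU,i) / (sd_CU,i * sqrt(1 + 1/n_CU)) with df = n_CU - 1:
    the subject is treated as a new draw from the CU population (prediction
    standard error).  Negative z means the subject is thinner than reference.
    """
    x = np.asarray(subject_values, dtype=float).ravel()
    if x.shape[0] != cu_reference.total_vertices:
        raise ValueError("subject vertex count does not match the reference")
    n = cu_reference.n_subjects
    if n < 2:
        raise ValueError("reference needs at least 2 subjects")
    mu = cu_reference.values.mean(axis=0)
    sd = cu_reference.values.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        raise ZeroDivisionError(f"zero reference variance at vertex index {bad[0]}")
    t = (x - mu) / (sd * np.sqrt(1.0 + 1.0 / n))
    return AtrophyPattern(
        roi_names=list(cu_reference.roi_names),
        vertex_counts=cu_reference.vertex_counts.copy(),
        z=np.asarray(t_to_z(t, n - 1)),
        kind="individual",
        df=float(n - 1),
    )


def compute_unb(
    individual: AtrophyPattern, group: AtrophyPattern, subject: str = ""
) -> UNBVector:
    """Per-ROI inner product of the two z-maps, divided by 100."""
    if individual.kind != "individual" or group.kind != "group":
        raise ValueError("expected (individual, group) pattern kinds")
    if not individual.same_structure(group):
        mism = [
            n
            for n, a, b in zip(
                individual.roi_names,
                individual.vertex_counts,
                group.vertex_counts,
            )
            if a != b
        ] or ["<roi name lists differ>"]
        raise ValueError(f"pattern structure mismatch on ROIs: {mism}")
    prod = individual.z * group.z
    edges = np.concatenate([[0], np.cumsum(individual.vertex_counts)])
    unb = np.add.reduceat(prod, edges[:-1]) / UNB_SCALE
    return UNBVector(subject=subject, roi_names=list(individual.roi_names), unb=unb)


def unb_matrix(
    thickness: ThicknessDataset,
    covariates: pd.DataFrame,
    ad_subjects: list[str],
    cu_subjects: list[str],
    target_subjects: list[str] | None = None,
) -> pd.DataFrame:
    """UNB feature matrix (subjects x ROIs) for a whole cohort.

    The group pattern comes from an age/gender-adjusted fit on the pooled
    AD+CU sample (group retained in the design); individual patterns use a
    CU-only GLM fit applied to every target subject.
    """
    targets = target_subjects if target_subjects is not None else list(thickness.subjects)

    cov = covariates.copy()
    if "subject" not in cov.columns:
        cov.insert(0, "subject", thickness.subjects)

    # group-pattern path: pooled AD+CU adjustment with group retained
    pooled = thickness.subset(ad_subjects + cu_subjects)
    pooled_cov = cov.set_index("subject").loc[pooled.subjects].reset_index()
    pooled_cov["group"] = ["AD"] * len(ad_subjects) + ["CU"] * len(cu_subjects)
    pooled_adj = adjust_glm(pooled, pooled_cov)
    group = group_atrophy_pattern(
        pooled_adj.subset(ad_subjects), pooled_adj.subset(cu_subjects)
    )

    # individual path: CU-reference GLM fit applied to all subjects
    all_adj = adjust_glm(thickness, cov.drop(columns=["group"], errors="ignore"),
                         fit_subjects=cu_subjects)
    reference = all_adj.subset(cu_subjects)

    rows = []
    for s in targets:
        x = all_adj.values[all_adj.subjects.index(s)]
        indiv = individual_atrophy_pattern(x, reference)
        rows.append(compute_unb(indiv, group, subject=s).unb)
    return pd.DataFrame(np.vstack(rows), index=targets, columns=thickness.roi_names)


def longitudinal_unb_matrices(
    baseline: ThicknessDataset,
    followup: ThicknessDataset,
    covariates: pd.DataFrame,
    ad_subjects: list[str],
    cu_subjects: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """UNB matrices at baseline and follow-up against a fixed baseline frame.

    The group atrophy pattern and the CU reference distribution come from the
    baseline visit only; the age/gender nuisance model is fitted on the
    baseline CU subjects and applied unchanged to both visits, so follow-up
    UNB changes reflect longitudinal thinning, not a moving reference.
    """
    if not baseline.same_structure(followup):
        raise ValueError("baseline and follow-up vertex structure differ")
    cov = covariates.copy()
    if "subject" not in cov.columns:
        cov.insert(0, "subject", baseline.subjects)

    pooled = baseline.subset(ad_subjects + cu_subjects)
    pooled_cov = cov.set_index("subject").loc[pooled.subjects].reset_index()
    pooled_cov["group"] = ["AD"] * len(ad_subjects) + ["CU"] * len(cu_subjects)
    pooled_adj = adjust_glm(pooled, pooled_cov)
    group = group_atrophy_pattern(
        pooled_adj.subset(ad_subjects), pooled_adj.subset(cu_subjects)
    )

    cu_cov = cov.set_index("subject").loc[cu_subjects].reset_index()
    adjuster = GLMAdjuster.fit(baseline.subset(cu_subjects), cu_cov)
    base_adj = adjuster.apply(baseline, cov)
    fu_adj = adjuster.apply(followup, cov)
    reference = base_adj.subset(cu_subjects)

    def _matrix(ds: ThicknessDataset) -> pd.DataFrame:
        rows = [
            compute_unb(
                individual_atrophy_pattern(ds.values[i], reference), group, subject=s
            ).unb
            for i, s in enumerate(ds.subjects)
        ]
        return pd.DataFrame(np.vstack(rows), index=ds.subjects, columns=ds.roi_names)

    return _matrix(base_adj), _matrix(fu_adj)
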