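"""Drug-screen and cohort-comparison statistics.

The screening readout for each (cell subset, marker) feature is the
fractional difference (FD) of the treated median fluorescence intensity
against the vehicle control:

    FD = MFI_treatment / MFI_control - 1

so the control maps to 0, a doubling to +1 and a halving to -0.5; heatmaps
render FD in percent.  Per-feature inference compares the donor-level FD
replicates to 0 with a one-sample t-test (no multiplicity correction by
default, matching the raw-p star convention; Benjamini-Hochberg is available
as an option).  Extreme cells (|FD| > 150% strictly) are masked before
display and clustering.  Treatment columns are ordered by complete-linkage
hierarchical clustering on a pairwise-complete Euclidean distance rescaled
for missingness.

Cohort comparisons (cases vs controls) min-max normalise every feature,
drop the lowest-variance 10% of features, embed donors with 3-component PCA
and summarise group separation by the mean silhouette coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.cluster import hierarchy

__all__ = [
    "UndefinedTestError",
    "fractional_difference",
    "FDMatrix",
    "mask_outliers",
    "cluster_columns",
    "one_sample_t",
    "two_sample_t",
    "p_to_stars",
    "minmax_normalize",
    "variance_filter",
    "CohortEmbedding",
    "pca_embed",
    "separation_score",
    "screen",
    "ScreenResult",
    "cohort_compare",
    "CohortResult",
]

DEFAULT_OUTLIER_BOUND = 1.5  # fractional scale; equals +/-150% on heatmaps
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class UndefinedTestError(ValueError):
    """A test statistic is undefined (zero variance); never reported as p=0."""


def fractional_difference(mfi_treat, mfi_control):
    """FD = MFI_treatment / MFI_control - 1 (fractional scale).

    Accepts scalars or aligned arrays; missing treatment MFIs propagate as
    NaN, a non-positive control MFI is an error.
    """
    treat = np.asarray(mfi_treat, dtype=float)
    control = np.asarray(mfi_control, dtype=float)
    if np.any(np.nan_to_num(control, nan=1.0) <= 0):
        raise ValueError("control MFI must be > 0")
    out = treat / control - 1.0
    return float(out) if out.ndim == 0 else out


def p_to_stars(p: float) -> str:
    for thr, sym in STAR_THRESHOLDS:
        if p < thr:
            return sym
    return "ns"


@dataclass
class FDMatrix:
    """Mean-FD matrix (features x treatments) with mask and donor replicates.

    Rows are (subset, marker) features, columns treatments.  ``mask`` flags
    cells removed as outliers — flagged, never silently zeroed.  ``donor_fd``
    maps each treatment to its donors x features replicate table, retained
    for the per-feature tests.
    """

    values: pd.DataFrame
    mask: pd.DataFrame | None = None
    donor_fd: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self):
        if self.mask is None:
            self.mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if not self.mask.index.equals(self.values.index) or not self.mask.columns.equals(
            self.values.columns
        ):
            raise ValueError("mask must align with values")

    def masked_values(self) -> pd.DataFrame:
        """Values with masked cells as NaN (for display/clustering)."""
        return self.values.mask(self.mask)


def mask_outliers(fd: FDMatrix, bound: float = DEFAULT_OUTLIER_BOUND) -> FDMatrix:
    """Flag cells with FD < -bound or FD > bound (strict inequalities).

    Values exactly at +/-bound are retained.  Unmasked values are never
    altered; masking is idempotent.
    """
    if bound <= 0:
        raise ValueError("outlier bound must be > 0")
    extreme = (fd.values < -bound) | (fd.values > bound)
    return FDMatrix(fd.values.copy(), fd.mask | extreme, dict(fd.donor_fd))


def _masked_distance(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Condensed pairwise-complete Euclidean distance between columns.

    Distances computed on rows observed in both columns, rescaled by
    sqrt(total/observed) so sparser overlaps are not spuriously close.
    """
    n_rows, n_cols = values.shape
    ok = ~mask & np.isfinite(values)
    out = []
    for i in range(n_cols):
        for j in range(i + 1, n_cols):
            both = ok[:, i] & ok[:, j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"columns {i} and {j} share no unmasked rows; "
                    "clustering distance undefined"
                )
            d = values[both, i] - values[both, j]
            out.append(float(np.sqrt(np.sum(d * d) * n_rows / m)))
    return np.asarray(out)


@dataclass
class ColumnClustering:
    order: list[str]  # column labels, dendrogram leaf order
    linkage: np.ndarray  # scipy linkage matrix (merge heights in col 2)


def cluster_columns(fd: FDMatrix) -> ColumnClustering:
    """Complete-linkage hierarchical clustering of treatment columns."""
    cols = list(fd.values.columns)
    if len(cols) < 2:
        raise ValueError("clustering needs at least 2 columns")
    dist = _masked_distance(fd.values.to_numpy(), fd.mask.to_numpy())
    Z = hierarchy.linkage(dist, method="complete")
    order = [cols[i] for i in hierarchy.leaves_list(Z)]
    return ColumnClustering(order, Z)


def one_sample_t(values, mu: float = 0.0) -> tuple[float, int, float, str]:
    """Two-sided one-sample t-test of donor replicates against mu.

    Returns (t, df, p, stars) with df = n - 1 and stars at 0.05 / 0.01 /
    0.001.  Zero sample variance raises :class:`UndefinedTestError`.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("one-sample t-test needs n >= 2 replicates")
    if np.var(x, ddof=1) == 0:
        raise UndefinedTestError("zero variance across replicates; not testable")
    res = sstats.ttest_1samp(x, popmean=mu)
    t, p = float(res.statistic), float(res.pvalue)
    return t, x.size - 1, p, p_to_stars(p)


def two_sample_t(
    group_a, group_b, equal_var: bool = True
) -> tuple[float, float, float, str]:
    """Two-sided two-sample t-test (pooled-variance Student's form by default;
    set ``equal_var=False`` for Welch)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("two-sample t-test needs n >= 2 per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.median(a) == np.median(b):
            raise UndefinedTestError("both groups constant and equal; not testable")
    res = sstats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    df = a.size + b.size - 2 if equal_var else float(_welch_df(a, b))
    return t, df, p, p_to_stars(p)


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = np.var(a, ddof=1) / a.size, np.var(b, ddof=1) / b.size
    return (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))


def minmax_normalize(values):
    """(x - min) / (max - min) per feature; a constant feature maps to all 0
    (the 0/0 case of the formula, fixed by convention)."""
    x = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def variance_filter(matrix: pd.DataFrame, fraction: float = 0.10) -> list[str]:
    """Retained feature names after dropping the lowest-variance fraction.

    Exactly ``floor(fraction * F)`` features are removed; ties broken by
    original column order (stable sort). Deterministic.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    cols = list(matrix.columns)
    n_drop = int(np.floor(fraction * len(cols)))
    if n_drop == 0:
        return cols
    variances = matrix.var(axis=0, ddof=1).to_numpy()
    drop_idx = set(np.argsort(variances, kind="stable")[:n_drop])
    return [c for i, c in enumerate(cols) if i not in drop_idx]


@dataclass
class CohortEmbedding:
    scores: pd.DataFrame  # donors x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray
    retained_features: list[str]
    groups: pd.Series  # donor -> group label


def pca_embed(
    normalized: pd.DataFrame,
    groups: pd.Series,
    n_components: int = 3,
) -> CohortEmbedding:
    """Column-centred PCA of a donors x features matrix (already min-max
    normalised; no further re-scaling).

    Components are ordered by decreasing explained variance; the sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    from sklearn.decomposition import PCA

    if normalized.shape[0] < n_components + 1:
        raise ValueError(
            f"PCA with {n_components} components needs more than "
            f"{n_components} donors, got {normalized.shape[0]}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(normalized.to_numpy())
    loadings = pca.components_.T.copy()  # features x components
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return CohortEmbedding(
        scores=pd.DataFrame(scores, index=normalized.index, columns=comp_names),
        loadings=pd.DataFrame(
            loadings, index=normalized.columns, columns=comp_names
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
        retained_features=list(normalized.columns),
        groups=groups.loc[normalized.index],
    )


def separation_score(embedding: CohortEmbedding) -> float:
    """Mean silhouette coefficient of the group labels in component space.

    1 means perfectly separated compact groups, 0 indistinguishable groups,
    negative values systematic mixing.
    """
    from sklearn.metrics import silhouette_score

    labels = embedding.groups.to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("separation score needs at least 2 groups")
    if counts.min() < 2:
        raise ValueError("separation score needs >= 2 donors per group")
    return float(silhouette_score(embedding.scores.to_numpy(), labels))


# --- orchestration ---------------------------------------------------------


@dataclass
class ScreenResult:
    fd: FDMatrix  # masked mean-FD matrix
    tests: pd.DataFrame  # feature x treatment: mean_fd, t, df, p, stars
    clustering: ColumnClustering | None


def screen(
    mfi_long: pd.DataFrame,
    control: str = "DMSO",
    outlier_bound: float = DEFAULT_OUTLIER_BOUND,
    fdr: bool = False,
) -> ScreenResult:
    """Full drug-screen analysis from a long-format MFI table.

    ``mfi_long`` needs columns donor, condition, subset, marker, mfi.  Every
    donor's treated MFIs are referenced to that donor's own control, giving
    per-donor FD replicates per (subset, marker) feature; the reported matrix
    is the across-donor mean FD with the default +/-150% outlier mask, and
    each (feature, treatment) is tested against 0 across donors.  With
    ``fdr=True`` p-values are Benjamini-Hochberg adjusted before star
    annotation (off by default).
    """
    required = {"donor", "condition", "subset", "marker", "mfi"}
    missing = required - set(mfi_long.columns)
    if missing:
        raise ValueError(f"mfi table lacks columns: {sorted(missing)}")
    conditions = [c for c in mfi_long["condition"].unique() if c != control]
    if control not in set(mfi_long["condition"]):
        raise ValueError(f"control condition {control!r} absent from table")
    wide = mfi_long.pivot_table(
        index=["subset", "marker"],
        columns=["condition", "donor"],
        values="mfi",
        aggfunc="first",
        sort=False,
    )
    donors = sorted(mfi_long["donor"].unique())
    donor_fd: dict[str, pd.DataFrame] = {}
    mean_fd = {}
    for cond in conditions:
        cols = {}
        for d in donors:
            if (cond, d) not in wide.columns or (control, d) not in wide.columns:
                continue
            cols[d] = fractional_difference(
                wide[(cond, d)].to_numpy(), wide[(control, d)].to_numpy()
            )
        rep = pd.DataFrame(cols, index=wide.index).T  # donors x features
        donor_fd[cond] = rep
        mean_fd[cond] = rep.mean(axis=0, skipna=True)
    values = pd.DataFrame(mean_fd)
    fd = mask_outliers(FDMatrix(values, donor_fd=donor_fd), outlier_bound)

    rows = []
    for cond in conditions:
        rep = donor_fd[cond]
        for feat in rep.columns:
            x = rep[feat].to_numpy()
            entry = {
                "subset": feat[0],
                "marker": feat[1],
                "treatment": cond,
                "n_donors": int(np.isfinite(x).sum()),
                "mean_fd": float(np.nanmean(x)) if np.isfinite(x).any() else np.nan,
            }
            try:
                t, df, p, star = one_sample_t(x)
                entry.update({"t": t, "df": df, "p": p, "stars": star})
            except (UndefinedTestError, ValueError):
                entry.update({"t": np.nan, "df": np.nan, "p": np.nan, "stars": "nt"})
            rows.append(entry)
    tests = pd.DataFrame(rows)
    if fdr and tests["p"].notna().any():
        from statsmodels.stats.multitest import multipletests  # pragma: no cover

        ok = tests["p"].notna()
        adj = multipletests(tests.loc[ok, "p"], method="fdr_bh")[1]
        tests.loc[ok, "p"] = adj
        tests.loc[ok, "stars"] = [p_to_stars(p) for p in adj]
    clustering = cluster_columns(fd) if len(conditions) >= 2 else None
    return ScreenResult(fd, tests, clustering)


@dataclass
class CohortResult:
    embedding: CohortEmbedding
    separation: float
    tests: pd.DataFrame  # per-feature two-sample comparison


def cohort_compare(
    features: pd.DataFrame,
    groups: pd.Series,
    variance_fraction: float = 0.10,
    n_components: int = 3,
    equal_var: bool = True,
) -> CohortResult:
    """Two-group cohort comparison: min-max, variance filter, PCA, silhouette.

    ``features`` is donors x (subset, marker) feature values (MFIs); the
    min-max normalisation runs per feature across donors, then the
    lowest-variance 10% of normalised features are dropped, donors are
    embedded with 3-component PCA and the group separation is the mean
    silhouette of the labels.  Per-feature two-sample t-tests (raw features)
    accompany the embedding.
    """
    groups = groups.loc[features.index]
    normalized = features.apply(
        lambda col: pd.Series(minmax_normalize(col.to_numpy()), index=col.index),
        axis=0,
    )
    retained = variance_filter(normalized, variance_fraction)
    embedding = pca_embed(normalized[retained], groups, n_components)
    sep = separation_score(embedding)

    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError("cohort comparison expects exactly 2 groups")
    a_idx, b_idx = (groups == labels[0]), (groups == labels[1])
    rows = []
    for feat in features.columns:
        a = features.loc[a_idx, feat].to_numpy()
        b = features.loc[b_idx, feat].to_numpy()
        entry = {"feature": feat, "group_a": labels[0], "group_b": labels[1]}
        try:
            t, df, p, star = two_sample_t(a, b, equal_var=equal_var)
            entry.update({"t": t, "df": df, "p": p, "stars": star})
        except (UndefinedTestError, ValueError):
            entry.update({"t": np.nan, "df": np.nan, "p": np.nan, "stars": "nt"})
        rows.append(entry)
    return CohortResult(embedding, sep, pd.DataFrame(rows))
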