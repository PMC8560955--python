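"""Radiomic feature robustness: ICC(3,1), perturbation, bin selection, PCA.

The methodology quantifies how stable each texture feature is when the
gray-level quantization (or the ROI contour) changes:

* ``icc31`` — two-way mixed-effects, single-measurement, *consistency*
  intraclass correlation: (MS_R - MS_E) / (MS_R + (k-1) MS_E), where MS_R
  is the between-subject (row) mean square and MS_E the residual mean
  square after removing row and column effects;
* ``classify_robustness`` — Poor (<= 0.5), Moderate (<= 0.75),
  Good (<= 0.9), Excellent (> 0.9);
* ``perturb_roi`` — morphological opening/closing with the discrete
  radius-1 ball (the 7-voxel face-connected cross), emulating
  inter-reader contour variability;
* ``select_optimal_bins`` — the bin count whose perturbation-ICC yields
  the most Excellent features (ties broken toward fewer bins);
* ``pca_importance`` — eigendecomposition of the feature correlation
  matrix; per-feature importance is the quadrature sum of loadings on the
  first three principal components (eigenvalue-weighted by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

from .radiomics.table import FeatureTable

__all__ = [
    "ICCResult",
    "ImportanceRanking",
    "icc31",
    "classify_robustness",
    "icc_table",
    "perturb_roi",
    "select_optimal_bins",
    "pca_importance",
    "relative_difference",
    "robustness_report",
    "load_reference_icc",
    "ROBUSTNESS_CLASSES",
]

ROBUSTNESS_CLASSES = ("Poor", "Moderate", "Good", "Excellent")

# radius-1 ball: centre plus the 6 face neighbours (Euclidean distance <= 1)
BALL_R1 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class ICCResult:
    icc: float  # NaN when undefined (all-constant table)
    ms_r: float
    ms_e: float
    n: int
    k: int
    robustness: str | None  # None when undefined
    na_reason: str = ""


@dataclass(frozen=True)
class ImportanceRanking:
    features: list[str]
    eigenvalues: np.ndarray  # descending, all features
    loadings: np.ndarray  # features x 3 (unit-norm eigenvector columns)
    top3_variance_fraction: float
    importance: np.ndarray  # per feature
    rank: np.ndarray  # 1 = most important
    dropped: list[str]  # zero-variance features excluded

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "importance": self.importance,
                "rank": self.rank,
            }
        ).sort_values("rank")


def icc31(data: np.ndarray) -> ICCResult:
    """ICC(3,1): two-way mixed effects, consistency, single measurement.

    ``data`` is an n-subjects x k-measurements matrix.  The two-way ANOVA
    decomposition removes row (subject) and column (measurement-setting)
    effects; systematic column shifts therefore do not lower the ICC.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2D subjects x measurements matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 measurements, got {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError("non-finite entries in ICC input")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = max(ss_err, 0.0) / ((n - 1) * (k - 1))

    if ms_r == 0.0 and ms_e == 0.0:
        return ICCResult(
            icc=float("nan"), ms_r=0.0, ms_e=0.0, n=n, k=k,
            robustness=None, na_reason="all-constant table: ICC undefined",
        )
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    return ICCResult(
        icc=float(icc), ms_r=float(ms_r), ms_e=float(ms_e), n=n, k=k,
        robustness=classify_robustness(icc),
    )


def classify_robustness(icc: float) -> str:
    """Band an ICC value: Poor <= 0.5 < Moderate <= 0.75 < Good <= 0.9 < Excellent."""
    if np.isnan(icc):
        raise ValueError("cannot classify NaN ICC")
    if icc <= 0.5:
        return "Poor"
    if icc <= 0.75:
        return "Moderate"
    if icc <= 0.9:
        return "Good"
    return "Excellent"


def icc_table(
    table: FeatureTable,
    mode: str = "bins",
    roi_version: str = "original",
    n_bins: int | None = None,
) -> pd.DataFrame:
    """Per-feature ICC(3,1) across repeated measurements from a FeatureTable.

    ``mode='bins'``: the k repeated measurements are the bin settings (one
    ROI version, default the original contour).  ``mode='perturb'``: the k
    measurements are the ROI versions at one fixed bin setting.
    """
    rows = []
    for feature in table.features:
        if mode == "bins":
            mat = table.pivot(feature, columns="n_bins", roi_version=roi_version)
        elif mode == "perturb":
            if n_bins is None:
                raise ValueError("mode='perturb' requires n_bins")
            mat = table.pivot(feature, columns="roi_version", n_bins=n_bins)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        values = mat.to_numpy()
        if np.isnan(values).any():
            rows.append((feature, np.nan, np.nan, np.nan, None, "NA cells in table"))
            continue
        res = icc31(values)
        rows.append((feature, res.icc, res.ms_r, res.ms_e, res.robustness, res.na_reason))
    return pd.DataFrame(
        rows, columns=["feature", "icc", "ms_r", "ms_e", "robustness", "na_reason"]
    )


def perturb_roi(mask: np.ndarray) -> dict[str, np.ndarray]:
    """Original, opened and closed versions of a binary ROI mask.

    Opening and closing use the 3D spherical structuring element of
    1-voxel radius.  Opening never adds voxels and closing never removes
    them, so opened <= original <= closed voxelwise.  An opening that
    empties the mask is still returned (callers carry it as NA downstream).
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 3:
        raise ValueError("expected a 3D mask")
    if not m.any():
        raise ValueError("empty ROI mask")
    # pad before closing: the intermediate dilation must be allowed to grow
    # past the array border, or border voxels are wrongly eroded afterwards
    padded = np.pad(m, 1)
    closed = ndimage.binary_closing(padded, structure=BALL_R1)[1:-1, 1:-1, 1:-1]
    return {
        "original": m,
        "opened": ndimage.binary_opening(m, structure=BALL_R1),
        "closed": closed,
    }


def select_optimal_bins(table: FeatureTable) -> tuple[int, pd.DataFrame]:
    """Pick the bin count whose perturbation-ICC yields most Excellent features.

    For every bin setting, ICC(3,1) is computed per feature across the ROI
    versions (k = number of versions, typically original/opened/closed);
    the bin count with the highest count of Excellent (> 0.9) features
    wins, ties going to the smallest bin count.  Returns the winning bin
    count and the per-bin Excellent-count summary.
    """
    counts = []
    for nb in table.bins:
        icc = icc_table(table, mode="perturb", n_bins=nb)
        n_exc = int((icc["robustness"] == "Excellent").sum())
        counts.append((nb, n_exc))
    summary = pd.DataFrame(counts, columns=["n_bins", "n_excellent"])
    best = summary.sort_values(["n_excellent", "n_bins"], ascending=[False, True])
    return int(best.iloc[0]["n_bins"]), summary


def pca_importance(
    feature_matrix: pd.DataFrame | np.ndarray,
    feature_names: list[str] | None = None,
    n_components: int = 3,
    eigenvalue_weighted: bool = True,
) -> ImportanceRanking:
    """Rank features by their loading weight on the leading PCs.

    Principal components are the eigenvectors of the feature correlation
    matrix (features are implicitly z-scored).  The importance of feature
    j is the quadrature sum over the first ``n_components`` PCs:
    sqrt(sum_i lambda_i * v_ij^2) when ``eigenvalue_weighted`` (default),
    else sqrt(sum_i v_ij^2).  Zero-variance features are dropped (logged
    in ``dropped``) since they carry no correlation structure.
    """
    if isinstance(feature_matrix, pd.DataFrame):
        names = list(feature_matrix.columns)
        x = feature_matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(feature_matrix, dtype=float)
        names = feature_names or [f"f{i}" for i in range(x.shape[1])]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 subjects for PCA")

    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    names = [n for n, k in zip(names, keep) if k]
    x = x[:, keep]

    corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(corr)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    n_pos = int((evals > 1e-12).sum())
    n_use = min(n_components, n_pos) if n_pos else n_components
    lam = evals[:n_use]
    v = evecs[:, :n_use]
    weights = lam if eigenvalue_weighted else np.ones_like(lam)
    importance = np.sqrt((weights[None, :] * v**2).sum(axis=1))
    # rank 1 = most important; stable tie-break by feature order
    order_imp = np.lexsort((np.arange(len(names)), -importance))
    rank = np.empty(len(names), dtype=int)
    rank[order_imp] = np.arange(1, len(names) + 1)

    pad = max(3 - v.shape[1], 0)
    loadings3 = np.pad(v[:, :3], ((0, 0), (0, pad)))
    return ImportanceRanking(
        features=names,
        eigenvalues=evals,
        loadings=loadings3,
        top3_variance_fraction=float(evals[: min(3, evals.size)].sum() / evals.sum()),
        importance=importance,
        rank=rank,
        dropped=dropped,
    )


def relative_difference(icc_test: float, icc_ref: float) -> float:
    """Percent ICC difference of a test group against a reference group."""
    if icc_ref == 0:
        raise ValueError("reference ICC is zero")
    return 100.0 * (icc_test - icc_ref) / icc_ref


def robustness_report(
    icc_by_group: pd.DataFrame,
    test_group: str = "GAN-SR",
    diff_features: list[str] | None = None,
) -> dict:
    """Comparative robustness summary across image groups.

    ``icc_by_group``: features x groups matrix of ICC values (index =
    feature names).  Reports per-group Excellent counts, the per-feature
    strict winner (highest ICC, None on ties), the number of features the
    ``test_group`` strictly wins, and a relative-difference table (percent)
    of the test group against every other group for ``diff_features``.
    """
    groups = list(icc_by_group.columns)
    excellent = {
        g: int((icc_by_group[g] > 0.9).sum()) for g in groups
    }
    winners = {}
    for feature, row in icc_by_group.iterrows():
        top = row.max()
        best = [g for g in groups if row[g] == top]
        winners[feature] = best[0] if len(best) == 1 else None
    strict_wins = {g: sum(1 for w in winners.values() if w == g) for g in groups}

    diff_rows = []
    for feature in diff_features or []:
        row = icc_by_group.loc[feature]
        for g in groups:
            if g == test_group:
                continue
            diff_rows.append(
                {
                    "feature": feature,
                    "reference": g,
                    "relative_difference_pct": relative_difference(
                        float(row[test_group]), float(row[g])
                    ),
                }
            )
    return {
        "groups": groups,
        "excellent_counts": excellent,
        "winners": winners,
        "strict_wins": strict_wins,
        "relative_differences": pd.DataFrame(
            diff_rows, columns=["feature", "reference", "relative_difference_pct"]
        ),
    }


def load_reference_icc() -> pd.DataFrame:
    """Packaged 13-feature x 3-group reference ICC matrix (published values).

    Index: feature name (with ``#`` IDs in a column); columns: Original,
    Bicubic, GAN-SR.  The table maps the alias GLCM IDN == GLCM ID (#4).
    """
    with resources.files("lesionsr").joinpath("fixtures/table1_icc.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("feature")
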