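"""Multiparametric morphological profiling of per-image feature medians.

Single-cell descriptor vectors are summarized to per-image medians,
cleaned (rows with missing values and zero-variance columns dropped),
standardized to zero mean / unit SD, and decomposed by PCA.  Features
whose Pearson correlation with the first principal component exceeds a
magnitude cutoff (default 0.75) define the morphological profile used to
flag off-target perturbations such as TGN disruption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "ProfileMatrix", "PCAResult", "ProfileSelection",
    "summarize_per_image", "clean_and_scale", "correlation_matrix",
    "run_pca", "pc1_feature_correlations", "profile_summary",
    "MorphologicalProfiler",
]

PC1_CUTOFF = 0.75


@dataclass
class ProfileMatrix:
    """Images × features matrix with provenance of dropped rows/columns."""

    data: pd.DataFrame
    annotations: pd.DataFrame | None = None
    dropped_rows: list = field(default_factory=list)
    dropped_columns: list = field(default_factory=list)


@dataclass
class PCAResult:
    variance_ratio: np.ndarray          # non-increasing, sums to 1
    scores: pd.DataFrame                # images x components
    loadings: pd.DataFrame              # features x components
    sign_convention: str = "largest_loading_positive"


@dataclass
class ProfileSelection:
    correlations: pd.Series             # Pearson r of each feature with PC1
    selected: list[str]
    cutoff: float = PC1_CUTOFF


def summarize_per_image(cells: pd.DataFrame, image_col: str = "image_id",
                        feature_cols: list[str] | None = None,
                        annotation_cols: list[str] = (),
                        ) -> ProfileMatrix:
    """Per-image medians of single-cell features (one row per image).

    Annotation columns (condition, dose, ...) are carried through by
    their per-image first value; images with zero cells simply do not
    appear and empty input is an error.
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    if feature_cols is None:
        feature_cols = [c for c in cells.columns
                        if c != image_col and c not in annotation_cols
                        and pd.api.types.is_numeric_dtype(cells[c])]
    med = cells.groupby(image_col)[list(feature_cols)].median()
    ann = (cells.groupby(image_col)[list(annotation_cols)].first()
           if annotation_cols else None)
    return ProfileMatrix(data=med, annotations=ann)


def clean_and_scale(matrix: pd.DataFrame | ProfileMatrix,
                    ) -> tuple[pd.DataFrame, dict]:
    """Drop incomplete rows and zero-variance columns, then standardize.

    Columns are centred and scaled to unit sample SD (ddof=1).  Returns
    the scaled matrix and a drop log ``{"rows": [...], "columns": [...]}``.
    Idempotent: a matrix that is already clean and standardized passes
    through unchanged.  All columns degenerate is an error.
    """
    df = matrix.data if isinstance(matrix, ProfileMatrix) else matrix
    df = df.copy()
    bad_rows = df.index[df.isna().any(axis=1)].tolist()
    df = df.drop(index=bad_rows)
    sd = df.std(ddof=1)
    bad_cols = sd.index[(sd == 0) | sd.isna()].tolist()
    df = df.drop(columns=bad_cols)
    if df.shape[1] == 0:
        raise ValueError("all columns have zero variance")
    scaled = (df - df.mean()) / df.std(ddof=1)
    return scaled, {"rows": bad_rows, "columns": bad_cols}


def correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson feature-feature correlations, pairwise-complete.

    Entries with fewer than 2 complete observation pairs are NaN.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows")
    return matrix.corr(method="pearson", min_periods=2)


def run_pca(scaled: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of the standardized matrix with a deterministic sign convention.

    Because columns are standardized this is PCA on the correlation
    structure.  Each component's sign is fixed so its largest-magnitude
    loading is positive, making reports reproducible across runs and
    BLAS implementations.  With all components kept, variance ratios sum
    to 1 and are non-increasing.
    """
    if len(scaled) < 2:
        raise ValueError("need at least 2 rows")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(scaled.to_numpy())
    loadings = pca.components_.T            # features x components
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PCAResult(
        variance_ratio=pca.explained_variance_ratio_,
        scores=pd.DataFrame(scores, index=scaled.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=scaled.columns,
                              columns=comp_names),
    )


def pc1_feature_correlations(pca_result: PCAResult, scaled: pd.DataFrame,
                             cutoff: float = PC1_CUTOFF) -> ProfileSelection:
    """Pearson r of PC1 scores with every feature; select |r| > cutoff."""
    pc1 = pca_result.scores["PC1"]
    corr = scaled.apply(lambda col: col.corr(pc1))
    selected = corr.index[corr.abs() > cutoff].tolist()
    return ProfileSelection(correlations=corr, selected=selected,
                            cutoff=cutoff)


def profile_summary(scaled: pd.DataFrame, selected: list[str],
                    groups: pd.DataFrame,
                    group_cols: list[str] = ("condition", "dose"),
                    ) -> pd.DataFrame:
    """Heatmap-ready per-group mean ± SD of the selected profile features.

    ``groups`` aligns with the rows of ``scaled`` and provides the
    condition/dose annotations; output is ordered by dose within
    condition, on the standardized scale.
    """
    missing = [f for f in selected if f not in scaled.columns]
    if missing:
        raise ValueError(f"unknown features: {missing}")
    df = scaled[list(selected)].join(groups.loc[scaled.index, list(group_cols)])
    agg = df.groupby(list(group_cols), dropna=False).agg(["mean", "std"])
    agg.columns = [f"{feat}_{stat}" for feat, stat in agg.columns]
    return agg.sort_index()


class MorphologicalProfiler(TransformerMixin, BaseEstimator):
    """End-to-end profiling transformer over a per-image feature matrix.

    ``fit`` cleans and standardizes the matrix, runs PCA and selects the
    PC1-correlated profile features; ``transform`` projects (already
    summarized) images onto the fitted components using the stored
    centring/scaling.  Fitted attributes: ``scaled_``, ``pca_``,
    ``selection_``, ``drop_log_``.
    """

    def __init__(self, cutoff: float = PC1_CUTOFF,
                 n_components: int | None = None):
        self.cutoff = cutoff
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        scaled, log = clean_and_scale(X)
        self.drop_log_ = log
        self.scaled_ = scaled
        self.center_ = X[scaled.columns].drop(index=log["rows"]).mean()
        self.scale_ = X[scaled.columns].drop(index=log["rows"]).std(ddof=1)
        self.pca_ = run_pca(scaled, n_components=self.n_components)
        self.selection_ = pc1_feature_correlations(self.pca_, scaled,
                                                   cutoff=self.cutoff)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        z = (X[self.center_.index] - self.center_) / self.scale_
        proj = z.to_numpy() @ self.pca_.loadings.to_numpy()
        return pd.DataFrame(proj, index=X.index,
                            columns=self.pca_.loadings.columns)
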