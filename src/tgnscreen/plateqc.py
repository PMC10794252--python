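"""Plate-level quality control, normalization and assay-performance checks.

Screening plates carry negative controls (the disease phenotype, high
ratio) and positive controls (the rescued phenotype, low ratio) on every
plate.  A plate is usable when the two control groups separate cleanly:
robust Z'-factor ≥ 0.3, SSMD ≥ 3 and a negative-control coefficient of
variation ≤ 10% (all inclusive).  Compound wells are then standardised
against the same plate's negative controls, which removes additive
inter-plate shifts by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

__all__ = [
    "QCMetrics",
    "zprime_robust",
    "ssmd",
    "plate_cv",
    "qc_evaluate",
    "normalize_wells",
    "replicate_correlation",
    "control_separability_auc",
]

ZPRIME_MIN = 0.3
SSMD_MIN = 3.0
CV_MAX = 10.0


def _check_groups(neg, pos):
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if neg.size < 2 or pos.size < 2:
        raise ValueError("need at least 2 wells per control group")
    return neg, pos


def zprime_robust(neg, pos) -> float:
    """Robust Z'-factor between control groups.

    ``1 - 3*(1.4826*MAD_neg + 1.4826*MAD_pos) / |median_neg - median_pos|``
    — the median/MAD analogue of the Z'-factor, with the 1.4826 constant
    making the MAD consistent for a normal spread.  Equal medians give a
    ``-inf`` sentinel (no dynamic range).  Bounded above by 1.
    """
    neg, pos = _check_groups(neg, pos)
    med_n, med_p = np.median(neg), np.median(pos)
    if med_n == med_p:
        return -np.inf
    mad_n = stats.median_abs_deviation(neg, scale="normal")
    mad_p = stats.median_abs_deviation(pos, scale="normal")
    return 1.0 - 3.0 * (mad_n + mad_p) / abs(med_n - med_p)


def ssmd(neg, pos, robust: bool = False) -> float:
    """Strictly standardized mean difference between control groups.

    ``(mean_neg - mean_pos) / sqrt(sd_neg**2 + sd_pos**2)`` — positive
    when the negative control (retention phenotype) exceeds the positive
    control, the screen's sign convention.  ``robust=True`` substitutes
    medians and normal-consistent MADs.  Both spreads zero yields a
    signed-infinite sentinel.
    """
    neg, pos = _check_groups(neg, pos)
    if robust:
        loc_n, loc_p = np.median(neg), np.median(pos)
        s_n = stats.median_abs_deviation(neg, scale="normal")
        s_p = stats.median_abs_deviation(pos, scale="normal")
    else:
        loc_n, loc_p = neg.mean(), pos.mean()
        s_n, s_p = neg.std(ddof=1), pos.std(ddof=1)
    denom = np.sqrt(s_n ** 2 + s_p ** 2)
    diff = loc_n - loc_p
    if denom == 0:
        return np.inf * np.sign(diff) if diff != 0 else 0.0
    return diff / denom


def plate_cv(neg) -> float:
    """Coefficient of variation of negative-control wells, in percent."""
    neg = np.asarray(neg, dtype=float)
    if neg.size < 2:
        raise ValueError("need at least 2 negative-control wells")
    mean = neg.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return 100.0 * neg.std(ddof=1) / mean


@dataclass
class QCMetrics:
    """Per-plate control separation metrics and the conjunctive pass flag."""

    plate_id: str
    zprime_robust: float
    ssmd: float
    cv_percent: float
    n_neg: int
    n_pos: int
    passed: bool


def qc_evaluate(wells: pd.DataFrame, plate_id: str | None = None,
                value_col: str = "ratio", zprime_min: float = ZPRIME_MIN,
                ssmd_min: float = SSMD_MIN, cv_max: float = CV_MAX,
                ) -> QCMetrics:
    """Evaluate one plate's wells (needs a ``role`` column with both
    control groups).  Pass thresholds are inclusive: a plate at exactly
    Z' 0.3, SSMD 3 or CV 10% passes.
    """
    neg = wells.loc[wells["role"] == "negative_control", value_col].to_numpy()
    pos = wells.loc[wells["role"] == "positive_control", value_col].to_numpy()
    if neg.size == 0 or pos.size == 0:
        raise ValueError("plate lacks a control group")
    if plate_id is None:
        plate_id = str(wells["plate"].iloc[0]) if "plate" in wells else ""
    zp = zprime_robust(neg, pos)
    sm = ssmd(neg, pos)
    cv = plate_cv(neg)
    passed = bool(zp >= zprime_min and sm >= ssmd_min and cv <= cv_max)
    return QCMetrics(plate_id, float(zp), float(sm), float(cv),
                     int(neg.size), int(pos.size), passed)


def normalize_wells(wells: pd.DataFrame, value_col: str = "ratio",
                    count_col: str = "cell_count") -> pd.DataFrame:
    """Standardize wells against the same plate's negative controls.

    Adds ``ratio_z`` (and ``cellcount_z`` when a count column is present):
    ``(well - mean_neg) / sd_neg`` with in-plate negative-control moments,
    so any additive per-plate shift cancels exactly.  The negative
    (patient/knockout) wells are the reference population because both
    screen gates are defined as reductions relative to them.
    """
    out = []
    for plate, grp in wells.groupby("plate", sort=False):
        neg = grp[grp["role"] == "negative_control"]
        if len(neg) < 2:
            raise ValueError(f"plate {plate}: need >= 2 negative controls")
        mu, sd = neg[value_col].mean(), neg[value_col].std(ddof=1)
        if sd == 0:
            raise ValueError(f"plate {plate}: zero negative-control spread")
        g = grp.copy()
        g["ratio_z"] = (g[value_col] - mu) / sd
        if count_col in g:
            cmu = neg[count_col].mean()
            csd = neg[count_col].std(ddof=1)
            g["cellcount_z"] = (g[count_col] - cmu) / csd if csd > 0 else 0.0
        out.append(g)
    return pd.concat(out, ignore_index=True)


def replicate_correlation(plate_stack: np.ndarray | pd.DataFrame,
                          n_samplings: int = 100, seed: int = 0,
                          ) -> tuple[float, float]:
    """Replicate reproducibility by repeated random plate splitting.

    ``plate_stack`` is plates × well-positions (identical layouts).  Each
    of ``n_samplings`` rounds splits the plates into two disjoint halves
    (sizes ⌊N/2⌋ and ⌈N/2⌉), averages every well position within each
    half, and correlates the two position profiles (Pearson, missing
    positions dropped pairwise).  Returns (mean r, SD of r) over rounds.
    """
    arr = np.asarray(plate_stack, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a plates x positions array with >= 2 plates")
    n = arr.shape[0]
    rng = np.random.default_rng(seed)
    rs = np.empty(n_samplings)
    for k in range(n_samplings):
        perm = rng.permutation(n)
        half = n // 2
        a = np.nanmean(arr[perm[:half]], axis=0)
        b = np.nanmean(arr[perm[half:]], axis=0)
        keep = np.isfinite(a) & np.isfinite(b)
        rs[k] = stats.pearsonr(a[keep], b[keep]).statistic
    return float(rs.mean()), float(rs.std(ddof=1))


def control_separability_auc(values, labels, train_fraction: float = 0.7,
                             seed: int = 0) -> float:
    """Held-out AUC of a logistic model separating the two control classes.

    Single-cell (or well) values are split into a training fraction
    (default 70%) and a test fraction; a logistic regression of class on
    the value is fitted on the training split and scored on the held-out
    split with the rank-sum (Mann-Whitney U) AUC estimator, which makes
    the result invariant to any strictly increasing transform of the
    predictor.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("need exactly two classes")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, random_state=seed, stratify=y)
    model = LogisticRegression(max_iter=1000)
    model.fit(X_tr, y_tr)
    score = model.decision_function(X_te)
    pos = score[y_te == model.classes_[1]]
    neg = score[y_te == model.classes_[0]]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))
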