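"""Hit triage, dose-response confirmation and the screening funnel.

Primary-screen triage is a pair of inclusive SD gates on per-plate
z-scores: a compound is *active* when it lowers the translocation ratio
by at least 3 negative-control SDs (``ratio_z <= -3``) and *toxic* when
it lowers the well cell count by at least 2 SDs (``cellcount_z <= -2``).
Actives are confirmed in a replicated 11-point titration: activity at
two or more non-toxic concentrations in both replicates, and potency is
summarised by a four-parameter logistic (4PL) EC50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .simulate import four_param_logistic

__all__ = [
    "ACTIVITY_Z", "TOXICITY_Z",
    "TriageResult", "DoseResponseFit", "CounterScreenCall",
    "prefilter", "triage_primary", "FourParamLogistic", "fit_4pl",
    "counter_screen_call", "cascade_summary", "format_percent",
]

ACTIVITY_Z = -3.0     # ratio z-score gate, inclusive
TOXICITY_Z = -2.0     # cell-count z-score gate, inclusive

CATEGORIES = ("excluded_prefilter", "inactive", "toxic",
              "active_toxic", "active_nontoxic")


# ---------------------------------------------------------------------------
# Pre-filter and primary triage
# ---------------------------------------------------------------------------

def prefilter(wells: pd.DataFrame, min_cell_count: int = 50,
              artifact_col: str = "artifact",
              quantifiable_col: str = "quantifiable",
              count_col: str = "cell_count",
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove wells that cannot be scored at all.

    Exclusion reasons, checked in order: no quantifiable cargo signal
    (``quantifiable`` column false, when present), absolute cell count
    below ``min_cell_count`` (a floor catching wells with essentially no
    cells, distinct from the relative toxicity gate), and flagged imaging
    artifacts.  Returns ``(retained, excluded)`` with the reason recorded.
    """
    df = wells.copy()
    reason = pd.Series("", index=df.index, dtype=object)
    if quantifiable_col in df:
        reason[~df[quantifiable_col].astype(bool)] = "non_quantifiable_signal"
    if count_col in df:
        low = (df[count_col] < min_cell_count) & (reason == "")
        reason[low] = "low_cell_count"
    if artifact_col in df:
        art = df[artifact_col].astype(bool) & (reason == "")
        reason[art] = "imaging_artifact"
    excluded = df[reason != ""].copy()
    excluded["exclusion_reason"] = reason[reason != ""]
    return df[reason == ""].copy(), excluded


@dataclass
class TriageResult:
    """Per-compound category counts from the primary screen."""

    table: pd.DataFrame          # compound_id, ratio_z, cellcount_z, category
    counts: dict[str, int]
    activity_threshold: float = ACTIVITY_Z
    toxicity_threshold: float = TOXICITY_Z


def triage_primary(wells: pd.DataFrame,
                   activity_threshold: float = ACTIVITY_Z,
                   toxicity_threshold: float = TOXICITY_Z) -> TriageResult:
    """Assign every retained compound to exactly one triage category.

    Categories partition the input: ``active_nontoxic`` (ratio gate only),
    ``active_toxic`` (both gates), ``toxic`` (count gate only) and
    ``inactive`` (neither).  Both thresholds are inclusive ("by at least
    N SD").
    """
    for col in ("ratio_z", "cellcount_z"):
        if col not in wells:
            raise ValueError(f"missing z-score column {col!r}")
        if wells[col].isna().any():
            raise ValueError(f"NaN z-scores in {col!r}")
    df = wells.copy()
    is_active = df["ratio_z"] <= activity_threshold
    is_toxic = df["cellcount_z"] <= toxicity_threshold
    cat = np.where(is_active & is_toxic, "active_toxic",
                   np.where(is_active, "active_nontoxic",
                            np.where(is_toxic, "toxic", "inactive")))
    df["category"] = cat
    counts = {c: int((df["category"] == c).sum())
              for c in ("inactive", "toxic", "active_nontoxic", "active_toxic")}
    return TriageResult(df, counts, activity_threshold, toxicity_threshold)


# ---------------------------------------------------------------------------
# 4PL dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters with convergence/validity flags.

    ``bottom <= top`` is normalized (the two parametrisations related by
    ``hill -> -hill`` describe the same curve); ``ec50_in_range`` is true
    when the fitted EC50 lies within a decade of the tested dose range
    and the curve is not degenerate (flat).
    """

    bottom: float
    top: float
    ec50: float
    hill: float
    converged: bool
    ec50_in_range: bool
    residual_sse: float


class FourParamLogistic(RegressorMixin, BaseEstimator):
    """Four-parameter logistic dose-response regressor.

    Fits ``y = bottom + (top - bottom) / (1 + (x / ec50)**hill)`` by
    bounded least squares in log10-dose space, with a small multi-start
    over Hill slopes and EC50 decades to avoid boundary optima on shallow
    curves.  EC50 is bounded to [min dose / 10, max dose x 10].

    Parameters
    ----------
    hill_starts : tuple of float
        Hill-slope initialisations tried per EC50 start.
    n_ec50_starts : int
        EC50 initialisations, log-spaced over the dose range.
    ec50_range_factor : float
        Decade padding of the EC50 bounds around the dose range.

    Attributes (after :meth:`fit`)
    ------------------------------
    bottom_, top_, ec50_, hill_ : float
        Normalized curve parameters (``bottom_ <= top_``).
    converged_, ec50_in_range_ : bool
    residual_sse_ : float
    """

    def __init__(self, hill_starts: tuple = (0.5, 1.0, 2.0),
                 n_ec50_starts: int = 5, ec50_range_factor: float = 10.0):
        self.hill_starts = hill_starts
        self.n_ec50_starts = n_ec50_starts
        self.ec50_range_factor = ec50_range_factor

    @staticmethod
    def _curve(logx, bottom, top, log_ec50, hill):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - log_ec50)))

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("doses and responses differ in length")
        if np.any(x <= 0):
            raise ValueError("doses must be strictly positive")
        if np.unique(x).size < 4:
            raise ValueError("need at least 4 distinct doses")
        logx = np.log10(x)
        lo, hi = logx.min(), logx.max()
        pad = np.log10(self.ec50_range_factor)
        span = y.max() - y.min()
        margin = max(span, 1.0)
        bounds_lo = [y.min() - margin, y.min() - margin, lo - pad, -10.0]
        bounds_hi = [y.max() + margin, y.max() + margin, hi + pad, 10.0]

        def resid(p):
            return self._curve(logx, *p) - y

        best = None
        ec50_starts = np.linspace(lo, hi, self.n_ec50_starts)
        for h0 in self.hill_starts:
            for le0 in ec50_starts:
                p0 = [y.min(), y.max(), le0, h0]
                try:
                    sol = least_squares(resid, p0,
                                        bounds=(bounds_lo, bounds_hi))
                except Exception:       # numerical failure on one start
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol

        if best is None:
            self.bottom_ = self.top_ = self.ec50_ = self.hill_ = np.nan
            self.converged_ = False
            self.ec50_in_range_ = False
            self.residual_sse_ = np.nan
            return self

        bottom, top, log_ec50, hill = best.x
        self._raw_params_ = (bottom, top, log_ec50, hill)
        if bottom > top:                # same curve with hill negated
            bottom, top, hill = top, bottom, -hill
        self.bottom_ = float(bottom)
        self.top_ = float(top)
        self.ec50_ = float(10.0 ** log_ec50)
        self.hill_ = float(hill)
        self.converged_ = bool(best.success)
        self.residual_sse_ = float(2.0 * best.cost)
        degenerate = (self.top_ - self.bottom_) < 1e-6 * margin
        self.ec50_in_range_ = bool(
            not degenerate
            and 10.0 ** (lo - pad) < self.ec50_ < 10.0 ** (hi + pad))
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        b, t, le, h = self._raw_params_
        return self._curve(np.log10(x), b, t, le, h)

    def result_(self) -> DoseResponseFit:
        return DoseResponseFit(self.bottom_, self.top_, self.ec50_,
                               self.hill_, self.converged_,
                               self.ec50_in_range_, self.residual_sse_)


def fit_4pl(doses, responses) -> DoseResponseFit:
    """Fit a 4PL curve to (dose, response) data; replicates are simply
    repeated dose entries.  Non-convergence is returned as a flagged
    result, never raised."""
    return FourParamLogistic().fit(doses, responses).result_()


# ---------------------------------------------------------------------------
# Counter-screen calls
# ---------------------------------------------------------------------------

@dataclass
class CounterScreenCall:
    """Activity call for one compound's replicated titration."""

    compound_id: str
    active: bool
    n_active_concentrations: int
    active_in_both_replicates: bool
    toxic_concentrations: list = field(default_factory=list)


def counter_screen_call(titration: pd.DataFrame, compound_id: str = "",
                        activity_threshold: float = ACTIVITY_Z,
                        toxicity_threshold: float = TOXICITY_Z,
                        require_replicates: int = 2,
                        min_active_concentrations: int = 2,
                        ) -> CounterScreenCall:
    """Call a compound active from its replicated titration z-scores.

    ``titration`` needs columns ``dose_uM, replicate, ratio_z`` (and
    optionally ``cellcount_z``).  A concentration counts as evidence only
    if the ratio gate is met in *both* replicates and it is not toxic
    (cell-count gate in any replicate); a compound is active with
    evidence at ``min_active_concentrations`` or more concentrations.
    The call does not depend on the ordering of the rows.
    """
    for col in ("dose_uM", "replicate", "ratio_z"):
        if col not in titration:
            raise ValueError(f"missing column {col!r}")
    n_active = 0
    toxic_concs: list[float] = []
    for dose, grp in titration.groupby("dose_uM", sort=True):
        if grp["replicate"].nunique() != require_replicates:
            raise ValueError(
                f"dose {dose}: expected {require_replicates} replicates")
        toxic = ("cellcount_z" in grp
                 and bool((grp["cellcount_z"] <= toxicity_threshold).any()))
        if toxic:
            toxic_concs.append(float(dose))
            continue
        if bool((grp.groupby("replicate")["ratio_z"].min()
                 <= activity_threshold).all()):
            n_active += 1
    return CounterScreenCall(
        compound_id=compound_id,
        active=n_active >= min_active_concentrations,
        n_active_concentrations=n_active,
        active_in_both_replicates=n_active > 0,
        toxic_concentrations=toxic_concs,
    )


# ---------------------------------------------------------------------------
# Funnel summary
# ---------------------------------------------------------------------------

def format_percent(numerator: int, denominator: int) -> str:
    """Screen-report percentage convention: one decimal, e.g. '10.1%'."""
    if denominator == 0:
        return "0.0%"
    return f"{100.0 * numerator / denominator:.1f}%"


def cascade_summary(triage: TriageResult,
                    counter_calls: list[CounterScreenCall] | None = None,
                    fits: list[DoseResponseFit] | None = None,
                    n_input: int | None = None,
                    n_artifact_excluded_counter: int = 0) -> dict:
    """Per-stage counts and percentages of the screening funnel.

    Counts are conserved at every stage: the triage categories partition
    the retained compounds, and the counter-screen confirmed count equals
    the active calls minus post-hoc artifact exclusions.  EC50 summary
    (median and IQR) is over valid fits of confirmed compounds.
    """
    retained = len(triage.table)
    c = triage.counts
    assert sum(c.values()) == retained, "triage categories must partition input"
    active_total = c["active_nontoxic"] + c["active_toxic"]
    # reporting convention: the toxic headline count includes compounds that
    # are both active and toxic (they appear in the active total as well)
    toxic_total = c["toxic"] + c["active_toxic"]
    out = {
        "n_input": int(n_input) if n_input is not None else retained,
        "n_retained": retained,
        "n_excluded_prefilter": (int(n_input) - retained
                                 if n_input is not None else 0),
        "counts": dict(c),
        "n_active_total": active_total,
        "n_toxic_total": toxic_total,
        "pct_inactive": format_percent(c["inactive"], retained),
        "pct_toxic": format_percent(toxic_total, retained),
        "pct_active": format_percent(active_total, retained),
    }
    if counter_calls is not None:
        n_tested = len(counter_calls)
        n_hits = sum(cc.active for cc in counter_calls)
        confirmed = n_hits - n_artifact_excluded_counter
        out.update({
            "n_counter_tested": n_tested,
            "n_counter_active": n_hits,
            "pct_counter_active": format_percent(n_hits, n_tested),
            "n_counter_artifact_excluded": n_artifact_excluded_counter,
            "n_confirmed": confirmed,
        })
    if fits:
        ec50s = np.array([f.ec50 for f in fits
                          if f.converged and f.ec50_in_range])
        if ec50s.size:
            q1, q3 = np.percentile(ec50s, [25, 75])
            out["ec50_median_uM"] = float(np.median(ec50s))
            out["ec50_iqr_uM"] = float(q3 - q1)
    return out
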