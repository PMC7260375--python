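"""Discriminant validity, reliability, measurement error and learning effects.

Selection step 2.  For every metric (on the normalized percent scale) this
module computes:

* AUC of the intact-vs-affected ROC (Mann-Whitney identity, ties half credit),
* the agreement intraclass correlation ICC(A,k) from a two-way ANOVA of the
  test/retest sessions with both tested sides pooled,
* the smallest real difference ``SRD = 1.96 * sqrt(2) * Sigma * sqrt(1-ICC)``
  and its percentage of the intact range (SRD%),
* the learning slope ``eta = 100 * mean(retest - test) / range`` with a paired
  t-test,

and applies the combined filter AUC >= 0.7, ICC >= 0.7, SRD% below its
80th-percentile cutoff and eta above its 20th-percentile cutoff, the two
cutoffs being recomputed over the full evaluated metric set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "ClinimetricScores",
    "SelectionThresholds",
    "compute_auc",
    "compute_icc_agreement",
    "compute_srd",
    "compute_eta",
    "percentile",
    "percentile_cutoffs",
    "step2_filter",
    "score_metric",
]


@dataclass(frozen=True)
class SelectionThresholds:
    auc_min: float = 0.7
    icc_min: float = 0.7
    srd_pct_percentile: float = 80.0
    eta_percentile: float = 20.0
    percentile_convention: str = "nearest_rank"  # or "linear"


@dataclass
class ClinimetricScores:
    """Step-2 scores and pass/fail flags for one metric."""

    metric_name: str
    auc: float
    icc: float
    srd: float
    srd_pct: float
    eta: float
    paired_t_p: float
    flags: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return bool(self.flags) and all(self.flags.values())

    def failed_criteria(self) -> list[str]:
        return [k for k, ok in self.flags.items() if not ok]


def compute_auc(intact, affected, orientation: str = "higher_is_worse") -> float:
    """Probability that a random affected subject looks worse than an intact one.

    Equivalent to the Mann-Whitney U statistic divided by the number of
    (affected, intact) pairs; ties count half.
    """
    intact = np.asarray(intact, dtype=float)
    affected = np.asarray(affected, dtype=float)
    if intact.size == 0 or affected.size == 0:
        raise ValueError("both groups must be non-empty")
    sign = 1.0 if orientation == "higher_is_worse" else -1.0
    y = np.r_[np.zeros(intact.size), np.ones(affected.size)]
    return float(roc_auc_score(y, sign * np.r_[intact, affected]))


def compute_icc_agreement(paired) -> float:
    """Agreement ICC(A,k) from a two-way ANOVA of an n x k matrix.

    Rows are subject x side units, columns are sessions; with ``k`` sessions
    ``ICC(A,k) = (MS_rows - MS_err) / (MS_rows + (MS_cols - MS_err) / n)``.
    Requires at least 3 complete rows.
    """
    m = np.asarray(paired, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2")
    m = m[~np.isnan(m).any(axis=1)]
    n, k = m.shape
    if n < 3:
        raise ValueError("need >= 3 complete test/retest pairs")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ms_rows = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((m - row_means[:, None] - col_means[None, :] + grand) ** 2)
    ms_err = sse / ((n - 1) * (k - 1))
    denom = ms_rows + (ms_cols - ms_err) / n
    if denom == 0:
        return 1.0 if ms_rows == ms_err else 0.0
    return float((ms_rows - ms_err) / denom)


def compute_srd(paired, icc: float, normalized_range: float) -> tuple[float, float]:
    """Smallest real difference and its percentage of the intact range.

    ``Sigma`` is the standard deviation pooled over all subject x side x
    session values of the test-retest cohort (trial-level variance is already
    collapsed by the grand-median aggregation).
    """
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    if not normalized_range > 0:
        raise ValueError("normalized range must be positive")
    m = np.asarray(paired, dtype=float)
    sigma = float(np.std(m[~np.isnan(m)], ddof=1))
    srd = 1.96 * math.sqrt(2.0) * sigma * math.sqrt(max(1.0 - icc, 0.0))
    return srd, 100.0 * srd / normalized_range


def compute_eta(paired, normalized_range: float) -> tuple[float, float]:
    """Learning slope (percent of intact range, signed) and paired-t p-value.

    Negative eta means better scores at retest (task learning).
    """
    if not normalized_range > 0:
        raise ValueError("normalized range must be positive")
    m = np.asarray(paired, dtype=float)
    m = m[~np.isnan(m).any(axis=1)]
    if m.shape[0] < 3:
        raise ValueError("need >= 3 complete pairs")
    diff = m[:, 1] - m[:, 0]
    eta = 100.0 * float(np.mean(diff)) / normalized_range
    if np.allclose(diff, diff[0]):
        p = 1.0 if np.allclose(diff, 0) else 0.0
    else:
        p = float(stats.ttest_rel(m[:, 1], m[:, 0]).pvalue)
    return eta, p


def percentile(values, q: float, convention: str = "nearest_rank") -> float:
    """q-th percentile under the nearest-rank or linear convention.

    Nearest rank takes the ceil(q*n/100)-th order statistic, the convention
    that reproduces distribution-derived selection cutoffs exactly.
    """
    v = np.sort(np.asarray(values, dtype=float))
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("empty vector")
    if convention == "nearest_rank":
        k = max(int(math.ceil(q * v.size / 100.0)), 1)
        return float(v[k - 1])
    if convention == "linear":
        return float(np.percentile(v, q))
    raise ValueError(f"unknown percentile convention {convention!r}")


def percentile_cutoffs(
    all_srd_pct, all_eta, thresholds: SelectionThresholds = SelectionThresholds()
) -> tuple[float, float]:
    """Distribution-derived cutoffs over the full evaluated metric set.

    Returns the 80th percentile of SRD% (metrics at or above it fail) and the
    20th percentile of eta (metrics at or below it fail).
    """
    srd_cut = percentile(
        all_srd_pct, thresholds.srd_pct_percentile, thresholds.percentile_convention
    )
    eta_cut = percentile(
        all_eta, thresholds.eta_percentile, thresholds.percentile_convention
    )
    return srd_cut, eta_cut


def score_metric(
    metric_name: str,
    intact_norm,
    affected_norm,
    paired_norm,
) -> ClinimetricScores:
    """All step-2 scores for one metric on the normalized scale.

    ``paired_norm`` is the n x 2 test/retest matrix of intact subjects
    (both sides pooled).  Flags are filled in later by :func:`step2_filter`
    once the percentile cutoffs are known.
    """
    auc = compute_auc(intact_norm, affected_norm)  # already sign-aligned
    icc = compute_icc_agreement(paired_norm)
    normalized_range = float(np.ptp(np.asarray(intact_norm, dtype=float)))
    srd, srd_pct = compute_srd(paired_norm, icc, normalized_range)
    eta, p = compute_eta(paired_norm, normalized_range)
    return ClinimetricScores(metric_name, auc, icc, srd, srd_pct, eta, p)


def step2_filter(
    scores: list[ClinimetricScores],
    thresholds: SelectionThresholds = SelectionThresholds(),
    step1_survivors: set[str] | None = None,
) -> tuple[list[str], list[str], dict]:
    """Apply the combined step-2 criteria.

    Returns ``(criterion_passers, passers_intersected_with_step1, info)``
    where ``info`` records the recomputed cutoffs and per-metric reasons.
    Keep iff AUC >= auc_min, ICC >= icc_min (inclusive), SRD% strictly below
    its cutoff and eta strictly above its cutoff.
    """
    srd_cut, eta_cut = percentile_cutoffs(
        [s.srd_pct for s in scores], [s.eta for s in scores], thresholds
    )
    passers = []
    reasons: dict[str, list[str]] = {}
    for s in scores:
        s.flags = {
            f"auc>={thresholds.auc_min}": s.auc >= thresholds.auc_min,
            f"icc>={thresholds.icc_min}": s.icc >= thresholds.icc_min,
            f"srd_pct<{srd_cut:.4g}": s.srd_pct < srd_cut,
            f"eta>{eta_cut:.4g}": s.eta > eta_cut,
        }
        if s.passed:
            passers.append(s.metric_name)
        else:
            reasons[s.metric_name] = s.failed_criteria()
    if step1_survivors is None:
        both = list(passers)
    else:
        both = [m for m in passers if m in step1_survivors]
    info = {"srd_cutoff": srd_cut, "eta_cutoff": eta_cut, "reasons": reasons}
    return passers, both, info


def scores_table(scores: list[ClinimetricScores]) -> pd.DataFrame:
    """One row per metric with AUC/ICC/SRD%/eta and the pass flag."""
    return pd.DataFrame(
        [
            {
                "metric_name": s.metric_name,
                "auc": s.auc,
                "icc": s.icc,
                "srd": s.srd,
                "srd_pct": s.srd_pct,
                "eta": s.eta,
                "paired_t_p": s.paired_t_p,
                "passed": s.passed,
            }
            for s in scores
        ]
    ).set_index("metric_name")
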