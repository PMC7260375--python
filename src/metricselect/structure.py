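"""Structural validation: factor analysis and disability-subgroup testing.

Validation step 1 runs an exploratory maximum-likelihood factor analysis on
the core metrics (number of factors chosen by parallel analysis, promax
rotation, KMO sampling adequacy).  Validation step 2 groups affected subjects
into clinically defined severity bands and tests each metric across the bands
with a Kruskal-Wallis omnibus test plus Bonferroni-corrected pairwise
post-hoc rank tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor import Factor

from .data import SubjectRecord

__all__ = [
    "kmo",
    "parallel_analysis",
    "efa_promax",
    "FactorModel",
    "assign_severity_groups",
    "subgroup_tests",
    "SubgroupResult",
]


def kmo(table: pd.DataFrame) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy of a metric table.

    Ratio of summed squared correlations to summed squared correlations plus
    summed squared anti-image (partial) correlations; >= 0.6 is conventionally
    considered adequate for factor analysis.
    """
    if table.shape[1] < 3:
        raise ValueError("need >= 3 metrics")
    if table.shape[0] <= table.shape[1]:
        raise ValueError("need more rows than metrics")
    r = np.corrcoef(table.to_numpy(dtype=float), rowvar=False)
    try:
        prec = np.linalg.inv(r)
    except np.linalg.LinAlgError:
        prec = np.linalg.inv(r + 1e-10 * np.eye(r.shape[0]))
    d = np.sqrt(np.diag(prec))
    partial = -prec / np.outer(d, d)
    off = ~np.eye(r.shape[0], dtype=bool)
    ssr = np.sum(r[off] ** 2)
    ssp = np.sum(partial[off] ** 2)
    return float(ssr / (ssr + ssp))


def parallel_analysis(
    table: pd.DataFrame,
    n_sim: int = 200,
    seed: int | np.random.Generator = 0,
    criterion: str = "quantile",
    quantile: float = 0.95,
) -> int:
    """Number of factors by comparing eigenvalues against simulated noise.

    Eigenvalues of the observed correlation matrix are compared with those of
    ``n_sim`` standard-normal datasets of identical shape; ``k`` counts the
    leading observed eigenvalues exceeding the simulated threshold (the 95th
    percentile by default, which keeps pure noise at k = 0; ``criterion =
    "mean"`` uses the classical mean-eigenvalue rule).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    x = table.to_numpy(dtype=float)
    n, p = x.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, p))
    for s in range(n_sim):
        z = rng.standard_normal((n, p))
        sims[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(z, rowvar=False)))[::-1]
    if criterion == "mean":
        thresh = sims.mean(axis=0)
    elif criterion == "quantile":
        thresh = np.quantile(sims, quantile, axis=0)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    k = 0
    for j in range(p):
        if obs[j] > thresh[j]:
            k += 1
        else:
            break
    return k


@dataclass
class FactorModel:
    """Promax-rotated factor solution with the strong-loading map."""

    k: int
    loadings: pd.DataFrame  # metrics x factors
    uniquenesses: pd.Series
    kmo: float | None = None
    heywood: bool = False
    strong_threshold: float = 0.5
    strong_map: dict = field(default_factory=dict)

    def implied_correlation(self) -> pd.DataFrame:
        """Model-implied correlation L L' + Psi (unrotated fit is equivalent)."""
        L = self._unrotated
        sigma = L @ L.T + np.diag(self.uniquenesses.to_numpy())
        return pd.DataFrame(sigma, index=self.loadings.index,
                            columns=self.loadings.index)

    def summary(self) -> str:
        lines = [f"Exploratory factor analysis, k = {self.k}"]
        if self.kmo is not None:
            lines.append(f"  KMO = {self.kmo:.2f}")
        if self.heywood:
            lines.append("  warning: Heywood case (near-zero uniqueness)")
        with pd.option_context("display.float_format", "{:+.2f}".format):
            lines.append(self.loadings.to_string())
        return "\n".join(lines)


def efa_promax(table: pd.DataFrame, k: int, strong_threshold: float = 0.5
               ) -> FactorModel:
    """Maximum-likelihood common factor analysis with promax rotation.

    Loadings are sign-fixed so the largest-magnitude loading per factor is
    positive; metrics with an absolute rotated loading >= ``strong_threshold``
    enter ``strong_map`` (metric -> factor label).  A Heywood case (uniqueness
    collapsing to zero) is flagged, not fatal.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if table.shape[1] < k + 2:
        raise ValueError("need at least k + 2 metrics for identifiability")
    x = table.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = Factor(x, n_factor=k, method="ml").fit()
        unrotated = res.loadings.copy()
        if k > 1:
            res.rotate("promax")
    L = np.asarray(res.loadings, dtype=float)
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    L = L * signs
    factors = [f"F{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(L, index=table.columns, columns=factors)
    uniq = pd.Series(np.asarray(res.uniqueness, dtype=float),
                     index=table.columns)
    strong = {}
    for metric in loadings.index:
        row = loadings.loc[metric].abs()
        if row.max() >= strong_threshold:
            strong[metric] = str(row.idxmax())
    model = FactorModel(
        k=k,
        loadings=loadings,
        uniquenesses=uniq,
        heywood=bool((uniq < 5e-3).any()),
        strong_threshold=strong_threshold,
        strong_map=strong,
    )
    model._unrotated = unrotated
    return model


# ---------------------------------------------------------------------------
# Disability subgrouping
# ---------------------------------------------------------------------------

_FMA_BANDS = "stroke: ceiling FMA-UE = 66; mild 54-65; moderate 35-53"
_ARAT_BANDS = "ms: full 55-57; notable 43-54; limited 22-42"
_AGE_BANDS = "arsacs: young 26-36; mid-age 37-47; older-age 48-58"


def _severity(subject: SubjectRecord) -> str:
    if subject.group == "intact":
        return "intact"
    if subject.group == "stroke":
        fma = subject.clinical_scores.get("fma_ue")
        if fma is None:
            return "unclassified"
        if fma == 66:
            return "ceiling"
        if 54 <= fma < 66:
            return "mild impairment"
        if 35 <= fma < 54:
            return "moderate impairment"
        return "unclassified"
    if subject.group == "ms":
        arat = subject.clinical_scores.get("arat")
        if arat is None:
            return "unclassified"
        if 55 <= arat <= 57:
            return "full capacity"
        if 43 <= arat < 55:
            return "notable capacity"
        if 22 <= arat < 43:
            return "limited capacity"
        return "unclassified"
    if subject.group == "arsacs":
        if 26 <= subject.age <= 36:
            return "young"
        if 37 <= subject.age <= 47:
            return "mid-age"
        if 48 <= subject.age <= 58:
            return "older-age"
        return "unclassified"
    return "unclassified"


def assign_severity_groups(subjects: list[SubjectRecord]) -> pd.Series:
    """Severity band per subject from the disease-appropriate clinical score.

    Stroke uses FMA-UE, MS uses ARAT, ARSACS uses age bands; subjects whose
    score falls outside all bands (or is missing) are labelled
    ``unclassified`` with a warning and excluded from the banded comparison.
    """
    labels = {s.subject_id: _severity(s) for s in subjects}
    n_un = sum(1 for v in labels.values() if v == "unclassified")
    if n_un:
        warnings.warn(
            f"{n_un} subject(s) fall outside the severity bands "
            f"({_FMA_BANDS}; {_ARAT_BANDS}; {_AGE_BANDS})",
            stacklevel=2,
        )
    return pd.Series(labels, name="severity")


@dataclass
class SubgroupResult:
    """Kruskal-Wallis omnibus plus pairwise post-hoc tests for one metric."""

    metric_name: str
    groups: list[str]
    omnibus_h: float
    omnibus_df: int
    omnibus_p: float  # Bonferroni-corrected across metrics
    posthoc_p: pd.DataFrame | None
    medians: pd.Series
    excluded_groups: list[str] = field(default_factory=list)


def subgroup_tests(
    values: pd.Series,
    labels: pd.Series,
    metric_name: str = "",
    alpha: float = 0.05,
    n_metrics: int = 1,
    group_order: list[str] | None = None,
) -> SubgroupResult:
    """Omnibus + post-hoc comparison of a metric across severity bands.

    ``values`` and ``labels`` are aligned per analysis unit.  Groups with
    fewer than 2 members are excluded with a warning.  The omnibus p-value is
    Bonferroni-corrected across ``n_metrics`` metrics; post-hoc pairwise
    rank-sum tests are run only when the corrected omnibus is significant and
    are Bonferroni-corrected across the pairs.
    """
    df = pd.DataFrame({"v": values, "g": labels}).dropna()
    df = df[df["g"] != "unclassified"]
    counts = df["g"].value_counts()
    excluded = sorted(counts.index[counts < 2])
    if excluded:
        warnings.warn(f"excluding groups with < 2 members: {excluded}",
                      stacklevel=2)
        df = df[~df["g"].isin(excluded)]
    groups = group_order or sorted(df["g"].unique())
    groups = [g for g in groups if g in set(df["g"])]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    samples = [df.loc[df["g"] == g, "v"].to_numpy() for g in groups]
    h, p = stats.kruskal(*samples)
    p_corr = min(float(p) * n_metrics, 1.0)
    medians = pd.Series({g: float(np.median(s)) for g, s in zip(groups, samples)})

    posthoc = None
    if p_corr < alpha:
        npairs = len(groups) * (len(groups) - 1) // 2
        posthoc = pd.DataFrame(np.nan, index=groups, columns=groups)
        for i, gi in enumerate(groups):
            posthoc.loc[gi, gi] = 1.0
            for gj in groups[i + 1:]:
                pij = stats.mannwhitneyu(
                    df.loc[df["g"] == gi, "v"],
                    df.loc[df["g"] == gj, "v"],
                    alternative="two-sided",
                ).pvalue
                pij = min(float(pij) * npairs, 1.0)
                posthoc.loc[gi, gj] = posthoc.loc[gj, gi] = pij
    return SubgroupResult(
        metric_name=metric_name,
        groups=groups,
        omnibus_h=float(h),
        omnibus_df=len(groups) - 1,
        omnibus_p=p_corr,
        posthoc_p=posthoc,
        medians=medians,
        excluded_groups=excluded,
    )
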