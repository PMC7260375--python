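"""Confound modelling and normalization of metrics against a normative cohort.

Selection step 1.  Each metric is Box-Cox transformed, a linear mixed-effects
model with a subject random intercept regresses the transformed value on age,
sex, tested body side, handedness (dominant side tested) and stereo-vision
deficits using data from neurologically intact subjects only, and the quality
of that model decides whether the metric can be confound-corrected at all.
Corrected values are then standardized to the intact median/MAD and scaled so
the worst-performing affected subject scores 100%.

The mixed model is fitted by maximum likelihood with the variance ratio
profiled out (a one-dimensional optimisation), which makes the parametric
bootstrap of the likelihood-ratio test affordable; the model is the standard
random-intercept LMM and agrees with ``statsmodels`` MixedLM under ML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import CONFOUND_NAMES, MetricDescriptor

__all__ = [
    "BoxCoxTransform",
    "fit_boxcox",
    "ConfoundModel",
    "ConfoundModelResults",
    "ModelQuality",
    "model_quality",
    "NormalizationParams",
    "normalize",
    "normalization_params",
    "abnormality_cutoff",
    "step1_filter",
    "DegenerateMetricError",
]


class DegenerateMetricError(ValueError):
    """A metric's distribution is too degenerate to process (e.g. MAD = 0)."""


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxCoxTransform:
    """One-parameter power transform with an optional positivity shift.

    ``transform(y) = scale * ((y + shift)**lmbda - 1) / lmbda`` for
    ``lmbda != 0`` and ``scale * log(y + shift)`` in the ``lmbda -> 0``
    limit; strictly increasing on the shifted support and exactly
    invertible.  Fitted transforms use the Jacobian normalization
    ``scale = gm**(1 - lmbda)`` (gm = geometric mean of the training
    values), which anchors the transformed scale to the original data
    units so model coefficients stay comparable across fitted lambdas.
    """

    lmbda: float
    shift: float = 0.0
    scale: float = 1.0

    def transform(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float) + self.shift
        if np.any(y <= 0):
            raise ValueError("values not positive after shift")
        if abs(self.lmbda) < 1e-12:
            return self.scale * np.log(y)
        return self.scale * (np.power(y, self.lmbda) - 1.0) / self.lmbda

    def inverse(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float) / self.scale
        if abs(self.lmbda) < 1e-12:
            y = np.exp(z)
        else:
            y = np.power(self.lmbda * z + 1.0, 1.0 / self.lmbda)
        return y - self.shift


def fit_boxcox(
    values,
    grid: tuple[float, float, float] = (-3.0, 3.0, 0.01),
) -> BoxCoxTransform:
    """Fit the transform by profile log-likelihood over a bounded lambda grid.

    Values at or below zero are handled with ``shift = |min| + eps`` before
    the transform.  Requires at least 10 observations.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 10:
        raise ValueError("need >= 10 values to fit a Box-Cox transform")
    if np.ptp(y) == 0:
        raise DegenerateMetricError("all-constant input")
    shift = 0.0
    if y.min() <= 0:
        shift = abs(y.min()) + 1e-6 * max(np.ptp(y), 1.0)
    lo, hi, step = grid
    lambdas = np.arange(lo, hi + step / 2, step)
    llf = np.array([stats.boxcox_llf(l, y + shift) for l in lambdas])
    lmbda = float(lambdas[np.argmax(llf)])
    gm = float(np.exp(np.mean(np.log(y + shift))))
    return BoxCoxTransform(lmbda=lmbda, shift=shift, scale=gm ** (1.0 - lmbda))


# ---------------------------------------------------------------------------
# Random-intercept mixed model (profiled maximum likelihood)
# ---------------------------------------------------------------------------


@dataclass
class _MLFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau2: float
    llf: float
    no_random_effect: bool


def _profile_nll(rho, y, X, idx, n_g):
    """-2 log-likelihood profiled over beta and sigma2, up to constants."""
    c = rho / (1.0 + n_g * rho)  # per-group shrinkage
    Sx = np.stack([np.add.reduceat(X[:, j], idx) for j in range(X.shape[1])], axis=1)
    Sy = np.add.reduceat(y, idx)
    XtVX = X.T @ X - (Sx * c[:, None]).T @ Sx
    XtVy = X.T @ y - Sx.T @ (c * Sy)
    yVy = y @ y - np.sum(c * Sy**2)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = yVy - beta @ XtVy
    n = y.size
    sigma2 = max(rss / n, 1e-300)
    nll = n * np.log(sigma2) + np.sum(np.log1p(n_g * rho))
    return nll, beta, sigma2, XtVX


def fit_random_intercept_ml(y, X, groups) -> _MLFit:
    """ML fit of ``y = X beta + u_group + e`` with scalar random intercepts.

    ``X`` must include the intercept column.  When every group contributes a
    single observation the random intercept is unidentifiable and the fit
    degenerates to OLS, flagged ``no_random_effect``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, _ = pd.factorize(np.asarray(groups), sort=True)
    order = np.argsort(codes, kind="stable")
    y, X, codes = y[order], X[order], codes[order]
    idx = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    n_g = np.diff(np.r_[idx, codes.size]).astype(float)
    n = y.size

    if np.all(n_g == 1):
        nll, beta, sigma2, XtVX = _profile_nll(0.0, y, X, idx, n_g)
        llf = -0.5 * (nll + n * np.log(2 * np.pi) + n)
        return _MLFit(beta, sigma2 * np.linalg.inv(XtVX), sigma2, 0.0, llf, True)

    def objective(t):
        return _profile_nll(np.exp(t), y, X, idx, n_g)[0]

    res = optimize.minimize_scalar(
        objective, bounds=(-30.0, 12.0), method="bounded",
        options={"xatol": 1e-10},
    )
    rho = float(np.exp(res.x))
    nll0 = _profile_nll(0.0, y, X, idx, n_g)[0]
    if nll0 <= res.fun:  # boundary solution tau2 = 0
        rho = 0.0
    nll, beta, sigma2, XtVX = _profile_nll(rho, y, X, idx, n_g)
    llf = -0.5 * (nll + n * np.log(2 * np.pi) + n)
    return _MLFit(
        beta, sigma2 * np.linalg.inv(XtVX), sigma2, rho * sigma2, llf, False
    )


def _blup(y, X, groups, fit: _MLFit) -> np.ndarray:
    """Predicted random intercept per observation."""
    resid = y - X @ fit.beta
    if fit.no_random_effect or fit.tau2 == 0:
        return np.zeros_like(resid)
    df = pd.DataFrame({"g": np.asarray(groups), "r": resid})
    stats_ = df.groupby("g")["r"].agg(["mean", "count"])
    shrink = fit.tau2 / (fit.tau2 + fit.sigma2 / stats_["count"])
    u = (shrink * stats_["mean"]).to_dict()
    return df["g"].map(u).to_numpy()


# ---------------------------------------------------------------------------
# Confound model (Model / Results pair)
# ---------------------------------------------------------------------------


@dataclass
class ConfoundModelResults:
    """Fitted confound model for one metric.

    ``betas`` is the length-6 coefficient vector (intercept, age, sex, tested
    side, handedness, stereo deficit) in Box-Cox space; covariates dropped for
    singular design keep a 0.0 coefficient and are listed in ``flags``.
    ``confound_p`` holds p-values (Wald by default, parametric-bootstrap LRT
    when computed via :meth:`ConfoundModel.bootstrap_lrt`).
    """

    metric_name: str
    betas: np.ndarray
    bse: np.ndarray
    boxcox: BoxCoxTransform
    random_intercept_sd: float
    residual_sd: float
    llf: float
    confound_p: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    model: "ConfoundModel | None" = None

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.betas, index=("intercept",) + CONFOUND_NAMES)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.betas - z * self.bse
        hi = self.betas + z * self.bse
        return pd.DataFrame(
            {"lower": lo, "upper": hi}, index=("intercept",) + CONFOUND_NAMES
        )

    def remove_confounds(self, values, covariates) -> np.ndarray:
        """Confound-corrected values in Box-Cox space.

        Subtracts only the covariate terms ``beta_1..beta_5 x``; neither the
        intercept nor the subject random effect is removed, so the correction
        is deliberately not idempotent.
        """
        z = self.boxcox.transform(values)
        Xc = np.asarray(covariates, dtype=float)
        if Xc.ndim == 1:
            Xc = Xc[None, :]
        return z - Xc @ self.betas[1:]

    def fitted_original_units(self) -> np.ndarray:
        """Back-transformed fitted values (fixed effects + BLUP intercepts)."""
        m = self.model
        zhat = m.exog_full @ self.betas + _blup(
            m.endog_z, m.exog_full, m.groups, m._mlfit
        )
        return self.boxcox.inverse(zhat)

    def summary(self) -> str:
        lines = [
            f"Confound model: {self.metric_name}",
            f"  Box-Cox lambda = {self.boxcox.lmbda:+.2f}"
            f" (shift {self.boxcox.shift:g})",
            f"  random intercept sd = {self.random_intercept_sd:.4g},"
            f" residual sd = {self.residual_sd:.4g}, llf = {self.llf:.2f}",
            f"  {'term':<16}{'coef':>10}{'se':>10}{'p':>10}",
        ]
        names = ("intercept",) + CONFOUND_NAMES
        for i, name in enumerate(names):
            p = self.confound_p.get(name, np.nan)
            lines.append(
                f"  {name:<16}{self.betas[i]:>10.4f}{self.bse[i]:>10.4f}"
                f"{p:>10.4g}"
            )
        if self.flags:
            lines.append("  flags: " + ", ".join(self.flags))
        return "\n".join(lines)


class ConfoundModel:
    """Mixed-effects confound model for one metric on intact subjects.

    Parameters
    ----------
    values : Series
        Aggregated metric values of intact subjects, indexed by
        (subject_id, side[, session]); typically the test session only.
    covariates : DataFrame
        Design matrix aligned to ``values`` with the five confound columns.
    metric : MetricDescriptor or str
    """

    def __init__(self, values: pd.Series, covariates: pd.DataFrame, metric):
        values = values.dropna()
        covariates = covariates.loc[values.index]
        self.metric_name = metric.metric_name if hasattr(metric, "metric_name") else str(metric)
        self.values = values
        self.covariates = covariates
        self.groups = np.asarray(
            values.index.get_level_values("subject_id")
            if isinstance(values.index, pd.MultiIndex)
            else values.index
        )

    @classmethod
    def from_table(cls, table: pd.DataFrame, subjects, metric: MetricDescriptor):
        """Build from an aggregated metric table restricted to intact rows."""
        from .data import design_matrix

        col = metric.metric_name if hasattr(metric, "metric_name") else metric
        values = table[col]
        return cls(values, design_matrix(subjects, values.index), metric)

    def fit(self, dropped_tol: float = 1e-12) -> ConfoundModelResults:
        y = self.values.to_numpy(dtype=float)
        bc = fit_boxcox(y)
        z = bc.transform(y)

        Xc = self.covariates.to_numpy(dtype=float)
        flags = []
        active = []
        for j, name in enumerate(CONFOUND_NAMES):
            if np.ptp(Xc[:, j]) <= dropped_tol:
                flags.append(f"dropped_covariate:{name}")
            else:
                active.append(j)
        X = np.column_stack([np.ones(len(z)), Xc[:, active]])

        fit = fit_random_intercept_ml(z, X, self.groups)
        if fit.no_random_effect:
            flags.append("no_random_effect")

        betas = np.zeros(6)
        bse = np.full(6, np.nan)
        betas[0] = fit.beta[0]
        bse[0] = np.sqrt(fit.cov_beta[0, 0])
        for k, j in enumerate(active, start=1):
            betas[j + 1] = fit.beta[k]
            bse[j + 1] = np.sqrt(fit.cov_beta[k, k])
        wald_p = {}
        for j, name in enumerate(CONFOUND_NAMES):
            if j in active:
                zstat = betas[j + 1] / bse[j + 1]
                wald_p[name] = float(2 * stats.norm.sf(abs(zstat)))
            else:
                wald_p[name] = np.nan

        self.endog_z = z
        self.exog_full = np.column_stack([np.ones(len(z)), Xc])
        self._mlfit = _MLFit(
            betas, np.eye(6) * np.nan, fit.sigma2, fit.tau2, fit.llf,
            fit.no_random_effect,
        )
        self._active = active
        return ConfoundModelResults(
            metric_name=self.metric_name,
            betas=betas,
            bse=bse,
            boxcox=bc,
            random_intercept_sd=float(np.sqrt(fit.tau2)),
            residual_sd=float(np.sqrt(fit.sigma2)),
            llf=fit.llf,
            confound_p=wald_p,
            flags=flags,
            model=self,
        )

    # -- parametric bootstrap LRT -------------------------------------------

    def _design(self, exclude: str | None = None):
        cols = [j for j in self._active if exclude is None
                or CONFOUND_NAMES[j] != exclude]
        Xc = self.covariates.to_numpy(dtype=float)
        return np.column_stack([np.ones(len(self.endog_z)), Xc[:, cols]])

    def bootstrap_lrt(
        self,
        covariate: str,
        iterations: int = 1000,
        seed: int | np.random.Generator = 0,
        max_redraws: int | None = None,
    ) -> float:
        """Parametric-bootstrap likelihood-ratio p-value for one confound.

        Simulates responses under the reduced model (without ``covariate``),
        refits both models per replicate and returns
        ``p = (1 + #{LR_sim >= LR_obs}) / (1 + iterations)``.  Non-converged
        replicates are redrawn (counted in ``self.lrt_redraws``).
        """
        if iterations < 1:
            raise ValueError("iterations must be >= 1")
        if covariate not in CONFOUND_NAMES:
            raise ValueError(f"unknown covariate {covariate!r}")
        if not hasattr(self, "endog_z"):
            self.fit()
        if covariate not in [CONFOUND_NAMES[j] for j in self._active]:
            return np.nan  # dropped covariate: no test possible

        rng = np.random.default_rng(seed)
        X_full = self._design()
        X_red = self._design(exclude=covariate)
        y = self.endog_z
        groups = self.groups
        full = fit_random_intercept_ml(y, X_full, groups)
        red = fit_random_intercept_ml(y, X_red, groups)
        lr_obs = max(2.0 * (full.llf - red.llf), 0.0)

        uniq, inv = np.unique(groups, return_inverse=True)
        mean_red = X_red @ red.beta
        tau = np.sqrt(red.tau2)
        sig = np.sqrt(red.sigma2)
        exceed = 0
        self.lrt_redraws = 0
        budget = iterations if max_redraws is None else max_redraws
        done = 0
        while done < iterations:
            u = rng.normal(scale=tau, size=uniq.size)[inv]
            ysim = mean_red + u + rng.normal(scale=sig, size=y.size)
            try:
                f_s = fit_random_intercept_ml(ysim, X_full, groups)
                r_s = fit_random_intercept_ml(ysim, X_red, groups)
            except np.linalg.LinAlgError:
                self.lrt_redraws += 1
                if self.lrt_redraws > budget:
                    raise RuntimeError("too many bootstrap refit failures")
                continue
            if max(2.0 * (f_s.llf - r_s.llf), 0.0) >= lr_obs:
                exceed += 1
            done += 1
        return (1.0 + exceed) / (1.0 + iterations)


def fit_confound_model(table, subjects, metric) -> ConfoundModelResults:
    """Functional wrapper: fit the confound model from an intact metric table."""
    return ConfoundModel.from_table(table, subjects, metric).fit()


# ---------------------------------------------------------------------------
# Model quality (criteria C1 / C2)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelQuality:
    """Mean absolute estimation error of a confound model, as % of range.

    ``c1 = 100 * MAE / range`` and ``c2 = 100 * (MAE + 3 sigma) / range``
    where sigma is the standard deviation of the absolute residuals after
    trimming the 5% largest; a model passes iff c1 <= 15 and c2 <= 25.
    """

    mae: float
    sigma: float
    c1: float
    c2: float
    passed: bool


def model_quality(values, predictions, c1_max=15.0, c2_max=25.0) -> ModelQuality:
    """Quality criteria computed in original metric units.

    ``values``/``predictions`` are intact observations and back-transformed
    model predictions; the 5% largest absolute residuals are discarded first.
    """
    y = np.asarray(values, dtype=float)
    yhat = np.asarray(predictions, dtype=float)
    if y.size != yhat.size:
        raise ValueError("values and predictions must align")
    if y.size < 20:
        raise ValueError("need >= 20 aligned points")
    rng_ = float(np.ptp(y))
    if rng_ == 0:
        raise DegenerateMetricError("zero range")
    abs_res = np.abs(y - yhat)
    keep = int(np.floor(0.95 * abs_res.size))
    trimmed = np.sort(abs_res)[:keep]
    mae = float(np.mean(trimmed))
    sigma = float(np.std(trimmed, ddof=1))
    c1 = 100.0 * mae / rng_
    c2 = 100.0 * (mae + 3.0 * sigma) / rng_
    return ModelQuality(mae, sigma, c1, c2, bool(c1 <= c1_max and c2 <= c2_max))


# ---------------------------------------------------------------------------
# Normalization against the intact cohort (robust z, worst-case scaling)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalizationParams:
    """Intact-cohort location/scale and the worst-affected scaling factor."""

    intact_median: float
    mad: float
    sign: int
    worst_scale: float
    abnormal_cutoff: float | None = None


def normalization_params(
    intact_corrected, descriptor: MetricDescriptor, affected_corrected
) -> NormalizationParams:
    """Derive Eq.-style normalization constants from corrected values."""
    v = np.asarray(intact_corrected, dtype=float)
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    if mad == 0:
        raise DegenerateMetricError("MAD of intact values is zero")
    sign = descriptor.sign if descriptor is not None else 1
    aff = sign * (np.asarray(affected_corrected, dtype=float) - med) / mad
    worst = float(np.max(aff))
    if worst <= 0:
        raise DegenerateMetricError(
            "no affected subject performs worse than the intact median"
        )
    return NormalizationParams(med, mad, sign, worst)


def normalize(values, params: NormalizationParams) -> np.ndarray:
    """Percent scale: intact median -> 0, worst affected subject -> 100."""
    v = np.asarray(values, dtype=float)
    yhat = params.sign * (v - params.intact_median) / params.mad
    return 100.0 * yhat / params.worst_scale


def abnormality_cutoff(normalized_intact) -> float:
    """95th percentile of normalized intact values (5% imposed FPR)."""
    v = np.asarray(normalized_intact, dtype=float)
    if v.size < 20:
        raise ValueError("need >= 20 intact values")
    return float(np.percentile(v, 95))


def step1_filter(
    quality: ModelQuality, stereo_p: float, alpha: float = 0.05
) -> tuple[bool, str | None]:
    """Keep/drop decision for selection step 1 with the firing rule recorded."""
    if np.isfinite(stereo_p) and stereo_p < alpha:
        return False, f"stereo vision deficit effect (p={stereo_p:.3g} < {alpha})"
    if not quality.passed:
        reasons = []
        if quality.c1 > 15.0:
            reasons.append(f"C1 = {quality.c1:.1f}% > 15%")
        if quality.c2 > 25.0:
            reasons.append(f"C2 = {quality.c2:.1f}% > 25%")
        return False, " and ".join(reasons)
    return True, None
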