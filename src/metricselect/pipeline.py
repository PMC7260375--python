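"""End-to-end orchestration of the metric selection and validation framework.

``SelectionPipeline`` takes subject demographics, per-trial observations and
the metric registry, then runs:

1. confound modelling per metric on the intact cohort (Box-Cox + mixed
   model), model-quality gating (C1/C2) and the stereo-vision removal rule;
2. clinimetric scoring (AUC, ICC(A,k), SRD%, learning slope) with
   distribution-derived cutoffs over the full evaluated set;
3. iterative partial-Spearman redundancy reduction;
4. structural validation (parallel analysis + promax EFA + KMO) and
   disability-subgroup sensitivity tests.

Every number in the resulting :class:`SelectionLedger` is traceable to a
module operation, survivor sets shrink monotonically across steps, and the
whole run is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinimetrics as cm
from . import confounds as cf
from . import redundancy as rd
from . import structure as st
from .data import (
    MetricDescriptor,
    SubjectRecord,
    aggregate_trials,
    design_matrix,
    subjects_frame,
)

__all__ = ["SelectionPipeline", "SelectionLedger", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class SelectionLedger:
    """Complete audit trail of one framework run."""

    evaluated: list = field(default_factory=list)
    step1_survivors: list = field(default_factory=list)
    step1_reasons: dict = field(default_factory=dict)
    model_reports: dict = field(default_factory=dict)
    scores: pd.DataFrame | None = None
    step2_cutoffs: dict = field(default_factory=dict)
    step2_passers: list = field(default_factory=list)
    step2_survivors: list = field(default_factory=list)  # intersect step 1
    step2_reasons: dict = field(default_factory=dict)
    removal_decisions: list = field(default_factory=list)
    core_set: list = field(default_factory=list)
    degenerate: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    normalized: pd.DataFrame | None = None
    abnormality_cutoffs: dict = field(default_factory=dict)

    def check_monotonic(self) -> bool:
        s0 = set(self.evaluated)
        s1 = set(self.step1_survivors)
        s2 = set(self.step2_survivors)
        s3 = set(self.core_set)
        return s3 <= s2 <= s1 <= s0

    def to_dict(self) -> dict:
        return {
            "evaluated": self.evaluated,
            "step1": {
                "survivors": self.step1_survivors,
                "reasons": self.step1_reasons,
                "models": self.model_reports,
            },
            "step2": {
                "cutoffs": self.step2_cutoffs,
                "criterion_passers": self.step2_passers,
                "survivors": self.step2_survivors,
                "reasons": self.step2_reasons,
                "scores": (
                    self.scores.reset_index().to_dict(orient="records")
                    if self.scores is not None else []
                ),
            },
            "step3": {
                "removals": [d.as_dict() for d in self.removal_decisions],
                "core_set": self.core_set,
            },
            "degenerate": self.degenerate,
            "abnormality_cutoffs": self.abnormality_cutoffs,
            "validation": self.validation,
        }

    def write_report(self, out_dir: str | Path) -> None:
        """Write the machine-readable ledger plus delimited-text tables."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "ledger.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonable)
        if self.scores is not None:
            self.scores.to_csv(out / "scores.csv")
        if self.normalized is not None:
            self.normalized.to_csv(out / "normalized.csv")
        loadings = self.validation.get("loadings")
        if loadings is not None:
            loadings.to_csv(out / "factor_loadings.csv")
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary())

    def summary(self) -> str:
        lines = [
            f"Metrics evaluated: {len(self.evaluated)}",
            f"Step 1 survivors (confound model quality): "
            f"{len(self.step1_survivors)}",
            f"Step 2 criterion passers: {len(self.step2_passers)}"
            f" (intersected with step 1: {len(self.step2_survivors)})",
            f"Step 3 core set: {len(self.core_set)}",
        ]
        if self.core_set:
            lines.append("Core metrics: " + ", ".join(self.core_set))
        if "k" in self.validation:
            lines.append(
                f"Factor analysis: k = {self.validation['k']}, "
                f"KMO = {self.validation.get('kmo', float('nan')):.2f}"
            )
        return "\n".join(lines) + "\n"


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


class SelectionPipeline:
    """Run the full selection and validation framework on one cohort.

    Parameters
    ----------
    subjects, observations
        Cohort demographics and the per-trial observation table.
    registry
        Mapping metric name -> :class:`MetricDescriptor` (orientation).
        Metrics without a registry entry are skipped with a warning entry.
    lrt_iterations
        Parametric-bootstrap iterations for the stereo-vision significance
        test (the step-1 removal rule); other confounds are reported with
        Wald p-values unless ``full_lrt`` is set.
    """

    def __init__(
        self,
        subjects: list[SubjectRecord],
        observations: pd.DataFrame,
        registry: dict[str, MetricDescriptor],
        thresholds: cm.SelectionThresholds = cm.SelectionThresholds(),
        lrt_iterations: int = 1000,
        full_lrt: bool = False,
        seed: int = 0,
        manual_removals: dict | None = None,
        n_factors: int | None = None,
        parallel_sims: int = 200,
        run_validation: bool = True,
    ):
        self.subjects = subjects
        self.observations = observations
        self.registry = registry
        self.thresholds = thresholds
        self.lrt_iterations = lrt_iterations
        self.full_lrt = full_lrt
        self.seed = seed
        self.manual_removals = manual_removals or {}
        self.n_factors = n_factors
        self.parallel_sims = parallel_sims
        self.run_validation = run_validation

    # -- helpers ------------------------------------------------------------

    def _safe_transform(self, bc: cf.BoxCoxTransform, values: np.ndarray
                        ) -> np.ndarray:
        lo = -bc.shift + 1e-9
        return bc.transform(np.maximum(values, lo + 1e-12))

    def run(self) -> SelectionLedger:
        led = SelectionLedger()
        try:
            table = aggregate_trials(self.observations)
        except Exception as e:
            raise PipelineError(f"aggregation stage failed: {e}") from e
        sdf = subjects_frame(self.subjects)
        groups = sdf["group"]
        idx = table.index
        is_intact = idx.get_level_values("subject_id").map(groups).values == "intact"
        is_test = idx.get_level_values("session").values == "test"
        intact_test = table[is_intact & is_test]
        intact_all = table[is_intact]
        affected_test = table[~is_intact & is_test]

        metrics = [m for m in table.columns if m in self.registry]
        led.evaluated = list(metrics)

        X_all = design_matrix(self.subjects, table.index)
        normalized = {}
        rng = np.random.default_rng(self.seed)

        # ---- step 1: confound models, quality gating --------------------
        for m in metrics:
            desc = self.registry[m]
            try:
                model = cf.ConfoundModel.from_table(intact_test, self.subjects, desc)
                fit = model.fit()
                covars = (
                    cf.CONFOUND_NAMES if self.full_lrt else ("stereo_deficit",)
                )
                for cname in covars:
                    p = model.bootstrap_lrt(
                        cname, iterations=self.lrt_iterations,
                        seed=rng.integers(2**31),
                    )
                    fit.confound_p[cname] = p
                quality = cf.model_quality(
                    model.values.to_numpy(float), fit.fitted_original_units()
                )
                keep, reason = cf.step1_filter(
                    quality, fit.confound_p["stereo_deficit"]
                )
            except cf.DegenerateMetricError as e:
                led.degenerate[m] = f"step1: {e}"
                led.step1_reasons[m] = f"degenerate: {e}"
                continue
            except Exception as e:
                raise PipelineError(f"step 1 failed for {m!r}: {e}") from e
            led.model_reports[m] = {
                "lambda": fit.boxcox.lmbda,
                "shift": fit.boxcox.shift,
                "betas": fit.betas.tolist(),
                "p_values": {k: _nan_to_none(v)
                             for k, v in fit.confound_p.items()},
                "random_intercept_sd": fit.random_intercept_sd,
                "residual_sd": fit.residual_sd,
                "c1": quality.c1,
                "c2": quality.c2,
                "quality_pass": quality.passed,
                "flags": fit.flags,
            }
            if keep:
                led.step1_survivors.append(m)
            else:
                led.step1_reasons[m] = reason

            # ---- confound removal + normalization for every unit --------
            try:
                vals = table[m].dropna()
                Xc = X_all.loc[vals.index].to_numpy(float)
                z = self._safe_transform(fit.boxcox, vals.to_numpy(float))
                corrected = pd.Series(
                    z - Xc @ fit.betas[1:], index=vals.index
                )
                corr_intact = corrected[
                    corrected.index.isin(intact_test.index)
                ]
                corr_aff = corrected[
                    corrected.index.isin(affected_test.index)
                ]
                params = cf.normalization_params(
                    corr_intact.to_numpy(), desc, corr_aff.to_numpy()
                )
                norm = pd.Series(
                    cf.normalize(corrected.to_numpy(), params),
                    index=corrected.index, name=m,
                )
                normalized[m] = norm
                led.abnormality_cutoffs[m] = cf.abnormality_cutoff(
                    norm[norm.index.isin(intact_test.index)].to_numpy()
                )
            except cf.DegenerateMetricError as e:
                led.degenerate[m] = f"normalization: {e}"
                if m in led.step1_survivors:
                    led.step1_survivors.remove(m)
                    led.step1_reasons[m] = f"degenerate normalization: {e}"

        norm_table = pd.DataFrame(normalized)
        led.normalized = norm_table

        # ---- step 2: clinimetric scores ---------------------------------
        scores = []
        for m in norm_table.columns:
            col = norm_table[m]
            iv = col[col.index.isin(intact_test.index)].to_numpy(float)
            av = col[col.index.isin(affected_test.index)].to_numpy(float)
            pairs = (
                col[col.index.isin(intact_all.index)]
                .unstack("session")
                .reindex(columns=["test", "retest"])
                .dropna()
                .to_numpy(float)
            )
            try:
                scores.append(cm.score_metric(m, iv, av, pairs))
            except ValueError as e:
                led.degenerate[m] = f"step2: {e}"
        passers, both, info = cm.step2_filter(
            scores, self.thresholds, set(led.step1_survivors)
        )
        led.scores = cm.scores_table(scores)
        led.step2_cutoffs = {
            "srd_pct": info["srd_cutoff"], "eta": info["eta_cutoff"]
        }
        led.step2_passers = passers
        led.step2_survivors = both
        led.step2_reasons = info["reasons"]

        # ---- step 3: redundancy reduction -------------------------------
        if len(both) >= 2:
            red_table = norm_table[both][
                norm_table.index.isin(intact_test.index)
                | norm_table.index.isin(affected_test.index)
            ].dropna()
            priority = rd.psychometric_priority(led.scores)
            core, decisions = rd.iterative_reduction(
                red_table, priority, manual_removals=self.manual_removals
            )
            led.core_set = core
            led.removal_decisions = decisions
        else:
            led.core_set = list(both)

        # ---- validation --------------------------------------------------
        if self.run_validation and len(led.core_set) >= 3:
            try:
                self._validate(led, norm_table, intact_test, affected_test)
            except Exception as e:
                led.validation["error"] = f"validation stage failed: {e}"
        return led

    def _validate(self, led, norm_table, intact_test, affected_test):
        core_table = norm_table[led.core_set][
            norm_table.index.isin(intact_test.index)
            | norm_table.index.isin(affected_test.index)
        ].dropna()
        led.validation["kmo"] = st.kmo(core_table)
        k = self.n_factors
        if k is None:
            k = st.parallel_analysis(
                core_table, n_sim=max(self.parallel_sims, 100),
                seed=self.seed + 1,
            )
        led.validation["k"] = int(k)
        if 1 <= k <= len(led.core_set) - 2:
            fm = st.efa_promax(core_table, k)
            led.validation["loadings"] = fm.loadings
            led.validation["strong_map"] = fm.strong_map
            led.validation["heywood"] = fm.heywood

        labels = st.assign_severity_groups(self.subjects)
        unit_labels = pd.Series(
            norm_table.index.get_level_values("subject_id").map(labels),
            index=norm_table.index,
        )
        subgroups = {}
        sdf = subjects_frame(self.subjects)
        for disease in ("stroke", "ms", "arsacs"):
            dz_ids = set(sdf.index[sdf["group"] == disease])
            if not dz_ids:
                continue
            sel = (
                unit_labels.index.get_level_values("subject_id").isin(dz_ids)
                | (unit_labels == "intact")
            ) & (unit_labels.index.get_level_values("session") == "test")
            for m in led.core_set:
                try:
                    res = st.subgroup_tests(
                        norm_table.loc[sel, m], unit_labels[sel],
                        metric_name=m, n_metrics=len(led.core_set),
                    )
                except ValueError:
                    continue
                subgroups[f"{disease}:{m}"] = {
                    "groups": res.groups,
                    "h": res.omnibus_h,
                    "df": res.omnibus_df,
                    "p": res.omnibus_p,
                    "medians": res.medians.to_dict(),
                }
        led.validation["subgroups"] = subgroups


def _nan_to_none(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else v
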