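"""Redundancy reduction via iterative partial Spearman correlations.

Selection step 3.  Metrics are rank-transformed, the partial correlation of
every pair controlling for all remaining metrics is computed, and the pair
with the largest absolute partial correlation >= 0.5 loses its lower-priority
member; the matrix is recomputed after every single removal until no pair
reaches 0.5.  Priority defaults to the lexicographic psychometric-quality
order (AUC desc, ICC desc, SRD% asc) with an optional manual override list
so documented literature-preference removals stay reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "partial_spearman",
    "partial_spearman_residual",
    "classify_strength",
    "iterative_reduction",
    "RemovalDecision",
    "psychometric_priority",
]

#: Correlation-strength bands (Hinkle scheme) on |rho_p|.
_BANDS = (
    (0.9, "very high"),
    (0.7, "high"),
    (0.5, "moderate"),
    (0.3, "low"),
    (0.0, "very low"),
)


@dataclass(frozen=True)
class RemovalDecision:
    pair: tuple[str, str]
    removed: str
    kept: str
    rho_p: float
    rationale: str  # "worse_psychometrics" | "literature_preference" | "manual"

    def as_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "removed": self.removed,
            "kept": self.kept,
            "rho_p": self.rho_p,
            "rationale": self.rationale,
        }


def _ranked(table: pd.DataFrame) -> np.ndarray:
    x = table.to_numpy(dtype=float)
    return np.apply_along_axis(stats.rankdata, 0, x)


def partial_spearman(
    table: pd.DataFrame, ridge: float = 1e-10
) -> pd.DataFrame:
    """Partial Spearman correlation matrix via the precision matrix.

    With only two metrics there is nothing to control for and the result is
    the plain Spearman correlation.  A singular rank-correlation matrix is
    regularized with a documented ridge (warning flag in ``.attrs``).
    """
    names = list(table.columns)
    if len(names) < 2:
        raise ValueError("need >= 2 metrics")
    r = np.corrcoef(_ranked(table), rowvar=False)
    if len(names) == 2:
        out = pd.DataFrame(r, index=names, columns=names)
        out.attrs["regularized"] = False
        return out
    regularized = False
    try:
        prec = np.linalg.inv(r)
    except np.linalg.LinAlgError:
        prec = np.linalg.inv(r + ridge * np.eye(len(names)))
        regularized = True
    if np.linalg.cond(r) > 1e12 and not regularized:
        prec = np.linalg.inv(r + ridge * np.eye(len(names)))
        regularized = True
    d = np.sqrt(np.diag(prec))
    rho = -prec / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2.0
    out = pd.DataFrame(rho, index=names, columns=names)
    out.attrs["regularized"] = regularized
    return out


def partial_spearman_residual(table: pd.DataFrame) -> pd.DataFrame:
    """Same matrix by the residual-regression route (cross-check path).

    For each pair, both rank vectors are regressed on all remaining rank
    columns and the Pearson correlation of the residuals is taken.
    """
    names = list(table.columns)
    R = _ranked(table)
    p = len(names)
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            if others:
                Z = np.column_stack([np.ones(R.shape[0]), R[:, others]])
                coef_i, *_ = np.linalg.lstsq(Z, R[:, i], rcond=None)
                coef_j, *_ = np.linalg.lstsq(Z, R[:, j], rcond=None)
                ri = R[:, i] - Z @ coef_i
                rj = R[:, j] - Z @ coef_j
            else:
                ri, rj = R[:, i] - R[:, i].mean(), R[:, j] - R[:, j].mean()
            out[i, j] = out[j, i] = np.dot(ri, rj) / np.sqrt(
                np.dot(ri, ri) * np.dot(rj, rj)
            )
    return pd.DataFrame(out, index=names, columns=names)


def classify_strength(rho_p: float) -> str:
    """Band label for |rho_p| (very low ... very high)."""
    a = abs(rho_p)
    if a > 1 + 1e-12:
        raise ValueError("|rho_p| must be <= 1")
    for lo, label in _BANDS:
        if a >= lo:
            return label
    return "very low"


def psychometric_priority(scores: pd.DataFrame):
    """Total order over metrics: higher AUC, then higher ICC, then lower SRD%.

    ``scores`` is indexed by metric name with auc/icc/srd_pct columns.
    Returns a key function; larger key = higher priority (kept).  Metric name
    (reversed lexicographic) breaks exact ties deterministically.
    """

    def key(name: str):
        row = scores.loc[name]
        return (row["auc"], row["icc"], -row["srd_pct"], _name_key(name))

    return key


def _name_key(name: str):
    # later alphabetical names lose ties
    return tuple(-ord(c) for c in name)


def iterative_reduction(
    table: pd.DataFrame,
    priority,
    threshold: float = 0.5,
    manual_removals: dict[frozenset, str] | None = None,
    mode: str = "single",
) -> tuple[list[str], list[RemovalDecision]]:
    """Iteratively remove the lower-priority member of correlated pairs.

    Parameters
    ----------
    priority : callable
        Key function over metric names; the member with the smaller key is
        removed.
    manual_removals : mapping frozenset({a, b}) -> metric-to-remove
        Overrides the priority for documented literature-based choices.
    mode : "single" | "batch"
        Recompute the matrix after each removal (default) or remove every
        over-threshold pair member per sweep before recomputing.
    """
    manual_removals = manual_removals or {}
    remaining = list(table.columns)
    decisions: list[RemovalDecision] = []

    def decide(a: str, b: str, rho: float) -> RemovalDecision:
        override = manual_removals.get(frozenset((a, b)))
        if override is not None:
            removed = override
            rationale = "manual"
        else:
            removed = a if priority(a) < priority(b) else b
            rationale = "worse_psychometrics"
        kept = b if removed == a else a
        return RemovalDecision((a, b), removed, kept, float(rho), rationale)

    while len(remaining) >= 2:
        rho = partial_spearman(table[remaining])
        tri = rho.where(np.triu(np.ones(rho.shape, dtype=bool), k=1))
        flat = tri.abs().stack()
        over = flat[flat >= threshold]
        if over.empty:
            break
        if mode == "single":
            (a, b) = over.idxmax()
            d = decide(a, b, rho.loc[a, b])
            decisions.append(d)
            remaining.remove(d.removed)
        elif mode == "batch":
            batch_removed = set()
            for (a, b) in over.sort_values(ascending=False).index:
                if a in batch_removed or b in batch_removed:
                    continue
                d = decide(a, b, rho.loc[a, b])
                decisions.append(d)
                batch_removed.add(d.removed)
            remaining = [m for m in remaining if m not in batch_removed]
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return remaining, decisions
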