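"""Relative expression from qPCR Ct tables (comparative ddCt method).

Given per-well threshold cycles for a target and a reference gene across
conditions, expression relative to a control condition is
``2 ** -ddCt`` where ``dCt = Ct_target - Ct_reference`` within a sample and
``ddCt = mean dCt(condition) - mean dCt(control)``.  Confidence intervals
come from the t distribution on the per-replicate dCt values (Welch-style
variance pooling across the two condition groups).

The public surface follows the statsmodels convention: construct a
:class:`DeltaDeltaCt` model around a tidy table, call :meth:`~DeltaDeltaCt.fit`
to obtain a :class:`DeltaDeltaCtResults` with a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError

__all__ = [
    "DeltaDeltaCt",
    "DeltaDeltaCtResults",
    "compute_ddct",
    "crosstalk_report",
]

_REQUIRED = ("sample", "condition", "target", "ct")


def _check_table(table: pd.DataFrame, reference_target: str) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise InputError(f"Ct table missing columns: {missing}")
    t = table.copy()
    t["ct"] = pd.to_numeric(t["ct"], errors="coerce")
    if t["ct"].isna().any():
        raise InputError("non-numeric Ct values in table")
    if (t["ct"] <= 0).any() or (t["ct"] >= 50).any():
        raise InputError("Ct values must lie in (0, 50) cycles")
    if reference_target not in set(t["target"]):
        raise InputError(f"reference target {reference_target!r} absent from table")
    return t


def compute_ddct(
    table: pd.DataFrame,
    reference_target: str,
    control_condition: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-condition fold change relative to the control, with t-intervals.

    Returns one row per condition with columns ``condition, n, dct_mean,
    dct_sd, ddct, fold, ci_low, ci_high``.  The control row has fold 1.0 by
    construction (its own ddCt is zero) and an interval reflecting only its
    replicate scatter.
    """
    if not (0 < alpha < 1):
        raise ParameterError("alpha must be in (0, 1)")
    t = _check_table(table, reference_target)
    conditions = list(dict.fromkeys(t["condition"]))
    if control_condition not in conditions:
        raise InputError(f"control condition {control_condition!r} absent")

    # per-sample dCt = target Ct - reference Ct; samples lacking either
    # kind of well are dropped with a warning rather than failing the run
    dct_rows = []
    for (sample, cond), grp in t.groupby(["sample", "condition"], sort=False):
        ref = grp.loc[grp["target"] == reference_target, "ct"]
        tgt = grp.loc[grp["target"] != reference_target, "ct"]
        if ref.empty or tgt.empty:
            warnings.warn(
                f"sample {sample!r} lacks target or reference wells; dropped",
                stacklevel=2,
            )
            continue
        dct_rows.append(
            {"sample": sample, "condition": cond,
             "dct": float(tgt.mean() - ref.mean())}
        )
    dct = pd.DataFrame(dct_rows)
    surviving = set(dct["condition"]) if not dct.empty else set()
    empty = [c for c in conditions if c not in surviving]
    if empty:
        raise InputError(f"conditions with zero usable replicates: {empty}")

    ctrl = dct.loc[dct["condition"] == control_condition, "dct"].to_numpy()
    out = []
    for cond in conditions:
        vals = dct.loc[dct["condition"] == cond, "dct"].to_numpy()
        n = len(vals)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        if cond == control_condition:
            ddct = 0.0
            se = sd / np.sqrt(n) if n > 1 else 0.0
            df = n - 1
        else:
            ddct = mean - float(ctrl.mean())
            v1 = vals.var(ddof=1) / n if n > 1 else 0.0
            v0 = ctrl.var(ddof=1) / len(ctrl) if len(ctrl) > 1 else 0.0
            se = float(np.sqrt(v1 + v0))
            if v1 + v0 > 0 and n > 1 and len(ctrl) > 1:
                df = (v1 + v0) ** 2 / (
                    v1**2 / (n - 1) + v0**2 / (len(ctrl) - 1)
                )
            else:
                df = max(n - 1, 1)
        if se > 0 and df > 0:
            tcrit = float(stats.t.ppf(1 - alpha / 2, df))
            lo, hi = ddct - tcrit * se, ddct + tcrit * se
        else:
            lo = hi = ddct
        out.append(
            {
                "condition": cond,
                "n": n,
                "dct_mean": mean,
                "dct_sd": sd,
                "ddct": float(ddct),
                "fold": float(2.0**-ddct),
                "ci_low": float(2.0**-hi),
                "ci_high": float(2.0**-lo),
            }
        )
    return pd.DataFrame(out)


def crosstalk_report(
    folds: dict[str, float],
    threshold: float = 1.5,
) -> pd.DataFrame:
    """Qualitative direction-of-change summary over per-target fold changes.

    For each target the fold change (versus a shared control) is classified
    as ``up`` (fold > ``threshold``), ``down`` (fold < 1/``threshold``) or
    ``unchanged``.  This is the cross-knockdown specificity view: a
    knockdown intended for one isoform showing ``down`` on a different
    target reveals crosstalk, an unexpected ``up`` reveals compensation.

    Returns one row per target, ordered by target name, with columns
    ``target, fold, direction``.
    """
    if len(folds) < 2:
        raise InputError("crosstalk report needs at least two targets")
    if threshold <= 1:
        raise ParameterError("threshold must exceed 1")
    rows = []
    for target in sorted(folds):
        fold = float(folds[target])
        if fold <= 0:
            raise InputError(f"fold for {target!r} must be positive")
        if fold > threshold:
            direction = "up"
        elif fold < 1.0 / threshold:
            direction = "down"
        else:
            direction = "unchanged"
        rows.append({"target": target, "fold": fold, "direction": direction})
    return pd.DataFrame(rows)


class DeltaDeltaCt:
    """Comparative-Ct model over a tidy Ct table.

    Parameters
    ----------
    table:
        Long-format wells with columns ``sample, condition, target, ct``.
    reference_target:
        Housekeeping gene used for within-sample normalisation.
    control_condition:
        Condition whose expression defines fold 1.0.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        reference_target: str,
        control_condition: str,
    ):
        self.table = _check_table(table, reference_target)
        self.reference_target = reference_target
        self.control_condition = control_condition

    def fit(self, alpha: float = 0.05) -> "DeltaDeltaCtResults":
        folds = compute_ddct(
            self.table, self.reference_target, self.control_condition, alpha
        )
        return DeltaDeltaCtResults(self, folds, alpha)


@dataclass
class DeltaDeltaCtResults:
    model: DeltaDeltaCt
    folds: pd.DataFrame
    alpha: float

    def fold(self, condition: str) -> float:
        row = self.folds[self.folds["condition"] == condition]
        if row.empty:
            raise InputError(f"no condition {condition!r} in results")
        return float(row["fold"].iloc[0])

    def conf_int(self, condition: str) -> tuple[float, float]:
        row = self.folds[self.folds["condition"] == condition]
        if row.empty:
            raise InputError(f"no condition {condition!r} in results")
        return float(row["ci_low"].iloc[0]), float(row["ci_high"].iloc[0])

    def summary(self) -> str:
        lines = [
            "Relative expression (ddCt)",
            f"  reference: {self.model.reference_target}"
            f"   control: {self.model.control_condition}"
            f"   alpha: {self.alpha:g}",
            f"  {'condition':<16}{'n':>3}{'fold':>10}{'ci_low':>10}{'ci_high':>10}",
        ]
        for _, r in self.folds.iterrows():
            lines.append(
                f"  {r['condition']:<16}{int(r['n']):>3}"
                f"{r['fold']:>10.4f}{r['ci_low']:>10.4f}{r['ci_high']:>10.4f}"
            )
        return "\n".join(lines)
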