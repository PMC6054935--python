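"""Two-group differential expression: signed fold change, ANOVA, filtering.

Fold changes follow the signed-ratio convention used in microarray tables:
for the case/control ratio ``r``, the reported value is ``r`` when ``r >= 1``
and ``-1/r`` otherwise, so down-regulation reads as a negative magnitude and
``|fc| >= 1`` always.  Significance is a one-way ANOVA on log2 intensities,
which for two groups is equivalent to the pooled-variance t-test.  Multiple
testing uses the Bonferroni correction; whether the decision p-value is raw
or corrected is configurable (``p_mode``), with ``bonferroni`` the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from psanet.containers import ExpressionMatrix
from psanet.errors import DomainError, ParameterError

P_MODES = ("raw", "bonferroni")


@dataclass(frozen=True)
class FilterConfig:
    """Modulation thresholds: ``|fc| >= fc_threshold`` and ``p <= p_threshold``."""

    fc_threshold: float = 1.5
    p_threshold: float = 0.01
    p_mode: str = "bonferroni"

    def validate(self) -> "FilterConfig":
        if self.fc_threshold < 1.0:
            raise ParameterError("fc_threshold must be >= 1")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ParameterError("p_threshold must be in (0, 1]")
        if self.p_mode not in P_MODES:
            raise ParameterError(f"p_mode must be one of {P_MODES}")
        return self


@dataclass(frozen=True)
class DifferentialRecord:
    """Per-transcript differential-expression result."""

    transcript_id: str
    transcript_class: str
    fc: float
    p_raw: float
    p_adj: float
    modulated: bool
    p_upper_bound: bool = False


def signed_fold_change(case_mean: float, control_mean: float) -> float:
    """Signed linear fold change of case over control means.

    Both means must be positive (linear-scale intensities).
    """
    if case_mean <= 0 or control_mean <= 0:
        raise DomainError("fold change requires positive linear means")
    r = case_mean / control_mean
    return r if r >= 1.0 else -1.0 / r


def two_group_test(values_case, values_control) -> float:
    """One-way ANOVA p-value across two groups (caller supplies the scale).

    Equivalent to the two-sided pooled-variance t-test for two groups.  When
    both groups are constant with equal means the p-value is 1 by convention.
    """
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("need at least 2 values per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DomainError("non-finite expression values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.f_oneway(a, b).pvalue
    if np.isnan(p):  # zero variance everywhere: identical constant groups
        return 1.0
    return float(p)


def bonferroni_adjust(p_values) -> np.ndarray:
    """Bonferroni-corrected p-values: ``min(1, p * m)`` for m tests."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size)


def differential_table(
    expr: ExpressionMatrix, config: FilterConfig | None = None
) -> pd.DataFrame:
    """Compute the per-transcript differential table for a two-group cohort.

    Tests run on log2-transformed intensities; fold changes on linear group
    means.  Duplicate transcript ids keep the record with the largest ``|fc|``
    (a warning is emitted).  Returns a DataFrame indexed by ``transcript_id``
    with columns ``transcript_class, fc, p_raw, p_adj, modulated``, ordered by
    ``|fc|`` descending with ties broken by id.
    """
    config = (config or FilterConfig()).validate()
    case = expr.values[expr.case_samples].to_numpy(dtype=float)
    ctrl = expr.values[expr.control_samples].to_numpy(dtype=float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ParameterError("need at least 2 samples per group")
    if (case <= 0).any() or (ctrl <= 0).any():
        raise DomainError("linear intensities must be positive")

    case_mean = case.mean(axis=1)
    ctrl_mean = ctrl.mean(axis=1)
    r = case_mean / ctrl_mean
    fc = np.where(r >= 1.0, r, -1.0 / r)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_raw = stats.f_oneway(np.log2(case), np.log2(ctrl), axis=1).pvalue
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)

    table = pd.DataFrame(
        {
            "transcript_class": expr.transcript_class.to_numpy(),
            "fc": fc,
            "p_raw": p_raw,
        },
        index=expr.values.index.copy(),
    )

    if table.index.has_duplicates:
        warnings.warn(
            "duplicate transcript ids: keeping the record with max |fc|",
            stacklevel=2,
        )
        table = (
            table.assign(_absfc=table["fc"].abs())
            .sort_values("_absfc", ascending=False, kind="mergesort")
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_absfc")
        )

    table["p_adj"] = bonferroni_adjust(table["p_raw"].to_numpy())
    p_used = table["p_raw"] if config.p_mode == "raw" else table["p_adj"]
    table["modulated"] = (table["fc"].abs() >= config.fc_threshold) & (
        p_used <= config.p_threshold
    )
    order = np.lexsort((table.index.to_numpy(), -table["fc"].abs().to_numpy()))
    return table.iloc[order]


def filter_modulated(
    table: pd.DataFrame, config: FilterConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Partition the modulated subset of a differential table by class.

    A record is retained iff ``|fc| >= fc_threshold`` and the configured
    decision p-value is ``<= p_threshold``.  Each partition is ordered by
    ``|fc|`` descending, ties broken by transcript id.
    """
    config = (config or FilterConfig()).validate()
    p_used = table["p_raw"] if config.p_mode == "raw" else table["p_adj"]
    keep = table[
        (table["fc"].abs() >= config.fc_threshold) & (p_used <= config.p_threshold)
    ]
    order = np.lexsort((keep.index.to_numpy(), -keep["fc"].abs().to_numpy()))
    keep = keep.iloc[order]
    return {
        cls: sub for cls, sub in keep.groupby("transcript_class", sort=True)
    }
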