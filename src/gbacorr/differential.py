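"""Two-condition replicate differential analysis (volcano statistics).

Per protein: log2 fold change of condition B over condition A (difference of
replicate means on the log2 scale), a two-sided Welch unequal-variance
comparison of the replicate log2 values, and Benjamini–Hochberg q-values
across all tested proteins. Welch on log2 intensities is the robust default
for small-n (typically 4-replicate) proteomics designs; no between-replicate
normalisation is applied — inputs are assumed pre-normalised.

A group statistic aggregates named subunits (e.g. the members of a complex)
as the geometric mean fold change: 2 to the arithmetic mean of member log2
fold changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ConditionTable, ValidationError

logger = logging.getLogger("gbacorr")

_MIN_P = np.nextafter(0.0, 1.0)  # p must lie in (0, 1]


@dataclass
class DifferentialTable:
    """Per-protein log2fc, p and BH q; untested proteins keep NaN stats.

    ``table`` columns: ``log2fc``, ``p_value``, ``q_value``, ``n_a``,
    ``n_b``, ``tested``; index = protein ids. q-values satisfy the BH
    step-up monotonicity and are never below their raw p.
    """

    table: pd.DataFrame
    condition_a: str
    condition_b: str

    @property
    def protein_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_tested(self) -> int:
        return int(self.table["tested"].sum())


@dataclass
class GroupFoldChange:
    label: str
    members_used: list[str]
    members_skipped: list[str]
    fold_change: float  # linear scale, = 2**mean(member log2fc)
    member_log2fc: dict[str, float]


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a[0] == b[0]:
            logger.warning("all replicates identical in both conditions; p=1")
            return 1.0
        return _MIN_P  # zero variance, different means: infinitely strong
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    if np.isnan(p):
        return 1.0
    return float(np.clip(p, _MIN_P, 1.0))


def differential_table(
    t: ConditionTable, log_input: bool = False, min_replicates: int = 2
) -> DifferentialTable:
    """Welch test + BH over all proteins with ≥ ``min_replicates`` finite
    replicates per condition; others carry ABSENT (NaN) statistics.

    Raw intensities must be strictly positive unless ``log_input``; they are
    log2-transformed before testing. log2fc = mean(log2 B) − mean(log2 A).
    """
    a_raw, b_raw = t.a, t.b
    if not log_input:
        for arr in (a_raw, b_raw):
            finite = arr[np.isfinite(arr)]
            if (finite <= 0.0).any():
                raise ValidationError(
                    "raw intensities must be strictly positive; "
                    "pass log_input=True for log2-scale tables"
                )
        a_raw = np.log2(a_raw)
        b_raw = np.log2(b_raw)

    n = len(t.protein_ids)
    log2fc = np.full(n, np.nan)
    pvals = np.full(n, np.nan)
    n_a = np.isfinite(a_raw).sum(axis=1)
    n_b = np.isfinite(b_raw).sum(axis=1)
    tested = (n_a >= min_replicates) & (n_b >= min_replicates)
    if not tested.all():
        logger.warning(
            "%d protein(s) below the %d-replicate minimum; reported with "
            "ABSENT statistics", int((~tested).sum()), min_replicates,
        )
    for i in np.flatnonzero(tested):
        ai = a_raw[i][np.isfinite(a_raw[i])]
        bi = b_raw[i][np.isfinite(b_raw[i])]
        log2fc[i] = bi.mean() - ai.mean()
        pvals[i] = _welch_p(ai, bi)

    qvals = np.full(n, np.nan)
    idx = np.flatnonzero(tested)
    if idx.size:
        qvals[idx] = multipletests(pvals[idx], method="fdr_bh")[1]
        qvals[idx] = np.maximum(qvals[idx], pvals[idx])
        qvals[idx] = np.clip(qvals[idx], _MIN_P, 1.0)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": pvals,
            "q_value": qvals,
            "n_a": n_a,
            "n_b": n_b,
            "tested": tested,
        },
        index=pd.Index(t.protein_ids, name="protein_id"),
    )
    return DifferentialTable(table, t.condition_a, t.condition_b)


def group_fold_change(
    d: DifferentialTable, members, label: str = ""
) -> GroupFoldChange:
    """Linear fold change of a protein group: 2**(mean member log2fc)."""
    members = list(dict.fromkeys(members))
    used, skipped, fcs = [], [], {}
    for m in members:
        if m in d.table.index and bool(d.table.at[m, "tested"]):
            used.append(m)
            fcs[m] = float(d.table.at[m, "log2fc"])
        else:
            skipped.append(m)
    if not used:
        raise ValidationError("no group member was tested")
    if skipped:
        logger.warning("group %r: skipped untested members %s", label,
                       ", ".join(skipped))
    fold = float(2.0 ** np.mean([fcs[m] for m in used]))
    return GroupFoldChange(label=label, members_used=used,
                           members_skipped=skipped, fold_change=fold,
                           member_log2fc=fcs)
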