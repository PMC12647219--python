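"""Set-level validation statistics for the correlation matrix.

Two complementary checks that functionally related proteins correlate more
strongly than bulk proteins:

* per-annotation-term medians of within-term pairwise correlations, whose
  distribution across terms is compared with the global background median
  (the median of all off-diagonal correlations);
* the correlation distribution over a curated pair set (e.g. high-confidence
  synthetic-lethal pairs) versus the same background.

Pairs whose correlation equals 1 are excluded from term medians: with
zero-imputed sparse data, identical profiles (often all-zero duplicates)
produce exact rho = 1 entries that carry no evidence of coherent regulation.
An empirical null over random member sets of matched size turns the purely
visual shift comparison into a calibrated one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix
from .io import AnnotationMap, PairSet, ValidationError


@dataclass
class TermMedianProfile:
    term_id: str
    n_members_present: int
    n_pairs_used: int
    median_rho: float | None  # None (ABSENT) when no usable pair


@dataclass
class DistributionSummary:
    values: np.ndarray
    median: float | None
    label: str = ""

    @classmethod
    def from_values(cls, values, label: str = "") -> "DistributionSummary":
        arr = np.asarray(values, dtype=np.float64)
        med = float(np.median(arr)) if arr.size else None
        return cls(values=arr, median=med, label=label)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SetEnrichmentResult:
    set_distribution: DistributionSummary
    background_distribution: DistributionSummary
    shift: float | None  # set median − background median; None when empty
    n_pairs_absent: int = 0


def _present_sorted(c: CorrelationMatrix, members: Iterable[str]) -> list[str]:
    present = set(members) & set(c.rho.index)
    return sorted(present)


def term_median(
    c: CorrelationMatrix,
    members: Iterable[str],
    term_id: str = "",
    near_one_tol: float = 0.0,
) -> TermMedianProfile:
    """Median of within-member correlations, each unordered pair once.

    Diagonal entries never enter; pairs with rho exactly 1 are dropped
    (``near_one_tol > 0`` widens this to |rho| ≥ 1 − tol, catching
    floating-point duplicate profiles). Degenerate member sets (fewer than
    two present members, or all pairs excluded) yield an ABSENT median.
    """
    ids = _present_sorted(c, members)
    n_present = len(ids)
    if n_present < 2:
        return TermMedianProfile(term_id, n_present, 0, None)
    sub = c.rho.loc[ids, ids].to_numpy()
    iu = np.triu_indices(n_present, k=1)
    vals = sub[iu]
    if near_one_tol > 0.0:
        keep = np.abs(vals) < 1.0 - near_one_tol
    else:
        keep = vals != 1.0
    vals = vals[keep]
    if vals.size == 0:
        return TermMedianProfile(term_id, n_present, 0, None)
    return TermMedianProfile(term_id, n_present, int(vals.size),
                             float(np.median(vals)))


def background_distribution(
    c: CorrelationMatrix, include_undefined: bool = True
) -> DistributionSummary:
    """All off-diagonal correlations (upper triangle, each pair once).

    With ``include_undefined=False``, pairs involving a constant-vector
    protein (whose rho was set to 0) are left out of the background.
    """
    rho = c.rho.to_numpy()
    p = rho.shape[0]
    iu = np.triu_indices(p, k=1)
    vals = rho[iu]
    if not include_undefined and c.constant_ids:
        flag = np.fromiter((i in c.constant_ids for i in c.rho.index),
                           dtype=bool, count=p)
        keep = ~(flag[iu[0]] | flag[iu[1]])
        vals = vals[keep]
    return DistributionSummary.from_values(vals, label="background")


def all_term_medians(
    c: CorrelationMatrix,
    ann: AnnotationMap,
    near_one_tol: float = 0.0,
) -> tuple[list[TermMedianProfile], DistributionSummary, DistributionSummary]:
    """One profile per term, the distribution of present medians, and the
    global background distribution."""
    profiles = [
        term_median(c, ann.members(t), term_id=t, near_one_tol=near_one_tol)
        for t in ann.terms
    ]
    medians = [p.median_rho for p in profiles if p.median_rho is not None]
    med_summary = DistributionSummary.from_values(medians, label="term-medians")
    return profiles, med_summary, background_distribution(c)


def pair_set_enrichment(
    c: CorrelationMatrix, ps: PairSet, include_undefined: bool = True
) -> SetEnrichmentResult:
    """Pair-set correlation distribution vs the full background.

    Pairs with either member absent from the matrix are counted in
    ``n_pairs_absent`` and skipped. ``shift`` is set median − background
    median (ABSENT when no pair is usable).
    """
    ids = set(c.rho.index)
    vals = []
    absent = 0
    for a, b in sorted(ps.pairs):
        if a in ids and b in ids:
            vals.append(float(c.rho.at[a, b]))
        else:
            absent += 1
    set_dist = DistributionSummary.from_values(vals, label=ps.label or "pair-set")
    bg = background_distribution(c, include_undefined=include_undefined)
    shift = None
    if set_dist.median is not None and bg.median is not None:
        shift = set_dist.median - bg.median
    return SetEnrichmentResult(set_dist, bg, shift, n_pairs_absent=absent)


def random_set_null(
    c: CorrelationMatrix,
    set_size: int,
    n_draws: int,
    seed: int,
    near_one_tol: float = 0.0,
) -> DistributionSummary:
    """Empirical null: term medians of uniformly drawn member sets.

    Reproducible given ``seed``; draws with an ABSENT median (all pairs
    excluded) are skipped.
    """
    if set_size < 2:
        raise ValidationError("set_size must be ≥ 2")
    if n_draws < 1:
        raise ValidationError("n_draws must be ≥ 1")
    ids = np.asarray(c.rho.index, dtype=object)
    if set_size > ids.size:
        raise ValidationError("set_size exceeds protein count")
    rng = np.random.default_rng(seed)
    medians = []
    for _ in range(n_draws):
        draw = rng.choice(ids, size=set_size, replace=False)
        prof = term_median(c, draw, near_one_tol=near_one_tol)
        if prof.median_rho is not None:
            medians.append(prof.median_rho)
    return DistributionSummary.from_values(medians, label="random-set-null")


def term_medians_frame(profiles: Sequence[TermMedianProfile]) -> pd.DataFrame:
    """Per-term TSV-ready table: term, n_members, n_pairs, median."""
    return pd.DataFrame(
        {
            "term": [p.term_id for p in profiles],
            "n_members": [p.n_members_present for p in profiles],
            "n_pairs": [p.n_pairs_used for p in profiles],
            "median_rho": [
                np.nan if p.median_rho is None else p.median_rho
                for p in profiles
            ],
        }
    )
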