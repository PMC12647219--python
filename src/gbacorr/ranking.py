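"""Query-ranked association lists (guilt-by-association ranking).

For a query protein the full correlation row is sorted in descending order
— no significance cutoff is applied; the interest is in the top of the
ranking, not in p-values. By default the query appears in its own list at
rank 1 with rho = 1 (the self-association convention), so a reported
position like "729 of 15,312" counts the query; ``include_query=False``
gives partner-only ranks, which differ by exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix
from .io import ValidationError


@dataclass
class RankedAssociationList:
    """One query's partners ordered by descending rho.

    ``entries`` has columns ``partner_id``, ``rho``, ``rank`` (1-based,
    gap-free). Ties in rho are broken lexicographically on partner id so the
    ordering is deterministic.
    """

    query_id: str
    entries: pd.DataFrame
    dataset_label: str = ""

    def __len__(self) -> int:
        return len(self.entries)


def rank_associations(
    c: CorrelationMatrix,
    query_id: str,
    include_query: bool = True,
    dataset_label: str = "",
) -> RankedAssociationList:
    """Full-length descending-rho ranking of the query's correlation row.

    The query itself is pinned to rank 1 (its diagonal rho is 1); any other
    protein tied at rho = 1 sorts after it. Raises on an unknown query.
    """
    if query_id not in c.rho.index:
        raise ValidationError(f"unknown query id {query_id!r}")
    row = c.rho.loc[query_id]
    partners = np.asarray(row.index, dtype=object)
    rho = row.to_numpy(dtype=np.float64)
    is_query = partners == query_id
    # sort key: query first, then -rho, then lexicographic id
    order = np.lexsort((partners, -rho, ~is_query))
    if not include_query:
        order = order[~is_query[order]]
    entries = pd.DataFrame(
        {
            "partner_id": partners[order],
            "rho": rho[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    return RankedAssociationList(query_id=query_id, entries=entries,
                                 dataset_label=dataset_label)


def top_k(lst: RankedAssociationList, k: int) -> RankedAssociationList:
    """First ``k`` entries, ranks preserved; ``k`` must be in [1, N]."""
    if not 1 <= k <= len(lst):
        raise ValidationError(f"k={k} out of range 1..{len(lst)}")
    return RankedAssociationList(
        query_id=lst.query_id,
        entries=lst.entries.iloc[:k].reset_index(drop=True),
        dataset_label=lst.dataset_label,
    )


def rank_of(lst: RankedAssociationList, target_id: str) -> int:
    """1-based position of ``target_id`` under the list's tie rule."""
    hit = lst.entries.loc[lst.entries["partner_id"] == target_id, "rank"]
    if hit.empty:
        raise ValidationError(f"unknown target id {target_id!r}")
    return int(hit.iloc[0])


def top_k_overlap(
    a: RankedAssociationList, b: RankedAssociationList, k: int
) -> set[str]:
    """Shared partner ids of the two k-prefixes, excluding the queries."""
    ids_a = set(top_k(a, min(k, len(a))).entries["partner_id"]) - {a.query_id}
    ids_b = set(top_k(b, min(k, len(b))).entries["partner_id"]) - {b.query_id}
    return ids_a & ids_b


def write_ranked_list(lst: RankedAssociationList, path, full_precision=False):
    from .io import write_table

    frame = lst.entries[["rank", "partner_id", "rho"]].rename(
        columns={"partner_id": "protein"}
    )
    write_table(frame, path, full_precision=full_precision, index=False)
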