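"""Reading, validation and writing of the four input kinds.

All tabular formats are plain delimited text (TSV by default, CSV accepted):

* abundance matrix — wide table, one header row of sample ids, first column
  of protein ids (or transposed; see ``rows_are_proteins``);
* pair set — ``gene_a<TAB>gene_b[<TAB>evidence]``, no header;
* annotation map — ``protein_id<TAB>term_id``, no header;
* condition table — ``protein_id`` column plus replicate columns named
  ``<condition>_r1``, ``<condition>_r2``, ...

Missingness is represented internally as NaN inside a float64 pandas
DataFrame; configurable string tokens mark missing cells on disk.
Identifiers are opaque strings — no gene-symbol normalisation is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gbacorr")

#: String tokens treated as MISSING when reading abundance / condition tables.
DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN", "null"})

#: printf-style format used by all writers unless full precision is requested.
DEFAULT_FLOAT_FORMAT = "%.6g"


class ValidationError(ValueError):
    """A structural problem in an input file (named row/column where known)."""


def _check_unique_nonempty(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i, name in enumerate(ids):
        if name == "" or name is None:
            raise ValidationError(f"empty {what} id at position {i + 1}")
        if name in seen:
            raise ValidationError(f"duplicate {what} id {name!r}")
        seen.add(name)


@dataclass
class AbundanceMatrix:
    """Proteins × samples intensity grid with explicit missingness (NaN).

    ``data`` holds float64 values on the as-published scale; every cell is
    either finite or NaN (MISSING). Index = protein ids, columns = sample ids.
    """

    data: pd.DataFrame
    source_label: str = ""

    def __post_init__(self) -> None:
        _check_unique_nonempty([str(i) for i in self.data.index], "protein")
        _check_unique_nonempty([str(c) for c in self.data.columns], "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.floating):
            self.data = self.data.astype(np.float64)
            values = self.data.to_numpy()
        if np.isinf(values).any():
            i, j = np.argwhere(np.isinf(values))[0]
            raise ValidationError(
                f"non-finite value for protein {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class AnnotationMap:
    """Term → member-set mapping (flat; no ontology structure)."""

    term_to_members: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.term_to_members = {
            t: frozenset(m) for t, m in self.term_to_members.items() if m
        }

    @property
    def terms(self) -> list[str]:
        return list(self.term_to_members)

    def members(self, term: str) -> frozenset[str]:
        return self.term_to_members[term]

    def __len__(self) -> int:
        return len(self.term_to_members)


def _canon_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class PairSet:
    """Unordered, de-duplicated protein pairs (e.g. synthetic-lethal pairs)."""

    pairs: frozenset[tuple[str, str]]
    label: str = ""

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.pairs:
            if a == b:
                raise ValidationError(f"self-pair ({a!r}, {b!r}) not allowed")
            canon.add(_canon_pair(a, b))
        self.pairs = frozenset(canon)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _canon_pair(*pair) in self.pairs


@dataclass
class ConditionTable:
    """Replicate intensities for two conditions, one row per protein.

    ``a`` and ``b`` are proteins × replicates float64 arrays, NaN-padded when
    replicate counts vary. Values may be raw positive intensities or already
    log2-transformed; downstream analysis takes a flag.
    """

    protein_ids: list[str]
    condition_a: str
    condition_b: str
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        _check_unique_nonempty(self.protein_ids, "protein")
        self.a = np.asarray(self.a, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        n = len(self.protein_ids)
        if self.a.shape[0] != n or self.b.shape[0] != n:
            raise ValidationError("replicate arrays do not match protein count")
        for name, arr in ((self.condition_a, self.a), (self.condition_b, self.b)):
            if arr.size == 0 or np.isfinite(arr).sum(axis=1).min() < 1:
                raise ValidationError(
                    f"a protein has no recorded replicate in condition {name!r}"
                )


# ---------------------------------------------------------------------------
# readers


def _parse_float_grid(stripped: np.ndarray, is_missing: np.ndarray) -> np.ndarray:
    """Correctly-rounded string→float64 grid; unparseable cells become NaN
    (distinguished from MISSING by the caller via ``is_missing``)."""
    cleaned = stripped.copy()
    cleaned[is_missing] = "nan"
    try:
        return cleaned.astype(np.float64)  # numpy parses exactly
    except ValueError:
        pass
    # at least one bad cell: fall back to per-cell parsing to locate it
    numeric = np.full(stripped.shape, np.nan)
    for idx in np.ndindex(stripped.shape):
        if is_missing[idx]:
            continue
        try:
            numeric[idx] = float(stripped[idx])
        except ValueError:
            numeric[idx] = np.nan
    return numeric


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_abundance_matrix(
    path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    rows_are_proteins: bool = True,
    source_label: str | None = None,
) -> AbundanceMatrix:
    """Read a wide abundance table; cells matching ``missing_tokens`` → MISSING.

    Raises :class:`ValidationError` naming the offending row/column for
    malformed headers, duplicate ids, non-numeric cells, or ragged rows.
    """
    path = Path(path)
    tokens = set(missing_tokens)
    sep = _sniff_sep(path)
    try:
        raw = pd.read_csv(
            path, sep=sep, index_col=0, dtype=str,
            keep_default_na=False, na_values=[],
        )
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValidationError(f"malformed table {path.name}: {exc}") from exc
    if raw.columns.size == 0:
        raise ValidationError(f"malformed header in {path.name}: no sample columns")
    if not rows_are_proteins:
        raw = raw.T
    _check_unique_nonempty([str(i) for i in raw.index], "protein")
    _check_unique_nonempty([str(c) for c in raw.columns], "sample")

    cells = raw.to_numpy(dtype=object)
    stripped = np.vectorize(lambda s: s.strip(), otypes=[object])(cells)
    is_missing = np.isin(stripped, list(tokens))
    numeric = _parse_float_grid(stripped, is_missing)
    bad = ~is_missing & ~np.isfinite(numeric)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-numeric cell {stripped[i, j]!r} at protein {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} in {path.name}"
        )
    numeric[is_missing] = np.nan
    frame = pd.DataFrame(numeric, index=raw.index.astype(str),
                         columns=raw.columns.astype(str))
    return AbundanceMatrix(frame, source_label=source_label or path.name)


def read_pair_set(
    path: str | Path,
    reliability_filter: Iterable[str] | None = None,
    label: str = "",
) -> PairSet:
    """Read an unordered pair list, dropping self-pairs (warned, not fatal).

    When ``reliability_filter`` is given, rows whose third (evidence) column
    is not in the filter are dropped.
    """
    path = Path(path)
    keep = set(reliability_filter) if reliability_filter is not None else None
    pairs: set[tuple[str, str]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t" if "\t" in line else ",")
            if len(fields) < 2:
                raise ValidationError(
                    f"{path.name}:{lineno}: expected at least two columns"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise ValidationError(f"{path.name}:{lineno}: blank protein id")
            if a == b:
                logger.warning("%s:%d: dropping self-pair (%s, %s)",
                               path.name, lineno, a, b)
                continue
            if keep is not None:
                evidence = fields[2].strip() if len(fields) > 2 else ""
                if evidence not in keep:
                    continue
            pairs.add(_canon_pair(a, b))
    return PairSet(frozenset(pairs), label=label or path.name)


def read_annotation_map(path: str | Path) -> AnnotationMap:
    """Read a flat protein→term file and invert it into term→members."""
    path = Path(path)
    term_to_members: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t" if "\t" in line else ",")
            if len(fields) < 2:
                raise ValidationError(
                    f"{path.name}:{lineno}: expected protein_id and term_id"
                )
            protein, term = fields[0].strip(), fields[1].strip()
            if not protein or not term:
                raise ValidationError(f"{path.name}:{lineno}: blank id")
            term_to_members.setdefault(term, set()).add(protein)
    return AnnotationMap({t: frozenset(m) for t, m in term_to_members.items()})


def read_condition_table(
    path: str | Path,
    condition_a: str,
    condition_b: str,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> ConditionTable:
    """Read a replicate table with columns ``<cond>_r1 .. <cond>_rk``."""
    path = Path(path)
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                      na_values=[])
    cols = list(raw.columns)
    if not cols or cols[0] != "protein_id":
        raise ValidationError(
            f"malformed header in {path.name}: first column must be protein_id"
        )
    tokens = set(missing_tokens)

    def _cond_cols(cond: str) -> list[str]:
        found = [c for c in cols[1:] if c.startswith(f"{cond}_r")]
        if not found:
            raise ValidationError(
                f"{path.name}: no replicate columns for condition {cond!r}"
            )
        return found

    def _block(sub: pd.DataFrame) -> np.ndarray:
        cells = sub.to_numpy(dtype=object)
        stripped = np.vectorize(lambda s: s.strip(), otypes=[object])(cells)
        is_missing = np.isin(stripped, list(tokens))
        numeric = _parse_float_grid(stripped, is_missing)
        bad = ~is_missing & ~np.isfinite(numeric)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-numeric cell {stripped[i, j]!r} in column "
                f"{sub.columns[j]!r} of {path.name}"
            )
        numeric[is_missing] = np.nan
        return numeric

    a = _block(raw[_cond_cols(condition_a)])
    b = _block(raw[_cond_cols(condition_b)])
    return ConditionTable(
        protein_ids=[s.strip() for s in raw["protein_id"]],
        condition_a=condition_a, condition_b=condition_b, a=a, b=b,
    )


# ---------------------------------------------------------------------------
# writers


def _fmt(value: float, full_precision: bool) -> str:
    if isinstance(value, float) and math.isnan(value):
        return "NA"
    if full_precision:
        return repr(float(value))
    return DEFAULT_FLOAT_FORMAT % value


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    full_precision: bool = False,
    index: bool = True,
) -> None:
    """Write any result table as TSV; floats at 6 significant digits by
    default (shortest round-tripping representation when ``full_precision``)."""
    out = frame.copy()
    for col in out.columns:
        if np.issubdtype(out[col].dtype, np.floating):
            out[col] = out[col].map(lambda v: _fmt(v, full_precision))
    out.to_csv(path, sep="\t", index=index, na_rep="NA", lineterminator="\n")


def write_abundance_matrix(
    m: AbundanceMatrix, path: str | Path, full_precision: bool = False
) -> None:
    write_table(m.data, path, full_precision=full_precision)


def write_condition_table(
    t: ConditionTable, path: str | Path, full_precision: bool = False
) -> None:
    cols: dict[str, np.ndarray] = {}
    for cond, arr in ((t.condition_a, t.a), (t.condition_b, t.b)):
        for r in range(arr.shape[1]):
            cols[f"{cond}_r{r + 1}"] = arr[:, r]
    frame = pd.DataFrame(cols, index=pd.Index(t.protein_ids, name="protein_id"))
    write_table(frame, path, full_precision=full_precision)


def write_pair_set(ps: PairSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(ps.pairs):
            fh.write(f"{a}\t{b}\n")


def write_annotation_map(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(ann.term_to_members):
            for protein in sorted(ann.term_to_members[term]):
                fh.write(f"{protein}\t{term}\n")
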