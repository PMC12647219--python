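"""Panel (protein-complex) subsetting and range summaries.

Given a named panel — by default the canonical centromere proteins
(excluding CENP-F and CENP-J) plus the four NDC80-complex subunits — the
correlation matrix is restricted to the panel for heatmap display, and each
panel protein is summarised by the quartiles of (a) its correlations against
all proteins and (b) its abundance across samples. Abundance quartiles are
taken after NA→0 imputation, so a protein undetected in most samples has its
median and quartiles driven to 0 — a deliberate display of sparseness, not
an artifact. Quartiles use inclusive linear interpolation throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix, impute_zeros
from .io import AbundanceMatrix, ValidationError

logger = logging.getLogger("gbacorr")


@dataclass
class QuartileSummary:
    lower: float
    median: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.median <= self.upper):
            raise ValidationError("quartiles out of order")


@dataclass
class AbundanceSummary(QuartileSummary):
    n_zero_or_missing: int = 0


@dataclass
class PanelProfile:
    panel_ids: list[str]
    sub_matrix: CorrelationMatrix
    correlation_summaries: dict[str, QuartileSummary]
    abundance_summaries: dict[str, AbundanceSummary]


def default_panel() -> list[str]:
    """The bundled centromere + NDC80 panel (user-overridable via a file)."""
    text = resources.files("gbacorr").joinpath("data/default_panel.txt").read_text()
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]


def load_panel(path: str | Path) -> list[str]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    panel = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    if not panel:
        raise ValidationError(f"panel file {path} is empty")
    return panel


def subset_matrix(c: CorrelationMatrix, panel: Sequence[str]) -> CorrelationMatrix:
    """Restrict to the panel, preserving entry values and panel order.

    Panel ids absent from the matrix are dropped with a warning; an empty
    intersection is an error.
    """
    present = [p for p in panel if p in c.rho.index]
    missing = [p for p in panel if p not in c.rho.index]
    if missing:
        logger.warning("panel ids absent from matrix: %s", ", ".join(missing))
    if not present:
        raise ValidationError("no panel id present in the matrix")
    sub = c.rho.loc[present, present]
    return CorrelationMatrix(sub, constant_ids=c.constant_ids & set(present))


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    lo, med, hi = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return float(lo), float(med), float(hi)


def correlation_range_summary(c: CorrelationMatrix, id: str) -> QuartileSummary:
    """Median and quartiles of one protein's off-diagonal correlations."""
    if id not in c.rho.index:
        raise ValidationError(f"unknown protein id {id!r}")
    row = c.rho.loc[id].drop(labels=[id]).to_numpy(dtype=np.float64)
    if row.size == 0:
        raise ValidationError("matrix has a single protein; no correlations")
    lo, med, hi = _quartiles(row)
    return QuartileSummary(lo, med, hi)


def abundance_range_summary(m: AbundanceMatrix, id: str) -> AbundanceSummary:
    """Quartiles of one protein's abundances after NA→0 imputation, plus the
    count of samples at zero or MISSING."""
    if id not in m.data.index:
        raise ValidationError(f"unknown protein id {id!r}")
    raw = m.data.loc[id].to_numpy(dtype=np.float64)
    imputed = np.nan_to_num(raw, nan=0.0)
    lo, med, hi = _quartiles(imputed)
    n_zero = int(np.sum((imputed == 0.0)))
    return AbundanceSummary(lo, med, hi, n_zero_or_missing=n_zero)


def panel_profile(
    c: CorrelationMatrix, m: AbundanceMatrix, panel: Sequence[str]
) -> PanelProfile:
    """Sub-matrix plus per-protein correlation and abundance summaries."""
    sub = subset_matrix(c, panel)
    ids = sub.protein_ids
    corr = {i: correlation_range_summary(c, i) for i in ids}
    abund = {
        i: abundance_range_summary(m, i) for i in ids if i in m.data.index
    }
    return PanelProfile(panel_ids=ids, sub_matrix=sub,
                        correlation_summaries=corr, abundance_summaries=abund)


def panel_summary_frame(profile: PanelProfile) -> pd.DataFrame:
    rows = []
    for i in profile.panel_ids:
        cs = profile.correlation_summaries[i]
        ab = profile.abundance_summaries.get(i)
        rows.append(
            {
                "protein": i,
                "rho_q1": cs.lower, "rho_median": cs.median, "rho_q3": cs.upper,
                "abundance_q1": ab.lower if ab else np.nan,
                "abundance_median": ab.median if ab else np.nan,
                "abundance_q3": ab.upper if ab else np.nan,
                "n_zero_or_missing": ab.n_zero_or_missing if ab else -1,
            }
        )
    return pd.DataFrame(rows)
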