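"""Synthetic pan-cancer-style cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes in
real wide proteomes — co-regulated functional modules embedded in a mostly
independent background, and detection-limit missingness — without attempting
to mimic any real dataset's intensity distribution or tissue composition.

Model (log2-intensity scale). Protein *i* has a baseline ``b_i ~
N(baseline_log_mean, baseline_log_sd²)``; sample-level variation has unit
standard deviation. Members of a planted module share one latent factor per
sample: ``z_ij = b_i + λ f_j + sqrt(1 − λ²) ε_ij`` with ``f, ε ~ N(0,1)``;
non-module proteins are pure noise. The loading λ is calibrated so the
population Spearman correlation between two members hits the requested
target: for bivariate Gaussians ρ_S = (6/π)·arcsin(ρ_P/2), hence
ρ_P = 2·sin(π·ρ_S/6) and λ = sqrt(ρ_P). Intensities are 2**z (positive,
as-published scale).

Missingness is abundance-dependent: a cell is censored with probability
``sigmoid(c − slope·z_std)`` where ``z_std`` is the standardised latent
log2-abundance and the intercept *c* is solved so the expected global rate
matches the spec. With a positive slope, low-baseline proteins lose most of
their values — reproducing the >90 %-missing centromere-protein rows that
exercise the undefined-correlation policy.

All generators take explicit integer seeds; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import AbundanceMatrix, AnnotationMap, ConditionTable, PairSet, ValidationError


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula conversion: ρ_P = 2·sin(π·ρ_S/6)."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def default_protein_ids(n: int, prefix: str = "P") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


@dataclass
class ModuleSpec:
    size: int
    rho: float  # target intra-module Spearman, in [0, 1)

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValidationError("module size must be ≥ 2")
        if not 0.0 <= self.rho < 1.0:
            raise ValidationError("module rho must lie in [0, 1)")


@dataclass
class MissingnessSpec:
    global_rate: float = 0.0  # expected fraction of MISSING cells, [0, 1)
    detection_slope: float = 1.0  # ≥ 0; larger → sharper detection limit

    def __post_init__(self) -> None:
        if not 0.0 <= self.global_rate < 1.0:
            raise ValidationError("global_rate must lie in [0, 1)")
        if self.detection_slope < 0.0:
            raise ValidationError("detection_slope must be ≥ 0")


@dataclass
class CohortSpec:
    n_proteins: int
    n_samples: int
    modules: list[ModuleSpec] = field(default_factory=list)
    baseline_log_mean: float = 20.0
    baseline_log_sd: float = 1.5
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_samples < 2:
            raise ValidationError("need ≥1 protein and ≥2 samples")
        self.modules = [
            m if isinstance(m, ModuleSpec) else ModuleSpec(*m)
            for m in self.modules
        ]
        if sum(m.size for m in self.modules) > self.n_proteins:
            raise ValidationError("module sizes exceed protein count")
        if self.baseline_log_sd < 0.0:
            raise ValidationError("baseline_log_sd must be ≥ 0")
        if not isinstance(self.missingness, MissingnessSpec):
            self.missingness = MissingnessSpec(*self.missingness)


@dataclass
class CohortTruth:
    """Ground truth for a generated cohort (modules occupy the first ids)."""

    module_members: list[list[str]]
    module_rho: list[float]
    loadings: dict[str, float]  # λ per protein; 0 for independent proteins

    @property
    def module_proteins(self) -> set[str]:
        return {p for mod in self.module_members for p in mod}

    def independent_proteins(self, all_ids: Sequence[str]) -> list[str]:
        mod = self.module_proteins
        return [p for p in all_ids if p not in mod]


def generate_cohort(spec: CohortSpec) -> tuple[AbundanceMatrix, CohortTruth]:
    """Draw one cohort; fully reproducible from ``spec.seed``.

    Modules are assigned to the first proteins in id order (module 1 first),
    which keeps the truth interpretable; membership is recorded in the
    returned :class:`CohortTruth` either way.
    """
    rng = np.random.default_rng(spec.seed)
    p, n = spec.n_proteins, spec.n_samples
    ids = default_protein_ids(p)
    baselines = spec.baseline_log_mean + spec.baseline_log_sd * rng.standard_normal(p)
    noise = rng.standard_normal((p, n))

    loadings = np.zeros(p)
    members: list[list[str]] = []
    rhos: list[float] = []
    start = 0
    z = noise.copy()
    for mod in spec.modules:
        lam = float(np.sqrt(spearman_to_pearson(mod.rho)))
        factor = rng.standard_normal(n)
        rows = slice(start, start + mod.size)
        z[rows] = lam * factor[None, :] + np.sqrt(1.0 - lam**2) * noise[rows]
        loadings[rows] = lam
        members.append(ids[start:start + mod.size])
        rhos.append(mod.rho)
        start += mod.size

    z += baselines[:, None]
    intensities = np.exp2(z)

    rate = spec.missingness.global_rate
    if rate > 0.0:
        slope = spec.missingness.detection_slope
        z_std = (z - z.mean()) / z.std()
        if slope == 0.0:
            prob = np.full_like(z_std, rate)
        else:
            c = brentq(
                lambda c0: expit(c0 - slope * z_std).mean() - rate, -50.0, 50.0
            )
            prob = expit(c - slope * z_std)
        censored = rng.random(size=z.shape) < prob
        intensities = np.where(censored, np.nan, intensities)

    frame = pd.DataFrame(intensities, index=pd.Index(ids), columns=[
        f"S{j + 1:04d}" for j in range(n)
    ])
    truth = CohortTruth(
        module_members=members,
        module_rho=rhos,
        loadings={pid: float(l) for pid, l in zip(ids, loadings)},
    )
    return AbundanceMatrix(frame, source_label=f"synthetic-cohort-seed{spec.seed}"), truth


def generate_annotation(
    truth: CohortTruth,
    all_protein_ids: Sequence[str],
    n_random_terms: int,
    random_term_size: int,
    seed: int,
) -> AnnotationMap:
    """One coherent term per planted module plus uniformly random terms.

    Coherent terms are named ``TERM:M<k>``, random terms ``TERM:R<k>``.
    """
    rng = np.random.default_rng(seed)
    terms: dict[str, frozenset[str]] = {}
    for k, mod in enumerate(truth.module_members, start=1):
        terms[f"TERM:M{k}"] = frozenset(mod)
    pool = np.asarray(all_protein_ids, dtype=object)
    if n_random_terms > 0 and random_term_size > len(pool):
        raise ValidationError("random_term_size exceeds protein count")
    for k in range(1, n_random_terms + 1):
        draw = rng.choice(pool, size=random_term_size, replace=False)
        terms[f"TERM:R{k}"] = frozenset(draw.tolist())
    return AnnotationMap(terms)


@dataclass
class PlantedPairSet(PairSet):
    """PairSet whose pairs carry a recorded truth class."""

    classes: dict[tuple[str, str], str] = field(default_factory=dict)

    def pairs_of_class(self, cls: str) -> frozenset[tuple[str, str]]:
        return frozenset(p for p, c in self.classes.items() if c == cls)


def generate_pair_set(
    truth: CohortTruth,
    all_protein_ids: Sequence[str],
    n_planted: int,
    n_null: int,
    seed: int,
) -> PlantedPairSet:
    """Sample ``n_planted`` within-module pairs and ``n_null`` pairs among
    independent proteins; classes recorded per pair."""
    rng = np.random.default_rng(seed)
    within: list[tuple[str, str]] = []
    for mod in truth.module_members:
        for i in range(len(mod)):
            for j in range(i + 1, len(mod)):
                within.append(tuple(sorted((mod[i], mod[j]))))
    if n_planted > len(within):
        raise ValidationError(
            f"requested {n_planted} planted pairs but only {len(within)} "
            "within-module pairs exist"
        )
    chosen_idx = rng.choice(len(within), size=n_planted, replace=False) \
        if n_planted else np.empty(0, dtype=int)
    planted = [within[i] for i in chosen_idx]

    indep = truth.independent_proteins(all_protein_ids)
    nulls: set[tuple[str, str]] = set()
    if n_null:
        if len(indep) < 2:
            raise ValidationError("not enough independent proteins for null pairs")
        while len(nulls) < n_null:
            a, b = rng.choice(len(indep), size=2, replace=False)
            nulls.add(tuple(sorted((indep[a], indep[b]))))
    classes = {p: "planted" for p in planted}
    classes.update({p: "null" for p in sorted(nulls)})
    return PlantedPairSet(
        pairs=frozenset(classes),
        label=f"planted={n_planted};null={n_null}",
        classes=classes,
    )


def generate_depletion(
    n_proteins: int,
    n_replicates: int,
    planted: Mapping[str, float] | None,
    sigma: float,
    seed: int,
    condition_a: str = "wt",
    condition_b: str = "depleted",
    baseline_log_mean: float = 20.0,
    baseline_log_sd: float = 1.5,
) -> ConditionTable:
    """Two-condition replicate experiment with planted linear fold changes.

    Values are log2 intensities (analyse with ``log_input=True``): replicates
    scatter N(0, sigma²) around per-protein baselines, and condition B is
    shifted by log2(fold) for each planted protein. Protein ids follow
    :func:`default_protein_ids`; ``planted`` maps those ids to linear folds.
    """
    if sigma < 0.0:
        raise ValidationError("sigma must be ≥ 0")
    planted = dict(planted or {})
    for pid, fold in planted.items():
        if not fold > 0.0:
            raise ValidationError(f"fold for {pid!r} must be positive")
    rng = np.random.default_rng(seed)
    ids = default_protein_ids(n_proteins)
    unknown = set(planted) - set(ids)
    if unknown:
        raise ValidationError(f"planted ids not in table: {sorted(unknown)}")
    baselines = baseline_log_mean + baseline_log_sd * rng.standard_normal(n_proteins)
    shift = np.array([np.log2(planted.get(pid, 1.0)) for pid in ids])
    a = baselines[:, None] + sigma * rng.standard_normal((n_proteins, n_replicates))
    b = (baselines + shift)[:, None] + sigma * rng.standard_normal(
        (n_proteins, n_replicates)
    )
    return ConditionTable(protein_ids=ids, condition_a=condition_a,
                          condition_b=condition_b, a=a, b=b)
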