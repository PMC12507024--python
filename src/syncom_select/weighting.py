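"""Per-Pfam additive weights: core prevalence, differential prevalence, weight scans.

Two weighting strategies carry defaults: functions *core* to the studied
metagenome group (>50% prevalence) get +0.0005 each, and functions whose
prevalence differs between two groups at Fisher-exact p < .05 get +0.0012.
A third, *genomic* rarity weighting (down-weighting by prevalence across the
genome collection) is selectable but off by default. The weight-estimation
scan re-runs selection over a grid of weights and summarizes the agreement
of the selected communities with their source samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import PfamProfile, ProfileMatrix, match_stats

logger = logging.getLogger(__name__)

DEFAULT_W_CORE = 0.0005
DEFAULT_W_DISC = 0.0012

STRATEGIES = ("core", "disc", "genomic")


@dataclass(frozen=True)
class WeightVector:
    """Non-negative additive per-Pfam weights; absent accessions weigh 0."""

    weights: Mapping[str, float] = field(default_factory=dict)
    w_core: float = DEFAULT_W_CORE
    w_disc: float = DEFAULT_W_DISC

    def __post_init__(self) -> None:
        neg = {p: w for p, w in self.weights.items() if w < 0}
        if neg:
            raise ValueError(f"negative weights not allowed: {neg}")

    def __call__(self, pfam: str) -> float:
        return self.weights.get(pfam, 0.0)

    def __getitem__(self, pfam: str) -> float:
        return self.weights.get(pfam, 0.0)

    @classmethod
    def zero(cls) -> "WeightVector":
        """All-zero (unweighted baseline) vector."""
        return cls(weights={}, w_core=0.0, w_disc=0.0)


def core_functions(group: ProfileMatrix, prevalence_threshold: float = 0.5) -> set[str]:
    """Pfams with prevalence strictly greater than the threshold across the group."""
    if group.n_entities == 0:
        raise ValueError("cannot compute core functions of an empty matrix")
    prev = group.values.mean(axis=0)
    return {p for p, f in zip(group.pfam_universe, prev) if f > prevalence_threshold}


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]]."""
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def discriminatory_functions(
    groupA: ProfileMatrix,
    groupB: ProfileMatrix,
    alpha: float = 0.05,
    fdr: bool = False,
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Per-Pfam differential-prevalence test between two metagenome groups.

    For every Pfam in the union universe a 2x2 present/absent × group table is
    tested (two-sided Fisher exact). Pfams with p < ``alpha`` are assigned to
    the group with the higher prevalence. Returns the two enriched sets plus a
    prevalence table (counts, prevalences, p-values). ``fdr=True`` applies
    Benjamini–Hochberg before thresholding (off by default).
    """
    if groupA.n_entities == 0 or groupB.n_entities == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = groupA.n_entities, groupB.n_entities
    universe = sorted(set(groupA.pfam_universe) | set(groupB.pfam_universe))
    count_a = _presence_counts(groupA, universe)
    count_b = _presence_counts(groupB, universe)

    rows = []
    for p in universe:
        ca, cb = count_a[p], count_b[p]
        pval = fisher_exact_2x2(ca, n_a - ca, cb, n_b - cb)
        rows.append((p, ca, n_a, cb, n_b, ca / n_a, cb / n_b, pval))
    table = pd.DataFrame(
        rows,
        columns=[
            "pfam",
            "count_present_groupA",
            "n_groupA",
            "count_present_groupB",
            "n_groupB",
            "prevalence_A",
            "prevalence_B",
            "p_value",
        ],
    ).set_index("pfam")

    pvals = table["p_value"].to_numpy()
    if fdr:
        pvals = _benjamini_hochberg(pvals)
        table["q_value"] = pvals

    enriched_a: set[str] = set()
    enriched_b: set[str] = set()
    for p, pv in zip(universe, pvals):
        if pv >= alpha:
            continue
        pa, pb = table.at[p, "prevalence_A"], table.at[p, "prevalence_B"]
        if pa > pb:
            enriched_a.add(p)
        elif pb > pa:
            enriched_b.add(p)
        else:  # only reachable with unequal group sizes
            logger.warning("Pfam %s significant but prevalences tie; assigned to neither", p)
    return enriched_a, enriched_b, table


def _presence_counts(matrix: ProfileMatrix, universe: Sequence[str]) -> dict[str, int]:
    counts = dict.fromkeys(universe, 0)
    sums = matrix.values.sum(axis=0)
    for p, s in zip(matrix.pfam_universe, sums):
        counts[p] = int(s)
    return counts


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def build_weight_vector(
    core: Iterable[str],
    disc: Iterable[str],
    w_core: float = DEFAULT_W_CORE,
    w_disc: float = DEFAULT_W_DISC,
) -> WeightVector:
    """Additive weights: weight(p) = w_core·[p ∈ core] + w_disc·[p ∈ disc]."""
    if w_core < 0 or w_disc < 0:
        raise ValueError("weights must be non-negative")
    core, disc = set(core), set(disc)
    weights: dict[str, float] = {}
    for p in core | disc:
        weights[p] = w_core * (p in core) + w_disc * (p in disc)
    return WeightVector(weights=weights, w_core=w_core, w_disc=w_disc)


def genomic_rarity_weights(genomes: ProfileMatrix, w: float) -> WeightVector:
    """Rarity weighting: weight(p) = w · (1 − prevalence of p across the collection)."""
    if w < 0:
        raise ValueError("weight must be non-negative")
    prev = genomes.values.mean(axis=0)
    weights = {p: w * (1.0 - f) for p, f in zip(genomes.pfam_universe, prev) if f < 1.0}
    return WeightVector(weights=weights, w_core=0.0, w_disc=0.0)


def make_grid(stop: float = 0.01, step: float = 0.0001) -> list[float]:
    """Weight grid over (0, stop] in uniform steps — stop/step points.

    The weight-0 baseline is not part of the grid; compute it once separately
    (or include 0.0 explicitly in a custom grid).
    """
    n = round(stop / step)
    return [step * (i + 1) for i in range(n)]


@dataclass(frozen=True)
class WeightScanRow:
    """Summary of one grid weight: mean agreement of selected SynComs with samples."""

    strategy: str
    weight: float
    mean_jaccard: float
    mean_pct_matches: float
    mean_pct_mismatches: float


def weight_scan(
    samples: ProfileMatrix,
    genomes: ProfileMatrix,
    strategy: str,
    grid: Sequence[float],
    samples2: ProfileMatrix | None = None,
    depth: int = 20,
    prevalence_threshold: float = 0.5,
    alpha: float = 0.05,
    on_evaluation=None,
) -> list[WeightScanRow]:
    """Re-run sample-specific selection for each grid weight and summarize.

    For each weight w, only ``strategy`` is weighted (at w); every sample in
    ``samples`` gets an iterative greedy selection, the union profile of the
    picks is compared back to the sample, and the mean Jaccard distance /
    pct matches / pct mismatches over samples form one output row. Rows are
    emitted in grid order. ``on_evaluation(weight, sample_id)`` is invoked
    once per (weight, sample) evaluation when given (bookkeeping hook).
    """
    from .selection import iterative_select  # deferred: avoids import cycle

    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if any(w < 0 for w in grid):
        raise ValueError("grid weights must be non-negative")
    if strategy == "disc" and samples2 is None:
        raise ValueError("strategy 'disc' requires a second sample group")

    core = core_functions(samples) if strategy == "core" else set()
    if strategy == "disc":
        disc, _, _ = discriminatory_functions(samples, samples2, alpha=alpha)
    else:
        disc = set()

    genome_profiles = {p.entity_id: p for p in genomes.profiles()}
    sample_profiles = samples.profiles()

    rows: list[WeightScanRow] = []
    for w in grid:
        if strategy == "core":
            weights = build_weight_vector(core, set(), w_core=w, w_disc=0.0)
        elif strategy == "disc":
            weights = build_weight_vector(set(), disc, w_core=0.0, w_disc=w)
        else:
            weights = genomic_rarity_weights(genomes, w)
        jd, pm, pmm = [], [], []
        for sample in sample_profiles:
            if on_evaluation is not None:
                on_evaluation(w, sample.entity_id)
            trace = iterative_select(sample, genomes, weights, depth=depth)
            union: frozenset[str] = frozenset()
            for gid, _, _ in trace.picks:
                union |= genome_profiles[gid].pfams
            st = match_stats(PfamProfile("syncom", union), sample)
            jd.append(st.jaccard_distance)
            pm.append(st.pct_matches)
            pmm.append(st.pct_mismatches)
        rows.append(
            WeightScanRow(
                strategy=strategy,
                weight=w,
                mean_jaccard=float(np.mean(jd)),
                mean_pct_matches=float(np.mean(pm)),
                mean_pct_mismatches=float(np.mean(pmm)),
            )
        )
    return rows


def scan_design_size(
    n_strategies: int, grid: Sequence[float], n_samples: int
) -> int:
    """Number of (strategy, weight, sample) evaluations a scan schedules."""
    return n_strategies * len(grid) * n_samples
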