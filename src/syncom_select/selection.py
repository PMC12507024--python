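"""Four-step SynCom selection core.

Step 1: per-sample iterative greedy selection with masking — each round the
genome covering the most remaining sample Pfams (plus additive weights on
matches) is picked and its Pfams removed from consideration, up to a depth of
20 strains. Step 2: strains selected in at least a threshold fraction of
samples (default 33.3%) are shortlisted and all size-k combinations
enumerated. Step 3: combinations are filtered so no two members share a
taxon at the configured rank, then scored as a unit — the combined binary
vector against each sample, averaged into the *group score* — and ranked.
Step 4 (the viability walk-down) lives in :mod:`syncom_select.viability`.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from .profiles import PfamProfile, ProfileMatrix
from .weighting import WeightVector

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIX = dict(zip("dpcofgs", RANKS))

DEFAULT_DEPTH = 20
DEFAULT_SYN_SIZE = 10
DEFAULT_PREVALENCE = 1 / 3
DEFAULT_ENUM_CAP = 10**7
DEFAULT_TOP_K = 10_000


@dataclass(frozen=True)
class SelectionTrace:
    """Ordered greedy picks for one sample: (genome_id, score, newly covered Pfams)."""

    sample_id: str
    picks: tuple[tuple[str, float, int], ...]
    depth: int = DEFAULT_DEPTH

    @property
    def genome_ids(self) -> list[str]:
        return [gid for gid, _, _ in self.picks]


@dataclass(frozen=True)
class SynComCandidate:
    """A scored candidate community."""

    members: tuple[str, ...]
    combined_profile: PfamProfile
    group_score: float
    functional_redundancy_pct: float
    n_nonredundant_pfams: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(sorted(self.members)))


@dataclass(frozen=True)
class TaxonomyRecord:
    """GTDB-style rank labels for one genome; empty labels mean unassigned."""

    genome_id: str
    ranks: Mapping[str, str] = field(default_factory=dict)

    def label(self, level: str) -> str:
        return self.ranks.get(level, "")


def parse_gtdbtk_classification(genome_id: str, classification: str) -> TaxonomyRecord:
    """Parse a GTDB-Tk ``classification`` string (``d__...;p__...;...;s__...``)."""
    ranks: dict[str, str] = {}
    for part in classification.split(";"):
        part = part.strip()
        if len(part) >= 3 and part[1:3] == "__" and part[0] in _RANK_PREFIX:
            ranks[_RANK_PREFIX[part[0]]] = part[3:].strip()
    return TaxonomyRecord(genome_id=genome_id, ranks=ranks)


def read_gtdbtk_summary(path: str | Path | IO[str]) -> list[TaxonomyRecord]:
    """Read a GTDB-Tk summary TSV (columns ``user_genome``, ``classification``)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("user_genome", "classification"):
        if col not in df.columns:
            raise ValueError(f"taxonomy file missing required column {col!r}")
    return [
        parse_gtdbtk_classification(row.user_genome, row.classification)
        for row in df.itertuples()
    ]


def score_genome(
    genome: PfamProfile, remaining_sample: PfamProfile, weights: WeightVector
) -> float:
    """Match score: one point per shared Pfam plus its weight; mismatches score 0."""
    inter = genome.pfams & remaining_sample.pfams
    score = float(len(inter))
    if weights.weights:
        score += sum(weights.weights[p] for p in inter & weights.weights.keys())
    return score


def iterative_select(
    sample: PfamProfile,
    genomes: ProfileMatrix,
    weights: WeightVector,
    depth: int = DEFAULT_DEPTH,
) -> SelectionTrace:
    """Greedy sample-specific selection with masking.

    Each round scores every unselected genome against the remaining sample
    profile, picks the maximum (ties broken by lexicographically smallest
    genome_id), removes the pick's Pfams from the remaining profile, and
    repeats until ``depth`` picks have been made or every remaining score is
    zero (early stop, logged).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if genomes.n_entities == 0:
        raise ValueError("genome collection is empty")

    genome_pfams = genomes.pfam_sets()
    wmap = weights.weights
    wkeys = set(wmap)
    remaining = set(sample.pfams)
    unselected = sorted(genome_pfams)
    picks: list[tuple[str, float, int]] = []

    while len(picks) < depth and unselected:
        best_id, best_score, best_new = None, 0.0, 0
        for gid in unselected:  # sorted: first max wins ties lexicographically
            inter = genome_pfams[gid] & remaining
            score = float(len(inter))
            if wkeys:
                score += sum(wmap[p] for p in inter & wkeys)
            if score > best_score:
                best_id, best_score, best_new = gid, score, len(inter)
        if best_id is None:
            logger.info(
                "sample %s: early stop after %d picks (all remaining scores 0)",
                sample.entity_id,
                len(picks),
            )
            break
        picks.append((best_id, best_score, best_new))
        remaining -= genome_pfams[best_id]
        unselected.remove(best_id)
    return SelectionTrace(sample_id=sample.entity_id, picks=tuple(picks), depth=depth)


def shortlist(
    traces: Sequence[SelectionTrace], prevalence_threshold: float = DEFAULT_PREVALENCE
) -> set[str]:
    """Genomes selected in at least the threshold fraction of traces (inclusive)."""
    if not traces:
        raise ValueError("at least one trace required")
    n = len(traces)
    counts: dict[str, int] = {}
    for t in traces:
        for gid in t.genome_ids:
            counts[gid] = counts.get(gid, 0) + 1
    return {gid for gid, c in counts.items() if c / n >= prevalence_threshold}


def enumerate_candidates(
    shortlisted: Iterable[str],
    syn_size: int = DEFAULT_SYN_SIZE,
    cap: int | None = DEFAULT_ENUM_CAP,
) -> Iterator[tuple[str, ...]]:
    """Yield all size-``syn_size`` member sets in lexicographic order over sorted ids."""
    ids = sorted(set(shortlisted))
    if len(ids) < syn_size:
        raise ValueError(
            f"only {len(ids)} shortlisted strains for SynCom size {syn_size}; "
            "lower the prevalence threshold to shortlist more strains"
        )
    n_combos = comb(len(ids), syn_size)
    if cap is not None and n_combos > cap:
        raise ValueError(
            f"C({len(ids)}, {syn_size}) = {n_combos} combinations exceeds the cap "
            f"of {cap}; raise the prevalence threshold or the cap"
        )
    return itertools.combinations(ids, syn_size)


def taxonomic_filter(
    candidates: Iterable[tuple[str, ...]],
    taxonomy: Sequence[TaxonomyRecord] | Mapping[str, TaxonomyRecord],
    level: str = "species",
) -> Iterator[tuple[str, ...]]:
    """Drop candidates in which two members share a nonempty label at ``level``.

    Unassigned (empty) labels never collide. Raises ``KeyError`` naming the
    genome if a member lacks a taxonomy record.
    """
    if level not in RANKS:
        raise ValueError(f"unknown taxonomic level {level!r}; expected one of {RANKS}")
    if not isinstance(taxonomy, Mapping):
        taxonomy = {t.genome_id: t for t in taxonomy}
    for members in candidates:
        labels = []
        for gid in members:
            if gid not in taxonomy:
                raise KeyError(f"no taxonomy record for genome {gid!r}")
            lbl = taxonomy[gid].label(level)
            if lbl:
                labels.append(lbl)
        if len(labels) == len(set(labels)):
            yield members


def functional_redundancy(
    member_profiles: Sequence[PfamProfile],
) -> tuple[float, dict[int, int]]:
    """Percent of union Pfams encoded by exactly one member, plus the full histogram."""
    if not member_profiles:
        raise ValueError("at least one member required")
    counts: dict[str, int] = {}
    for prof in member_profiles:
        for p in prof.pfams:
            counts[p] = counts.get(p, 0) + 1
    histogram: dict[int, int] = {}
    for c in counts.values():
        histogram[c] = histogram.get(c, 0) + 1
    n_union = len(counts)
    n_unique = histogram.get(1, 0)
    pct_unique = 100.0 * n_unique / n_union if n_union else 100.0
    return pct_unique, histogram


def group_score(
    candidate_members: Iterable[str],
    genomes: ProfileMatrix,
    samples: ProfileMatrix,
    weights: WeightVector,
) -> SynComCandidate:
    """Score a member set as a unit: mean combined-vector score over all samples."""
    if samples.n_entities == 0:
        raise ValueError("no samples to score against")
    members = tuple(sorted(set(candidate_members)))
    member_profiles = [genomes.profile(g) for g in members]
    union: frozenset[str] = frozenset().union(*(p.pfams for p in member_profiles))
    combined = PfamProfile(entity_id="+".join(members), pfams=union)

    total = 0.0
    for sid in samples.entity_ids:
        total += score_genome(combined, samples.profile(sid), weights)
    pct_unique, histogram = functional_redundancy(member_profiles)
    return SynComCandidate(
        members=members,
        combined_profile=combined,
        group_score=total / samples.n_entities,
        functional_redundancy_pct=pct_unique,
        n_nonredundant_pfams=histogram.get(1, 0),
    )


def rank_candidates(
    candidates: Iterable[SynComCandidate], top_k: int | None = DEFAULT_TOP_K
) -> list[SynComCandidate]:
    """Order by descending group score; ties by lexicographic member tuple.

    Materialized as a bounded top-K heap (default 10,000) so ranking a large
    candidate stream stays in constant memory.
    """
    keyed = ((-c.group_score, c.members, c) for c in candidates)
    if top_k is None:
        best = sorted(keyed, key=lambda t: (t[0], t[1]))
    else:
        best = heapq.nsmallest(top_k, keyed, key=lambda t: (t[0], t[1]))
    return [c for _, _, c in best]
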