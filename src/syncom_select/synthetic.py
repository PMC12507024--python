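"""Seeded synthetic fixtures for every input the pipeline consumes.

The generators emulate the statistical structure of real inputs — genomes
with a shared functional core plus random accessory families, metagenomes
that are noisy unions of a planted "truth" community, two sample groups with
planted differentially prevalent functions, taxonomy tables with deliberate
same-species duplicates, and growth tables with planted interaction types —
without any downloads. Everything is a pure function of (spec, seed).

Universe layout: the first ``core_frac`` of accessions are core (present in
every genome), the last ``reserved_frac`` form a reserved pool encoded by no
genome (hosting the planted discriminatory functions and part of the sample
noise, so greedy selection still early-stops once the coverable Pfams are
exhausted), and the middle is the accessory pool genomes draw from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .profiles import PfamProfile, ProfileMatrix, build_profile_matrix
from .selection import TaxonomyRecord
from .viability import LABELS, GrowthTable

VALID_LABELS = tuple(sorted(set(LABELS.values())))

#: per-label (effect on i, effect on j) planted as relative growth changes;
#: ±0.20 classifies as signed, ±0.05 as neutral, at the default 0.10 threshold
_LABEL_DELTAS = {
    "mutualism": (0.20, 0.20),
    "commensalism": (0.20, 0.05),
    "parasitism": (0.20, -0.20),
    "neutralism": (0.05, -0.05),
    "amensalism": (-0.05, -0.20),
    "competition": (-0.20, -0.20),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture; all generators are seeded by it."""

    seed: int = 0
    n_genomes: int = 40
    n_samples_per_group: int = 60
    n_groups: int = 1
    universe_size: int = 1000
    core_frac: float = 0.10
    accessory_frac: float = 0.15
    reserved_frac: float = 0.20
    planted_truth_members: int = 10
    planted_disc_pfams: int = 20
    noise_frac: float = 0.05
    n_species_duplicates: int = 2
    interaction_mix: Mapping[str, float] = field(
        default_factory=lambda: {"mutualism": 0.5, "commensalism": 0.3, "neutralism": 0.2}
    )

    def __post_init__(self) -> None:
        if self.n_groups not in (1, 2):
            raise ValueError("n_groups must be 1 or 2")
        for name in ("core_frac", "accessory_frac", "reserved_frac", "noise_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = sum(self.interaction_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"interaction_mix must sum to 1, got {total}")
        bad = set(self.interaction_mix) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"unknown interaction label(s): {sorted(bad)}")


def _universe(spec: FixtureSpec) -> list[str]:
    return [f"PF{i + 1:05d}" for i in range(spec.universe_size)]


def _partition(spec: FixtureSpec) -> tuple[list[str], list[str], list[str]]:
    """Split the universe into (core, accessory pool, reserved pool)."""
    u = _universe(spec)
    n_core = round(spec.core_frac * spec.universe_size)
    n_reserved = round(spec.reserved_frac * spec.universe_size)
    n_acc_each = round(spec.accessory_frac * spec.universe_size)
    accessory = u[n_core : spec.universe_size - n_reserved]
    if len(accessory) < n_acc_each:
        raise ValueError(
            f"universe too small: accessory pool of {len(accessory)} cannot supply "
            f"{n_acc_each} accessory Pfams per genome"
        )
    return u[:n_core], accessory, u[spec.universe_size - n_reserved :]


def genome_ids(spec: FixtureSpec) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(spec.n_genomes)]


def generate_genomes(spec: FixtureSpec) -> tuple[ProfileMatrix, list[TaxonomyRecord]]:
    """Genome profiles (shared core + random accessory) plus taxonomy labels.

    The last ``2 * n_species_duplicates`` genomes are organized into pairs
    sharing a species label, to exercise the taxonomic filter; all other
    species labels are unique.
    """
    core, accessory, _ = _partition(spec)
    n_acc = round(spec.accessory_frac * spec.universe_size)
    rng = np.random.default_rng(spec.seed)
    ids = genome_ids(spec)

    profiles = []
    for gid in ids:
        acc = rng.choice(len(accessory), size=n_acc, replace=False)
        pfams = frozenset(core) | frozenset(accessory[k] for k in acc)
        profiles.append(PfamProfile(entity_id=gid, pfams=pfams))
    matrix = build_profile_matrix(profiles, universe=_universe(spec))

    if 2 * spec.n_species_duplicates > spec.n_genomes:
        raise ValueError("too many species duplicates for the number of genomes")
    taxonomy = []
    n_dup_tail = 2 * spec.n_species_duplicates
    for i, gid in enumerate(ids):
        if i >= spec.n_genomes - n_dup_tail:
            pair = (i - (spec.n_genomes - n_dup_tail)) // 2
            genus = f"Genus{pair % 5 + 1}"  # shared within the planted pair
            species = f"{genus} duplicated{pair + 1}"
        else:
            genus = f"Genus{i % 5 + 1}"
            species = f"{genus} species{i + 1}"
        taxonomy.append(
            TaxonomyRecord(
                genome_id=gid,
                ranks={
                    "domain": "Bacteria",
                    "phylum": f"Phylum{i % 3 + 1}",
                    "class": f"Class{i % 3 + 1}",
                    "order": f"Order{i % 4 + 1}",
                    "family": f"Family{i % 4 + 1}",
                    "genus": genus,
                    "species": species,
                },
            )
        )
    return matrix, taxonomy


def truth_members(spec: FixtureSpec) -> list[str]:
    """The planted community: drawn (seeded) from the non-duplicate genomes."""
    rng = np.random.default_rng(spec.seed + 101)
    eligible = genome_ids(spec)[: spec.n_genomes - 2 * spec.n_species_duplicates]
    if spec.planted_truth_members > len(eligible):
        raise ValueError("not enough non-duplicate genomes for the planted community")
    idx = rng.choice(len(eligible), size=spec.planted_truth_members, replace=False)
    return sorted(eligible[k] for k in idx)


def generate_metagenomes(
    genomes: ProfileMatrix, spec: FixtureSpec
) -> tuple[ProfileMatrix, ProfileMatrix | None, list[str]]:
    """Sample profiles as noisy unions of the planted truth community.

    Each sample is the union of the truth members' profiles plus
    ``noise_frac × |union|`` extra Pfams drawn from the reserved pool. With
    two groups, ``planted_disc_pfams`` reserved-pool Pfams are injected at
    prevalence 0.9 in group A and 0.1 in group B (deterministic counts).
    Returns (group A, group B or None, truth member ids).
    """
    _, accessory, reserved = _partition(spec)
    truth = truth_members(spec)
    truth_union = frozenset().union(*(genomes.pfam_sets()[g] for g in truth))

    disc = reserved[: spec.planted_disc_pfams]
    # noise spans coverable (accessory) and uncoverable (reserved) Pfams so
    # greedy traces vary between samples without bloating the shortlist
    noise_pool = accessory + reserved[spec.planted_disc_pfams :]
    n_noise = round(spec.noise_frac * len(truth_union))
    if n_noise > len(noise_pool):
        raise ValueError("reserved pool too small for the requested noise fraction")
    rng = np.random.default_rng(spec.seed + 202)

    def make_group(group_name: str, disc_prevalence: float | None) -> ProfileMatrix:
        n = spec.n_samples_per_group
        # deterministic per-Pfam presence counts; rng picks which samples
        carriers: dict[str, set[int]] = {}
        if disc_prevalence is not None:
            k = round(disc_prevalence * n)
            for p in disc:
                chosen = rng.choice(n, size=k, replace=False)
                carriers[p] = set(int(c) for c in chosen)
        profiles = []
        for s in range(n):
            pfams = set(truth_union)
            if n_noise:
                noise_idx = rng.choice(len(noise_pool), size=n_noise, replace=False)
                pfams.update(noise_pool[k] for k in noise_idx)
            for p, who in carriers.items():
                if s in who:
                    pfams.add(p)
                else:
                    pfams.discard(p)
            profiles.append(PfamProfile(entity_id=f"{group_name}{s + 1:03d}", pfams=pfams))
        return build_profile_matrix(profiles, universe=_universe(spec))

    if spec.n_groups == 1:
        return make_group("S", None), None, truth
    group_a = make_group("A", 0.9)
    group_b = make_group("B", 0.1)
    return group_a, group_b, truth


def generate_hmmer_files(profiles: ProfileMatrix, out_dir: str | Path) -> list[Path]:
    """Write one syntactically valid HMMER tblout file per entity.

    Accessions are emitted versioned (``.1`` suffix) so the round-trip also
    exercises version stripping. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = (
        "#                                                               --- full sequence ---"
        " --- best 1 domain --- --- domain number estimation ---\n"
        "# target name        accession  query name           accession    E-value  score  bias"
        "   E-value  score  bias   exp reg clu  ov env dom rep inc description of target\n"
        "#------------------- ---------- -------------------- ---------- --------- ------ -----"
        " --------- ------ ----- --- --- --- --- --- --- --- --- ---------------------\n"
    )
    paths = []
    for eid in profiles.entity_ids:
        path = out_dir / f"{eid}.tblout"
        with open(path, "w") as fh:
            fh.write(header)
            for k, acc in enumerate(sorted(profiles.pfam_sets()[eid])):
                fh.write(
                    f"FAM_{acc}             {acc}.1    protein_{k + 1:05d}        -"
                    f"    1.2e-30   99.9   0.1   1.5e-30   99.1   0.1"
                    f"   1.0   1   0   0   1   1   1   1 synthetic family\n"
                )
            fh.write("#\n# Program:         hmmscan\n# [ok]\n")
        paths.append(path)
    return paths


def _label_counts(n_pairs: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of pair labels to the mix fractions."""
    items = sorted(mix.items())
    raw = [(lbl, frac * n_pairs) for lbl, frac in items]
    counts = {lbl: floor(x) for lbl, x in raw}
    short = n_pairs - sum(counts.values())
    by_remainder = sorted(raw, key=lambda t: (-(t[1] - floor(t[1])), t[0]))
    for lbl, _ in by_remainder[:short]:
        counts[lbl] += 1
    return counts


def generate_growth_fixture(
    members: Sequence[str],
    interaction_mix: Mapping[str, float],
    seed: int = 0,
    baseline: float = 100.0,
) -> GrowthTable:
    """A growth table whose pairwise classifications reproduce the mix exactly.

    Each unordered pair is assigned a label (largest-remainder apportionment
    over the mix, shuffled by the seed), then alone/paired growth values are
    constructed so that classification at the default 0.10 threshold recovers
    exactly that label (±20% changes for signed effects, ±5% for neutral).
    Community growth is held at the positive baseline for every strain.
    """
    total = sum(interaction_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"interaction_mix must sum to 1, got {total}")
    bad = set(interaction_mix) - set(VALID_LABELS)
    if bad:
        raise ValueError(f"unknown interaction label(s): {sorted(bad)}")

    strains = sorted(set(members))
    pairs = [(i, j) for a, i in enumerate(strains) for j in strains[a + 1 :]]
    counts = _label_counts(len(pairs), interaction_mix)
    labels = [lbl for lbl, c in sorted(counts.items()) for _ in range(c)]
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)

    alone = {s: baseline for s in strains}
    paired: dict[tuple[str, str], float] = {}
    for (i, j), lbl in zip(pairs, labels):
        d_i, d_j = _LABEL_DELTAS[lbl]
        if rng.random() < 0.5:  # randomize which partner gets which side
            d_i, d_j = d_j, d_i
        paired[(i, j)] = baseline * (1.0 + d_i)
        paired[(j, i)] = baseline * (1.0 + d_j)
    community = {s: baseline for s in strains}
    return GrowthTable(
        strains=tuple(strains),
        growth_alone=alone,
        growth_paired=paired,
        growth_community=community,
    )
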