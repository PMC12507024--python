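"""Ecological viability screening of ranked candidate communities.

Pairwise interactions are classified from growth outcomes: each partner's
growth in co-culture is compared with its growth alone, a relative change
beyond ±10% counting as a positive/negative effect. The unordered effect
pair maps to a label (mutualism, commensalism, parasitism, amensalism,
neutralism, competition). A community is viable when (1) more than 50% of
pairs are non-negative, (2) every strain receives at least one positive
effect, and (3) every strain grows in the full-community run. Candidates are
screened in rank order until a viable one is found.

Growth data arrive through the :class:`GrowthTable` contract (three CSVs:
alone, pairs, community), produced by any external simulator or by the
built-in toy simulator.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.10
DEFAULT_MIN_NONNEG_FRAC = 0.5

#: unordered effect pair -> interaction label
LABELS = {
    frozenset({"+"}): "mutualism",
    frozenset({"+", "0"}): "commensalism",
    frozenset({"+", "-"}): "parasitism",
    frozenset({"0"}): "neutralism",
    frozenset({"0", "-"}): "amensalism",
    frozenset({"-"}): "competition",
}

#: labels in which neither partner is harmed (rule-1 "neutral or positive")
NONNEGATIVE_LABELS = frozenset({"mutualism", "commensalism", "neutralism"})


@dataclass(frozen=True)
class GrowthTable:
    """Per-strain growth alone, in each ordered pair, and in the full community."""

    strains: tuple[str, ...]
    growth_alone: Mapping[str, float]
    growth_paired: Mapping[tuple[str, str], float]
    growth_community: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "strains", tuple(self.strains))
        for s in self.strains:
            if s not in self.growth_alone:
                raise ValueError(f"growth_alone missing strain {s!r}")
            if s not in self.growth_community:
                raise ValueError(f"growth_community missing strain {s!r}")
        for i in self.strains:
            for j in self.strains:
                if i != j and (i, j) not in self.growth_paired:
                    raise ValueError(f"growth_paired missing ordered pair ({i!r}, {j!r})")
        all_values = (
            list(self.growth_alone.values())
            + list(self.growth_paired.values())
            + list(self.growth_community.values())
        )
        if any(v < 0 for v in all_values):
            raise ValueError("growth values must be non-negative")

    def write_csv(self, out_dir: str | Path) -> None:
        """Write the three-file CSV contract: alone.csv, pairs.csv, community.csv."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "alone.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["strain", "growth"])
            for s in self.strains:
                w.writerow([s, repr(self.growth_alone[s])])
        with open(out_dir / "pairs.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["strain", "partner", "growth"])
            for i in self.strains:
                for j in self.strains:
                    if i != j:
                        w.writerow([i, j, repr(self.growth_paired[(i, j)])])
        with open(out_dir / "community.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["strain", "growth"])
            for s in self.strains:
                w.writerow([s, repr(self.growth_community[s])])

    @classmethod
    def read_csv(cls, in_dir: str | Path) -> "GrowthTable":
        in_dir = Path(in_dir)
        alone: dict[str, float] = {}
        paired: dict[tuple[str, str], float] = {}
        community: dict[str, float] = {}
        strains: list[str] = []
        with open(in_dir / "alone.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                strains.append(row["strain"])
                alone[row["strain"]] = float(row["growth"])
        with open(in_dir / "pairs.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                paired[(row["strain"], row["partner"])] = float(row["growth"])
        with open(in_dir / "community.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                community[row["strain"]] = float(row["growth"])
        return cls(
            strains=tuple(strains),
            growth_alone=alone,
            growth_paired=paired,
            growth_community=community,
        )


def classify_effect(alone: float, paired: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Sign of the co-culture effect on one partner: '+', '0' or '-'.

    Relative change r = (paired − alone)/alone; '+' if r > threshold, '-' if
    r < −threshold, else '0'. A strain with zero growth alone is a degenerate
    case: '+' if any paired growth appears, else '0' (logged).
    """
    if alone == 0:
        logger.warning("strain with zero growth alone: degenerate effect classification")
        return "+" if paired > 0 else "0"
    r = (paired - alone) / alone
    if r > threshold:
        return "+"
    if r < -threshold:
        return "-"
    return "0"


@dataclass(frozen=True)
class PairInteraction:
    """Classified interaction for one unordered strain pair."""

    strain_i: str
    strain_j: str
    effect_on_i: str
    effect_on_j: str
    label: str


def classify_pair(
    growth: GrowthTable, i: str, j: str, threshold: float = DEFAULT_THRESHOLD
) -> PairInteraction:
    """Classify the unordered interaction between strains ``i`` and ``j``."""
    if i == j:
        raise ValueError("a strain cannot be paired with itself")
    for pair in ((i, j), (j, i)):
        if pair not in growth.growth_paired:
            raise KeyError(f"growth_paired missing ordered pair {pair}")
    eff_i = classify_effect(growth.growth_alone[i], growth.growth_paired[(i, j)], threshold)
    eff_j = classify_effect(growth.growth_alone[j], growth.growth_paired[(j, i)], threshold)
    return PairInteraction(
        strain_i=i,
        strain_j=j,
        effect_on_i=eff_i,
        effect_on_j=eff_j,
        label=LABELS[frozenset({eff_i, eff_j})],
    )


def interaction_matrix(
    growth: GrowthTable, threshold: float = DEFAULT_THRESHOLD
) -> list[PairInteraction]:
    """Classify every unordered pair in the table."""
    out = []
    strains = sorted(growth.strains)
    for a, i in enumerate(strains):
        for j in strains[a + 1 :]:
            out.append(classify_pair(growth, i, j, threshold))
    return out


@dataclass(frozen=True)
class ViabilityReport:
    """Outcome of the three viability rules on one community."""

    pct_nonnegative_pairs: float
    pct_nonnegative_effects: float
    strains_lacking_positive: tuple[str, ...]
    strains_not_growing_in_community: tuple[str, ...]
    viable: bool
    rule_results: Mapping[str, bool]
    interactions: tuple[PairInteraction, ...] = field(default=(), repr=False)

    def to_dict(self) -> dict:
        return {
            "pct_nonnegative_pairs": self.pct_nonnegative_pairs,
            "pct_nonnegative_effects": self.pct_nonnegative_effects,
            "strains_lacking_positive": list(self.strains_lacking_positive),
            "strains_not_growing_in_community": list(self.strains_not_growing_in_community),
            "viable": self.viable,
            "rule_results": dict(self.rule_results),
            "interactions": [
                {
                    "strain_i": x.strain_i,
                    "strain_j": x.strain_j,
                    "effect_on_i": x.effect_on_i,
                    "effect_on_j": x.effect_on_j,
                    "label": x.label,
                }
                for x in self.interactions
            ],
        }


def assess_syncom(
    growth: GrowthTable,
    threshold: float = DEFAULT_THRESHOLD,
    min_nonneg_frac: float = DEFAULT_MIN_NONNEG_FRAC,
    community_growth_floor: float = 0.0,
) -> ViabilityReport:
    """Apply the three viability rules to one community's growth table.

    A pair is non-negative iff neither effect is '-'; the fraction must
    strictly exceed ``min_nonneg_frac`` (rule 1). Every strain must receive at
    least one '+' effect (rule 2) and grow above ``community_growth_floor`` in
    the full-community run (rule 3). The per-effect non-negative percentage is
    reported alongside for comparison but does not enter the verdict.
    """
    if len(growth.strains) < 2:
        raise ValueError("viability assessment needs at least 2 strains")
    pairs = interaction_matrix(growth, threshold)

    n_nonneg = sum(1 for p in pairs if p.label in NONNEGATIVE_LABELS)
    pct_pairs = 100.0 * n_nonneg / len(pairs)
    effects = [e for p in pairs for e in (p.effect_on_i, p.effect_on_j)]
    pct_effects = 100.0 * sum(1 for e in effects if e != "-") / len(effects)

    received_positive: set[str] = set()
    for p in pairs:
        if p.effect_on_i == "+":
            received_positive.add(p.strain_i)
        if p.effect_on_j == "+":
            received_positive.add(p.strain_j)
    lacking = tuple(s for s in growth.strains if s not in received_positive)
    not_growing = tuple(
        s for s in growth.strains if growth.growth_community[s] <= community_growth_floor
    )

    rules = {
        "nonnegative_pairs": pct_pairs > 100.0 * min_nonneg_frac,
        "every_strain_positive": not lacking,
        "every_strain_grows": not not_growing,
    }
    return ViabilityReport(
        pct_nonnegative_pairs=pct_pairs,
        pct_nonnegative_effects=pct_effects,
        strains_lacking_positive=lacking,
        strains_not_growing_in_community=not_growing,
        viable=all(rules.values()),
        rule_results=rules,
        interactions=tuple(pairs),
    )


@dataclass(frozen=True)
class ToySimParams:
    """Parameters of the built-in toy growth simulator.

    ``baseline`` maps strain -> growth alone; ``effects`` maps ordered pairs
    (i, j) -> signed relative effect of partner j on strain i (absent pairs
    default to 0). ``noise`` is a uniform relative noise amplitude.
    """

    baseline: Mapping[str, float]
    effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    noise: float = 0.0


def toy_simulate(
    members: Iterable[str], params: ToySimParams, seed: int = 0
) -> GrowthTable:
    """Deterministic toy growth simulation under a signed pairwise-effect model.

    growth_alone(i) = baseline_i; growth_paired(i|j) = baseline_i·(1 + e_ij + ε);
    growth_community(i) = baseline_i·(1 + mean_j e_ij + ε), with ε uniform in
    ±noise (zero by default). Negative outcomes are clipped at 0.
    """
    strains = tuple(sorted(set(members)))
    missing = [s for s in strains if s not in params.baseline]
    if missing:
        raise ValueError(f"no baseline growth for strain(s) {missing}")
    rng = np.random.default_rng(seed)

    def eps() -> float:
        return float(rng.uniform(-params.noise, params.noise)) if params.noise else 0.0

    alone = {s: float(params.baseline[s]) for s in strains}
    paired: dict[tuple[str, str], float] = {}
    community: dict[str, float] = {}
    for i in strains:
        for j in strains:
            if i != j:
                e = params.effects.get((i, j), 0.0)
                paired[(i, j)] = max(0.0, alone[i] * (1.0 + e + eps()))
    for i in strains:
        others = [s for s in strains if s != i]
        mean_e = (
            float(np.mean([params.effects.get((i, j), 0.0) for j in others])) if others else 0.0
        )
        community[i] = max(0.0, alone[i] * (1.0 + mean_e + eps()))
    return GrowthTable(
        strains=strains, growth_alone=alone, growth_paired=paired, growth_community=community
    )


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of walking the ranked candidate list."""

    winner: object | None  # SynComCandidate when found
    winner_rank: int | None
    reports: tuple[ViabilityReport | None, ...]

    @property
    def success(self) -> bool:
        return self.winner is not None


def screen_ranked(
    candidates: Sequence,
    simulator: Callable[[Sequence[str]], GrowthTable],
    threshold: float = DEFAULT_THRESHOLD,
    min_nonneg_frac: float = DEFAULT_MIN_NONNEG_FRAC,
    community_growth_floor: float = 0.0,
) -> ScreenResult:
    """Walk candidates in rank order; return the first viable one plus all reports.

    A simulator failure marks the candidate inviable (report ``None``, logged)
    and the walk continues. If no candidate is viable the result carries
    ``winner=None`` and one report slot per candidate.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    reports: list[ViabilityReport | None] = []
    for rank, cand in enumerate(candidates, start=1):
        try:
            growth = simulator(list(cand.members))
            report = assess_syncom(
                growth,
                threshold=threshold,
                min_nonneg_frac=min_nonneg_frac,
                community_growth_floor=community_growth_floor,
            )
        except Exception:
            logger.exception("simulator failed for candidate %s; skipped as inviable", rank)
            reports.append(None)
            continue
        reports.append(report)
        if report.viable:
            return ScreenResult(winner=cand, winner_rank=rank, reports=tuple(reports))
    return ScreenResult(winner=None, winner_rank=None, reports=tuple(reports))
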