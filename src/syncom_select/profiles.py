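"""Binary Pfam profiles: HMMER tabular parsing, profile matrices and comparison metrics.

A *profile* is the set of Pfam accessions (version-stripped, ``PF#####``)
encoded by one entity — a genome, a metagenome assembly, or the union profile
of a candidate community. Profiles for many entities are collected into a
binary :class:`ProfileMatrix` (entities × Pfam universe) that round-trips
losslessly through TSV.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PFAM_RE = re.compile(r"^PF\d{5}$")

#: minimum whitespace-separated fields before the free-text description column
_MIN_FIELDS = {"tblout": 18, "domtblout": 22}

#: column index (0-based) of the target accession and the full-sequence score
_ACC_COL = 1
_SCORE_COL = {"tblout": 5, "domtblout": 7}


class ParseError(ValueError):
    """Raised for malformed HMMER tabular input."""


def strip_version(accession: str) -> str:
    """Drop a trailing ``.N`` version suffix: ``PF00001.21`` → ``PF00001``."""
    return accession.split(".", 1)[0]


@dataclass(frozen=True)
class PfamProfile:
    """Binary presence set of Pfam accessions for one entity."""

    entity_id: str
    pfams: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pfams", frozenset(self.pfams))
        bad = [p for p in self.pfams if not PFAM_RE.match(p)]
        if bad:
            raise ValueError(
                f"profile {self.entity_id!r}: invalid Pfam accession(s) {sorted(bad)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.pfams)


def parse_hmmer_tblout(
    stream: IO[str] | Iterable[str],
    dialect: str = "tblout",
    entity_id: str = "",
    min_score: float | None = None,
) -> PfamProfile:
    """Parse HMMER3 ``tblout``/``domtblout`` text into a :class:`PfamProfile`.

    The target accession column is used (for hmmscan the target is the Pfam
    model); version suffixes are stripped and hits from multiple proteins to
    the same family collapse to one entry. No score filtering is applied by
    default — the gathering threshold is assumed to have been applied by the
    annotation run — but ``min_score`` optionally drops hits below a
    full-sequence bit-score floor.

    Raises
    ------
    ParseError
        If a non-comment line has fewer columns than the dialect requires.
    """
    if dialect not in _MIN_FIELDS:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tblout' or 'domtblout'")
    min_fields = _MIN_FIELDS[dialect]
    score_col = _SCORE_COL[dialect]

    pfams: set[str] = set()
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) < min_fields:
            raise ParseError(
                f"line {lineno}: expected >= {min_fields} columns for {dialect}, "
                f"got {len(fields)}"
            )
        acc = strip_version(fields[_ACC_COL])
        if not PFAM_RE.match(acc):
            logger.warning(
                "line %d: accession %r is not a Pfam accession after version "
                "stripping; record skipped",
                lineno,
                fields[_ACC_COL],
            )
            continue
        if min_score is not None and float(fields[score_col]) < min_score:
            continue
        pfams.add(acc)
    return PfamProfile(entity_id=entity_id, pfams=frozenset(pfams))


def parse_hmmer_file(path: str | Path, dialect: str = "tblout", **kwargs) -> PfamProfile:
    """Parse one annotation file; the entity id is the filename stem."""
    path = Path(path)
    with open(path) as fh:
        return parse_hmmer_tblout(fh, dialect=dialect, entity_id=path.stem, **kwargs)


@dataclass
class ProfileMatrix:
    """Entities × Pfam-universe binary matrix with row/column labels.

    ``values[i, j] == 1`` iff ``pfam_universe[j]`` is present in the profile
    of ``entity_ids[i]``. The universe is sorted and duplicate-free.
    """

    entity_ids: list[str]
    pfam_universe: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.entity_ids), len(self.pfam_universe)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.pfam_universe)} Pfams"
            )
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity_id in matrix")
        if len(set(self.pfam_universe)) != len(self.pfam_universe):
            raise ValueError("duplicate accession in pfam_universe")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix values must be binary")
        self._row_index = {e: i for i, e in enumerate(self.entity_ids)}

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    def pfam_sets(self) -> dict[str, frozenset[str]]:
        """Per-entity Pfam sets, computed once and cached."""
        if not hasattr(self, "_pfam_cache"):
            universe = np.asarray(self.pfam_universe, dtype=object)
            self._pfam_cache = {
                e: frozenset(universe[self.values[i].astype(bool)])
                for i, e in enumerate(self.entity_ids)
            }
        return self._pfam_cache

    def profile(self, entity_id: str) -> PfamProfile:
        """Extract one row back as a :class:`PfamProfile`."""
        return PfamProfile(entity_id=entity_id, pfams=self.pfam_sets()[entity_id])

    def profiles(self) -> list[PfamProfile]:
        return [self.profile(e) for e in self.entity_ids]

    def prevalence(self) -> pd.Series:
        """Per-Pfam presence fraction across entities."""
        return pd.Series(self.values.mean(axis=0), index=self.pfam_universe)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileMatrix):
            return NotImplemented
        return (
            self.entity_ids == other.entity_ids
            and self.pfam_universe == other.pfam_universe
            and np.array_equal(self.values, other.values)
        )


def build_profile_matrix(
    profiles: Sequence[PfamProfile],
    universe: Sequence[str] | None = None,
) -> ProfileMatrix:
    """Stack profiles into a binary matrix over a shared (sorted) universe.

    Without an explicit ``universe`` the sorted union of all profile
    accessions is used. With one, Pfams outside it are dropped (the count is
    logged).
    """
    ids = [p.entity_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({e for e in ids if ids.count(e) > 1})
        raise ValueError(f"duplicate entity_id(s): {dupes}")
    if universe is None:
        universe = sorted(set().union(*(p.pfams for p in profiles)) if profiles else set())
    else:
        universe = list(universe)
        if len(set(universe)) != len(universe):
            raise ValueError("explicit universe contains duplicates")
        known = set(universe)
        n_dropped = sum(len(p.pfams - known) for p in profiles)
        if n_dropped:
            logger.info("%d Pfam occurrences outside the explicit universe dropped", n_dropped)
    col = {p: j for j, p in enumerate(universe)}
    values = np.zeros((len(profiles), len(universe)), dtype=np.int8)
    for i, prof in enumerate(profiles):
        for p in prof.pfams:
            j = col.get(p)
            if j is not None:
                values[i, j] = 1
    return ProfileMatrix(entity_ids=ids, pfam_universe=list(universe), values=values)


@dataclass(frozen=True)
class MatchStats:
    """Comparison of a candidate profile A against a sample profile B.

    ``pct_matches`` is relative to the sample size (coverage of the target
    ecosystem); ``pct_mismatches`` is relative to the candidate size
    (extraneous functions introduced).
    """

    n_matches: int
    n_mismatches: int
    pct_matches: float
    pct_mismatches: float
    jaccard_distance: float


def match_stats(candidate: PfamProfile, sample: PfamProfile) -> MatchStats:
    """Matching/mismatching Pfam counts and Jaccard distance of candidate vs sample."""
    if not sample.pfams:
        raise ValueError("sample profile is empty: pct_matches undefined")
    inter = candidate.pfams & sample.pfams
    union = candidate.pfams | sample.pfams
    n_matches = len(inter)
    n_mismatches = len(candidate.pfams - sample.pfams)
    return MatchStats(
        n_matches=n_matches,
        n_mismatches=n_mismatches,
        pct_matches=100.0 * n_matches / len(sample.pfams),
        pct_mismatches=(100.0 * n_mismatches / len(candidate.pfams)) if candidate.pfams else 0.0,
        jaccard_distance=1.0 - (n_matches / len(union)) if union else 0.0,
    )


def write_profile_matrix(matrix: ProfileMatrix, path: str | Path) -> None:
    """Write a matrix as TSV: first column ``entity_id``, then 0/1 Pfam columns."""
    df = pd.DataFrame(matrix.values, index=matrix.entity_ids, columns=matrix.pfam_universe)
    df.index.name = "entity_id"
    df.to_csv(path, sep="\t")


def read_profile_matrix(path: str | Path) -> ProfileMatrix:
    """Read a profile-matrix TSV written by :func:`write_profile_matrix`.

    Raises ``ValueError`` naming the offending entity and Pfam on any
    non-binary cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = np.zeros(df.shape, dtype=np.int8)
    arr = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = arr[i, j]
            if cell not in ("0", "1"):
                raise ValueError(
                    f"non-binary cell {cell!r} at entity {df.index[i]!r}, "
                    f"Pfam {df.columns[j]!r}"
                )
            values[i, j] = int(cell)
    return ProfileMatrix(
        entity_ids=[str(e) for e in df.index],
        pfam_universe=[str(c) for c in df.columns],
        values=values,
    )
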