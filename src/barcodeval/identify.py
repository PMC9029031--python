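"""Species identification scoring: Best Match, Best Close Match, and a
best-hit (BLAST1-style) criterion, all leave-one-out.

Best Match (BM): each query is matched against every other sequence in
the group; the set of references at the minimum defined K2P distance
(ties kept, exact comparison) decides the verdict — *correct* if every
best match is conspecific, *incorrect* if none is, *ambiguous* if the
set mixes conspecific and heterospecific references.

Best Close Match (BCM): BM after discarding references farther than a
threshold, conventionally the 95th percentile of all pooled
intraspecific distances; an empty surviving set yields *no match*.

Best-hit criterion: references are ranked by a similarity scorer (the
built-in scorer is the fraction of matching comparable sites on the
aligned sequences); the species composition of the tied top-scoring hit
set is classified by the same three-way rule.  An external hit table
(BLAST outfmt-6-like: query id, subject id, bit score) can be supplied
instead of the internal scorer.

Only queries whose species has at least two sequences in the dataset are
eligible (a singleton species can never find a conspecific match and is
removed by validation anyway).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._fmt import round_half_up
from .divergence import intraspecific_distances
from .io import AlignedDataset
from .k2p import DistanceMatrix, distance_matrix, encode_alignment

BM = "BM"
BCM = "BCM"
BLAST1 = "BLAST1"
METHODS = (BM, BCM, BLAST1)

CORRECT = "correct"
INCORRECT = "incorrect"
AMBIGUOUS = "ambiguous"
NO_MATCH = "no-match"


@dataclass
class QueryVerdict:
    query_id: str
    query_species: str
    method: str
    verdict: str
    best_ids: list[str] = field(default_factory=list)
    best_species: list[str] = field(default_factory=list)
    best_score: float = math.nan   # distance (BM/BCM) or similarity (BLAST1)
    threshold: float | None = None


def _classify(query_species: str, best_species: Sequence[str]) -> str:
    kinds = set(best_species)
    if kinds == {query_species}:
        return CORRECT
    if query_species in kinds:
        return AMBIGUOUS
    return INCORRECT


def _verdict_from_scores(
    qi: int,
    ids: Sequence[str],
    species: np.ndarray,
    scores: np.ndarray,
    usable: np.ndarray,
    method: str,
    minimize: bool,
    threshold: float | None = None,
) -> QueryVerdict:
    usable = usable.copy()
    usable[qi] = False
    if not usable.any():
        return QueryVerdict(
            query_id=ids[qi],
            query_species=str(species[qi]),
            method=method,
            verdict=NO_MATCH,
            threshold=threshold,
        )
    pool = np.flatnonzero(usable)
    vals = scores[pool]
    best_val = vals.min() if minimize else vals.max()
    best = pool[vals == best_val]  # exact ties kept
    best_sp = [str(species[j]) for j in best]
    return QueryVerdict(
        query_id=ids[qi],
        query_species=str(species[qi]),
        method=method,
        verdict=_classify(str(species[qi]), best_sp),
        best_ids=[ids[j] for j in best],
        best_species=best_sp,
        best_score=float(best_val),
        threshold=threshold,
    )


def best_match(dm: DistanceMatrix, query_index: int) -> QueryVerdict:
    """BM verdict for one query, leave-one-out over the matrix."""
    row = dm.d[query_index]
    return _verdict_from_scores(
        query_index, dm.ids, dm.species, row, dm.defined[query_index].copy(),
        BM, minimize=True,
    )


def bcm_threshold(dm: DistanceMatrix, percentile: float = 95.0) -> float:
    """Threshold for BCM: a percentile (default 95th, linear
    interpolation) of all pooled defined intraspecific distances."""
    intra = intraspecific_distances(dm)
    if intra.size == 0:
        raise ValueError("no defined intraspecific pairs; cannot set BCM threshold")
    return float(np.percentile(intra, percentile))


def best_close_match(
    dm: DistanceMatrix, query_index: int, threshold: float
) -> QueryVerdict:
    """BCM verdict: BM restricted to references within the threshold."""
    row = dm.d[query_index]
    usable = dm.defined[query_index] & ~(row > threshold)  # keep d ≤ threshold
    return _verdict_from_scores(
        query_index, dm.ids, dm.species, row, usable, BCM,
        minimize=True, threshold=threshold,
    )


# ---------------------------------------------------------------------------
# best-hit (BLAST1-style) criterion


def similarity_matrix(dataset: AlignedDataset) -> np.ndarray:
    """Built-in scorer: fraction of matching comparable sites per pair
    (NaN where no site is comparable)."""
    x = encode_alignment([r.sequence for r in dataset.records])
    n = dataset.n
    s = np.full((n, n), np.nan)
    np.fill_diagonal(s, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = (x[i] < 4) & (x[j] < 4)
            L = int(both.sum())
            if L:
                s[i, j] = s[j, i] = float((both & (x[i] == x[j])).sum()) / L
    return s


def blast1_classify(
    query_index: int,
    ids: Sequence[str],
    species: Sequence[str],
    similarity: np.ndarray,
) -> QueryVerdict:
    """Three-way best-hit classification from a similarity matrix."""
    sp = np.asarray(species, dtype=object)
    row = similarity[query_index]
    usable = ~np.isnan(row)
    return _verdict_from_scores(
        query_index, list(ids), sp, row, usable, BLAST1, minimize=False,
    )


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read an external tab-separated hit table (outfmt-6 dialect):
    first, second and last columns are query id, subject id, bit score."""
    df = pd.read_csv(path, sep="\t", header=None)
    return pd.DataFrame(
        {"query": df.iloc[:, 0], "subject": df.iloc[:, 1], "score": df.iloc[:, -1]}
    )


def blast1_from_hits(
    query_id: str,
    query_species: str,
    species_of: dict[str, str],
    hits: pd.DataFrame,
) -> QueryVerdict:
    """Best-hit verdict from an external hit table (self-hits dropped)."""
    mine = hits[(hits["query"] == query_id) & (hits["subject"] != query_id)]
    if mine.empty:
        return QueryVerdict(query_id, query_species, BLAST1, NO_MATCH)
    top = mine[mine["score"] == mine["score"].max()]
    best_ids = top["subject"].tolist()
    best_sp = [species_of[s] for s in best_ids]
    return QueryVerdict(
        query_id=query_id,
        query_species=query_species,
        method=BLAST1,
        verdict=_classify(query_species, best_sp),
        best_ids=best_ids,
        best_species=best_sp,
        best_score=float(top["score"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# per-group reports


@dataclass
class IdentificationReport:
    """Per-method identification rates for one group (the leave-one-out
    verdict of every eligible query plus the summary percentages)."""

    group: str
    level: str
    method: str
    verdicts: list[QueryVerdict]
    threshold: float | None = None

    @property
    def n_queries(self) -> int:
        return len(self.verdicts)

    def rate(self, verdict: str) -> float:
        """Percentage of queries with the given verdict (2 decimals,
        half-up)."""
        if not self.verdicts:
            return math.nan
        share = sum(v.verdict == verdict for v in self.verdicts) / self.n_queries
        return round_half_up(100.0 * share, 2)

    def as_row(self) -> dict:
        return {
            "level": self.level,
            "group": self.group,
            "method": self.method,
            "n_queries": self.n_queries,
            "correct": self.rate(CORRECT),
            "incorrect": self.rate(INCORRECT),
            "ambiguous": self.rate(AMBIGUOUS),
            "no_match": self.rate(NO_MATCH),
            "threshold": self.threshold,
        }

    def verdict_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "query_id": [v.query_id for v in self.verdicts],
                "species": [v.query_species for v in self.verdicts],
                "method": [v.method for v in self.verdicts],
                "verdict": [v.verdict for v in self.verdicts],
                "best_ids": [";".join(v.best_ids) for v in self.verdicts],
                "best_species": [";".join(v.best_species) for v in self.verdicts],
                "best_score": [v.best_score for v in self.verdicts],
            }
        )


def identification_report(
    dataset: AlignedDataset,
    method: str,
    dm: DistanceMatrix | None = None,
    group: str = "",
    level: str = "",
    bcm_percentile: float = 95.0,
    similarity: np.ndarray | None = None,
) -> IdentificationReport:
    """Run one identification method for every eligible query of a
    dataset, leave-one-out."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    counts = dataset.species_counts()
    eligible = [i for i, sp in enumerate(dataset.species) if counts[sp] >= 2]
    if not eligible:
        raise ValueError(f"no eligible queries (no species with ≥2 sequences) in {group or 'dataset'}")
    threshold = None
    if method in (BM, BCM):
        if dm is None:
            dm = distance_matrix(dataset)
        if method == BCM:
            threshold = bcm_threshold(dm, bcm_percentile)
            verdicts = [best_close_match(dm, i, threshold) for i in eligible]
        else:
            verdicts = [best_match(dm, i) for i in eligible]
    else:
        if similarity is None:
            similarity = similarity_matrix(dataset)
        verdicts = [
            blast1_classify(i, dataset.ids, dataset.species, similarity)
            for i in eligible
        ]
    return IdentificationReport(
        group=group, level=level, method=method, verdicts=verdicts, threshold=threshold
    )
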