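"""Alignment-variability statistics: conserved, variable,
parsimony-informative and singleton sites, plus the overall mean
distance (OMD) of a group.

Column classification uses only unambiguous residues (A/C/G/T): gaps and
ambiguity codes are ignored when counting base types, and a column with
fewer than two usable residues is *indeterminate* — counted in the
alignment length but in neither the conserved nor the variable tally.
This is why CS + VS can fall short of AL on gappy alignments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._fmt import round_half_up
from .io import AlignedDataset
from .k2p import DistanceMatrix, distance_matrix

CONSERVED = "conserved"
SINGLETON = "singleton"
PARSIMONY_INFORMATIVE = "parsimony-informative"
VARIABLE_OTHER = "variable-other"
INDETERMINATE = "indeterminate"

_BASES = frozenset("ACGT")


def classify_site(column: Iterable[str]) -> str:
    """Classify one alignment column.

    conserved: exactly one base type among ≥2 usable residues;
    parsimony-informative: ≥2 base types each in ≥2 sequences;
    singleton: variable with at most one base type occurring more than
    once; indeterminate: fewer than 2 usable residues.
    """
    residues = list(column)
    if not residues:
        raise ValueError("empty alignment column")
    counts = Counter(c for c in residues if c in _BASES)
    usable = sum(counts.values())
    if usable < 2:
        return INDETERMINATE
    if len(counts) == 1:
        return CONSERVED
    repeated = sum(1 for c in counts.values() if c >= 2)
    if repeated >= 2:
        return PARSIMONY_INFORMATIVE
    if repeated <= 1:
        return SINGLETON
    return VARIABLE_OTHER  # unreachable under this gap rule; kept defensively


@dataclass
class SiteStats:
    """Per-group alignment variability summary."""

    al: int
    cs: int
    vs: int
    pis: int
    ss: int
    indeterminate: int
    omd: float
    n_pairs_defined: int
    n_pairs_undefined: int

    def pct(self, count: int) -> float:
        """Percentage of AL, rounded half-up to 2 decimals."""
        return round_half_up(100.0 * count / self.al, 2)

    @property
    def pct_cs(self) -> float:
        return self.pct(self.cs)

    @property
    def pct_vs(self) -> float:
        return self.pct(self.vs)

    @property
    def pct_pis(self) -> float:
        return self.pct(self.pis)

    @property
    def pct_ss(self) -> float:
        return self.pct(self.ss)


def site_stats(
    dataset: AlignedDataset, dm: DistanceMatrix | None = None
) -> SiteStats:
    """Tally column classes over the alignment and compute the OMD.

    OMD is the arithmetic mean of all defined pairwise K2P distances
    (undefined pairs excluded).  Supply a precomputed ``dm`` to avoid
    recomputation.
    """
    if dataset.n < 2:
        raise ValueError("site statistics require at least 2 sequences")
    if dm is None:
        dm = distance_matrix(dataset)
    seqs = [r.sequence for r in dataset.records]
    tallies = Counter(
        classify_site(col) for col in zip(*seqs)
    )
    cs = tallies[CONSERVED]
    pis = tallies[PARSIMONY_INFORMATIVE]
    ss = tallies[SINGLETON]
    vs = pis + ss + tallies[VARIABLE_OTHER]
    indet = tallies[INDETERMINATE]
    iu, ju = dm.pair_indices()
    ok = dm.defined[iu, ju]
    vals = dm.d[iu, ju][ok]
    omd = float(vals.mean()) if vals.size else float("nan")
    return SiteStats(
        al=dataset.aligned_length,
        cs=cs,
        vs=vs,
        pis=pis,
        ss=ss,
        indeterminate=indet,
        omd=omd,
        n_pairs_defined=int(ok.sum()),
        n_pairs_undefined=int((~ok).sum()),
    )
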