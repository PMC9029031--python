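"""Kimura two-parameter distances under pairwise deletion.

The K2P model corrects observed divergence for multiple hits while
distinguishing transitions (A↔G, C↔T) from transversions.  For a pair of
aligned sequences, sites where either member carries a gap or an
ambiguity code are excluded (pairwise deletion), leaving L comparable
sites with transition proportion P and transversion proportion Q; the
distance is

    d = -(1/2) * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

in substitutions per site.  When L = 0 or the log argument is
non-positive (saturation) the distance is undefined; undefined pairs
propagate as missing values, never as infinities or clamped numbers, and
every downstream summary reports how many pairs were dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AlignedDataset

# byte → code: A,C,G,T = 0..3; everything else (gaps, ambiguity) = 4.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode_alignment(seqs: Sequence[str]) -> np.ndarray:
    """(n, L) uint8 matrix; 0–3 for A,C,G,T, 4 for gap/ambiguous."""
    n = len(seqs)
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE[raw.reshape(n, -1)]


def _pair_stats(xa: np.ndarray, xb: np.ndarray) -> tuple[float, int, float, float, bool]:
    both = (xa < 4) & (xb < 4)
    L = int(both.sum())
    if L == 0:
        return math.nan, 0, math.nan, math.nan, False
    diff = both & (xa != xb)
    # A(0)^G(2) == C(1)^T(3) == 2; every transversion pair xors to 1 or 3
    ts = int((diff & ((xa ^ xb) == 2)).sum())
    tv = int(diff.sum()) - ts
    P, Q = ts / L, tv / L
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan, L, P, Q, False
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return d + 0.0, L, P, Q, True  # + 0.0 normalizes IEEE −0.0


def k2p_pair(seq_a: str, seq_b: str) -> tuple[float, int, float, float, bool]:
    """K2P distance for one aligned pair.

    Returns ``(d, L, P, Q, defined)``: the distance (NaN when undefined),
    the comparable-site count, and the transition/transversion
    proportions.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"unequal aligned lengths: {len(seq_a)} vs {len(seq_b)}"
        )
    x = encode_alignment([seq_a.upper(), seq_b.upper()])
    return _pair_stats(x[0], x[1])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances with per-pair bookkeeping.

    ``d`` holds NaN for undefined pairs; ``defined`` is True on the
    diagonal (a sequence is at distance 0 from itself by convention).
    """

    ids: list[str]
    species: np.ndarray  # (n,) array of species labels, aligned with ids
    d: np.ndarray        # (n, n) float, NaN where undefined
    L: np.ndarray        # (n, n) int comparable-site counts
    P: np.ndarray        # (n, n) float transition proportions
    Q: np.ndarray        # (n, n) float transversion proportions
    defined: np.ndarray  # (n, n) bool

    @property
    def n(self) -> int:
        return len(self.ids)

    def pair_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (i, j) index arrays, i < j."""
        return np.triu_indices(self.n, k=1)

    def n_undefined_pairs(self) -> int:
        iu, ju = self.pair_indices()
        return int((~self.defined[iu, ju]).sum())

    def to_long_frame(self) -> pd.DataFrame:
        iu, ju = self.pair_indices()
        return pd.DataFrame(
            {
                "id_a": [self.ids[i] for i in iu],
                "id_b": [self.ids[j] for j in ju],
                "d": self.d[iu, ju],
                "L": self.L[iu, ju],
                "P": self.P[iu, ju],
                "Q": self.Q[iu, ju],
                "defined": self.defined[iu, ju],
            }
        )

    def write_long_tsv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    def write_phylip(self, path: str | Path, undefined_as: float = -1.0) -> None:
        """Square PHYLIP distance matrix; undefined pairs written as the
        sentinel ``undefined_as`` (PHYLIP has no missing-value notion)."""
        with Path(path).open("w") as fh:
            fh.write(f"{self.n}\n")
            for i, sid in enumerate(self.ids):
                row = np.where(self.defined[i], self.d[i], undefined_as)
                vals = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{sid:<12s}{vals}\n")


def distance_matrix(dataset: AlignedDataset) -> DistanceMatrix:
    """All pairwise K2P distances of a dataset, pairwise deletion."""
    if dataset.n < 2:
        raise ValueError("distance matrix requires at least 2 sequences")
    x = encode_alignment([r.sequence for r in dataset.records])
    n = dataset.n
    d = np.zeros((n, n))
    L = np.zeros((n, n), dtype=int)
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    L[np.diag_indices(n)] = (x < 4).sum(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            dij, lij, pij, qij, ok = _pair_stats(x[i], x[j])
            d[i, j] = d[j, i] = dij
            L[i, j] = L[j, i] = lij
            P[i, j] = P[j, i] = pij
            Q[i, j] = Q[j, i] = qij
            defined[i, j] = defined[j, i] = ok
    return DistanceMatrix(
        ids=dataset.ids,
        species=np.asarray(dataset.species, dtype=object),
        d=d,
        L=L,
        P=P,
        Q=Q,
        defined=defined,
    )
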