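"""Group-level genetic divergence indices.

Five indices characterize a taxonomic group from its K2P distance
matrix:

* **all interspecific distance** — mean over every defined heterospecific
  pair in the group;
* **minimum interspecific distance** — per species, the smallest defined
  distance to any non-conspecific sequence, averaged over species (shared
  identical haplotypes between species force this to zero);
* **all intraspecific distance** — mean over all defined conspecific
  pairs, pooled;
* **theta (θ)** — per species with ≥2 sequences, the mean conspecific
  distance, averaged over species (equal-weights the species, reducing
  bias from uneven sampling);
* **coalescent depth** — per species with ≥2 sequences, the maximum
  conspecific distance, averaged over species.

Each index is reported as mean ± dispersion.  The dispersion is the
sample standard deviation over the constituent values (pairwise
distances for the pooled indices, per-species values otherwise); the
standard error is carried alongside in the long-form report.  Species
with a single sequence contribute to the interspecific indices but are
skipped — not zero-filled — for theta and coalescent depth.  A group
containing a single species reports 0 for all five indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._fmt import fmt_mean_sd
from .k2p import DistanceMatrix


@dataclass
class IndexValue:
    """One divergence index: mean ± dispersion over its constituents."""

    mean: float
    sd: float
    se: float
    n: int  # constituent count (pairs or species)

    @classmethod
    def from_values(cls, values: np.ndarray) -> "IndexValue":
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            return cls(math.nan, math.nan, math.nan, 0)
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return cls(mean, sd, sd / math.sqrt(v.size), int(v.size))

    @classmethod
    def zero(cls) -> "IndexValue":
        return cls(0.0, 0.0, 0.0, 0)

    def __str__(self) -> str:
        return fmt_mean_sd(self.mean, self.sd)


@dataclass
class DivergenceSummary:
    """The five divergence indices for one group at one level."""

    group: str
    level: str
    n_sequences: int
    n_species: int
    all_interspecific: IndexValue
    min_interspecific: IndexValue
    all_intraspecific: IndexValue
    theta: IndexValue
    coalescent_depth: IndexValue
    n_pairs_dropped: int = 0

    def as_row(self) -> dict:
        row: dict = {
            "level": self.level,
            "group": self.group,
            "n_sequences": self.n_sequences,
            "n_species": self.n_species,
            "n_pairs_dropped": self.n_pairs_dropped,
        }
        for name, idx in (
            ("all_interspecific", self.all_interspecific),
            ("min_interspecific", self.min_interspecific),
            ("all_intraspecific", self.all_intraspecific),
            ("theta", self.theta),
            ("coalescent_depth", self.coalescent_depth),
        ):
            row[name] = str(idx)
            row[f"{name}_mean"] = idx.mean
            row[f"{name}_sd"] = idx.sd
            row[f"{name}_se"] = idx.se
            row[f"{name}_n"] = idx.n
        return row


def _pair_arrays(dm: DistanceMatrix):
    iu, ju = dm.pair_indices()
    same = dm.species[iu] == dm.species[ju]
    ok = dm.defined[iu, ju]
    return iu, ju, same, ok


def divergence_summary(
    dm: DistanceMatrix, group: str = "", level: str = ""
) -> DivergenceSummary:
    """Compute the five divergence indices from a group's own distance
    matrix (the matrix should be built on the group's alignment view)."""
    species_list = sorted(set(dm.species.tolist()))
    n_seq = dm.n
    iu, ju, same, ok = _pair_arrays(dm)
    dropped = int((~ok).sum())

    if len(species_list) == 1:
        # single-taxon group: all five indices are zero by definition
        return DivergenceSummary(
            group=group,
            level=level,
            n_sequences=n_seq,
            n_species=1,
            all_interspecific=IndexValue.zero(),
            min_interspecific=IndexValue.zero(),
            all_intraspecific=IndexValue.zero(),
            theta=IndexValue.zero(),
            coalescent_depth=IndexValue.zero(),
            n_pairs_dropped=dropped,
        )

    dist = dm.d[iu, ju]
    inter_vals = dist[~same & ok]
    intra_vals = dist[same & ok]

    min_inter = []
    thetas = []
    depths = []
    for sp in species_list:
        in_sp = dm.species == sp
        # min distance from any member of sp to any non-conspecific
        mask = (
            (in_sp[iu] & ~in_sp[ju]) | (~in_sp[iu] & in_sp[ju])
        ) & ok
        if mask.any():
            min_inter.append(float(dist[mask].min()))
        if int(in_sp.sum()) >= 2:
            cmask = in_sp[iu] & in_sp[ju] & ok
            if cmask.any():
                conspecific = dist[cmask]
                thetas.append(float(conspecific.mean()))
                depths.append(float(conspecific.max()))
    return DivergenceSummary(
        group=group,
        level=level,
        n_sequences=n_seq,
        n_species=len(species_list),
        all_interspecific=IndexValue.from_values(inter_vals),
        min_interspecific=IndexValue.from_values(np.array(min_inter)),
        all_intraspecific=IndexValue.from_values(intra_vals),
        theta=IndexValue.from_values(np.array(thetas)),
        coalescent_depth=IndexValue.from_values(np.array(depths)),
        n_pairs_dropped=dropped,
    )


def intraspecific_distances(dm: DistanceMatrix) -> np.ndarray:
    """Pooled defined conspecific pairwise distances."""
    iu, ju, same, ok = _pair_arrays(dm)
    return dm.d[iu, ju][same & ok]


def interspecific_distances(dm: DistanceMatrix) -> np.ndarray:
    """Pooled defined heterospecific pairwise distances."""
    iu, ju, same, ok = _pair_arrays(dm)
    return dm.d[iu, ju][~same & ok]
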