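"""Synthetic aligned datasets with nested species/genus/subfamily
structure under a Kimura two-parameter substitution process.

Sequences evolve along a star-within-star scheme: a family root sequence
spawns genus ancestors, each genus ancestor spawns species ancestors,
and each species ancestor spawns individual sequences.  Branch lengths
are chosen so that *expected* pairwise divergences hit three targets:

* conspecific pairs:            δ_w = 2·t_individual
* congeneric heterospecifics:   δ_b = 2·(t_species + t_individual)
* cross-genus pairs:            δ_g = 2·(t_genus + t_species + t_individual)

with branch lengths in expected substitutions per site.  Substitutions
follow the K2P process with transition/transversion rate ratio κ,
normalized so a branch of length t accumulates t substitutions per site
in expectation (α + 2β = 1, α/β = κ).  Because the K2P distance
estimator is consistent for its own model, the expected estimated
distance over a total branch length t is t itself — which is what the
parameter-recovery tests exploit.

Two regimes mimic pathologies real barcode data show: a
*zero-variation species complex* (every member of the flagged complex
carries one identical haplotype, so all divergence indices collapse to
zero and identification becomes 100% ambiguous) and *haplotype sharing*
(the first sequence of a genus's second species is copied from its
first species, forcing a 0.0 minimum interspecific distance for both).

No indels are simulated by default; an optional gap-column injector
writes gaps into random columns to exercise pairwise deletion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import AlignedDataset, SequenceRecord, TaxonomyTable, write_fasta, write_taxonomy

_BASES = np.array(list("ACGT"))


@dataclass
class GenusSpec:
    """One simulated genus: its subfamily, species count and per-species
    sampling depth (fixed int or inclusive (lo, hi) range)."""

    name: str
    subfamily: str
    n_species: int
    seqs_per_species: int | tuple[int, int] = 3
    complex_name: str | None = None   # label applied to the first
    complex_size: int = 0             # `complex_size` species of the genus


@dataclass
class SynthConfig:
    """Study conditions for one simulated dataset.

    Defaults emulate a conifer-family barcode survey: ~250 bp marker,
    divergence regimes inside the empirically observed spans
    (intraspecific means up to ~0.20, interspecific up to ~0.36
    substitutions/site), uneven per-species sampling, one zero-variation
    species complex and shared haplotypes between close congeners.
    """

    seed: int = 0
    length: int = 250
    genera: list[GenusSpec] = field(default_factory=lambda: default_genera())
    delta_w: float = 0.01    # expected conspecific divergence
    delta_b: float = 0.10    # expected within-genus heterospecific divergence
    delta_g: float = 0.30    # expected cross-genus divergence
    kappa: float = 2.0       # transition/transversion rate ratio
    share_haplotypes: bool = False
    zero_variation_complex: bool = False
    n_gap_columns: int = 0
    gap_prob: float = 0.3    # per-sequence gap chance inside an injected column

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta_w <= self.delta_b <= self.delta_g:
            raise ValueError(
                "divergence targets must satisfy 0 ≤ δ_w ≤ δ_b ≤ δ_g; got "
                f"{self.delta_w}, {self.delta_b}, {self.delta_g}"
            )
        if self.length < 1:
            raise ValueError("sequence length must be ≥ 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def default_genera() -> list[GenusSpec]:
    """A conifer-family-like roster: 7 genera in 3 subfamilies, uneven
    species counts and sampling depths, one 5-species complex inside the
    largest genus."""
    return [
        GenusSpec("GenusA", "SubfamilyI", n_species=8, seqs_per_species=(1, 6)),
        GenusSpec("GenusB", "SubfamilyI", n_species=2, seqs_per_species=(2, 4)),
        GenusSpec("GenusC", "SubfamilyI", n_species=3, seqs_per_species=(1, 3)),
        GenusSpec("GenusD", "SubfamilyII", n_species=6, seqs_per_species=(1, 8)),
        GenusSpec("GenusE", "SubfamilyII", n_species=1, seqs_per_species=4),
        GenusSpec("GenusF", "SubfamilyIII", n_species=6, seqs_per_species=(2, 5)),
        GenusSpec(
            "GenusG",
            "SubfamilyIII",
            n_species=14,
            seqs_per_species=(1, 10),
            complex_name="CPX",
            complex_size=5,
        ),
    ]


# ---------------------------------------------------------------------------
# K2P substitution process


def _rates(kappa: float) -> tuple[float, float]:
    """(α, β) normalized so total substitution rate α + 2β = 1."""
    beta = 1.0 / (kappa + 2.0)
    return kappa * beta, beta


def transition_matrix(t: float, kappa: float) -> np.ndarray:
    """K2P transition-probability matrix P(t), base order A,C,G,T.

    Closed form: p_ts = 1/4 + 1/4·e^(−4βt) − 1/2·e^(−2(α+β)t),
    p_tv = 1/4 − 1/4·e^(−4βt) per transversion target.
    """
    if t < 0:
        raise ValueError("branch length must be ≥ 0")
    alpha, beta = _rates(kappa)
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    p_same = 1.0 - p_ts - 2.0 * p_tv
    # transition partners: A(0)↔G(2), C(1)↔T(3)
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    P[0, 2] = P[2, 0] = P[1, 3] = P[3, 1] = p_ts
    return P


def expected_k2p(branch_length_sum: float, kappa: float) -> float:
    """Expected K2P distance estimate across a total branch length.

    The estimator is consistent for its own generating model under this
    rate normalization, so the expectation equals the branch length.
    """
    if branch_length_sum < 0:
        raise ValueError("branch length must be ≥ 0")
    return branch_length_sum


def expected_pq(t: float, kappa: float) -> tuple[float, float]:
    """Expected transition and transversion proportions at divergence t."""
    P = transition_matrix(t, kappa)
    return float(P[0, 2]), float(2.0 * P[0, 1])


def evolve(seq: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded (0–3) sequence along a branch of length t."""
    if t == 0.0:
        return seq.copy()
    P = transition_matrix(t, kappa)
    cum = P.cumsum(axis=1)
    u = rng.random(seq.size)
    return (u[:, None] > cum[seq]).sum(axis=1).astype(seq.dtype)


# ---------------------------------------------------------------------------
# dataset generation


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def simulate_dataset(config: SynthConfig) -> tuple[AlignedDataset, dict]:
    """Generate one dataset plus its ground-truth record.

    All randomness flows through a single generator seeded from
    ``config.seed``; a fixed seed yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    t_ind = config.delta_w / 2.0
    t_sp = (config.delta_b - config.delta_w) / 2.0
    t_gen = (config.delta_g - config.delta_b) / 2.0

    root = rng.integers(0, 4, size=config.length, dtype=np.int64)
    records: list[SequenceRecord] = []
    genus_map: dict[str, str] = {}
    subfam_map: dict[str, str] = {}
    complex_map: dict[str, str] = {}
    shared_pairs: list[tuple[str, str]] = []
    acc = 0

    for gspec in config.genera:
        genus_anc = evolve(root, t_gen, config.kappa, rng)
        complex_haplotype: np.ndarray | None = None
        first_seq_of_species: dict[int, int] = {}  # species idx → record idx
        for s in range(gspec.n_species):
            sp_name = f"{gspec.name}_sp{s + 1:02d}"
            genus_map[sp_name] = gspec.name
            subfam_map[sp_name] = gspec.subfamily
            in_complex = gspec.complex_name is not None and s < gspec.complex_size
            if in_complex:
                complex_map[sp_name] = gspec.complex_name
            sp_anc = evolve(genus_anc, t_sp, config.kappa, rng)
            if isinstance(gspec.seqs_per_species, tuple):
                lo, hi = gspec.seqs_per_species
                n_seqs = int(rng.integers(lo, hi + 1))
            else:
                n_seqs = gspec.seqs_per_species
            if (
                in_complex
                and config.zero_variation_complex
                and complex_haplotype is None
            ):
                complex_haplotype = sp_anc
            for k in range(n_seqs):
                acc += 1
                if in_complex and config.zero_variation_complex:
                    seq = complex_haplotype.copy()
                else:
                    seq = evolve(sp_anc, t_ind, config.kappa, rng)
                records.append(
                    SequenceRecord(f"SYN{acc:05d}", sp_name, _decode(seq))
                )
                if k == 0:
                    first_seq_of_species[s] = len(records) - 1
        if config.share_haplotypes and len(first_seq_of_species) >= 2:
            # copy species 1's first haplotype into species 2's first slot
            src = records[first_seq_of_species[0]]
            dst_idx = first_seq_of_species[1]
            dst = records[dst_idx]
            records[dst_idx] = SequenceRecord(dst.id, dst.species, src.sequence)
            shared_pairs.append((src.id, dst.id))

    if config.n_gap_columns:
        records = _inject_gap_columns(records, config, rng)

    taxonomy = TaxonomyTable(genus=genus_map, subfamily=subfam_map, complex=complex_map)
    dataset = AlignedDataset(records=records, taxonomy=taxonomy)
    truth = {
        "seed": config.seed,
        "length": config.length,
        "kappa": config.kappa,
        "branch_lengths": {"individual": t_ind, "species": t_sp, "genus": t_gen},
        "expected_divergence": {
            "intraspecific": config.delta_w,
            "interspecific_within_genus": config.delta_b,
            "interspecific_between_genus": config.delta_g,
        },
        "n_sequences": dataset.n,
        "n_species": len(genus_map),
        "shared_haplotype_pairs": shared_pairs,
        "zero_variation_complex": sorted(
            {complex_map[sp] for sp in complex_map}
        )
        if config.zero_variation_complex
        else [],
    }
    return dataset, truth


def _inject_gap_columns(
    records: list[SequenceRecord], config: SynthConfig, rng: np.random.Generator
) -> list[SequenceRecord]:
    cols = rng.choice(config.length, size=min(config.n_gap_columns, config.length), replace=False)
    mats = [list(r.sequence) for r in records]
    for j in cols:
        for row in mats:
            if rng.random() < config.gap_prob:
                row[j] = "-"
    return [
        SequenceRecord(r.id, r.species, "".join(m)) for r, m in zip(records, mats)
    ]


def write_dataset(
    dataset: AlignedDataset,
    truth: dict,
    fasta_path: str | Path,
    taxonomy_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Emit the FASTA + taxonomy TSV the pipeline reads, plus the
    ground-truth JSON."""
    write_fasta(dataset.records, fasta_path)
    write_taxonomy(dataset.records, dataset.taxonomy, taxonomy_path)
    if truth_path is not None:
        Path(truth_path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
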