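"""Reading, validating and slicing aligned barcode datasets.

The pipeline consumes a multi-FASTA of nuclear barcode sequences (an
ITS2-style marker, pre-aligned) together with a tab-separated taxonomy
table assigning every sequence id to a species, a genus, a subfamily and,
optionally, a named species complex.  Analyses run at four nested
taxonomic levels — species complex, genus, subfamily, family — and this
module provides the group views: a level/group subset of the master
alignment with columns that became all-gap removed, so each group gets
its own group-specific alignment length.

Validation mirrors standard barcode-study practice: sequences containing
ambiguity codes are discarded, and species left with a single sequence
are excluded (they can never be identified by a conspecific match).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

#: Taxonomic levels, innermost first.  "family" always denotes the whole
#: dataset; the other three are read from the taxonomy table.
LEVELS = ("complex", "genus", "subfamily", "family")

_VALID_CHARS = frozenset("ACGT-")


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned (or raw) nucleotide sequence with its species label."""

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be nonempty")
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} is empty")

    @property
    def is_ambiguous(self) -> bool:
        """True if any residue is outside {A,C,G,T,-} (IUPAC codes, N...)."""
        return not _VALID_CHARS.issuperset(self.sequence)


def _normalize(seq: str) -> str:
    """Uppercase and U→T; tolerates GenBank dialect variance."""
    return seq.upper().replace("U", "T")


@dataclass
class TaxonomyTable:
    """Species → (genus, subfamily, optional complex) mapping.

    Every species maps to exactly one genus and one subfamily; complex
    membership is optional and typically covers only a handful of
    closely related species (e.g. a "PMC"-style mountain-pine complex).
    """

    genus: dict[str, str]
    subfamily: dict[str, str]
    complex: dict[str, str] = field(default_factory=dict)
    family_name: str = "family"

    def __post_init__(self) -> None:
        missing = set(self.genus) ^ set(self.subfamily)
        if missing:
            raise ValueError(
                f"species missing a genus or subfamily assignment: {sorted(missing)}"
            )
        unknown = set(self.complex) - set(self.genus)
        if unknown:
            raise ValueError(f"complex assigned to unknown species: {sorted(unknown)}")

    @property
    def species(self) -> list[str]:
        return sorted(self.genus)

    def group_of(self, species: str, level: str) -> str | None:
        """The group label of ``species`` at ``level`` (None if outside any
        complex at the complex level)."""
        if level == "family":
            return self.family_name
        if level == "genus":
            return self.genus[species]
        if level == "subfamily":
            return self.subfamily[species]
        if level == "complex":
            return self.complex.get(species)
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")

    def groups(self, level: str, species: Iterable[str] | None = None) -> list[str]:
        """Distinct group labels present at ``level`` (restricted to the
        given species when provided)."""
        pool = self.species if species is None else sorted(set(species))
        out = {g for sp in pool if (g := self.group_of(sp, level)) is not None}
        return sorted(out)


@dataclass
class AlignedDataset:
    """An alignment matrix plus per-sequence taxonomy: the object every
    analysis stage consumes."""

    records: list[SequenceRecord]
    taxonomy: TaxonomyTable

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("dataset has no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        unknown = {r.species for r in self.records} - set(self.taxonomy.genus)
        if unknown:
            raise ValueError(f"species absent from taxonomy: {sorted(unknown)}")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def aligned_length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.species] = counts.get(r.species, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# file I/O


def read_taxonomy(path: str | Path) -> tuple[dict[str, str], TaxonomyTable]:
    """Read a per-sequence taxonomy TSV.

    Required header columns: id, species, genus, subfamily; optional:
    complex (empty cell = no complex membership).  Returns the id→species
    map and the species-level :class:`TaxonomyTable`.
    """
    path = Path(path)
    id_to_species: dict[str, str] = {}
    genus: dict[str, str] = {}
    subfamily: dict[str, str] = {}
    complex_: dict[str, str] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "species", "genus", "subfamily"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: taxonomy header must contain columns {sorted(required)}"
            )
        for row in reader:
            sid, sp = row["id"].strip(), row["species"].strip()
            if sid in id_to_species:
                raise ValueError(f"{path}: duplicate id {sid!r}")
            id_to_species[sid] = sp
            for store, col in ((genus, "genus"), (subfamily, "subfamily")):
                val = row[col].strip()
                if sp in store and store[sp] != val:
                    raise ValueError(
                        f"{path}: species {sp!r} mapped to both "
                        f"{store[sp]!r} and {val!r} in column {col}"
                    )
                store[sp] = val
            cx = (row.get("complex") or "").strip()
            if cx:
                if sp in complex_ and complex_[sp] != cx:
                    raise ValueError(f"{path}: conflicting complex for {sp!r}")
                complex_[sp] = cx
    return id_to_species, TaxonomyTable(genus=genus, subfamily=subfamily, complex=complex_)


def read_fasta_with_taxonomy(
    fasta_path: str | Path, taxonomy_path: str | Path
) -> tuple[list[SequenceRecord], TaxonomyTable]:
    """Pair a multi-FASTA with its taxonomy table, in file order.

    Raises if a FASTA id lacks a taxonomy row or appears twice.
    Sequences are uppercased and U→T normalized on read.
    """
    id_to_species, taxonomy = read_taxonomy(taxonomy_path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        if rec.id not in id_to_species:
            raise KeyError(f"FASTA id {rec.id!r} has no taxonomy row")
        records.append(
            SequenceRecord(rec.id, id_to_species[rec.id], _normalize(str(rec.seq)))
        )
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return records, taxonomy


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    bio = [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def write_taxonomy(
    records: Sequence[SequenceRecord], taxonomy: TaxonomyTable, path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "species", "genus", "subfamily", "complex"])
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.species,
                    taxonomy.genus[r.species],
                    taxonomy.subfamily[r.species],
                    taxonomy.complex.get(r.species, ""),
                ]
            )


def write_exclusion_log(
    exclusions: Sequence[tuple[str, str]], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "reason"])
        writer.writerows(exclusions)


# ---------------------------------------------------------------------------
# validation filters


def filter_valid(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """Apply the two standard barcode-study validation filters.

    First discards sequences containing ambiguity codes (any character
    outside {A,C,G,T,-}, case handled on read); then drops every species
    left with exactly one sequence.  Returns the retained records and an
    exclusion log of ``(id, reason)`` pairs.
    """
    if not records:
        raise ValueError("filter_valid: no records")
    log: list[tuple[str, str]] = []
    clean = []
    for r in records:
        if r.is_ambiguous:
            log.append((r.id, "ambiguous bases"))
        else:
            clean.append(r)
    counts: dict[str, int] = {}
    for r in clean:
        counts[r.species] = counts.get(r.species, 0) + 1
    kept = []
    for r in clean:
        if counts[r.species] == 1:
            log.append((r.id, "singleton species"))
        else:
            kept.append(r)
    if not kept:
        raise ValueError("empty dataset after validation")
    return kept, log


# ---------------------------------------------------------------------------
# level views


def strip_all_gap_columns(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Remove columns that are gap in every record (alignment length
    becomes group-specific after subsetting)."""
    keep = [
        j
        for j in range(len(records[0].sequence))
        if any(r.sequence[j] != "-" for r in records)
    ]
    if len(keep) == len(records[0].sequence):
        return list(records)
    return [
        replace(r, sequence="".join(r.sequence[j] for j in keep)) for r in records
    ]


Realigner = Callable[[Sequence[SequenceRecord]], list[SequenceRecord]]


def subset_by_level(
    dataset: AlignedDataset,
    level: str,
    group: str | None = None,
    realign: Realigner | None = None,
) -> AlignedDataset:
    """Return the group view of a dataset at one taxonomic level.

    At family level the dataset is returned unchanged.  Otherwise the
    matching records are subset and all-gap columns stripped; under
    pairwise deletion this never changes any pairwise distance.  An
    external per-group ``realign`` hook may be supplied instead for
    strict per-group realignment.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    if level == "family":
        return dataset
    available = dataset.taxonomy.groups(level, dataset.species)
    if group not in available:
        raise KeyError(
            f"unknown {level} group {group!r}; available: {available}"
        )
    subset = [
        r
        for r in dataset.records
        if dataset.taxonomy.group_of(r.species, level) == group
    ]
    subset = realign(subset) if realign is not None else strip_all_gap_columns(subset)
    return AlignedDataset(records=subset, taxonomy=dataset.taxonomy)
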