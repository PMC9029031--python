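"""Shared loader for the analysis drivers: validated dataset from the
01_simulate output."""

import sys
from pathlib import Path

from barcodeval.io import AlignedDataset, filter_valid, read_fasta_with_taxonomy

ROOT = Path(__file__).resolve().parent.parent
SYNTH = ROOT / "results" / "synthetic"
RESULTS = ROOT / "results"


def load_survey() -> AlignedDataset:
    fasta = SYNTH / "sequences.fasta"
    if not fasta.exists():
        sys.exit("run analysis/01_simulate.py first")
    records, taxonomy = read_fasta_with_taxonomy(fasta, SYNTH / "taxonomy.tsv")
    kept, excluded = filter_valid(records)
    if excluded:
        print(f"validation excluded {len(excluded)} sequences")
    return AlignedDataset(records=kept, taxonomy=taxonomy)
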