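#!/usr/bin/env python
"""Distance-frequency distributions and barcode-gap overlap per genus
and for the whole family."""

import pandas as pd

from barcodeval.gap import INTER, INTRA, barcode_gap_summary, distance_histogram, range_share
from barcodeval.io import subset_by_level
from barcodeval.k2p import distance_matrix

from _data import RESULTS, load_survey


def main() -> None:
    dataset = load_survey()
    (RESULTS / "histograms").mkdir(parents=True, exist_ok=True)
    rows = []
    family_hist = None
    groups = [("family", dataset.taxonomy.family_name)] + [
        ("genus", g) for g in dataset.taxonomy.groups("genus", dataset.species)
    ]
    for level, group in groups:
        view = subset_by_level(dataset, level, group)
        hist = distance_histogram(distance_matrix(view))
        hist.write_csv(RESULTS / "histograms" / f"{level}__{group}.csv")
        if level == "family":
            family_hist = hist
        g = barcode_gap_summary(hist)
        rows.append(
            {
                "level": level, "group": group,
                "max_intra_pct": round(g.max_intraspecific, 2) if g.complete else None,
                "min_inter_pct": round(g.min_interspecific, 2) if g.complete else None,
                "gap_pct": round(g.gap, 2) if g.complete else None,
                "overlap_share_pct": round(g.overlap_share, 2) if g.complete else None,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(RESULTS / "gap_summary.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))
    for lo, hi, cls in ((0, 2, INTRA), (0, 8, INTRA), (0, 6, INTER), (0, 14, INTER)):
        share = range_share(family_hist, cls, lo, hi)
        print(f"family-level {cls} pairs in [{lo}%, {hi}%): {share:.2f}%")


if __name__ == "__main__":
    main()
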