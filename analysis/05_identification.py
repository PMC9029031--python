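#!/usr/bin/env python
"""Leave-one-out identification success per group and method: Best
Match, Best Close Match (95th-percentile threshold) and the internal
best-hit criterion."""

import pandas as pd

from barcodeval.identify import METHODS, identification_report
from barcodeval.io import LEVELS, subset_by_level
from barcodeval.k2p import distance_matrix

from _data import RESULTS, load_survey


def main() -> None:
    dataset = load_survey()
    rows = []
    for level in LEVELS:
        groups = (
            [dataset.taxonomy.family_name]
            if level == "family"
            else dataset.taxonomy.groups(level, dataset.species)
        )
        for group in groups:
            view = subset_by_level(dataset, level, group)
            dm = distance_matrix(view)
            for method in METHODS:
                rows.append(
                    identification_report(
                        view, method, dm=dm, group=group, level=level
                    ).as_row()
                )
    frame = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "identification.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))
    cpx = frame[(frame.level == "complex")]
    fam = frame[(frame.level == "family") & (frame.method == "BM")].iloc[0]
    print(
        f"\nthe zero-variation complex is 100% ambiguous under every method "
        f"(observed: {sorted(set(cpx.ambiguous))}); family-level BM is "
        f"{fam.correct}% correct over {fam.n_queries} queries — success "
        "drops as taxa get closer and haplotypes are shared"
    )


if __name__ == "__main__":
    main()
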