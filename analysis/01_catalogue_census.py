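#!/usr/bin/env python
"""Census of the catalogue of 50 primate-specific progenitor-enriched genes.

Tabulates the catalogue by occurrence clade, origin mechanism and
zinc-finger annotation, partitions the five dataset-membership sets into
Venn regions, and computes their pairwise overlap matrix.  Writes
results/catalogue_census.tsv, results/catalogue_venn.tsv and
results/catalogue_overlap.tsv.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from cortevo.datasets_io import fixture_gene_sets, load_table1_fixture
from cortevo.screen import overlap_matrix, venn_partition

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    records = load_table1_fixture()
    clades = Counter(r.occurrence for r in records)
    mechanisms = Counter(r.mechanism for r in records)
    pre_ape = [r for r in records if r.occurrence in ("Catarrhini", "Simiiformes", "Haplorrhini")]

    census = pd.DataFrame(
        [
            {"quantity": "total_genes", "count": len(records)},
            *({"quantity": f"clade_{c}", "count": n} for c, n in sorted(clades.items())),
            {"quantity": "predate_ape_ancestor", "count": len(pre_ape)},
            {"quantity": "zinc_finger_among_pre_ape", "count": sum(r.is_znf for r in pre_ape)},
            *(
                {"quantity": f"mechanism_{m}", "count": n}
                for m, n in sorted(mechanisms.items())
            ),
            {
                "quantity": "human_specific_whole_duplication",
                "count": sum(
                    r.occurrence == "Homo" and r.mechanism == "whole_duplication"
                    for r in records
                ),
            },
        ]
    )
    census.to_csv(OUT / "catalogue_census.tsv", sep="\t", index=False)

    sets = fixture_gene_sets(records)
    regions = venn_partition(sets)
    venn = pd.DataFrame(
        [
            {"combination": "+".join(sorted(combo)), "cardinality": len(combo), "genes": count}
            for combo, count in sorted(regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
    )
    venn.to_csv(OUT / "catalogue_venn.tsv", sep="\t", index=False)
    overlap = overlap_matrix(sets)
    overlap.to_csv(OUT / "catalogue_overlap.tsv", sep="\t")

    print(f"catalogue: {len(records)} genes across {len(clades)} clades")
    print(f"  human-specific (Homo): {clades['Homo']}, Catarrhini: {clades['Catarrhini']}")
    print(
        f"  {len(pre_ape)} genes predate the ape ancestor; "
        f"{sum(r.is_znf for r in pre_ape)} of them are zinc-finger genes"
    )
    print(f"  Venn regions: {len(regions)} ({sum(1 for c in regions if len(c) == 3)} three-set combinations)")
    print(f"wrote {OUT / 'catalogue_census.tsv'}")


if __name__ == "__main__":
    main()
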