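#!/usr/bin/env python
"""Regulated-set classification and hypergeometric overlap of the two tables.

Both perturbations act through the same regulon, so their up-regulated sets
(and down-regulated sets) should overlap far beyond chance within the merged
expressed universe.
"""

from pathlib import Path

import pandas as pd

from episeq import classify_regulated, merge_by_gene, overlap_batch, read_de_table

BASE = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    down = read_de_table(BASE / "sim" / "downstream.tsv", label="downstream")
    up = read_de_table(BASE / "sim" / "upstream.tsv", label="upstream")
    merged = merge_by_gene(down, up)

    sets = {
        (lbl, direction): classify_regulated(t, direction) & merged.genes
        for lbl, t in (("downstream", down), ("upstream", up))
        for direction in ("up", "down")
    }
    pairs = [
        (sets[("downstream", "up")], sets[("upstream", "up")]),
        (sets[("downstream", "down")], sets[("upstream", "down")]),
    ]
    results = overlap_batch(pairs, merged.genes)
    df = pd.DataFrame(
        [
            {
                "comparison": name,
                "n_universe": r.n_universe,
                "n_down_set": r.n_a,
                "n_up_set": r.n_b,
                "overlap": r.n_overlap,
                "expected": round(r.expected_overlap, 1),
                "fold_enrichment": round(r.fold_enrichment, 2),
                "p_adj": r.p_adj,
            }
            for name, r in zip(["up~up", "down~down"], results)
        ]
    )
    df.to_csv(BASE / "overlaps.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
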