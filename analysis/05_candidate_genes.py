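"""Annotate candidate SNPs with genes (±50 kb) and intersect the gene sets.

Per pair: genes near Fst candidates, genes near XP-EHH candidates, and their
intersection (the merged set); across pairs: the overlap of the merged sets.
Writes the full membership table to results/gene_sets.tsv and a count summary
to results/gene_set_counts.tsv.
"""

from pathlib import Path

import pandas as pd

from sweepscan import io
from sweepscan.pipeline import genes_near, merge_methods, overlap_pairs

PANEL = Path("scratch/panel")
RESULTS = Path("results")
PAIRS = ("MGR-HHG", "LNR-HHG")
FLANK = 50_000


def main() -> None:
    genes = io.read_gene_models(PANEL / "genes.bed")
    rows, counts = [], []
    merged_by_pair = {}
    for pair in PAIRS:
        df = io.read_scan_results(PANEL / f"scan_{pair}.tsv")
        sets = {}
        for method in ("fst", "xpehh"):
            cands = df.loc[df[f"candidate_{method}"], ["chrom", "pos"]]
            sets[method] = genes_near(cands, genes, FLANK)
            rows += [(pair, method, g) for g in sorted(sets[method])]
        merged = merge_methods(sets["fst"], sets["xpehh"])
        merged_by_pair[pair] = merged
        rows += [(pair, "merged", g) for g in sorted(merged)]
        counts.append({"pair": pair, "fst_genes": len(sets["fst"]),
                       "xpehh_genes": len(sets["xpehh"]), "merged": len(merged)})
        print(f"{pair}: {len(sets['fst'])} Fst genes, {len(sets['xpehh'])} XP-EHH genes, "
              f"{len(merged)} merged")
    overlap = overlap_pairs(merged_by_pair)
    rows += [("all", "overlap", g) for g in sorted(overlap)]
    counts.append({"pair": "all", "fst_genes": "", "xpehh_genes": "",
                   "merged": len(overlap)})
    print(f"overlap across cashmere-type pairs: {len(overlap)} genes: {sorted(overlap)}")

    pd.DataFrame(rows, columns=["pair", "method", "gene_id"]).to_csv(
        RESULTS / "gene_sets.tsv", sep="\t", index=False)
    pd.DataFrame(counts).to_csv(RESULTS / "gene_set_counts.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
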