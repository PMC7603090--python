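"""Pathway over-representation of each pair's merged candidate gene set.

Hypergeometric upper-tail test against the synthetic pathway map with the
full gene annotation as background; Benjamini–Hochberg control, significance
at q < 0.05. Writes one table per pair to results/.
"""

from pathlib import Path

import pandas as pd

from sweepscan import io
from sweepscan.enrichment import hypergeom_enrich, write_enrichment

PANEL = Path("scratch/panel")
RESULTS = Path("results")
PAIRS = ("MGR-HHG", "LNR-HHG")


def main() -> None:
    background = {g.gene_id for g in io.read_gene_models(PANEL / "genes.bed")}
    pathways = io.read_pathway_map(PANEL / "pathways.tsv")
    gene_sets = pd.read_csv(RESULTS / "gene_sets.tsv", sep="\t", dtype=str)
    for pair in PAIRS:
        merged = set(gene_sets.loc[(gene_sets["pair"] == pair)
                                   & (gene_sets["method"] == "merged"), "gene_id"])
        rows = hypergeom_enrich(merged & background, pathways, background)
        write_enrichment(rows, RESULTS / f"enrichment_{pair}.tsv")
        n_sig = sum(r.significant for r in rows)
        top = rows[0].pathway_id if rows else "-"
        print(f"{pair}: {len(merged)} merged genes, {n_sig} significant pathways "
              f"(q<0.05) of {len(rows)}; top pathway {top}")


if __name__ == "__main__":
    main()
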