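"""Population structure of the QC'd panel: pairwise Fst, NJ tree, PCA.

Writes the pairwise-Fst matrix, the neighbor-joining tree (newick) and PCA
sample coordinates to results/; the PCA scatter plot goes to scratch/.
"""

from pathlib import Path

import pandas as pd

from sweepscan import io
from sweepscan.plots import pca_scatter
from sweepscan.popstruct import genotype_pca, nj_tree, pairwise_fst_matrix, tree_to_newick

PANEL = Path("scratch/panel")
RESULTS = Path("results")


def main() -> None:
    variants, haps = io.read_phased_vcf(PANEL / "qc.vcf")
    pops = io.read_population_map(PANEL / "pops.tsv")
    geno = haps.to_genotypes()

    dm = pairwise_fst_matrix(geno, pops)
    pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels).to_csv(
        RESULTS / "fst_matrix.tsv", sep="\t", float_format="%.6f")
    nwk = tree_to_newick(nj_tree(dm))
    (RESULTS / "nj_tree.nwk").write_text(nwk + "\n")

    coords, explained = genotype_pca(geno, 2)
    sample_pops = [pops.assignments[s] for s in geno.sample_ids]
    df = pd.DataFrame({"sample_id": geno.sample_ids, "population": sample_pops,
                       "PC1": coords[:, 0], "PC2": coords[:, 1]})
    df.to_csv(RESULTS / "pca.tsv", sep="\t", index=False, float_format="%.6f")
    pca_scatter(coords, sample_pops, Path("scratch") / "pca.png")

    print("pairwise Fst:")
    print(pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels).round(4))
    print("NJ tree:", nwk)
    print(f"PC1/PC2 explained variance: {explained[0]:.2f}, {explained[1]:.2f}")


if __name__ == "__main__":
    main()
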