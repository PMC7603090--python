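"""Per-SNP Fst and XP-EHH scans of both cashmere-type populations against the
reference, with empirical top-5% candidate flags.

One scan per pair (MGR-HHG, LNR-HHG). Full per-SNP tables go to scratch/
(one row per SNP); the thresholds and candidate counts go to
results/scan_thresholds.tsv; Manhattan-style plots go to scratch/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sweepscan import io
from sweepscan.pipeline import score_candidates
from sweepscan.plots import manhattan
from sweepscan.stats import fst_scan, xpehh_scan
from sweepscan.types import ScanResult

PANEL = Path("scratch/panel")
RESULTS = Path("results")
PAIRS = (("MGR", "HHG"), ("LNR", "HHG"))


def main() -> None:
    variants, haps = io.read_phased_vcf(PANEL / "qc.vcf")
    pops = io.read_population_map(PANEL / "pops.tsv")
    geno = haps.to_genotypes()

    rows = []
    for obj, ref in PAIRS:
        fst = fst_scan(geno, pops, obj, ref)
        h_obj = haps.subset_samples(pops.samples_in(obj))
        h_ref = haps.subset_samples(pops.samples_in(ref))
        ratio, ln_ratio = xpehh_scan(h_obj, h_ref, variants)
        res = ScanResult(variants=variants, breed_pair=f"{obj}-{ref}",
                         fst=fst, xpehh=ratio, ln_xpehh=ln_ratio)
        score_candidates(res)
        io.write_scan_results(res, PANEL / f"scan_{obj}-{ref}.tsv")
        for stat in ("fst", "xpehh"):
            manhattan(res, stat, Path("scratch") / f"manhattan_{stat}_{obj}-{ref}.png")
        rows.append({
            "pair": f"{obj}-{ref}",
            "fst_threshold": round(res.thresholds["fst"], 6),
            "xpehh_threshold": round(res.thresholds["xpehh"], 6),
            "n_candidate_fst": int(res.candidate_fst.sum()),
            "n_candidate_xpehh": int(res.candidate_xpehh.sum()),
            "max_xpehh_pos": int(variants.pos[np.nanargmax(ratio)]),
        })
        print(f"{obj}-{ref}: fst>{res.thresholds['fst']:.4f} "
              f"({rows[-1]['n_candidate_fst']} SNPs), "
              f"xpehh>{res.thresholds['xpehh']:.4f} "
              f"({rows[-1]['n_candidate_xpehh']} SNPs); "
              f"strongest XP-EHH at {rows[-1]['max_xpehh_pos']/1e6:.2f} Mb")
    pd.DataFrame(rows).to_csv(RESULTS / "scan_thresholds.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
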