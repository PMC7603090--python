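"""Apply the four SNP quality-control filters to the simulated panel.

Filters: exact HWE p >= 1e-6, call rate > 0.90, MAF > 0.01, autosomal only.
Writes the filtered phased VCF to scratch/panel/qc.vcf and the per-rule
failure counts to results/qc_report.tsv.
"""

from pathlib import Path

from sweepscan import io
from sweepscan.qc import QcThresholds, apply_qc

PANEL = Path("scratch/panel")
RESULTS = Path("results")


def main() -> None:
    variants, haps = io.read_phased_vcf(PANEL / "panel.vcf")
    _, kept, report = apply_qc(haps.to_genotypes(), variants, QcThresholds())
    io.write_phased_vcf(PANEL / "qc.vcf", kept, haps.subset_variants(report.pass_mask))
    (RESULTS / "qc_report.tsv").write_text(report.summary())
    print(f"{report.n_pass}/{report.n_input} SNPs pass QC; "
          f"failures by rule: {report.n_fail_by_rule}")


if __name__ == "__main__":
    main()
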