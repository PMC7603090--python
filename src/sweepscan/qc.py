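"""SNP-level quality control: the four chip-QC filters.

A SNP passes iff (i) exact Hardy–Weinberg p ≥ 1e-6, (ii) call rate > 0.90,
(iii) MAF > 0.01, and (iv) it maps to an autosome. The pass rules use strict
inequalities for call rate and MAF (a SNP exactly at the bound fails). HWE is
tested on all samples pooled by default; per-population testing is available
via ``QcThresholds.hwe_per_population``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import MISSING, GenotypeMatrix, PopulationMap, VariantTable
from .io import DEFAULT_NON_AUTOSOMES, is_autosome


@dataclass(frozen=True)
class QcThresholds:
    hwe_p_min: float = 1e-6
    call_rate_min: float = 0.90
    maf_min: float = 0.01
    autosomes_only: bool = True
    hwe_per_population: bool = False
    non_autosomes: tuple[str, ...] = DEFAULT_NON_AUTOSOMES

    def __post_init__(self) -> None:
        for v in (self.hwe_p_min, self.call_rate_min, self.maf_min):
            if not (0 <= v <= 1):
                raise ValueError("QC bounds must lie in [0, 1]")


@dataclass
class QcReport:
    n_input: int
    n_pass: int
    n_fail_by_rule: dict[str, int]
    pass_mask: np.ndarray

    def summary(self) -> str:
        lines = [f"input SNPs\t{self.n_input}", f"passing SNPs\t{self.n_pass}"]
        for rule, n in self.n_fail_by_rule.items():
            lines.append(f"fail {rule}\t{n}")
        return "\n".join(lines) + "\n"


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Conditions on the total genotype count and the minor-allele count, and sums
    the probabilities of all heterozygote counts whose conditional probability
    does not exceed that of the observed count (no mid-p correction). Returns
    NaN when no genotypes were observed; monomorphic sites return 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return float("nan")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0

    # Heterozygote counts share the parity of the minor-allele count.
    het_lo = n_rare % 2
    hets = np.arange(het_lo, n_rare + 1, 2)
    # Unnormalized probabilities by the standard recurrence:
    # P(h+2)/P(h) = [ (nr-h)(2n-nr-h) ] / [ (h+2)(h+1)/... ]  — done in log space
    # for stability at large n.
    probs = np.empty(len(hets), dtype=float)
    probs[0] = 0.0  # log scale, relative
    for i in range(1, len(hets)):
        h = hets[i - 1]
        num = (n_rare - h) * (2 * n - n_rare - h)
        den = (h + 2) * (h + 1)
        probs[i] = probs[i - 1] + np.log(num) - np.log(den)
    probs = np.exp(probs - probs.max())
    probs /= probs.sum()

    obs = np.searchsorted(hets, n_het)
    if obs >= len(hets) or hets[obs] != n_het:
        raise ValueError("heterozygote count inconsistent with allele-count parity")
    p = probs[probs <= probs[obs] * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def snp_call_rate(column: np.ndarray) -> float:
    """Fraction of non-missing genotypes in one SNP column."""
    column = np.asarray(column)
    if column.size == 0:
        raise ValueError("empty genotype column")
    return float(np.mean(column != MISSING))


def snp_maf(column: np.ndarray) -> float:
    """Minor-allele frequency over non-missing genotypes of one SNP column."""
    column = np.asarray(column)
    obs = column[column != MISSING]
    if obs.size == 0:
        raise ValueError("no non-missing genotypes")
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def _hwe_column(column: np.ndarray) -> float:
    obs = column[column != MISSING]
    if obs.size == 0:
        return float("nan")
    counts = np.bincount(obs, minlength=3)
    return hwe_exact_p(int(counts[0]), int(counts[1]), int(counts[2]))


def apply_qc(geno: GenotypeMatrix, variants: VariantTable, thr: QcThresholds = QcThresholds(),
             pops: PopulationMap | None = None):
    """Filter a panel by the four SNP rules.

    Returns ``(GenotypeMatrix, VariantTable, QcReport)`` with variant order
    preserved. With ``hwe_per_population`` a SNP fails HWE if it fails in any
    population (requires ``pops``).
    """
    if geno.n_variants != variants.n_variants:
        raise ValueError("genotype/variant shape mismatch")
    n = variants.n_variants
    ent = geno.entries

    call = np.array([snp_call_rate(ent[:, j]) for j in range(n)])
    maf = np.full(n, np.nan)
    hwe = np.full(n, np.nan)
    for j in range(n):
        col = ent[:, j]
        if np.any(col != MISSING):
            maf[j] = snp_maf(col)
            if thr.hwe_per_population and pops is not None:
                ps = []
                for pop in pops.populations:
                    sub = geno.subset_samples(pops.samples_in(pop))
                    ps.append(_hwe_column(sub.entries[:, j]))
                hwe[j] = np.nanmin(ps) if ps else np.nan
            else:
                hwe[j] = _hwe_column(col)

    # A threshold of exactly 0 disables its rule, so 0/0/0 with
    # autosomes_only=False is the identity filter.
    fail_hwe = (~np.isnan(hwe) & (hwe < thr.hwe_p_min)) if thr.hwe_p_min > 0 \
        else np.zeros(n, bool)
    fail_call = ~(call > thr.call_rate_min) if thr.call_rate_min > 0 else np.zeros(n, bool)
    fail_maf = (np.isnan(maf) | ~(maf > thr.maf_min)) if thr.maf_min > 0 \
        else np.zeros(n, bool)
    if thr.autosomes_only:
        fail_auto = np.array([not is_autosome(c, thr.non_autosomes) for c in variants.chrom])
    else:
        fail_auto = np.zeros(n, bool)

    pass_mask = ~(fail_hwe | fail_call | fail_maf | fail_auto)
    report = QcReport(
        n_input=n,
        n_pass=int(pass_mask.sum()),
        n_fail_by_rule={
            "hwe": int(fail_hwe.sum()),
            "call_rate": int(fail_call.sum()),
            "maf": int(fail_maf.sum()),
            "non_autosomal": int(fail_auto.sum()),
        },
        pass_mask=pass_mask,
    )
    if report.n_pass == 0:
        warnings.warn("no SNPs pass QC", stacklevel=2)
    return geno.subset_variants(pass_mask), variants.subset(pass_mask), report
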