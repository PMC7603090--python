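"""Synthetic phased SNP panels with controlled differentiation and planted sweeps.

The generator emulates a 50K-chip-like panel for the three-breed goat design
(17 + 20 + 16 diploid samples) at desk scale: one chromosome, uniformly placed
SNPs, Balding–Nichols population allele frequencies around a common ancestral
frequency, independent sites (no background LD), and an optional selective
sweep modeled as distance-decaying copying from a single donor haplotype.

Balding–Nichols gives each population frequency
``p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` so the differentiation parameter ``F``
equals the expected per-SNP Fst — which makes parameter-recovery tests exact
in expectation without a coalescent simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import HaplotypeMatrix, PopulationMap, VariantTable, GeneModel


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: distance-decaying copying from one donor haplotype.

    ``decay_length`` is the e-folding distance (bp) of the per-site copy
    probability ``exp(-|pos - core_pos| / decay_length)``.
    """

    target_pop: str
    core_pos: int
    carrier_fraction: float = 0.8
    decay_length: float = 2e6

    def __post_init__(self) -> None:
        if not (0 < self.carrier_fraction <= 1):
            raise ValueError("carrier_fraction must be in (0, 1]")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the synthetic panel.

    Defaults mirror the three-breed chip design: 17/20/16 diploid samples,
    5,000 SNPs on a 50 Mb chromosome, ancestral frequencies uniform on
    (0.05, 0.95), between-population differentiation F = 0.1.
    """

    n_pops: int = 3
    samples_per_pop: tuple[int, ...] = (17, 20, 16)
    pop_labels: tuple[str, ...] | None = None
    n_snps: int = 5000
    chrom: str = "1"
    chrom_length: int = 50_000_000
    divergence_F: float = 0.1
    ancestral_maf_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    sweep_specs: tuple[SweepSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_pop) != self.n_pops:
            raise ValueError("samples_per_pop length must equal n_pops")
        if any(n < 2 for n in self.samples_per_pop):
            raise ValueError("each population needs >= 2 samples")
        if self.n_snps < 10:
            raise ValueError("n_snps must be >= 10")
        if not (0 < self.divergence_F < 1):
            raise ValueError("divergence_F must be in (0, 1)")
        for spec in self.sweep_specs:
            if not (1 <= spec.core_pos <= self.chrom_length):
                raise ValueError("sweep core_pos outside chromosome")

    @property
    def labels(self) -> tuple[str, ...]:
        if self.pop_labels is not None:
            if len(self.pop_labels) != self.n_pops:
                raise ValueError("pop_labels length must equal n_pops")
            return self.pop_labels
        return tuple(f"pop{k + 1}" for k in range(self.n_pops))


def simulate_panel(config: SimConfig):
    """Draw a phased panel under the Balding–Nichols model.

    Returns ``(VariantTable, HaplotypeMatrix, PopulationMap)``; any configured
    sweeps are planted afterwards. Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    for _attempt in range(100):
        pos = np.sort(rng.integers(1, config.chrom_length + 1, size=config.n_snps))
        if len(np.unique(pos)) == config.n_snps:
            break
    else:
        raise RuntimeError("could not draw unique SNP positions in 100 attempts")

    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=config.n_snps)
    F = config.divergence_F
    scale = (1.0 - F) / F
    # population frequencies, one row per population
    p_pop = rng.beta(np.maximum(p_anc * scale, 1e-12),
                     np.maximum((1.0 - p_anc) * scale, 1e-12),
                     size=(config.n_pops, config.n_snps))

    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    blocks = []
    for k, (label, n) in enumerate(zip(config.labels, config.samples_per_pop)):
        ids = [f"{label}_{i + 1:02d}" for i in range(n)]
        sample_ids.extend(ids)
        assignments.update({s: label for s in ids})
        blocks.append((rng.random((2 * n, config.n_snps)) < p_pop[k]).astype(np.int8))
    entries = np.vstack(blocks)

    if config.missing_rate > 0:
        miss = rng.random((len(sample_ids), config.n_snps)) < config.missing_rate
        miss2 = np.repeat(miss, 2, axis=0)
        entries = np.where(miss2, np.int8(-1), entries)

    ids = [f"snp{j + 1:05d}" for j in range(config.n_snps)]
    ref = np.where(rng.random(config.n_snps) < 0.5, "A", "C")
    alt = np.where(ref == "A", "G", "T")
    table = VariantTable(pd.DataFrame({
        "variant_id": ids, "chrom": config.chrom, "pos": pos,
        "ref": ref, "alt": alt,
    }))
    haps = HaplotypeMatrix(entries, sample_ids, phased=True)
    pops = PopulationMap(assignments)

    for i, spec in enumerate(config.sweep_specs):
        haps = plant_sweep(haps, table, pops, spec, seed=config.seed + 1000 + i)
    return table, haps, pops


def plant_sweep(haps: HaplotypeMatrix, variants: VariantTable, pops: PopulationMap,
                spec: SweepSpec, seed: int) -> HaplotypeMatrix:
    """Copy a donor haplotype into carriers with distance-decaying probability.

    One donor haplotype is chosen uniformly in ``target_pop``; a
    ``carrier_fraction`` of that population's haplotypes receive the donor
    allele at each site with probability ``exp(-d / decay_length)`` where ``d``
    is the bp distance to ``core_pos``. Other populations are untouched.
    """
    rng = np.random.default_rng(seed)
    target_samples = pops.samples_in(spec.target_pop)
    index = {s: k for k, s in enumerate(haps.sample_ids)}
    rows = np.array([r for s in target_samples for r in (2 * index[s], 2 * index[s] + 1)])

    n_carriers = int(round(spec.carrier_fraction * len(rows)))
    if n_carriers < 2:
        warnings.warn("fewer than 2 carrier haplotypes: EHH undefined on the swept class",
                      stacklevel=2)
    donor_row = rows[rng.integers(len(rows))]
    carrier_rows = rng.choice(rows, size=n_carriers, replace=False)

    d = np.abs(variants.pos.astype(float) - float(spec.core_pos))
    p_copy = np.exp(-d / spec.decay_length)

    entries = haps.entries.copy()
    donor = entries[donor_row]
    for r in carrier_rows:
        take = rng.random(len(p_copy)) < p_copy
        entries[r, take] = donor[take]
    return HaplotypeMatrix(entries, list(haps.sample_ids), haps.phased)


def make_gene_fixture(variants: VariantTable, n_genes: int, seed: int,
                      n_pathways: int | None = None):
    """Tile non-overlapping genes (5–50 kb) over the chromosome and assign each
    to 1–3 synthetic pathways.

    Returns ``(list of GeneModel, pathway → gene-id set)``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom = str(variants.chrom[0])
    chrom_len = int(variants.pos.max())
    lengths = rng.integers(5_000, 50_001, size=n_genes)
    gap = (chrom_len - int(lengths.sum())) // (n_genes + 1)
    if gap < 1:
        raise ValueError("chromosome too short to tile n_genes non-overlapping genes")
    genes: list[GeneModel] = []
    cursor = 1
    for i, length in enumerate(lengths):
        start = cursor + int(rng.integers(1, gap + 1))
        end = start + int(length) - 1
        genes.append(GeneModel(gene_id=f"gene{i + 1:04d}", name=f"gene{i + 1:04d}",
                               chrom=chrom, start=start, end=end,
                               strand="+" if rng.random() < 0.5 else "-"))
        cursor = end + 1

    if n_pathways is None:
        n_pathways = max(3, n_genes // 10)
    pathways: dict[str, set[str]] = {f"pw{i + 1:03d}": set() for i in range(n_pathways)}
    pw_ids = sorted(pathways)
    for g in genes:
        for pw in rng.choice(pw_ids, size=int(rng.integers(1, 4)), replace=False):
            pathways[pw].add(g.gene_id)
    # drop pathways that drew no genes so the map has no empty entries
    pathways = {pw: members for pw, members in pathways.items() if members}
    return genes, pathways
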