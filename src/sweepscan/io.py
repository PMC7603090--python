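"""Readers and writers for every external format the pipeline touches.

Formats: phased VCF 4.x (GT only), two-column population map TSV, gene models
as BED4+ (0-based half-open) or GFF3 (1-based inclusive), pathway→gene TSV,
and the per-SNP scan-result TSV. All TSV output is UTF-8, tab-delimited, '.'
decimal, floats at 6 decimals so write→read→write is byte-stable.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    MISSING,
    FormatError,
    GeneModel,
    HaplotypeMatrix,
    PopulationMap,
    ScanResult,
    VariantTable,
)

logger = logging.getLogger(__name__)

#: Chromosome names (upper-cased, 'chr' prefix stripped) treated as non-autosomal.
DEFAULT_NON_AUTOSOMES = ("X", "Y", "MT", "M")


def is_autosome(chrom: str, non_autosomes=DEFAULT_NON_AUTOSOMES) -> bool:
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return name.upper() not in {c.upper() for c in non_autosomes}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(path, require_phased: bool = True):
    """Read a VCF with per-sample GT into (VariantTable, HaplotypeMatrix).

    Only biallelic SNPs are kept; multiallelic records and indels are dropped
    with a logged count. Allele 0 maps to REF, 1 to ALT. Unphased genotypes
    ('/' separator) raise :class:`FormatError` when ``require_phased`` is set,
    otherwise they are accepted with a warning, keeping the written allele
    order (deterministic but arbitrary). './.' becomes MISSING on both
    haplotypes.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib rejects e.g. duplicated sample names here
        raise FormatError(f"cannot parse VCF header of {path} "
                          f"(duplicated sample id or malformed header): {exc}") from exc
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise FormatError("duplicated sample id in VCF header")
    if not samples:
        raise FormatError("VCF has no samples")

    rows = []
    haps: list[np.ndarray] = []
    n_dropped = 0
    any_unphased = False
    for k, rec in enumerate(vcf):
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            n_dropped += 1
            continue
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        if any(len(g) < 3 for g in gts):
            raise FormatError(f"record {rec.CHROM}:{rec.POS} lacks a diploid GT")
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if not g[2] and not (a0 < 0 and a1 < 0):
                if require_phased:
                    raise FormatError(
                        f"unphased genotype at {rec.CHROM}:{rec.POS} sample {samples[i]}")
                any_unphased = True
            col[2 * i] = a0 if a0 >= 0 else MISSING
            col[2 * i + 1] = a1 if a1 >= 0 else MISSING
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        rows.append((vid, rec.CHROM, rec.POS, rec.REF, alts[0]))
        haps.append(col)
    if n_dropped:
        logger.info("dropped %d non-biallelic-SNP records from %s", n_dropped, path)
    if any_unphased:
        warnings.warn("unphased genotypes accepted with file phase order",
                      stacklevel=2)
    if not rows:
        raise FormatError(f"no biallelic SNP records in {path}")
    table = VariantTable(pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"]))
    entries = np.column_stack(haps) if haps else np.empty((2 * len(samples), 0), np.int8)
    return table, HaplotypeMatrix(entries, samples, phased=not any_unphased)


def write_phased_vcf(path, variants: VariantTable, haps: HaplotypeMatrix) -> None:
    """Write a minimal phased VCF 4.2 ('|' separators, '.|.' for missing)."""
    if variants.n_variants != haps.n_variants:
        raise ValueError("variant/haplotype shape mismatch")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(variants.df["chrom"]):
            length = int(variants.df.loc[variants.df["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(haps.sample_ids) + "\n")
        ent = haps.entries
        for j, row in enumerate(variants.df.itertuples(index=False)):
            gt_fields = []
            for k in range(haps.n_samples):
                a, b = ent[2 * k, j], ent[2 * k + 1, j]
                sa = "." if a == MISSING else str(int(a))
                sb = "." if b == MISSING else str(int(b))
                gt_fields.append(f"{sa}|{sb}")
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gt_fields) + "\n")


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

def read_population_map(path) -> PopulationMap:
    """Two-column TSV: sample_id <TAB> population."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("population map needs two tab-separated columns")
    if df[0].duplicated().any():
        raise FormatError("sample assigned to more than one population")
    return PopulationMap(dict(zip(df[0], df[1])))


def write_population_map(path, pops: PopulationMap) -> None:
    with Path(path).open("w") as fh:
        for s, p in pops.assignments.items():
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# Gene models (BED / GFF3)
# ---------------------------------------------------------------------------

def read_gene_models(path, format: str | None = None) -> list[GeneModel]:
    """Read gene intervals from BED4+ or GFF3; coordinates normalized to
    1-based inclusive (BED start s → s+1).

    ``format`` is inferred from the suffix when omitted.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "gff3" if suffix in (".gff", ".gff3", ".gtf") else "bed"
    if format == "bed":
        return _read_bed(path)
    if format == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown gene file format {format!r}")


def _read_bed(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise FormatError("BED gene file needs at least 4 columns (chrom start end name)")
    genes = []
    for row in df.itertuples(index=False):
        start = int(row[1]) + 1  # 0-based half-open → 1-based inclusive
        end = int(row[2])
        strand = str(row[5]) if len(row) > 5 and str(row[5]) in "+-" else "."
        genes.append(GeneModel(gene_id=str(row[3]), name=str(row[3]),
                               chrom=str(row[0]), start=start, end=end, strand=strand))
    return genes


def _gff3_attr(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        item = item.strip()
        if item.startswith(key + "="):
            return item[len(key) + 1:]
    return None


def _read_gff3(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 9:
        raise FormatError("GFF3 needs 9 columns")
    genes = []
    for row in df.itertuples(index=False):
        if row[2] != "gene":
            continue
        attrs = row[8]
        gid = _gff3_attr(attrs, "ID") or _gff3_attr(attrs, "gene_id")
        name = _gff3_attr(attrs, "Name") or gid
        if gid is None:
            raise FormatError("gene feature without ID attribute")
        strand = row[6] if row[6] in "+-" else "."
        genes.append(GeneModel(gene_id=gid, name=name, chrom=str(row[0]),
                               start=int(row[3]), end=int(row[4]), strand=strand))
    return genes


def write_gene_models_bed(path, genes: list[GeneModel]) -> None:
    """Write genes as BED4+2 (0-based half-open)."""
    with Path(path).open("w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Pathway map
# ---------------------------------------------------------------------------

def read_pathway_map(path) -> dict[str, set[str]]:
    """pathway_id <TAB> gene_id, one pair per line → pathway → gene set."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("pathway map needs two tab-separated columns")
    out: dict[str, set[str]] = {}
    for pw, gene in zip(df[0], df[1]):
        out.setdefault(pw, set()).add(gene)
    return out


def write_pathway_map(path, pathways: dict[str, set[str]]) -> None:
    with Path(path).open("w") as fh:
        for pw in sorted(pathways):
            for gene in sorted(pathways[pw]):
                fh.write(f"{pw}\t{gene}\n")


# ---------------------------------------------------------------------------
# Scan results
# ---------------------------------------------------------------------------

_SCAN_COLUMNS = ["breed_pair", "chrom", "pos", "fst", "xpehh", "ln_xpehh",
                 "candidate_fst", "candidate_xpehh", "genes"]


def _fmt_float(x: float) -> str:
    return "NA" if np.isnan(x) else f"{x:.6f}"


def write_scan_results(result: ScanResult, path) -> None:
    """Serialize a ScanResult to TSV (floats at 6 decimals, NA for undefined)."""
    n = result.variants.n_variants
    cand_f = result.candidate_fst if result.candidate_fst is not None else np.zeros(n, bool)
    cand_x = result.candidate_xpehh if result.candidate_xpehh is not None else np.zeros(n, bool)
    genes = result.genes if result.genes is not None else ["."] * n
    with Path(path).open("w") as fh:
        fh.write("\t".join(_SCAN_COLUMNS) + "\n")
        for j in range(n):
            fh.write("\t".join([
                result.breed_pair,
                str(result.variants.chrom[j]),
                str(int(result.variants.pos[j])),
                _fmt_float(result.fst[j]),
                _fmt_float(result.xpehh[j]),
                _fmt_float(result.ln_xpehh[j]),
                str(int(cand_f[j])),
                str(int(cand_x[j])),
                genes[j] if genes[j] else ".",
            ]) + "\n")


def read_scan_results(path) -> pd.DataFrame:
    """Parse a scan-result TSV back into a DataFrame (NaN for NA)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "genes": str},
                     na_values=["NA"], keep_default_na=False)
    missing = [c for c in _SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"scan TSV missing columns: {missing}")
    df["candidate_fst"] = df["candidate_fst"].astype(int).astype(bool)
    df["candidate_xpehh"] = df["candidate_xpehh"].astype(int).astype(bool)
    return df
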