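"""From statistic vectors to candidate SNPs, ±50 kb regions, genes and overlaps.

Candidates are the empirical top 5% per statistic and population pair
(nearest-rank upper quantile, ties included). Candidate regions are the 50 kb
flanks on either side of each candidate SNP; a gene is a candidate gene when
its span intersects at least one such region. Per pair, the merged set is the
intersection of the Fst and XP-EHH gene sets; the cross-pair overlap is the
intersection of the merged sets.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .types import GeneModel, GeneSetReport, ScanResult

DEFAULT_FLANK = 50_000


def empirical_threshold(values: np.ndarray, quantile: float = 0.95) -> float:
    """Nearest-rank upper-quantile threshold over non-missing values.

    Sorts descending and returns the value at rank ``ceil((1-quantile)*n)``,
    so the threshold is always attained by at least one SNP and, for distinct
    values, exactly ``ceil((1-quantile)*n)`` SNPs sit at or above it.
    """
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no non-missing values")
    # n - floor(q*n) equals ceil((1-q)*n) without the float round-off that
    # (1 - q) * n introduces
    k = max(v.size - math.floor(quantile * v.size), 1)
    return float(np.sort(v)[::-1][k - 1])


def candidate_mask(values: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean per-variant flag: value defined and >= threshold."""
    v = np.asarray(values, float)
    return ~np.isnan(v) & (v >= threshold)


def candidate_snps(result: ScanResult) -> dict[str, pd.DataFrame]:
    """Per-method candidate lists (chrom, pos, value), sorted by value descending."""
    out: dict[str, pd.DataFrame] = {}
    for method, vec, mask in (("fst", result.fst, result.candidate_fst),
                              ("xpehh", result.xpehh, result.candidate_xpehh)):
        if mask is None:
            raise ValueError("thresholds not computed; call score_candidates first")
        df = pd.DataFrame({
            "chrom": result.variants.chrom[mask],
            "pos": result.variants.pos[mask],
            "value": vec[mask],
        }).sort_values("value", ascending=False, kind="stable").reset_index(drop=True)
        out[method] = df
    return out


def score_candidates(result: ScanResult, quantile: float = 0.95) -> ScanResult:
    """Fill thresholds and candidate flags on a ScanResult (in place, returned)."""
    result.thresholds["fst"] = empirical_threshold(result.fst, quantile)
    result.thresholds["xpehh"] = empirical_threshold(result.xpehh, quantile)
    result.candidate_fst = candidate_mask(result.fst, result.thresholds["fst"])
    result.candidate_xpehh = candidate_mask(result.xpehh, result.thresholds["xpehh"])
    return result


def genes_near(snps: pd.DataFrame, genes: list[GeneModel],
               flank: int = DEFAULT_FLANK) -> set[str]:
    """Gene ids whose span intersects any candidate SNP's ±flank window.

    ``snps`` needs ``chrom`` and ``pos`` columns; windows are clipped at 1.
    """
    out: set[str] = set()
    if len(snps) == 0:
        return out
    by_chrom: dict[str, np.ndarray] = {
        str(c): np.sort(sub["pos"].to_numpy())
        for c, sub in snps.groupby("chrom")
    }
    for g in genes:
        pos = by_chrom.get(g.chrom)
        if pos is None:
            continue
        lo, hi = max(1, g.start - flank), g.end + flank
        i = np.searchsorted(pos, lo, side="left")
        if i < len(pos) and pos[i] <= hi:
            out.add(g.gene_id)
    return out


def nearest_gene_per_snp(snps: pd.DataFrame, genes: list[GeneModel],
                         flank: int = DEFAULT_FLANK) -> list[str]:
    """Best gene per candidate SNP: nearest within ±flank, ties to smallest start.

    Distance to a gene is 0 when the SNP lies inside it, else the gap to the
    closer end. Returns '.' where no gene is in range.
    """
    labels: list[str] = []
    for row in snps.itertuples(index=False):
        best: tuple[int, int, str] | None = None
        for g in genes:
            if g.chrom != str(row.chrom):
                continue
            if g.start <= row.pos <= g.end:
                dist = 0
            elif row.pos < g.start:
                dist = g.start - row.pos
            else:
                dist = row.pos - g.end
            if dist > flank:
                continue
            key = (dist, g.start, g.gene_id)
            if best is None or key < best:
                best = key
        labels.append(best[2] if best is not None else ".")
    return labels


def merge_methods(fst_genes: set[str], xpehh_genes: set[str]) -> set[str]:
    """Genes supported by both statistics (Venn overlap of the two methods)."""
    return set(fst_genes) & set(xpehh_genes)


def overlap_pairs(merged_by_pair: dict[str, set[str]]) -> set[str]:
    """Genes shared by every population pair's merged set."""
    if len(merged_by_pair) < 2:
        raise ValueError("need >= 2 population pairs")
    sets = list(merged_by_pair.values())
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def build_gene_report(results: dict[str, ScanResult], genes: list[GeneModel],
                      flank: int = DEFAULT_FLANK) -> GeneSetReport:
    """Per-pair method gene sets, per-pair merges, and the cross-pair overlap."""
    sets: dict[tuple[str, str], set[str]] = {}
    merged: dict[str, set[str]] = {}
    for pair, res in results.items():
        cands = candidate_snps(res)
        sets[(pair, "fst")] = genes_near(cands["fst"], genes, flank)
        sets[(pair, "xpehh")] = genes_near(cands["xpehh"], genes, flank)
        merged[pair] = merge_methods(sets[(pair, "fst")], sets[(pair, "xpehh")])
    overlap = overlap_pairs(merged) if len(merged) >= 2 else set()
    return GeneSetReport(sets=sets, merged=merged, overlap=overlap)
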