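"""Per-SNP selection statistics: two-population Fst and EHH / XP-EHH.

Fst uses the mean-square (allele-frequency ANOVA) estimator

    Fst = (MSP - MSG) / (MSP + (n_c - 1) * MSG)

with MSP the among-population mean square, MSG the within-population mean
square and n_c the size-imbalance-corrected average allele sample size. Sample
sizes are counted in alleles (2 × genotyped individuals). Negative values are
reported as computed.

EHH partitions a population's haplotypes by their allele vector over the
closed interval from a core SNP out to marker x:

    EHH(x) = sum_i C(n_i, 2) / (C(n_a, 2) + C(n_A, 2))

where n_i are the haplotype-class sizes and n_a, n_A the counts of the two
core alleles (denominator fixed at the core). The default denominator pools
both core-allele classes; ``ehh_mode="per_allele"`` restricts numerator and
denominator to one core-allele class (the classical definition). XP-EHH is
the ratio of the two populations' trapezoid-integrated EHH over a shared
domain D that extends outward until both curves fall below ``epsilon``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import MISSING, GenotypeMatrix, HaplotypeMatrix, PopulationMap, VariantTable


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FstComponents:
    msp: float
    msg: float
    n_c: float
    fst: float


def fst_per_snp(m1: float, p1: float, m2: float, p2: float) -> FstComponents:
    """Mean-square Fst for one SNP from allele counts and frequencies.

    ``m1``, ``m2`` are non-missing allele counts (2 × genotyped samples);
    ``p1``, ``p2`` the alt-allele frequencies. Fst is NaN where the
    denominator vanishes (both populations monomorphic for the same allele).
    """
    if m1 < 2 or m2 < 2:
        raise ValueError("need >= 2 non-missing alleles per population")
    for p in (p1, p2):
        if not (0.0 <= p <= 1.0):
            raise ValueError("allele frequencies must lie in [0, 1]")
    m = np.array([m1, m2], float)
    p = np.array([p1, p2], float)
    r = 2
    total = m.sum()
    pbar = (m * p).sum() / total
    msp = (m * (p - pbar) ** 2).sum() / (r - 1)
    msg = (m * p * (1.0 - p)).sum() / (m - 1.0).sum()
    n_c = (total - (m ** 2).sum() / total) / (r - 1)
    denom = msp + (n_c - 1.0) * msg
    fst = float("nan") if denom == 0 else (msp - msg) / denom
    return FstComponents(float(msp), float(msg), float(n_c), float(fst))


def _pop_allele_stats(geno: GenotypeMatrix, rows: np.ndarray):
    """Per-SNP non-missing allele counts and alt frequencies for one population."""
    sub = geno.entries[rows].astype(float)
    obs = sub != MISSING
    m = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(m > 0, np.where(obs, sub, 0.0).sum(axis=0) / m, np.nan)
    return m, p


def fst_scan(geno: GenotypeMatrix, pops: PopulationMap,
             pop1: str | None = None, pop2: str | None = None) -> np.ndarray:
    """Vector of per-SNP Fst values between two populations (NaN = undefined)."""
    if pop1 is None or pop2 is None:
        pop1 = pops.object_pop if pop1 is None else pop1
        pop2 = pops.reference_pop if pop2 is None else pop2
    if pop1 is None or pop2 is None:
        raise ValueError("two population labels required")
    index = {s: k for k, s in enumerate(geno.sample_ids)}
    rows1 = np.array([index[s] for s in pops.samples_in(pop1)])
    rows2 = np.array([index[s] for s in pops.samples_in(pop2)])
    m1, p1 = _pop_allele_stats(geno, rows1)
    m2, p2 = _pop_allele_stats(geno, rows2)

    with np.errstate(invalid="ignore", divide="ignore"):
        total = m1 + m2
        pbar = (m1 * p1 + m2 * p2) / total
        msp = m1 * (p1 - pbar) ** 2 + m2 * (p2 - pbar) ** 2  # r - 1 = 1
        msg = (m1 * p1 * (1 - p1) + m2 * p2 * (1 - p2)) / (total - 2.0)
        n_c = total - (m1 ** 2 + m2 ** 2) / total
        denom = msp + (n_c - 1.0) * msg
        fst = np.where(denom != 0, (msp - msg) / denom, np.nan)
    fst[(m1 < 2) | (m2 < 2)] = np.nan
    return fst


def fst_components_scan(geno: GenotypeMatrix, pops: PopulationMap,
                        pop1: str, pop2: str):
    """Per-SNP (MSP, MSG, n_c) vectors — building blocks of multi-locus Fst."""
    index = {s: k for k, s in enumerate(geno.sample_ids)}
    rows1 = np.array([index[s] for s in pops.samples_in(pop1)])
    rows2 = np.array([index[s] for s in pops.samples_in(pop2)])
    m1, p1 = _pop_allele_stats(geno, rows1)
    m2, p2 = _pop_allele_stats(geno, rows2)
    with np.errstate(invalid="ignore", divide="ignore"):
        total = m1 + m2
        pbar = (m1 * p1 + m2 * p2) / total
        msp = m1 * (p1 - pbar) ** 2 + m2 * (p2 - pbar) ** 2
        msg = (m1 * p1 * (1 - p1) + m2 * p2 * (1 - p2)) / (total - 2.0)
        n_c = total - (m1 ** 2 + m2 ** 2) / total
    ok = (m1 >= 2) & (m2 >= 2)
    return msp, msg, n_c, ok


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

@dataclass
class EhhCurve:
    """EHH values around one core SNP; offsets are signed bp from the core."""

    core_index: int
    positions: np.ndarray  # signed bp offsets, sorted ascending, 0 at the core
    values: np.ndarray
    n_a: int
    n_A: int


def _pairs(counts: np.ndarray) -> float:
    return float((counts * (counts - 1)).sum()) / 2.0


class _PartitionTracker:
    """Incrementally refine haplotype classes marker by marker.

    Haplotypes with a missing allele are dropped from the partition at the
    first missing site outward; the denominator stays fixed at the core.
    """

    __slots__ = ("labels", "active", "_depth")

    #: relabel after this many un-normalized extensions to avoid int64 overflow
    _RELABEL_EVERY = 54

    def __init__(self, core_alleles: np.ndarray, keep: np.ndarray):
        self.active = keep.copy()
        self.labels = np.where(keep, core_alleles, 0).astype(np.int64)
        self._depth = 0

    def extend(self, alleles: np.ndarray) -> None:
        miss = alleles == MISSING
        if miss.any():
            self.active &= ~miss
            alleles = np.where(miss, 0, alleles)
        # labels stay distinct under doubling; renormalize lazily
        self.labels = self.labels * 2 + alleles
        self._depth += 1
        if self._depth >= self._RELABEL_EVERY:
            _, self.labels = np.unique(self.labels, return_inverse=True)
            self._depth = 0

    def numerator(self) -> float:
        act = self.labels[self.active]
        if act.size < 2:
            return 0.0
        _, counts = np.unique(act, return_counts=True)
        return _pairs(counts)


def _core_denominator(core_alleles: np.ndarray, mode: str, core_allele: int | None):
    """(denominator, keep-mask, n_a, n_A) at the core for the chosen mode."""
    obs = core_alleles != MISSING
    n1 = int((core_alleles[obs] == 1).sum())
    n0 = int(obs.sum()) - n1
    if mode == "pooled":
        denom = n0 * (n0 - 1) / 2 + n1 * (n1 - 1) / 2
        keep = obs
    elif mode == "per_allele":
        if core_allele is None:
            core_allele = 1 if n1 >= n0 else 0
        n_sel = n1 if core_allele == 1 else n0
        denom = n_sel * (n_sel - 1) / 2
        keep = obs & (core_alleles == core_allele)
    else:
        raise ValueError(f"unknown ehh_mode {mode!r}")
    return float(denom), keep, n0, n1


def ehh_curve(haps: HaplotypeMatrix, variants: VariantTable, core: int,
              epsilon: float = 0.05, ehh_mode: str = "pooled",
              core_allele: int | None = None) -> EhhCurve | None:
    """EHH decay curve around ``core`` for one population's haplotypes.

    Extension stops in each direction once EHH drops below ``epsilon`` (the
    first sub-epsilon marker is included) or the chromosome end is reached.
    Returns None when the denominator is zero (no core-allele class holds two
    haplotypes).
    """
    if haps.n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    ent = haps.entries
    pos = variants.pos.astype(np.int64)
    chrom = variants.chrom
    core_col = ent[:, core]
    denom, keep, n0, n1 = _core_denominator(core_col, ehh_mode, core_allele)
    if denom == 0:
        return None

    offsets = [0]
    values = [1.0]
    for step in (-1, 1):
        tracker = _PartitionTracker(core_col, keep)
        j = core + step
        while 0 <= j < len(pos) and chrom[j] == chrom[core]:
            tracker.extend(ent[:, j])
            v = tracker.numerator() / denom
            offsets.append(int(pos[j] - pos[core]))
            values.append(v)
            if v < epsilon:
                break
            j += step

    order = np.argsort(offsets)
    return EhhCurve(core_index=core,
                    positions=np.asarray(offsets)[order],
                    values=np.asarray(values, float)[order],
                    n_a=n0, n_A=n1)


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------

@dataclass
class XpehhResult:
    iehh_obj: float
    iehh_ref: float
    ratio: float
    ln_ratio: float
    domain: tuple[int, int]


def xpehh_at(core: int, haps_obj: HaplotypeMatrix, haps_ref: HaplotypeMatrix,
             variants: VariantTable, epsilon: float = 0.05,
             ehh_mode: str = "pooled") -> XpehhResult | None:
    """XP-EHH at one core SNP: ratio of integrated EHH, object over reference.

    The integration domain D extends outward per direction until
    ``max(EHH_obj, EHH_ref) < epsilon`` (that marker is kept as the endpoint)
    or the chromosome runs out; both curves are integrated by the trapezoid
    rule over the same D, in bp. Returns None when either population's EHH is
    undefined at the core.
    """
    ent_o, ent_r = haps_obj.entries, haps_ref.entries
    pos = variants.pos.astype(np.int64)
    chrom = variants.chrom
    core_o, core_r = ent_o[:, core], ent_r[:, core]
    denom_o, keep_o, _, _ = _core_denominator(core_o, ehh_mode, None)
    denom_r, keep_r, _, _ = _core_denominator(core_r, ehh_mode, None)
    if denom_o == 0 or denom_r == 0:
        return None

    iehh_o = 0.0
    iehh_r = 0.0
    left = right = int(pos[core])
    for step in (-1, 1):
        trk_o = _PartitionTracker(core_o, keep_o)
        trk_r = _PartitionTracker(core_r, keep_r)
        prev_pos = pos[core]
        prev_o, prev_r = 1.0, 1.0
        j = core + step
        while 0 <= j < len(pos) and chrom[j] == chrom[core]:
            trk_o.extend(ent_o[:, j])
            trk_r.extend(ent_r[:, j])
            v_o = trk_o.numerator() / denom_o
            v_r = trk_r.numerator() / denom_r
            width = abs(int(pos[j]) - int(prev_pos))
            iehh_o += 0.5 * (prev_o + v_o) * width
            iehh_r += 0.5 * (prev_r + v_r) * width
            prev_pos, prev_o, prev_r = pos[j], v_o, v_r
            if step < 0:
                left = int(pos[j])
            else:
                right = int(pos[j])
            if max(v_o, v_r) < epsilon:
                break
            j += step

    if iehh_r == 0.0:
        return XpehhResult(iehh_o, iehh_r, float("nan"), float("nan"), (left, right))
    ratio = iehh_o / iehh_r
    return XpehhResult(float(iehh_o), float(iehh_r), float(ratio),
                       float(np.log(ratio)), (left, right))


def xpehh_scan(haps_obj: HaplotypeMatrix, haps_ref: HaplotypeMatrix,
               variants: VariantTable, epsilon: float = 0.05,
               ehh_mode: str = "pooled"):
    """Per-variant XP-EHH ratio and ln-ratio vectors (NaN where undefined)."""
    n = variants.n_variants
    ratio = np.full(n, np.nan)
    ln_ratio = np.full(n, np.nan)
    for core in range(n):
        res = xpehh_at(core, haps_obj, haps_ref, variants, epsilon, ehh_mode)
        if res is not None:
            ratio[core] = res.ratio
            ln_ratio[core] = res.ln_ratio
    return ratio, ln_ratio


def standardize_ln_ratio(ln_ratio: np.ndarray) -> np.ndarray:
    """Genome-wide z-standardized ln XP-EHH (extra diagnostic column)."""
    ok = ~np.isnan(ln_ratio)
    mu = ln_ratio[ok].mean()
    sd = ln_ratio[ok].std(ddof=1)
    out = np.full_like(ln_ratio, np.nan)
    if sd > 0:
        out[ok] = (ln_ratio[ok] - mu) / sd
    return out
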