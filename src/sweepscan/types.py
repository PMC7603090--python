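"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Coordinates are 1-based inclusive base pairs everywhere inside the package;
  BED input is converted on read.
* Genotype/haplotype matrices are small integer arrays; missing calls use the
  sentinel :data:`MISSING` (−1), never 0.
* Variants are ordered by (chromosome in input order, position); haplotype rows
  2k and 2k+1 belong to sample k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing allele/dosage in haplotype and genotype matrices.
MISSING: int = -1


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class VariantTable:
    """Ordered catalogue of biallelic SNPs.

    ``df`` columns: ``variant_id, chrom, pos, ref, alt`` with ``pos`` a 1-based
    integer. Positions are strictly increasing within each chromosome and
    variant ids are unique.
    """

    df: pd.DataFrame

    REQUIRED = ("variant_id", "chrom", "pos", "ref", "alt")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"VariantTable missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        ids = self.df["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise FormatError(f"duplicate variant id {dup!r}")
        for _, sub in self.df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise FormatError("positions not strictly increasing within chromosome")

    @property
    def n_variants(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(self.df.loc[np.asarray(mask, bool)].reset_index(drop=True))

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantTable):
            return NotImplemented
        return self.df.equals(other.df)


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 haplotypes: shape ``(2 * n_samples, n_variants)``.

    ``entries`` is an int8 array over {0, 1, MISSING}. ``phased`` records
    whether every genotype in the source was phased; unphased input is allowed
    only when the reader was told to tolerate it.
    """

    entries: np.ndarray
    sample_ids: list[str]
    phased: bool = True

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.int8)
        if self.entries.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.entries.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("row count must equal 2 * n_samples")
        bad = ~np.isin(self.entries, (0, 1, MISSING))
        if bad.any():
            raise ValueError("haplotype entries must be 0, 1 or MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_variants(self) -> int:
        return self.entries.shape[1]

    def to_genotypes(self) -> "GenotypeMatrix":
        """Collapse to alt-allele dosages; missing if either haplotype is missing."""
        a = self.entries[0::2].astype(np.int16)
        b = self.entries[1::2].astype(np.int16)
        dose = a + b
        dose[(a == MISSING) | (b == MISSING)] = MISSING
        return GenotypeMatrix(dose.astype(np.int8), list(self.sample_ids))

    def subset_variants(self, mask: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.entries[:, np.asarray(mask, bool)],
                               list(self.sample_ids), self.phased)

    def subset_samples(self, sample_ids: Sequence[str]) -> "HaplotypeMatrix":
        index = {s: k for k, s in enumerate(self.sample_ids)}
        rows: list[int] = []
        for s in sample_ids:
            k = index[s]
            rows.extend((2 * k, 2 * k + 1))
        return HaplotypeMatrix(self.entries[rows], list(sample_ids), self.phased)


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage 0/1/2 (or MISSING) per sample × variant."""

    entries: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.int8)
        if self.entries.shape[0] != len(self.sample_ids):
            raise ValueError("row count must equal n_samples")
        bad = ~np.isin(self.entries, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return self.entries.shape[1]

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.entries[:, np.asarray(mask, bool)], list(self.sample_ids))

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: k for k, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(self.entries[rows], list(sample_ids))


@dataclass
class PopulationMap:
    """Sample → population assignment plus the object/reference roles of a scan."""

    assignments: dict[str, str]
    object_pop: str | None = None
    reference_pop: str | None = None

    def __post_init__(self) -> None:
        if (self.object_pop is not None and self.reference_pop is not None
                and self.object_pop == self.reference_pop):
            raise ValueError("object and reference population must differ")

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.assignments.values():
            if p not in seen:
                seen.append(p)
        return seen

    def samples_in(self, pop: str) -> list[str]:
        if pop not in self.populations:
            raise KeyError(f"unknown population label {pop!r}")
        return [s for s, p in self.assignments.items() if p == pop]

    def with_roles(self, object_pop: str, reference_pop: str) -> "PopulationMap":
        for p in (object_pop, reference_pop):
            if p not in self.populations:
                raise KeyError(f"unknown population label {p!r}")
        return PopulationMap(dict(self.assignments), object_pop, reference_pop)


@dataclass(frozen=True)
class GeneModel:
    """A gene interval; 1-based inclusive coordinates, ``start <= end``."""

    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(f"gene {self.gene_id}: end < start after normalization")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ScanResult:
    """Per-variant selection statistics for one population pair.

    ``fst``, ``xpehh`` (plain integral ratio), and ``ln_xpehh`` are float
    vectors aligned to ``variants`` (NaN = undefined). Candidate flags mark
    membership in the empirical top tail of each statistic.
    """

    variants: VariantTable
    breed_pair: str
    fst: np.ndarray
    xpehh: np.ndarray
    ln_xpehh: np.ndarray
    thresholds: dict[str, float] = field(default_factory=dict)
    candidate_fst: np.ndarray | None = None
    candidate_xpehh: np.ndarray | None = None
    genes: list[str] | None = None  # per-variant nearest-gene labels ('.' if none)

    def __post_init__(self) -> None:
        n = self.variants.n_variants
        for name in ("fst", "xpehh", "ln_xpehh"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, v)


@dataclass
class GeneSetReport:
    """Candidate gene sets per (pair, method), their per-pair merges and the
    cross-pair overlap."""

    sets: dict[tuple[str, str], set[str]]
    merged: dict[str, set[str]]
    overlap: set[str]
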