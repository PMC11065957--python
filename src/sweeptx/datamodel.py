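"""Shared coordinate-aware containers used by every pipeline stage.

All genomic coordinates are 1-based closed intervals, matching VCF and GFF3.
Conversion to 0-based half-open happens only when writing BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # allele code for a missing haplotype slot

#: the three scan statistics used as evidence labels throughout
TESTS = ("HP", "FST", "XPEHH")


class FormatError(ValueError):
    """Malformed input file."""


class ConfigError(ValueError):
    """Inconsistent configuration (sample maps, thresholds, intervals)."""


@dataclass
class GenotypeMatrix:
    """Phased diploid genotypes for two populations.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, one per diploid individual.
    pops : ndarray of str
        Population label per sample, ``"A"`` or ``"B"``.
    chrom, pos, ref, alt, qual : ndarray
        Per-variant fields; ``pos`` is 1-based and strictly increasing
        within each chromosome. ``alt`` joins multiple ALT alleles with
        commas; ``n_alt`` records how many there are.
    alleles : int8 ndarray, shape (n_variants, n_samples, 2)
        Allele code per haplotype slot: 0 (ref), 1.. (alt index + 1),
        or -1 for missing.
    phased : bool ndarray, shape (n_variants, n_samples)
        Whether the genotype was phased in the source.
    """

    samples: list[str]
    pops: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    alleles: np.ndarray
    phased: np.ndarray
    n_alt: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.qual = np.asarray(self.qual, dtype=float)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_variants, n_samples, 2)")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise FormatError(f"positions not strictly increasing on {c}")

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, population: str) -> np.ndarray:
        """Indices of the samples in ``population`` ('A', 'B' or 'pooled')."""
        if population == "pooled":
            return np.arange(self.n_samples)
        idx = np.flatnonzero(np.asarray(self.pops) == population)
        if idx.size == 0:
            raise ConfigError(f"no samples in population {population!r}")
        return idx

    def take(self, mask_or_index) -> "GenotypeMatrix":
        """Subset variants, preserving order."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=self.samples,
            pops=self.pops,
            chrom=np.asarray(self.chrom)[idx],
            pos=self.pos[idx],
            ref=np.asarray(self.ref)[idx],
            alt=np.asarray(self.alt)[idx],
            qual=self.qual[idx],
            alleles=self.alleles[idx],
            phased=self.phased[idx],
            n_alt=np.asarray(self.n_alt)[idx],
        )

    def haplotypes(self, population: str) -> np.ndarray:
        """Haplotype matrix for a population, shape (2 * n_pop, n_variants)."""
        idx = self.sample_indices(population)
        h = self.alleles[:, idx, :]  # (v, n, 2)
        return h.reshape(h.shape[0], -1).T.copy()

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage per sample (0/1/2), NaN where any slot missing."""
        a = self.alleles.astype(float)
        a[a == MISSING] = np.nan
        return a.sum(axis=2)


@dataclass
class GeneModel:
    """A gene with optional exon structure (1-based closed intervals)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exon_spans: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"gene {self.gene_id}: start > end")

    @property
    def length_bp(self) -> int:
        """Merged exon length; falls back to the gene span without exons."""
        if not self.exon_spans:
            return self.end - self.start + 1
        spans = sorted((int(s), int(e)) for s, e in self.exon_spans)
        total = 0
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
        return total


@dataclass
class CountTable:
    """Gene-level read counts for the two pooled RNA libraries."""

    gene_ids: list[str]
    library_ids: list[str]
    counts: np.ndarray  # (n_genes, n_libraries) non-negative ints
    lib_size: np.ndarray  # total mapped reads per library
    gene_length_bp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        if self.lib_size is None:
            self.lib_size = self.counts.sum(axis=0)
        self.lib_size = np.asarray(self.lib_size, dtype=np.int64)
        if np.any(self.lib_size < self.counts.sum(axis=0)):
            raise FormatError("lib_size smaller than column sum of counts")
        if self.gene_length_bp is not None:
            self.gene_length_bp = np.asarray(self.gene_length_bp, dtype=np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


class GeneSetCollection(dict):
    """Mapping set_id -> (description, member gene ids)."""

    def members(self, set_id: str) -> list[str]:
        return self[set_id][1]


@dataclass
class SweepRegion:
    """A merged run of outlier windows supporting one or more tests."""

    chrom: str
    start: int
    end: int
    evidence: frozenset
    windows: list = field(default_factory=list)

    def extended(self, flank: int) -> tuple[int, int]:
        return max(1, self.start - flank), self.end + flank


@dataclass
class CandidateGeneSet:
    """Genes near outlier regions, with their supporting tests.

    ``table`` has one row per gene touched by any test's regions with
    boolean columns HP/FST/XPEHH, ``n_tests`` and ``candidate``;
    ``venn`` counts genes per evidence combination (gene level).
    """

    table: pd.DataFrame
    venn: dict
    min_tests: int

    @property
    def candidates(self) -> list[str]:
        return self.table.index[self.table["candidate"]].tolist()
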