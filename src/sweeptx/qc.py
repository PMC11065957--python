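"""Variant retention filters and per-population allele counting.

The retained set is: biallelic variants with calling rate strictly above
90% and QUAL strictly above 30 (both thresholds configurable). Call rate
is defined over samples — a sample is called at a site iff both haplotype
slots are non-missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import MISSING, ConfigError, GenotypeMatrix


@dataclass
class AlleleCounts:
    """Per-variant allele tallies within one population (or pooled)."""

    n_ref: np.ndarray
    n_alt: np.ndarray
    n_called_samples: np.ndarray
    call_rate: np.ndarray

    @property
    def n_major(self) -> np.ndarray:
        """Count of the more frequent allele; ties resolve to ref."""
        return np.where(self.n_alt > self.n_ref, self.n_alt, self.n_ref)

    @property
    def n_minor(self) -> np.ndarray:
        return np.where(self.n_alt > self.n_ref, self.n_ref, self.n_alt)

    @property
    def alt_freq(self) -> np.ndarray:
        tot = self.n_ref + self.n_alt
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.n_alt / tot, np.nan)


def call_rate(gm: GenotypeMatrix, scope: str = "all") -> np.ndarray:
    """Fraction of samples fully called per variant.

    ``scope="all"`` pools every sample; ``scope="per_pop"`` returns the
    minimum of the two per-population rates (a site must be well called
    in both cohorts).
    """
    called = np.all(gm.alleles != MISSING, axis=2)  # (v, s)
    if scope == "all":
        return called.mean(axis=1)
    if scope == "per_pop":
        rates = [called[:, gm.sample_indices(p)].mean(axis=1) for p in ("A", "B")]
        return np.minimum(*rates)
    raise ConfigError(f"unknown call-rate scope {scope!r}")


def snp_mask(gm: GenotypeMatrix) -> np.ndarray:
    """True for single-nucleotide substitutions (every allele length 1)."""
    ok = np.empty(gm.n_variants, dtype=bool)
    for i in range(gm.n_variants):
        alts = str(gm.alt[i]).split(",")
        ok[i] = len(str(gm.ref[i])) == 1 and all(len(a) == 1 for a in alts)
    return ok


def filter_variants(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_qual: float = 30.0,
    biallelic_only: bool = True,
    call_rate_scope: str = "all",
) -> GenotypeMatrix:
    """Apply the retention filters; both thresholds are strict (> not >=)."""
    keep = np.ones(gm.n_variants, dtype=bool)
    keep &= call_rate(gm, call_rate_scope) > min_call_rate
    with np.errstate(invalid="ignore"):
        keep &= np.nan_to_num(gm.qual, nan=-np.inf) > min_qual
    if biallelic_only:
        keep &= np.asarray(gm.n_alt) == 1
    return gm.take(keep)


def allele_counts(gm: GenotypeMatrix, population: str = "pooled") -> AlleleCounts:
    """Tally ref/alt haplotypes over the selected samples.

    Counts run over non-missing haplotype slots; any non-ref code counts
    as alt (multi-allelic sites should already have been filtered).
    """
    idx = gm.sample_indices(population)
    a = gm.alleles[:, idx, :]
    called_slot = a != MISSING
    n_alt = ((a > 0) & called_slot).sum(axis=(1, 2))
    n_ref = ((a == 0) & called_slot).sum(axis=(1, 2))
    called_sample = np.all(called_slot, axis=2)
    n_called = called_sample.sum(axis=1)
    return AlleleCounts(
        n_ref=n_ref.astype(np.int64),
        n_alt=n_alt.astype(np.int64),
        n_called_samples=n_called.astype(np.int64),
        call_rate=n_called / len(idx),
    )
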