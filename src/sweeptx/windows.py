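"""Sliding-window engine and the frequency-based scan statistics.

The scan works in 100-kb windows sliding by half a window. Two statistics
are computed per window: pooled heterozygosity

    H_P = 2 * sum(n_MAJ) * sum(n_MIN) / (sum(n_MAJ) + sum(n_MIN))**2

with the major/minor allele counts summed over the window's SNPs, and the
window mean of per-SNP Weir–Cockerham F_ST between the two populations.
Both are standardised genome-wide to Z-scores for empirical outlier calling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import ConfigError, GenotypeMatrix
from .qc import AlleleCounts, allele_counts

DEFAULT_WINDOW = 100_000
DEFAULT_STEP = 50_000
DEFAULT_MIN_SNPS = 10


def make_windows(chrom_lengths: dict, size: int = DEFAULT_WINDOW,
                 step: int = DEFAULT_STEP) -> pd.DataFrame:
    """Enumerate half-step sliding windows (1-based closed intervals).

    Starts run 1, 1+step, 1+2*step, ... while start <= chromosome length;
    the final windows are truncated at the chromosome end, and truncated
    windows shorter than ``step`` are dropped — unless that would leave a
    chromosome with no window at all.
    """
    if step > size:
        raise ConfigError("step must not exceed window size")
    rows = []
    for chrom, length in chrom_lengths.items():
        chrom_rows = []
        start = 1
        while start <= length:
            end = min(start + size - 1, length)
            if end - start + 1 >= step:
                chrom_rows.append((chrom, start, end))
            start += step
        if not chrom_rows:  # chromosome shorter than one step
            chrom_rows.append((chrom, 1, length))
        rows.extend(chrom_rows)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_variant_indices(chrom: np.ndarray, pos: np.ndarray,
                           windows: pd.DataFrame) -> list[np.ndarray]:
    """Variant index array per window (closed-interval membership)."""
    chrom = np.asarray(chrom)
    out = []
    by_chrom = {}
    for c in pd.unique(windows["chrom"]):
        idx = np.flatnonzero(chrom == c)
        by_chrom[c] = (idx, pos[idx])
    for c, s, e in windows[["chrom", "start", "end"]].itertuples(index=False):
        idx, p = by_chrom.get(c, (np.array([], dtype=int), np.array([], dtype=np.int64)))
        lo = np.searchsorted(p, s, side="left")
        hi = np.searchsorted(p, e, side="right")
        out.append(idx[lo:hi])
    return out


def pooled_heterozygosity(counts: AlleleCounts,
                          index: np.ndarray | None = None) -> float:
    """H_P from summed major/minor allele counts over a window's SNPs."""
    n_maj, n_min = counts.n_major, counts.n_minor
    if index is not None:
        n_maj, n_min = n_maj[index], n_min[index]
    s_maj = float(np.sum(n_maj))
    s_min = float(np.sum(n_min))
    tot = s_maj + s_min
    if tot == 0:
        return np.nan
    return 2.0 * s_maj * s_min / tot**2


def fst_per_snp(gm: GenotypeMatrix) -> np.ndarray:
    """Weir–Cockerham theta-hat per variant between populations A and B.

    Uses fully-called diploid samples only; negative estimates are kept.
    Sites monomorphic in both populations (zero total variance components)
    and sites with fewer than 2 called haplotypes in either population
    return NaN.
    """
    comps = _wc_components(gm)
    if comps is None:
        return np.full(gm.n_variants, np.nan)
    a, b, c = comps
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    return theta


def _wc_components(gm: GenotypeMatrix):
    """Per-variant Weir–Cockerham variance components (a, b, c), r=2."""
    if gm.n_variants == 0:
        return None
    n = np.empty((gm.n_variants, 2))
    p = np.empty((gm.n_variants, 2))
    h = np.empty((gm.n_variants, 2))
    from .datamodel import MISSING

    for k, popname in enumerate(("A", "B")):
        idx = gm.sample_indices(popname)
        al = gm.alleles[:, idx, :]
        called = np.all(al != MISSING, axis=2)  # fully-called diploids
        nk = called.sum(axis=1)
        alt = ((al > 0) & called[:, :, None]).sum(axis=(1, 2))
        het = (((al[:, :, 0] > 0) != (al[:, :, 1] > 0)) & called).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, k] = np.where(nk > 0, alt / (2 * nk), np.nan)
            h[:, k] = np.where(nk > 0, het / nk, np.nan)
        n[:, k] = nk

    valid = (n[:, 0] >= 1) & (n[:, 1] >= 1) & (n.sum(axis=1) > 2)
    n_bar = n.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = 2 * n_bar - (n**2).sum(axis=1) / (2 * n_bar)
        p_bar = (n * p).sum(axis=1) / (2 * n_bar)
        s2 = (n * (p - p_bar[:, None]) ** 2).sum(axis=1) / n_bar
        h_bar = (n * h).sum(axis=1) / (2 * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 / 2 - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 / 2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
    bad = ~valid
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def window_mean(pos_or_indices, values: np.ndarray, windows: pd.DataFrame = None,
                chrom: np.ndarray = None,
                min_snps: int = DEFAULT_MIN_SNPS) -> np.ndarray:
    """Arithmetic mean of non-NA per-variant values within each window.

    Accepts either precomputed per-window index lists (from
    :func:`window_variant_indices`) or raw ``chrom``/``pos`` arrays plus a
    window frame. Windows with fewer than ``min_snps`` contributing
    (non-NA) variants return NaN.
    """
    if windows is not None:
        indices = window_variant_indices(chrom, np.asarray(pos_or_indices), windows)
    else:
        indices = pos_or_indices
    values = np.asarray(values, dtype=float)
    out = np.full(len(indices), np.nan)
    for i, idx in enumerate(indices):
        v = values[idx]
        v = v[~np.isnan(v)]
        if v.size >= min_snps:
            out[i] = v.mean()
    return out


def z_transform(values: np.ndarray) -> np.ndarray:
    """Standardise genome-wide to mean 0, sd 1 (population sd, NaN-aware)."""
    values = np.asarray(values, dtype=float)
    finite = values[~np.isnan(values)]
    if finite.size < 2 or np.std(finite) == 0:
        warnings.warn("z_transform: fewer than 2 distinct values; returning NAs")
        return np.full_like(values, np.nan)
    return (values - finite.mean()) / finite.std()


def build_window_table(gm: GenotypeMatrix, windows: pd.DataFrame,
                       xpehh: np.ndarray | None = None,
                       min_snps: int = DEFAULT_MIN_SNPS) -> pd.DataFrame:
    """Assemble the per-window statistics table from filtered genotypes.

    Columns: ``n_snps``, per-population H_P, windowed F_ST mean, windowed
    XP-EHH mean (if per-variant values are supplied), and Z-scores for
    H_P in population A and for F_ST.
    """
    indices = window_variant_indices(gm.chrom, gm.pos, windows)
    counts = {p: allele_counts(gm, p) for p in ("A", "B")}
    n_snps = np.array([idx.size for idx in indices])

    def hp_for(pop):
        ac = counts[pop]
        return np.array([
            pooled_heterozygosity(ac, idx) if idx.size >= min_snps else np.nan
            for idx in indices])

    hp_a, hp_b = hp_for("A"), hp_for("B")
    fst = fst_per_snp(gm)
    fst_mean = window_mean(indices, fst, min_snps=min_snps)
    xp_mean = (window_mean(indices, xpehh, min_snps=min_snps)
               if xpehh is not None else np.full(len(indices), np.nan))

    wt = windows.copy()
    wt["n_snps"] = n_snps
    wt["hp_A"] = hp_a
    wt["hp_B"] = hp_b
    wt["fst_mean"] = fst_mean
    wt["xpehh_mean"] = xp_mean
    wt["z_hp_A"] = z_transform(hp_a)
    wt["z_fst"] = z_transform(fst_mean)
    wt["flags"] = [frozenset() for _ in range(len(wt))]
    return wt
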