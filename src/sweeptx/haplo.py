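"""Extended haplotype homozygosity (EHH), its integral (iHH), and XP-EHH.

EHH at marker k steps from a core site is the probability that two
haplotypes drawn without replacement are identical over every variant
from the core out to k. iHH integrates the EHH decay curve over physical
distance (trapezoid rule) until it first drops below a cutoff; XP-EHH is
ln(iHH_A / iHH_B) at the same core, positive when haplotype homozygosity
extends further in population A.

Distance is physical (bp); no genetic map is used. All haplotypes of each
population enter the EHH at a core (no core-allele stratification), the
cross-population construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import MISSING, GenotypeMatrix

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_EXTENT = 1_000_000


@dataclass
class HaplotypeBlock:
    """Fully-called haplotypes over a contiguous set of variants."""

    alleles: np.ndarray  # (n_haplotypes, n_variants) 0/1 codes
    pos: np.ndarray  # bp, strictly increasing
    core_index: int

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.alleles.shape[0] < 2:
            raise ValueError("EHH needs at least 2 haplotypes")
        if np.any(self.alleles == MISSING):
            raise ValueError("haplotype block contains missing data")


def _pair_homozygosity(group_sizes: np.ndarray, n: int) -> float:
    return float((group_sizes * (group_sizes - 1)).sum()) / (n * (n - 1))


def ehh(block: HaplotypeBlock, core_index: int | None = None,
        direction: str = "right") -> tuple[np.ndarray, np.ndarray]:
    """EHH decay curve away from the core.

    Returns ``(distances, values)`` starting at (0, 1.0) and then one point
    per marker outward; the curve is non-increasing because each step
    refines the haplotype partition.
    """
    core = block.core_index if core_index is None else core_index
    h, pos = block.alleles, block.pos
    n = h.shape[0]
    step = 1 if direction == "right" else -1
    js = range(core + step, h.shape[1], step) if direction == "right" \
        else range(core + step, -1, step)
    dists, vals = [0.0], [1.0]
    codes = h[:, core].astype(np.int64)
    for j in js:
        _, codes = np.unique(codes * 2 + h[:, j], return_inverse=True)
        sizes = np.bincount(codes)
        dists.append(abs(int(pos[j]) - int(pos[core])))
        vals.append(_pair_homozygosity(sizes, n))
    return np.asarray(dists, dtype=float), np.asarray(vals, dtype=float)


def ihh(curve: tuple[np.ndarray, np.ndarray], cutoff: float = DEFAULT_CUTOFF,
        max_extent: float = DEFAULT_MAX_EXTENT, interpolate: bool = True,
        gap_scale: float | None = None, max_gap: float | None = None) -> float:
    """Integrate an EHH curve out to where it first drops below ``cutoff``.

    The default integrates trapezoids marker to marker and linearly
    interpolates the crossing point where EHH meets the cutoff. If the
    curve never falls below the cutoff within ``max_extent`` (or runs out
    of markers first) the core is unresolved and NaN is returned.

    ``interpolate=False`` stops the integral at the first marker at or
    below the cutoff without interpolating, and ``gap_scale``/``max_gap``
    rescale or reject large inter-marker gaps — together these reproduce
    the integration conventions of the common haplotype-scan tools for
    cross-checking.
    """
    dist, val = np.asarray(curve[0], dtype=float), np.asarray(curve[1], dtype=float)
    area = 0.0
    for i in range(1, len(dist)):
        gap = dist[i] - dist[i - 1]
        if max_gap is not None and gap > max_gap:
            return np.nan
        if gap_scale is not None and gap > gap_scale:
            gap = gap_scale
        if val[i] < cutoff:
            if interpolate:
                # linear crossing between (dist[i-1], val[i-1]) and (dist[i], val[i])
                frac = (val[i - 1] - cutoff) / (val[i - 1] - val[i])
                area += 0.5 * (val[i - 1] + cutoff) * gap * frac
            else:
                area += 0.5 * (val[i - 1] + val[i]) * gap
            return area
        area += 0.5 * (val[i - 1] + val[i]) * gap
        if val[i] == cutoff:  # reached exactly: resolved without extra mass
            return area
        if dist[i] >= max_extent:
            return np.nan
    return np.nan  # ran out of markers before decaying below the cutoff


def _ihh_two_sided(h: np.ndarray, pos: np.ndarray, core: int, cutoff: float,
                   max_extent: float, interpolate: bool,
                   gap_scale: float | None, max_gap: float | None) -> float:
    """Sum of left and right iHH at a core; NaN if either side unresolved."""
    n = h.shape[0]
    total = 0.0
    for step in (1, -1):
        codes = h[:, core].astype(np.int64)
        prev_d, prev_v = 0.0, 1.0
        area = np.nan
        j = core + step
        acc = 0.0
        while 0 <= j < h.shape[1]:
            _, codes = np.unique(codes * 2 + h[:, j], return_inverse=True)
            sizes = np.bincount(codes)
            v = _pair_homozygosity(sizes, n)
            d = abs(int(pos[j]) - int(pos[core]))
            gap = d - prev_d
            if max_gap is not None and gap > max_gap:
                break
            if gap_scale is not None and gap > gap_scale:
                gap = gap_scale
            if v < cutoff:
                if interpolate:
                    frac = (prev_v - cutoff) / (prev_v - v)
                    acc += 0.5 * (prev_v + cutoff) * gap * frac
                else:
                    acc += 0.5 * (prev_v + v) * gap
                area = acc
                break
            acc += 0.5 * (prev_v + v) * gap
            if v == cutoff:
                area = acc
                break
            if d >= max_extent:
                break
            prev_d, prev_v = d, v
            j += step
        if np.isnan(area):
            return np.nan
        total += area
    return total


def xpehh(block_a: HaplotypeBlock, block_b: HaplotypeBlock,
          cutoff: float = DEFAULT_CUTOFF, max_extent: float = DEFAULT_MAX_EXTENT,
          interpolate: bool = True, gap_scale: float | None = None,
          max_gap: float | None = None) -> float:
    """ln(iHH_A / iHH_B) at a shared core; NaN if either side is unresolved."""
    if not np.array_equal(block_a.pos, block_b.pos):
        raise ValueError("blocks must share the same variant positions")
    if block_a.core_index != block_b.core_index:
        raise ValueError("blocks must share the same core")
    args = (cutoff, max_extent, interpolate, gap_scale, max_gap)
    ihh_a = _ihh_two_sided(block_a.alleles, block_a.pos, block_a.core_index, *args)
    ihh_b = _ihh_two_sided(block_b.alleles, block_b.pos, block_b.core_index, *args)
    if np.isnan(ihh_a) or np.isnan(ihh_b) or ihh_a <= 0 or ihh_b <= 0:
        return np.nan
    return float(np.log(ihh_a / ihh_b))


def xpehh_scan(gm: GenotypeMatrix, cutoff: float = DEFAULT_CUTOFF,
               max_extent: float = DEFAULT_MAX_EXTENT, interpolate: bool = True,
               gap_scale: float | None = None,
               max_gap: float | None = None) -> np.ndarray:
    """Per-variant XP-EHH (population A vs reference B) across the genome.

    Sites with missing data in either population are dropped before the
    EHH computation (they receive NaN); unphased heterozygous genotypes
    are rejected — the scan requires phased input or simulated haplotypes.
    """
    out = np.full(gm.n_variants, np.nan)
    het = gm.alleles[:, :, 0] != gm.alleles[:, :, 1]
    if np.any(het & ~gm.phased):
        raise ValueError("unphased heterozygous genotypes: phase the input "
                         "before running haplotype statistics")
    hap_a_all = gm.haplotypes("A")
    hap_b_all = gm.haplotypes("B")
    complete = np.all(hap_a_all != MISSING, axis=0) & np.all(hap_b_all != MISSING, axis=0)
    chrom = np.asarray(gm.chrom)
    for c in pd_unique(chrom):
        on_c = np.flatnonzero((chrom == c) & complete)
        if on_c.size < 2:
            continue
        pos = gm.pos[on_c]
        ha = np.ascontiguousarray(hap_a_all[:, on_c])
        hb = np.ascontiguousarray(hap_b_all[:, on_c])
        for k in range(on_c.size):
            a = _ihh_two_sided(ha, pos, k, cutoff, max_extent, interpolate,
                               gap_scale, max_gap)
            if np.isnan(a) or a <= 0:
                continue
            b = _ihh_two_sided(hb, pos, k, cutoff, max_extent, interpolate,
                               gap_scale, max_gap)
            if np.isnan(b) or b <= 0:
                continue
            out[on_c[k]] = np.log(a / b)
    return out


def pd_unique(arr):
    """Order-preserving unique (chromosomes keep input order)."""
    seen, out = set(), []
    for x in arr:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out
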