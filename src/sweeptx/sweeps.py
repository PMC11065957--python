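"""Empirical outlier calling, region merging, and candidate-gene assignment.

Windows are flagged per statistic against empirical top-5% cutoffs
(lower tail of Z(H_P) in the focal population, upper tails of Z(F_ST) and
windowed XP-EHH), flagged windows are merged into regions, and genes
within +/-50 kb of a region are assigned to that test. A gene supported by
at least ``min_tests`` statistics (default 2) is a candidate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .datamodel import TESTS, CandidateGeneSet, ConfigError, GeneModel, SweepRegion

DEFAULT_Q = 0.05
DEFAULT_FLANK = 50_000
DEFAULT_MIN_TESTS = 2

#: statistic -> (window-table column, tail)
FLAG_SPEC = {
    "HP": ("z_hp_A", "lower"),
    "FST": ("z_fst", "upper"),
    "XPEHH": ("xpehh_mean", "upper"),
}


def empirical_threshold(values, tail: str, q: float = DEFAULT_Q) -> float:
    """Cutoff such that exactly floor(q*N) distinct values lie strictly beyond.

    For the upper tail this is the (floor(q*N)+1)-th largest value; for the
    lower tail, the corresponding smallest. Flagging uses strict inequality,
    so ties at the cutoff are never flagged.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no non-NA values to threshold")
    if v.size < 1 / q:
        warnings.warn(f"only {v.size} values for a q={q} tail; cutoff unstable")
    k = int(np.floor(q * v.size))
    if tail not in ("lower", "upper"):
        raise ConfigError(f"unknown tail {tail!r}")
    if k >= v.size:
        # everything is beyond the cutoff
        return np.inf if tail == "lower" else -np.inf
    v_sorted = np.sort(v)
    return float(v_sorted[k]) if tail == "lower" else float(v_sorted[-(k + 1)])


def flag_windows(wt: pd.DataFrame, thresholds: dict) -> pd.DataFrame:
    """Set per-window evidence flags using strict inequality beyond cutoffs.

    ``thresholds`` maps statistic names (HP/FST/XPEHH) to numeric cutoffs;
    direction conventions are fixed: HP flags the lower tail of Z(H_P) in
    population A, FST and XPEHH flag upper tails.
    """
    wt = wt.copy()
    flags = [set() for _ in range(len(wt))]
    for stat, cut in thresholds.items():
        col, tail = FLAG_SPEC[stat]
        x = wt[col].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            hit = (x < cut) if tail == "lower" else (x > cut)
        hit &= ~np.isnan(x)
        for i in np.flatnonzero(hit):
            flags[i].add(stat)
    wt["flags"] = [frozenset(f) for f in flags]
    return wt


def merge_flagged(wt: pd.DataFrame, statistic: str) -> list[SweepRegion]:
    """Merge overlapping or book-ended flagged windows into regions."""
    sel = wt[[statistic in f for f in wt["flags"]]]
    sel = sel.sort_values(["chrom", "start"])
    regions: list[SweepRegion] = []
    for _, row in sel.iterrows():
        if (regions and regions[-1].chrom == row["chrom"]
                and row["start"] <= regions[-1].end + 1):
            regions[-1].end = max(regions[-1].end, int(row["end"]))
            regions[-1].windows.append((int(row["start"]), int(row["end"])))
        else:
            regions.append(SweepRegion(chrom=row["chrom"], start=int(row["start"]),
                                       end=int(row["end"]),
                                       evidence=frozenset([statistic]),
                                       windows=[(int(row["start"]), int(row["end"]))]))
    return regions


def assign_genes(regions_by_test: dict, genes: list[GeneModel],
                 flank: int = DEFAULT_FLANK,
                 min_tests: int = DEFAULT_MIN_TESTS) -> CandidateGeneSet:
    """Assign genes to tests via +/-flank extended regions; call candidates.

    A gene supports a test iff the closed interval
    [region.start - flank, region.end + flank] intersects [gene.start,
    gene.end] for at least one of that test's regions. Also reports the
    gene-level Venn counts over the three evidence sets.
    """
    region_chroms = {r.chrom for rs in regions_by_test.values() for r in rs}
    gene_chroms = {g.chrom for g in genes}
    if region_chroms and not (region_chroms & gene_chroms):
        raise ConfigError(
            "chromosome names differ between scan and annotation: "
            f"scan={sorted(region_chroms)} annotation={sorted(gene_chroms)}")

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # half-open tree coordinates: closed [start, end] -> [start, end+1)
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)

    support: dict[str, set] = {}
    for test, regions in regions_by_test.items():
        for r in regions:
            s, e = r.extended(flank)
            tree = trees.get(r.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(s, e + 1):
                support.setdefault(iv.data, set()).add(test)

    rows = {gid: {t: (t in ts) for t in TESTS} for gid, ts in support.items()}
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(TESTS))
    if table.empty:
        table = pd.DataFrame(columns=list(TESTS), dtype=bool)
    table = table.fillna(False).astype(bool).sort_index()
    table["n_tests"] = table[list(TESTS)].sum(axis=1)
    table["candidate"] = table["n_tests"] >= min_tests

    venn = {}
    for combo in _nonempty_subsets(TESTS):
        mask = np.ones(len(table), dtype=bool)
        for t in TESTS:
            want = t in combo
            mask &= table[t].to_numpy() == want
        venn[combo] = int(mask.sum())
    return CandidateGeneSet(table=table, venn=venn, min_tests=min_tests)


def _nonempty_subsets(items):
    from itertools import combinations

    for r in range(1, len(items) + 1):
        yield from combinations(items, r)


def call_sweeps(wt: pd.DataFrame, genes: list[GeneModel] | None = None,
                q: float = DEFAULT_Q, flank: int = DEFAULT_FLANK,
                min_tests: int = DEFAULT_MIN_TESTS,
                thresholds: dict | None = None):
    """End-to-end outlier calling on a window table.

    Computes empirical thresholds (unless explicit numeric cutoffs are
    given for replication), flags windows, merges regions per test, and —
    when annotation is supplied — assigns candidate genes.

    Returns ``(flagged window table, thresholds, regions_by_test,
    CandidateGeneSet or None)``.
    """
    if thresholds is None:
        thresholds = {}
        for stat, (col, tail) in FLAG_SPEC.items():
            vals = wt[col].to_numpy(dtype=float)
            if np.all(np.isnan(vals)):
                continue
            thresholds[stat] = empirical_threshold(vals, tail, q)
    flagged = flag_windows(wt, thresholds)
    regions = {stat: merge_flagged(flagged, stat) for stat in thresholds}
    cgs = assign_genes(regions, genes, flank, min_tests) if genes is not None else None
    return flagged, thresholds, regions, cgs
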