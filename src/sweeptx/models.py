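"""Model-style front ends over the pipeline stages.

``SelectionScan`` wraps QC -> windowed H_P / F_ST / XP-EHH -> empirical
outlier calling -> candidate genes; ``TwoLibraryDE`` wraps RPKM -> exact
test -> BH-FDR -> DEG calling. Both follow the fit()/results pattern: the
model holds data and configuration, ``fit()`` returns a results object
with the tables, thresholds and a ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import de as _de
from . import haplo, qc, sweeps, windows
from .datamodel import CountTable, GeneModel, GenotypeMatrix


class SelectionScanResults:
    """Fitted selective-sweep scan."""

    def __init__(self, window_table, thresholds, regions, candidates, params):
        self.windows = window_table
        self.thresholds = thresholds
        self.regions = regions
        self.candidates = candidates
        self.params = params

    @property
    def n_flagged(self) -> dict:
        return {t: sum(t in f for f in self.windows["flags"])
                for t in self.thresholds}

    def summary(self) -> str:
        lines = ["Selective-sweep scan", "=" * 40]
        analyzable = {
            "HP": int(self.windows["z_hp_A"].notna().sum()),
            "FST": int(self.windows["z_fst"].notna().sum()),
            "XPEHH": int(self.windows["xpehh_mean"].notna().sum()),
        }
        lines.append(f"windows: {len(self.windows)} "
                     f"(size {self.params['size']/1000:g} kb, "
                     f"step {self.params['step']/1000:g} kb, "
                     f"min {self.params['min_snps']} SNPs)")
        for t, cut in self.thresholds.items():
            tail = "<" if sweeps.FLAG_SPEC[t][1] == "lower" else ">"
            lines.append(f"{t:>6}: cutoff {tail} {cut:+.3f}  "
                         f"flagged {self.n_flagged[t]}/{analyzable[t]} windows, "
                         f"{len(self.regions.get(t, []))} regions")
        if self.candidates is not None:
            lines.append(f"candidate genes (>= {self.candidates.min_tests} tests): "
                         f"{len(self.candidates.candidates)}")
        return "\n".join(lines)

    def plot_manhattan(self, ax=None):
        """Per-window Z(H_P), Z(F_ST) and XP-EHH tracks along the genome."""
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(3, 1, sharex=True, figsize=(10, 6)) \
            if ax is None else (None, ax)
        mid = (self.windows["start"] + self.windows["end"]) / 2
        for a, col, label in zip(axes, ("z_hp_A", "z_fst", "xpehh_mean"),
                                 ("Z(H_P) pop A", "Z(F_ST)", "XP-EHH")):
            a.scatter(mid, self.windows[col], s=4)
            a.set_ylabel(label)
        axes[-1].set_xlabel("position (bp)")
        return fig


class SelectionScan:
    """Three-statistic selective-sweep scan between two populations.

    Parameters
    ----------
    gm : GenotypeMatrix
        Raw (unfiltered) genotypes with population labels.
    genes : list of GeneModel, optional
        Annotation for candidate-gene assignment.
    """

    def __init__(self, gm: GenotypeMatrix, genes: list[GeneModel] | None = None,
                 size: int = windows.DEFAULT_WINDOW, step: int = windows.DEFAULT_STEP,
                 min_snps: int = windows.DEFAULT_MIN_SNPS,
                 chrom_lengths: dict | None = None,
                 min_call_rate: float = 0.90, min_qual: float = 30.0,
                 snps_only: bool = True,
                 xpehh_cutoff: float = haplo.DEFAULT_CUTOFF,
                 xpehh_max_extent: int = haplo.DEFAULT_MAX_EXTENT):
        self.gm_raw = gm
        self.genes = genes
        self.params = dict(size=size, step=step, min_snps=min_snps,
                           min_call_rate=min_call_rate, min_qual=min_qual,
                           snps_only=snps_only, xpehh_cutoff=xpehh_cutoff,
                           xpehh_max_extent=xpehh_max_extent)
        self.chrom_lengths = chrom_lengths

    def fit(self, q: float = sweeps.DEFAULT_Q, flank: int = sweeps.DEFAULT_FLANK,
            min_tests: int = sweeps.DEFAULT_MIN_TESTS,
            thresholds: dict | None = None) -> SelectionScanResults:
        p = self.params
        gm = qc.filter_variants(self.gm_raw, p["min_call_rate"], p["min_qual"])
        if p["snps_only"]:
            gm = gm.take(qc.snp_mask(gm))
        lengths = self.chrom_lengths or {
            c: int(gm.pos[np.asarray(gm.chrom) == c].max())
            for c in haplo.pd_unique(np.asarray(gm.chrom))}
        win = windows.make_windows(lengths, p["size"], p["step"])
        xp = haplo.xpehh_scan(gm, cutoff=p["xpehh_cutoff"],
                              max_extent=p["xpehh_max_extent"])
        wt = windows.build_window_table(gm, win, xpehh=xp, min_snps=p["min_snps"])
        flagged, cuts, regions, cand = sweeps.call_sweeps(
            wt, self.genes, q=q, flank=flank, min_tests=min_tests,
            thresholds=thresholds)
        res = SelectionScanResults(flagged, cuts, regions, cand,
                                   {**p, "q": q, "flank": flank,
                                    "min_tests": min_tests})
        res.gm_filtered = gm
        res.xpehh_per_site = xp
        return res


class DEResults:
    """Fitted two-library differential-expression contrast."""

    def __init__(self, table: pd.DataFrame, params: dict):
        self.table = table
        self.params = params

    @property
    def degs(self) -> pd.DataFrame:
        return self.table[self.table["status"] != "ns"]

    @property
    def counts_by_status(self) -> dict:
        vc = self.table["status"].value_counts()
        return {k: int(vc.get(k, 0)) for k in ("up", "down", "ns")}

    def summary(self) -> str:
        c = self.counts_by_status
        return "\n".join([
            "Two-library differential expression (exact test)",
            "=" * 48,
            f"genes tested: {len(self.table)}",
            f"thresholds: FDR <= {self.params['max_fdr']}, "
            f"|log2 ratio| >= {self.params['min_abs_log2']}",
            f"DEGs: {c['up'] + c['down']} ({c['up']} up, {c['down']} down in A)",
        ])

    def plot_volcano(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        logp = -np.log10(np.clip(t["fdr"], 1e-300, None))
        colors = t["status"].map({"up": "tab:orange", "down": "tab:green",
                                  "ns": "0.7"})
        ax.scatter(t["log2_ratio"], logp, s=5, c=colors)
        ax.set_xlabel("log2 ratio (A / B)")
        ax.set_ylabel("-log10 FDR")
        return ax


class TwoLibraryDE:
    """Exact-test DE between two pooled RNA libraries (one per breed)."""

    def __init__(self, ct: CountTable, pseudocount: float = 1.0):
        self.ct = ct
        self.pseudocount = pseudocount

    def fit(self, max_fdr: float = _de.DEFAULT_MAX_FDR,
            min_abs_log2: float = _de.DEFAULT_MIN_ABS_LOG2) -> DEResults:
        tab = _de.de_table(self.ct, pseudocount=self.pseudocount)
        tab = _de.call_degs(tab, max_fdr=max_fdr, min_abs_log2=min_abs_log2)
        return DEResults(tab, dict(max_fdr=max_fdr, min_abs_log2=min_abs_log2,
                                   pseudocount=self.pseudocount))
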