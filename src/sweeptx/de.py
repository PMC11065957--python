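"""Two-library differential expression: RPKM, exact test, BH-FDR, DEG calls.

Expression is quantified as RPKM = 1e9 * count / (lib_size * length_bp).
With exactly one pooled library per breed there is no replicate dispersion
to estimate, so significance comes from the Audic–Claverie exact test: the
posterior-predictive probability of the second library's count given the
first,

    P(y | x) = (N_B/N_A)^y (x+y)! / (x! y! (1 + N_B/N_A)^(x+y+1)),

summed over the observed tail, two-sided as min(1, 2*min(lower, upper)).
This distribution is a negative binomial with r = x+1 and success
probability N_A/(N_A+N_B), which is how the tails are evaluated
numerically (exact, log-space stable). DEGs require FDR <= 0.001 and
|log2 ratio| >= 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import CountTable

DEFAULT_MAX_FDR = 0.001
DEFAULT_MIN_ABS_LOG2 = 1.0


def rpkm(ct: CountTable) -> np.ndarray:
    """Reads per kilobase of gene model per million mapped reads."""
    if ct.gene_length_bp is None:
        raise ValueError("gene lengths required for RPKM")
    if np.any(ct.gene_length_bp <= 0):
        raise ValueError("gene lengths must be positive")
    if np.any(ct.lib_size <= 0):
        raise ValueError("library sizes must be positive")
    return (1e9 * ct.counts
            / (ct.lib_size[None, :].astype(float)
               * ct.gene_length_bp[:, None].astype(float)))


def expressed_gene_sets(rpkm_matrix: np.ndarray, gene_ids: list[str],
                        min_expr: float = 0.0, n_annotated: int | None = None):
    """Per-library expressed-gene sets (rpkm strictly above ``min_expr``).

    Returns a dict with the two sets, their intersection, and each size as
    a fraction of the annotated gene count.
    """
    gene_ids = np.asarray(gene_ids)
    n_annotated = n_annotated or len(gene_ids)
    sets = [set(gene_ids[rpkm_matrix[:, j] > min_expr])
            for j in range(rpkm_matrix.shape[1])]
    inter = set.intersection(*sets) if sets else set()
    return {
        "sets": sets,
        "intersection": inter,
        "sizes": [len(s) for s in sets],
        "intersection_size": len(inter),
        "fractions": [len(s) / n_annotated for s in sets],
        "intersection_fraction": len(inter) / n_annotated,
    }


def de_test(count_a, count_b, lib_a: int, lib_b: int) -> np.ndarray:
    """Audic–Claverie two-library exact test (vectorised, two-sided).

    Given x = count_a, the distribution of count_b is NB(x+1, N_A/(N_A+N_B));
    p = min(1, 2*min(P(Y <= y), P(Y >= y))).
    """
    x = np.atleast_1d(np.asarray(count_a, dtype=np.int64))
    y = np.atleast_1d(np.asarray(count_b, dtype=np.int64))
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    prob = lib_a / (lib_a + lib_b)
    lower = stats.nbinom.cdf(y, x + 1, prob)  # P(Y <= y)
    upper = stats.nbinom.sf(y - 1, x + 1, prob)  # P(Y >= y)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return p if np.ndim(count_a) or np.ndim(count_b) else float(p[0])


def ac_probability(count_a: int, count_b: int, lib_a: int, lib_b: int) -> float:
    """Single Audic–Claverie term P(y | x) (the posterior-predictive pmf)."""
    return float(stats.nbinom.pmf(count_b, count_a + 1, lib_a / (lib_a + lib_b)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN p-values propagate."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p[~np.isnan(p)] < 0) | (p[~np.isnan(p)] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def log2_ratio(count_a, count_b, lib_a: int, lib_b: int,
               lengths=None, pseudocount: float = 1.0) -> np.ndarray:
    """log2 of normalised A over normalised B (RPKM scale when lengths given).

    When either raw count is zero the pseudocount is added to both
    normalised values so the ratio stays finite.
    """
    x = np.asarray(count_a, dtype=float)
    y = np.asarray(count_b, dtype=float)
    if lengths is not None:
        lengths = np.asarray(lengths, dtype=float)
        na = 1e9 * x / (lib_a * lengths)
        nb = 1e9 * y / (lib_b * lengths)
    else:
        na = 1e6 * x / lib_a
        nb = 1e6 * y / lib_b
    zero = (x == 0) | (y == 0)
    na = np.where(zero, na + pseudocount, na)
    nb = np.where(zero, nb + pseudocount, nb)
    with np.errstate(divide="ignore"):
        return np.log2(na / nb)


def de_table(ct: CountTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Full per-gene DE table: counts, RPKM, log2 ratio, p, FDR."""
    if len(ct.library_ids) != 2:
        raise ValueError("the DE contrast needs exactly two libraries")
    x, y = ct.counts[:, 0], ct.counts[:, 1]
    la, lb = int(ct.lib_size[0]), int(ct.lib_size[1])
    r = rpkm(ct) if ct.gene_length_bp is not None else None
    tab = pd.DataFrame(index=pd.Index(ct.gene_ids, name="gene_id"))
    tab["count_A"], tab["count_B"] = x, y
    if r is not None:
        tab["rpkm_A"], tab["rpkm_B"] = r[:, 0], r[:, 1]
    tab["log2_ratio"] = log2_ratio(
        x, y, la, lb, lengths=ct.gene_length_bp, pseudocount=pseudocount)
    tab["p_value"] = de_test(x, y, la, lb)
    tab["fdr"] = bh_fdr(tab["p_value"].to_numpy())
    return tab


def call_degs(results: pd.DataFrame, max_fdr: float = DEFAULT_MAX_FDR,
              min_abs_log2: float = DEFAULT_MIN_ABS_LOG2) -> pd.DataFrame:
    """Set per-gene status: up/down in population A, or ns."""
    results = results.copy()
    sig = results["fdr"] <= max_fdr
    up = sig & (results["log2_ratio"] >= min_abs_log2)
    down = sig & (results["log2_ratio"] <= -min_abs_log2)
    results["status"] = np.where(up, "up", np.where(down, "down", "ns"))
    return results
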