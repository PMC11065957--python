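"""Candidate-gene x DEG intersection and gene-set over-representation.

The enrichment is an upper-tail hypergeometric test per gene set against a
user-supplied universe, BH-corrected across sets — a database-free
over-representation analysis taking term membership from a GMT file.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CandidateGeneSet, GeneSetCollection
from .de import bh_fdr


def intersect_gene_sets(candidates: CandidateGeneSet,
                        degs: pd.DataFrame) -> pd.DataFrame:
    """Genes that are both sweep candidates and DEGs, with provenance.

    ``degs`` is a :func:`sweeptx.de.call_degs` table; only rows with status
    up/down count as DEGs. Returns a sorted table with the supporting sweep
    tests and the DE direction per overlapping gene.
    """
    cand = set(candidates.candidates)
    deg_tab = degs[degs["status"] != "ns"]
    deg_ids = set(deg_tab.index)
    if cand and deg_ids and not (cand & deg_ids):
        pref = lambda ids: {i[:3] for i in ids}
        if not (pref(cand) & pref(deg_ids)):
            warnings.warn("candidate and DEG gene-id namespaces look disjoint")
    shared = sorted(cand & deg_ids)
    rows = []
    for g in shared:
        tests = [t for t in ("HP", "FST", "XPEHH") if candidates.table.loc[g, t]]
        rows.append({"gene_id": g, "tests": ",".join(tests),
                     "de_status": deg_tab.loc[g, "status"]})
    return pd.DataFrame(rows, columns=["gene_id", "tests", "de_status"]
                        ).set_index("gene_id")


def hypergeom_enrichment(study, population, sets: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    ``study`` must be a subset of ``population``; each set is intersected
    with the population before testing. p = P(X >= k) for k study hits in
    a set of size K, study size n, universe size N; BH-FDR across sets.
    """
    study = set(study)
    population = set(population)
    stray = study - population
    if stray:
        raise ValueError(f"study genes outside the population: {sorted(stray)[:10]}")
    N, n = len(population), len(study)
    rows = []
    for sid, (desc, members) in sets.items():
        mem = set(members) & population
        K = len(mem)
        k = len(mem & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set_id": sid, "description": desc,
                     "k": k, "n": n, "K": K, "N": N, "p_value": p})
    tab = pd.DataFrame(rows).set_index("set_id")
    if len(tab):
        tab["fdr"] = bh_fdr(tab["p_value"].to_numpy())
    else:
        tab["fdr"] = np.nan
    return tab.sort_values("p_value")


def read_edge_list(path) -> pd.DataFrame:
    """Convenience: plain two-column interaction edge list -> degree table."""
    edges = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], comment="#")
    deg = pd.concat([edges["a"], edges["b"]]).value_counts().rename("degree")
    return deg.to_frame()
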