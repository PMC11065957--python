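"""Population structure: allele-sharing distances, NJ tree, genotype PCA.

The distance between two diploids is one minus the average fraction of
alleles shared per co-called site (identity-by-state); the tree is
neighbour joining on that matrix; the PCA normalises alt-allele dosages
per site by sqrt(p(1-p)) (the classic eigenanalysis scaling), with
missing dosages mean-imputed.
"""

from __future__ import annotations

import warnings

import numpy as np
import skbio
from skbio.tree import nj as _skbio_nj

from .datamodel import GenotypeMatrix


def pairwise_distance(gm: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Allele-sharing distance matrix over all sample pairs.

    d(i,j) = 1 - (1/2L) * sum over the L co-called sites of the number of
    shared alleles (0, 1 or 2; computed as 2 - |dosage_i - dosage_j|).
    Pairs with zero co-called sites get NaN with a warning.
    """
    dos = gm.dosage()  # (v, s), NaN where not fully called
    n = gm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(dos[:, i]) & ~np.isnan(dos[:, j])
            L = int(both.sum())
            if L == 0:
                warnings.warn(f"samples {gm.samples[i]} and {gm.samples[j]} share "
                              "no called sites; distance undefined")
                d[i, j] = d[j, i] = np.nan
                continue
            shared = 2.0 - np.abs(dos[both, i] - dos[both, j])
            d[i, j] = d[j, i] = 1.0 - shared.sum() / (2 * L)
    return d, list(gm.samples)


def neighbor_joining(dm: np.ndarray, ids: list[str]) -> "skbio.TreeNode":
    """Canonical neighbour joining; negative branch lengths clamp to zero."""
    if np.any(np.isnan(dm)):
        raise ValueError("distance matrix contains NaN")
    if len(ids) < 3:
        raise ValueError("neighbour joining needs at least 3 samples")
    sk_dm = skbio.DistanceMatrix(dm, ids)
    tree = _skbio_nj(sk_dm)
    clamped = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0")
    return tree


def to_newick(tree) -> str:
    from io import StringIO

    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def pca(gm: GenotypeMatrix, n_components: int = 10):
    """Genotype PCA with per-site sqrt(p(1-p)) scaling.

    Returns ``(coordinates, explained_variance)`` where coordinates has
    shape (n_samples, k). Monomorphic sites are skipped and missing
    dosages mean-imputed per site.
    """
    dos = gm.dosage()  # (v, s)
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    mu = np.nanmean(dos, axis=1)
    p = mu / 2.0
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not np.any(poly):
        raise ValueError("all sites monomorphic; PCA undefined")
    x = dos[poly]
    mu, p = mu[poly], p[poly]
    # mean-impute missing dosages, centre, scale
    x = np.where(np.isnan(x), mu[:, None], x)
    x = (x - mu[:, None]) / np.sqrt(p * (1 - p))[:, None]
    u, s, _ = np.linalg.svd(x.T, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    explained = (s[:k] ** 2) / max(gm.n_samples - 1, 1)
    return coords, explained
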