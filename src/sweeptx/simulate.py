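"""Synthetic two-population genotypes, annotation and RNA counts.

The genotype simulator is a Balding–Nichols frequency-perturbation model:
each site has an ancestral frequency, and the two population frequencies
are independent Beta(p(1-F)/F, (1-p)(1-F)/F) draws, so the expected
between-population differentiation is the target F. A sweep is planted in
population A over an interval by (a) shrinking the minor-allele frequency
toward 0 by ``strength`` and (b) resampling the interval's haplotypes
from a reduced founder pool of k = max(1, round((1-strength) * 2n))
haplotypes — jointly lowering H_P, raising F_ST, and extending haplotype
homozygosity at the swept locus. Outside sweeps, sites are in linkage
equilibrium.

QUAL values and missingness are planted so the QC filters have work to do;
a stated fraction of sites is multi-allelic or an INDEL.

The count simulator draws per-gene baseline expression (log-normal over an
"expressed" subset of genes), multiplies library A's mean by 2^(+/-lfc)
for the planted DE genes, and emits Poisson (or gamma-Poisson at a stated
dispersion) counts for the two libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np

from .datamodel import ConfigError, CountTable, GeneModel, GenotypeMatrix


@dataclass
class SweepSpec:
    chrom: str
    center: int
    width: int
    strength: float  # in [0, 1]; 0 = neutral, 1 = complete sweep

    @property
    def start(self) -> int:
        return self.center - self.width // 2

    @property
    def end(self) -> int:
        return self.center + self.width // 2


@dataclass
class SimParams:
    """Study conditions for the synthetic data.

    Defaults mirror a two-breed resequencing contrast at desk scale:
    12 + 10 diploid samples, one 10-Mb chromosome at ~1 SNP/kb,
    background F_ST 0.10, one strong sweep (strength 0.9, 300 kb) in the
    focal population, and two pooled RNA libraries with 5% of expressed
    genes differentially expressed at |log2 fc| = 2.
    """

    seed: int
    n_samples: dict = field(default_factory=lambda: {"A": 12, "B": 10})
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 10_000_000})
    snp_density_per_kb: float = 1.0
    background_fst: float = 0.10
    sweeps: list = field(default_factory=lambda: [
        SweepSpec("chr1", 5_000_000, 300_000, 0.9)])
    missing_rate: float = 0.01
    high_missing_frac: float = 0.03
    high_missing_rate: float = 0.20
    qual_pass_frac: float = 0.95
    multiallelic_frac: float = 0.01
    indel_frac: float = 0.02
    # count-simulation block
    de_fraction: float = 0.05
    lfc: float = 2.0
    lib_sizes: tuple = (12_000_000, 10_000_000)
    expressed_fraction: float = 0.55
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        self.sweeps = [s if isinstance(s, SweepSpec) else SweepSpec(*s)
                       for s in self.sweeps]
        for frac in (self.background_fst, self.missing_rate, self.de_fraction,
                     self.expressed_fraction, self.qual_pass_frac):
            if not 0 <= frac <= 1:
                raise ConfigError("fractions must lie in [0, 1]")
        for s in self.sweeps:
            if s.strength < 0 or s.strength > 1 or s.width <= 0:
                raise ConfigError("sweep strength in [0,1], width > 0")
            L = self.chrom_lengths.get(s.chrom)
            if L is None or s.start < 1 or s.end > L:
                raise ConfigError(f"sweep interval outside {s.chrom}")


@dataclass
class SyntheticTruth:
    """What was planted, for recovery testing."""

    swept_intervals: list  # (chrom, start, end, strength)
    swept_genes: list
    de_genes: dict  # gene_id -> "up" | "down"
    site_freqs: dict  # chrom -> {"pos": ..., "p_A": ..., "p_B": ...}

    def to_json(self, path) -> None:
        payload = {
            "swept_intervals": self.swept_intervals,
            "swept_genes": self.swept_genes,
            "de_genes": self.de_genes,
            "site_freqs": {c: {k: np.asarray(v).tolist() for k, v in d.items()}
                           for c, d in self.site_freqs.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _sweep_shift(p: np.ndarray, strength: float) -> np.ndarray:
    """Push the minor allele toward loss by ``strength``."""
    return np.where(p >= 0.5, 1 - (1 - p) * (1 - strength), p * (1 - strength))


def simulate_genotypes(params: SimParams) -> tuple[GenotypeMatrix, SyntheticTruth]:
    rng = np.random.default_rng(params.seed)
    nA, nB = params.n_samples["A"], params.n_samples["B"]
    n_samp = nA + nB
    samples = [f"A{i+1:02d}" for i in range(nA)] + [f"B{i+1:02d}" for i in range(nB)]
    pops = np.array(["A"] * nA + ["B"] * nB)

    chroms, positions, quals, n_alt = [], [], [], []
    refs, alts = [], []
    hap_rows = []
    site_freqs = {}
    F = params.background_fst
    mean_gap = 1000.0 / params.snp_density_per_kb

    for chrom, length in params.chrom_lengths.items():
        gaps = rng.exponential(mean_gap, size=int(2 * length / mean_gap) + 100)
        pos = 1 + np.cumsum(gaps).astype(np.int64)
        pos = np.unique(pos[pos <= length])
        m = pos.size

        p0 = np.clip(rng.beta(0.8, 0.8, size=m), 0.05, 0.95)
        if F > 0:
            a, b = p0 * (1 - F) / F, (1 - p0) * (1 - F) / F
            pA = rng.beta(a, b)
            pB = rng.beta(a, b)
        else:
            pA = p0.copy()
            pB = p0.copy()

        sweep_masks = []
        for s in params.sweeps:
            if s.chrom != chrom:
                continue
            in_sweep = (pos >= s.start) & (pos <= s.end)
            pA[in_sweep] = _sweep_shift(pA[in_sweep], s.strength)
            sweep_masks.append((in_sweep, s))

        hapA = (rng.random((2 * nA, m)) < pA[None, :]).astype(np.int8)
        hapB = (rng.random((2 * nB, m)) < pB[None, :]).astype(np.int8)
        for in_sweep, s in sweep_masks:
            k = max(1, round((1 - s.strength) * 2 * nA))
            founders = (rng.random((k, int(in_sweep.sum())))
                        < pA[None, in_sweep]).astype(np.int8)
            assign = rng.integers(0, k, size=2 * nA)
            hapA[:, in_sweep] = founders[assign]

        chroms.append(np.full(m, chrom, dtype=object))
        positions.append(pos)
        site_freqs[chrom] = {"pos": pos, "p_A": pA, "p_B": pB}

        qual = np.where(rng.random(m) < params.qual_pass_frac,
                        rng.uniform(30.5, 60.0, m),
                        rng.uniform(5.0, 30.0, m))
        quals.append(qual)

        is_multi = rng.random(m) < params.multiallelic_frac
        is_indel = (rng.random(m) < params.indel_frac) & ~is_multi
        refs.append(np.where(is_indel, "AC", "A").astype(object))
        alts.append(np.where(is_multi, "C,G", np.where(is_indel, "A", "C")).astype(object))
        n_alt.append(np.where(is_multi, 2, 1).astype(np.int16))

        hap_rows.append(np.vstack([hapA, hapB]))  # (2*n_samp, m)

    m_total = sum(p.size for p in positions)
    alleles = np.empty((m_total, n_samp, 2), dtype=np.int8)
    off = 0
    rng_missing = np.random.default_rng(params.seed + 1)
    for hap in hap_rows:
        m = hap.shape[1]
        block = hap.T.reshape(m, n_samp, 2)
        miss_rate = np.full(m, params.missing_rate)
        hi = rng_missing.random(m) < params.high_missing_frac
        miss_rate[hi] = params.high_missing_rate
        miss = rng_missing.random((m, n_samp)) < miss_rate[:, None]
        block = block.copy()
        block[miss] = -1
        alleles[off:off + m] = block
        off += m

    gm = GenotypeMatrix(
        samples=samples,
        pops=pops,
        chrom=np.concatenate(chroms),
        pos=np.concatenate(positions),
        ref=np.concatenate(refs),
        alt=np.concatenate(alts),
        qual=np.concatenate(quals),
        alleles=alleles,
        phased=np.ones((m_total, n_samp), dtype=bool),
        n_alt=np.concatenate(n_alt),
    )
    truth = SyntheticTruth(
        swept_intervals=[(s.chrom, s.start, s.end, s.strength) for s in params.sweeps],
        swept_genes=[],
        de_genes={},
        site_freqs=site_freqs,
    )
    return gm, truth


def make_annotation(params: SimParams, genes_per_mb: float = 20.0,
                    gene_span: int = 20_000, n_exons: int = 3,
                    truth: SyntheticTruth | None = None) -> list[GeneModel]:
    """Tile non-overlapping genes along each chromosome.

    Genes are evenly spaced; one gene is re-centred onto each planted
    sweep so recovery tests have a known target. Exons split the span with
    introns in between. Swept gene ids are appended to ``truth`` if given.
    """
    genes = []
    counter = 1
    for chrom, length in params.chrom_lengths.items():
        n_genes = int(genes_per_mb * length / 1e6)
        if n_genes == 0:
            continue
        spacing = length / n_genes
        starts = (np.arange(n_genes) * spacing + spacing / 2).astype(np.int64)
        starts = np.clip(starts, 1, length - gene_span)
        for s in params.sweeps:
            if s.chrom != chrom:
                continue
            nearest = int(np.argmin(np.abs(starts + gene_span // 2 - s.center)))
            starts[nearest] = max(1, s.center - gene_span // 2)
        for st in starts:
            gid = f"g{counter:05d}"
            counter += 1
            end = int(st) + gene_span - 1
            exon_len = gene_span // (2 * n_exons - 1)
            exons = [(int(st) + 2 * i * exon_len,
                      int(st) + 2 * i * exon_len + exon_len - 1)
                     for i in range(n_exons)]
            genes.append(GeneModel(gene_id=gid, chrom=chrom, start=int(st),
                                   end=end, strand="+", exon_spans=exons))
    if truth is not None:
        for g in genes:
            for (c, s, e, _strength) in truth.swept_intervals:
                if g.chrom == c and g.start <= e and g.end >= s:
                    truth.swept_genes.append(g.gene_id)
    return genes


def simulate_counts(params: SimParams, genes: list[GeneModel],
                    truth: SyntheticTruth | None = None,
                    force_de: dict | None = None
                    ) -> tuple[CountTable, SyntheticTruth]:
    """Two-library gene counts with planted DE genes.

    Expected gene counts take ~80% of each library (the remainder stands
    in for reads mapped outside annotated genes), so declared library
    sizes always dominate the column sums. ``force_de`` maps specific gene
    ids to "up"/"down" to plant them as expressed DE genes regardless of
    the random draw (used to plant jointly swept-and-DE genes).
    """
    rng = np.random.default_rng(params.seed + 2)
    n = len(genes)
    ids = [g.gene_id for g in genes]
    lengths = np.array([g.length_bp for g in genes], dtype=float)
    expressed = rng.random(n) < params.expressed_fraction
    w = np.zeros(n)
    w[expressed] = rng.lognormal(mean=0.0, sigma=1.2, size=int(expressed.sum()))
    force_de = force_de or {}
    for gid in force_de:
        i = ids.index(gid)
        if w[i] == 0:
            expressed[i] = True
            w[i] = 1.0
    # length-proportional read mass, normalised to 80% of the library
    mass = w * lengths / 1000.0
    rel = 0.8 * mass / mass.sum()

    n_de = int(round(params.de_fraction * expressed.sum()))
    de_idx = rng.choice(np.flatnonzero(expressed), size=n_de, replace=False)
    direction = rng.random(n_de) < 0.5
    fold = np.ones(n)
    fold[de_idx[direction]] = 2.0 ** params.lfc
    fold[de_idx[~direction]] = 2.0 ** -params.lfc
    for gid, d in force_de.items():
        i = ids.index(gid)
        fold[i] = 2.0 ** (params.lfc if d == "up" else -params.lfc)

    la, lb = params.lib_sizes
    mu_a = rel * fold * la / (rel * fold).sum() * rel.sum()  # renormalise A
    mu_b = rel * lb

    def draw(mu):
        if params.dispersion > 0:
            shape = 1.0 / params.dispersion
            lam = rng.gamma(shape, mu * params.dispersion)
            return rng.poisson(lam)
        return rng.poisson(mu)

    counts = np.stack([draw(mu_a), draw(mu_b)], axis=1)
    ct = CountTable(
        gene_ids=[g.gene_id for g in genes],
        library_ids=["A", "B"],
        counts=counts,
        lib_size=np.array([la, lb], dtype=np.int64),
        gene_length_bp=lengths.astype(np.int64),
    )
    if truth is None:
        truth = SyntheticTruth(swept_intervals=[], swept_genes=[],
                               de_genes={}, site_freqs={})
    gene_ids = np.array(ids)
    truth.de_genes = {
        **{gene_ids[i]: "up" for i in de_idx[direction]},
        **{gene_ids[i]: "down" for i in de_idx[~direction]},
        **force_de,
    }
    return ct, truth
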