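import numpy as np
import pytest

from sweeptx.datamodel import GenotypeMatrix
from sweeptx.simulate import SimParams, SweepSpec, make_annotation, simulate_genotypes


def make_gm(alleles, pops=None, pos=None, chrom="chr1", qual=None, n_alt=None,
            ref=None, alt=None, phased=True):
    """Small-genotype builder for hand-written fixtures.

    ``alleles`` is (n_variants, n_samples, 2) with -1 for missing.
    """
    alleles = np.asarray(alleles, dtype=np.int8)
    v, s, _ = alleles.shape
    pops = np.asarray(pops if pops is not None else ["A"] * s)
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(s)],
        pops=pops,
        chrom=np.asarray([chrom] * v, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, v + 1) * 100,
                       dtype=np.int64),
        ref=np.asarray(ref if ref is not None else ["A"] * v, dtype=object),
        alt=np.asarray(alt if alt is not None else ["C"] * v, dtype=object),
        qual=np.asarray(qual if qual is not None else [50.0] * v, dtype=float),
        alleles=alleles,
        phased=np.full((v, s), phased, dtype=bool),
        n_alt=np.asarray(n_alt if n_alt is not None else [1] * v, dtype=np.int16),
    )


@pytest.fixture(scope="session")
def neutral_params():
    """Clean two-population data: no sweeps, no missingness or QC failures."""
    return SimParams(
        seed=11,
        n_samples={"A": 10, "B": 10},
        chrom_lengths={"chr1": 2_000_000},
        sweeps=[],
        missing_rate=0.0, high_missing_frac=0.0,
        qual_pass_frac=1.0, multiallelic_frac=0.0, indel_frac=0.0,
    )


@pytest.fixture(scope="session")
def neutral_gm(neutral_params):
    gm, _ = simulate_genotypes(neutral_params)
    return gm


@pytest.fixture(scope="session")
def sweep_params():
    """One planted sweep (strength 0.9, 300 kb) on a 10-Mb chromosome."""
    return SimParams(seed=7)


@pytest.fixture(scope="session")
def sweep_scan(sweep_params):
    """Fitted selective-sweep scan on the planted-sweep genome."""
    from sweeptx.models import SelectionScan
    from sweeptx.simulate import simulate_genotypes

    gm, truth = simulate_genotypes(sweep_params)
    genes = make_annotation(sweep_params, truth=truth)
    res = SelectionScan(gm, genes, chrom_lengths=sweep_params.chrom_lengths).fit()
    return res, truth
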