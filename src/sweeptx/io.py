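"""Readers and writers for the standard formats the pipeline touches.

VCF v4.x is read through cyvcf2 and written as plain text (GT only);
GFF3 goes through an in-memory gffutils database; counts, window tables
and sample maps are TSV via pandas; gene sets are GMT; regions are BED6.
"""

from __future__ import annotations

import warnings

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import (
    MISSING,
    ConfigError,
    CountTable,
    FormatError,
    GeneModel,
    GeneSetCollection,
    GenotypeMatrix,
    SweepRegion,
)

WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_snps",
    "hp_A", "hp_B", "fst_mean", "xpehh_mean",
    "z_hp_A", "z_fst", "flags",
]


def read_sample_map(path) -> dict:
    """Two-column TSV (sample, population) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("sample map needs two columns: sample, population")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_vcf(path, sample_map: dict) -> GenotypeMatrix:
    """Load phased genotypes for the mapped samples from a VCF.

    Multi-allelic records are retained but carry ``n_alt > 1`` so the QC
    stage can drop them; unphased genotypes load with ``phased=False``.
    """
    vcf = VCF(str(path), gts012=False)
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise FormatError("VCF has no GT FORMAT field")
    vcf_samples = list(vcf.samples)
    missing = [s for s in sample_map if s not in vcf_samples]
    if missing:
        raise ConfigError(f"samples in map absent from VCF: {missing}")
    samples = [s for s in vcf_samples if s in sample_map]
    col = [vcf_samples.index(s) for s in samples]
    pops = np.array([sample_map[s] for s in samples])

    chrom, pos, ref, alt, qual, n_alt = [], [], [], [], [], []
    alleles, phased = [], []
    for v in vcf:
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(",".join(v.ALT) if v.ALT else ".")
        qual.append(np.nan if v.QUAL is None else v.QUAL)
        n_alt.append(len(v.ALT))
        g = v.genotypes  # [a0, a1, phased] per sample
        row = np.full((len(samples), 2), MISSING, dtype=np.int8)
        ph = np.zeros(len(samples), dtype=bool)
        for i, c in enumerate(col):
            gt = g[c]
            a = [x if x is not None and x >= 0 else MISSING for x in gt[:-1]]
            if len(a) == 1:  # haploid record: treat second slot as missing
                a = [a[0], MISSING]
            row[i] = a[:2]
            ph[i] = bool(gt[-1])
        alleles.append(row)
        phased.append(ph)

    n = len(pos)
    return GenotypeMatrix(
        samples=samples,
        pops=pops,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        qual=np.array(qual, dtype=float),
        alleles=(np.stack(alleles) if n else np.empty((0, len(samples), 2), np.int8)),
        phased=(np.stack(phased) if n else np.empty((0, len(samples)), bool)),
        n_alt=np.array(n_alt, dtype=np.int16),
    )


def write_vcf(gm: GenotypeMatrix, path, chrom_lengths: dict | None = None) -> None:
    """Write a minimal VCF v4.2 with GT genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if chrom_lengths:
            for c, length in chrom_lengths.items():
                fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for i in range(gm.n_variants):
            q = gm.qual[i]
            qs = "." if np.isnan(q) else f"{q:g}"
            gts = []
            for j in range(gm.n_samples):
                a0, a1 = gm.alleles[i, j]
                sep = "|" if gm.phased[i, j] else "/"
                gts.append(f"{'.' if a0 == MISSING else a0}{sep}"
                           f"{'.' if a1 == MISSING else a1}")
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}\t"
                     f"{qs}\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_gff(path) -> list[GeneModel]:
    """Parse gene models (with exon structure) from a GFF3 file.

    Exons are grouped under their ``Parent`` gene; exons whose parent is
    unknown are skipped with a warning.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: dict[str, GeneModel] = {}
    for f in db.features_of_type("gene"):
        gid = f.attributes.get("ID", [f.id])[0]
        genes[gid] = GeneModel(gene_id=gid, chrom=f.seqid, start=f.start,
                               end=f.end, strand=f.strand or "+")
    for f in db.features_of_type("exon"):
        parents = f.attributes.get("Parent", [])
        # exons may hang off an mRNA; walk up until we hit a gene id we know
        target = None
        queue = list(parents)
        seen = set()
        while queue:
            p = queue.pop()
            if p in seen:
                continue
            seen.add(p)
            if p in genes:
                target = p
                break
            try:
                pf = db[p]
            except gffutils.FeatureNotFoundError:
                continue
            queue.extend(pf.attributes.get("Parent", []))
        if target is None:
            warnings.warn(f"exon at {f.seqid}:{f.start}-{f.end} has no known "
                          "parent gene; skipped")
            continue
        g = genes[target]
        if not (g.start <= f.start and f.end <= g.end):
            warnings.warn(f"exon outside gene span for {target}; clipped")
        g.exon_spans.append((f.start, f.end))
    return list(genes.values())


def write_gff(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tsweeptx\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for k, (s, e) in enumerate(sorted(g.exon_spans), 1):
                fh.write(f"{g.chrom}\tsweeptx\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.exon{k};Parent={g.gene_id}\n")


def read_counts(path) -> CountTable:
    """Read a gene x library count TSV.

    First column is the gene id; remaining columns are integer counts.
    Library sizes may be supplied in a ``#lib_size`` comment line; an
    optional ``length_bp`` column carries gene lengths.
    """
    lib_size = None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for ln in lines:
        if ln.startswith("#lib_size"):
            lib_size = [int(x) for x in ln.rstrip("\n").split("\t")[1:]]
        elif not ln.startswith("#"):
            body.append(ln)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), sep="\t")
    df = df.set_index(df.columns[0])
    lengths = None
    if "length_bp" in df.columns:
        lengths = df.pop("length_bp").to_numpy()
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or np.any(vals != np.floor(vals)):
        raise FormatError("counts must be integers")
    if np.any(vals < 0):
        raise FormatError("counts must be non-negative")
    return CountTable(
        gene_ids=df.index.tolist(),
        library_ids=df.columns.tolist(),
        counts=vals.astype(np.int64),
        lib_size=(np.asarray(lib_size) if lib_size is not None
                  else vals.sum(axis=0).astype(np.int64)),
        gene_length_bp=lengths,
    )


def write_counts(ct: CountTable, path) -> None:
    df = pd.DataFrame(ct.counts, index=pd.Index(ct.gene_ids, name="gene_id"),
                      columns=ct.library_ids)
    if ct.gene_length_bp is not None:
        df["length_bp"] = ct.gene_length_bp
    with open(path, "w") as fh:
        fh.write("#lib_size\t" + "\t".join(str(int(x)) for x in ct.lib_size) + "\n")
        df.to_csv(fh, sep="\t")


def read_gmt(path) -> GeneSetCollection:
    """GMT: one set per line — id, description, then member gene ids."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for ln in fh:
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line with <3 fields: {parts[:1]}")
            sid, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                warnings.warn(f"duplicate members in gene set {sid}; deduplicated")
            if not uniq:
                raise FormatError(f"gene set {sid} is empty")
            coll[sid] = (desc, uniq)
    return coll


def write_regions_bed(regions: list[SweepRegion], path) -> None:
    """BED6 with evidence labels in the name column (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tevidence\tscore\tstrand\n")
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            ev = ",".join(sorted(r.evidence))
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{ev}\t0\t.\n")


def write_window_table(wt: pd.DataFrame, path) -> None:
    out = wt.copy()
    if "flags" in out.columns:
        out["flags"] = out["flags"].map(
            lambda s: ",".join(sorted(s)) if s else ".")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_window_table(path) -> pd.DataFrame:
    wt = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "flags" in wt.columns:
        wt["flags"] = wt["flags"].map(
            lambda s: frozenset() if pd.isna(s) or s == "." else frozenset(s.split(",")))
    return wt
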