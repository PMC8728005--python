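"""Readers and writers for the external formats the pipeline touches.

FASTA, Jellyfish histo text, GFF3 (1-based inclusive on disk), BED (0-based
half-open), newick, a minimal VCF 4.x subset, and the TSV dialects for
orthogroup matrices, gene evidence flags, and population maps. All
coordinate conversion happens here and only here.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import dendropy
import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    EvidenceFlags,
    GeneModel,
    IntervalRecord,
    KmerHistogram,
    OrthogroupMatrix,
    SequenceRecord,
    VariantTable,
    revcomp,
    softmask_fraction,
)

logger = logging.getLogger("redwoodkit")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA preserving case (softmasking) and record order.

    Duplicate record ids raise :class:`FormatError`; an empty file yields an
    empty list.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if not rec.id:
                raise FormatError(f"{path}: record with empty id")
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, str(rec.seq)))
    except ValueError as exc:  # Biopython signals malformed FASTA this way
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Jellyfish histo


def read_histo(path: str | Path, k: int = 31) -> KmerHistogram:
    """Read whitespace-separated ``coverage count`` pairs.

    Out-of-order lines are sorted on load (logged); duplicate coverages or
    non-integer/negative tokens raise :class:`FormatError`.
    """
    covs: list[int] = []
    counts: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two fields")
            try:
                x, n = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer token") from exc
            if x < 1:
                raise FormatError(f"{path}:{lineno}: coverage must be >= 1")
            if n < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            covs.append(x)
            counts.append(n)
    if len(set(covs)) != len(covs):
        raise FormatError(f"{path}: duplicate coverage value")
    order = np.argsort(covs)
    if not np.array_equal(order, np.arange(len(covs))):
        logger.warning("%s: coverages out of order; sorted on load", path)
    return KmerHistogram(
        k=k,
        coverages=np.asarray(covs)[order],
        counts=np.asarray(counts)[order],
    )


def write_histo(hist: KmerHistogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        for x, n in hist.bins:
            fh.write(f"{x} {n}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[IntervalRecord]:
    out: list[IntervalRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            out.append(IntervalRecord(f[0], int(f[1]), int(f[2]), strand, name))
    return out


def write_bed(intervals: list[IntervalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# GFF3


def _splice(seqs: dict[str, str], scaffold: str, parts: list[tuple[int, int]], strand: str) -> str:
    seq = "".join(seqs[scaffold][s:e] for s, e in parts)
    return revcomp(seq) if strand == "-" else seq


def read_gff3(
    path: str | Path, fasta: list[SequenceRecord] | None = None
) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    An mRNA without a gene parent gets a synthesized container (warning
    logged); a model whose CDS extends outside its exon span is flagged
    ``valid=False`` rather than dropped. When ``fasta`` is given, the
    softmask fraction over the gene span, spliced CDS, and protein
    translation are filled in.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc

    seqs = {r.id: r.sequence for r in fasta} if fasta else None
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        if not parents:
            logger.warning("mRNA %s has no gene parent; container synthesized", mrna.id)
        gene_id = parents[0].id if parents else mrna.id
        exons = [
            (e.start - 1, e.end)
            for e in db.children(mrna, featuretype="exon", order_by="start")
        ]
        cds = [
            (c.start - 1, c.end)
            for c in db.children(mrna, featuretype="CDS", order_by="start")
        ]
        if not exons and cds:
            exons = list(cds)
        model = GeneModel(
            id=gene_id,
            scaffold=mrna.seqid,
            strand=mrna.strand,
            exons=exons,
            cds=cds,
        )
        if cds and exons:
            span_ok = all(
                any(es <= cs and ce <= ee for es, ee in exons) for cs, ce in cds
            )
            if not span_ok:
                model.valid = False
                logger.warning("gene %s: CDS outside exon span; flagged invalid", gene_id)
        if seqs is not None and mrna.seqid in seqs:
            s, e = model.span
            model.softmask_fraction = softmask_fraction(seqs[mrna.seqid][s:e])
            if cds:
                model.cds_seq = _splice(seqs, mrna.seqid, cds, mrna.strand).upper()
                if len(model.cds_seq) % 3 == 0:
                    model.protein = str(Seq(model.cds_seq).translate())
        models.append(model)
    return models


def write_gff3(models: list[GeneModel], path: str | Path, source: str = "redwoodkit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            fh.write(
                f"{m.scaffold}\t{source}\tgene\t{s + 1}\t{e}\t.\t{m.strand}\t.\tID={m.id}\n"
            )
            mid = f"{m.id}.t1"
            fh.write(
                f"{m.scaffold}\t{source}\tmRNA\t{s + 1}\t{e}\t.\t{m.strand}\t.\tID={mid};Parent={m.id}\n"
            )
            for xs, xe in m.exons:
                fh.write(
                    f"{m.scaffold}\t{source}\texon\t{xs + 1}\t{xe}\t.\t{m.strand}\t.\tParent={mid}\n"
                )
            for cs, ce in m.cds:
                fh.write(
                    f"{m.scaffold}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t0\tParent={mid}\n"
                )


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path) -> list[dendropy.Tree]:
    """Read one or more newick trees; leaf labels preserved verbatim."""
    text = Path(path).read_text().strip()
    if not text:
        raise FormatError(f"{path}: empty newick file")
    try:
        trees = dendropy.TreeList.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not trees:
        raise FormatError(f"{path}: no trees parsed")
    return list(trees)


def write_newick(trees: list[dendropy.Tree], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(
                t.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
            )


# ---------------------------------------------------------------------------
# Minimal VCF subset

_GT_DOSAGE = {
    (0, 0): 0,
    (0, 1): 1,
    (1, 0): 1,
    (1, 1): 2,
    (None, None): -1,
}


def read_variants(
    path: str | Path, populations: dict[str, str] | None = None
) -> VariantTable:
    """Read a minimal biallelic VCF.

    Multi-allelic sites are skipped with a warning and counted on the
    returned table; a record without GT raises :class:`FormatError`.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vf = pysam.VariantFile(str(path))
        samples = list(vf.header.samples)
        scaffolds: list[str] = []
        positions: list[int] = []
        ref: list[str] = []
        alt: list[str] = []
        rows: list[list[int]] = []
        skipped = 0
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                logger.warning(
                    "%s:%s multi-allelic or ALT-less site skipped", rec.chrom, rec.pos
                )
                continue
            row = []
            for s in samples:
                if "GT" not in rec.samples[s]:
                    raise FormatError(f"{path}: sample {s} missing GT at {rec.pos}")
                gt = rec.samples[s]["GT"]
                if gt not in _GT_DOSAGE:
                    raise FormatError(f"{path}: unsupported genotype {gt}")
                row.append(_GT_DOSAGE[gt])
            scaffolds.append(rec.chrom)
            positions.append(rec.pos)
            ref.append(rec.ref)
            alt.append(rec.alts[0])
            rows.append(row)
    return VariantTable(
        scaffolds=scaffolds,
        positions=np.array(positions, dtype=np.int64),
        ref=ref,
        alt=alt,
        genotypes=np.array(rows, dtype=np.int8).reshape(len(rows), len(samples)),
        samples=samples,
        populations=populations or {},
        skipped_multiallelic=skipped,
    )


_DOSAGE_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_variants(table: VariantTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for sc in dict.fromkeys(table.scaffolds):
            fh.write(f"##contig=<ID={sc}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i in range(table.n_sites):
            gts = "\t".join(_DOSAGE_GT[int(g)] for g in table.genotypes[i])
            fh.write(
                f"{table.scaffolds[i]}\t{table.positions[i]}\t.\t{table.ref[i]}\t"
                f"{table.alt[i]}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_populations(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample id, population id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"])
    return dict(zip(df["sample"].astype(str), df["population"].astype(str)))


def write_populations(populations: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in populations.items():
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# Orthogroup matrix + gene metadata TSV


def read_orthogroup_matrix(
    matrix_path: str | Path, gene_meta_path: str | Path | None = None
) -> OrthogroupMatrix:
    counts = pd.read_csv(matrix_path, sep="\t", index_col=0)
    counts = counts.astype(int)
    if gene_meta_path is not None:
        meta = pd.read_csv(gene_meta_path, sep="\t", index_col=0)
    else:
        meta = pd.DataFrame(
            columns=["family", "species", "length_aa", "scaffold", "start"]
        )
    return OrthogroupMatrix(counts=counts, gene_meta=meta)


def write_orthogroup_matrix(
    matrix: OrthogroupMatrix,
    matrix_path: str | Path,
    gene_meta_path: str | Path | None = None,
) -> None:
    matrix.counts.to_csv(matrix_path, sep="\t", index_label="family")
    if gene_meta_path is not None:
        matrix.gene_meta.to_csv(gene_meta_path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Evidence flags TSV


def read_evidence(path: str | Path) -> dict[str, EvidenceFlags]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    out: dict[str, EvidenceFlags] = {}
    for gene, row in df.iterrows():
        out[str(gene)] = EvidenceFlags(
            has_similarity_hit=bool(row["has_similarity_hit"]),
            domain_count=int(row["domain_count"]),
            has_family_assignment=bool(row["has_family_assignment"]),
            retro_domain_flag=bool(row["retro_domain_flag"]),
        )
    return out


def write_evidence(flags: dict[str, EvidenceFlags], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\thas_similarity_hit\tdomain_count\thas_family_assignment\tretro_domain_flag\n"
        )
        for gene, ev in flags.items():
            fh.write(
                f"{gene}\t{int(ev.has_similarity_hit)}\t{ev.domain_count}\t"
                f"{int(ev.has_family_assignment)}\t{int(ev.retro_domain_flag)}\n"
            )


def attach_evidence(models: list[GeneModel], flags: dict[str, EvidenceFlags]) -> None:
    for m in models:
        if m.id in flags:
            m.evidence = flags[m.id]


# ---------------------------------------------------------------------------
# Protein FASTA convenience


def write_protein_fasta(proteins: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in proteins.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: r.sequence for r in read_fasta(path)}
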