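"""Genome sequence/annotation I/O, operon and divergon modelling, upstream extraction.

All internal coordinates are 0-based half-open on the forward strand of the
contig; GFF3 I/O converts from/to the 1-based closed convention. Upstream
regions are reported in coding-strand orientation, 5'->3' toward the start
codon, so that the last base of the region is the base immediately before the
predicted translation start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM_WINDOW = 250
DEFAULT_OPERON_GAP = 150


class GenomeFormatError(ValueError):
    """Raised when sequence and annotation inputs are inconsistent."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GeneFeature:
    """A CDS feature; ``start``/``end`` are 0-based half-open."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise GenomeFormatError(f"{self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise GenomeFormatError(
                f"{self.gene_id}: invalid coordinates [{self.start},{self.end})"
            )


@dataclass
class GenomeRecord:
    genome_id: str
    contigs: dict[str, str]
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.contigs = {c: s.upper() for c, s in self.contigs.items()}
        for c, s in self.contigs.items():
            if not s:
                raise GenomeFormatError(f"contig {c} is empty")
        for f in self.features:
            if f.contig_id not in self.contigs:
                raise GenomeFormatError(
                    f"feature {f.gene_id} references unknown contig {f.contig_id}"
                )
            if f.end > len(self.contigs[f.contig_id]):
                raise GenomeFormatError(
                    f"feature {f.gene_id} extends past the end of {f.contig_id}"
                )
        self.features = sorted(self.features, key=lambda f: (f.contig_id, f.start, f.end))


@dataclass
class Operon:
    operon_id: str
    member_gene_ids: list[str]
    leader_gene_id: str
    strand: str
    contig_id: str


@dataclass
class UpstreamRegion:
    """The (up to) ``window`` bases upstream of an operon leader.

    ``span`` is the genome interval the sequence was cut from; for a minus
    strand leader the sequence is the reverse complement of that interval.
    """

    gene_id: str
    genome_id: str
    sequence: str
    span: tuple[int, int]
    contig_id: str
    strand: str
    truncated: bool = False
    divergon_partner: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def read_genome(fasta_path: str | Path, annotation_path: str | Path,
                genome_id: str | None = None) -> GenomeRecord:
    """Read a multi-contig FASTA plus a GFF3 of CDS features.

    GFF3 1-based closed coordinates are converted to 0-based half-open. The
    gene identifier is taken from the ``ID`` attribute, falling back to
    ``locus_tag``. A genome with zero CDS features is rejected.
    """
    fasta_path, annotation_path = Path(fasta_path), Path(annotation_path)
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not contigs:
        raise GenomeFormatError(f"{fasta_path}: no FASTA records")

    try:
        db = gffutils.create_db(str(annotation_path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    except Exception as exc:
        raise GenomeFormatError(f"{annotation_path}: cannot parse GFF3: {exc}") from exc
    features = []
    for f in db.features_of_type("CDS", order_by=("seqid", "start")):
        if f.seqid not in contigs:
            raise GenomeFormatError(
                f"{annotation_path}: feature {f.id} references contig "
                f"{f.seqid!r} absent from {fasta_path}"
            )
        locus = f.attributes.get("locus_tag", [""])[0]
        gene_id = f.attributes.get("ID", [None])[0] or locus or f.id
        features.append(GeneFeature(gene_id=gene_id, contig_id=f.seqid,
                                    start=f.start - 1, end=f.end,
                                    strand=f.strand, locus_tag=locus))
    if not features:
        raise GenomeFormatError(f"{annotation_path}: no CDS features")
    return GenomeRecord(genome_id=genome_id or fasta_path.stem,
                        contigs=contigs, features=features)


def write_genome(genome: GenomeRecord, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Write FASTA + GFF3 (CDS rows, 1-based closed) for a GenomeRecord."""
    with open(fasta_path, "w") as fh:
        for cid in sorted(genome.contigs):
            fh.write(f">{cid}\n")
            seq = genome.contigs[cid]
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in genome.features:
            attrs = f"ID={f.gene_id}"
            if f.locus_tag:
                attrs += f";locus_tag={f.locus_tag}"
            fh.write("\t".join([f.contig_id, "regulonscan", "CDS",
                                str(f.start + 1), str(f.end), ".",
                                f.strand, "0", attrs]) + "\n")


def infer_operons(genome: GenomeRecord, max_gap: int = DEFAULT_OPERON_GAP) -> list[Operon]:
    """Merge consecutive same-strand, same-contig genes with intergenic gap
    <= ``max_gap`` nt into operons; the leader is the 5'-most member on the
    coding strand. Every gene ends up in exactly one operon."""
    operons: list[Operon] = []
    run: list[GeneFeature] = []

    def flush(run):
        if not run:
            return
        strand = run[0].strand
        members = [g.gene_id for g in run]  # coordinate order
        if strand == "-":
            members = members[::-1]  # 5'->3' on the coding strand
        leader = members[0]
        operons.append(Operon(operon_id=f"opn_{leader}", member_gene_ids=members,
                              leader_gene_id=leader, strand=strand,
                              contig_id=run[0].contig_id))

    for f in genome.features:
        if run and (f.contig_id == run[-1].contig_id and f.strand == run[-1].strand
                    and f.start - run[-1].end <= max_gap):
            run.append(f)
        else:
            flush(run)
            run = [f]
    flush(run)
    return operons


def _feature_map(genome: GenomeRecord) -> dict[str, GeneFeature]:
    return {f.gene_id: f for f in genome.features}


def upstream_span(leader: GeneFeature, contig_len: int,
                  window: int = DEFAULT_UPSTREAM_WINDOW) -> tuple[int, int, bool]:
    """Genome interval of the leader's upstream window, clipped at contig ends."""
    if leader.strand == "+":
        lo, hi = max(0, leader.start - window), leader.start
        truncated = leader.start - window < 0
    else:
        lo, hi = leader.end, min(contig_len, leader.end + window)
        truncated = leader.end + window > contig_len
    return lo, hi, truncated


def extract_upstream(genome: GenomeRecord, operon: Operon,
                     window: int = DEFAULT_UPSTREAM_WINDOW) -> UpstreamRegion:
    """Extract the upstream region of the operon leader in coding-strand
    orientation. A leader flush against the contig edge yields an empty,
    truncated region rather than an error."""
    leader = _feature_map(genome)[operon.leader_gene_id]
    contig = genome.contigs[leader.contig_id]
    lo, hi, truncated = upstream_span(leader, len(contig), window)
    seq = contig[lo:hi]
    if leader.strand == "-":
        seq = reverse_complement(seq)
    return UpstreamRegion(gene_id=leader.gene_id, genome_id=genome.genome_id,
                          sequence=seq, span=(lo, hi), contig_id=leader.contig_id,
                          strand=leader.strand, truncated=truncated)


def classify_divergons(genome: GenomeRecord, operons: list[Operon]) -> dict[str, str]:
    """Map leader gene_id -> divergon partner leader gene_id.

    Two operon leaders arranged head-to-head (a minus-strand operon directly
    followed by a plus-strand operon on the same contig, sharing one
    intergenic interval) are mutual partners.
    """
    feats = _feature_map(genome)

    def op_extent(op):
        coords = [(feats[g].start, feats[g].end) for g in op.member_gene_ids]
        return min(s for s, _ in coords), max(e for _, e in coords)

    partners: dict[str, str] = {}
    by_contig: dict[str, list[tuple[int, int, Operon]]] = {}
    for op in operons:
        lo, hi = op_extent(op)
        by_contig.setdefault(op.contig_id, []).append((lo, hi, op))
    for ops in by_contig.values():
        ops.sort()
        for (_, _, left), (_, _, right) in zip(ops, ops[1:]):
            if left.strand == "-" and right.strand == "+":
                partners[left.leader_gene_id] = right.leader_gene_id
                partners[right.leader_gene_id] = left.leader_gene_id
    return partners


def write_upstream_fasta(regions: list[UpstreamRegion], path: str | Path) -> None:
    """Write regions as FASTA with headers ``genome|gene|start-end|strand``."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.genome_id, r.gene_id)):
            fh.write(f">{r.genome_id}|{r.gene_id}|{r.span[0]}-{r.span[1]}|{r.strand}\n")
            fh.write(r.sequence + "\n")
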