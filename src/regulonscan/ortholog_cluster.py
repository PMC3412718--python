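"""Ortholog grouping from tabular homology hits by the e-value-gap rule.

A family search with one representative query typically yields a tight
in-group of very low e-values (< 1e-30) separated from background hits by many
orders of magnitude. Membership is decided by the core cutoff alone; the size
of the log10 gap between the last included and first excluded hit is reported,
and a gap below ``gap_orders`` (default 15 orders of magnitude) flags the
group for manual review rather than failing it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

INCLUDE_CUTOFF = 1e-5       # BLAST collection cutoff
CORE_CUTOFF = 1e-30         # in-group e-value bound
GAP_ORDERS = 15.0           # log10 separation regarded as clean
ZERO_EVALUE_SENTINEL = 1e-200

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                   "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    subject_genome_id: str
    evalue: float
    bitscore: float | None = None

    @property
    def log10_evalue(self) -> float:
        return math.log10(self.evalue if self.evalue > 0 else ZERO_EVALUE_SENTINEL)


@dataclass
class OrthologGroup:
    family_name: str
    members: list[tuple[str, str, float]]  # (genome_id, gene_id, evalue)
    separation_log10: float
    clean_separation: bool

    def genomes(self) -> set[str]:
        return {g for g, _, _ in self.members}

    def copy_count(self, genome_id: str) -> int:
        return sum(1 for g, _, _ in self.members if g == genome_id)


def _split_subject(subject_id: str) -> tuple[str, str]:
    """Subjects are encoded ``genome_id|gene_id``; a bare id maps to itself."""
    if "|" in subject_id:
        genome, _, gene = subject_id.partition("|")
        return genome, gene
    return subject_id, subject_id


def read_hit_table(path: str | Path, include_cutoff: float = INCLUDE_CUTOFF,
                   genome_map: dict[str, str] | None = None) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table (outfmt-6 dialect).

    Columns 1, 2 and 11 (query, subject, e-value) are used; extra columns are
    ignored. E-values above the collection cutoff are dropped with a logged
    count; an exact 0.0 is stored as the 1e-200 sentinel so log arithmetic
    stays finite.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse hit table: {exc}") from exc
    if df.shape[1] < 12:
        raise ValueError(f"{path}: expected >=12 tab-separated columns, got {df.shape[1]}")
    records, dropped = [], 0
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        try:
            evalue = float(row[10])
            bitscore = float(row[11])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
        if evalue > include_cutoff:
            dropped += 1
            continue
        if evalue == 0.0:
            evalue = ZERO_EVALUE_SENTINEL
        subject = str(row[1])
        if genome_map is not None:
            genome, gene = genome_map.get(subject, subject), subject
        else:
            genome, gene = _split_subject(subject)
        records.append(HitRecord(query_id=str(row[0]), subject_id=gene,
                                 subject_genome_id=genome, evalue=evalue,
                                 bitscore=bitscore))
    if dropped:
        logger.info("%s: dropped %d hit(s) above the %.0e collection cutoff",
                    path, dropped, include_cutoff)
    return records


def evalue_gap_cluster(hits: list[HitRecord], core_cutoff: float = CORE_CUTOFF,
                       gap_orders: float = GAP_ORDERS,
                       family_name: str = "") -> OrthologGroup:
    """Group hits below the core cutoff; measure the log10 gap to the rest.

    ``separation_log10`` is log10(first excluded e-value) minus log10(last
    included e-value); with no excluded hits the separation is infinite and
    the group is clean by construction. Duplicate (genome, gene) subjects keep
    their best e-value.
    """
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        key = (h.subject_genome_id, h.subject_id)
        if key not in best or h.evalue < best[key]:
            best[key] = h.evalue
    ordered = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
    included = [(g, s, e) for (g, s), e in ordered if e < core_cutoff]
    excluded = [e for (_, _), e in ordered if e >= core_cutoff]
    if not ordered:
        return OrthologGroup(family_name, [], math.inf, True)
    if not included or not excluded:
        return OrthologGroup(family_name, included, math.inf, True)
    last_in = included[-1][2]
    sep = math.log10(excluded[0]) - math.log10(last_in)
    return OrthologGroup(family_name, included, sep, sep >= gap_orders)


def build_presence_absence(groups: dict[str, OrthologGroup], genomes: list[str],
                           regulon: dict[str, "object"] | None = None) -> pd.DataFrame:
    """Ortholog-family x genome copy-count matrix.

    Cells are strings: total copy count, with the number of copies preceded by
    a qualifying predicted site appended in parentheses ("2(1)"); zero copies
    render blank. ``regulon`` maps genome_id to a RegulonPrediction whose
    entries carry ``target_gene_ids``.
    """
    regulated: dict[str, set[str]] = {}
    if regulon:
        for genome_id, pred in regulon.items():
            regulated[genome_id] = {g for e in pred.entries for g in e.target_gene_ids}
    data = {}
    for family in sorted(groups):
        group = groups[family]
        row = {}
        for genome_id in genomes:
            total = group.copy_count(genome_id)
            if total == 0:
                row[genome_id] = ""
                continue
            reg = sum(1 for g, gene, _ in group.members
                      if g == genome_id and gene in regulated.get(genome_id, ()))
            row[genome_id] = f"{total}({reg})" if reg else str(total)
        data[family] = row
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(genomes))
    df.index.name = "family"
    return df


def write_presence_absence(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")
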