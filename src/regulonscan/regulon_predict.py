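"""Regulon prediction and cross-species conservation analysis.

A gene/operon joins the predicted regulon when its upstream window carries a
site passing both selection criteria: (i) relative similarity score of at
least the threshold (default 0.87; the stricter preset used for high
confidence work is 0.89) and (ii) position within the 250..0 nt window
upstream of the predicted translation start. Experimentally verified distant
sites can be whitelisted, which relaxes only the distance criterion. A site
falling inside the shared intergenic interval of a divergon is assigned to
both partners and flagged — the biology (a pure repressor usually acts on one
partner only) is annotation, not filtering.

Conservation across species is summarised per ortholog family; an association
supported by at least ``min_conserved_species`` genomes (default 3) counts as
conserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .genome_io import (GenomeRecord, Operon, classify_divergons, extract_upstream,
                        infer_operons, upstream_span)
from .motif_builder import FrequencyMatrix
from .sms_scanner import (DEFAULT_THRESHOLD, HIGH_CONFIDENCE_THRESHOLD, SiteHit,
                          scan_genome_upstreams, scan_region)

logger = logging.getLogger(__name__)

SCORE_DECIMALS = 2  # report precision for similarity scores


@dataclass
class PipelineConfig:
    """Thresholds and knobs of the prediction pipeline."""

    window: int = 250
    threshold: float = DEFAULT_THRESHOLD
    operon_gap: int = 150
    min_conserved_species: int = 3
    both_strands: bool = True
    whitelist: list[tuple[str, str]] = field(default_factory=list)
    whitelist_window: int = 600   # extended window for whitelisted loci
    pseudocount: float = 0.0

    def __post_init__(self):
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must lie in (0, 1]")
        if self.window <= 0 or self.operon_gap < 0:
            raise ValueError("window must be positive and operon_gap non-negative")
        self.whitelist = [tuple(w) for w in self.whitelist]

    @classmethod
    def high_confidence(cls, **kw) -> "PipelineConfig":
        kw.setdefault("threshold", HIGH_CONFIDENCE_THRESHOLD)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if data.pop("preset", None) == "high_confidence":
            return cls.high_confidence(**data)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True)
                              .encode()).hexdigest()[:12]


@dataclass
class RegulonEntry:
    operon_id: str
    target_gene_ids: list[str]
    best_hit: SiteHit
    rank: int
    divergon_note: str = ""


@dataclass
class RegulonPrediction:
    genome_id: str
    entries: list[RegulonEntry] = field(default_factory=list)


def _round_score(x: float) -> float:
    return round(x, SCORE_DECIMALS)


def assign_targets(hit: SiteHit, genome: GenomeRecord, operons: list[Operon],
                   divergons: dict[str, str], window: int = 250) -> list[tuple[str, str]]:
    """Operons a hit belongs to: the scanned operon, plus the divergon partner
    when the site also lies entirely within the partner's upstream window.

    Returns (operon_id, note) pairs; the note is "divergon" for shared sites.
    """
    feats = {f.gene_id: f for f in genome.features}
    by_leader = {op.leader_gene_id: op for op in operons}
    leader = feats[hit.region_ref]
    op = by_leader[hit.region_ref]
    lo, hi, _ = upstream_span(leader, len(genome.contigs[leader.contig_id]), window)
    i = len(hit.window_sequence)
    if leader.strand == "+":
        gs = lo + hit.offset
    else:
        gs = hi - hit.offset - i
    ge = gs + i

    partner_id = divergons.get(hit.region_ref)
    out = [(op.operon_id, "")]
    if partner_id is not None and partner_id in by_leader:
        partner = feats[partner_id]
        plo, phi, _ = upstream_span(partner, len(genome.contigs[partner.contig_id]), window)
        if plo <= gs and ge <= phi:
            out = [(op.operon_id, "divergon"),
                   (by_leader[partner_id].operon_id, "divergon")]
    return out


def _rank(entries: list[RegulonEntry]) -> None:
    """Genome-wide ranks over qualifying operons, descending rounded score;
    tied (printed) scores share the lower rank."""
    entries.sort(key=lambda e: (-_round_score(e.best_hit.relative),
                                -e.best_hit.relative, e.operon_id))
    scores = [_round_score(e.best_hit.relative) for e in entries]
    for k, e in enumerate(entries):
        e.rank = 1 + sum(1 for s in scores if s > scores[k])


def predict_regulon(genome: GenomeRecord, pfm: FrequencyMatrix,
                    config: PipelineConfig | None = None) -> RegulonPrediction:
    """Apply both selection criteria genome-wide and rank the surviving operons.

    Whitelisted (genome, gene) loci are rescanned with the extended window so
    a verified distant site can qualify; the score criterion still applies.
    """
    config = config or PipelineConfig()
    if config.window <= pfm.length:
        raise ValueError("upstream window must exceed the motif length")
    operons = infer_operons(genome, max_gap=config.operon_gap)
    divergons = classify_divergons(genome, operons)
    scans = scan_genome_upstreams(pfm, genome, operons, window=config.window,
                                  threshold=config.threshold,
                                  both_strands=config.both_strands)
    whitelisted = {gene for g, gene in config.whitelist if g == genome.genome_id}

    ops_by_id = {op.operon_id: op for op in operons}
    entries: list[RegulonEntry] = []
    for operon_id in sorted(scans):
        op = ops_by_id[operon_id]
        scan = scans[operon_id]
        note = ""
        best = scan.best
        if best is None and op.leader_gene_id in whitelisted:
            region = extract_upstream(genome, op, window=config.whitelist_window)
            best = scan_region(pfm, region, both_strands=config.both_strands,
                               threshold=config.threshold).best
            note = "whitelist"
        if best is None:
            continue
        if not note:
            assigned = assign_targets(best, genome, operons, divergons,
                                      window=config.window)
            note = dict(assigned).get(operon_id, "")
        entries.append(RegulonEntry(operon_id=operon_id,
                                    target_gene_ids=list(op.member_gene_ids),
                                    best_hit=best, rank=0, divergon_note=note))
    _rank(entries)
    return RegulonPrediction(genome_id=genome.genome_id, entries=entries)


def conserved_associations(predictions: dict[str, RegulonPrediction],
                           families: dict, config: PipelineConfig | None = None
                           ) -> pd.DataFrame:
    """Cross-species conservation report (one row per ortholog family).

    ``families`` maps gene ids to family names, keyed either by
    ``(genome_id, gene_id)`` or by bare ``gene_id``; predicted targets with no
    mapping are collected under "unassigned". Columns: family, n_support,
    genomes, scores (genome:score pairs at report precision), conserved.
    Rows are sorted by support (desc) then family name.
    """
    config = config or PipelineConfig()

    def family_of(genome_id, gene_id):
        return families.get((genome_id, gene_id), families.get(gene_id, "unassigned"))

    per_family: dict[str, dict[str, float]] = {}
    for genome_id in sorted(predictions):
        for e in predictions[genome_id].entries:
            for gene in e.target_gene_ids:
                fam = family_of(genome_id, gene)
                best = per_family.setdefault(fam, {})
                score = e.best_hit.relative
                if score > best.get(genome_id, -1.0):
                    best[genome_id] = score
    rows = []
    for fam, scores in per_family.items():
        genomes = sorted(scores)
        rows.append({
            "family": fam,
            "n_support": len(genomes),
            "genomes": ",".join(genomes),
            "scores": ";".join(f"{g}:{_round_score(scores[g]):.2f}" for g in genomes),
            "conserved": len(genomes) >= config.min_conserved_species,
        })
    rows.sort(key=lambda r: (-r["n_support"], r["family"]))
    return pd.DataFrame(rows, columns=["family", "n_support", "genomes",
                                       "scores", "conserved"])


# ---------------------------------------------------------------------------
# report I/O — deterministic, byte-identical on identical inputs

REGULON_COLUMNS = ["genome", "operon", "target_genes", "leader_gene", "score",
                   "rank", "distance_to_start", "strand", "window_seq",
                   "divergon_note", "relative"]


def write_regulon_tsv(prediction: RegulonPrediction, path: str | Path) -> None:
    """Regulon report: one row per predicted operon, score printed at 2
    decimals (the ranking precision), full relative score in the last column."""
    with open(path, "w") as fh:
        fh.write("\t".join(REGULON_COLUMNS) + "\n")
        for e in sorted(prediction.entries,
                        key=lambda e: (e.rank, -e.best_hit.relative, e.operon_id)):
            h = e.best_hit
            fh.write("\t".join([
                prediction.genome_id, e.operon_id, ";".join(e.target_gene_ids),
                h.region_ref, f"{_round_score(h.relative):.2f}", str(e.rank),
                str(h.distance_to_start), h.strand, h.window_sequence,
                e.divergon_note, repr(h.relative)]) + "\n")


def read_regulon_tsv(path: str | Path) -> RegulonPrediction:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    genome_id = df["genome"].iloc[0] if len(df) else ""
    entries = []
    for row in df.itertuples(index=False):
        relative = float(row.relative)
        i = len(row.window_seq)
        hit = SiteHit(window_sequence=row.window_seq, raw=float("nan"),
                      similarity=float("nan"), relative=relative,
                      offset=-1, distance_to_start=int(row.distance_to_start),
                      strand=row.strand, region_ref=row.leader_gene,
                      genome_id=row.genome)
        entries.append(RegulonEntry(operon_id=row.operon,
                                    target_gene_ids=row.target_genes.split(";"),
                                    best_hit=hit, rank=int(row.rank),
                                    divergon_note=row.divergon_note))
    return RegulonPrediction(genome_id=genome_id, entries=entries)


def write_conservation_tsv(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)


def write_run_log(path: str | Path, config: PipelineConfig, seed: int | None = None,
                  dropped_genomes: list[str] | None = None) -> None:
    payload = {"config": asdict(config), "config_hash": config.digest(),
               "seed": seed, "dropped_genomes": dropped_genomes or []}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
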