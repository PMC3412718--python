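"""Similar Motif Scoring (SMS) and upstream-region scanning.

SMS scores a target window of length i against a position frequency matrix by
summing, position by position, the frequency of the window's nucleotide:
raw = sum_j f_{w_j}(j). Dividing by i gives the *similarity* (0..1); dividing
by the matrix's highest attainable raw score gives the *relative similarity*
(0..1, 1 iff every position carries a column-maximal nucleotide). There is no
background model and no log-odds transform: the statistic is the frequency sum
itself, which makes the score directly interpretable as closeness to the
motif's consensus. N or any non-ACGT character contributes 0.

Regulon candidates are windows with relative similarity at or above the
selection threshold (default 0.87, preset "high_confidence" 0.89) lying
entirely within the upstream window (default 250 nt) of an operon leader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (GenomeRecord, Operon, UpstreamRegion, extract_upstream,
                        reverse_complement)
from .motif_builder import FrequencyMatrix

DEFAULT_THRESHOLD = 0.87
HIGH_CONFIDENCE_THRESHOLD = 0.89

_ENC = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _padded(pfm: FrequencyMatrix) -> np.ndarray:
    # fifth row: score 0 for N / anything non-ACGT
    return np.vstack([pfm.freqs, np.zeros(pfm.length)])


@dataclass
class SiteHit:
    window_sequence: str
    raw: float
    similarity: float
    relative: float
    offset: int                  # left edge within the region (coding orientation)
    distance_to_start: int       # 3' site edge to translation start; 1 = adjacent
    strand: str                  # relative to the coding strand of the leader
    region_ref: str              # leader gene_id
    genome_id: str = ""

    def sort_key(self):
        return (-self.relative, self.distance_to_start,
                self.strand != "+", self.offset)


@dataclass
class ScanResult:
    region_ref: str
    hits: list[SiteHit] = field(default_factory=list)
    threshold: float = DEFAULT_THRESHOLD

    @property
    def best(self) -> SiteHit | None:
        return self.hits[0] if self.hits else None


def max_attainable(pfm: FrequencyMatrix) -> float:
    """Highest raw score any window can reach: sum_j max_N f_N(j)."""
    return float(pfm.freqs.max(axis=0).sum())


def sms_score(pfm: FrequencyMatrix, window: str) -> tuple[float, float, float]:
    """Return (raw, similarity, relative) of one window.

    raw sums the matrix frequency of the window's base at each position;
    similarity = raw / i; relative = raw / max_attainable.
    """
    if len(window) != pfm.length:
        raise ValueError(f"window length {len(window)} != matrix length {pfm.length}")
    codes = _encode(window.upper())
    raw = float(_padded(pfm)[codes, np.arange(pfm.length)].sum())
    return raw, raw / pfm.length, raw / pfm.max_attainable


def _raw_scores(pfm_padded: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Raw SMS score of every window of length i over an encoded sequence."""
    i = pfm_padded.shape[1]
    n = len(codes) - i + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, i)
    return pfm_padded[windows, np.arange(i)].sum(axis=1)


def scan_region(pfm: FrequencyMatrix, region: UpstreamRegion,
                both_strands: bool = True,
                threshold: float = DEFAULT_THRESHOLD) -> ScanResult:
    """Score every window of the region (and of its reverse complement when
    ``both_strands``) and keep hits with relative similarity >= threshold.

    Hits are ranked by relative similarity (desc), then smaller distance to
    the translation start, then + strand before -, then smaller offset.
    """
    i, L = pfm.length, len(region.sequence)
    result = ScanResult(region_ref=region.gene_id, threshold=threshold)
    if L < i:
        return result
    pad = _padded(pfm)
    strands = [("+", region.sequence)]
    if both_strands:
        strands.append(("-", reverse_complement(region.sequence)))
    for strand, seq in strands:
        raws = _raw_scores(pad, _encode(seq))
        for o, raw in enumerate(raws):
            relative = raw / pfm.max_attainable
            if relative < threshold:
                continue
            offset = o if strand == "+" else L - i - o
            result.hits.append(SiteHit(
                window_sequence=seq[o:o + i], raw=float(raw),
                similarity=float(raw) / i, relative=float(relative),
                offset=offset, distance_to_start=L - (offset + i) + 1,
                strand=strand, region_ref=region.gene_id,
                genome_id=region.genome_id))
    result.hits.sort(key=SiteHit.sort_key)
    return result


def scan_genome_upstreams(pfm: FrequencyMatrix, genome: GenomeRecord,
                          operons: list[Operon], window: int = 250,
                          threshold: float = DEFAULT_THRESHOLD,
                          both_strands: bool = True) -> dict[str, ScanResult]:
    """Scan the upstream window of every operon leader.

    Only sites lying entirely within the window qualify (the region itself is
    at most ``window`` nt, so every reported site does). Returns one
    ScanResult per operon, empty when nothing passes the threshold.
    """
    out = {}
    for op in operons:
        region = extract_upstream(genome, op, window=window)
        out[op.operon_id] = scan_region(pfm, region, both_strands=both_strands,
                                        threshold=threshold)
    return out


# ---------------------------------------------------------------------------
# writers

HITS_TSV_HEADER = ("genome\toperon\tleader_gene\toffset\tdistance_to_start\t"
                   "strand\twindow_seq\traw\tsimilarity\trelative\n")


def write_hits_tsv(scans: dict[str, ScanResult], path: str | Path,
                   genome_id: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(HITS_TSV_HEADER)
        for operon_id in sorted(scans):
            for h in scans[operon_id].hits:
                fh.write("\t".join([
                    h.genome_id or genome_id, operon_id, h.region_ref,
                    str(h.offset), str(h.distance_to_start), h.strand,
                    h.window_sequence, f"{h.raw:.6f}", f"{h.similarity:.6f}",
                    f"{h.relative:.6f}"]) + "\n")


def write_hits_bed(scans: dict[str, ScanResult], genome: GenomeRecord,
                   operons: list[Operon], path: str | Path,
                   window: int = 250) -> None:
    """BED6 of hits in genome coordinates; score = round(1000 * relative)."""
    from .genome_io import upstream_span
    feats = {f.gene_id: f for f in genome.features}
    ops = {op.operon_id: op for op in operons}
    rows = []
    for operon_id, scan in scans.items():
        op = ops[operon_id]
        leader = feats[op.leader_gene_id]
        lo, hi, _ = upstream_span(leader, len(genome.contigs[leader.contig_id]), window)
        for h in scan.hits:
            i = len(h.window_sequence)
            if leader.strand == "+":
                gs = lo + h.offset
            else:
                gs = hi - h.offset - i
            strand = h.strand if leader.strand == "+" else ("-" if h.strand == "+" else "+")
            rows.append((leader.contig_id, gs, gs + i,
                         f"{operon_id}|{h.region_ref}",
                         int(round(1000 * h.relative)), strand))
    rows.sort()
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
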