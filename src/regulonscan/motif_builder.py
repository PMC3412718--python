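"""Phylogenetic-footprint motif building.

Orthologous upstream regions are assumed to share a binding motif (the GOOFE
assumption: groups of orthologous functional equivalents inherit their
regulatory sites). The anchor site of the nitrogen regulators GlnR/TnrA is a
near-palindromic element, consensus TGTNA-N7-TNACA, typically found 3-6 nt
upstream of a TTGAC -35-like promoter element. This module locates that seed
site in each genome's anchor upstream region and assembles one site per genome
into a position frequency matrix (PFM) of per-position nucleotide fractions
f_N(j), N in {A,C,G,T}, j = 1..i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import UpstreamRegion, reverse_complement

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
IUPAC_BY_SET = {frozenset(v): k for k, v in IUPAC.items()}

DEFAULT_SEED_CONSENSUS = "TGTNA" + "N" * 7 + "TNACA"


class MotifError(ValueError):
    pass


@dataclass
class BindingSiteSet:
    """Aligned equal-length binding sites with per-site provenance."""

    sites: list[str]
    provenance: list[tuple[str, str, int, str]] = field(default_factory=list)
    # provenance entries: (genome_id, gene_id, offset, strand)

    def __post_init__(self):
        if not self.sites:
            raise MotifError("a BindingSiteSet needs at least one site")
        self.sites = [s.upper() for s in self.sites]
        i = len(self.sites[0])
        for s in self.sites:
            if len(s) != i:
                raise MotifError("sites must all have the same length")
            if set(s) - set(BASES):
                raise MotifError(f"site {s!r} contains non-ACGT characters")

    @property
    def motif_length(self) -> int:
        return len(self.sites[0])


@dataclass
class FrequencyMatrix:
    """Per-position nucleotide fractions; rows A,C,G,T; columns 1..i.

    ``max_attainable`` is the highest raw score any window can reach,
    sum_j max_N f_N(j); it is computed once and cached on the instance.
    """

    freqs: np.ndarray
    n_sites: int
    family_label: str = ""
    max_attainable: float = field(init=False)

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[0] != 4:
            raise MotifError("frequency matrix must have shape (4, i)")
        if np.any(self.freqs < 0) or np.any(self.freqs > 1):
            raise MotifError("frequencies must lie in [0, 1]")
        if not np.allclose(self.freqs.sum(axis=0), 1.0, atol=1e-9):
            raise MotifError("each matrix column must sum to 1")
        self.max_attainable = float(self.freqs.max(axis=0).sum())

    @property
    def length(self) -> int:
        return self.freqs.shape[1]


@dataclass
class SeedPattern:
    """Degenerate anchor-site pattern with its promoter-element context."""

    pattern: str = DEFAULT_SEED_CONSENSUS
    promoter_element: str = "TTGAC"
    spacer_range: tuple[int, int] = (3, 6)
    max_mismatches: int = 2

    def __post_init__(self):
        self.pattern = self.pattern.upper()
        if set(self.pattern) - set(IUPAC):
            raise MotifError(f"pattern {self.pattern!r} has non-IUPAC characters")
        if self.spacer_range[0] > self.spacer_range[1]:
            raise MotifError("spacer_range min must be <= max")

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def defined_positions(self) -> list[int]:
        """Indices of the non-N (consensus-defined) pattern positions."""
        return [j for j, c in enumerate(self.pattern) if c != "N"]


@dataclass
class SeedSite:
    sequence: str            # in pattern (match) orientation
    offset: int              # left edge in region coordinates
    strand: str              # relative to the region's coding-strand sequence
    mismatches: int
    promoter_anchored: bool


def _mismatches(window: str, pattern: str) -> int | None:
    """Mismatch count at non-N pattern positions; None if window has non-ACGT."""
    n = 0
    for w, p in zip(window, pattern):
        if w not in BASES:
            return None
        if p != "N" and w not in IUPAC[p]:
            n += 1
    return n


def find_seed_site(region: UpstreamRegion, pattern: SeedPattern | None = None,
                   both_strands: bool = True) -> SeedSite | None:
    """Locate the best seed-site window in an upstream region.

    Windows matching the degenerate pattern with at most ``max_mismatches``
    (counted at non-N positions only) are candidates. A candidate whose 3' end
    lies 3-6 nt upstream of an exact promoter-element occurrence is preferred;
    within the preferred class ties go to fewer mismatches, then to the window
    closest to the translation start, then + strand, then smaller offset.
    Returns None when no window fits the mismatch budget.
    """
    pattern = pattern or SeedPattern()
    i, L = pattern.length, len(region.sequence)
    if L < i:
        return None
    pe, (smin, smax) = pattern.promoter_element, pattern.spacer_range

    def candidates(seq, strand):
        for o in range(L - i + 1):
            window = seq[o:o + i]
            mism = _mismatches(window, pattern.pattern)
            if mism is None or mism > pattern.max_mismatches:
                continue
            anchored = any(seq[o + i + s: o + i + s + len(pe)] == pe
                           for s in range(smin, smax + 1))
            offset = o if strand == "+" else L - i - o
            # distance from the site's 3' edge to the translation start
            distance = L - (offset + i) + 1
            yield (not anchored, mism, distance, strand != "+", offset), \
                SeedSite(window, offset, strand, mism, anchored)

    pool = list(candidates(region.sequence, "+"))
    if both_strands:
        pool += list(candidates(reverse_complement(region.sequence), "-"))
    if not pool:
        return None
    return min(pool, key=lambda kv: kv[0])[1]


def build_pfm(sites: BindingSiteSet, pseudocount: float = 0.0,
              family_label: str = "") -> FrequencyMatrix:
    """Count-based PFM: f_N(j) = (count_N(j) + pseudocount) / (n + 4*pseudocount)."""
    i, n = sites.motif_length, len(sites.sites)
    counts = np.zeros((4, i))
    for s in sites.sites:
        for j, b in enumerate(s):
            counts[BASE_INDEX[b], j] += 1
    freqs = (counts + pseudocount) / (n + 4 * pseudocount)
    return FrequencyMatrix(freqs=freqs, n_sites=n, family_label=family_label)


def consensus(pfm: FrequencyMatrix, degeneracy_threshold: float = 0.5) -> str:
    """IUPAC consensus: the single nucleotide when its fraction exceeds the
    degeneracy threshold, else the code covering all nucleotides at >= 0.25."""
    out = []
    for col in pfm.freqs.T:
        top = int(np.argmax(col))
        if col[top] > degeneracy_threshold:
            out.append(BASES[top])
            continue
        present = frozenset(BASES[k] for k in range(4) if col[k] >= 0.25)
        out.append(IUPAC_BY_SET.get(present, "N") if present else "N")
    return "".join(out)


def footprint_family(regions: dict[str, UpstreamRegion],
                     pattern: SeedPattern | None = None,
                     min_genomes: int = 4,
                     both_strands: bool = True,
                     pseudocount: float = 0.0,
                     family_label: str = "") -> tuple[BindingSiteSet, FrequencyMatrix]:
    """Footprint a family: one seed site per genome, assembled into a PFM.

    Genomes in which no window fits the mismatch budget are logged and
    excluded; fewer than ``min_genomes`` surviving sites is an error.
    """
    pattern = pattern or SeedPattern()
    sites, prov, failed = [], [], []
    for genome_id in sorted(regions):
        region = regions[genome_id]
        hit = find_seed_site(region, pattern, both_strands=both_strands)
        if hit is None:
            failed.append(genome_id)
            continue
        sites.append(hit.sequence)
        prov.append((genome_id, region.gene_id, hit.offset, hit.strand))
    if failed:
        logger.warning("no seed site in %d genome(s): %s", len(failed), ", ".join(failed))
    if len(sites) < min_genomes:
        raise MotifError(
            f"only {len(sites)} genomes yielded a seed site (min {min_genomes}); "
            f"failing genomes: {', '.join(failed) or 'none'}"
        )
    site_set = BindingSiteSet(sites=sites, provenance=prov)
    return site_set, build_pfm(site_set, pseudocount=pseudocount, family_label=family_label)


# ---------------------------------------------------------------------------
# I/O: aligned-FASTA site sets and 4-row TSV matrices

def write_site_fasta(sites: BindingSiteSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        prov = sites.provenance or [("", "", 0, "+")] * len(sites.sites)
        for s, (g, gene, off, strand) in zip(sites.sites, prov):
            fh.write(f">{g}|{gene}|{off}|{strand}\n{s}\n")


def read_site_fasta(path: str | Path) -> BindingSiteSet:
    sites, prov = [], []
    header = None
    for line in open(path):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            header = line[1:]
        else:
            sites.append(line.upper())
            parts = (header or "|||+").split("|")
            parts += [""] * (4 - len(parts))
            prov.append((parts[0], parts[1], int(parts[2] or 0), parts[3] or "+"))
    return BindingSiteSet(sites=sites, provenance=prov)


def write_pfm_tsv(pfm: FrequencyMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#n_sites={pfm.n_sites}\tfamily_label={pfm.family_label}\t"
                 f"max_attainable={pfm.max_attainable!r}\n")
        fh.write("base\t" + "\t".join(str(j + 1) for j in range(pfm.length)) + "\n")
        for k, b in enumerate(BASES):
            fh.write(b + "\t" + "\t".join(repr(float(x)) for x in pfm.freqs[k]) + "\n")


def read_pfm_tsv(path: str | Path) -> FrequencyMatrix:
    n_sites, family = 0, ""
    rows = {}
    for line in open(path):
        line = line.rstrip("\n")
        if line.startswith("#"):
            for kv in line[1:].split("\t"):
                k, _, v = kv.partition("=")
                if k == "n_sites":
                    n_sites = int(v)
                elif k == "family_label":
                    family = v
        elif line and not line.startswith("base\t"):
            parts = line.split("\t")
            rows[parts[0]] = [float(x) for x in parts[1:]]
    freqs = np.array([rows[b] for b in BASES])
    return FrequencyMatrix(freqs=freqs, n_sites=n_sites, family_label=family)
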