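"""Synthetic bacterial genomes, planted binding sites and homology-hit tables.

The generator emulates the statistical structure the comparative analysis
assumes, at desk scale: i.i.d. background sequence with configurable GC
content, CDS features laid out on both strands, binding sites sampled
position-wise from a planting frequency matrix and written into the upstream
window of chosen leader genes, an anchor construct (a glnRA-like operon whose
promoter region carries a conserved TGTNA-N7-TNACA site 3-6 nt upstream of a
TTGAC element) present in every genome, and outfmt-6 hit tables whose
in-group/background e-values are log-uniform in disjoint decades. Every draw
flows from one integer seed, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import GeneFeature, GenomeRecord, reverse_complement, write_genome
from .motif_builder import (BASES, DEFAULT_SEED_CONSENSUS, FrequencyMatrix)

MOTIF_LENGTH = len(DEFAULT_SEED_CONSENSUS)

TRUTH_COLUMNS = ["genome_id", "gene_id", "site_seq", "offset",
                 "distance_to_start", "strand", "family"]


DEFAULT_SPACER_CONSENSUS = "ATAAATATT"  # one base per N position, AT-rich


def default_planting_pfm(consensus: str = DEFAULT_SEED_CONSENSUS,
                         defined_fraction: float = 0.95,
                         spacer_fraction: float = 0.85,
                         spacer_consensus: str = DEFAULT_SPACER_CONSENSUS
                         ) -> FrequencyMatrix:
    """Sharp planting matrix over a degenerate consensus.

    Defined (non-N) positions put ``defined_fraction`` on the consensus base;
    N positions put ``spacer_fraction`` on an AT-rich spacer consensus; the
    remainder is split evenly. The defaults mirror real orthologous anchor
    sites, which are conserved essentially across the whole 17-mer (spacer
    included, by shared descent), with only occasional per-species deviations.
    A ``spacer_fraction`` of 0.25 gives an uninformative (uniform) spacer.
    """
    n_pos = [j for j, c in enumerate(consensus.upper()) if c == "N"]
    if len(spacer_consensus) != len(n_pos):
        raise ValueError(f"spacer_consensus must cover the {len(n_pos)} N positions")
    cols, si = [], 0
    for c in consensus.upper():
        if c == "N":
            b, q = spacer_consensus[si], spacer_fraction
            si += 1
        else:
            b, q = c, defined_fraction
        col = [(1 - q) / 3] * 4
        col[BASES.index(b)] = q
        cols.append(col)
    return FrequencyMatrix(freqs=np.array(cols).T, n_sites=0,
                           family_label="planting")


def sample_site(pfm: FrequencyMatrix, rng: np.random.Generator) -> str:
    """Draw one site position-wise from the matrix columns."""
    return "".join(BASES[rng.choice(4, p=pfm.freqs[:, j] / pfm.freqs[:, j].sum())]
                   for j in range(pfm.length))


@dataclass
class SimulationSpec:
    """The stated world of one synthetic genome (or of each panel species)."""

    seed: int = 0
    n_genomes: int = 1
    genes_per_genome: int = 40
    gene_length: tuple[int, int] = (300, 900)
    intergenic_length: tuple[int, int] = (150, 400)
    gc_content: float = 0.40          # low-GC Gram-positive background
    planting_pfm: FrequencyMatrix | None = None
    planted_fraction: float = 0.0
    planted_targets: list[int] | None = None   # gene indices to plant
    position_range: tuple[int, int] = (20, 200)  # site 3' edge distance to start
    strand_choice: str = "coding"     # "coding" | "random"
    anchor: bool = True
    strand_pattern: str = "alternating"  # "alternating" | "forward" | "random"
    window: int = 250

    def __post_init__(self):
        if not (0 <= self.gc_content <= 1):
            raise ValueError("gc_content must be a fraction")
        if not (0 <= self.planted_fraction <= 1):
            raise ValueError("planted_fraction must be a fraction")
        if self.strand_choice not in ("coding", "random"):
            raise ValueError("strand_choice must be 'coding' or 'random'")
        if self.strand_pattern not in ("alternating", "forward", "random"):
            raise ValueError("unknown strand_pattern")

    def pfm(self) -> FrequencyMatrix:
        return self.planting_pfm or default_planting_pfm()


class PlantingError(RuntimeError):
    """Raised when a site cannot be placed without collisions."""


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _layout(spec: SimulationSpec, rng: np.random.Generator):
    """Gene coordinates/strands; the first and last gap leave room for the
    full upstream window so anchor regions are never truncated."""
    genes = []
    cursor = 0
    for k in range(spec.genes_per_genome):
        gap = int(rng.integers(spec.intergenic_length[0], spec.intergenic_length[1] + 1))
        if k == 0:
            gap = max(gap, spec.window + 10)
        length = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
        if spec.strand_pattern == "alternating":
            strand = "+" if k % 2 == 0 else "-"
        elif spec.strand_pattern == "forward":
            strand = "+"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        if spec.anchor and k == 0:
            strand = "+"   # anchor operon laid on the forward strand
        cursor += gap
        genes.append((cursor, cursor + length, strand))
        cursor += length
    total = cursor + spec.window + 10
    return genes, total


def _write_window(codes: np.ndarray, gene: tuple[int, int, str], window_seq: str,
                  distance: int) -> tuple[int, int]:
    """Write a coding-orientation window whose 3' edge sits ``distance`` nt
    before the gene start; returns the genome interval occupied."""
    s, e, strand = gene
    i = len(window_seq)
    if strand == "+":
        gs = s - distance - i + 1
        out = window_seq
    else:
        gs = e + distance - 1
        out = reverse_complement(window_seq)
    ge = gs + i
    if gs < 0 or ge > len(codes):
        raise PlantingError("window outside the contig")
    codes[gs:ge] = [BASES.index(b) for b in out]
    return gs, ge


def _gap_before_start(genes, k, total) -> int:
    """Free intergenic space directly upstream of gene k (coding orientation)."""
    s, e, strand = genes[k]
    if strand == "+":
        prev_end = genes[k - 1][1] if k > 0 else 0
        return s - prev_end
    nxt_start = genes[k + 1][0] if k + 1 < len(genes) else total
    return nxt_start - e


def simulate_genome(spec: SimulationSpec, genome_id: str = "synth",
                    rng: np.random.Generator | None = None
                    ) -> tuple[GenomeRecord, pd.DataFrame]:
    """One synthetic genome plus the truth table of its planted sites.

    Planted sites are sampled from the planting matrix and written into the
    upstream window of their target gene; overlapping placements are redrawn
    (error after 100 attempts). The anchor construct occupies gene 0.
    """
    rng = rng or np.random.default_rng(spec.seed)
    pfm = spec.pfm()
    genes, total = _layout(spec, rng)
    codes = _background(rng, total, spec.gc_content)
    occupied: list[tuple[int, int]] = []
    truth_rows = []

    def reserve(iv):
        for lo, hi in occupied:
            if iv[0] < hi and lo < iv[1]:
                return False
        occupied.append(iv)
        return True

    if spec.anchor:
        site = sample_site(pfm, rng)
        spacer = int(rng.integers(3, 7))
        promoter_distance = int(rng.integers(30, 61))
        block = site + "".join(BASES[c] for c in _background(rng, spacer, spec.gc_content)) \
            + "TTGAC"
        iv = _write_window(codes, genes[0], block, promoter_distance)
        if not reserve(iv):
            raise PlantingError("anchor block collision")
        # 3' edge of the 17-mer site itself: promoter element + spacer away
        dist = promoter_distance + len("TTGAC") + spacer
        truth_rows.append([genome_id, f"{genome_id}_g000", site,
                           spec.window - dist - pfm.length + 1, dist, "+", "anchor"])

    if spec.planted_targets is not None:
        targets = list(spec.planted_targets)
    else:
        pool = [k for k in range(spec.genes_per_genome) if not (spec.anchor and k == 0)]
        n = int(round(spec.planted_fraction * len(pool)))
        targets = sorted(rng.choice(pool, size=n, replace=False)) if n else []

    for k in targets:
        gap = _gap_before_start(genes, k, total)
        site = sample_site(pfm, rng)
        strand = "+" if spec.strand_choice == "coding" or rng.random() < 0.5 else "-"
        window_seq = site if strand == "+" else reverse_complement(site)
        placed = False
        for _ in range(100):
            d = int(rng.integers(spec.position_range[0], spec.position_range[1] + 1))
            if d + pfm.length - 1 > min(gap, spec.window):
                continue
            iv_probe = None
            s, e, gstrand = genes[k]
            if gstrand == "+":
                iv_probe = (s - d - pfm.length + 1, s - d + 1)
            else:
                iv_probe = (e + d - 1, e + d + pfm.length - 1)
            if not reserve(iv_probe):
                continue
            _write_window(codes, genes[k], window_seq, d)
            truth_rows.append([genome_id, f"{genome_id}_g{k:03d}", site,
                               spec.window - d - pfm.length + 1, d, strand,
                               f"fam{k:02d}"])
            placed = True
            break
        if not placed:
            raise PlantingError(f"could not place a site upstream of gene {k} "
                                f"after 100 attempts")

    contig = "".join(BASES[c] for c in codes)
    features = [GeneFeature(gene_id=f"{genome_id}_g{k:03d}", contig_id="chr",
                            start=s, end=e, strand=strand,
                            locus_tag=f"{genome_id.upper()}_{k:04d}")
                for k, (s, e, strand) in enumerate(genes)]
    genome = GenomeRecord(genome_id=genome_id, contigs={"chr": contig},
                          features=features)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return genome, truth


def simulate_genomes(spec: SimulationSpec) -> list[tuple[GenomeRecord, pd.DataFrame]]:
    """``spec.n_genomes`` independent genomes with per-genome child seeds."""
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_genomes)
    return [simulate_genome(spec, genome_id=f"synth{k:02d}",
                            rng=np.random.default_rng(streams[k]))
            for k in range(spec.n_genomes)]


def simulate_hit_table(n_in: int, n_bg: int,
                       in_log10_range: tuple[float, float] = (-120.0, -40.0),
                       bg_log10_range: tuple[float, float] = (-12.0, -6.0),
                       seed: int = 0, family: str = "fam",
                       path: str | Path | None = None) -> pd.DataFrame:
    """Outfmt-6 hit table with log-uniform e-values in two decades bands.

    In-group subjects are named ``g<k>|<family>_<k>`` so the genome encoding
    round-trips through the hit-table reader; alignment columns are dummies.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def add(prefix, count, lo, hi):
        exps = lo + (hi - lo) * rng.random(count)
        for k, x in enumerate(sorted(exps)):
            subject = f"{prefix}{k:03d}|{family}_{prefix}{k:03d}"
            rows.append([f"{family}_query", subject, 90.0, 100, 0, 0, 1, 100,
                         1, 100, float(10.0 ** x), 200.0])

    add("g", n_in, *in_log10_range)
    add("bg", n_bg, *bg_log10_range)
    df = pd.DataFrame(rows, columns=range(12))
    if path is not None:
        df.to_csv(path, sep="\t", header=False, index=False)
    return df


def simulate_species_panel(spec: SimulationSpec, n_species: int = 10,
                           shared_families: int = 12,
                           per_species_dropout: float = 0.0,
                           outdir: str | Path | None = None
                           ) -> tuple[dict[str, GenomeRecord], pd.DataFrame, dict]:
    """Multi-species panel with a shared planted regulon and a universal anchor.

    Family ``fam<j>`` is planted upstream of gene j in every species unless
    dropped out (per species, independently); the anchor family is never
    dropped, mirroring the universal regulator-autoregulation association.
    Returns (genomes, global truth table, gene->family mapping keyed by
    (genome_id, gene_id)).
    """
    if shared_families >= spec.genes_per_genome:
        raise ValueError("shared_families must be below genes_per_genome")
    streams = np.random.SeedSequence(spec.seed).spawn(n_species)
    genomes, truths, families = {}, [], {}
    for s in range(n_species):
        rng = np.random.default_rng(streams[s])
        genome_id = f"sp{s:02d}"
        keep = [j for j in range(1, shared_families + 1)
                if rng.random() >= per_species_dropout]
        gspec = replace(spec, planted_targets=keep, anchor=True)
        genome, truth = simulate_genome(gspec, genome_id=genome_id, rng=rng)
        genomes[genome_id] = genome
        truths.append(truth)
        # orthology in the panel is by gene index: gene j of every species is
        # one family — "anchor", a planted "famXX" or a background "bgXX"
        families[(genome_id, f"{genome_id}_g000")] = "anchor"
        for j in range(1, spec.genes_per_genome):
            fam = f"fam{j:02d}" if j <= shared_families else f"bg{j:02d}"
            families[(genome_id, f"{genome_id}_g{j:03d}")] = fam
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            write_genome(genome, outdir / f"{genome_id}.fna", outdir / f"{genome_id}.gff")
    truth = pd.concat(truths, ignore_index=True) if truths else \
        pd.DataFrame(columns=TRUTH_COLUMNS)
    if outdir is not None:
        truth.to_csv(Path(outdir) / "truth.tsv", sep="\t", index=False)
    return genomes, truth, families
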