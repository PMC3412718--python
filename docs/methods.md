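# Methods

## Model and procedure

The pipeline reconstructs a transcription-factor regulon comparatively, in
four stages.

**1. Genome model.** Genomes are multi-contig FASTA plus GFF3 CDS features.
Internally every coordinate is 0-based half-open on the forward strand; GFF3
I/O converts from/to 1-based closed. Operons are inferred with the standard
prokaryotic distance heuristic: consecutive same-strand, same-contig genes
with an intergenic gap ≤ 150 nt (configurable) are co-transcribed; the leader
is the 5′-most member on the coding strand. Upstream regions are the fixed
window (default 250 nt) before the leader's translation start, reported in
coding-strand orientation; the window is *not* clipped at the 3′ end of the
nearest upstream gene (published anchor alignments use fixed windows), and is
truncated only at contig edges. Two leaders arranged head-to-head around one
shared intergenic interval form a divergon; their windows may overlap.

**2. Phylogenetic footprint.** The anchor family's upstream regions (one per
genome) are searched for the degenerate seed pattern TGTNA-N7-TNACA, allowing
≤ 2 mismatches at the 8 defined (non-N) positions, on both strands (the
consensus is its own reverse complement). A window whose 3′ end lies 3–6 nt
upstream of an exact TTGAC occurrence is preferred — that is the biological
anchor geometry; remaining ties go to fewer mismatches, then proximity to the
translation start. One site per genome is collected (genomes with no window
inside the mismatch budget are logged and dropped; fewer than `min_genomes`
surviving sites is an error) and turned into a position frequency matrix
f_N(j) = count_N(j)/n. The pseudocount default is 0 so the matrix is the raw
site frequencies; a Laplace pseudocount is exposed for users scanning
taxonomically distant genomes.

**3. SMS scanning.** A window scores raw = Σ_j f_{w_j}(j); similarity =
raw/i; relative similarity = raw / Σ_j max_N f_N(j). N and any non-ACGT base
contribute 0. Both strands are scanned by default (the motif is
near-palindromic and divergon sites read in either orientation);
forward-only is available for exact-reproduction runs. Hits are ranked by
relative score, ties broken by smaller distance to start, then + strand, then
smaller offset, so rankings are reproducible. A region shorter than the motif
yields an empty result.

**4. Selection, ranking, conservation.** An operon is predicted when its best
upstream hit has relative similarity ≥ threshold and the whole site lies in
the upstream window. The threshold is ≥ 0.87 with the boundary *inclusive*
(the published cut-off is printed as a 2-digit percentage; float equality at a
printed cut-off is a convention choice, documented, not biology). The
stricter preset `high_confidence` (0.89) reproduces the conservative
single-genome analysis mode. Whitelisted loci — experimentally verified
distant sites — are rescanned with an extended window (default 600 nt); only
the distance criterion is relaxed, never the score. Scores are reported at 2
decimals and tied printed scores share the lower rank, matching how such
tables are conventionally printed. Associations are aggregated per ortholog
family; support ≥ `min_conserved_species` (default 3) marks an association
conserved. The source text uses both "more than three" and "at least three";
the default follows the latter and the knob is configurable.

Ortholog families come from 12-column tabular homology hits: membership is
e-value < 1e−30, and the log10 gap between the last included and first
excluded hit is reported. A gap below 15 orders of magnitude sets
`clean_separation = False` — a review flag, not a failure, because the
printed description of the separation rule is ambiguous about the inequality
direction; the implemented reading (≥ 15 orders between groups) is the only
one under which the groups are in fact separated. Exact 0.0 e-values are
stored as 1e−200 so log arithmetic stays finite.

## Synthetic data: what it emulates and what it does not

`synthetic_data` generates the statistical structure the analysis assumes:
i.i.d. background sequence at configurable GC (default 0.40, low-GC
Gram-positive), CDS features laid out on alternating strands (giving a
realistic mix of divergons and convergent pairs), binding sites sampled
position-wise from a planting PFM and written into upstream windows (3′ edge
uniform at 20–200 nt from the start), an anchor construct
(site + 3–6 nt spacer + TTGAC) upstream of gene 0 in every genome, and
hit tables with log-uniform e-values in disjoint decade bands. All
randomness flows from one integer seed; identical seeds give byte-identical
FASTA/GFF/TSV.

The default planting PFM puts 0.95 on the consensus base at the 8 defined
positions and 0.85 on an AT-rich spacer consensus at the 9 N positions. The
defined-position value mirrors the near-invariant anchor sites observed
across real species (occasional genomes deviate). The spacer value encodes a
real property of orthologous sites: they share descent, so their spacers are
largely conserved too, and regulon member sites share the same preferences.
This matters numerically: with an uninformative (uniform) spacer, a footprint
matrix built from only ~10 sites at pseudocount 0 has jagged spacer columns
whose maxima inflate the attainable score, and even consensus-perfect targets
with independent random spacers score only ~0.83 relative — below any useful
threshold. That bias is a genuine small-sample property of the relative-
similarity statistic, not an implementation artifact; it fades with more
footprinted genomes or a pseudocount. Uniform-spacer worlds remain available
(`spacer_fraction=0.25`) for studying exactly this effect.

What the generator does **not** emulate: Markov or repeat structure in the
background (the SMS statistic itself uses no background model, so nothing
richer is required for fidelity), indels/rearrangements, protein sequences,
or operon content variation across species (panel orthology is by gene
index). A green end-to-end test therefore establishes that the method
recovers planted truth under its own assumptions at desk scale — not
performance on real genomes, which additionally face promoter annotation
error and compositional heterogeneity.

## Numerical and design choices

- Matrix columns are validated to sum to 1 within 1e−9; `max_attainable` is
  computed once and cached.
- N bases in genomes never match a motif position (score contribution 0);
  windows containing N are rejected as footprint seeds.
- Seed-pattern matching counts mismatches only at defined (non-N) pattern
  positions; IUPAC codes are allowed in patterns, forbidden in site sets.
- Reported site offsets are always in region coordinates with strand
  recorded; `distance_to_start` runs from the site's 3′-most region position
  to the first base of the start codon (distance 1 = immediately adjacent),
  and the whole site must fit inside the window.
- Overlapping hits are all reported; prediction takes the best per operon,
  the full list stays in the scan TSV/BED output.
- Report writers sort on fixed keys and format scores at fixed precision, so
  reruns on identical inputs are byte-identical.
- Divergon logic annotates (both partners flagged) rather than filters: a
  repressor plausibly acts on one partner only, but deciding which one needs
  expression data that is out of scope here.
- An empty prediction is valid — some real species' regulons reduce to the
  anchor operon alone.

## Known limitations

- The footprint reconstructs what was originally a partly manual alignment
  step; it assumes the anchor site survives with ≤ 2 consensus mismatches per
  genome, and a genome whose site drifted further is dropped rather than
  rescued by eye.
- Relative similarity has no significance calibration (no p-values/E-values);
  thresholds are conventions carried by the config, and the small-sample bias
  described above means thresholds are not transferable between matrices
  built from very different numbers of sites.
- Ortholog grouping by e-value gap assumes a single-representative query per
  family and cannot resolve families that need tree-based analysis; matrix
  rows for such families accept externally curated membership.
- Conservation support counts treat genomes as independent; phylogenetic
  correlation between close strains is not corrected for.
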