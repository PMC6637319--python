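# Methods

qcblind screens a bacterial sequencing run for contamination without any
reference genome.  The only biological prior it needs is a handful of
clade-specific marker genes of the target species.  This note documents the
model behind each stage, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the numerical
choices a maintainer would want to know about.

## Pipeline model

The pipeline assumes a single target species per run, mixed with an unknown
number of contaminant species, and proceeds:

1. **Trimming.** Leading/trailing bases with quality below a threshold
   (default phred 3) are removed base-by-base from each end; survivors
   shorter than `min_length` (default 50 bp) are discarded.  When either
   mate of a pair is discarded the whole pair is dropped — the assembler and
   mapper downstream assume intact pairs, and the ledger arithmetic stays
   simple.  Adapter clipping and sliding-window trimming are out of scope.

2. **Assembly.** A minimal de Bruijn assembler for low-error reads:
   canonical k-mers (odd k, default 31) are counted over all reads; k-mers
   seen fewer than `min_count = 2` times are dropped (this purges singleton
   error k-mers when the substitution error model is enabled, and only trims
   the once-covered genome tips on clean data); maximal non-branching paths
   of the bidirected graph are emitted as unitigs in canonical orientation.
   k = 31 was chosen over small legacy values (e.g. 12) because k must
   exceed the log-scale uniqueness length of realistic genomes; it remains a
   flag.  Externally assembled contigs can be substituted for this stage and
   flow through everything downstream.

3. **Contig preparation.** Contigs are limited to the 1,000–10,000 bp
   window before binning: shorter contigs are removed (low-quality, low
   statistical weight), longer ones are cut into consecutive 10 kb pieces so
   each genome contributes many comparable observations.  An undersized tail
   (< 1 kb) is merged into the previous piece rather than dropped, so bases
   are conserved.  The lower cutoff is a flag (600 bp is a common
   alternative for other binning tools).

4. **Read mapping and coverage.** Reads are assigned end-to-end to contigs
   via exact 21-mer seeds at three read offsets on both strands, accepting
   the best placement with identity ≥ 0.95 (ties to the lowest contig id).
   Alignments onto the prepared pieces are *projected* from the unitig
   alignments through the fragmentation plan rather than re-mapped: a read
   survives iff its interval lies inside one piece.  For unambiguously
   mapping reads this is exactly equivalent to re-mapping (a test asserts
   it) at a fraction of the cost; reads straddling a cut are charged to the
   binning stage of the data-loss ledger.  Contig coverage is total aligned
   bases over contig length, one value per sample.

5. **Cluster count K.** K is the number of species-level groups and is
   fixed before binning, either manually or by a small-subunit rRNA
   similarity survey: reads aligning to a user-supplied rRNA FASTA at
   ≥ 0.95 identity over ≥ 90% of the read are tallied per taxon, and K is
   the number of taxa with ≥ `min_hits = 5` reads (single-read hits are
   almost always spurious).  Ties count for both taxa — K needs the taxon
   set, and double counting cannot shrink it.  Zero passing taxa degrades to
   K = 1 with a warning.

6. **Binning.** Each prepared contig is featurized as its canonical
   tetranucleotide frequency vector (136 dimensions after
   reverse-complement collapsing, +1 pseudocount, log) concatenated with
   log(depth + 1) per sample.  Features stay on their natural log scales;
   per-dimension z-scoring was deliberately rejected because it inflates
   all 136 composition dimensions to unit variance even when they carry
   pure sampling noise, which drowns a single coverage dimension — with
   z-scoring, two composition-identical genomes at 10X vs 100X are
   unclusterable (ARI ≈ 0); without it they separate perfectly.  PCA keeps
   the leading components explaining 90% of variance; a diagonal-covariance
   Gaussian mixture with exactly K components (best of 10 seeded restarts
   by log-likelihood) hard-assigns every contig by maximum responsibility,
   ties to the lowest cluster id.  Diagonal covariance is used because full
   covariance is unstable at desk-scale contig counts.  There is no
   "unbinned" category: the method's dichotomy is target vs everything
   else.

7. **Marker screening and rescue.** Marker genes are locally aligned to
   the prepared contigs by seed-and-extend (exact 15-mer seeds, ungapped
   x-drop extension with match +1 / mismatch −2, drop-off 20).  Hit
   significance follows the Karlin–Altschul form `E = K·m·n·exp(−λS)` with
   λ solved from `(1/4)e^λ + (3/4)e^{−2λ} = 1` (λ ≈ 1.333) and K = 0.621,
   n the total contig bases; hits are kept at E ≤ 1e−20.  Optional identity
   and length floors exist but are off by default — the e-value alone gates
   hits, as is conventional.  An external 12-column tabular hits file can
   replace the built-in aligner and is filtered at the same cutoff.  Every
   cluster with ≥ `min_markers = 1` distinct markers hitting its contigs is
   called a target cluster (several clusters can be called; a split target
   genome is still recovered).  All contigs of called clusters are target
   contigs; pairs with either mate's best alignment on a target contig are
   rescued, both mates emitted — mate rescue preserves genomic information
   at negligible specificity cost, and the evaluation formulas use
   alignment membership (not mate rescue), so the reported specificity is
   unaffected.  Zero called clusters is an explicit NO_TARGET outcome
   (CLI exit code 2), not an exception.

## Evaluation formulas

All metrics are ratios of integer counts × 100:

* **Purity** (per cluster, contig and read level): items of the dominant
  species over all items; the dominant species is the most frequent contig
  label, ties to the lexicographically smallest id; reads inherit their
  contig's label.  Tier counts at 100 / 90+ / 80+ are cumulative (a
  100%-pure cluster also counts in 90+ and 80+).
* **Target concentration** over truth-defined target clusters (clusters
  holding ≥ 1 truth-target contig); the distribution sums to 100%.  This is
  a different concept from the marker-identified clusters and is kept under
  a different name in code.
* **Sensitivity / specificity** at contig and read level: truth-target
  items inside marker-identified clusters over, respectively, all
  truth-target items present at this stage (labeled contigs; mapped reads)
  and everything inside those clusters.  Taking the denominator
  post-preparation isolates the binning+marker stages; the preparation
  losses are charged separately by the ledger.
* **Base coverage**: union length of rescued-read alignments on the target
  genome over genome length.  **Gene coverage**: genes overlapped ≥ 1 bp
  (configurable) by a target-contig alignment over all annotated genes.
* **Data loss**: the stage ledger records reads (total and truth-target)
  surviving raw → trim → assembly (mapped to unitigs) → binning (mapped to
  prepared pieces) → marker (on target contigs); marginal and cumulative
  losses are both derived, and marginal survivals multiply to the
  cumulative one by construction.

In simulated mode contigs are labeled by the majority species of their
mapped reads (ties lexicographic); in reference mode by their best
whole-contig alignment at ≥ 0.95 identity over ≥ 90% of the contig.
Unlabeled contigs are `UNKNOWN`.

## The synthetic-data generator

The simulator emulates the screening study design: one target genome plus
`n` contaminant genomes mixed at a chosen target read proportion, paired
120 bp reads from 200 bp fragments.  Genomes are i.i.d. random sequences at
controlled GC; contaminants alternate around the target's GC 0.5 with
pairwise gaps ≥ `gc_gap` (default 0.05).  Markers, gene intervals and
16S-like sequences are planted so every stage has recoverable truth, and
markers are re-drawn until they share no 15-mer with any contaminant genome
(so marker hits cannot seed off-target).

Two simulator conventions deserve a note:

* **Coverage** is the fold coverage of the combined genome pool: the pair
  count is `N = coverage · ΣL_i / (2 · read_length)`.  Each genome's
  realized depth is then `p_i · coverage · ΣL_i / L_i`.  This mirrors
  mixing independently simulated per-genome read sets at fixed proportions;
  defining coverage on a proportion-weighted pool instead would starve the
  target of depth at low proportions (≈ 1.3X at 5%) and make the design
  untestable.
* **Fragments** have constant length (no insert-size variance is modeled)
  and are drawn uniformly; a `tiled` mode lays fragments deterministically
  every `fragment_length` for determinism-hungry tests.  Fragments never
  cross the genome end (genomes are linear).

What the generator does *not* emulate — and hence what passing tests do not
show about real data: real genomic repeat structure and shared sequence
between species (random genomes are repeat-free at k = 31, so assembly and
mapping ambiguity are far milder than in vivo), quality-score-dependent
error profiles, indels and chimeras, GC-dependent coverage bias,
multi-sample designs (a single coverage column), and eukaryotic
contamination.  The substitution-only error mode exists for robustness
tests, not realism.

## Problem sizes

The standard desk-scale experiment (tests and `scripts/acceptance.py`) uses
a ~200 kb target (5 × 600 bp markers, 50 × 900 bp genes) with ten ~100 kb
contaminants at 50X pool coverage — about 250 k read pairs (~60 Mbp) per
proportion, four proportions, K = 11, binning seed 42.  One proportion runs
in about a minute and a half on one core.  Unit tests use a three-genome
community (~100 kb pool, GC gap 0.15, i.e. the "well-separated" regime) so
the full pipeline runs in seconds.

## Numerical choices and degenerate inputs

* k-mers containing N are skipped everywhere; k must be odd so no k-mer is
  its own reverse complement.
* Phred+33 only; qualities below `!` are a parse error, never re-encoded.
* Coordinates are 0-based half-open internally; GFF's 1-based closed
  convention is converted only at the file boundary (an involution).
* GMM ties (equal responsibility) go to the lowest cluster id; dominant
  species ties to the lexicographically smallest id; read-mapping ties to
  the lowest contig id — all for determinism.  `reg_covar = 1e-4` keeps the
  diagonal mixture away from singular components at small n.
* Empty clusters report purity as NA and count 0; an empty assembly, an
  empty hit list, and a no-target call are warnings or explicit outcomes,
  not exceptions; fewer prepared contigs than K is an error advising a
  smaller K.
* All randomness flows from explicit integer seeds (simulation seeds,
  binning seed); identical seed and config reproduce outputs byte for byte.

## Known limitations

The built-in assembler and mapper are exact-match tools for low-error
reads; at realistic error rates a production assembler/aligner should be
substituted via the external-contigs and external-hits entry points.  The
e-value's K parameter is the standard ungapped nucleotide constant, not
re-derived per scoring scheme.  Specificity of the whole method rests on
marker uniqueness: shared marker sequence between target and contaminants
would flag contaminant clusters, and nothing in a reference-free setting
can detect that.
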