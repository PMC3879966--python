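# Methods

## The problem

A conserved noncoding sequence (CNS) is a stretch of genome outside
annotated genes that stays recognizably similar across related species for
longer than neutral drift would allow — the standard proxy for a
cis-regulatory element. Calling CNSs between species separated by only
50–60 My is dominated by one confound: recently diverged neutral DNA is
still alignable. The package's answer, following the coding-calibrated
design it implements, is to let each lineage's own protein-coding genes set
the bar: a noncoding alignment qualifies only if it is at least as conserved
as an average coding gene of that lineage, over at least 100 bp.

## Threshold calibration (`calibrate`)

For the reference species and the most diverged lineage member, one-to-one
ortholog CDS pairs are locally aligned (`align`); per gene, the most
conserved local alignment passing the e-value filter contributes its percent
divergence (gap columns count as differences), and genes whose best
alignment covers <30% of the shorter CDS are excluded — mirroring how the
e-value filter suppresses spurious, high-variance alignments. The
**whole-coding threshold** is the mean of these per-gene divergences; its SD
and two stricter presets (mean − 1 SD, mean/2) are recorded. The **skip3
threshold** removes every third codon position (mostly synonymous, hence
fastest) from the positionally paired CDS, concatenates the remainder across
genes, and takes the position-wise divergence — always more stringent than
the whole-coding value when third positions evolve fastest. Sequences are
never re-aligned after base removal: deleting the same columns from an
in-frame pair preserves homology, and re-alignment would blur the statistic.
A report-only `divergence_stats` provides the D'Agostino–Pearson omnibus
normality test and coding-vs-noncoding t statistics; thresholds never depend
on them.

## Homology search (`align`)

Two engines share one surface. The internal engine seeds on exact 11-mers
(numpy; soft-masked and ambiguous bases never seed), requires two seeds per
diagonal band (two-hit triggering), clusters seeds, and runs exact local
dynamic programming (Biopython's C aligner) on the padded cluster segment —
a seed-and-extend design whose extension step is exact rather than X-drop,
so the admissibility property (≥0.95 of the full Smith–Waterman score on
≤10 kb inputs) holds with margin. The `blast` engine shells out to
`blastn -task blastn` and reconstructs per-column match strings from btop;
it is the practical choice above a few hundred kb. Default scoring is
match +1 / mismatch −2 / gap open −5 / gap extend −2 with Karlin–Altschul
λ=1.28, K=0.46 and an effective database size of 3×10⁹, so e-values are
comparable between engines. Percent identity is matches over all alignment
columns, gaps included; divergence = 100 − identity.

## CNS detection (`detect`)

Per partner species: hits whose reference interval is completely contained
in another's are discarded (the shorter one loses; exact ties resolve by
score, then subject start). Alignments that pass the threshold outright and
span ≥100 bp are kept whole; otherwise a sliding window of 100 alignment
columns marks every position covered by some window meeting the identity
threshold, runs of marked columns are trimmed so both ends are match
columns, mapped to reference coordinates, and dropped if shorter than
100 bp. Windows are measured in columns (the unit in which the identity
statistic is exact), and the trim prevents mismatch-padded ends.

Group-common CNSs are the base-level intersection of all members' merged
core tracks, minus exclusion tracks (coding exons, RNA genes, pseudogenes,
masked repeats), keeping fragments ≥100 bp. Group-unique CNSs subtract every
outgroup's conserved cores — each outgroup screened at its own calibrated
threshold where available, because per-lineage rate correction is the whole
point of calibrated thresholds. Duplicate flagging re-aligns each CNS
against its own genome and marks multi-copy when a second conserved core
≥100 bp exists at the lineage threshold away from the CNS's own locus.

A known boundary property of window-union cores: a window can pass while
straddling the element edge, extending the called core by up to
`window × (threshold_rate − element_rate) / (neutral_rate − element_rate)`
columns per side (≈37 at the whole-coding threshold, ≈6–10 at skip3, largely
independent of tree depth). Pipelines that need tight boundaries should use
the skip3 threshold; the planted-recovery checks do.

## Loss bookkeeping and trees (`phylo`)

Ancestral CNSs are rows of a presence matrix built on an outgroup-referenced
union of per-species conserved tracks (overlapping/adjacent hits merged); a
species is "present" on a row when its track covers ≥50% of the row's bases
(the conventional reciprocal-style default; configurable). Loss assignment
is Dollo: each row originated once, so each maximal clade whose leaves are
all absent receives one loss on its stem branch — provably the minimal
explanation, and verified against exhaustive search on every tree shape with
≤6 leaves. Loss is deliberately mechanism-agnostic: deletion and
divergence-past-threshold are both "absent".

Tree building stacks per-CNS reference-anchored alignments, drops every
column with a gap or ambiguity in any species, concatenates, and runs
canonical neighbor joining (Q-criterion, via scikit-bio) on p-distances
(JC correction optional; p-distance is the common NJ default for closely
related taxa). Bootstrap resamples columns with a fixed seed; support is the
fraction of replicate trees containing each bipartition of the main tree.

## Genomic context (`annotate`)

Location classes use fixed priority UTR > promoter > intron > intergenic
with any-base overlap; the promoter is the 1,000 bp upstream of a
transcript's TSS on its strand. Priority rather than overlap size decides
(a CNS touching a UTR by 20 bp and an intron by 80 bp is a UTR CNS); ties
across genes break by larger overlap then gene id, and between UTR classes
by larger overlap then 5′. Relocation counts compare class labels of
single-copy orthologous CNSs pairwise between species. Target genes minimize
the average of the two species' CNS–gene distances (edge-to-edge, 0 when
overlapping) among one-to-one ortholog pairs within 1 Mbp of the CNS in
both species. CNS–gene density correlation uses 1-Mbp windows stepped by
100 kbp, midpoint membership (avoids double counting across overlapping
windows), Pearson r over windows containing at least one CNS and one gene.
Enrichment is the exact binomial tail on term frequency among target genes
versus a background set, with the depletion tail reported separately.

## Positional signatures (`profiles`)

Conservation and GC profiles slide windows outward from just inside the CNS
edges through 1,500-bp flanks (50 bp / step 20 / inset 30 for conservation;
200 bp / step 10 / inset 50 for GC); point 0 is the central 100 bp.
Conservation is computed on a per-reference-position projection of the
pairwise alignment (match/mismatch/gap/unaligned; gaps count against
identity, unaligned windows are excluded from that window's mean and the
contributing count is reported, SEM uses contributing CNSs only). Windows
are defined on the reference strand regardless of gene strand. Excluding
unaligned windows conditions the far flank on alignability: beyond the
extension range of element-anchored alignments, only locally better-matching
flanks contribute, so the far-flank mean sits ~1–2 points above the true
neutral identity. The profile therefore decays from the CNS peak to the
neutral baseline and then drifts slightly upward — visible in profile
checks, and inherent to any aligned-windows-only flank statistic. SNP coverage
is variants per 100 bp per interval class, with control intervals
length-matched, chromosome-matched and rejection-sampled away from
masked/genic bases under a fixed seed. DAF polarization takes the ancestral
allele as whichever allele matches the outgroup (records matching neither
are excluded and counted), bins derived-allele frequencies at 0.1, and tests
lowest-bin excess in CNSs against the control proportion with an exact
binomial tail. Substitution polarity counts a site only when partner and
outgroup agree and the reference differs, so the change is placed on the
reference lineage; GC→AT versus AT→GC totals follow from the inferred
ancestral base. Multi-allelic records are counted once.

## The synthetic clade (`simulate`)

The generator evolves a single ancestral chromosome along a rooted tree
under Jukes–Cantor with per-site rate multipliers; all randomness flows from
one seed and identical configs give byte-identical outputs.

* **Genes** (default 30): three coding exons with 5′/3′ UTRs and two
  introns, both strands, CDS in frame. Codon positions evolve at
  `codon_rate_profile` (default 0.5/0.4/3.0) normalised so the fastest
  position — the third, mostly synonymous — runs at the neutral rate;
  positions 1/2 are then 6× and 7.5× slower. This places mean coding
  divergence at ≈0.43× neutral, the regime in which a coding-calibrated
  threshold is meaningful (coding more conserved than neutral noncoding).
* **Elements** (default 100, 150–400 bp) are planted in intergenic space and
  introns, evolve at `constrained_rate_factor` (default 0.1) times neutral,
  start at GC 0.42 (below the 0.50 background) and substitute toward an
  AT-rich equilibrium (GC 0.30) — old constrained elements are AT-enriched
  and keep decaying, which yields both the V-shaped flanking GC profile and
  a genuine GC→AT > AT→GC substitution excess (starting *at* equilibrium
  would balance the two fluxes by detailed balance).
* **Loss** events either excise the element below the loss branch
  (`deletion`) or release it to the neutral rate from that branch onward
  (`release`), the two biological loss processes.
* **Indels** (geometric length, mean 3 bp) are sampled along the root-to-leaf
  path length but applied at the leaves and only in background DNA, so
  shared internal-branch indels do not occur; this keeps every feature
  coordinate exactly trackable through a per-leaf offset map and confines
  alignment gaps to neutral DNA.
* **Masking**: output FASTA is soft-masked (lowercase) over gene exons and
  simulated repeat runs (~15% of background); masked bases never seed
  alignments and are excluded from CNS calls.
* **Variants** overlay the reference leaf: derived-allele frequencies follow
  a 1/i spectrum, damped by exp(−γf) (γ=6) at element sites to emulate
  purifying selection; with probability f the reference assembly carries the
  derived allele, and ~1% of outgroup alleles match neither allele, so
  polarization and exclusion rules are genuinely exercised.
* A **relocation** toggle moves a chosen element between intron and
  intergenic context in one leaf — a single-event stand-in for the gene
  restructuring that relocates real CNSs.

What the generator does **not** emulate: realistic repeat families,
recombination, rearrangements beyond the relocation toggle, selection
coefficients, context-dependent mutation, or assembly/annotation error.
Tests passing on this generator show the *pipeline arithmetic* is right
under a known model; they do not validate biological conclusions on real
genomes, where alignment quality and annotation completeness dominate.

## Problem sizes used in checks

The planted-recovery check runs five seeds of a 1-Mb, five-species clade
(three lineage members, two outgroups, 200 elements, constrained factor
0.1) with neutral p-distance ≈29% between members — comfortably above both
calibrated thresholds — and detects at the skip3 threshold, whose tighter
boundary slop is what makes base-level precision meaningful (see the
boundary note above). Threshold-ordering statistics use 100 two-species
seeds with 100 genes each; Dollo and NJ oracles enumerate all tree shapes
with ≤6 and ≤8 leaves respectively; profile and DAF checks use 300–400 kb
clades with 100–150 elements and, for DAF, ~20 variants/kb so that ≥500
variants fall inside elements.

## Numerical choices and degenerate inputs

Identity thresholds compare `matches ≥ (1 − divergence/100) × window`
exactly; window unions use cumulative sums, so implementation and
enumeration oracle agree bit-for-bit. E-values clamp to 0.0 on exp
underflow. Zero-column alignments, empty interval tracks, fewer than 2
usable genes, JC distances at p ≥ 0.75, <3 correlation bins, and
zero-variance t-tests all raise or flag rather than return silent defaults.
Containment ties: higher score, then lower subject start. NJ bootstrap
bipartitions are encoded canonically (side not containing the
lexicographically first taxon). Control-interval sampling retries up to
1,000 placements before logging a failure for that interval.
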