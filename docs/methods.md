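# Methods

orgkit reimplements, as one testable pipeline, the comparative analyses
commonly applied to plant organelle genomes: how repetitive each genome
is, how much DNA the nucleus shares with each organelle (and in which
direction it moved), whether any of that shared DNA forms large
contiguous insertions, which mitochondrial genes have been lost, split,
or pseudogenized, and whether a functionally transferred gene moved to
the nucleus once or repeatedly. This note records the models, the
defaults and their rationale, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Local alignment engine

All sequence comparison runs through one in-repo BLASTN-style engine:
exact word seeding, ungapped x-drop extension, then banded affine-gap
x-drop extension anchored at the seed, with per-diagonal seed skipping
and coordinate-level deduplication. Two presets mirror the two search
configurations the analyses need:

| preset | word | match/mismatch | gap open/extend | E cutoff | use |
|---|---|---|---|---|---|
| sensitive | 7 | +2 / −3 | 5 / 2 | 1e−6 | dispersed repeats within a genome |
| fast | 28 | +2 / −4 | 0 / 5 | 1e−6 | shared DNA between genomes |

The sensitive preset is the classic BLASTN default scoring at word size
7; the fast preset is MegaBLAST's default scoring (+1/−2, open 0,
extend 2.5) doubled to integers. The x-drop is 20·match by default.

E-values use the ungapped Karlin–Altschul theory, E = K·m·n·e^(−λS).
λ is obtained by root-finding on Σ pᵢpⱼ e^(λ·sᵢⱼ) = 1; K from the
lattice-case clump series σ = Σₖ (1/k)[P(Sₖ ≥ 0) + E(e^(λSₖ); Sₖ < 0)]
with K = δ·e^(−2σ)/(H·(1 − e^(−λδ))). For the two presets this
reproduces the published ungapped constants (λ = 1.33, K = 0.62 for
+1/−2; λ = 0.634, K = 0.41 for +2/−3). Applying ungapped constants to
gapped scores is a deliberate, conventional approximation: it shifts
every E-value by a scheme-wide constant and therefore moves only the
effective significance threshold, not the ranking of hits.

Word seeding is a heuristic, and on small problems we can afford not to
be heuristic: when m·n ≤ `exact_cells` (default 10⁶) and the search is
not a self-search, `align_pair` additionally runs an exact row-vectorized
Smith–Waterman pass per strand, so the top reported hit is guaranteed to
be the true local optimum. The vectorization resolves the horizontal gap
state by a prefix-maximum scan, which is exact because opening a gap
from a cell that itself ends in a horizontal gap is always dominated by
extending the existing gap.

Numerical/tie-break choices: equal-scoring cells resolve toward the
smaller query coordinate (row-major argmax); hits identical in
(query interval, subject interval, strand) are deduplicated keeping the
higher score; N never counts as a match and words containing N are not
seeded.

## Repeat content

The reported statistic is the percentage of a genome covered by the
union of tandem-array loci and dispersed-repeat hits, overlapping
regions counted once (the `IntervalSet` union is the single primitive
behind every such number in the package). Dispersed repeats come from a
self-search with the sensitive preset, dropping the trivial self-identity
and hits shorter than 31 columns ("larger than 30 bp"); no identity
floor is applied in repeat mode — every significant hit is retained.
Only query-side intervals are accumulated; since a self-search reports
each repeat pair in both orientations, the partner locus is covered by
the mirrored hit.

The tandem detector is a simplified reimplementation of the classic
period-scanning approach, calibrated to the conventional defaults
(match 2, mismatch 7, indel 7, minimum score 50, maximum period 500,
two-copy minimum): candidate periods come from dense runs in the lag-p
self-match profile seq[i] = seq[i+p], the consensus is the per-phase
majority base, scoring is against the repeated consensus (substitution
only, matching the generator's divergence model), the reported period is
minimized over rotations, and harmonic re-detections are resolved
greedily by score. It is deliberately not a bug-for-bug clone of any
external tool; on this package's synthetic material it recovers planted
arrays exactly and reports nothing on random sequence.

Known bias: alignment hits occasionally extend a few bases past a true
repeat boundary when flanking sequence happens to align at a small net
positive score. This is a property of maximal-scoring local alignment
itself — any BLAST-based repeat percentage carries it — and bounds the
recovery accuracy at roughly ±1 percentage point under the validation
conditions below.

## Shared DNA and IGT blocks

Shared DNA between two compartments is measured with the fast preset,
keeping hits with identity strictly greater than 90%, and reporting hit
count, mean identity, length summary (median of an even count is the
midpoint average), the overlap-excluded total on the query side, and the
GC of the query sequence under that coverage. Directionality is part of
the contract: swapping query and subject changes the merged total (the
coverage side changes) but not the hit count. For organelle-versus-
nuclear comparisons the organelle genome is the query; for the
organelle-organelle comparison the plastome is the query. GC content is
the diagnostic of origin: organelle-derived nuclear insertions retain
organelle-like GC (~45% mitochondrial against a ~33% nuclear
background), which is why the report computes GC over covered regions.
The alternative (subject-side GC) would measure the same regions on the
other genome; we report query-side and note the choice here.

Large putative insertions are found by chaining retained hits along each
nuclear sequence with an inter-hit gap of at most `max_gap_bp` and
keeping chains whose span reaches `min_span_kb` (default 100 kb).
`max_gap_bp` defaults to 10,000 — tolerant of post-insertion indels and
internal decay, yet below gene-scale spacing so unrelated short NUMTs do
not chain; the chosen value is echoed into every report. Blocks are
always labelled putative: a draft nuclear assembly can manufacture a
long organelle-like block, and distinguishing genuine insertions from
assembly artifacts is out of scope.

## Gene status: loss, pseudogenization, fission, intron loss

A gene is located on a target genome by chaining sensitive-preset hits
of its reference CDS (same strand, gap ≤ 5 kb) and requiring at least
30% of the CDS aligned; below that the gene is called absent, which is
the expected signature of a complete, precise deletion. Equal-scoring
loci are flagged ambiguous.

Classification aligns the reference CDS to the extracted locus
(Bio.Align.PairwiseAligner, global mode with free end gaps on the locus
side) and canonicalizes every deletion by left-shifting gaps through
equal flanking bases, reporting coordinates in 1-based reference CDS
space. The decision logic is the fission model:

- deletion length ≡ 0 (mod 3): reading frame preserved — intact (minus
  codons);
- first frame-shifting deletion: translate the locus in the reference
  frame to the premature stop, then scan up to 200 bp downstream for a
  start codon (default set {ATG}, configurable to include GTG) sitting
  on a reference-frame codon boundary whose reading frame runs to the
  reference C-terminus without stops. Success is a fission event —
  two expressed ORFs — with `adjacent` true when both ORFs share the
  locus within 5,000 bp; failure is a pseudogene;
- premature stop without any frame shift (substitution-induced):
  pseudogene.

When conserved-domain intervals are supplied, a fission event also
reports whether any domain overlaps the deleted or untranslated
inter-ORF region — intact domains are the evidence that the two ORFs
remain functional rather than decaying. The premature-stop position is
checked in tests against an independent frame-by-frame translation scan.

Intron status aligns each flanking exon independently: an intron is
"lost" when the exons are contiguous in the target (gap ≤ 10 bp,
tolerating alignment-end wobble), "present" otherwise, "unknown" when an
exon cannot be located. Introns are named gene + "i" + the CDS position
of the last base of the upstream exon (e.g. a gene split after CDS
position 829 yields geneNamei829); this naming convention is an
assumption recorded here.

## Duplicate-copy phylogeny and transfer counting

Copies are labelled `taxon|mt` or `taxon|nuc[|chromosome]`; multiple
nuclear copies of one genome are distinct leaves. Distances are JC69 or
K2P with pairwise deletion of gap columns; saturated pairs are flagged
infinite and refuse tree building rather than silently clamping.
Trees are built with neighbor joining implemented in-repo: labels are
sorted first so exact ties in the Q criterion resolve independently of
input order; negative branch-length estimates are clamped to zero with
the deficit moved to the sister edge. Rooting uses the edge whose
bipartition separates the outgroup, placing the root at its midpoint.

Distance-based inference here replaces the ML stage a full study would
run through external software. That substitution is safe for the claims
the module makes — counting transfer events and contrasting rates are
topology- and depth-level statements, robust at these divergences — and
the model is configurable. Full ML/Bayesian inference and model
selection are non-goals.

The transfer count is the number of maximal nuclear-only clades on the
rooted tree. Because an organelle-to-nucleus transfer is not reversible,
this equals the Fitch parsimony minimum for the compartment character:
each maximal nuclear clade is one state change on its stem. Nuclear
copies falling in two separate clades — rather than one — is exactly the
signature distinguishing repeated independent transfers from a single
ancestral one.

Rate acceleration is the ratio of mean root-to-tip path length for
nuclear versus mitochondrial leaves, with a percentile bootstrap
(column resampling, default 1000 replicates, seeded) for the interval;
a single-leaf class is estimated but flagged. Bootstrap support for
internal edges counts bipartition recovery over the same kind of
replicates and is reproducible for a fixed seed.

## Synthetic data: what it emulates and what it does not

Every generator is seeded through one root `SeedSequence` with one
spawned substream per feature, so outputs are byte-identical for a given
recipe and adding a feature does not perturb the others. Every planted
feature writes a truth record with exact coordinates; detectors are
scored against truth, never against re-derived coordinates.

Defaults are the study conditions: organelle background GC 45%, nuclear
33% (the empirical contrast that makes GC diagnostic of origin);
divergence applied as an exact count of substitutions, no indels unless
requested, keeping truth coordinates exact; dispersed repeats planted as
a family of one unit re-sampled per copy; insertions copied from a real
generated organelle source with post-transfer divergence; coding lesions
planted into clean random CDSs (ATG + sense codons + stop). The fission
generator rejection-samples CDSs until the planted deletion genuinely
yields a premature stop plus a clean second ORF — the biological
precondition of fission — using direct translation bookkeeping that is
independent of the alignment-based detector it will be tested against.

Transfer scenarios graft, for each event, a rate-multiplied duplicate of
a species-tree clade at the top of that clade's stem, relabelled as
nuclear copies, then evolve sequences by per-site JC sampling along the
copy tree. The default species tree has two outgroup taxa and an
eight-taxon ingroup of balanced quartets with depths ≤ 0.15
substitutions/site, so a ×5 nuclear multiplier stays far from
saturation.

What passing these tests does not show: real organelle genomes
recombine, rearrange, and carry indels and mosaic repeats that the
substitution-only generator does not emulate; real nuclear assemblies
have gaps and collapsed duplications; real gene models have RNA editing
and trans-splicing (both out of scope). The synthetic suite validates
the *inference machinery* under known truth, not the biology of any
particular genome.

## Validation problem sizes

The test suite and acceptance script run, per seed: 200 random pairs up
to 300 bp against the exact-DP oracle; 20 repeat genomes of 10 kb with
5–20% planted content at up to 5% divergence; 5 kb insertion recovery in
60 kb chromosomes plus one 150 kb insertion in a 400 kb chromosome; 50
planted coding lesions (deletion lengths 1–79) with matched unmodified
loci; 20 transfer histories each for one and two events at 1,000 sites
plus three ×5-acceleration scenarios; and a double run of the full demo
pipeline compared byte-for-byte. These sizes are the package's chosen
validation scale; every stage accepts real full-size genomes through the
same interfaces.

## Known limitations

- Circular topology: region extraction supports origin wrap; the
  self-search operates on the linear representation, so a repeat copy
  spanning the origin may be undercounted (at organelle scale this is
  below 0.1 percentage points of repeat content).
- Gapped E-values reuse ungapped Karlin–Altschul constants (see above).
- The tandem detector's substitution-only scoring will fragment arrays
  with frequent indels.
- Repeat and shared-DNA boundaries carry maximal-local-alignment
  overhang noise of a few bases per hit end.
- `count_transfer_events` assumes compartment labels are correct and
  transfers are irreversible; a nuclear copy re-inserted into the
  organelle would be miscounted.
- Long-branch effects are only warned about (any branch exceeding 3× the
  median), not corrected.
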