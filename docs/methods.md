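# Methods

This note documents the models, estimators, parameter choices and known
limitations behind each wgdscape stage, in the order the pipeline runs them.

## Homology search

Candidate protein pairs are found by exact k-mer seeding (`k_seed`, default
4 at the module level; the pipeline uses 5 because the candidate set grows
quadratically with sequence length and, at ≥50% identity over 200+ residue
proteins, dozens of exact 5-mers are expected, so sensitivity is not
limiting).  Each candidate pair is scored with an exact Smith–Waterman
local alignment (BLOSUM62, gap open 11 / extend 1, Biopython's C aligner);
a score-only pass discards pairs below the e-value threshold before any
traceback is computed.  Percent identity is identities over alignment
columns (gaps included).

E-values are a surrogate: Karlin–Altschul with fixed λ = 0.267, K = 0.041
and a plain m×n search space — not NCBI-identical (no length or
composition corrections).  The contract is thresholding behaviour at
conventional cutoffs (identity ≥ 50%, e-value ≤ 1e-20), which is how the
downstream tandem and synteny stages consume hits.  Imported outfmt-6
tables take precedence over the internal search when provided; both enter
the pipeline through the same filtered-pair representation, with self-hits
removed and reciprocal duplicates collapsed to the better bitscore.

## Synteny

Anchors (homologous gene pairs indexed by gene *rank* — order along the
chromosome) are chained per chromosome pair by sparse dynamic programming:
chain score = Σ anchor bitscores − 1 per skipped rank on either axis;
consecutive anchors may not be separated by more than `max_gap` (default
25) ranks; same and inverted orientations are searched separately; the best
chain is extracted, its anchors removed, and the search repeated until no
chain of `min_anchors` (default 5) remains.  Ties prefer the predecessor
with the smaller b-side rank, making builds deterministic.  These defaults
are MCScanX-like conventions.

For self-comparisons, anchors are canonicalised so the lexicographically
smaller (chromosome, rank) end is always side a — removing diagonal
self-matches and mirror duplicates — and anchors within `tandem_exclusion`
(default 1) ranks on the same chromosome are excluded so tandem arrays
cannot masquerade as WGD blocks.

Syntenic depth counts, for every gene of a target genome, the number of
distinct blocks whose rank interval on that genome covers the gene; the
modal depth is taken over covered genes.  Against a relative that lacks the
focal lineage's WGDs, one WGD gives modal depth 2 and two WGDs give modal
depth 4; block rank-intervals (rather than per-gene anchor counts) make the
statistic robust to post-WGD gene losses inside blocks.

## Ka, Ks and 4dTv

Codon alignments come from global protein alignment (Needleman–Wunsch,
BLOSUM62, affine 11/1) back-translated to codons; gap columns and codons
containing N are dropped pairwise.

Ks and Ka use Nei–Gojobori (1986) counting: each codon position contributes
the fraction of its three possible changes that are synonymous (changes to
stop codons count as nonsynonymous); codons differing at several positions
average their synonymous/nonsynonymous differences over all minimal
substitution pathways, excluding pathways through stop codons (falling back
to all pathways if every one hits a stop).  Proportions are corrected with
Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is reported as saturated
(`None` plus a flag), never as 0.  NG86+JC was chosen over ML codon models
because it is deterministic, dependency-free, and accurate for peak-position
inference in the Ks ≤ 1 range where WGD dating happens; absolute Ks values
can differ from ML estimators by a few hundredths, which is why acceptance
tolerances on peak positions are ±0.04 or wider.

4dTv is the transversion proportion at third positions of aligned codon
pairs where both codons are fourfold-degenerate and share their first two
bases.  The correction is the transversion component of the HKY/TN93
distance, c = −2·πR·πY·ln(1 − raw/(2·πR·πY)), with purine/pyrimidine
frequencies pooled over the 4d third positions of both sequences; a
non-positive log argument is reported as saturated.

## WGD peak detection and dating

Ks values in the window (0.005, 2.0] — excluding allelic/assembly artifacts
below and saturation above; both bounds configurable — are log-transformed
and fitted with Gaussian mixtures (EM, 5 restarts from the given seed), k
selected by BIC over 1–4.  A fitted component (w, μ, σ) is reported as its
Ks-scale lognormal density mode exp(μ − σ²), matching what a peak in a Ks
histogram shows.  A kernel-density local-maxima list on the Ks scale is
emitted alongside as an estimator-independent cross-check.  Because σ
includes estimation noise, reported modes sit slightly below the true pair
divergence for short genes; at the 300-codon default this bias is ≲3% and
inside every tolerance used here.

Rate calibration: r = Ks_ortholog/(2T) with T the known outgroup divergence
time (default 36.4 MY).  The ortholog Ks statistic is the fitted mode by
default — robust to the tail — with a flag for the geometric mean.  Dates
follow as T = Ks_mode/(2r).  Pairs are assigned to WGD events by maximal
posterior responsibility under the fitted mixture; retained-gene counts per
event are distinct genes over assigned pairs.  Gene-set enrichment of
retained genes is a one-sided hypergeometric tail per user-supplied set with
Benjamini–Hochberg q-values; no pathway database is bundled.

## Tandem blocks and gene clusters

A homolog pair (identity ≥ 50%, e-value ≤ 1e-20) is tandem iff its genes
are rank-adjacent on one chromosome — "no other genes interspersed" read
strictly as rank distance 1.  Qualifying pairs merge transitively into
maximal blocks; block ranks are contiguous runs by construction, and
summaries report blocks, genes and percent of all genes.

The terpenoid cluster scan labels genes TPS / CYP450 / BAHD from a
user-supplied family map and finds maximal runs with ≤ `max_intervening`
(default 10) non-pathway genes between consecutive members and span ≤
`max_span_kb` (default 200).  The defaults are inferred from typical
plant terpenoid-cluster geometry and are configurable; the scan is a
transparent positional rule, not a biosynthetic-gene-cluster miner.
Cluster types: ≥3 families → mixed; TPS with CYP450 → TPS-CYP450; TPS with
BAHD → TPS-BAHD; otherwise ≥2 TPS → TPS-TPS.

## Coexpression modules and the gene–metabolite network

Expression is log2(x+1)-transformed throughout.  Modules are hierarchical
clustering (average linkage) on 1 − Pearson distance, cut to k = 5, each
module labelled by the tissue with the highest mean within-module
expression; zero-variance genes go to a sink module.  This is a transparent
stand-in for WGCNA: it reproduces the module count and tissue alignment
structurally but has no soft-thresholding or topological-overlap step, so
module boundaries on real, noisier data would differ.

Gene–metabolite edges are Pearson correlations over shared samples, kept iff
|r| strictly exceeds the cutoff (default 0.7; a pair at exactly 0.7 is
excluded) and signed.  Edges are exported as TSV and GraphML.  Correlating
over tissue means instead of replicate samples is supported by passing the
averaged matrix.

## k-mer survey

Canonical 17-mers (lexicographic min of k-mer and reverse complement,
odd k required) are counted with a vectorised 2-bit encoding.  The error
cutoff defaults to the first local minimum of the (smoothed) depth
histogram, kept only if it lies below the global peak so error-free
spectra are not truncated.  The homozygous peak is the smoothed global
maximum above the cutoff, unless a comparable peak sits near twice its
depth (het/hom pair), in which case the higher-depth peak is used.  Genome
size = total k-mers above the cutoff divided by a count-weighted centroid
of the hom-peak region (0.7×–1.5×, asymmetric because a Poisson-like peak
carries more mass above its integer mode; the het half-peak stays outside).
Note the peak depth is *k-mer* coverage, ≈ base coverage × (L−k+1)/L.
Heterozygosity is a rough areal estimate, h ≈ 1 − (1 − a)^(1/k) with a the
het-peak fraction of distinct k-mers — flagged experimental; no full
spectrum-model fit is attempted.

## Forward simulator

The simulator provides ground truth, and its defaults are the study
conditions: synonymous rate 6.59e-9 /site/year, WGDs at 29.6 and 6.9 MYA,
outgroup split 36.4 MYA, ts/tv ratio κ = 2, ω = 0.2, retention 0.7 per WGD,
300-codon genes (the organism's mean CDS is ~1100 bp), 200 genes per
chromosome on 2 chromosomes unless a config says otherwise.

Sequences evolve by per-site nucleotide events: attempts arrive at rate
`SYN_RATE_CALIBRATION · r` per site, the change is a transition with
probability κ/(κ+2), substitutions creating stops are rejected, and
nonsynonymous changes are accepted with probability ω (acceptance
thinning) — so the synonymous clock is exact by construction and only its
per-NG86-site normalisation needs calibrating.  NG86 counts synonymous
sites without transition weighting, so a transition-biased engine realises
more synonymous change per NG86 site than its attempt rate;
`SYN_RATE_CALIBRATION = 0.8872` rescales attempts so realised NG86+JC Ks
matches 2rt (within 2% over Ks 0.1–0.48; derivation in
`scripts/derive_sim_calibration.py`).

WGDs duplicate every chromosome at their event time; each duplicate gene is
retained independently with the retention probability, and losses close the
rank gap (no pseudogene placeholders, matching how annotations present).
Tandem events (Poisson over the run, uniform in time) insert a copy at an
adjacent rank.  The event ledger records every extant gene's root ancestor,
parent, origin and birth time, plus direct duplicate pairs and ortholog
pairs with their divergence times — the oracle for parameter-recovery
tests.  A snapshot of the lineage just before its first WGD (ids prefixed
`anc_`) supports the syntenic-depth signature test; the outgroup lineage
(ids `out_`) evolves from the common ancestor with no duplications.

What the simulator deliberately omits: indels within CDS, repeats and
transposons, rate variation among sites and lineages, gene conversion,
and expression evolution.  Passing tests therefore demonstrate estimator
correctness under clock-like, indel-free evolution with clean annotations —
not robustness to assembly artifacts or rate heterogeneity in real genomes.

Diploid read simulation plants heterozygous SNVs at a per-base rate on a
second haplotype and samples uniform error-prone reads; expression
simulation elevates each module's genes by `effect` log2-units in its home
tissue (5 tissues: root, stem, leaf, flower, glandular trichome) and builds
metabolites as ±(module mean profile) + Gaussian noise, so attractant-like
compounds covary with flower/trichome modules and repellent-like compounds
anti-covary — planted signed truth for the network stage.

## Pipeline

A single global seed fans out to per-stage seeds through a fixed affine
derivation.  Every stage writes a JSON manifest containing a hash of its
inputs and parameters; re-running with unchanged inputs loads the cached
result instead of recomputing.  The summary JSON (block counts, Ks modes,
dates, rate, tandem and cluster counts, signed edge counts, filter
pass/fail counts) is checked against a published key/type schema before it
is written.

## Problem sizes

Demo and test problem sizes are chosen so the full chain exercises every
code path at desk scale: 2 chromosomes × 120–200 genes (≈700–1100 genes
after two WGDs), 300-codon genes, 2,000 simulated pairs for peak-recovery
checks, 100–200 kb genomes at 25–60× for the k-mer survey.  At these sizes
the complete pipeline runs in well under a minute per stage on one CPU.
Genome-scale counts (tens of thousands of genes) are out of scope for the
bundled simulations and are not claimed to be reproduced.

## Known limitations

- NG86+JC underestimates Ks at high divergence relative to ML codon models;
  peaks beyond Ks ≈ 1.5 should not be dated with this tool.
- The mixture's reported mode carries the estimation-noise shrinkage
  described above; for very short genes (< 150 codons) the bias can reach
  5–10%.
- The e-value surrogate is uncalibrated against NCBI BLAST; use identity
  plus e-value jointly, as the defaults do.
- The cluster scan requires an external family map; no HMM-based family
  assignment is bundled.
- The heterozygosity estimate is areal and experimental; use a dedicated
  spectrum-model fitter for publication-grade values.
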