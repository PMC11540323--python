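# Methods

This note documents what each stage of the toolkit computes, the
parameters that matter, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Canonical k-mer features

Composition features are canonical tetranucleotide counts: each 4-mer
and its reverse complement share one key (the lexicographic minimum of
the pair), reducing 256 features to 136 and making a read and its
reverse complement identical feature vectors. With bases encoded
A=0 < C=1 < G=2 < T=3, lexicographic order equals numeric order of the
2-bit packed codes, so canonicalisation is `min(code, revcomp_code)`
and counting is a `bincount` over a precomputed code→column map.
k = 4 balances resolution against cost; the index supports k ≤ 8.

Sequences are uppercased on ingest and any character outside
{A, C, G, T} becomes N. Windows containing N are dropped from both
numerators and denominators everywhere, so counts remain interpretable
as frequencies. Counting is vectorised per record and streams through
the file: memory scales with the longest read, never the read count.
Reads shorter than k produce a zero row plus a flag and are excluded
from embedding rather than silently embedded.

Per-read GC content excludes N from both sides of the ratio. The
distinct-8-mer fraction (distinct noncanonical 8-mers over total
8-mer windows) separates reads that are abundant because their source
molecule is abundant from reads that are internally repetitive; k = 8
keeps 4^k above typical HiFi read lengths so the fraction can reach 1.

## Coverage from 31-mer multiplicities

A read's coverage is estimated as the *lower median* of the whole-set
occurrence counts of its canonical 31-mers. k = 31 is long enough that
a random 31-mer rarely recurs within a genome and short enough to
survive HiFi-scale error rates; the approach is unsuitable for noisy
uncorrected long reads, whose k-mers are mostly unique to their read.
k must be odd so no k-mer is its own reverse complement. The table is
a sorted array of 2-bit packed codes with counts capped at 2^16 − 1
(cap events are tallied and reported); lookups are binary searches.
The lower median makes even-window medians deterministic and
conservative. A read's own k-mers contribute to the table, so every
multiplicity includes a +1 self-count — negligible at assembly-grade
coverage, visible at very low coverage. Reads with no valid window are
flagged with 0.
Singleton k-mers (mostly sequencing errors) are kept by default; a
`min_count` filter is exposed.

The coverage histogram (distinct k-mers per multiplicity value) is
exact and conserves the table's distinct-k-mer total. Coverage bands
for cross-referenced plots are either manual closed intervals
(validated non-overlapping and ordered) or automatic decade bands.

## Coding density

Coding density is the ratio of predicted coding bases to read length.
Hexamers are scored at stride 3 within a frame (codon-aligned
dicodons) with score `ln f_c(h) − ln f_0(h)`, where f_c comes from a
pseudocounted frequency table trained on in-frame coding sequence and
f_0 is a mononucleotide product null. Two open points were resolved as
follows and are isolated behind single functions:

- **Composition control.** The null uses the *scanned strand's own*
  mononucleotide frequencies, not the training set's. This prevents a
  merely GC-shifted sequence from scoring as coding, and makes the
  density of a read exactly equal to that of its reverse complement
  (the reverse scan of one is the forward scan of the other).
- **Segments.** All maximal scoring segments per frame are found with
  the linear-time maximal-scoring-subsequence decomposition
  (Ruzzo–Tompa), JIT-compiled, and kept when their total score reaches
  the threshold (default 20, interpreted as a segment score). A
  segment's span in bases is (last hexamer start + 6) − (first hexamer
  start). Spans are summed over all three frames of both strands
  without merging, which is why densities may exceed 1.

Windows containing N receive a large negative sentinel so no segment
can absorb them. The table is trainable from any user-supplied coding
FASTA; tests and the bundled default use synthetic coding sequence
from the generator's codon model (below) — a synthetic stand-in for a
real coding-sequence reference, not an approximation of any organism.

## The β-VAE embedding

Counts are converted to per-read proportions and standardised per
column (zero-variance columns are centred only); the fitted scaler is
stored with the model so new reads are encoded on the same scale.
Encoder and decoder are mirrored fully connected ReLU networks
(136 → 150 → 150 → 2+2 and back). The encoder outputs the mean μ and
log-variance of a diagonal Gaussian posterior; training samples
z = μ + ε·σ and minimises

    per-feature mean squared reconstruction error + β · KL(q ‖ N(0, I)).

The KL term uses the closed form ½ Σ (μ² + σ² − 1 − ln σ²), checked
against Monte-Carlo estimation in the tests. On the per-feature-mean
scale the two loss terms are comparable at β ≈ 1, which is exactly the
regime where the posterior collapses onto the prior and the latents
stop carrying information — hence the default β = 0.1 and a loud
warning (not an error) for β ≥ 1. The collapse experiment in the test
suite runs both arms to near-convergence (120 epochs) because collapse
is an asymptotic property of the optimisation.

Optimisation is Adam (lr 10⁻³) with cosine learning-rate decay over
the run. The decay is functional, not cosmetic: with a constant step
size, Adam's normalised updates keep near-zero weights oscillating at
the step scale, leaving a spurious variance floor in μ that masks true
posterior collapse. Defaults: 15 epochs, batch 256, trained on CPU.
All randomness (init, shuffles, reparameterisation noise) derives from
one seed; a fixed seed reproduces μ bit for bit. Reads are embedded
with μ, never with sampled z — the means give sharper cluster
boundaries. Network sizes, β, epochs and batch size are configuration,
not constants.

The implementation is plain NumPy with hand-written backpropagation:
the model is two small fixed-topology MLPs, and a self-contained
implementation keeps the package dependency-light and bit-reproducible.

## Peaks and read sampling

The 2D histogram of μ uses 200×200 bins over the bounding box padded
by 1% per side (half-open bins, last bin closed). The value surface
for peak finding is lightly Gaussian-smoothed (σ = 1 bin, switchable
off) and then equalised by rank-transforming nonzero bins to a uniform
(0, 1] scale. Both steps are about robustness at realistic densities:
equalisation stops the target genome's huge clusters from dominating
the value range, and smoothing connects sparsely sampled cluster
fringes that would otherwise be isolated islands.

Peaks are births of connected components when sweeping the level from
high to low (union-find persistence, 8-neighbour connectivity);
persistence = birth − death, with components alive at the end dying at
level 0. Three filters apply, in order: minimum persistence (default:
the median nonzero bin value), a minimum read mass of 5 in the 5×5
neighbourhood of the birth bin (an isolated one-read bin is
topologically a strong peak but is noise, not a cluster), and
suppression of any candidate within window/2 Chebyshev bins of a
stronger peak (window default 20 — interpreted as a suppression
neighbourhood and exposed as a parameter).

For each peak, n reads (default 2) are sampled for external
spot-checking: reads strictly inside the smallest Chebyshev ring
containing n candidates are all taken and the remaining slots are
drawn uniformly (seeded) from the boundary ring. Sampling fewer reads
than requested is flagged, not an error.

## Synthetic mixtures

The generator emulates the sample structure the method targets: a
large heterogeneous low-coding host, compact coding-dense cobionts at
distinct GC and coverage, a tiny very-high-coverage organelle, trace
contaminants, and tandem repeat arrays. Components are simulated
~100× smaller than their real counterparts so end-to-end runs take
minutes; coverages stay realistic so coverage contrasts survive the
scaling. Reads per component = coverage × genome length / mean read
length.

- **Backgrounds** draw strong/weak (G+C vs A+T) states iid at the
  target GC — realised GC therefore concentrates tightly on target —
  with the base choice inside each group following a two-state chain
  whose repeat probability grows with the Markov order (short-range
  structure without disturbing GC). Heterogeneity = equal-length
  blocks with GC spread linearly across ± spread/2.
- **Coding blocks** are sampled as iid codons from a biased usage
  model: a single fixed lognormal codon-preference draw shared by all
  components (so coding sequence carries a common hexamer signature),
  multiplied by per-component GC base weights, with stop codons
  excluded and the effective base composition bisected until the
  usage's expected GC hits the component target. Blocks of ~0.3–3 kb
  are planted at codon stride to a target coding fraction, on either
  strand, with coordinates recorded.
- **Reads** are HiFi-like: truncated-normal lengths (default
  10 ± 1.5 kb), uniform circular start positions (uniform depth —
  exact for organelles and bacteria, a stated convenience for the
  host), random strand, substitution errors only (default 0.1%;
  indels are not modelled, as substitutions are what stress 31-mer
  counting at HiFi error rates). Every read has exactly one truth row
  (component, start, strand); ids are anonymised after interleaving.
- Per-component randomness derives from (seed, component name), so
  adding a component never changes another's reads.

What passing tests on these mixtures does *not* show: real insect
genomes have isochore-like structure, transposon landscapes and biased
error profiles that iid-GC backgrounds and substitution-only errors do
not reproduce; real coding sequence has amino-acid structure beyond a
biased codon usage; and real samples contain many more, less cleanly
separated components. The synthetic conditions test the machinery and
its contrasts, not field performance.

## Problem sizes used in tests and the acceptance script

The bundled mixed-sample scenario is host 300 kb @ 30×, endosymbiont
150 kb @ 120×, organelle 16 kb @ 2000×, contaminant 100 kb @ 3×
(~6,700 reads). The GC-gradient set is 8 components spanning GC
0.25–0.60 (~20,000 reads of 2 kb). The peak workflow uses 20 seeded
runs of a 3-component mixture (GC 0.25/0.40/0.55, ~2,000 reads of
2 kb each) — sizes chosen so a full run of everything completes in
minutes on one CPU while keeping every contrast at realistic strength.

## Numerical and degenerate-input conventions

- Lower median on even counts; first-index tie-breaks in segment
  extraction and peak ordering; deterministic rasterisation.
- Undefined statistics (GC of an all-N read, uniqueness of a too-short
  read) are NaN flags, never silent zeros; windowless reads get
  multiplicity 0 and band "outside".
- Quantile binning collapses duplicate edges (mass points such as the
  zeros of coding density) and reports the merge; an all-constant
  vector yields a single flagged bin.
- Scatter rendering aggregates points per pixel (majority category,
  log-density intensity, unassigned in gray) so arbitrarily large read
  sets render in memory bounded by the pixel grid.

## Known limitations

- Coverage estimates degrade on reads with error rates far above HiFi
  levels and on highly repetitive reads (the distinct-k-mer fraction
  exists to flag the latter).
- The hexamer scorer is a coding-density estimator, not a gene finder;
  its absolute scale depends on the training table.
- Persistence peak detection needs clusters to be denser than their
  surroundings after equalisation; diffuse low-coverage contaminants
  may not form peaks (by design, such components are still findable by
  coverage-range filtering).
- Two latent dimensions are a visualisation choice; components with
  near-identical tetranucleotide composition will overlap regardless
  of training.
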