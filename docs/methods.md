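# Methods

## Data model

A GAM experiment is summarized by a binary co-segregation matrix: rows
are fixed-width genomic bins (0-based half-open intervals; the last bin
of a chromosome may be short), columns are nuclear profiles (NPs), and an
entry is 1 when the bin's DNA was observed in that NP. Tables whose
entries are read counts are thresholded to `count > 0` with a warning:
the underlying model is binary detection. All frequencies are computed
over NPs: `f_A` is the per-bin detection frequency and `f_AB` the cis
co-detection frequency, so the raw contact value is the linkage
disequilibrium `D_AB = f_AB − f_A f_B`, bounded in [−0.25, 0.25] and
possibly negative.

Bins with `f_A ∈ {0, 1}` have an identically zero D row — they carry no
co-segregation information — and are flagged invalid in the matrix mask.
The dense computed matrix is kept in `ContactMatrix.data` (finite
wherever the formula is defined); `ContactMatrix.values` reports masked
rows/columns as NaN, and every normalizer operates on valid bins only and
emits NaN at masked bins. Normalization is per-chromosome (cis); trans
contacts are out of scope.

## Bias tracks

* **WDF** — row sums of the detection matrix (integer ≥ 0).
* **Fragment length** — per NP and per chromosome, detected bins are
  partitioned into maximal runs of consecutive bins; each bin receives
  the length of its containing run (0 when undetected), summed over NPs.
  Division by the NP count is deliberately omitted — it is common to all
  bins and cancels in any comparison. Runs never span chromosome
  boundaries (a cryosection fragment is a physical piece of one
  chromosome), and an undetected bin always splits a run, whatever the
  reason for non-detection.
* **GC content** — per-bin G+C fraction among non-N bases from a FASTA
  genome, case-insensitive; all-N bins are missing (NaN, written as the
  literal `NA`).
* **Mappability** — ingested as a bedGraph aligned to bin boundaries;
  track generation is out of scope.

## Normalization methods

All five methods assume the bias acts as a positive multiplicative
per-bin factor on D. Row norms use absolute values so the factor methods
are well defined on the signed matrix; every scale factor is therefore
positive and entry signs are preserved. Diagonal entries participate in
row norms and balancing.

* **NLD**: `D_AB / D_max` with
  `D_max = min(f_A f_B, (1−f_A)(1−f_B))` when `D_AB < 0` and
  `D_max = min(f_B(1−f_A), f_A(1−f_B))` when `D_AB > 0`. Output lies in
  [−1, 1]. The definition is silent at `D_AB = 0`; we output 0 there.
  Bins with `f ∈ {0, 1}` would give `D_max = 0` and are masked.
* **VC**: one pass of `D_ij / (e_i e_j)` with `e_i` the row 1-norm.
* **SCN**: the same form with row 2-norms; exactly one iteration by
  default (further iterations do not help on GAM data).
* **ICE**: iterate `D_ij ← D_ij / (e_i e_j)` with
  `e_i = ‖row_i‖₁ / mean(‖row‖₁ over nonzero rows)`; the convergence
  error is `max|e_i − 1|` per iteration (the standard criterion; the
  stopping rule only names an "error"), tolerance 1e−3, at most 100
  iterations. `max_iter = 0` returns the input unchanged with
  `converged = False`.
* **KR2**: `D₂ = D ∘ D` (elementwise square), `D₃ = KR(D₂)`
  (Knight–Ruiz balanced), `D_norm = D₃ ∘ sign(D)`. No square root is
  taken; the reported per-bin factor x is the balancing vector of D₂
  (the factor of |D| in the 2-norm sense would be its square root; we
  report the solver's x and document it here).

**Knight–Ruiz balancer.** Solves `diag(x) D x = e` on a non-negative
symmetric matrix by the inner–outer Newton scheme: each outer step solves
`(B_k + diag(B_k e)) y = (B_k + I) e` with `B_k = diag(x_k) D diag(x_k)`
by conjugate gradients, truncated by an adaptive forcing term
(η ≤ 0.1, safeguarded cone 0.1 ≤ y ≤ 3 per step), with initial x = e,
outer tolerance 1e−6 on `max|diag(x)Dx − e|`, and at most 300 outer
iterations. Non-convergence returns the best iterate with
`converged = False` and a warning, never silently. All-zero rows are a
structural error instructing the caller to mask them; the matrix front
ends drop masked/zero rows before balancing and reinsert NaN afterwards.

## Evaluation protocol

Bins are pooled genome-wide, sorted by a bias track (ties broken by
stable bin order for determinism) and split into 20 near-equal quantile
strata; cell (s, t) of the heat map is the mean cis contact over pairs
i ≠ j with i ∈ s, j ∈ t, both valid. A bias-free matrix yields a flat
map. The diagonal is excluded throughout: self-contacts equal
`f_A(1−f_A)` by construction and would dominate. Signed entries enter
means and correlations as-is.

The bias–contact correlation pairs each cis entry `D_ij` with the product
`b_i b_j` — the pairing implied by the multiplicative per-bin factor
model — and reports Pearson's r pooled over chromosomes; constant inputs
raise rather than silently returning 0. Cross-matrix comparison uses
Spearman (or Pearson) correlation over cis pairs valid in both matrices
with at least one nonzero entry. The WDF vs fragment-length comparison
runs a paired t-test and a Wilcoxon signed-rank test per chromosome on
the two tracks, reporting raw p-values (no multiplicity correction); an
all-zero difference vector is reported as degenerate, not raised.

## Simulator

Each chromosome is a fixed-bond random walk confined to a sphere
(rejection sampling of steps), one bead per bin. Each NP slices a
*freshly folded* nucleus — GAM takes one section per cell — with a slab
of uniformly random orientation and uniformly random offset within
[−R, R], so partial edge slabs occur naturally; a bin is detected iff its
bead is inside the slab and a Bernoulli(p_i) efficiency coin succeeds.
Ground truth is `1/(1 + d_ij)` on the model's own coordinates. Bias
injection shapes p_i: `uniform` (none), `linear_gradient` (p spans
[p₀(1−s), p₀] along the genome) or `gc_coupled` (affine in min–max
scaled GC). `random_cosegregation` additionally provides a structureless
two-state Markov generator with geometric fragment lengths for tests
that only need run-length structure.

Defaults: radius 1.0, bond length 0.08 (free-walk RMS ≈ radius, so a
chromosome explores the nucleus), slab thickness 0.3 (15 % of the
diameter), efficiency 0.8. At 400 NPs these give mean per-bin detection
frequencies around 0.09, the order observed in real 1-Mb GAM data.
Test and example problem sizes (120–200 bins, 300–400 NPs; 2000 bins for
the run-length tests) keep the whole suite in seconds while leaving
binomial sampling error well below the effects asserted.

What the simulator does **not** emulate: chromatin physics (loops,
compartments, territories beyond confinement), the wet-lab fragmentation
chemistry (fragments emerge geometrically as contiguous slab captures,
which is exactly what the fragment-length bias measures), amplification
or sequencing noise, and trans contacts. Passing tests therefore
demonstrate correct behaviour under a multiplicative detection-efficiency
bias on a distance-decaying contact structure, not performance on every
real-data pathology.

## Known limitations and observed behaviour

A *monotone* efficiency gradient along a single chromosome is a partly
pathological test condition: close cis pairs then have similar — and on
average higher — efficiency products, so the bias products correlate with
genomic-distance decay itself. Even an exactly balanced matrix (KR2
removes any multiplicative per-bin factor exactly) retains a structural
bias correlation of ≈ +0.12 under the default geometry, and VC
over-corrects (its row 1-norms embed the neighbourhood-average
efficiency, effectively dividing by the factor twice), which also costs
it some rank agreement with ground truth. When the same efficiency
values are scattered along the genome — as real WDF/GC/mappability
biases are — VC and KR2 reduce the bias correlation to |r| ≈ 0.02–0.05
and all five methods shrink it; the suite contains both conditions.
Pooling several separately normalized chromosomes mixes each method's
absolute-scale convention into cross-chromosome comparisons (ICE
preserves a per-chromosome mean scale, KR balances rows to exactly one),
which matters whenever a bias varies systematically *between*
chromosomes.
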