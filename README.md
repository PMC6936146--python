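# gamnorm

Bias quantification and normalization for **genome architecture mapping
(GAM)** contact matrices.

GAM is a ligation-free 3D-genome assay: thin slabs (*nuclear profiles*,
NPs) are cryosectioned at random orientations through hundreds of nuclei
and sequenced; loci that are close in 3D space co-segregate into the same
slab more often than chance. The data arrive as a binary co-segregation
matrix (genomic bins × NPs), and the raw contact value between two bins
A and B is their linkage disequilibrium over NPs,

    D_AB = f_AB − f_A · f_B,

where f_A is the fraction of NPs detecting A and f_AB the fraction
detecting both. D_AB may be negative. Raw GAM matrices carry four
systematic per-bin biases — window detection frequency (WDF), fragment
length, GC content and mappability — that must be removed before contacts
can be interpreted.

`gamnorm` is written for computational biologists working with GAM (or
GAM-like co-segregation) data. It provides:

* construction of raw cis contact matrices and segregation frequencies
  from co-segregation tables;
* the two detection-bias tracks: **WDF** (NPs detecting each bin) and
  **fragment length** (per NP, the length of the maximal run of
  consecutively detected bins containing the bin, summed over NPs), plus
  GC-content tracks from FASTA and bedGraph ingestion for external
  mappability/GC tracks;
* five normalization methods: **NLD** (D_AB divided by its sign-dependent
  theoretical maximum, bounded in [−1, 1]), **VC** (row 1-norm factors),
  **SCN** (row 2-norm factors, one pass), **ICE** (iterative mean-scaled
  1-norm factors, tol 1e−3, ≤100 iterations) and **KR2** — Knight–Ruiz
  balancing in the 2-norm: square the signed matrix elementwise, balance
  the square with an inner–outer Newton/conjugate-gradient Knight–Ruiz
  solver so that diag(x)·D·x = e, then restore the original signs;
* the evaluation protocol: 20-strata bias heat maps, Pearson correlation
  between contacts D_ij and bias products b_i·b_j, Spearman comparison
  against a second matrix (e.g. Hi-C), and paired t / Wilcoxon tests of
  WDF vs fragment-length bias;
* a geometric simulator (confined random-walk nuclei, random slab per
  nucleus, injectable per-bin detection efficiency) providing synthetic
  GAM experiments with known ground truth.

## Worked example

```python
import numpy as np, gamnorm as gn

binning = gn.GenomeBinning.single(3, resolution=1_000_000)
coseg = gn.CosegregationMatrix(
    binning, ("NP1", "NP2", "NP3"),
    np.array([[1, 1, 1],    # bin A1: in all three NPs
              [1, 0, 1],    # bin A2: in NP1 and NP3
              [1, 0, 1]]))  # bin A3: in NP1 and NP3

print(gn.window_detection_frequency(coseg).values)  # [3. 2. 2.]
print(gn.fragment_length_bias(coseg).values)        # [7. 6. 6.]

freqs = gn.segregation_frequencies(coseg, "chr1")
raw = gn.raw_contact_matrix(freqs)
print(round(raw.data[1, 2], 4))                     # 0.2222
```

A1 is detected 3 times, A2 and A3 twice each — the WDF track. A1 sits in
detected runs of length 3, 1 and 3 across the three NPs, so its
fragment-length bias is 7; A2 in runs of 3, 0, 3, giving 6. The raw
contact D(A2, A3) = 2/3 − (2/3)² = 2/9 ≈ 0.2222: the two bins
co-segregate more than independent detection would predict. A bin
detected in every NP (f = 1) carries no co-segregation information and is
masked.

The scripts in `examples/` extend this: `01_toy_biases.py` (the example
above), `02_normalization_methods.py` (five methods on a simulated
experiment; bias correlation drops from +0.36 raw to ≈0.03 after VC) and
`03_gradient_recovery.py` (Spearman agreement with ground-truth 3D
proximity, raw +0.57 → KR2 +0.59). A thin CLI mirrors the library:

```sh
gamnorm simulate --bins 60 --nps 80 --seed 3 --out coseg.tsv
gamnorm quantify-bias coseg.tsv --wdf-out wdf.bg --fragment-out frag.bg
gamnorm normalize coseg.tsv --method kr2 --out kr2.txt
```

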