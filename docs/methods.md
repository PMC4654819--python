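# Methods

## Problem setting

A polysome-profiling experiment sequences two RNA populations per cell
state: *total* cytoplasmic RNA (the transcriptome) and RNA from
sucrose-gradient fractions carrying two or more ribosomes (the
polysomal fraction, the translatome). With replicated libraries in two
states (case vs control; e.g. a tumoural and a non-tumoural breast
epithelial line), the ratio of polysomal to total abundance per gene
measures translational efficiency (TE), and its between-state fold
change identifies genes whose regulation is translational rather than
transcriptional. Because alternative transcription start sites (TSSs)
give one gene several 5′ transcript leaders (TLs) with different
regulatory content, the package also annotates leader features
(uAUGs/uORFs, Kozak context, cap proximity) and quantifies TSS-variant
usage separately in the two RNA populations.

## Normalisation

Depth is equalised by dividing each sample's counts by
`depth / min(group depths)`, computed independently for the total and
the polysomal libraries (the two fractions have systematically
different yields, so a common minimum would conflate fraction with
depth; a pooled `all` grouping is available for sensitivity checks).
Depth is the column sum of the supplied count table. Division is
deterministic and values stay fractional: stochastic sub-sampling or
re-rounding would break the exact conservation property (equal
within-group column sums) that the tests rely on, and adds variance
without adding information. The shallowest sample of each group is
returned bit-for-bit unchanged.

One consequence worth knowing: any *net* shift of translational
efficiency across many genes (e.g. an asymmetric set of planted
effects) changes the polysomal library depth and is absorbed into the
rescale factor, shifting every gene's Δ by the same constant. The
binned Z-score is invariant to such a constant (the bin mean absorbs
it), but absolute Δ values should only be compared within a run, or
against the unregulated background.

## TE and binned Z-scores

Per gene, replicate means give four expression values E[condition,
fraction]; genes with any zero cell are excluded by default (a zero
denominator has no defined TE; an optional global pseudocount is
provided instead of filtering, off by default because it fabricates
signal at the low end). Δ = log₂((E[case,poly]/E[case,total]) /
(E[ctrl,poly]/E[ctrl,total])). The log scale makes up- and
down-regulation symmetric, so swapping the condition labels negates
every Δ and Z exactly; a raw-ratio mode exists for sensitivity
analysis.

Genes are sorted ascending by their minimum of the four E values (ties
broken by gene id, so runs are bit-reproducible) and cut into bins of
300; a trailing remainder joins the preceding bin so no bin has fewer
than 300 genes and an unstable standard deviation. Z standardises Δ by
the bin mean and bin sd (denominator n−1), and strict |Z| > 2 calls
up/down. The null expectation for a Gaussian Δ is 2·Φ(−2) ≈ 4.55% of
genes beyond the threshold; simulated null data land at 4.3–4.5%.

Because each gene is standardised against *all* genes of similar
expression — including any truly regulated ones — a planted-effect
minority inflates the bin sd and caps sensitivity: with 5% of genes at
±2 log₂ units the bin sd rises from ≈0.64 to ≈0.78 and sensitivity at
|Z| > 2 settles at ≈0.79 (direction always concordant), versus ≈0.94 if
bins could be standardised against the null genes alone. This is a
property of the method, not a defect of the implementation.

## Leader annotation

Coordinates are 0-based half-open internally; reports are 1-based
inclusive. Sequences are canonicalised to uppercase DNA (U→T). Every
ATG strictly 5′ of the main start opens a uORF translated in its own
frame through the *full* transcript to the first stop (TAA/TAG/TGA):

* stop ends at or before the main start → **upstream**; `n_codons`
  counts sense codons including the initiator and excluding the stop
  (a minimal ATG-stop uORF is 1 codon), and `gap_to_main` is the
  nucleotides strictly between the stop and the main ATG;
* in frame with the main ORF and no stop before it → **in_frame_extension**
  (a potential N-terminal extension; its reading merges with the main
  ORF, so codon count and stop are not reported);
* otherwise → **overlapping** (out of frame, terminating inside or past
  the coding region, or never).

Nested uAUGs sharing a stop each get their own record. Kozak classes
use only the −3 and +4 positions (ideal (A/G)CCAUGG): strong = both
criteria, moderate = exactly one, weak = neither; positions off the
transcript ends pad with N, which satisfies neither. The three-class
scheme is deliberately coarse — literature descriptions like
"relatively strong" for ACCAUGC (purine −3, C at +4) fall in this
package's *moderate* class; the class boundaries are a labelling
convention, the context 7-mer is always reported alongside. uAUGs
closer to the cap than 15 nt (configurable) are flagged cap-proximal,
reflecting the scanning ribosome's poor recognition of starts within
roughly the first dozen nucleotides.

## TSS usage and gradients

Transcripts sharing a `tss_id` are pooled (splice variants from one
TSS share a leader); abundances are replicate-averaged per condition ×
fraction and converted to within-gene proportions. Single-TSS genes
carry no usage information and are excluded. Cells with a zero gene
total propagate as *undefined*, never as zeros. Differences between
fingerprints are scored with the Jensen–Shannon divergence (mixture
M=(p+q)/2, base-2 logs, hence bounded by 1); it is a transparent
descriptive score, not a calibrated test, so an optional permutation
test over replicate labels (add-one rule, p ≥ 1/(n_perm+1),
deterministic given a seed) provides uncertainty. Null permutation
p-values are verified super-uniform.

Gradient RT-PCR intensity vectors are normalised to unit mass;
`polysome_share` and `heavy_share` sum the mass over user-supplied
fraction masks. The disome boundary and the light/heavy split are
labelling choices of the experimenter, so masks are inputs, never
inferred.

## The simulator

`simulate_counts` emulates the profiled design: 3 biological replicates
× 2 conditions × 2 fractions; per-gene baseline means 2^N(6, 2²)
(median ≈64 counts, spanning single digits to tens of thousands, a
typical bulk RNA-seq spread at this depth); negative-binomial counts
with variance μ + φμ², φ = 0.1 (typical bulk overdispersion; φ = 0
gives Poisson); per-library depth factors uniform on [0.7, 1.4],
matching the roughly two-fold depth spread of real paired libraries.
TE effects are planted multiplicatively on the polysomal mean only
(total unchanged), on a 5% minority restricted to baselines ≥ 50, at
±2 log₂ units with random sign — so transcription and translation are
separable in the truth table. The generator does **not** emulate:
gene-length effects, GC/mappability bias, batch structure, correlated
replicates, or transcription-level differences between conditions
(which cancel in TE). Passing tests therefore demonstrate correctness
of the statistics under a clean NB world, not robustness to alignment
artefacts.

`simulate_transcripts` builds leaders on an ATG-free random background
(accidental ATGs are scrubbed by mutating a background base, never a
planted one) and plants non-overlapping upstream-class uORFs with drawn
codon counts; the planted coordinates are therefore the *exact* expected
annotation, which is what makes field-for-field recovery a meaningful
oracle. `simulate_usage` gives every gene 2–3 TSS variants with
Dirichlet(2) proportions; a planted subset draws independent polysomal
proportions ("differential recruitment"), and observed abundances are
NB around expression × proportion × library factor.

All three generators derive independent streams from one master seed
via fixed spawn keys, so identical specs are bit-reproducible and the
components never share randomness.

### Synthetic worked-example leaders

`translatome.synthetic_examples` constructs five stand-in leaders
(random backgrounds, published geometry) for TSS variants of 53BP1,
WNT5B and CLDN7: a 5-codon uORF ending 15 nt before the main start;
1- and 3-codon uORFs with a 62-nt gap and an ACCATGC main context; a
6-codon uORF 12 nt from the cap; a 902-nt uAUG-free leader; and a
50-codon uORF. They verify that the annotator reports exactly those
published metrics under this package's codon-count convention — the
convention (initiator counted, stop excluded) was fixed because it
reproduces those printed values.

## Problem sizes and numerical choices

Tests and the acceptance script run the full simulated design: 6000
genes × 12 samples for the TE stages, 1000 random + 500 planted
transcripts for the scanner oracle, 200 multi-TSS genes for usage, and
1000 null genes × 200 permutations for p-value calibration — the
complete analysis finishes in well under a minute. Conservation and
standardisation identities are asserted to 1e-9 (they hold to machine
precision); JSD cross-checks to 1e-10; proportions are validated to
1e-8 before divergence. Degenerate inputs fail loudly with the
offending record named: zero-depth samples, bins with fewer than two
genes or zero sd, all-zero gradient vectors, non-ATG start triplets.

## Known limitations

* The Z-cut is a ranking device, not a calibrated test: no replicate-
  level variance model, no multiple-testing correction.
* Whether fold changes should be Z-scored on the raw or log scale is
  ambiguous in the method's usual description; log2 is the default for
  its exact antisymmetry, with the raw mode behind a flag.
* Only AUG starts are scanned; near-cognate initiation, RNA structure,
  and IRES elements are out of scope.
* The JSD fingerprint score is descriptive; the permutation p-value
  permutes replicate labels and has very coarse resolution at n = 3.
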