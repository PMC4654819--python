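# translatome

Tools for comparing the transcriptome (total RNA) with the translatome
(polysome-associated RNA) of two cell states from bulk RNA-seq of
sucrose-gradient fractions, and for asking how 5′ transcript-leader (TL)
heterogeneity — alternative transcription start sites (TSSs), upstream
AUGs and uORFs, Kozak context — shapes what the ribosome actually
translates.

The package is aimed at groups running polysome-profiling RNA-seq
(paired *total* and *polysomal* libraries, replicated, in two conditions
such as a tumoural and a non-tumoural cell line) who want the complete
downstream analysis without read alignment: normalisation, differential
translational-efficiency calling, leader annotation, and TSS-usage
fingerprints — plus a ground-truthed simulator so every stage can be
validated end to end.

## The statistics at the core

**Depth equalisation.** Raw per-gene fragment counts are down-sampled by
a per-sample rescale factor

&nbsp;&nbsp;&nbsp;&nbsp;factor<sub>n</sub> = x<sub>n</sub> / min<sub>i</sub>(x<sub>i</sub>),

where x<sub>n</sub> is the total assigned fragments of sample *n* and the
minimum is taken within the total and within the polysomal libraries
separately. Division is deterministic; after it all samples in a group
have identical column sums and the shallowest library is untouched.

**Translational efficiency (TE).** For each gene, expression is averaged
over replicates to four means E[condition, fraction]; TE is
E[·, polysomal] / E[·, total], and the statistic of interest is

&nbsp;&nbsp;&nbsp;&nbsp;Δ = log₂( TE<sub>case</sub> / TE<sub>control</sub> ).

**Expression-binned Z-scores.** Because Δ is noisier for weakly expressed
genes, genes are sorted by their minimum expression over the four means
and grouped into bins of 300 (a trailing remainder is merged into the
last bin). Each gene's Z is Δ standardised by its bin's mean and
standard deviation (denominator n−1); |Z| > 2 (strict) calls the gene
translationally up- or down-regulated.

**Leader annotation.** Every upstream ATG in the TL opens a uORF that is
translated in its own frame to the first stop and classified *upstream*
(stops before the main start), *overlapping* (out of frame, runs into
the coding region), or *in_frame_extension* (in frame, no intervening
stop). Codon counts include the initiator AUG and exclude the stop.
Kozak context uses the −3/+4 rule (ideal (A/G)CCAUGG): *strong* = purine
at −3 and G at +4, *moderate* = exactly one, *weak* = neither. uAUGs
closer than 15 nt to the 5′ cap are flagged cap-proximal.

**TSS fingerprints.** For multi-TSS genes, transcript abundances are
pooled by TSS and converted to usage proportions per condition ×
fraction; total-vs-polysomal and case-vs-control differences are scored
with the Jensen–Shannon divergence (base 2, range [0, 1]) with an
optional replicate-label permutation p-value. Gradient RT-PCR intensity
vectors are normalised to distributions with polysomal/heavy mass shares.

## Worked example

```
python analysis/01_simulate.py
python analysis/02_normalize.py
python analysis/03_te_calls.py
```

which prints (seed 17):

```
simulated 6000 genes x 12 samples (300 with a planted 2.0-log2 TE shift)
...
total: column sums after down-sampling agree to 0.00e+00 relative
polysomal: column sums after down-sampling agree to 1.45e-16 relative
TE calls: {'unchanged': 5655, 'up': 185, 'down': 153, 'filtered': 7}
planted-effect sensitivity at |z|>2: 0.797 (239/300), direction concordance 1.000
false-positive rate among unregulated genes: 0.0174
```

300 of 6000 genes carry a planted 4-fold TE shift; the binned Z-score
recovers ~80% of them at |Z| > 2, always in the right direction, while
calling ~1.7% of unregulated genes (some of the 338 up/down calls are
those false positives, enriched by construction near |Z| = 2).
`analysis/04–06` annotate the simulated leaders (all 300 planted uORF
sets recovered exactly), rank planted TSS-usage shifts by JSD
(AUROC 0.90), and summarise example gradient profiles.

The same stages are available as a CLI:

```
translatome simulate --seed 17 --outdir sim/
translatome normalize --counts sim/counts.tsv --samples sim/samples.tsv --out norm.tsv
translatome te --normalized norm.tsv --samples sim/samples.tsv --out te.tsv
translatome annotate-tl --fasta sim/transcripts.fa --table sim/transcripts.tsv --out tl.tsv
translatome run --config run.yaml        # all stages + manifest.json
```

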