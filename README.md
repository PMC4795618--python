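# varthesaurus

Comparison of genetic variants in matched samples using **thesaurus
annotation**: a toolkit for detecting somatic and de novo point mutations in
the low-mappability (repeat-rich) fraction of a genome, where short reads
align ambiguously and conventional callers go blind.

## The problem and the approach

When a variant sits in a region whose sequence occurs elsewhere in the
reference, reads carrying the evidence scatter across the homologous loci.
The local allele frequency at site *i*,

```
AF_local(i) = m(i) / C(i)
```

(*m* = reads supporting the mismatch, *C* = coverage), is then diluted — a
heterozygous variant in a two-copy repeat shows up at ~0.25 at either locus —
and stringent mapping-quality filters remove the region from analysis
entirely.

A *thesaurus link* records that two loci are sequence-similar enough to be
indistinguishable to short reads. Links are symmetric and close transitively
into clusters. Writing T(*i*) for the set of loci linked to *i* (including
*i* itself), the thesaurus-adjusted allele frequency pools the scattered
evidence:

```
AF_thesaurus(i) = |T(i)| * (Σ_{j∈T(i)} m(j)) / (Σ_{k∈T(i)} C(k))
```

This restores a diluted heterozygous variant toward 0.5 (the value may
exceed 1 and is stored uncapped). Candidate sites from a case sample (tumor,
or child of a trio) are annotated with links discovered by a seed-and-extend
homology search over the reference; allele frequencies are then collected at
all linked loci **in every matched sample**, and transparent threshold rules
call mutations:

* **somatic**: tumor AF ≥ 0.15, tumor/normal fold change ≥ 1.2, normal
  AF ≤ 0.05 (or a single AF-difference rule, e.g. tumor − normal ≥ 0.2);
* **de novo**: child AF ≥ 0.3, both parents ≤ 0.02, parental coverage ≥ 10
  (father only on chrY); optional strand-bias (Fisher *P* < 0.06) and
  mismatch-load (mean NM > 6) read filters for noisy real data.

Benchmarking uses link-aware metrics: a call linked to a truth site is a
*thesaurus true positive* rather than a false positive, and

```
TPR = (AP − FN) / AP        FDR = (0.5 + FP) / (0.5 + FP + AP − FN)
```

where AP are the actual positives and the 0.5 smoothing keeps FDR strictly
positive.

The package ships a fully synthetic study system — repeat-bearing reference
genomes with a machine-readable repeat map, matched tumor/normal and trio
genomes, regular-interval error-free read pairs at exact coverage, and a
deterministic hermetic aligner that scatters multi-mapping reads across
repeat copies — so every claim is testable against known ground truth.
Everything consumes/produces standard formats (FASTA, FASTQ, BAM, VCF, BED,
TSV), so external aligners (e.g. `bwa mem ref.fa R1.fq R2.fq`) and variant
callers drop in for the built-in ones.

## Worked example

A complete matched-pair experiment on a 1 Mb genome with 10% two-copy
repeats (germline 1e-3/bp, somatic 5e-4/bp, 20× reads), analysed three ways:

```python
from varthesaurus.pipeline import run_pair_benchmark
from varthesaurus.benchmark import result_summary

run = run_pair_benchmark(seed=7, genome_size=1_000_000)
for name, key in [
    ("MQ16 local", "result_mq16_local"),
    ("MQ1 local", "result_mq1_local"),
    ("MQ1 thesaurus", "result_mq1_thesaurus"),
]:
    print(result_summary(name, run[key]))
```

prints

```
MQ16 local: AP=472 TP=426 TTP=0 FP=0 FN=46 TPR=0.9025 FDR=0.00117
MQ1 local: AP=472 TP=461 TTP=0 FP=38 FN=11 TPR=0.9767 FDR=0.0771
MQ1 thesaurus: AP=472 TP=471 TTP=46 FP=1 FN=0 TPR=1.0000 FDR=0.00317
```

Reading the three lines: conventional stringent calling (only reads with
mapping quality ≥ 16) recovers 90% of the 472 simulated somatic events —
the missing tail sits inside repeats, where it has no uniquely-mapped
coverage. Relaxing the threshold to MQ ≥ 1 recovers most of those but
admits 38 false positives (mismatch evidence mirrored at the wrong repeat
copy), inflating FDR to ~0.08. With thesaurus annotation the mirrored calls
become link-mediated true positives, the adjusted frequencies rescue the
diluted sites, and false discovery drops by more than an order of magnitude
while recall exceeds the stringent setting by ~10 percentage points.

The same analysis is scriptable step by step from the shell
(`varthesaurus simulate pair`, `screen`, `thesaurus`, `annotate`,
`call somatic`, `benchmark`); see `varthesaurus --help`.

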