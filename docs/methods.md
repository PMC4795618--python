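# Methods

This note documents the models, algorithms, parameter choices and known
limitations of varthesaurus, in the order the pipeline runs.

## Synthetic study system

**Reference genomes.** `build_repeat_reference` draws i.i.d. uniform
nucleotides and overwrites selected intervals so that a chosen fraction of
bases lies in families of exact sequence copies. Interval slots sit on a
uniform grid (no overlap by construction) and are assigned to families by a
seeded permutation, scattering the copies of each family across the contig.
The default copy length is 1000 bp per unit — long against the 100 bp read
window, so repeat interiors are genuinely multi-mapping, while a 1000 bp
unit still divides typical desk-scale genome sizes into integer family
counts. The repeat map (source interval, copy intervals, copy number) is
retained on the genome object and exported as BED; it doubles as an exact
coordinate-transfer oracle for testing homology search.

**Sample genomes.** Variants are inserted by independent per-base Bernoulli
draws (rates are specified as probabilities, not counts; tests therefore use
binomial tolerances). Heterozygous events land on one uniformly chosen
haplotype (expected AF exactly 0.5), substituted alleles are uniform over
the three non-reference bases, and a position already carrying a recorded
variant is skipped and logged, so somatic events never overwrite germline
ones. Standard conditions: diploid genomes; germline heterozygous variants
at 1e-3/bp; somatic at 5e-4/bp on a copy of the normal genome; trio parents
built independently at 1e-3/bp, the child receiving one randomly chosen
haplotype per contig from each parent plus de novo heterozygous events at
1e-4/bp. Insertion does not avoid repeat boundaries or any other feature;
collisions are only logged.

**Reads.** 2 × 100 bp mates are the first and last 100 bp of a 400 bp
fragment ("400 bp insert" is read as the outer fragment span, the common
usage that keeps placement arithmetic exact). Per haplotype,
`n = round(L · coverage / (2 · read_length · ploidy))` fragment starts are
spread evenly over the valid range, with haplotype *h* phase-shifted by
*h/ploidy* of one step so diploid coverage interleaves; mean coverage is
exact by construction and positional coverage is uniform away from contig
ends. Base errors default to 0. Mixtures draw each pair from the tumor
collection with probability equal to the purity. What this generator
deliberately does **not** emulate: coverage dispersion and GC bias,
sequencing errors and quality variation, indels and structural variation,
inverted or diverged repeats. Passing benchmarks therefore demonstrate the
mappability mechanics in isolation — detection failures in these data are
attributable to mappability alone — and say nothing about robustness to
noise sources that real data add on top.

## Hermetic aligner

Downstream stages consume coordinate-sorted indexed BAM; any aligner can
produce it. The built-in aligner is specialised to the substitution-only
genomes above: each mate's true placement is known, and the aligner's job
reduces to deciding ambiguity. A read is ambiguous iff its reference window
occurs identically elsewhere in the reference; duplicate windows are found
with a 64-bit polynomial rolling hash and every candidate group is verified
base-by-base, so the decision is exact. Ambiguous reads are placed uniformly
at random (seeded) among the duplicate loci — reproducing how production
aligners scatter multi-mapping reads across repeat copies, which is the
mechanism that dilutes allele frequencies — and receive mapping quality 1;
unique reads are placed at their true locus with mapping quality 40. The
binary MQ preserves the two standard operating points: min-MQ 16
("stringent") sees only unique reads, min-MQ 1 ("lenient") sees everything.
Mates are placed independently; NM tags carry the true edit distance at the
chosen placement. Only direct (same-strand) duplicates are detected, which
matches the generator's repeat structure.

## Pileups and candidate screening

`pileup_at_sites` counts, per site and sample: alt-supporting reads *m*,
total coverage *C*, stranded alt/ref counts, and the mean per-read mismatch
load (NM) of alt-supporting reads. Unmapped, secondary, supplementary and
duplicate-flagged reads are excluded from both *m* and *C*; reads spanning
the site with a deletion or reference skip are excluded from *C* so it
stays a substitution-informative denominator; mapping- and base-quality
thresholds remove reads from both counts symmetrically. The base-quality
default is 5 (synthetic data are error-free, so results are insensitive to
it). Coordinates are 1-based inclusive throughout the data model; BED
interfaces convert explicitly.

`scan_candidates` is the rudimentary screening caller that produces the
candidate VCF: one sweep over primary gapless reads, reporting sites with
≥ 2 supporting reads and local AF ≥ 0.05 at the requested MQ threshold. It
is deliberately permissive — final calling happens later — but, like any
screening stage, it bounds what annotation can rescue: a site with no
mismatch evidence in the case sample never becomes a candidate.

## Thesaurus links

Link discovery is a deterministic seed-and-extend homology search. The
candidate's flanking window (default 200 bp = 2 × read length, clipped and
flagged at contig ends) is seeded with exact 16-mers into a sorted 2-bit
packed genome index; candidate placements are verified by Hamming distance
(default budget 5% of the window) on both strands, reverse-strand hits
projecting the site through the reverse complement. Mismatches at positions
that are themselves candidates can be exempted from the budget so germline
variation does not sever true links. Hits are reported in (contig,
position, strand) order and capped.

When an alignment is available, a link is retained only if at least one
low-MQ (ambiguous) read covers the site or its alternative locus: ambiguous
reads are exactly the ones consistent with the alternative placement.
Candidate-to-candidate links are symmetrised, and clusters are the
union-find transitive closure over all involved loci. Per-site filter codes:
`thesaurus` (1..max_links links, default cap 100), `thesaurusmany` (over
the cap; the site keeps no links and is excluded from aggregation and
clustering), `thesaurushard` (flank extraction failed, e.g. shorter than a
seed). A negative-control generator reproduces the per-site link counts of
a real network with uniformly random target loci.

## Annotation

For every candidate the annotator collects pileups at the site and all its
linked loci, in the case sample and every matched sample, and reports both
frequency estimates per sample, plus the pooled cluster counts, link count,
filter code, and the stranded/mismatch statistics the read filters need.
Pileups for this pass default to min-MQ 0: evidence at alternative loci is
by construction low-MQ, so excluding multi-mapped reads would empty the
pooled sums. The adjusted frequency of an unlinked site equals its local
frequency exactly (same arithmetic expression); `thesaurusmany` and
`thesaurushard` sites get no adjusted value. Output: an annotated VCF
(original records preserved; only FILTER codes and the integer FORMAT field
`TS` carrying the per-site link count are added), the dedicated links file
(TSV: site, flag, link count, semicolon-joined `contig:pos:strand`
alternatives), and the AF table (TSV, one row per site, paired
`<sample>.af_local` / `<sample>.af_thesaurus` columns; missing values are
`.` in VCF and `NA` in tables). Annotation never drops a record — it is a
summary-statistics layer, not a call set.

## Calling

Thresholds are compared inclusively (≥ / ≤); a case AF exactly at the
threshold passes. Fold change with control AF 0 is +∞ and passes any
fold-change requirement. The AF source defaults to the thesaurus-adjusted
value where available, local otherwise; a flag selects pure-local calling.
`min_case_af` may exceed 1 because adjusted frequencies are uncapped and
threshold sweeps legitimately probe beyond unity. Criterion evaluation
order — flag exclusions, case AF, control AF, fold change/difference,
parental coverage, strand bias, mismatch load — affects only the
first-failure traces, never the final set. The parental-coverage rule
(default 10 reads, father-only on the contig named by `chr_y_label`)
belongs to the trio caller; the pair criteria carry no coverage term. The
strand-bias and mismatch-load filters target error-prone real data and are
not part of the synthetic benchmark conditions (they are exercised by unit
tests; note that on clean data a strand filter removes a few percent of
true heterozygous calls by chance alone).

## Benchmarking

Classification is position-level by default, since link projection can
change the reported allele across strands. A call matching truth both at
its own position and through a link counts once, as TP. Truth sites can be
rescued through links discovered from case candidates only; the resulting
asymmetry (a truth site that never became a candidate can still be credited
via a linked candidate) is inherent to link-aware evaluation. Two empty
call sets have Jaccard concordance 1.0 by definition; link-mediated
matching in the concordance metric is off by default.

## Benchmark scale and expectations

The standard scaled experiment uses a 5 Mb single-contig genome (10%
two-copy repeats), chosen so that each run holds a few thousand somatic and
a few hundred de novo events — enough to resolve TPR to about a percentage
point in minutes on one CPU. At this scale the stringent-local somatic and
de novo TPRs land near 0.9 (the undetectable mass is essentially the
repeat-interior fraction), thesaurus-assisted lenient calling recovers the
repeat events (≥ 5 percentage points over stringent local), and annotation
reduces lenient-regime FDR by over an order of magnitude relative to both
local calling and the random-link control. Absolute FDR values in the 1e-5
range are not resolvable here: they require on the order of 1e5 calls, so
the package asserts orderings, not absolute lenient-regime FDRs.

## Known limitations

* Substitutions only: no indels, no variants near structural breakpoints.
* Candidates missed by the initial screening stage cannot be rescued later.
* The homology search is a reconstruction of link discovery from first
  principles (seed-and-extend with Hamming verification); no claim is made
  that its link sets match any other implementation's site for site.
* The hermetic aligner models ambiguity as an exact binary and ignores
  mate-pair rescue; real aligners grade mapping quality continuously and
  can anchor a repeat-interior mate through its unique partner.
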