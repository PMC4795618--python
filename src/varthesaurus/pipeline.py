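"""End-to-end scaled benchmarks on fully synthetic matched samples.

These drivers reproduce the complete workflow at desk scale: build a
repeat-bearing reference, derive matched sample genomes, simulate and align
reads, screen candidates at stringent (min MQ 16) and lenient (min MQ 1)
mapping-quality settings, build the thesaurus network, annotate allele
frequencies, call mutations and benchmark against the known truth.

Default study conditions: a 5 Mb single-contig genome with two-copy repeat
families covering 10% of bases; heterozygous germline variants at 1e-3/bp;
somatic mutations at 5e-4/bp (pair) or de novo mutations at 1e-4/bp (trio);
error-free 2 x 100 bp pairs with 400 bp fragments at exactly 20x coverage.
The somatic rule is the AF-difference form (tumor - normal >= 0.2 with
normal <= 0.05); the trio rule is child AF >= 0.3, parents <= 0.02 with
parental coverage >= 10.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .align import align_and_write, build_duplicate_index
from .annotate import annotate_matched
from .benchmark import classify_calls
from .calling import call_denovo_trio, call_somatic, somatic_defaults, trio_defaults
from .links import build_network, generate_random_links
from .pileup import SiteKey, scan_candidates, write_candidate_vcf
from .synthetic import (ReadSimParams, build_repeat_reference, derive_child,
                        derive_tumor, insert_variants, mix_samples,
                        simulate_reads)

MQ_STRINGENT = 16
MQ_LENIENT = 1


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _sites(candidates) -> list[SiteKey]:
    return [
        SiteKey(r.contig, r.position, r.ref, r.alt)
        for r in candidates.itertuples(index=False)
    ]


def run_pair_benchmark(
    seed: int,
    genome_size: int = 5_000_000,
    repeat_fraction: float = 0.1,
    copy_number: int = 2,
    germline_rate: float = 1e-3,
    somatic_rate: float = 5e-4,
    coverage: float = 20.0,
    purity: float = 1.0,
    max_links: int = 100,
    workdir: str | Path | None = None,
) -> dict:
    """Synthetic tumor/normal benchmark; returns data, calls and metrics.

    The result maps names to intermediate artefacts (reference, truth sets,
    BAM paths, candidate tables, networks, annotation tables, call sets)
    and to BenchmarkResults for: MQ16 local, MQ1 local, MQ1 thesaurus, and
    the random-link negative control.
    """
    sub = _subseeds(seed, 10)
    if workdir is None:
        workdir = tempfile.mkdtemp(prefix="varthesaurus_pair_")
    wd = Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)

    reference = build_repeat_reference(
        1, genome_size, repeat_fraction, copy_number, seed=sub[0]
    )
    normal, germline_truth = insert_variants(
        reference.to_diploid(), germline_rate, "germline", seed=sub[1]
    )
    tumor, somatic_truth = derive_tumor(normal, somatic_rate, seed=sub[2])

    params = ReadSimParams(target_coverage=coverage, seed=sub[3])
    reads_normal = simulate_reads(normal, params)
    reads_tumor = simulate_reads(tumor, params)
    if purity < 1.0:
        reads_tumor = mix_samples(reads_tumor, reads_normal, purity, seed=sub[4])

    dup = build_duplicate_index(reference, params.read_length)
    normal_bam = align_and_write(
        reads_normal, reference, wd / "normal.bam", seed=sub[5],
        sample="normal", dup_index=dup,
    )
    tumor_bam = align_and_write(
        reads_tumor, reference, wd / "tumor.bam", seed=sub[6],
        sample="tumor", dup_index=dup,
    )

    cands_mq16 = scan_candidates(tumor_bam, reference, MQ_STRINGENT)
    cands_mq1 = scan_candidates(tumor_bam, reference, MQ_LENIENT)
    sites16, sites1 = _sites(cands_mq16), _sites(cands_mq1)
    write_candidate_vcf(cands_mq1, reference, wd / "tumor.candidates.vcf")

    network = build_network(
        reference, sites1, alignment_source=tumor_bam, max_links=max_links
    )

    matched = {"normal": normal_bam}
    ann16 = annotate_matched(
        sites16, tumor_bam, matched, None, reference, case="tumor",
        min_mapping_quality=MQ_STRINGENT,
    )
    ann1_local = annotate_matched(
        sites1, tumor_bam, matched, None, reference, case="tumor",
        min_mapping_quality=MQ_LENIENT,
    )
    ann1_thes = annotate_matched(
        sites1, tumor_bam, matched, network, reference, case="tumor",
        min_mapping_quality=0, out_prefix=str(wd / "pair_thesaurus"),
    )

    thresholds = somatic_defaults(min_af_difference=0.2)
    calls16 = call_somatic(
        ann16.table, "tumor", "normal", thresholds, use_thesaurus_af=False
    )
    calls1_local = call_somatic(
        ann1_local.table, "tumor", "normal", thresholds, use_thesaurus_af=False
    )
    calls1_thes = call_somatic(
        ann1_thes.table, "tumor", "normal", thresholds, use_thesaurus_af=True
    )

    res16 = classify_calls(calls16, somatic_truth, None)
    res1_local = classify_calls(calls1_local, somatic_truth, None)
    res1_thes = classify_calls(calls1_thes, somatic_truth, network)

    random_net = generate_random_links(sites1, reference, network, seed=sub[7])
    ann_rand = annotate_matched(
        sites1, tumor_bam, matched, random_net, reference, case="tumor",
        min_mapping_quality=0,
    )
    calls_rand = call_somatic(
        ann_rand.table, "tumor", "normal", thresholds, use_thesaurus_af=True
    )
    res_rand = classify_calls(calls_rand, somatic_truth, random_net)

    return {
        "workdir": str(wd),
        "reference": reference,
        "normal": normal,
        "tumor": tumor,
        "germline_truth": germline_truth,
        "somatic_truth": somatic_truth,
        "normal_bam": normal_bam,
        "tumor_bam": tumor_bam,
        "candidates_mq16": cands_mq16,
        "candidates_mq1": cands_mq1,
        "network": network,
        "random_network": random_net,
        "annotation_mq16": ann16,
        "annotation_mq1_local": ann1_local,
        "annotation_mq1_thesaurus": ann1_thes,
        "calls_mq16_local": calls16,
        "calls_mq1_local": calls1_local,
        "calls_mq1_thesaurus": calls1_thes,
        "calls_random_links": calls_rand,
        "result_mq16_local": res16,
        "result_mq1_local": res1_local,
        "result_mq1_thesaurus": res1_thes,
        "result_random_links": res_rand,
    }


def run_trio_benchmark(
    seed: int,
    genome_size: int = 5_000_000,
    repeat_fraction: float = 0.1,
    copy_number: int = 2,
    germline_rate: float = 1e-3,
    denovo_rate: float = 1e-4,
    coverage: float = 20.0,
    workdir: str | Path | None = None,
) -> dict:
    """Synthetic family-trio benchmark: de novo detection in the child at
    the stringent mapping-quality setting."""
    sub = _subseeds(seed + 1, 10)
    if workdir is None:
        workdir = tempfile.mkdtemp(prefix="varthesaurus_trio_")
    wd = Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)

    reference = build_repeat_reference(
        1, genome_size, repeat_fraction, copy_number, seed=sub[0]
    )
    mother, _ = insert_variants(
        reference.to_diploid(), germline_rate, "germline", seed=sub[1]
    )
    father, _ = insert_variants(
        reference.to_diploid(), germline_rate, "germline", seed=sub[2]
    )
    child, denovo_truth = derive_child(mother, father, denovo_rate, seed=sub[3])

    params = ReadSimParams(target_coverage=coverage, seed=sub[4])
    dup = build_duplicate_index(reference, params.read_length)
    bams = {}
    for name, genome, s in (
        ("child", child, sub[5]), ("mother", mother, sub[6]), ("father", father, sub[7])
    ):
        bams[name] = align_and_write(
            simulate_reads(genome, params), reference, wd / f"{name}.bam",
            seed=s, sample=name, dup_index=dup,
        )

    cands_mq16 = scan_candidates(bams["child"], reference, MQ_STRINGENT)
    sites16 = _sites(cands_mq16)
    ann16 = annotate_matched(
        sites16, bams["child"], {"mother": bams["mother"], "father": bams["father"]},
        None, reference, case="child", min_mapping_quality=MQ_STRINGENT,
    )
    thresholds = trio_defaults(max_strand_p=None, max_mean_mismatches=None)
    calls16 = call_denovo_trio(
        ann16.table, "child", "mother", "father", thresholds,
        use_thesaurus_af=False,
    )
    res16 = classify_calls(calls16, denovo_truth, None)

    return {
        "workdir": str(wd),
        "reference": reference,
        "mother": mother,
        "father": father,
        "child": child,
        "denovo_truth": denovo_truth,
        "bams": bams,
        "candidates_mq16": cands_mq16,
        "annotation_mq16": ann16,
        "calls_mq16_local": calls16,
        "result_mq16_local": res16,
    }
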