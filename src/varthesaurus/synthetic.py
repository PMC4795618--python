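"""Synthetic genomes, matched samples and regular-interval paired reads.

This module generates the study material for mappability-aware variant
benchmarks entirely in silico:

* a random reference genome carrying exact repeat families so that a chosen
  fraction of bases is non-uniquely mappable;
* sample genomes derived from it — a diploid "normal" with heterozygous
  germline substitutions (default rate 1e-3 /bp), a matched "tumor" with
  additional somatic substitutions (5e-4 /bp), or a mother/father/child trio
  with de novo substitutions in the child (1e-4 /bp);
* error-free 2 x 100 bp read pairs with a 400 bp outer fragment span placed
  on a regular lattice so that mean coverage is exact (default 20x);
* tumor/normal read mixtures at a chosen purity.

Every operation is deterministic given its seed, and every inserted variant
is recorded in a TruthSet, which is the actual-positive set for downstream
benchmarking. Coverage has deliberately no sampling variability: any
detection failure in these data is attributable to mappability alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _seq
from .genome import RepeatFamily, SyntheticGenome, TruthRecord, TruthSet

logger = logging.getLogger(__name__)

DEFAULT_REPEAT_UNIT = 1000  # bp per repeat copy


# ----------------------------------------------------------------- reference


def build_repeat_reference(
    n_contigs: int,
    contig_length: int,
    repeat_fraction: float,
    copy_number: int = 2,
    seed: int = 0,
    unit_length: int = DEFAULT_REPEAT_UNIT,
) -> SyntheticGenome:
    """Random haploid reference in which ``repeat_fraction`` of bases lie in
    exact repeat families of ``copy_number`` copies of ``unit_length`` bp.

    Interval slots are laid out on a uniform grid (guaranteeing no overlap)
    and assigned to families by a seeded permutation, so copies of one family
    are scattered across the contig.
    """
    if not 0 <= repeat_fraction < 1:
        raise ValueError(f"repeat_fraction must be in [0, 1), got {repeat_fraction}")
    if copy_number < 2:
        raise ValueError("copy_number must be >= 2")

    rng = np.random.default_rng(seed)
    haplotypes: dict[str, list[np.ndarray]] = {}
    repeat_map: list[RepeatFamily] = []
    for ci in range(n_contigs):
        contig = f"chr{ci + 1}"
        seq = rng.integers(0, 4, size=contig_length, dtype=np.uint8)
        n_families = int(round(contig_length * repeat_fraction / (copy_number * unit_length)))
        if n_families > 0:
            n_slots = n_families * copy_number
            stride = contig_length // n_slots
            if stride < unit_length + 2:
                raise ValueError(
                    f"cannot place {n_slots} repeat copies of {unit_length} bp "
                    f"in {contig_length} bp without overlap"
                )
            pad = (stride - unit_length) // 2
            slot_starts = np.arange(n_slots) * stride + pad
            perm = rng.permutation(n_slots)
            for f in range(n_families):
                starts = sorted(int(slot_starts[s]) for s in perm[f * copy_number:(f + 1) * copy_number])
                src = starts[0]
                for s in starts[1:]:
                    seq[s:s + unit_length] = seq[src:src + unit_length]
                repeat_map.append(RepeatFamily(contig, unit_length, starts))
        haplotypes[contig] = [seq]
    return SyntheticGenome(haplotypes, repeat_map=repeat_map)


# ------------------------------------------------------------------ variants


def insert_variants(
    genome: SyntheticGenome,
    rate: float,
    origin_label: str,
    zygosity: str = "heterozygous",
    seed: int = 0,
) -> tuple[SyntheticGenome, TruthSet]:
    """Insert i.i.d. per-base substitutions at ``rate``; returns a new genome
    (input untouched) and the TruthSet of just the inserted events.

    Heterozygous events land on one uniformly chosen haplotype (expected AF
    exactly 0.5), homozygous ones on all haplotypes (AF 1.0). Positions that
    already carry a recorded variant are skipped and logged, so earlier
    events are never overwritten.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"substitution rate must be in [0, 1), got {rate}")
    if zygosity not in ("heterozygous", "homozygous"):
        raise ValueError(f"unknown zygosity {zygosity!r}")
    if zygosity == "heterozygous" and genome.ploidy < 2:
        raise ValueError("heterozygous insertion requires a diploid genome")

    out = genome.copy()
    rng = np.random.default_rng(seed)
    new_records: list[TruthRecord] = []
    expected_af = 0.5 if zygosity == "heterozygous" else 1.0
    n_skipped = 0
    for contig in out.contigs:
        haps = out.haplotypes[contig]
        length = len(haps[0])
        if rate == 0:
            continue
        positions = np.flatnonzero(rng.random(length) < rate)
        offsets = rng.integers(1, 4, size=positions.size, dtype=np.uint8)
        hap_choice = rng.integers(0, len(haps), size=positions.size)
        occupied = out.truth.positions(contig)
        for pos0, off, h in zip(positions, offsets, hap_choice):
            pos1 = int(pos0) + 1
            if pos1 in occupied:
                n_skipped += 1
                continue
            ref_code = int(haps[0][pos0])
            alt_code = (ref_code + int(off)) % 4
            if zygosity == "heterozygous":
                haps[h][pos0] = alt_code
                hap_label: int | None = int(h)
            else:
                for hap in haps:
                    hap[pos0] = alt_code
                hap_label = None
            new_records.append(
                TruthRecord(
                    contig, pos1, _seq.BASES[ref_code], _seq.BASES[alt_code],
                    hap_label, origin_label, expected_af,
                )
            )
    if n_skipped:
        logger.info(
            "insert_variants(%s): skipped %d positions already carrying a variant",
            origin_label, n_skipped,
        )
    inserted = TruthSet(new_records)
    out.truth = out.truth + inserted
    return out, inserted


def derive_tumor(
    normal: SyntheticGenome, somatic_rate: float, seed: int = 0
) -> tuple[SyntheticGenome, TruthSet]:
    """Mutate a matched tumor from the normal genome; the returned TruthSet
    holds only the somatic events. Germline positions are never overwritten."""
    return insert_variants(normal, somatic_rate, "somatic", "heterozygous", seed)


def derive_child(
    mother: SyntheticGenome,
    father: SyntheticGenome,
    denovo_rate: float,
    seed: int = 0,
) -> tuple[SyntheticGenome, TruthSet]:
    """Transmit one randomly chosen haplotype per contig from each parent,
    then add heterozygous de novo substitutions; returns (child, de novo
    TruthSet). All de novo records have expected AF exactly 0.5."""
    if mother.contigs != father.contigs or mother.lengths() != father.lengths():
        raise ValueError("parents must share contig names and lengths")
    if mother.ploidy != 2 or father.ploidy != 2:
        raise ValueError("parents must be diploid")

    rng = np.random.default_rng(seed)
    haplotypes: dict[str, list[np.ndarray]] = {}
    transmitted: list[TruthRecord] = []
    for contig in mother.contigs:
        hm = int(rng.integers(0, 2))
        hf = int(rng.integers(0, 2))
        haplotypes[contig] = [
            mother.haplotypes[contig][hm].copy(),
            father.haplotypes[contig][hf].copy(),
        ]
        for parent, chosen, child_hap in ((mother, hm, 0), (father, hf, 1)):
            for r in parent.truth.records:
                if r.contig == contig and (r.haplotype is None or r.haplotype == chosen):
                    transmitted.append(
                        TruthRecord(r.contig, r.position, r.ref, r.alt,
                                    child_hap, r.origin, 0.5)
                    )
    child = SyntheticGenome(
        haplotypes, repeat_map=list(mother.repeat_map), truth=TruthSet(transmitted)
    )
    child, denovo = insert_variants(
        child, denovo_rate, "denovo", "heterozygous", seed=seed + 1
    )
    return child, denovo


# --------------------------------------------------------------------- reads


@dataclass
class ReadSimParams:
    """Paired-read simulation parameters.

    ``insert_size`` is the outer fragment span: the two mates are the first
    and last ``read_length`` bases of an ``insert_size``-bp fragment.
    """

    read_length: int = 100
    insert_size: int = 400
    target_coverage: float = 20.0
    base_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.insert_size < 2 * self.read_length:
            raise ValueError("insert_size must be >= 2 * read_length")
        if self.target_coverage <= 0:
            raise ValueError("target_coverage must be > 0")


@dataclass
class ReadSet:
    """A collection of read pairs, stored as fragment placements.

    Sequences are materialised lazily from the source genomes, which keeps
    simulation and mixing cheap at scale. ``source_idx`` selects the genome
    in ``sources`` each pair was drawn from (mixtures have two sources).
    """

    sources: list[SyntheticGenome]
    contig_names: list[str]
    contig_idx: np.ndarray  # int32, index into contig_names
    start: np.ndarray  # int64, 0-based fragment start
    haplotype: np.ndarray  # int8
    source_idx: np.ndarray  # int8
    params: ReadSimParams
    pair_ids: np.ndarray = field(default=None)  # stable ids for read names

    def __post_init__(self):
        if self.pair_ids is None:
            self.pair_ids = np.arange(len(self.start), dtype=np.int64)

    def __len__(self) -> int:
        return len(self.start)

    def pair_sequences(self) -> tuple[np.ndarray, np.ndarray]:
        """Materialise (R1, R2) code matrices, shape (n_pairs, read_length).

        R1 is the forward strand at the fragment start; R2 is the reverse
        complement of the last read_length bases of the fragment. Base errors
        (if any) are injected deterministically from ``params.seed``.
        """
        rl = self.params.read_length
        ins = self.params.insert_size
        n = len(self)
        r1 = np.empty((n, rl), dtype=np.uint8)
        r2f = np.empty((n, rl), dtype=np.uint8)  # R2 in forward orientation
        offs = np.arange(rl)
        for si, genome in enumerate(self.sources):
            for ci, contig in enumerate(self.contig_names):
                if contig not in genome.haplotypes:
                    continue
                for h in range(genome.ploidy):
                    sel = np.flatnonzero(
                        (self.source_idx == si)
                        & (self.contig_idx == ci)
                        & (self.haplotype == h)
                    )
                    if sel.size == 0:
                        continue
                    hap = genome.haplotypes[contig][h]
                    starts = self.start[sel]
                    r1[sel] = hap[starts[:, None] + offs]
                    r2f[sel] = hap[(starts + ins - rl)[:, None] + offs]
        if self.params.base_error_rate > 0:
            rng = np.random.default_rng(self.params.seed)
            for mat in (r1, r2f):
                err = rng.random(mat.shape) < self.params.base_error_rate
                shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
                mat[err] = (mat[err] + shift) % 4
        r2 = _seq.complement(r2f)[:, ::-1]
        return r1, r2

    def read_names(self) -> list[str]:
        """Names encode source/contig/haplotype/fragment start (debug plumbing)."""
        return [
            f"frag_{self.contig_names[c]}_s{s}_h{h}_p{p}_{i}"
            for c, s, h, p, i in zip(
                self.contig_idx, self.source_idx, self.haplotype,
                self.start, self.pair_ids,
            )
        ]

    def write_fastq(self, path_r1: str | Path, path_r2: str | Path) -> None:
        r1, r2 = self.pair_sequences()
        names = self.read_names()
        qual = "I" * self.params.read_length
        with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
            for i, name in enumerate(names):
                f1.write(f"@{name}/1\n{_seq.decode(r1[i])}\n+\n{qual}\n")
                f2.write(f"@{name}/2\n{_seq.decode(r2[i])}\n+\n{qual}\n")


def simulate_reads(genome: SyntheticGenome, params: ReadSimParams) -> ReadSet:
    """Paired reads at regular fragment intervals giving exact mean coverage.

    Per haplotype, ``n = round(L * coverage / (2 * read_length * ploidy))``
    fragment starts are spread evenly over the valid range; haplotype h is
    phase-shifted by h/ploidy of one step so diploid coverage interleaves.
    Deterministic; ``params.seed`` is consulted only for base errors.
    """
    rl, ins = params.read_length, params.insert_size
    ploidy = genome.ploidy
    contig_names = genome.contigs
    chunks = []
    for ci, contig in enumerate(contig_names):
        length = genome.length(contig)
        if length <= ins:
            raise ValueError(f"contig {contig} ({length} bp) shorter than fragment span {ins}")
        span = length - ins
        n = int(round(length * params.target_coverage / (2 * rl * ploidy)))
        if n < 1:
            raise ValueError("target_coverage too low: no fragments to place")
        step = span / max(n - 1, 1)
        for h in range(ploidy):
            starts = np.floor((np.arange(n) + h / ploidy) * step).astype(np.int64)
            starts = np.clip(starts, 0, span)
            chunks.append((
                np.full(n, ci, dtype=np.int32),
                starts,
                np.full(n, h, dtype=np.int8),
            ))
    contig_idx = np.concatenate([c[0] for c in chunks])
    start = np.concatenate([c[1] for c in chunks])
    hap = np.concatenate([c[2] for c in chunks])
    return ReadSet(
        sources=[genome],
        contig_names=contig_names,
        contig_idx=contig_idx,
        start=start,
        haplotype=hap,
        source_idx=np.zeros(len(start), dtype=np.int8),
        params=params,
    )


def mix_samples(
    reads_a: ReadSet, reads_b: ReadSet, fraction_a: float, seed: int = 0
) -> ReadSet:
    """Mixture sample: each output pair drawn from ``reads_a`` with
    probability ``fraction_a``, else from ``reads_b``. The output preserves
    the pair count of the larger design; deterministic per seed."""
    if not 0 <= fraction_a <= 1:
        raise ValueError("fraction_a must be in [0, 1]")
    if len(reads_a) == 0 or len(reads_b) == 0:
        raise ValueError("cannot mix empty read collections")
    if reads_a.params.read_length != reads_b.params.read_length or \
            reads_a.params.insert_size != reads_b.params.insert_size:
        raise ValueError("read designs differ between collections")

    n = max(len(reads_a), len(reads_b))
    rng = np.random.default_rng(seed)
    take_a = rng.random(n) < fraction_a
    idx = np.arange(n)
    ia = idx % len(reads_a)
    ib = idx % len(reads_b)

    n_sources_a = len(reads_a.sources)
    contig_names = list(dict.fromkeys(reads_a.contig_names + reads_b.contig_names))
    remap_a = np.array([contig_names.index(c) for c in reads_a.contig_names])
    remap_b = np.array([contig_names.index(c) for c in reads_b.contig_names])

    def pick(field_a, field_b):
        out = np.where(take_a, field_a[ia], field_b[ib])
        return out

    contig_idx = pick(remap_a[reads_a.contig_idx], remap_b[reads_b.contig_idx]).astype(np.int32)
    start = pick(reads_a.start, reads_b.start)
    hap = pick(reads_a.haplotype, reads_b.haplotype).astype(np.int8)
    source = np.where(
        take_a, reads_a.source_idx[ia], reads_b.source_idx[ib] + n_sources_a
    ).astype(np.int8)
    return ReadSet(
        sources=reads_a.sources + reads_b.sources,
        contig_names=contig_names,
        contig_idx=contig_idx,
        start=start,
        haplotype=hap,
        source_idx=source,
        params=reads_a.params,
    )
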