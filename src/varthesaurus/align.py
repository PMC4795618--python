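"""Hermetic placement aligner for simulated reads.

The annotation pipeline consumes coordinate-sorted indexed BAM files and is
agnostic to how they were produced; any short-read aligner can be used. For
self-contained experiments this module provides a deterministic aligner
specialised to the substitution-only genomes of :mod:`varthesaurus.synthetic`:

* every read derives from a known reference interval, so gapless placement
  is exact;
* a read whose reference window has exact duplicates elsewhere in the
  reference is ambiguous: it is placed uniformly at random (seeded) among
  the duplicate loci and receives mapping quality 1, mimicking how
  production aligners scatter multi-mapping reads across repeat copies;
* uniquely mappable reads are placed at their true locus with mapping
  quality 40.

The binary MQ {1, 40} preserves the two standard operating points: a
stringent min-MQ of 16 sees only unique reads, a lenient min-MQ of 1 sees
every read. Duplicate windows are found with a rolling hash and verified
base-by-base, so the ambiguity calls are exact, not probabilistic.
Mates are placed independently; NM tags carry the true edit distance at the
chosen placement.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from . import _seq
from ._hashing import rolling_hash
from .genome import SyntheticGenome
from .synthetic import ReadSet

UNIQUE_MAPQ = 40
AMBIGUOUS_MAPQ = 1


@dataclass
class DuplicateIndex:
    """Exact duplicate-window structure of a reference genome.

    ``group_id[gpos]`` is -1 for unique windows, otherwise an index into the
    flattened (``members``, ``grp_start``, ``grp_size``) group table holding
    all global start positions sharing that window sequence.
    """

    contig_names: list[str]
    offsets: np.ndarray  # global offset per contig, plus total length sentinel
    group_id: np.ndarray  # int32 per global position
    members: np.ndarray  # int64 global positions, grouped
    grp_start: np.ndarray
    grp_size: np.ndarray

    def to_global(self, contig_idx: np.ndarray, pos: np.ndarray) -> np.ndarray:
        return self.offsets[contig_idx] + pos

    def to_local(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ci = np.searchsorted(self.offsets, gpos, side="right") - 1
        return ci.astype(np.int32), gpos - self.offsets[ci]


def build_duplicate_index(reference: SyntheticGenome, window: int) -> DuplicateIndex:
    """Group all window-length reference positions by exact sequence identity."""
    contig_names = reference.contigs
    codes = [reference.haplotypes[c][0] for c in contig_names]
    offsets = np.concatenate([[0], np.cumsum([len(c) for c in codes])]).astype(np.int64)
    cat = np.concatenate(codes)

    hashes, positions = [], []
    for ci, arr in enumerate(codes):
        h = rolling_hash(arr, window)
        hashes.append(h)
        positions.append(offsets[ci] + np.arange(h.size, dtype=np.int64))
    H = np.concatenate(hashes)
    pos = np.concatenate(positions)

    order = np.argsort(H, kind="stable")
    hs, ps = H[order], pos[order]
    change = np.flatnonzero(np.concatenate(([True], hs[1:] != hs[:-1], [True])))
    starts, ends = change[:-1], change[1:]
    sizes = ends - starts
    multi = np.flatnonzero(sizes >= 2)

    group_id = np.full(int(offsets[-1]), -1, dtype=np.int32)
    members_list, grp_start, grp_size = [], [], []
    if multi.size:
        # verify candidate groups base-by-base against the representative
        mstarts = starts[multi]
        msizes = sizes[multi]
        member_pos = np.concatenate([ps[s:s + n] for s, n in zip(mstarts, msizes)])
        rep_pos = np.repeat(ps[mstarts], msizes)
        offs = np.arange(window)
        ok = np.empty(member_pos.size, dtype=bool)
        for lo in range(0, member_pos.size, 200_000):
            hi = min(lo + 200_000, member_pos.size)
            ok[lo:hi] = np.all(
                cat[member_pos[lo:hi, None] + offs] == cat[rep_pos[lo:hi, None] + offs],
                axis=1,
            )
        cursor = 0
        flat = 0
        for s, n in zip(mstarts, msizes):
            sel = member_pos[cursor:cursor + n][ok[cursor:cursor + n]]
            cursor += n
            if sel.size >= 2:
                gid = len(grp_start)
                grp_start.append(flat)
                grp_size.append(sel.size)
                members_list.append(np.sort(sel))
                group_id[np.sort(sel)] = gid
                flat += sel.size
    members = np.concatenate(members_list) if members_list else np.empty(0, np.int64)
    return DuplicateIndex(
        contig_names, offsets, group_id, members,
        np.asarray(grp_start, dtype=np.int64), np.asarray(grp_size, dtype=np.int64),
    )


@dataclass
class PlacedReads:
    """Flat per-read (not per-pair) placement table; rows are R1s then R2s."""

    contig_names: list[str]
    qname: list[str]
    contig_idx: np.ndarray
    pos: np.ndarray  # 0-based leftmost placed position
    is_read2: np.ndarray
    mapq: np.ndarray
    nm: np.ndarray
    seq_fwd: np.ndarray  # (n, read_length) codes in reference orientation
    mate_row: np.ndarray
    read_length: int


def place_reads(
    reads: ReadSet,
    reference: SyntheticGenome,
    seed: int = 0,
    dup_index: DuplicateIndex | None = None,
) -> PlacedReads:
    """Assign a placement and mapping quality to every mate."""
    rl = reads.params.read_length
    ins = reads.params.insert_size
    if dup_index is None:
        dup_index = build_duplicate_index(reference, rl)
    rng = np.random.default_rng(seed)

    r1, r2 = reads.pair_sequences()
    r2f = _seq.complement(r2)[:, ::-1]  # reference orientation
    name_stems = reads.read_names()

    # reference contig indexing may differ from the ReadSet's contig order
    remap = np.array(
        [dup_index.contig_names.index(c) for c in reads.contig_names], dtype=np.int32
    )
    ref_contig_idx = remap[reads.contig_idx]
    n = len(reads)
    true_pos = np.concatenate([reads.start, reads.start + ins - rl])
    contig_idx = np.concatenate([ref_contig_idx, ref_contig_idx])
    gpos = dup_index.to_global(contig_idx, true_pos)

    gid = dup_index.group_id[gpos]
    ambiguous = gid >= 0
    placed_g = gpos.copy()
    if ambiguous.any():
        g = gid[ambiguous]
        choice = dup_index.grp_start[g] + rng.integers(0, dup_index.grp_size[g])
        placed_g[ambiguous] = dup_index.members[choice]
    mapq = np.where(ambiguous, AMBIGUOUS_MAPQ, UNIQUE_MAPQ).astype(np.int16)
    placed_ci, placed_pos = dup_index.to_local(placed_g)

    # NM = Hamming distance between the (forward-orientation) read and the
    # reference at the chosen placement
    cat = np.concatenate([reference.haplotypes[c][0] for c in dup_index.contig_names])
    seq_fwd = np.concatenate([r1, r2f])
    nm = np.empty(2 * n, dtype=np.int32)
    offs = np.arange(rl)
    for lo in range(0, 2 * n, 200_000):
        hi = min(lo + 200_000, 2 * n)
        nm[lo:hi] = (seq_fwd[lo:hi] != cat[placed_g[lo:hi, None] + offs]).sum(axis=1)

    return PlacedReads(
        contig_names=dup_index.contig_names,
        qname=name_stems + name_stems,
        contig_idx=placed_ci,
        pos=placed_pos,
        is_read2=np.concatenate([np.zeros(n, bool), np.ones(n, bool)]),
        mapq=mapq,
        nm=nm,
        seq_fwd=seq_fwd,
        mate_row=np.concatenate([np.arange(n, 2 * n), np.arange(0, n)]),
        read_length=rl,
    )


def write_bam(
    placed: PlacedReads,
    reference: SyntheticGenome,
    bam_path: str | Path,
    sample: str | None = None,
) -> str:
    """Write placements as a coordinate-sorted, indexed BAM."""
    bam_path = str(bam_path)
    sam_path = bam_path + ".tmp.sam"
    rl = placed.read_length
    qual = b"I" * rl
    lengths = reference.lengths()
    seq_ascii = _seq._CODE_TO_ASCII[placed.seq_fwd]

    order = np.lexsort((placed.pos, placed.contig_idx))
    pos1 = placed.pos + 1
    mate_pos1 = pos1[placed.mate_row]
    with open(sam_path, "wb") as fh:
        fh.write(b"@HD\tVN:1.6\tSO:coordinate\n")
        for c in placed.contig_names:
            fh.write(f"@SQ\tSN:{c}\tLN:{lengths[c]}\n".encode())
        if sample is not None:
            fh.write(f"@RG\tID:{sample}\tSM:{sample}\n".encode())
        cigar = f"{rl}M".encode()
        rg = f"\tRG:Z:{sample}".encode() if sample is not None else b""
        names = [c.encode() for c in placed.contig_names]
        for i in order:
            flag = 145 if placed.is_read2[i] else 97
            fh.write(
                b"\t".join((
                    placed.qname[i].encode(),
                    str(flag).encode(),
                    names[placed.contig_idx[i]],
                    str(pos1[i]).encode(),
                    str(placed.mapq[i]).encode(),
                    cigar,
                    b"=",
                    str(mate_pos1[i]).encode(),
                    b"0",
                    seq_ascii[i].tobytes(),
                    qual,
                    b"NM:i:" + str(placed.nm[i]).encode() + rg,
                )) + b"\n"
            )
    pysam.samtools.view("-b", "-o", bam_path, sam_path, catch_stdout=False)
    pysam.samtools.index(bam_path)
    os.remove(sam_path)
    return bam_path


def align_and_write(
    reads: ReadSet,
    reference: SyntheticGenome,
    bam_path: str | Path,
    seed: int = 0,
    sample: str | None = None,
    dup_index: DuplicateIndex | None = None,
) -> str:
    """Place reads and write a sorted, indexed BAM in one step."""
    placed = place_reads(reads, reference, seed=seed, dup_index=dup_index)
    return write_bam(placed, reference, bam_path, sample=sample)
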