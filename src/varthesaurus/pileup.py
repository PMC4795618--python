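"""Per-site pileup statistics from alignments.

Reads coordinate-sorted indexed BAM/SAM alignments with pysam and produces,
for each requested substitution site, the counts that drive allele-frequency
estimation and filtering: alt-supporting reads m, total coverage C, stranded
alt/ref counts for the strand-bias test, and the mean per-read mismatch load
(NM tag) of alt-supporting reads.

Filtering contract: unmapped, secondary, supplementary and duplicate-flagged
reads are excluded from both m and C, as are reads below the mapping- or
base-quality thresholds; reads spanning the site with a deletion or
reference skip are excluded from C so that C stays a substitution-informative
denominator. Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from scipy import stats

from . import _seq

_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x400 | 0x800  # unmapped/secondary/dup/supplementary
VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SiteKey:
    """A single-nucleotide substitution candidate (1-based coordinate)."""

    contig: str
    position: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"alleles must be in ACGT, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.contig}:{self.position}")


@dataclass
class PileupCounts:
    """Pileup summary for one site in one sample."""

    site: SiteKey
    sample: str
    m: int  # reads supporting alt
    C: int  # total coverage
    fwd_alt: int
    rev_alt: int
    fwd_ref: int
    rev_ref: int
    mean_mismatches: float  # mean NM over alt-supporting reads; nan if m == 0

    @property
    def af_local(self) -> float:
        return self.m / self.C if self.C > 0 else float("nan")


def strand_bias_p(counts: PileupCounts) -> float:
    """Two-sided Fisher exact P on [[fwd_alt, rev_alt], [fwd_ref, rev_ref]]."""
    if counts.C <= 0:
        raise ValueError("strand_bias_p requires nonzero coverage")
    table = [[counts.fwd_alt, counts.rev_alt], [counts.fwd_ref, counts.rev_ref]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _site_tuple(site) -> tuple[str, int, str, str]:
    if isinstance(site, SiteKey):
        return site.contig, site.position, site.ref, site.alt
    contig, position, ref, alt = site
    return contig, int(position), ref, alt


def _base_at(read, pos0: int):
    """Read base and quality at reference position pos0, or None if the read
    does not place a base there (deletion / reference skip / soft clip)."""
    if read.cigartuples is not None and len(read.cigartuples) == 1 \
            and read.cigartuples[0][0] == 0:  # single M: the overwhelming fast path
        off = pos0 - read.reference_start
        if 0 <= off < read.query_length:
            q = read.query_qualities
            return read.query_sequence[off], (q[off] if q is not None else 255)
        return None
    for qoff, rpos in read.get_aligned_pairs(matches_only=False):
        if rpos == pos0:
            if qoff is None:
                return None
            q = read.query_qualities
            return read.query_sequence[qoff], (q[qoff] if q is not None else 255)
    return None


class _Accumulator:
    __slots__ = ("m", "C", "fa", "ra", "fr", "rr", "nm_sum")

    def __init__(self):
        self.m = self.C = self.fa = self.ra = self.fr = self.rr = 0
        self.nm_sum = 0

    def add(self, base: str, reverse: bool, ref: str, alt: str, nm: int):
        self.C += 1
        if base == alt:
            self.m += 1
            self.nm_sum += nm
            if reverse:
                self.ra += 1
            else:
                self.fa += 1
        elif base == ref:
            if reverse:
                self.rr += 1
            else:
                self.fr += 1


def _read_nm(read) -> int:
    try:
        return read.get_tag("NM")
    except KeyError:
        return 0


def pileup_at_sites(
    alignment_source: str | Path | pysam.AlignmentFile,
    sites: Sequence,
    min_mapping_quality: int = 0,
    min_base_quality: int = 5,
    sample: str = "sample",
) -> list[PileupCounts]:
    """Pileup counts for each requested site, in input order.

    ``sites`` may be SiteKeys or (contig, position, ref, alt) tuples; the
    tuple form additionally allows ref == alt, which is useful when counting
    projected alleles at thesaurus-linked loci. Sites must be sorted by
    coordinate within each contig. For large site lists a single sweep per
    contig is used instead of per-site fetches.
    """
    own = not isinstance(alignment_source, pysam.AlignmentFile)
    bam = (
        pysam.AlignmentFile(str(alignment_source)) if own else alignment_source
    )
    try:
        tuples = [_site_tuple(s) for s in sites]
        for contig, *_ in tuples:
            if contig not in bam.references:
                raise ValueError(f"contig {contig!r} absent from alignment header")
        acc = [_Accumulator() for _ in tuples]
        by_contig: dict[str, list[int]] = {}
        for i, (contig, *_rest) in enumerate(tuples):
            by_contig.setdefault(contig, []).append(i)

        for contig, idxs in by_contig.items():
            positions = [tuples[i][1] for i in idxs]
            if positions != sorted(positions):
                raise ValueError(f"sites on {contig} must be coordinate-sorted")
            if len(idxs) <= 200:
                for i in idxs:
                    pos = tuples[i][1]
                    for read in bam.fetch(contig, pos - 1, pos):
                        _tally(read, [i], tuples, acc,
                               min_mapping_quality, min_base_quality)
            else:
                span = 0
                for read in bam.fetch(contig):
                    span = max(span, read.reference_length or 0)
                    rs = read.reference_start
                    lo = bisect.bisect_left(positions, rs + 1)
                    hi = bisect.bisect_right(positions, rs + span)
                    if lo < hi:
                        _tally(read, idxs[lo:hi], tuples, acc,
                               min_mapping_quality, min_base_quality)
        out = []
        for (contig, pos, ref, alt), a in zip(tuples, acc):
            site = SiteKey(contig, pos, ref, alt) if ref != alt else None
            out.append(
                PileupCounts(
                    site=site if site is not None else _LooseSite(contig, pos, ref, alt),
                    sample=sample,
                    m=a.m, C=a.C,
                    fwd_alt=a.fa, rev_alt=a.ra, fwd_ref=a.fr, rev_ref=a.rr,
                    mean_mismatches=(a.nm_sum / a.m) if a.m else float("nan"),
                )
            )
        return out
    finally:
        if own:
            bam.close()


@dataclass(frozen=True)
class _LooseSite:
    """Site-like record without the ref != alt constraint (projected loci)."""

    contig: str
    position: int
    ref: str
    alt: str


def _tally(read, idxs, tuples, acc, min_mq, min_bq):
    if read.flag & _EXCLUDE_FLAGS or read.mapping_quality < min_mq:
        return
    nm = None
    for i in idxs:
        _, pos, ref, alt = tuples[i]
        if not (read.reference_start < pos <= (read.reference_end or read.reference_start)):
            continue
        got = _base_at(read, pos - 1)
        if got is None:
            continue
        base, bq = got
        if bq < min_bq or base not in VALID_BASES:
            continue
        if nm is None:
            nm = _read_nm(read)
        acc[i].add(base, read.is_reverse, ref, alt, nm)


# ------------------------------------------------------- candidate screening


def scan_candidates(
    alignment_source: str | Path,
    reference,
    min_mapping_quality: int = 16,
    min_alt_reads: int = 2,
    min_af: float = 0.05,
    min_base_quality: int = 5,
):
    """Genome-wide substitution candidate screen.

    Sweeps every primary read once, collects mismatches against the
    reference, and reports sites with at least ``min_alt_reads`` supporting
    reads and local allele frequency >= ``min_af`` at the given
    mapping-quality threshold. Returns a DataFrame with columns
    contig, position, ref, alt, m, C. This is the rudimentary screening
    caller that produces the candidate VCF for thesaurus annotation; it is
    not a final mutation caller.
    """
    import pandas as pd

    from .genome import SyntheticGenome, load_fasta

    if not isinstance(reference, SyntheticGenome):
        reference = load_fasta(reference)

    rows = []
    with pysam.AlignmentFile(str(alignment_source)) as bam:
        for contig in bam.references:
            if contig not in reference.haplotypes:
                raise ValueError(f"alignment contig {contig!r} missing from reference")
            ref_codes = reference.haplotypes[contig][0]
            length = len(ref_codes)
            cov_diff = np.zeros(length + 1, dtype=np.int32)
            mm_pos: list[np.ndarray] = []
            mm_alt: list[np.ndarray] = []
            for read in bam.fetch(contig):
                if read.flag & _EXCLUDE_FLAGS or read.mapping_quality < min_mapping_quality:
                    continue
                ct = read.cigartuples
                if ct is None or len(ct) != 1 or ct[0][0] != 0:
                    continue  # screening handles gapless reads only
                rs = read.reference_start
                rlen = read.query_length
                cov_diff[rs] += 1
                cov_diff[rs + rlen] -= 1
                codes = _seq.ascii_to_codes(
                    np.frombuffer(read.query_sequence.encode(), dtype=np.uint8)
                )
                diff = np.flatnonzero((codes != ref_codes[rs:rs + rlen]) & (codes < 4))
                if diff.size:
                    if read.query_qualities is not None:
                        quals = np.asarray(read.query_qualities, dtype=np.int16)
                        diff = diff[quals[diff] >= min_base_quality]
                    mm_pos.append(rs + diff)
                    mm_alt.append(codes[diff])
            if not mm_pos:
                continue
            coverage = np.cumsum(cov_diff[:-1])
            pos_all = np.concatenate(mm_pos)
            alt_all = np.concatenate(mm_alt).astype(np.int64)
            keys, counts = np.unique(pos_all * 4 + alt_all, return_counts=True)
            pos0 = keys // 4
            altc = keys % 4
            cov = coverage[pos0]
            keep = (counts >= min_alt_reads) & (counts >= min_af * cov)
            for p, a, m, c in zip(pos0[keep], altc[keep], counts[keep], cov[keep]):
                ref_base = _seq.BASES[ref_codes[p]]
                rows.append((contig, int(p) + 1, ref_base, _seq.BASES[a], int(m), int(c)))
    return pd.DataFrame(rows, columns=["contig", "position", "ref", "alt", "m", "C"])


def write_candidate_vcf(candidates, reference, path: str | Path) -> str:
    """Write a screening DataFrame as a minimal VCF 4.2 file."""
    header = pysam.VariantHeader()
    header.add_line('##source=varthesaurus-screen')
    for contig, length in reference.lengths().items():
        header.contigs.add(contig, length=length)
    header.info.add("DP", 1, "Integer", "Total read depth at the site")
    header.info.add("AO", 1, "Integer", "Reads supporting the alternate allele")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in candidates.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.contig, start=row.position - 1,
                alleles=(row.ref, row.alt),
            )
            rec.info["DP"] = int(row.C)
            rec.info["AO"] = int(row.m)
            vcf.write(rec)
    return str(path)


def read_candidate_vcf(path: str | Path) -> list[SiteKey]:
    """Load substitution candidates from a VCF; non-SNV records are skipped."""
    sites = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1 \
                        and rec.ref in VALID_BASES and alt in VALID_BASES:
                    sites.append(SiteKey(rec.contig, rec.pos, rec.ref, alt))
    return sites


def pileups_to_dataframe(pileups: Iterable[PileupCounts]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "contig": p.site.contig, "position": p.site.position,
                "ref": p.site.ref, "alt": p.site.alt, "sample": p.sample,
                "m": p.m, "C": p.C,
                "fwd_alt": p.fwd_alt, "rev_alt": p.rev_alt,
                "fwd_ref": p.fwd_ref, "rev_ref": p.rev_ref,
                "mean_mismatches": p.mean_mismatches,
            }
            for p in pileups
        ]
    )
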