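"""In-memory genomes with explicit repeat structure and variant bookkeeping.

A :class:`SyntheticGenome` holds one or two haplotype sequences per contig
together with a machine-readable map of its repeat families (intervals that
were created as exact sequence copies of one another) and the registry of
variants inserted so far. The repeat map is what makes desk-scale
mappability experiments possible: it plays the role that the non-unique
fraction of a mammalian reference genome plays at full scale, and it doubles
as an independent oracle for homology-search tests.

Coordinates are 0-based half-open internally; all serialised variant
coordinates are 1-based (VCF convention), BED output is 0-based half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from . import _seq


@dataclass(frozen=True)
class TruthRecord:
    """A single inserted substitution with its ground-truth provenance."""

    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    haplotype: int | None  # haplotype index, None = all haplotypes
    origin: str  # germline | somatic | denovo
    expected_af: float


class TruthSet:
    """Registry of inserted variants; the actual-positive set for benchmarks."""

    def __init__(self, records: Iterable[TruthRecord] = ()):
        self.records: list[TruthRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __add__(self, other: "TruthSet") -> "TruthSet":
        return TruthSet(self.records + list(other.records))

    def positions(self, contig: str | None = None) -> set:
        if contig is None:
            return {(r.contig, r.position) for r in self.records}
        return {r.position for r in self.records if r.contig == contig}

    def subset(self, origin: str) -> "TruthSet":
        return TruthSet(r for r in self.records if r.origin == origin)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [dataclasses.asdict(r) for r in self.records],
            columns=[f.name for f in dataclasses.fields(TruthRecord)],
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tposition\tref\talt\thaplotype\torigin\texpected_af\n")
            for r in self.records:
                hap = "." if r.haplotype is None else str(r.haplotype)
                fh.write(
                    f"{r.contig}\t{r.position}\t{r.ref}\t{r.alt}\t{hap}\t"
                    f"{r.origin}\t{r.expected_af:g}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthSet":
        records = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("contig"):
                raise ValueError(f"{path}: missing truth-set header")
            for line in fh:
                c, p, ref, alt, hap, origin, af = line.rstrip("\n").split("\t")
                records.append(
                    TruthRecord(
                        c, int(p), ref, alt,
                        None if hap == "." else int(hap), origin, float(af),
                    )
                )
        return cls(records)


@dataclass
class RepeatFamily:
    """A family of sequence-identical intervals (identical at creation)."""

    contig: str
    length: int
    starts: list[int]  # 0-based interval starts; starts[0] is the source copy

    @property
    def copy_number(self) -> int:
        return len(self.starts)

    def intervals(self) -> list[tuple[str, int, int]]:
        return [(self.contig, s, s + self.length) for s in self.starts]


@dataclass
class SyntheticGenome:
    """Named contigs (one array per haplotype), repeat map and truth registry."""

    haplotypes: dict[str, list[np.ndarray]]
    repeat_map: list[RepeatFamily] = field(default_factory=list)
    truth: TruthSet = field(default_factory=TruthSet)

    @property
    def contigs(self) -> list[str]:
        return list(self.haplotypes)

    @property
    def ploidy(self) -> int:
        return len(next(iter(self.haplotypes.values())))

    def length(self, contig: str) -> int:
        return len(self.haplotypes[contig][0])

    def lengths(self) -> dict[str, int]:
        return {c: self.length(c) for c in self.contigs}

    def sequence(self, contig: str, haplotype: int = 0) -> str:
        return _seq.decode(self.haplotypes[contig][haplotype])

    def to_diploid(self) -> "SyntheticGenome":
        """Duplicate a haploid genome into two identical haplotypes."""
        if self.ploidy != 1:
            raise ValueError("to_diploid requires a haploid genome")
        return SyntheticGenome(
            {c: [h[0].copy(), h[0].copy()] for c, h in self.haplotypes.items()},
            repeat_map=list(self.repeat_map),
            truth=TruthSet(self.truth.records),
        )

    def copy(self) -> "SyntheticGenome":
        return SyntheticGenome(
            {c: [h.copy() for h in haps] for c, haps in self.haplotypes.items()},
            repeat_map=list(self.repeat_map),
            truth=TruthSet(self.truth.records),
        )

    # ------------------------------------------------------------------ I/O

    def write_fasta(self, path: str | Path, haplotype_suffix: bool | None = None) -> None:
        """Write contigs as FASTA.

        Diploid genomes get ``_h<i>`` suffixes per haplotype unless
        ``haplotype_suffix`` is explicitly False (then haplotype 0 only).
        """
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        if haplotype_suffix is None:
            haplotype_suffix = self.ploidy > 1
        records = []
        for contig, haps in self.haplotypes.items():
            if haplotype_suffix:
                for i, hap in enumerate(haps):
                    records.append(
                        SeqRecord(Seq(_seq.decode(hap)), id=f"{contig}_h{i}", description="")
                    )
            else:
                records.append(
                    SeqRecord(Seq(_seq.decode(haps[0])), id=contig, description="")
                )
        SeqIO.write(records, str(path), "fasta")

    def write_repeat_bed(self, path: str | Path) -> None:
        """Repeat map as BED (0-based half-open); the name field carries
        family id, copy index and the family's other copy coordinates."""
        with open(path, "w") as fh:
            for fam_id, fam in enumerate(self.repeat_map):
                for copy_idx, start in enumerate(fam.starts):
                    others = ",".join(
                        f"{fam.contig}:{s}-{s + fam.length}"
                        for j, s in enumerate(fam.starts)
                        if j != copy_idx
                    )
                    fh.write(
                        f"{fam.contig}\t{start}\t{start + fam.length}\t"
                        f"family{fam_id};copy{copy_idx};{others}\n"
                    )


def load_fasta(path: str | Path) -> SyntheticGenome:
    """Read a FASTA file into a haploid SyntheticGenome (no repeat map)."""
    import pysam

    haps: dict[str, list[np.ndarray]] = {}
    with pysam.FastaFile(str(path)) as fa:
        for contig in fa.references:
            haps[contig] = [_seq.encode(fa.fetch(contig))]
    return SyntheticGenome(haps)
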