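"""Thesaurus link discovery: sequence-similar alternative loci per candidate.

A thesaurus link records that two genomic loci are surrounded by sequence
similar enough that short reads cannot distinguish them, so evidence for a
variant at one locus may appear at the other. Links are discovered by a
deterministic seed-and-extend homology search over the reference: the
candidate site's flanking window (default 2 x read length = 200 bp) is
seeded with exact 16-mers into a genome index, and hits are verified by
Hamming distance on both strands. Mismatches at positions that are
themselves candidate variants can be exempted from the mismatch budget so
germline variation does not sever true links.

Links are symmetrised over candidate sites and closed transitively into
clusters (union-find). Per-site filter codes follow the annotation
vocabulary: ``thesaurus`` (1..max_links links), ``thesaurusmany`` (more
links than the cap; excluded from frequency aggregation) and
``thesaurushard`` (the flanking sequence could not be extracted/projected).
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import _seq
from ._hashing import pack_kmers
from .genome import SyntheticGenome, load_fasta
from .pileup import SiteKey

FLAG_NONE = "none"
FLAG_THESAURUS = "thesaurus"
FLAG_MANY = "thesaurusmany"
FLAG_HARD = "thesaurushard"

DEFAULT_MAX_LINKS = 100
DEFAULT_WINDOW = 200
DEFAULT_SEED_K = 16

Locus = namedtuple("Locus", ["contig", "position", "strand"])  # position 1-based


class GenomeIndex:
    """Sorted exact k-mer index of a reference genome (haplotype 0)."""

    def __init__(self, genome: SyntheticGenome | str | Path, k: int = DEFAULT_SEED_K):
        if not isinstance(genome, SyntheticGenome):
            genome = load_fasta(genome)
        self.genome = genome
        self.k = k
        self.contig_names = genome.contigs
        self.codes = {c: genome.haplotypes[c][0] for c in self.contig_names}
        lengths = [len(self.codes[c]) for c in self.contig_names]
        self.offsets = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)
        hashes, positions = [], []
        for ci, c in enumerate(self.contig_names):
            h = pack_kmers(self.codes[c], k)
            hashes.append(h)
            positions.append(self.offsets[ci] + np.arange(h.size, dtype=np.int64))
        cat_h = np.concatenate(hashes) if hashes else np.empty(0, np.uint64)
        cat_p = np.concatenate(positions) if positions else np.empty(0, np.int64)
        order = np.argsort(cat_h, kind="stable")
        self._sorted_hash = cat_h[order]
        self._sorted_pos = cat_p[order]
        self.cat = np.concatenate([self.codes[c] for c in self.contig_names])

    def query(self, kmer_hash: np.uint64) -> np.ndarray:
        """Global start positions of all exact occurrences of the k-mer."""
        lo = np.searchsorted(self._sorted_hash, kmer_hash, side="left")
        hi = np.searchsorted(self._sorted_hash, kmer_hash, side="right")
        return self._sorted_pos[lo:hi]

    def to_local(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return self.contig_names[ci], int(gpos - self.offsets[ci])

    def contig_bounds(self, gpos: int) -> tuple[int, int]:
        ci = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return int(self.offsets[ci]), int(self.offsets[ci + 1])


@dataclass
class LinkSearchResult:
    loci: list[Locus]
    truncated: bool = False  # hit list capped at max_hits
    flank_truncated: bool = False  # flank clipped at a contig end
    hard: bool = False  # flank extraction failed


def find_alternative_loci(
    index: GenomeIndex | SyntheticGenome,
    site: SiteKey,
    window: int = DEFAULT_WINDOW,
    max_mismatches: int | None = None,
    max_hits: int = DEFAULT_MAX_LINKS,
    exempt_positions: set | None = None,
) -> LinkSearchResult:
    """All loci whose window-length neighbourhood matches the site's flank
    with at most ``max_mismatches`` substitutions, on either strand.

    Each hit carries the coordinate homologous to the site itself; the
    site's own locus is excluded. Flanks running off a contig end are
    truncated, flagged, and still searched.
    """
    if not isinstance(index, GenomeIndex):
        index = GenomeIndex(index)
    if max_mismatches is None:
        max_mismatches = max(1, round(0.05 * window))
    k = index.k
    exempt = exempt_positions or set()

    codes = index.codes[site.contig]
    length = len(codes)
    pos0 = site.position - 1
    if not 0 <= pos0 < length:
        raise ValueError(f"site {site.contig}:{site.position} outside contig bounds")
    a = max(0, pos0 - window // 2)
    b = min(length, a + window)
    a = max(0, b - window)
    flank = codes[a:b]
    w = len(flank)
    off = pos0 - a
    flank_truncated = w < window
    if w < k:
        return LinkSearchResult([], hard=True, flank_truncated=True)

    seed_offsets = sorted({*range(0, w - k + 1, k), w - k})
    found: dict[tuple[int, str], None] = {}

    def _search(query: np.ndarray, strand: str):
        cand: set[int] = set()
        for j in seed_offsets:
            h = pack_kmers(query[j:j + k], k)[0]
            for gp in index.query(h):
                cand.add(int(gp) - j)
        for s in cand:
            lo, hi = index.contig_bounds(min(max(s, 0), index.cat.size - 1))
            if s < lo or s + w > hi:
                continue
            target = index.cat[s:s + w]
            mism = np.flatnonzero(target != query)
            if mism.size > max_mismatches and not exempt:
                n_mm = mism.size
            else:
                n_mm = 0
                t_contig, t_local = index.to_local(s)
                for t in mism:
                    t = int(t)
                    if strand == "+":
                        qpos = a + t + 1
                        tpos = t_local + t + 1
                    else:
                        qpos = a + (w - 1 - t) + 1
                        tpos = t_local + t + 1
                    if (site.contig, qpos) in exempt or (t_contig, tpos) in exempt:
                        continue
                    n_mm += 1
            if n_mm > max_mismatches:
                continue
            t_contig, t_local = index.to_local(s)
            site_off = off if strand == "+" else (w - 1 - off)
            found[(s + site_off, strand)] = None

    _search(flank, "+")
    _search(_seq.revcomp(flank), "-")

    loci = []
    for (gp, strand) in found:
        contig, local = index.to_local(gp)
        if strand == "+" and contig == site.contig and local == pos0:
            continue  # self locus
        loci.append(Locus(contig, local + 1, strand))
    loci.sort(key=lambda x: (x.contig, x.position, x.strand))
    truncated = len(loci) > max_hits
    return LinkSearchResult(loci[:max_hits], truncated=truncated,
                            flank_truncated=flank_truncated)


# ------------------------------------------------------------------ network


class _DSU:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        root = x
        while self.parent.setdefault(root, root) != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


@dataclass
class SiteEntry:
    site: SiteKey
    flag: str
    links: list[Locus] = field(default_factory=list)


class ThesaurusNetwork:
    """Symmetric link sets per candidate site plus their transitive clusters."""

    def __init__(self, max_links: int = DEFAULT_MAX_LINKS):
        self.max_links = max_links
        self.sites: dict[tuple[str, int], SiteEntry] = {}
        self._adjacency: dict | None = None
        self._clusters: dict | None = None

    def add_site(self, site: SiteKey, flag: str, links: Iterable[Locus] = ()):
        self.sites[(site.contig, site.position)] = SiteEntry(site, flag, list(links))
        self._adjacency = self._clusters = None

    def __len__(self):
        return len(self.sites)

    def __contains__(self, key):
        return key in self.sites

    def entry(self, contig: str, position: int) -> SiteEntry | None:
        return self.sites.get((contig, position))

    def flag(self, contig: str, position: int) -> str:
        e = self.entry(contig, position)
        return e.flag if e is not None else FLAG_NONE

    def n_links(self, contig: str, position: int) -> int:
        e = self.entry(contig, position)
        return len(e.links) if e is not None else 0

    def t_set(self, contig: str, position: int) -> list[Locus]:
        """T(i): the site itself plus its linked loci. Sites flagged
        thesaurusmany/thesaurushard aggregate over themselves only."""
        self_locus = Locus(contig, position, "+")
        e = self.entry(contig, position)
        if e is None or e.flag != FLAG_THESAURUS:
            return [self_locus]
        return [self_locus] + list(e.links)

    def adjacency(self) -> dict:
        """Symmetric position-level adjacency over all involved loci."""
        if self._adjacency is None:
            adj: dict[tuple[str, int], set] = {}
            for (c, p), e in self.sites.items():
                for loc in e.links:
                    adj.setdefault((c, p), set()).add((loc.contig, loc.position))
                    adj.setdefault((loc.contig, loc.position), set()).add((c, p))
            self._adjacency = adj
        return self._adjacency

    def neighbors(self, contig: str, position: int) -> set:
        return self.adjacency().get((contig, position), set())

    def clusters(self) -> dict:
        """Map every involved locus to a cluster id (transitive closure)."""
        if self._clusters is None:
            dsu = _DSU()
            for (c, p), e in self.sites.items():
                dsu.find((c, p))
                for loc in e.links:
                    dsu.union((c, p), (loc.contig, loc.position))
            roots: dict = {}
            out = {}
            for node in list(dsu.parent):
                r = dsu.find(node)
                out[node] = roots.setdefault(r, len(roots))
            self._clusters = out
        return self._clusters


def _low_mapq_mask(alignment_source, contigs: dict[str, int], max_mapq: int):
    """Boolean per-position masks of coverage by ambiguous (low-MQ) reads."""
    import pysam

    masks = {c: np.zeros(n + 1, dtype=np.int32) for c, n in contigs.items()}
    with pysam.AlignmentFile(str(alignment_source)) as bam:
        for read in bam.fetch():
            if read.is_unmapped or read.mapping_quality > max_mapq:
                continue
            m = masks.get(read.reference_name)
            if m is None:
                continue
            m[read.reference_start] += 1
            m[read.reference_end or read.reference_start] -= 1
    return {c: np.cumsum(m[:-1]) > 0 for c, m in masks.items()}


def build_network(
    genome: SyntheticGenome | str | Path,
    candidate_sites: Sequence[SiteKey],
    alignment_source=None,
    max_links: int = DEFAULT_MAX_LINKS,
    window: int = DEFAULT_WINDOW,
    max_mismatches: int | None = None,
    require_read_support: bool = True,
    ambiguous_mapq_max: int = 3,
    exempt_candidate_flanks: bool = True,
    index: GenomeIndex | None = None,
) -> ThesaurusNetwork:
    """Discover, vet, symmetrise and cluster thesaurus links for candidates.

    When an alignment is supplied and ``require_read_support`` is on, a link
    is retained only if at least one ambiguous (low mapping quality) read
    covers the site or its alternative locus — such reads are exactly the
    ones consistent with the alternative placement. Flags are assigned per
    site; ``thesaurusmany`` sites keep no links and are excluded from
    aggregation and clustering.
    """
    if index is None:
        index = GenomeIndex(genome)
    exempt = (
        {(s.contig, s.position) for s in candidate_sites}
        if exempt_candidate_flanks else set()
    )
    lowmq = None
    if alignment_source is not None and require_read_support:
        contigs = {c: len(index.codes[c]) for c in index.contig_names}
        lowmq = _low_mapq_mask(alignment_source, contigs, ambiguous_mapq_max)

    net = ThesaurusNetwork(max_links=max_links)
    for site in candidate_sites:
        res = find_alternative_loci(
            index, site, window=window, max_mismatches=max_mismatches,
            max_hits=max_links + 1, exempt_positions=exempt,
        )
        if res.hard:
            net.add_site(site, FLAG_HARD)
            continue
        loci = res.loci
        if lowmq is not None:
            def witnessed(loc: Locus) -> bool:
                here = lowmq[site.contig][site.position - 1]
                there_mask = lowmq.get(loc.contig)
                there = bool(there_mask[loc.position - 1]) if there_mask is not None else False
                return bool(here) or there
            loci = [l for l in loci if witnessed(l)]
        if res.truncated or len(loci) > max_links:
            net.add_site(site, FLAG_MANY)
        elif loci:
            net.add_site(site, FLAG_THESAURUS, loci)
        else:
            net.add_site(site, FLAG_NONE)

    _symmetrize(net)
    return net


def _symmetrize(net: ThesaurusNetwork) -> None:
    """Ensure that candidate-to-candidate links are mutual."""
    for (c, p), e in list(net.sites.items()):
        if e.flag not in (FLAG_THESAURUS,):
            continue
        for loc in e.links:
            other = net.entry(loc.contig, loc.position)
            if other is None or other.flag in (FLAG_MANY, FLAG_HARD):
                continue
            back = Locus(c, p, loc.strand)
            if (c, p) not in {(l.contig, l.position) for l in other.links}:
                other.links.append(back)
                other.links.sort(key=lambda x: (x.contig, x.position, x.strand))
                if other.flag == FLAG_NONE and len(other.links) <= net.max_links:
                    other.flag = FLAG_THESAURUS
    net._adjacency = net._clusters = None


def generate_random_links(
    candidate_sites: Sequence[SiteKey],
    genome: SyntheticGenome,
    degrees: "ThesaurusNetwork | dict",
    seed: int = 0,
) -> ThesaurusNetwork:
    """Negative-control network: same per-site link counts, uniformly random
    target loci. Used to show the benchmark gain requires computed links."""
    rng = np.random.default_rng(seed)
    if isinstance(degrees, ThesaurusNetwork):
        deg = {k: len(e.links) if e.flag == FLAG_THESAURUS else 0
               for k, e in degrees.sites.items()}
        max_links = degrees.max_links
    else:
        deg = dict(degrees)
        max_links = DEFAULT_MAX_LINKS
    contigs = genome.contigs
    lengths = genome.lengths()
    net = ThesaurusNetwork(max_links=max_links)
    for site in candidate_sites:
        n = deg.get((site.contig, site.position), 0)
        loci = []
        for _ in range(n):
            c = contigs[int(rng.integers(0, len(contigs)))]
            p = int(rng.integers(1, lengths[c] + 1))
            loci.append(Locus(c, p, "+"))
        loci.sort(key=lambda x: (x.contig, x.position, x.strand))
        net.add_site(site, FLAG_THESAURUS if loci else FLAG_NONE, loci)
    return net


# ---------------------------------------------------------------------- I/O

_LINKS_HEADER = "#contig\tposition\tref\talt\tflag\tn_links\talt_loci\n"


def write_links(network: ThesaurusNetwork, path: str | Path) -> str:
    """Serialise the network as the dedicated links file (TSV)."""
    with open(path, "w") as fh:
        fh.write(f"##varthesaurus links max_links={network.max_links}\n")
        fh.write(_LINKS_HEADER)
        for (c, p) in sorted(network.sites):
            e = network.sites[(c, p)]
            alts = ";".join(f"{l.contig}:{l.position}:{l.strand}" for l in e.links) or "."
            fh.write(
                f"{c}\t{p}\t{e.site.ref}\t{e.site.alt}\t{e.flag}\t{len(e.links)}\t{alts}\n"
            )
    return str(path)


def read_links(path: str | Path, contigs: Sequence[str] | None = None) -> ThesaurusNetwork:
    """Parse a links file; malformed lines are reported with line numbers."""
    net = ThesaurusNetwork()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                if "max_links=" in line:
                    net.max_links = int(line.split("max_links=")[1].split()[0])
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            c, p, ref, alt, flag, n_links, alts = parts
            if contigs is not None and c not in contigs:
                raise ValueError(f"{path}:{lineno}: unknown contig {c!r}")
            try:
                position = int(p)
                loci = []
                if alts != ".":
                    for tok in alts.split(";"):
                        lc, lp, strand = tok.rsplit(":", 2)
                        if contigs is not None and lc not in contigs:
                            raise ValueError(f"{path}:{lineno}: unknown contig {lc!r}")
                        loci.append(Locus(lc, int(lp), strand))
            except ValueError as err:
                if "unknown contig" in str(err):
                    raise
                raise ValueError(f"{path}:{lineno}: malformed line ({err})") from err
            net.add_site(SiteKey(c, position, ref, alt), flag, loci)
    return net
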