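"""Matched-sample annotation: local and thesaurus-adjusted allele frequencies.

The annotator runs the second pass of the thesaurus workflow: given the case
sample's candidate sites and the link network built from them, it collects
pileups at every candidate and every linked locus, in the case sample and in
each matched sample, and computes two frequency estimates per (site, sample):

* the local allele frequency, m(i)/C(i), from reads at the site alone;
* the thesaurus-adjusted allele frequency,
  |T(i)| * (sum of m over T(i)) / (sum of C over T(i)),
  which pools the evidence scattered across all loci in the linked set T(i)
  (the site plus its links) and rescales by the set size so a heterozygous
  variant diluted over copies is restored toward its true frequency. The
  adjusted value may exceed 1; it is stored raw, never capped.

Sites flagged ``thesaurusmany``/``thesaurushard`` receive no adjusted
frequency; unlinked sites have the adjusted value equal to the local one by
construction. The output is a representation of summary statistics on all
candidate sites — not a call set; no candidate is ever dropped here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam

from . import _seq
from .genome import SyntheticGenome
from .links import (FLAG_HARD, FLAG_MANY, FLAG_NONE, FLAG_THESAURUS,
                    ThesaurusNetwork, write_links)
from .pileup import SiteKey, pileup_at_sites, read_candidate_vcf

TS_FORMAT_FIELD = "TS"  # per-genotype thesaurus link count

_PER_SAMPLE_COLS = (
    "m", "C", "af_local", "af_thesaurus", "cluster_m", "cluster_C",
    "fwd_alt", "rev_alt", "fwd_ref", "rev_ref", "mean_mismatches",
)


def af_local(m: int, C: int) -> float:
    """Local allele frequency m/C; NaN when there is no coverage."""
    if m < 0 or C < 0 or m > C:
        raise ValueError(f"invalid counts m={m}, C={C}")
    return m / C if C > 0 else float("nan")


def af_thesaurus(cluster_counts: Sequence[tuple[int, int]], cluster_size: int) -> float:
    """Thesaurus-adjusted allele frequency over a linked set of loci.

    ``cluster_counts`` are the (m, C) pairs at each locus of T(i), the site
    itself included; ``cluster_size`` is |T(i)|. Returns
    cluster_size * sum(m) / sum(C), NaN when total coverage is zero. The
    value is intentionally allowed to exceed 1.
    """
    if cluster_size < 1:
        raise ValueError("cluster_size must be >= 1")
    m_sum = sum(m for m, _ in cluster_counts)
    c_sum = sum(c for _, c in cluster_counts)
    if c_sum <= 0:
        return float("nan")
    return cluster_size * m_sum / c_sum


@dataclass
class AnnotationResult:
    """AF table plus the artefacts of an annotation run."""

    table: pd.DataFrame
    case: str
    samples: list[str]
    network: ThesaurusNetwork | None
    vcf_path: str | None = None
    links_path: str | None = None
    table_path: str | None = None

    def write_table(self, path: str | Path) -> str:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")
        self.table_path = str(path)
        return str(path)


def _projected_query(site: SiteKey, locus, reference: SyntheticGenome):
    """(contig, pos, ref, alt) to count at a linked locus: the site's alt
    projected through the link (complemented for reverse-strand links)."""
    codes = reference.haplotypes[locus.contig][0]
    ref_base = _seq.BASES[codes[locus.position - 1]]
    alt = site.alt if locus.strand == "+" else _seq.complement_base(site.alt)
    return (locus.contig, locus.position, ref_base, alt)


def annotate_matched(
    candidates,
    case_alignment,
    matched_alignments: Mapping[str, object],
    network: ThesaurusNetwork | None,
    reference: SyntheticGenome,
    case: str = "case",
    min_mapping_quality: int = 0,
    min_base_quality: int = 5,
    out_prefix: str | Path | None = None,
) -> AnnotationResult:
    """Annotate every candidate with per-sample local/adjusted frequencies.

    ``candidates`` may be a list of SiteKeys or a VCF path. Pileups at
    linked loci are collected at ``min_mapping_quality`` (default 0: the
    evidence at alternative loci is by construction low-MQ, so excluding
    multi-mapped reads would empty the sums). When ``out_prefix`` is given,
    writes ``<prefix>.vcf`` (annotated), ``<prefix>.links.tsv`` and
    ``<prefix>.af.tsv``.
    """
    in_vcf = None
    if isinstance(candidates, (str, Path)):
        in_vcf = str(candidates)
        sites = read_candidate_vcf(candidates)
    else:
        sites = list(candidates)

    alignments = {case: case_alignment, **dict(matched_alignments)}
    sample_names = list(alignments)

    # one pileup query per distinct (contig, pos, ref, alt)
    queries: dict[tuple, int] = {}
    site_query: list[int] = []
    tset_queries: list[list[int]] = []
    for site in sites:
        own = (site.contig, site.position, site.ref, site.alt)
        site_query.append(queries.setdefault(own, len(queries)))
        qlist = []
        if network is not None:
            entry = network.entry(site.contig, site.position)
            if entry is not None and entry.flag == FLAG_THESAURUS:
                qlist = [
                    queries.setdefault(_projected_query(site, loc, reference), len(queries))
                    for loc in entry.links
                ]
        tset_queries.append(qlist)

    ordered = sorted(queries, key=lambda q: (q[0], q[1]))
    reindex = {queries[q]: i for i, q in enumerate(ordered)}
    site_query = [reindex[i] for i in site_query]
    tset_queries = [[reindex[i] for i in qs] for qs in tset_queries]

    per_sample = {}
    for name in sample_names:
        per_sample[name] = pileup_at_sites(
            alignments[name], ordered,
            min_mapping_quality=min_mapping_quality,
            min_base_quality=min_base_quality, sample=name,
        )

    rows = []
    for i, site in enumerate(sites):
        flag = network.flag(site.contig, site.position) if network is not None else FLAG_NONE
        n_links = network.n_links(site.contig, site.position) if network is not None else 0
        if flag in (FLAG_MANY, FLAG_HARD):
            n_links = 0
        row = {
            "contig": site.contig, "position": site.position,
            "ref": site.ref, "alt": site.alt,
            "n_links": n_links, "filter": flag,
        }
        for name in sample_names:
            own = per_sample[name][site_query[i]]
            local = af_local(own.m, own.C)
            if flag == FLAG_THESAURUS and n_links > 0:
                cluster = [own] + [per_sample[name][q] for q in tset_queries[i]]
                counts = [(p.m, p.C) for p in cluster]
                adjusted = af_thesaurus(counts, len(cluster))
                cm = sum(p.m for p in cluster)
                cc = sum(p.C for p in cluster)
            elif flag in (FLAG_MANY, FLAG_HARD):
                adjusted, cm, cc = float("nan"), own.m, own.C
            else:
                adjusted, cm, cc = local, own.m, own.C
            row.update({
                f"{name}.m": own.m, f"{name}.C": own.C,
                f"{name}.af_local": local, f"{name}.af_thesaurus": adjusted,
                f"{name}.cluster_m": cm, f"{name}.cluster_C": cc,
                f"{name}.fwd_alt": own.fwd_alt, f"{name}.rev_alt": own.rev_alt,
                f"{name}.fwd_ref": own.fwd_ref, f"{name}.rev_ref": own.rev_ref,
                f"{name}.mean_mismatches": own.mean_mismatches,
            })
        rows.append(row)
    columns = ["contig", "position", "ref", "alt", "n_links", "filter"] + [
        f"{name}.{c}" for name in sample_names for c in _PER_SAMPLE_COLS
    ]
    table = pd.DataFrame(rows, columns=columns)

    result = AnnotationResult(table=table, case=case, samples=sample_names,
                              network=network)
    if out_prefix is not None:
        prefix = str(out_prefix)
        result.vcf_path = write_annotated_vcf(
            sites, network, reference, prefix + ".vcf",
            samples=sample_names, in_vcf=in_vcf,
        )
        if network is not None:
            result.links_path = write_links(network, prefix + ".links.tsv")
        result.write_table(prefix + ".af.tsv")
    return result


def write_annotated_vcf(
    sites: Sequence[SiteKey],
    network: ThesaurusNetwork | None,
    reference: SyntheticGenome,
    path: str | Path,
    samples: Sequence[str] = ("case",),
    in_vcf: str | None = None,
) -> str:
    """Emit the candidates as VCF with thesaurus FILTER codes and a
    per-genotype TS (link count) FORMAT field.

    When the candidates came from a VCF, its header INFO definitions and
    per-record INFO content are carried over; records are otherwise
    preserved as-is, with only FILTER codes and FORMAT fields added.
    """
    header = pysam.VariantHeader()
    info_by_key: dict[tuple, dict] = {}
    if in_vcf is not None:
        with pysam.VariantFile(in_vcf) as src:
            for rec in src.header.records:
                if rec.type in ("INFO", "FILTER", "CONTIG"):
                    header.add_record(rec)
            for rec in src:
                for alt in rec.alts or ():
                    info_by_key[(rec.contig, rec.pos, rec.ref, alt)] = dict(rec.info)
    if not list(header.contigs):
        for contig, length in reference.lengths().items():
            header.contigs.add(contig, length=length)
    for flag, desc in (
        (FLAG_THESAURUS, "Site has thesaurus links to alternative loci"),
        (FLAG_MANY, "Site linked to an excessive number of alternative sites"),
        (FLAG_HARD, "Thesaurus links could not be computed for this site"),
    ):
        if flag not in header.filters:
            header.filters.add(flag, None, None, desc)
    header.formats.add(TS_FORMAT_FIELD, 1, "Integer", "Number of thesaurus links")
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sorted(set(sites), key=lambda s: (s.contig, s.position, s.alt)):
            rec = out.new_record(
                contig=site.contig, start=site.position - 1,
                alleles=(site.ref, site.alt),
            )
            for k, v in info_by_key.get(
                (site.contig, site.position, site.ref, site.alt), {}
            ).items():
                if k in header.info:
                    rec.info[k] = v
            flag = network.flag(site.contig, site.position) if network is not None else FLAG_NONE
            n_links = network.n_links(site.contig, site.position) if network is not None else 0
            if flag == FLAG_NONE:
                rec.filter.add("PASS")
            else:
                rec.filter.add(flag)
            for s in samples:
                rec.samples[s][TS_FORMAT_FIELD] = n_links
            out.write(rec)
    return str(path)


def read_af_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
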