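"""Threshold-based somatic and de novo mutation calling from AF tables.

Deliberately transparent rule-based callers over the annotated allele
frequencies:

* somatic (tumor/normal): case AF >= 0.15, case/control fold change >= 1.2,
  control AF <= 0.05 by default; alternatively a single AF-difference rule
  (case - control >= d, control still below its cap) replaces the first two
  criteria when ``min_af_difference`` is set.
* de novo (child/mother/father): child AF >= 0.3, both parents' AF <= 0.02,
  both parents covered by >= 10 reads — except on the Y chromosome, where
  the coverage requirement applies to the father only.

Variants flagged ``thesaurusmany``/``thesaurushard`` or marked structural
are excluded up front. Each candidate keeps a trace naming the first
criterion it failed (evaluation order: flag exclusions, case AF, control AF,
fold change/difference, coverage, strand bias, mismatch load), so call sets
are fully auditable. Read-level filters for noisy real data — strand-bias
Fisher P below a cutoff (default 0.06) and mean mismatch load of supporting
reads above a cap (default 6) — can be applied to any call set.

Boundary convention: thresholds are compared inclusively (>= / <=).
A control AF of zero gives an infinite fold change, which passes any
fold-change threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .pileup import PileupCounts, SiteKey, strand_bias_p

DEFAULT_EXCLUDED_FILTERS = ("thesaurusmany", "thesaurushard", "structural")


@dataclass
class CallingThresholds:
    """Tunable thresholds for the rule-based callers.

    ``max_strand_p`` / ``max_mean_mismatches`` set to None disable the
    corresponding read-level filter.
    """

    min_case_af: float = 0.15
    min_fold_change: float = 1.2
    max_control_af: float = 0.05
    min_af_difference: float | None = None
    max_strand_p: float | None = 0.06
    max_mean_mismatches: float | None = 6.0
    min_control_coverage: int = 10
    chr_y_label: str = "chrY"

    def __post_init__(self):
        # min_case_af may exceed 1: thesaurus-adjusted AFs are uncapped and
        # threshold sweeps legitimately probe values above unity
        if self.min_case_af < 0:
            raise ValueError(f"min_case_af must be >= 0, got {self.min_case_af}")
        if not 0 <= self.max_control_af <= 1:
            raise ValueError(
                f"max_control_af must be in [0, 1], got {self.max_control_af}")
        if self.min_fold_change < 1:
            raise ValueError("min_fold_change must be >= 1")
        if self.min_af_difference is not None and not 0 <= self.min_af_difference <= 1:
            raise ValueError("min_af_difference must be in [0, 1]")


def somatic_defaults(**overrides) -> CallingThresholds:
    return replace(CallingThresholds(), **overrides)


def trio_defaults(**overrides) -> CallingThresholds:
    return replace(
        CallingThresholds(min_case_af=0.3, max_control_af=0.02), **overrides
    )


@dataclass
class CallSet:
    """All evaluated candidates with per-candidate pass/trace bookkeeping."""

    table: pd.DataFrame  # includes 'called' (bool) and 'trace' columns
    mode: str  # somatic | denovo
    used_af: str  # local | thesaurus

    @property
    def calls(self) -> pd.DataFrame:
        return self.table[self.table["called"]]

    def __len__(self) -> int:
        return int(self.table["called"].sum())

    def positions(self) -> list[tuple[str, int]]:
        return list(zip(self.calls["contig"], self.calls["position"]))

    def sites(self) -> list[SiteKey]:
        return [
            SiteKey(r.contig, r.position, r.ref, r.alt)
            for r in self.calls.itertuples(index=False)
        ]

    def write_tsv(self, path: str | Path) -> str:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")
        return str(path)

    def to_vcf(self, reference, path: str | Path) -> str:
        """Calls only, FILTER=PASS, INFO carrying mode and AF source."""
        import pysam

        header = pysam.VariantHeader()
        for contig, length in reference.lengths().items():
            header.contigs.add(contig, length=length)
        header.info.add("MODE", 1, "String", "Calling mode (somatic or denovo)")
        header.info.add("AFSRC", 1, "String", "Allele-frequency source (local or thesaurus)")
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for r in self.calls.itertuples(index=False):
                rec = vcf.new_record(
                    contig=r.contig, start=r.position - 1, alleles=(r.ref, r.alt)
                )
                rec.filter.add("PASS")
                rec.info["MODE"] = self.mode
                rec.info["AFSRC"] = self.used_af
                vcf.write(rec)
        return str(path)


def _af_columns(table: pd.DataFrame, sample: str, use_thesaurus_af: bool) -> pd.Series:
    local = table[f"{sample}.af_local"]
    if not use_thesaurus_af:
        return local
    adjusted = table[f"{sample}.af_thesaurus"]
    return adjusted.where(adjusted.notna(), local)


def _flag_excluded(row_filter, excluded: Sequence[str]) -> bool:
    if not isinstance(row_filter, str):
        return False
    codes = set(row_filter.split(";"))
    return bool(codes & set(excluded))


def call_somatic(
    annotations: pd.DataFrame,
    case: str,
    control: str,
    thresholds: CallingThresholds | None = None,
    use_thesaurus_af: bool = True,
    excluded_filters: Sequence[str] = DEFAULT_EXCLUDED_FILTERS,
) -> CallSet:
    """Call somatic mutations from a case/control annotated AF table."""
    th = thresholds or somatic_defaults()
    for s in (case, control):
        if f"{s}.af_local" not in annotations.columns:
            raise ValueError(f"sample {s!r} not present in the annotation table")

    table = annotations.copy()
    case_af = _af_columns(table, case, use_thesaurus_af).to_numpy(dtype=float)
    ctrl_af = _af_columns(table, control, use_thesaurus_af).to_numpy(dtype=float)
    filters = table["filter"] if "filter" in table.columns else pd.Series("", index=table.index)

    traces = []
    called = []
    for i in range(len(table)):
        trace = _somatic_trace(
            case_af[i], ctrl_af[i], filters.iloc[i], th, excluded_filters
        )
        traces.append(trace)
        called.append(trace == "pass")
    table["case_af"] = case_af
    table["control_af"] = ctrl_af
    table["trace"] = traces
    table["called"] = called
    return CallSet(table, mode="somatic",
                   used_af="thesaurus" if use_thesaurus_af else "local")


def _somatic_trace(case_af, ctrl_af, flt, th: CallingThresholds, excluded) -> str:
    if _flag_excluded(flt, excluded):
        return "filter_code"
    ctrl = 0.0 if math.isnan(ctrl_af) else ctrl_af
    if th.min_af_difference is not None:
        if math.isnan(case_af) or case_af - ctrl < th.min_af_difference:
            return "af_difference"
        if ctrl > th.max_control_af:
            return "control_af"
        return "pass"
    if math.isnan(case_af) or case_af < th.min_case_af:
        return "case_af"
    if ctrl > th.max_control_af:
        return "control_af"
    fold = math.inf if ctrl == 0 else case_af / ctrl
    if fold < th.min_fold_change:
        return "fold_change"
    return "pass"


def call_denovo_trio(
    annotations: pd.DataFrame,
    child: str,
    mother: str,
    father: str,
    thresholds: CallingThresholds | None = None,
    use_thesaurus_af: bool = True,
    excluded_filters: Sequence[str] = DEFAULT_EXCLUDED_FILTERS,
) -> CallSet:
    """Call de novo mutations in the child of a family trio.

    Parental absence must be certified by coverage: both parents need
    ``min_control_coverage`` reads at the site, except on the Y chromosome
    where only the father is required. Strand-bias and mismatch-load
    eliminations run automatically when the child's pileup columns are
    present and the corresponding thresholds are set.
    """
    th = thresholds or trio_defaults()
    for s in (child, mother, father):
        if f"{s}.af_local" not in annotations.columns:
            raise ValueError(f"sample {s!r} not present in the annotation table")

    table = annotations.copy()
    child_af = _af_columns(table, child, use_thesaurus_af).to_numpy(dtype=float)
    mo_af = _af_columns(table, mother, use_thesaurus_af).to_numpy(dtype=float)
    fa_af = _af_columns(table, father, use_thesaurus_af).to_numpy(dtype=float)
    mo_cov = table[f"{mother}.C"].to_numpy()
    fa_cov = table[f"{father}.C"].to_numpy()
    filters = table["filter"] if "filter" in table.columns else pd.Series("", index=table.index)
    has_pileup_cols = f"{child}.fwd_alt" in table.columns

    traces = []
    for i in range(len(table)):
        trace = _trio_trace(
            child_af[i], mo_af[i], fa_af[i], int(mo_cov[i]), int(fa_cov[i]),
            table["contig"].iloc[i], filters.iloc[i], th, excluded_filters,
        )
        if trace == "pass" and has_pileup_cols:
            trace = _read_filter_trace(table.iloc[i], child, th)
        traces.append(trace)
    table["case_af"] = child_af
    table["mother_af"] = mo_af
    table["father_af"] = fa_af
    table["trace"] = traces
    table["called"] = [t == "pass" for t in traces]
    return CallSet(table, mode="denovo",
                   used_af="thesaurus" if use_thesaurus_af else "local")


def _trio_trace(child_af, mo_af, fa_af, mo_cov, fa_cov, contig, flt,
                th: CallingThresholds, excluded) -> str:
    if _flag_excluded(flt, excluded):
        return "filter_code"
    if math.isnan(child_af) or child_af < th.min_case_af:
        return "case_af"
    mo = 0.0 if math.isnan(mo_af) else mo_af
    fa = 0.0 if math.isnan(fa_af) else fa_af
    if mo > th.max_control_af or fa > th.max_control_af:
        return "control_af"
    on_y = contig == th.chr_y_label
    if fa_cov < th.min_control_coverage:
        return "coverage"
    if not on_y and mo_cov < th.min_control_coverage:
        return "coverage"
    return "pass"


def _read_filter_trace(row, sample: str, th: CallingThresholds) -> str:
    """Strand-bias / mismatch-load elimination from pileup columns."""
    if th.max_strand_p is not None:
        counts = PileupCounts(
            site=None, sample=sample,
            m=int(row[f"{sample}.fwd_alt"]) + int(row[f"{sample}.rev_alt"]),
            C=int(row[f"{sample}.C"]),
            fwd_alt=int(row[f"{sample}.fwd_alt"]),
            rev_alt=int(row[f"{sample}.rev_alt"]),
            fwd_ref=int(row[f"{sample}.fwd_ref"]),
            rev_ref=int(row[f"{sample}.rev_ref"]),
            mean_mismatches=float(row[f"{sample}.mean_mismatches"]),
        )
        if counts.C > 0 and strand_bias_p(counts) < th.max_strand_p:
            return "strand_bias"
    if th.max_mean_mismatches is not None:
        mn = float(row[f"{sample}.mean_mismatches"])
        if not math.isnan(mn) and mn > th.max_mean_mismatches:
            return "mismatch_load"
    return "pass"


def apply_read_filters(
    calls: CallSet,
    pileups,
    thresholds: CallingThresholds | None = None,
) -> CallSet:
    """Remove calls with excessive strand bias or mismatch load.

    ``pileups`` are case-sample PileupCounts (list or DataFrame from
    ``pileups_to_dataframe``), matched to calls by (contig, position, alt).
    Removed calls keep a trace naming the removing filter.
    """
    th = thresholds or CallingThresholds()
    if isinstance(pileups, pd.DataFrame):
        lookup = {
            (r.contig, r.position, r.alt): PileupCounts(
                site=None, sample=getattr(r, "sample", "case"),
                m=r.m, C=r.C, fwd_alt=r.fwd_alt, rev_alt=r.rev_alt,
                fwd_ref=r.fwd_ref, rev_ref=r.rev_ref,
                mean_mismatches=r.mean_mismatches,
            )
            for r in pileups.itertuples(index=False)
        }
    else:
        lookup = {
            (p.site.contig, p.site.position, p.site.alt): p for p in pileups
        }

    table = calls.table.copy()
    for i in table.index[table["called"]]:
        key = (table.at[i, "contig"], table.at[i, "position"], table.at[i, "alt"])
        p = lookup.get(key)
        if p is None:
            continue
        if th.max_strand_p is not None and p.C > 0 \
                and strand_bias_p(p) < th.max_strand_p:
            table.at[i, "called"] = False
            table.at[i, "trace"] = "strand_bias"
            continue
        if th.max_mean_mismatches is not None and p.m > 0 \
                and p.mean_mismatches > th.max_mean_mismatches:
            table.at[i, "called"] = False
            table.at[i, "trace"] = "mismatch_load"
    return CallSet(table, mode=calls.mode, used_af=calls.used_af)
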