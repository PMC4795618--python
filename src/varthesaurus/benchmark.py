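"""Thesaurus-aware benchmarking of call sets against a known truth.

Classification vocabulary: truth sites are actual positives (AP). A call at
a truth position is a true positive (TP); a call that is not at a truth
position but is linked to one through the thesaurus network is a thesaurus
true positive (TTP); any other call is a false positive (FP). A truth site
that is neither called nor linked to a called site is a false negative (FN).

Derived metrics avoid referencing TP directly:

    TPR = (AP - FN) / AP
    FDR = (0.5 + FP) / (0.5 + FP + AP - FN)

The 0.5 smoothing keeps FDR strictly positive so it can be shown on a log
scale; with very few recovered positives it deliberately saturates high.
With an empty network TTP is impossible and the definitions reduce to the
classical lenient-free ones (plus smoothing).

Matching is position-level by default (alt alleles at linked loci may be
strand-projected); a strict allele-matching mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .calling import CallSet
from .genome import TruthSet
from .links import ThesaurusNetwork


@dataclass
class BenchmarkResult:
    AP: int
    TP: int
    TTP: int
    FP: int
    FN: int

    @property
    def tpr(self) -> float:
        return tpr(self.AP, self.FN)

    @property
    def fdr(self) -> float:
        return fdr(self.FP, self.AP, self.FN)

    @property
    def n_calls(self) -> int:
        return self.TP + self.TTP + self.FP


def tpr(AP: int, FN: int) -> float:
    """True positive rate (AP - FN) / AP; counts link-mediated recoveries."""
    if AP <= 0:
        raise ValueError("TPR undefined for AP = 0")
    if not 0 <= FN <= AP:
        raise ValueError(f"FN must be in [0, AP], got FN={FN}, AP={AP}")
    return (AP - FN) / AP


def fdr(FP: int, AP: int, FN: int) -> float:
    """Smoothed false discovery rate (0.5 + FP) / (0.5 + FP + AP - FN)."""
    if FP < 0 or AP < 0 or not 0 <= FN <= AP:
        raise ValueError("invalid counts")
    return (0.5 + FP) / (0.5 + FP + (AP - FN))


def _call_positions(calls) -> list[tuple[str, int]]:
    if isinstance(calls, CallSet):
        return calls.positions()
    if isinstance(calls, pd.DataFrame):
        return list(zip(calls["contig"], calls["position"]))
    out = []
    for c in calls:
        if hasattr(c, "contig"):
            out.append((c.contig, c.position))
        else:
            out.append((c[0], int(c[1])))
    return out


def _truth_positions(truth) -> list[tuple[str, int]]:
    if isinstance(truth, TruthSet):
        return [(r.contig, r.position) for r in truth.records]
    return _call_positions(truth)


def classify_calls(
    calls,
    truth,
    network: ThesaurusNetwork | None = None,
) -> BenchmarkResult:
    """Classify calls into TP/TTP/FP and truth sites into found/FN."""
    call_pos = set(_call_positions(calls))
    truth_pos = set(_truth_positions(truth))
    neighbors = (lambda p: network.neighbors(*p)) if network is not None else (lambda p: ())

    TP = TTP = FP = 0
    for p in call_pos:
        if p in truth_pos:
            TP += 1
        elif any(q in truth_pos for q in neighbors(p)):
            TTP += 1
        else:
            FP += 1
    FN = 0
    for t in truth_pos:
        if t in call_pos:
            continue
        if any(q in call_pos for q in neighbors(t)):
            continue
        FN += 1
    return BenchmarkResult(AP=len(truth_pos), TP=TP, TTP=TTP, FP=FP, FN=FN)


def jaccard_concordance(
    calls_a,
    calls_b,
    network: ThesaurusNetwork | None = None,
    link_matching: bool = False,
) -> float:
    """Jaccard index of two call sets.

    A site in one set matches the other on exact position, or — with
    ``link_matching`` — through a thesaurus link. Two empty sets are defined
    as fully concordant (1.0).
    """
    a = set(_call_positions(calls_a))
    b = set(_call_positions(calls_b))
    if not a and not b:
        return 1.0

    def matched(p, other):
        if p in other:
            return True
        if link_matching and network is not None:
            return any(q in other for q in network.neighbors(*p))
        return False

    inter = (sum(matched(p, b) for p in a) + sum(matched(p, a) for p in b)) / 2.0
    union = len(a) + len(b) - inter
    return inter / union if union > 0 else 1.0


def sweep_af_thresholds(
    annotations: pd.DataFrame,
    truth,
    network: ThesaurusNetwork | None,
    thresholds_grid: Sequence[float],
    caller,
    **caller_kwargs,
) -> pd.DataFrame:
    """Re-call at a grid of case-AF thresholds and benchmark each call set.

    ``caller`` is ``call_somatic`` or ``call_denovo_trio``; its
    ``thresholds`` object is rebuilt with ``min_case_af`` swept over the
    grid. Returns one row per threshold with counts, TPR and FDR.
    """
    from dataclasses import replace

    if len(thresholds_grid) == 0:
        raise ValueError("thresholds_grid must be nonempty")
    base = caller_kwargs.pop("thresholds", None)
    rows = []
    for t in thresholds_grid:
        th = replace(base, min_case_af=t) if base is not None else None
        if th is None:
            from .calling import CallingThresholds

            th = CallingThresholds(min_case_af=t)
        cs = caller(annotations, thresholds=th, **caller_kwargs)
        res = classify_calls(cs, truth, network)
        rows.append({
            "threshold": t, "n_calls": res.n_calls,
            "TP": res.TP, "TTP": res.TTP, "FP": res.FP, "FN": res.FN,
            "tpr": res.tpr, "fdr": res.fdr,
        })
    return pd.DataFrame(rows)


def result_summary(name: str, res: BenchmarkResult) -> str:
    return (
        f"{name}: AP={res.AP} TP={res.TP} TTP={res.TTP} FP={res.FP} FN={res.FN} "
        f"TPR={res.tpr:.4f} FDR={res.fdr:.3g}"
    )
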