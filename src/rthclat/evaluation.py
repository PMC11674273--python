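"""Accuracy accounting against reference labels (murine LLNA, h-CLAT).

Every report states its own denominator: chemicals whose reference label is
ND are counted in ``n_total`` but excluded from ``n_evaluable`` and from
the match/mismatch tally.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import (
    AccuracyReport,
    Call,
    ChemicalRecord,
    DecisionRule,
    FoldChangeTriplicate,
    HclatJudgment,
    Judgment,
    LlnaCategory,
    MatchStatus,
    ValidationError,
    llna_to_binary,
)
from .qpcr import classify_triplicates, gene_positive

__all__ = [
    "judge_against_llna",
    "attach_reference",
    "accuracy",
    "hclat_accuracy",
    "marker_sweep",
]


def judge_against_llna(call: Call, llna: LlnaCategory) -> MatchStatus:
    """Match/mismatch of a binary call versus the binarized LLNA class."""
    reference = llna_to_binary(llna)
    if reference is None:
        return MatchStatus.NOT_EVALUABLE
    return MatchStatus.MATCH if Call(call) == reference else MatchStatus.MISMATCH


def attach_reference(judgment: Judgment, llna: LlnaCategory) -> Judgment:
    """Return a copy of the judgment with its LLNA reference and match filled in."""
    reference = llna_to_binary(llna)
    return Judgment(
        chemical=judgment.chemical,
        per_gene_positive=dict(judgment.per_gene_positive),
        call=judgment.call,
        reference_binary=reference,
        match=judge_against_llna(judgment.call, llna),
    )


def accuracy(judgments: Sequence[Judgment]) -> AccuracyReport:
    """Tally matches/mismatches; also score each panel gene on its own.

    ``per_gene_consistency`` asks, for every gene seen in the judgments,
    how often a single-gene rule (that gene's positivity alone) would have
    matched the reference among evaluable chemicals.
    """
    if not judgments:
        raise ValidationError("accuracy needs at least one judgment")
    n_total = len(judgments)
    evaluable = [j for j in judgments if j.match is not MatchStatus.NOT_EVALUABLE]
    mismatched = [j.chemical for j in evaluable if j.match is MatchStatus.MISMATCH]
    n_match = sum(j.match is MatchStatus.MATCH for j in evaluable)

    genes = sorted({g for j in judgments for g in j.per_gene_positive})
    per_gene: dict[str, tuple[int, int]] = {}
    for gene in genes:
        scored = [j for j in evaluable if gene in j.per_gene_positive]
        hits = 0
        for j in scored:
            solo = Call.SENSITIZER if j.per_gene_positive[gene] else Call.NON_SENSITIZER
            hits += solo == j.reference_binary
        per_gene[gene] = (hits, len(scored))

    return AccuracyReport(
        n_total=n_total,
        n_evaluable=len(evaluable),
        n_match=n_match,
        n_mismatch=len(mismatched),
        mismatched_chemicals=mismatched,
        per_gene_consistency=per_gene,
    )


def hclat_accuracy(records: Sequence[ChemicalRecord]) -> AccuracyReport:
    """Score the carried h-CLAT judgments (p/n) against the LLNA categories.

    Chemicals with no h-CLAT judgment or no LLNA label are counted in
    ``n_total`` only.
    """
    if not records:
        raise ValidationError("hclat_accuracy needs at least one record")
    n_total = len(records)
    mismatched: list[str] = []
    n_evaluable = 0
    for r in records:
        reference = llna_to_binary(r.llna_category)
        if r.hclat_judgment is HclatJudgment.ND or reference is None:
            continue
        call = (
            Call.SENSITIZER
            if r.hclat_judgment is HclatJudgment.POSITIVE
            else Call.NON_SENSITIZER
        )
        n_evaluable += 1
        if call != reference:
            mismatched.append(r.name)
    return AccuracyReport(
        n_total=n_total,
        n_evaluable=n_evaluable,
        n_match=n_evaluable - len(mismatched),
        n_mismatch=len(mismatched),
        mismatched_chemicals=mismatched,
    )


def marker_sweep(
    triplicates: Iterable[FoldChangeTriplicate],
    llna: Mapping[str, LlnaCategory],
    genes: Sequence[str],
    thresholds: Sequence[float],
    rule_template: DecisionRule | None = None,
) -> pd.DataFrame:
    """Accuracy of each single-gene rule and of the full panel at each threshold.

    Returns one row per (marker, threshold) where ``marker`` is each gene in
    ``genes`` plus ``"panel"`` for the OR-combination of all of them.
    """
    template = rule_template or DecisionRule()
    trips = list(triplicates)
    rows = []
    for thr in thresholds:
        if not thr > 1:
            raise ValidationError(f"threshold must be > 1, got {thr}")
        rule = DecisionRule(
            threshold=thr,
            quorum=template.quorum,
            n_replicates=template.n_replicates,
            panel=tuple(genes),
            inclusive=template.inclusive,
        )
        judged = [
            attach_reference(j, llna[j.chemical])
            for j in classify_triplicates(
                [t for t in trips if t.gene in genes], rule
            )
            if j.chemical in llna
        ]
        panel_report = accuracy(judged)
        rows.append(
            {
                "marker": "panel",
                "threshold": thr,
                "n_evaluable": panel_report.n_evaluable,
                "n_match": panel_report.n_match,
                "accuracy": panel_report.accuracy,
            }
        )
        for gene in genes:
            n_match = n_eval = 0
            for t in trips:
                if t.gene != gene or t.chemical not in llna:
                    continue
                reference = llna_to_binary(llna[t.chemical])
                if reference is None:
                    continue
                call = Call.SENSITIZER if gene_positive(t, rule) else Call.NON_SENSITIZER
                n_eval += 1
                n_match += call == reference
            rows.append(
                {
                    "marker": gene,
                    "threshold": thr,
                    "n_evaluable": n_eval,
                    "n_match": n_match,
                    "accuracy": n_match / n_eval if n_eval else float("nan"),
                }
            )
    return pd.DataFrame(rows)
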