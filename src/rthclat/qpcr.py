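"""Comparative-Cq quantification and the RT h-CLAT decision rule.

Relative expression is computed by the comparative-Cq (delta-delta-Cq)
method: each target gene's Cq is normalized to a reference gene (GAPDH),
the treated delta-Cq is contrasted against the solvent control, and the
linear fold change is ``2 ** -ddCq``.  No amplification-efficiency
correction is applied.

The decision rule then asks, per gene, whether the fold change reaches the
threshold in a majority of replicates, and calls the chemical a sensitizer
if any panel gene is positive.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import pandas as pd

from .types import (
    Call,
    CqTable,
    DecisionRule,
    FoldChangeTriplicate,
    Judgment,
    MatchStatus,
    ValidationError,
)

__all__ = [
    "delta_cq",
    "fold_change",
    "foldchange_table_from_cq",
    "gene_positive",
    "classify",
    "classify_triplicates",
]


def delta_cq(cq_target: float, cq_reference: float) -> float:
    """Normalize a target-gene Cq to the reference gene: ``cq_target - cq_reference``."""
    if not (math.isfinite(cq_target) and math.isfinite(cq_reference)):
        raise ValidationError("Cq values must be finite")
    return cq_target - cq_reference


def fold_change(dcq_treated: float, dcq_control: float) -> float:
    """Linear expression ratio treated/control: ``2 ** -(dCq_treated - dCq_control)``.

    One cycle earlier in the treated sample (ddCq = -1) doubles the ratio.
    """
    if not (math.isfinite(dcq_treated) and math.isfinite(dcq_control)):
        raise ValidationError("delta-Cq values must be finite")
    return 2.0 ** -(dcq_treated - dcq_control)


def foldchange_table_from_cq(
    cq: CqTable,
    reference_gene: str = "GAPDH",
    control_aggregation: str = "paired",
) -> list[FoldChangeTriplicate]:
    """Compute one fold-change triplicate per (chemical, target gene).

    ``control_aggregation`` chooses how the solvent-control delta-Cq enters
    the contrast: ``"paired"`` pairs control replicate i with treated
    replicate i; ``"mean"`` contrasts every treated replicate against the
    mean control delta-Cq.  Both are common comparative-Cq conventions.
    """
    if control_aggregation not in ("paired", "mean"):
        raise ValueError(f"unknown control_aggregation {control_aggregation!r}")
    cq.require_complete(reference_gene)
    f = cq.frame
    pivot = f.set_index(["chemical", "gene", "condition", "replicate"])["cq"].sort_index()

    out: list[FoldChangeTriplicate] = []
    targets = sorted(
        {(c, g) for c, g in zip(f["chemical"], f["gene"]) if g != reference_gene}
    )
    for chem, gene in targets:
        try:
            treated = pivot.loc[(chem, gene, "treated")].sort_index()
            control = pivot.loc[(chem, gene, "solvent_control")].sort_index()
            ref_treated = pivot.loc[(chem, reference_gene, "treated")].sort_index()
            ref_control = pivot.loc[(chem, reference_gene, "solvent_control")].sort_index()
        except KeyError as exc:  # pragma: no cover - require_complete guards this
            raise ValidationError(f"block ({chem}, {gene}): missing rows ({exc})")
        dcq_t = treated - ref_treated.reindex(treated.index)
        dcq_c = control - ref_control.reindex(control.index)
        if dcq_t.isna().any() or dcq_c.isna().any():
            raise ValidationError(
                f"block ({chem}, {gene}): replicate indices do not align with "
                f"the reference gene"
            )
        if control_aggregation == "mean":
            fcs = [fold_change(t, dcq_c.mean()) for t in dcq_t]
        else:
            dcq_c = dcq_c.reindex(dcq_t.index)
            if dcq_c.isna().any():
                raise ValidationError(
                    f"block ({chem}, {gene}): treated and control replicate "
                    f"indices do not pair up"
                )
            fcs = [fold_change(t, c) for t, c in zip(dcq_t, dcq_c)]
        out.append(FoldChangeTriplicate(chem, gene, tuple(fcs)))
    return out


def gene_positive(fc: FoldChangeTriplicate, rule: DecisionRule | None = None) -> bool:
    """True when enough replicates reach the fold-change threshold.

    Only increases count: a triplicate of strong down-regulation is simply
    negative, it never offsets another gene.
    """
    rule = rule or DecisionRule()
    if len(fc.values) != rule.n_replicates:
        raise ValidationError(
            f"({fc.chemical}, {fc.gene}): rule expects {rule.n_replicates} "
            f"replicates, got {len(fc.values)}"
        )
    if rule.inclusive:
        hits = sum(v >= rule.threshold for v in fc.values)
    else:
        hits = sum(v > rule.threshold for v in fc.values)
    return hits >= rule.quorum


def classify(
    chemical: str,
    panel_fcs: Mapping[str, FoldChangeTriplicate],
    rule: DecisionRule | None = None,
) -> Judgment:
    """Apply the panel OR-rule: sensitizer iff any panel gene is positive."""
    rule = rule or DecisionRule()
    per_gene: dict[str, bool] = {}
    for gene in rule.panel:
        if gene not in panel_fcs:
            raise ValidationError(f"{chemical}: panel gene {gene!r} missing from fold changes")
        per_gene[gene] = gene_positive(panel_fcs[gene], rule)
    call = Call.SENSITIZER if any(per_gene.values()) else Call.NON_SENSITIZER
    return Judgment(chemical=chemical, per_gene_positive=per_gene, call=call,
                    reference_binary=None, match=MatchStatus.NOT_EVALUABLE)


def classify_triplicates(
    triplicates: Iterable[FoldChangeTriplicate],
    rule: DecisionRule | None = None,
) -> list[Judgment]:
    """Group triplicates by chemical and classify each against the rule's panel."""
    rule = rule or DecisionRule()
    by_chem: dict[str, dict[str, FoldChangeTriplicate]] = {}
    for t in triplicates:
        by_chem.setdefault(t.chemical, {})[t.gene] = t
    return [classify(chem, fcs, rule) for chem, fcs in by_chem.items()]


def judgments_frame(judgments: Iterable[Judgment]) -> pd.DataFrame:
    """Flatten judgments to a DataFrame for reporting."""
    rows = []
    for j in judgments:
        row = {"chemical": j.chemical, "call": j.call.value, "match": j.match.value}
        for gene, pos in j.per_gene_positive.items():
            row[f"{gene}_positive"] = pos
        rows.append(row)
    return pd.DataFrame(rows)
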