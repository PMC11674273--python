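"""Cross-platform (qPCR vs RNA-Seq) concordance rule for marker retention.

A candidate marker is trusted only when the fold change measured by
real-time PCR agrees with the fold change derived from RNA-Seq TPM ratios.
Per chemical x gene cell: each PCR replicate is flagged when it differs
from the RNA-Seq value by two-fold or more (symmetric ratio, inclusive);
the cell is a mismatch when two or more of the three replicates are
flagged.  A gene is retained as a marker only when every reference
chemical's cell is a match.

Values rounded to one decimal can hit 0.0 for near-silent genes; the flag
treats two zeros as agreement and a zero against a positive value as a
discrepancy, which reproduces the published verdicts for those cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import FoldChangeTriplicate, MatchStatus, ValidationError

__all__ = [
    "discrepancy_flag",
    "concordance_cell",
    "ConcordanceCell",
    "retain_markers",
    "concordance_table",
    "retained_genes",
]

#: replicates that must disagree for a cell-level mismatch
MISMATCH_QUORUM = 2


def discrepancy_flag(pcr_fc: float, ngs_fc: float, threshold: float = 2.0) -> bool:
    """True when the two platform fold changes differ ``threshold``-fold or more.

    Symmetric and scale-invariant: the flag depends only on the ratio
    ``max/min`` of the two values, compared inclusively against the
    threshold.
    """
    if pcr_fc < 0 or ngs_fc < 0:
        raise ValidationError(f"fold changes must be non-negative, got ({pcr_fc}, {ngs_fc})")
    if pcr_fc == 0 and ngs_fc == 0:
        return False
    if pcr_fc == 0 or ngs_fc == 0:
        return True
    hi, lo = (pcr_fc, ngs_fc) if pcr_fc >= ngs_fc else (ngs_fc, pcr_fc)
    return hi / lo >= threshold


@dataclass(frozen=True)
class ConcordanceCell:
    """Platform agreement for one chemical x gene."""

    chemical: str
    gene: str
    ngs_fc: float
    pcr_fc: tuple[float, float, float]
    replicate_flags: tuple[bool, bool, bool]
    verdict: MatchStatus

    def __post_init__(self) -> None:
        expected = (
            MatchStatus.MISMATCH
            if sum(self.replicate_flags) >= MISMATCH_QUORUM
            else MatchStatus.MATCH
        )
        if self.verdict != expected:
            raise ValidationError(
                f"({self.chemical}, {self.gene}): verdict {self.verdict} "
                f"inconsistent with flags {self.replicate_flags}"
            )


def _cell(chemical: str, gene: str, pcr_values: tuple[float, ...], ngs_fc: float) -> ConcordanceCell:
    flags = tuple(discrepancy_flag(v, ngs_fc) for v in pcr_values)
    verdict = MatchStatus.MISMATCH if sum(flags) >= MISMATCH_QUORUM else MatchStatus.MATCH
    return ConcordanceCell(
        chemical=chemical,
        gene=gene,
        ngs_fc=ngs_fc,
        pcr_fc=tuple(pcr_values),
        replicate_flags=flags,
        verdict=verdict,
    )


def concordance_cell(pcr: FoldChangeTriplicate, ngs_fc: float) -> ConcordanceCell:
    """Flag each PCR replicate against the RNA-Seq value; mismatch on >=2 of 3."""
    return _cell(pcr.chemical, pcr.gene, pcr.values, ngs_fc)


def retain_markers(
    cells: Iterable[ConcordanceCell],
    required_chemicals: Sequence[str] | None = None,
) -> bool:
    """A gene survives only when every reference chemical's cell is a match.

    When ``required_chemicals`` is given, a missing chemical is an error
    (the retention decision is undefined on a partial panel).
    """
    cells = list(cells)
    if not cells:
        raise ValidationError("retain_markers needs at least one cell")
    genes = {c.gene for c in cells}
    if len(genes) != 1:
        raise ValidationError(f"cells span multiple genes: {sorted(genes)}")
    if required_chemicals is not None:
        seen = {c.chemical for c in cells}
        missing = [c for c in required_chemicals if c not in seen]
        if missing:
            raise ValidationError(
                f"gene {cells[0].gene}: missing chemical(s) {missing}"
            )
    return all(c.verdict is MatchStatus.MATCH for c in cells)


def concordance_table(
    pcr: Iterable[FoldChangeTriplicate],
    ngs: Mapping[tuple[str, str], float],
) -> pd.DataFrame:
    """Per-cell verdicts for every (chemical, gene) with both platform values.

    ``ngs`` maps (chemical, gene) to the RNA-Seq linear fold change.
    """
    rows = []
    for trip in pcr:
        key = (trip.chemical, trip.gene)
        if key not in ngs:
            raise ValidationError(f"no RNA-Seq fold change for {key}")
        cell = concordance_cell(trip, ngs[key])
        rows.append(
            {
                "chemical": cell.chemical,
                "gene": cell.gene,
                "ngs_fc": cell.ngs_fc,
                "pcr_1": cell.pcr_fc[0],
                "pcr_2": cell.pcr_fc[1],
                "pcr_3": cell.pcr_fc[2],
                "n_flags": sum(cell.replicate_flags),
                "verdict": cell.verdict.value,
            }
        )
    return pd.DataFrame(rows)


def panel_concordance(panel: pd.DataFrame) -> pd.DataFrame:
    """Recompute verdicts for a panel frame (chemical, gene, ngs_fc, pcr_1..3).

    Unlike :func:`concordance_table` this path tolerates fold changes of
    exactly zero, which occur in published tables rounded to one decimal.
    """
    for col in ("chemical", "gene", "ngs_fc", "pcr_1", "pcr_2", "pcr_3"):
        if col not in panel.columns:
            raise ValidationError(f"panel frame missing column {col!r}")
    rows = []
    for r in panel.itertuples():
        cell = _cell(r.chemical, r.gene, (r.pcr_1, r.pcr_2, r.pcr_3), r.ngs_fc)
        rows.append(
            {
                "chemical": cell.chemical,
                "gene": cell.gene,
                "ngs_fc": cell.ngs_fc,
                "pcr_1": cell.pcr_fc[0],
                "pcr_2": cell.pcr_fc[1],
                "pcr_3": cell.pcr_fc[2],
                "n_flags": sum(cell.replicate_flags),
                "verdict": cell.verdict.value,
            }
        )
    return pd.DataFrame(rows)


def retained_genes(table: pd.DataFrame, required_chemicals: Sequence[str] | None = None) -> list[str]:
    """Genes whose cells are all matches, in the table's gene order."""
    out: list[str] = []
    for gene, sub in table.groupby("gene", sort=False):
        if required_chemicals is not None:
            missing = [c for c in required_chemicals if c not in set(sub["chemical"])]
            if missing:
                raise ValidationError(f"gene {gene}: missing chemical(s) {missing}")
        if (sub["verdict"] == MatchStatus.MATCH.value).all():
            out.append(gene)
    return out
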