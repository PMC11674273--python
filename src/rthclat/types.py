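"""Domain types shared across the RT h-CLAT pipeline.

The assay treats THP-1 cells with a test chemical, measures marker-gene
expression by real-time PCR (triplicate), and calls the chemical a
sensitizer when any panel gene shows a sufficient fold-change increase in a
majority of replicates.  The types here carry the tabular inputs (chemical
metadata, raw Cq values, fold-change triplicates, RNA-Seq counts) and the
per-chemical verdicts.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "Solvent",
    "LlnaCategory",
    "HclatJudgment",
    "Call",
    "MatchStatus",
    "ChemicalRecord",
    "CqTable",
    "FoldChangeTriplicate",
    "CountMatrix",
    "Judgment",
    "DecisionRule",
    "AccuracyReport",
    "SchemaError",
    "ValidationError",
    "llna_to_binary",
    "CAS_PATTERN",
]


class SchemaError(ValueError):
    """A table is missing a required column or has the wrong layout."""


class ValidationError(ValueError):
    """A row or value violates a domain invariant."""


class Solvent(str, enum.Enum):
    DMSO = "DMSO"
    MEDIUM = "medium"


class LlnaCategory(str, enum.Enum):
    """Murine local lymph node assay potency class (the in vivo reference)."""

    EXTREME = "extreme"
    STRONG = "strong"
    MODERATE = "moderate"
    WEAK = "weak"
    NON_SENSITIZER = "non_sensitizer"
    ND = "ND"


class HclatJudgment(str, enum.Enum):
    """h-CLAT flow-cytometry outcome: positive, negative, or no data."""

    POSITIVE = "p"
    NEGATIVE = "n"
    ND = "ND"


class Call(str, enum.Enum):
    SENSITIZER = "sensitizer"
    NON_SENSITIZER = "non_sensitizer"


class MatchStatus(str, enum.Enum):
    MATCH = "match"
    MISMATCH = "mismatch"
    NOT_EVALUABLE = "not_evaluable"


CAS_PATTERN = re.compile(r"^\d{2,7}-\d{2}-\d$")

_POSITIVE_LLNA = frozenset(
    {LlnaCategory.EXTREME, LlnaCategory.STRONG, LlnaCategory.MODERATE, LlnaCategory.WEAK}
)


def llna_to_binary(category: LlnaCategory) -> Call | None:
    """Collapse an LLNA potency class to a binary sensitizer label.

    Every potency class (extreme/strong/moderate/weak) counts as a
    sensitizer; ``ND`` (no data) maps to ``None`` (not evaluable).
    """
    category = LlnaCategory(category)
    if category is LlnaCategory.ND:
        return None
    if category in _POSITIVE_LLNA:
        return Call.SENSITIZER
    return Call.NON_SENSITIZER


@dataclass(frozen=True)
class ChemicalRecord:
    """One test chemical with its reference labels.

    ``cv75`` (the concentration giving 75% viability, which sets the exposure
    dose) is carried as opaque metadata: the raw string plus a parsed number
    when the string is numeric.  No dose computation is performed here.
    """

    name: str
    abbreviation: str = ""
    cas: str = ""
    solvent: Solvent | None = None
    cv75: str = ""
    llna_category: LlnaCategory = LlnaCategory.ND
    hclat_judgment: HclatJudgment = HclatJudgment.ND

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("chemical name must be non-empty")
        if self.cas and not CAS_PATTERN.match(self.cas):
            raise ValidationError(f"{self.name}: CAS {self.cas!r} does not match NN..N-NN-N")
        object.__setattr__(self, "llna_category", LlnaCategory(self.llna_category))
        object.__setattr__(self, "hclat_judgment", HclatJudgment(self.hclat_judgment))
        if self.solvent is not None:
            object.__setattr__(self, "solvent", Solvent(self.solvent))

    @property
    def cv75_value(self) -> float | None:
        """CV75 as a number when the leading token parses; otherwise None."""
        token = self.cv75.split()[0] if self.cv75.strip() else ""
        token = token.rstrip("%")
        try:
            return float(token)
        except ValueError:
            return None

    @property
    def llna_binary(self) -> Call | None:
        return llna_to_binary(self.llna_category)


#: Canonical column set for a long-format Cq table.
CQ_COLUMNS = ("chemical", "gene", "condition", "replicate", "cq")


@dataclass
class CqTable:
    """Raw quantification-cycle values, one row per well.

    Long format: (chemical, gene, condition in {treated, solvent_control},
    replicate 1..n, cq).  Every treated block must have a matching
    solvent-control block, and the reference gene must be measured alongside
    every target gene so the comparative-Cq normalization is possible.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CQ_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"Cq table missing column(s): {', '.join(missing)}")
        f = self.frame
        bad_cond = set(f["condition"]) - {"treated", "solvent_control"}
        if bad_cond:
            raise ValidationError(f"unknown condition value(s): {sorted(bad_cond)}")
        cq = pd.to_numeric(f["cq"], errors="coerce")
        if cq.isna().any() or not pd.Series(cq).map(math.isfinite).all():
            raise ValidationError("Cq values must be finite numbers")
        if (cq <= 0).any():
            raise ValidationError("Cq values must be positive cycle numbers")
        dup = f.duplicated(subset=["chemical", "gene", "condition", "replicate"])
        if dup.any():
            row = f[dup].iloc[0]
            raise ValidationError(
                f"duplicate replicate_index {row['replicate']} for "
                f"({row['chemical']}, {row['gene']}, {row['condition']})"
            )

    def require_complete(self, reference_gene: str) -> None:
        """Check every treated target block has reference-gene and control rows."""
        f = self.frame
        keys = {(c, g, cond) for c, g, cond in zip(f["chemical"], f["gene"], f["condition"])}
        for chem, gene, cond in sorted(keys):
            if gene == reference_gene:
                continue
            for need in (
                (chem, gene, "solvent_control"),
                (chem, reference_gene, "treated"),
                (chem, reference_gene, "solvent_control"),
            ):
                if need not in keys:
                    raise ValidationError(
                        f"block ({chem}, {gene}): missing rows for "
                        f"({need[0]}, {need[1]}, {need[2]})"
                    )


@dataclass(frozen=True)
class FoldChangeTriplicate:
    """Three linear expression ratios (treated/control) for one chemical x gene.

    This is the unit the decision rule consumes.
    """

    chemical: str
    gene: str
    values: tuple[float, float, float]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) != 3:
            raise ValidationError(
                f"({self.chemical}, {self.gene}): expected exactly 3 fold changes, "
                f"got {len(vals)}"
            )
        for v in vals:
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"({self.chemical}, {self.gene}): fold changes must be finite "
                    f"and > 0, got {v}"
                )
        object.__setattr__(self, "values", vals)

    def __iter__(self):
        return iter(self.values)


class CountMatrix:
    """Gene x sample raw read counts with group labels and gene lengths.

    Parameters
    ----------
    counts
        Integer DataFrame, genes as index, samples as columns.
    lengths
        Effective gene length in bases (for TPM), indexed like ``counts``.
    groups
        Sample -> group label in {sensitizer, non_sensitizer, control}.
    treatments
        Sample -> treatment (test-segment) id.  Defaults to the group label,
        i.e. one segment per group.
    """

    VALID_GROUPS = frozenset({"sensitizer", "non_sensitizer", "control"})

    def __init__(
        self,
        counts: pd.DataFrame,
        lengths: pd.Series,
        groups: Mapping[str, str] | pd.Series,
        treatments: Mapping[str, str] | pd.Series | None = None,
    ) -> None:
        counts = counts.copy()
        arr = counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        if not (arr == arr.astype(int)).all():
            raise ValidationError("counts must be integral")
        self.counts = counts.astype(int)

        lengths = pd.Series(lengths).reindex(counts.index)
        if lengths.isna().any():
            missing = lengths[lengths.isna()].index[0]
            raise ValidationError(f"gene {missing!r} has no length")
        if (lengths <= 0).any():
            raise ValidationError("gene lengths must be > 0")
        self.lengths = lengths.astype(float)

        groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
        missing = [s for s in counts.columns if s not in groups.index]
        if missing:
            raise ValidationError(f"sample(s) missing from metadata: {missing}")
        self.groups = groups.reindex(counts.columns)
        bad = set(self.groups) - self.VALID_GROUPS
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")

        if treatments is None:
            self.treatments = self.groups.copy()
        else:
            treatments = pd.Series(
                dict(treatments) if not isinstance(treatments, pd.Series) else treatments
            )
            self.treatments = treatments.reindex(counts.columns)
            if self.treatments.isna().any():
                miss = self.treatments[self.treatments.isna()].index[0]
                raise ValidationError(f"sample {miss!r} has no treatment id")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[list(genes)],
            self.lengths.loc[list(genes)],
            self.groups,
            self.treatments,
        )

    def replicate_counts(self) -> pd.Series:
        """Number of samples per treatment (test segment)."""
        return self.treatments.value_counts()


@dataclass
class DecisionRule:
    """The RT h-CLAT positivity rule.

    A gene is positive for a chemical when at least ``quorum`` of
    ``n_replicates`` fold changes reach ``threshold`` (inclusive by default:
    a replicate exactly at the threshold counts).  A chemical is called a
    sensitizer when any gene in ``panel`` is positive.  Only increases count;
    down-regulation never contributes.
    """

    threshold: float = 2.0
    quorum: int = 2
    n_replicates: int = 3
    panel: tuple[str, ...] = ("HMOX1", "JUN")
    inclusive: bool = True

    def __post_init__(self) -> None:
        self.panel = tuple(self.panel)
        if not self.threshold > 1:
            raise ValidationError(f"threshold must be > 1, got {self.threshold}")
        if not 1 <= self.quorum <= self.n_replicates:
            raise ValidationError(
                f"quorum must satisfy 1 <= quorum <= n_replicates, got "
                f"{self.quorum}/{self.n_replicates}"
            )

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "DecisionRule":
        known = {"threshold", "quorum", "n_replicates", "panel", "inclusive"}
        kwargs = {k: v for k, v in cfg.items() if k in known}
        if "panel" in kwargs and isinstance(kwargs["panel"], str):
            kwargs["panel"] = tuple(g.strip() for g in kwargs["panel"].split(","))
        return cls(**kwargs)


@dataclass
class Judgment:
    """Per-chemical outcome of the decision rule, plus its reference status."""

    chemical: str
    per_gene_positive: dict[str, bool]
    call: Call
    reference_binary: Call | None = None  # None encodes ND
    match: MatchStatus = MatchStatus.NOT_EVALUABLE

    def __post_init__(self) -> None:
        expected = Call.SENSITIZER if any(self.per_gene_positive.values()) else Call.NON_SENSITIZER
        if self.call != expected:
            raise ValidationError(
                f"{self.chemical}: call {self.call} inconsistent with per-gene "
                f"positivity {self.per_gene_positive}"
            )
        if self.reference_binary is None and self.match != MatchStatus.NOT_EVALUABLE:
            raise ValidationError(f"{self.chemical}: ND reference must be not_evaluable")

    def to_dict(self) -> dict:
        return {
            "chemical": self.chemical,
            "per_gene_positive": dict(self.per_gene_positive),
            "call": self.call.value,
            "reference_binary": None if self.reference_binary is None else self.reference_binary.value,
            "match": self.match.value,
        }


@dataclass
class AccuracyReport:
    """Match/mismatch accounting against a reference label set.

    ``n_evaluable`` excludes chemicals whose reference label is ND; the
    denominator of every rate reported by this package is explicit.
    """

    n_total: int
    n_evaluable: int
    n_match: int
    n_mismatch: int
    mismatched_chemicals: list[str] = field(default_factory=list)
    per_gene_consistency: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_match + self.n_mismatch != self.n_evaluable:
            raise ValidationError("n_match + n_mismatch must equal n_evaluable")
        if self.n_evaluable > self.n_total:
            raise ValidationError("n_evaluable cannot exceed n_total")

    @property
    def accuracy(self) -> float:
        if self.n_evaluable == 0:
            return float("nan")
        return self.n_match / self.n_evaluable

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_evaluable": self.n_evaluable,
            "n_match": self.n_match,
            "n_mismatch": self.n_mismatch,
            "accuracy": self.accuracy,
            "mismatched_chemicals": list(self.mismatched_chemicals),
            "per_gene_consistency": {
                g: {"n_match": m, "n_evaluable": n}
                for g, (m, n) in self.per_gene_consistency.items()
            },
        }
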