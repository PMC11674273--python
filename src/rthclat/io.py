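"""Delimited-text readers and writers for the pipeline's tables.

All tables are UTF-8 CSV/TSV with a header (the delimiter follows the file
extension: ``.tsv`` -> tab, anything else -> comma).  Long-format tables
carry one row per (chemical, gene, replicate).  Judgment reports are JSON.
Readers reject malformed input with errors naming the offending column or
row; writers and readers are mutually inverse on valid data.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .types import (
    ChemicalRecord,
    CountMatrix,
    CqTable,
    FoldChangeTriplicate,
    HclatJudgment,
    Judgment,
    LlnaCategory,
    SchemaError,
    Solvent,
    ValidationError,
)

__all__ = [
    "read_chemical_table",
    "write_chemical_table",
    "read_foldchange_table",
    "write_foldchange_table",
    "read_cq_table",
    "write_cq_table",
    "read_count_matrix",
    "write_count_matrix",
    "write_judgments",
    "read_judgments",
    "load_config",
]

_LLNA_ALIASES = {
    "extreme": LlnaCategory.EXTREME,
    "strong": LlnaCategory.STRONG,
    "moderate": LlnaCategory.MODERATE,
    "weak": LlnaCategory.WEAK,
    "non_sensitizer": LlnaCategory.NON_SENSITIZER,
    "non-sensitizer": LlnaCategory.NON_SENSITIZER,
    "nd": LlnaCategory.ND,
    "": LlnaCategory.ND,
}

_HCLAT_ALIASES = {
    "p": HclatJudgment.POSITIVE,
    "n": HclatJudgment.NEGATIVE,
    "nd": HclatJudgment.ND,
    "": HclatJudgment.ND,
}


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    return df


def read_chemical_table(path: str | Path) -> list[ChemicalRecord]:
    """Read chemical metadata (name, CAS, solvent, CV75, LLNA class, h-CLAT)."""
    df = _read_table(path, ["name", "llna_category", "hclat_judgment"])
    records = []
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based, after the header
        llna_raw = row["llna_category"].strip()
        if llna_raw.lower() not in _LLNA_ALIASES:
            raise ValidationError(
                f"{path} row {rownum}: unknown llna_category {llna_raw!r}"
            )
        hclat_raw = row["hclat_judgment"].strip()
        if hclat_raw.lower() not in _HCLAT_ALIASES:
            raise ValidationError(
                f"{path} row {rownum}: unknown hclat_judgment {hclat_raw!r}"
            )
        solvent_raw = row.get("solvent", "").strip()
        if solvent_raw and solvent_raw not in (s.value for s in Solvent):
            raise ValidationError(f"{path} row {rownum}: unknown solvent {solvent_raw!r}")
        try:
            records.append(
                ChemicalRecord(
                    name=row["name"].strip(),
                    abbreviation=row.get("abbreviation", "").strip(),
                    cas=row.get("cas", "").strip(),
                    solvent=Solvent(solvent_raw) if solvent_raw else None,
                    cv75=row.get("cv75", "").strip(),
                    llna_category=_LLNA_ALIASES[llna_raw.lower()],
                    hclat_judgment=_HCLAT_ALIASES[hclat_raw.lower()],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {rownum}: {exc}") from exc
    return records


def write_chemical_table(records: Iterable[ChemicalRecord], path: str | Path) -> None:
    rows = [
        {
            "name": r.name,
            "abbreviation": r.abbreviation,
            "cas": r.cas,
            "solvent": r.solvent.value if r.solvent else "",
            "cv75": r.cv75,
            "llna_category": r.llna_category.value,
            "hclat_judgment": r.hclat_judgment.value,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def read_foldchange_table(path: str | Path) -> list[FoldChangeTriplicate]:
    """Read long-format fold changes: one row per (chemical, gene, replicate)."""
    df = _read_table(path, ["chemical", "gene", "replicate", "fold_change"])
    fc = pd.to_numeric(df["fold_change"], errors="coerce")
    if fc.isna().any():
        i = int(fc[fc.isna()].index[0])
        raise ValidationError(f"{path} row {i + 2}: non-numeric fold_change")
    df = df.assign(fold_change=fc)
    out = []
    for (chem, gene), sub in df.groupby(["chemical", "gene"], sort=False):
        vals = sub.sort_values("replicate")["fold_change"].tolist()
        if len(vals) != 3:
            raise ValidationError(
                f"{path}: ({chem}, {gene}) has {len(vals)} replicates, expected 3"
            )
        out.append(FoldChangeTriplicate(chem, gene, tuple(vals)))
    return out


def write_foldchange_table(
    triplicates: Iterable[FoldChangeTriplicate], path: str | Path
) -> None:
    rows = [
        {"chemical": t.chemical, "gene": t.gene, "replicate": i + 1, "fold_change": v}
        for t in triplicates
        for i, v in enumerate(t.values)
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def read_cq_table(path: str | Path) -> CqTable:
    df = _read_table(path, ["chemical", "gene", "condition", "replicate", "cq"])
    df = df.assign(
        replicate=pd.to_numeric(df["replicate"], errors="coerce"),
        cq=pd.to_numeric(df["cq"], errors="coerce"),
    )
    if df["cq"].isna().any():
        i = int(df[df["cq"].isna()].index[0])
        raise ValidationError(f"{path} row {i + 2}: non-numeric cq")
    return CqTable(df)


def write_cq_table(cq: CqTable, path: str | Path) -> None:
    cq.frame.to_csv(path, sep=_sep(path), index=False)


def read_count_matrix(
    path: str | Path,
    metadata_path: str | Path,
    lengths_path: str | Path | None = None,
) -> CountMatrix:
    """Read a gene x sample count table plus sample metadata.

    The counts file has genes in the first column; an optional ``length``
    column carries gene lengths, or they may come from ``lengths_path``
    (columns ``gene``, ``length``).  Metadata assigns each sample a
    ``group`` and optionally a ``treatment``; sample order follows the
    counts file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if lengths_path is not None:
        ldf = _read_table(lengths_path, ["gene", "length"])
        lengths = pd.Series(
            pd.to_numeric(ldf["length"]).to_numpy(), index=ldf["gene"].to_numpy()
        )
    elif "length" in df.columns:
        lengths = df.pop("length")
    else:
        raise SchemaError(
            f"{path}: no 'length' column and no lengths file given"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        col = numeric.columns[numeric.isna().any()][0]
        raise ValidationError(f"{path}: non-numeric count in sample {col!r}")
    if (numeric < 0).any().any():
        raise ValidationError(f"{path}: negative count")
    if not (numeric.to_numpy() == numeric.to_numpy().astype(int)).all():
        raise ValidationError(f"{path}: non-integer count")

    meta = _read_table(metadata_path, ["sample", "group"])
    groups = pd.Series(meta["group"].to_numpy(), index=meta["sample"].to_numpy())
    treatments = None
    if "treatment" in meta.columns:
        treatments = pd.Series(meta["treatment"].to_numpy(), index=meta["sample"].to_numpy())
    return CountMatrix(numeric, lengths, groups, treatments)


def write_count_matrix(cm: CountMatrix, counts_path: str | Path, metadata_path: str | Path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length", cm.lengths)
    out.to_csv(counts_path, sep=_sep(counts_path))
    meta = pd.DataFrame(
        {
            "sample": cm.samples,
            "group": cm.groups.to_numpy(),
            "treatment": cm.treatments.to_numpy(),
        }
    )
    meta.to_csv(metadata_path, sep=_sep(metadata_path), index=False)


def write_judgments(judgments: Iterable[Judgment], path: str | Path) -> None:
    payload = [j.to_dict() for j in judgments]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_judgments(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


def load_config(path: str | Path) -> dict:
    """Flat YAML key-value configuration (thresholds, panel definition...)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg
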