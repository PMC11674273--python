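"""Packaged study fixtures.

Three small tables ship with the package, transcribed from the published
study this pipeline operationalizes:

* the **concordance panel** — 9 reference chemicals x 12 candidate marker
  genes, each cell holding the RNA-Seq (TPM-ratio) fold change, the
  triplicate qPCR fold changes, and the published Match/Mismatch verdict;
* the **screening panel** — 28 further chemicals with HMOX1/JUN qPCR
  triplicates plus the published per-chemical judgment;
* the **chemical metadata** table — names, LLNA potency categories and
  h-CLAT judgments for all 37 chemicals (CAS/solvent/CV75 only where the
  published tables state them).

All fold changes are as printed, one decimal place.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import _HCLAT_ALIASES, _LLNA_ALIASES
from .types import ChemicalRecord, FoldChangeTriplicate, LlnaCategory, Solvent

__all__ = [
    "load_concordance_panel",
    "load_screening_foldchanges",
    "load_screening_printed",
    "load_chemicals",
    "load_chemical_records",
    "REFERENCE_CHEMICALS",
    "CANDIDATE_GENES",
    "RETAINED_MARKERS",
]

#: the 12 candidate marker genes carried through the concordance panel
CANDIDATE_GENES = (
    "HMOX1", "JUN", "PPP1R15A", "BTG2", "DDIT3", "EGR1",
    "GADD45B", "PMAIP1", "SAT1", "ULBP2", "CCR2", "ICMT",
)

#: the five markers that survive the cross-platform concordance rule
RETAINED_MARKERS = ("HMOX1", "JUN", "PPP1R15A", "BTG2", "PMAIP1")

#: the nine h-CLAT proficiency chemicals used for RNA-Seq and concordance
REFERENCE_CHEMICALS = (
    "2,4-Dinitrochlorobenzene",
    "1,4-Phenylendiamine",
    "Nickel sulfate",
    "2-Mercaptobenzothiazole",
    "R(+)-Limonene",
    "Imidazolidinyl urea",
    "Isopropanol",
    "Glycerol",
    "4-Aminobenzoic acid",
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("rthclat.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def load_concordance_panel() -> pd.DataFrame:
    """108 chemical x gene cells: ngs_fc, pcr_1..3, printed_verdict."""
    return _read("concordance_panel.tsv")


def load_screening_foldchanges() -> list[FoldChangeTriplicate]:
    """HMOX1/JUN triplicates for the 28 screening-panel chemicals."""
    df = _read("screening_foldchanges.tsv")
    out = []
    for (chem, gene), sub in df.groupby(["chemical", "gene"], sort=False):
        vals = tuple(sub.sort_values("replicate")["fold_change"].astype(float))
        out.append(FoldChangeTriplicate(chem, gene, vals))
    return out


def load_screening_printed() -> pd.DataFrame:
    """Published per-chemical call and LLNA match for the screening panel."""
    return _read("screening_printed.tsv")


def load_chemicals(panel: str | None = None) -> pd.DataFrame:
    """Chemical metadata; ``panel`` filters to 'reference' or 'screening'."""
    df = _read("chemicals.tsv")
    if panel is not None:
        df = df[df["panel"] == panel].reset_index(drop=True)
    return df


def load_chemical_records(panel: str | None = None) -> list[ChemicalRecord]:
    df = load_chemicals(panel)
    return [
        ChemicalRecord(
            name=row["name"],
            abbreviation=row["abbreviation"],
            cas=row["cas"],
            solvent=Solvent(row["solvent"]) if row["solvent"] else None,
            cv75=row["cv75"],
            llna_category=_LLNA_ALIASES[row["llna_category"].lower()],
            hclat_judgment=_HCLAT_ALIASES[row["hclat_judgment"].lower()],
        )
        for _, row in df.iterrows()
    ]


def llna_lookup(panel: str | None = None) -> dict[str, LlnaCategory]:
    """Chemical -> LLNA category mapping from the metadata table."""
    return {r.name: r.llna_category for r in load_chemical_records(panel)}
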