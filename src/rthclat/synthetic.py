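"""Synthetic inputs for every pipeline stage.

Two generators emulate the measurement structure of the assay without any
download: a qPCR scenario (stable reference-gene Cq, treatment-shifted
target-gene Cq, additive Gaussian replicate noise on the cycle scale) and
an RNA-Seq scenario (negative-binomial counts over the study design of
6 sensitizer + 3 non-sensitizer treatments + 2 controls at n = 3, with
planted sensitizer-specific genes).  Both are bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .types import (
    ChemicalRecord,
    CountMatrix,
    CqTable,
    HclatJudgment,
    LlnaCategory,
    ValidationError,
)

__all__ = [
    "QpcrScenario",
    "RnaseqScenario",
    "generate_cq",
    "generate_counts",
    "generate_chemical_panel",
]


@dataclass
class QpcrScenario:
    """True per-chemical, per-gene linear fold changes plus a noise model.

    Cq noise is additive Gaussian on the cycle scale, i.e. log2-normal on
    the ratio scale, the standard qPCR error model.  The reference gene has
    a true fold change fixed at 1.
    """

    chemicals: Mapping[str, Mapping[str, float]]  # chemical -> gene -> true FC
    reference_gene: str = "GAPDH"
    baseline_cq: Mapping[str, float] = field(default_factory=dict)  # gene -> cycles
    replicate_noise_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")
        for chem, genes in self.chemicals.items():
            for gene, fc in genes.items():
                if not fc > 0:
                    raise ValidationError(f"({chem}, {gene}): true fold change must be > 0")


def generate_cq(scenario: QpcrScenario) -> CqTable:
    """Simulate a raw Cq table for the scenario.

    Treated target wells sit ``log2(trueFC)`` cycles below baseline (more
    template amplifies earlier); control and reference-gene wells sit at
    baseline.  Every well gets independent N(0, sd) noise.
    """
    rng = np.random.default_rng(scenario.seed)
    default_baseline = 25.0
    rows = []
    for chem in scenario.chemicals:
        genes = [scenario.reference_gene] + [
            g for g in scenario.chemicals[chem] if g != scenario.reference_gene
        ]
        for gene in genes:
            base = float(scenario.baseline_cq.get(gene, default_baseline))
            true_fc = 1.0 if gene == scenario.reference_gene else scenario.chemicals[chem][gene]
            for condition in ("treated", "solvent_control"):
                shift = -np.log2(true_fc) if condition == "treated" else 0.0
                for rep in range(1, scenario.n_replicates + 1):
                    noise = rng.normal(0.0, scenario.replicate_noise_sd) if scenario.replicate_noise_sd else 0.0
                    rows.append(
                        {
                            "chemical": chem,
                            "gene": gene,
                            "condition": condition,
                            "replicate": rep,
                            "cq": base + shift + noise,
                        }
                    )
    return CqTable(pd.DataFrame(rows))


@dataclass
class RnaseqScenario:
    """Group-structured count simulation with planted sensitizer-specific genes.

    Defaults mirror the study design the pipeline targets: ~8000 expressed
    genes across 11 treatments (6 sensitizers, 3 non-sensitizers, 2
    controls) at n = 3, with 60 up- and 2 down-regulated genes shifted only
    in the sensitizer-treated samples.  Planted |log2FC| is drawn uniform in
    [1.5, 6], straddling effects up to the very large ones marker screens
    report.  Gene lengths are log-uniform in [500, 1e5] bases so TPM's
    length normalization is exercised nontrivially.
    """

    n_genes: int = 8000
    n_sensitizer_treatments: int = 6
    n_nonsensitizer_treatments: int = 3
    n_control_treatments: int = 2
    n_replicates: int = 3
    planted_up: int = 60
    planted_down: int = 2
    lfc_low: float = 1.5
    lfc_high: float = 6.0
    dispersion: float = 0.05
    library_size: float = 2e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_up + self.planted_down > self.n_genes:
            raise ValidationError("more planted genes than genes")


def generate_counts(scenario: RnaseqScenario) -> CountMatrix:
    """Simulate a CountMatrix; planted genes are named ``planted_up_*``/``planted_down_*``.

    Expected counts are ``base_expression * length/1kb``, scaled per sample
    to the target library size, NB-distributed with the scenario dispersion.
    Planted genes are shifted by their log2 fold change in sensitizer
    samples only, so TPM expectations are invariant to library-size scaling.
    """
    rng = np.random.default_rng(scenario.seed)
    s = scenario
    n_planted = s.planted_up + s.planted_down

    genes = (
        [f"planted_up_{i:03d}" for i in range(s.planted_up)]
        + [f"planted_down_{i:03d}" for i in range(s.planted_down)]
        + [f"null_{i:05d}" for i in range(s.n_genes - n_planted)]
    )
    lengths = np.exp(rng.uniform(np.log(500.0), np.log(1e5), size=s.n_genes))
    # Base expression on the transcript-abundance scale (log-normal).
    expression = np.exp(rng.normal(np.log(50.0), 1.2, size=s.n_genes))

    lfc = np.zeros(s.n_genes)
    lfc[: s.planted_up] = rng.uniform(s.lfc_low, s.lfc_high, size=s.planted_up)
    lfc[s.planted_up : n_planted] = -rng.uniform(s.lfc_low, s.lfc_high, size=s.planted_down)

    treatments: list[tuple[str, str]] = []  # (treatment id, group)
    treatments += [(f"sens_{i+1}", "sensitizer") for i in range(s.n_sensitizer_treatments)]
    treatments += [
        (f"nonsens_{i+1}", "non_sensitizer") for i in range(s.n_nonsensitizer_treatments)
    ]
    treatments += [(f"control_{i+1}", "control") for i in range(s.n_control_treatments)]

    sample_ids, sample_group, sample_treatment = [], {}, {}
    columns = {}
    rate_base = expression * lengths / 1e3  # reads scale with transcript length
    for tid, group in treatments:
        rate = rate_base.copy()
        if group == "sensitizer":
            rate[:n_planted] = rate[:n_planted] * 2.0 ** lfc[:n_planted]
        rate = rate / rate.sum()
        for rep in range(1, s.n_replicates + 1):
            sid = f"{tid}_r{rep}"
            lib = s.library_size * rng.uniform(0.85, 1.15)
            mu = rate * lib
            # NB via gamma-Poisson mixture
            if s.dispersion > 0:
                lam = rng.gamma(shape=1.0 / s.dispersion, scale=mu * s.dispersion)
            else:
                lam = mu
            columns[sid] = rng.poisson(lam)
            sample_ids.append(sid)
            sample_group[sid] = group
            sample_treatment[sid] = tid

    counts = pd.DataFrame(columns, index=genes)[sample_ids]
    return CountMatrix(
        counts=counts,
        lengths=pd.Series(lengths, index=genes),
        groups=pd.Series(sample_group),
        treatments=pd.Series(sample_treatment),
    )


_POTENCY = (
    LlnaCategory.EXTREME,
    LlnaCategory.STRONG,
    LlnaCategory.MODERATE,
    LlnaCategory.WEAK,
)


def generate_chemical_panel(
    n_sensitizers: int, n_nonsensitizers: int, seed: int = 0
) -> list[ChemicalRecord]:
    """Chemical metadata records with internally consistent labels.

    Sensitizers get a potency class drawn uniformly and an h-CLAT positive
    judgment; non-sensitizers are labelled negative throughout.
    """
    if n_sensitizers < 0 or n_nonsensitizers < 0:
        raise ValidationError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_sensitizers):
        records.append(
            ChemicalRecord(
                name=f"synthetic sensitizer {i+1}",
                abbreviation=f"S{i+1}",
                llna_category=_POTENCY[rng.integers(len(_POTENCY))],
                hclat_judgment=HclatJudgment.POSITIVE,
            )
        )
    for i in range(n_nonsensitizers):
        records.append(
            ChemicalRecord(
                name=f"synthetic non-sensitizer {i+1}",
                abbreviation=f"N{i+1}",
                llna_category=LlnaCategory.NON_SENSITIZER,
                hclat_judgment=HclatJudgment.NEGATIVE,
            )
        )
    return records
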