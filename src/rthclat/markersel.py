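"""RNA-Seq marker discovery: low-count filter, TPM, differential testing,
sensitizer-specific selection and candidate ranking.

The differential test is a deliberately simple, self-contained
negative-binomial Wald test: median-of-ratios size factors, gene-wise
method-of-moments dispersion with a small floor (no empirical-Bayes
shrinkage toward a trend), and a normal approximation for the log2
fold change of group means, followed by Benjamini-Hochberg adjustment.
It approximates the DESeq2-style analysis such pipelines usually run;
exact numerical agreement with that package is not a goal, the filter
cascade and set logic built on top of it are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CountMatrix, ValidationError

__all__ = [
    "filter_low_counts",
    "compute_tpm",
    "size_factors",
    "differential_test",
    "select_sensitizer_specific",
    "MarkerCandidate",
    "rank_candidates",
]

#: dispersion floor for the method-of-moments estimator
DISPERSION_FLOOR = 1e-4
#: dispersion ceiling guarding against degenerate estimates
DISPERSION_CEILING = 10.0
#: pseudocount applied to normalized group means in the log2 ratio
MEAN_PSEUDOCOUNT = 0.5


def filter_low_counts(
    cm: CountMatrix,
    min_count: int = 10,
    segment_statistic: str = "mean",
    inclusive: bool = True,
) -> CountMatrix:
    """Drop genes that stay below ``min_count`` reads in every test segment.

    A "test segment" is one treatment condition (all its replicates); the
    per-segment statistic is the mean over replicates by default (``"sum"``
    is also supported).  A gene is retained when its statistic reaches
    ``min_count`` in at least one segment; ``inclusive`` picks the boundary
    (>= by default, > otherwise).
    """
    if min_count < 0:
        raise ValidationError(f"min_count must be >= 0, got {min_count}")
    if segment_statistic not in ("mean", "sum"):
        raise ValueError(f"unknown segment_statistic {segment_statistic!r}")
    seg = cm.counts.T.groupby(cm.treatments, sort=False)
    stat = seg.mean().T if segment_statistic == "mean" else seg.sum().T
    best = stat.max(axis=1)
    keep = best >= min_count if inclusive else best > min_count
    return cm.subset_genes(list(cm.genes[keep]))


def compute_tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates rescaled to 1e6 per sample."""
    rate = cm.counts.div(cm.lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"sample(s) with zero total rate: {list(zero.index)}")
    return rate.div(totals, axis=1) * 1e6


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    Ratios are taken to the geometric mean over samples, using only genes
    expressed in every sample (the standard reference-pseudo-sample trick).
    Falls back to library-size factors if no gene is ubiquitously expressed.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        libsize = arr.sum(axis=0)
        if (libsize == 0).any():
            raise ValidationError("sample with zero total counts")
        sf = libsize / np.exp(np.mean(np.log(libsize)))
        return pd.Series(sf, index=counts.columns)
    loggeo = np.log(arr[positive]).mean(axis=1)
    sf = np.exp(np.median(np.log(arr[positive]) - loggeo[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def differential_test(
    cm: CountMatrix,
    group_a: str = "sensitizer",
    group_b: str = "control",
) -> pd.DataFrame:
    """Negative-binomial Wald test of group_a vs group_b, gene by gene.

    Returns a DataFrame indexed by gene with columns ``log2_fold_change``
    (a relative to b), ``p_value``, ``adjusted_p`` (Benjamini-Hochberg over
    all tested genes) and ``base_mean`` (mean normalized count over the two
    groups' samples).
    """
    sa = cm.samples_in_group(group_a)
    sb = cm.samples_in_group(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValidationError(
            f"each group needs >= 2 samples (got {len(sa)} {group_a!r}, "
            f"{len(sb)} {group_b!r})"
        )
    counts = cm.counts[sa + sb]
    sf = size_factors(counts)
    norm = counts.div(sf, axis=1)
    a = norm[sa].to_numpy()
    b = norm[sb].to_numpy()
    na, nb = a.shape[1], b.shape[1]

    mu_a = a.mean(axis=1)
    mu_b = b.mean(axis=1)
    base_mean = norm.mean(axis=1).to_numpy()

    # Gene-wise dispersion: pooled within-group method of moments,
    # var = mu + alpha * mu^2, clipped to [floor, ceiling].
    var_pool = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    mu_pool = (na * mu_a + nb * mu_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_pool - mu_pool) / np.square(mu_pool)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    alpha = np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CEILING)

    c = MEAN_PSEUDOCOUNT
    lfc = np.log2((mu_a + c) / (mu_b + c))

    ln2 = np.log(2.0)
    var_mean_a = (mu_a + alpha * np.square(mu_a)) / na
    var_mean_b = (mu_b + alpha * np.square(mu_b)) / nb
    se = np.sqrt(
        var_mean_a / np.square((mu_a + c) * ln2) + var_mean_b / np.square((mu_b + c) * ln2)
    )

    z = np.zeros_like(lfc)
    nonzero = se > 0
    z[nonzero] = lfc[nonzero] / se[nonzero]
    # Reference the Wald statistic against a t distribution with the pooled
    # residual degrees of freedom: at n = 3 per group the gene-wise variance
    # is itself noisy, and the normal reference is anti-conservative.
    p = 2.0 * stats.t.sf(np.abs(z), df=na + nb - 2)
    # genes absent from both groups carry no evidence
    p[(mu_a == 0) & (mu_b == 0)] = 1.0
    p = np.clip(p, 0.0, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": p,
            "adjusted_p": padj,
            "base_mean": base_mean,
        },
        index=counts.index,
    )


@dataclass(frozen=True)
class MarkerCandidate:
    """A sensitizer-specific gene proposed as a qPCR marker."""

    gene: str
    direction: str  # "up" or "down"
    log2_fold_change: float
    mean_tpm: float = float("nan")

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValidationError(f"direction must be 'up' or 'down', got {self.direction!r}")


def _significant(de: pd.DataFrame, lfc_cut: float, alpha: float) -> pd.Series:
    return (de["log2_fold_change"].abs() > lfc_cut) & (de["adjusted_p"] < alpha)


def select_sensitizer_specific(
    de_sens_ctrl: pd.DataFrame,
    de_nonsens_ctrl: pd.DataFrame,
    lfc_cut: float = 1.0,
    alpha: float = 0.05,
) -> list[MarkerCandidate]:
    """Genes altered by sensitizers but not by non-sensitizers.

    A gene qualifies when it passes |log2FC| > ``lfc_cut`` and adjusted
    p < ``alpha`` in the sensitizer-vs-control contrast and does NOT pass
    the same joint cut in the non-sensitizer-vs-control contrast.
    Direction comes from the sensitizer contrast's sign.
    """
    if set(de_sens_ctrl.index) != set(de_nonsens_ctrl.index):
        raise ValidationError("contrasts cover different gene universes")
    de_nonsens_ctrl = de_nonsens_ctrl.reindex(de_sens_ctrl.index)
    sig_sens = _significant(de_sens_ctrl, lfc_cut, alpha)
    sig_non = _significant(de_nonsens_ctrl, lfc_cut, alpha)
    chosen = de_sens_ctrl[sig_sens & ~sig_non]
    return [
        MarkerCandidate(
            gene=g,
            direction="up" if row["log2_fold_change"] > 0 else "down",
            log2_fold_change=float(row["log2_fold_change"]),
        )
        for g, row in chosen.iterrows()
    ]


def rank_candidates(
    candidates: list[MarkerCandidate],
    tpm: pd.DataFrame,
    sensitizer_samples: list[str],
    n_up: int = 10,
    n_down: int = 2,
    min_tpm: float = 10.0,
) -> list[MarkerCandidate]:
    """Pick the strongest, well-expressed candidates for qPCR follow-up.

    Among candidates whose mean TPM over sensitizer-treated samples reaches
    ``min_tpm``, take the ``n_up`` largest up-regulated log2 fold changes
    and the ``n_down`` most negative down-regulated ones.  Ties break toward
    higher mean TPM, then lexicographic gene id.
    """
    if not candidates:
        raise ValidationError("no candidates to rank")
    mean_tpm = tpm[sensitizer_samples].mean(axis=1)
    enriched = [
        MarkerCandidate(c.gene, c.direction, c.log2_fold_change, float(mean_tpm.get(c.gene, 0.0)))
        for c in candidates
    ]
    expressed = [c for c in enriched if c.mean_tpm >= min_tpm]
    ups = sorted(
        (c for c in expressed if c.direction == "up"),
        key=lambda c: (-c.log2_fold_change, -c.mean_tpm, c.gene),
    )
    downs = sorted(
        (c for c in expressed if c.direction == "down"),
        key=lambda c: (c.log2_fold_change, -c.mean_tpm, c.gene),
    )
    if len(ups) < n_up or len(downs) < n_down:
        warnings.warn(
            f"requested {n_up} up + {n_down} down candidates but only "
            f"{len(ups)} up / {len(downs)} down pass min_tpm={min_tpm}; "
            f"returning all",
            stacklevel=2,
        )
    return ups[:n_up] + downs[:n_down]
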