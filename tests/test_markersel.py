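"""RNA-Seq marker discovery: filter, TPM, differential test, selection, ranking."""

import numpy as np
import pandas as pd
import pytest

from rthclat import (
    CountMatrix,
    MarkerCandidate,
    ValidationError,
    compute_tpm,
    differential_test,
    filter_low_counts,
    rank_candidates,
    select_sensitizer_specific,
)


def _matrix(counts, lengths=None, groups=None, treatments=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{i}" for i in range(counts.shape[1])]
    if lengths is None:
        lengths = pd.Series(1000.0, index=counts.index)
    else:
        lengths = pd.Series(lengths, index=counts.index)
    if groups is None:
        half = counts.shape[1] // 2
        groups = {
            s: ("sensitizer" if i < half else "control")
            for i, s in enumerate(counts.columns)
        }
    return CountMatrix(counts, lengths, groups, treatments)


class TestFilterLowCounts:
    def test_all_zero_gene_removed(self):
        cm = _matrix([[0] * 6, [50] * 6])
        out = filter_low_counts(cm)
        assert list(out.genes) == ["g1"]

    def test_one_hot_segment_retains_gene(self):
        # mean 50 in the sensitizer segment, zero elsewhere
        cm = _matrix([[50, 50, 50, 0, 0, 0]])
        assert list(filter_low_counts(cm).genes) == ["g0"]

    def test_counts_on_constructed_thousand_gene_matrix(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(20, 200, size=(1000, 6))
        counts[:100] = rng.integers(0, 6, size=(100, 6))  # max segment mean 5
        out = filter_low_counts(_matrix(counts))
        assert len(out.genes) == 900

    def test_idempotent_and_subset(self):
        rng = np.random.default_rng(4)
        cm = _matrix(rng.integers(0, 30, size=(50, 6)))
        once = filter_low_counts(cm)
        twice = filter_low_counts(once)
        assert list(once.genes) == list(twice.genes)
        assert set(once.genes) <= set(cm.genes)

    def test_negative_min_count_rejected(self):
        with pytest.raises(ValidationError):
            filter_low_counts(_matrix([[1] * 6]), min_count=-1)


class TestTpm:
    def test_single_gene_takes_the_whole_million(self):
        cm = _matrix([[7, 12, 100, 3, 8, 9]])
        assert np.allclose(compute_tpm(cm).to_numpy(), 1e6)

    def test_length_normalization(self):
        # equal counts, lengths 1 kb vs 2 kb -> rates 2:1
        cm = _matrix([[100] * 6, [100] * 6], lengths=[1000.0, 2000.0])
        tpm = compute_tpm(cm)
        assert np.allclose(tpm.iloc[0], 2e6 / 3)
        assert np.allclose(tpm.iloc[1], 1e6 / 3)

    def test_columns_sum_to_one_million(self, toy_counts):
        tpm = compute_tpm(toy_counts)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_silent_sample_rejected(self):
        cm = _matrix([[0, 10, 10, 10, 10, 10]])
        with pytest.raises(ValidationError, match="s0"):
            compute_tpm(cm)


def _nb_counts(rng, mean, dispersion, size):
    lam = rng.gamma(1.0 / dispersion, mean * dispersion, size=size)
    return rng.poisson(lam)


class TestDifferentialTest:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(5)
        block = rng.integers(0, 500, size=(100, 3))
        cm = _matrix(np.hstack([block, block]))
        de = differential_test(cm, "sensitizer", "control")
        assert np.allclose(de["log2_fold_change"], 0.0)
        assert (de["p_value"] > 0.99).all()

    def test_planted_fourfold_shift_detected(self):
        # 200 planted genes at log2FC 3, mean 500, dispersion 0.05, n = 3 vs 3,
        # on a background of 1000 null genes: >= 90% flagged after BH.
        rng = np.random.default_rng(6)
        n_planted, n_null = 200, 1000
        mu = np.full(n_planted + n_null, 500.0)
        a = _nb_counts(rng, np.where(np.arange(len(mu)) < n_planted, mu * 8, mu)[:, None],
                       0.05, (len(mu), 3))
        b = _nb_counts(rng, mu[:, None], 0.05, (len(mu), 3))
        cm = _matrix(np.hstack([a, b]))
        de = differential_test(cm, "sensitizer", "control")
        flagged = de["adjusted_p"] < 0.05
        assert flagged[:n_planted].mean() >= 0.90

    def test_null_simulation_controls_false_positives(self):
        rng = np.random.default_rng(7)
        mu = np.exp(rng.normal(np.log(200), 1.0, size=5000))
        a = _nb_counts(rng, mu[:, None], 0.05, (5000, 3))
        b = _nb_counts(rng, mu[:, None], 0.05, (5000, 3))
        cm = _matrix(np.hstack([a, b]))
        de = differential_test(cm, "sensitizer", "control")
        assert (de["adjusted_p"] < 0.05).mean() <= 0.01

    def test_swapping_groups_negates_log2fc(self, toy_counts):
        fwd = differential_test(toy_counts, "sensitizer", "control")
        rev = differential_test(toy_counts, "control", "sensitizer")
        assert np.allclose(
            fwd["log2_fold_change"], -rev["log2_fold_change"], atol=1e-12
        )
        assert np.allclose(fwd["p_value"], rev["p_value"], atol=1e-12)

    def test_sample_order_within_groups_is_irrelevant(self, toy_counts):
        shuffled = CountMatrix(
            toy_counts.counts[["s2", "s0", "s1", "s5", "s4", "s3"]],
            toy_counts.lengths,
            toy_counts.groups,
            toy_counts.treatments,
        )
        a = differential_test(toy_counts, "sensitizer", "control")
        b = differential_test(shuffled, "sensitizer", "control")
        assert np.allclose(a["log2_fold_change"], b["log2_fold_change"])

    def test_single_sample_group_rejected(self):
        cm = _matrix(
            [[10, 10, 10], [20, 20, 20]],
            groups={"s0": "sensitizer", "s1": "control", "s2": "control"},
        )
        with pytest.raises(ValidationError, match="2 samples"):
            differential_test(cm, "sensitizer", "control")

    def test_agrees_with_independent_nb_reference_fit(self):
        """Cross-check against an established DESeq2 implementation.

        On a simulated 300-gene, 3 vs 3 design the simplified Wald test
        should rank and flag essentially the same genes.
        """
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(0)
        n_genes = 300
        mu = np.exp(rng.normal(np.log(100), 1.0, n_genes))
        lfc = np.zeros(n_genes)
        lfc[:30] = rng.uniform(1.5, 4, 30)
        a = _nb_counts(rng, (mu * 2.0 ** lfc)[:, None], 0.05, (n_genes, 3))
        b = _nb_counts(rng, mu[:, None], 0.05, (n_genes, 3))
        cm = _matrix(np.hstack([a, b]))

        mine = differential_test(cm, "sensitizer", "control")

        meta = pd.DataFrame(
            {"condition": ["A"] * 3 + ["B"] * 3}, index=cm.counts.columns
        )
        dds = DeseqDataSet(
            counts=cm.counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "A", "B"], quiet=True)
        ds.summary()
        ref = ds.results_df

        corr = np.corrcoef(mine["log2_fold_change"], ref["log2FoldChange"])[0, 1]
        assert corr > 0.95
        mine_sig = set(mine.index[(mine["adjusted_p"] < 0.05) & (mine["log2_fold_change"].abs() > 1)])
        ref_sig = set(ref.index[(ref["padj"] < 0.05) & (ref["log2FoldChange"].abs() > 1)])
        jaccard = len(mine_sig & ref_sig) / max(1, len(mine_sig | ref_sig))
        assert jaccard >= 0.8


class TestSelection:
    def _de(self, genes, lfc, padj):
        return pd.DataFrame(
            {
                "log2_fold_change": lfc,
                "p_value": padj,
                "adjusted_p": padj,
                "base_mean": 100.0,
            },
            index=genes,
        )

    def test_gene_significant_in_both_contrasts_excluded(self):
        genes = ["a", "b"]
        sens = self._de(genes, [3.0, 2.5], [1e-8, 1e-8])
        non = self._de(genes, [3.0, 0.0], [1e-8, 0.9])
        out = select_sensitizer_specific(sens, non)
        assert [c.gene for c in out] == ["b"]

    def test_strong_specific_gene_included_with_direction(self):
        sens = self._de(["a"], [5.2], [1e-8])
        non = self._de(["a"], [0.1], [0.9])
        (cand,) = select_sensitizer_specific(sens, non)
        assert cand.direction == "up" and cand.log2_fold_change == 5.2

    def test_empty_when_significant_sets_coincide(self):
        genes = [f"g{i}" for i in range(10)]
        lfc = [3.0] * 5 + [0.0] * 5
        padj = [1e-6] * 5 + [0.8] * 5
        sens = self._de(genes, lfc, padj)
        assert select_sensitizer_specific(sens, sens.copy()) == []

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValidationError):
            select_sensitizer_specific(
                self._de(["a"], [3.0], [1e-8]), self._de(["b"], [0.0], [0.9])
            )


class TestRanking:
    def _tpm(self, values):
        return pd.DataFrame(
            {f"s{i}": values for i in range(3)},
            index=[f"g{i}" for i in range(len(values))],
        )

    def test_single_candidate(self):
        cand = MarkerCandidate("g0", "up", 2.0)
        out = rank_candidates([cand], self._tpm([50.0]), ["s0", "s1", "s2"], n_up=1, n_down=0)
        assert [c.gene for c in out] == ["g0"]

    def test_ties_break_toward_higher_tpm(self):
        cands = [MarkerCandidate("g0", "up", 2.0), MarkerCandidate("g1", "up", 2.0)]
        out = rank_candidates(
            cands, self._tpm([10.0, 100.0]), ["s0", "s1", "s2"], n_up=2, n_down=0
        )
        assert [c.gene for c in out] == ["g1", "g0"]

    def test_order_matches_bruteforce_sort(self):
        rng = np.random.default_rng(9)
        n = 30
        lfc = rng.uniform(1.1, 6, n) * rng.choice([1, 1, 1, -1], n)
        tpm_vals = rng.uniform(0, 200, n)
        cands = [
            MarkerCandidate(f"g{i}", "up" if lfc[i] > 0 else "down", float(lfc[i]))
            for i in range(n)
        ]
        out = rank_candidates(
            cands, self._tpm(list(tpm_vals)), ["s0", "s1", "s2"],
            n_up=10, n_down=2, min_tpm=10.0,
        )
        eligible = [(c, tpm_vals[int(c.gene[1:])]) for c in cands
                    if tpm_vals[int(c.gene[1:])] >= 10.0]
        ups = sorted(
            [x for x in eligible if x[0].direction == "up"],
            key=lambda x: (-x[0].log2_fold_change, -x[1], x[0].gene),
        )[:10]
        downs = sorted(
            [x for x in eligible if x[0].direction == "down"],
            key=lambda x: (x[0].log2_fold_change, -x[1], x[0].gene),
        )[:2]
        assert [c.gene for c in out] == [x[0].gene for x in ups + downs]

    def test_warns_when_too_few_candidates(self):
        cands = [MarkerCandidate("g0", "up", 2.0)]
        with pytest.warns(UserWarning, match="returning all"):
            out = rank_candidates(
                cands, self._tpm([50.0]), ["s0", "s1", "s2"], n_up=10, n_down=2
            )
        assert len(out) == 1
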