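"""Depth-ratio copy-number estimation and two-probe signal quantification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import small_lib
from replikit.depth import compare_strains, replicon_depths, signal_ratio_test
from replikit.mapping import PairTable
from replikit.synth import RepliconSpec, generate_genome, simulate_matepairs


def pt_from_counts(counts: dict[str, int], names=None):
    """PairTable of uniquely mapped single-placement reads."""
    rows = []
    pid = 0
    for rep, n in counts.items():
        for _ in range(n):
            rows.append((pid, 1, rep, 1, "+", 100, 1))
            pid += 1
    pl = pd.DataFrame(
        rows, columns=["pair_id", "mate", "replicon", "start", "strand", "score", "nhits"]
    )
    pairs = pd.DataFrame({"pair_id": np.arange(pid), "paired": True})
    return PairTable(pl, pairs, names or list(counts))


def pt_from_truth(truth: pd.DataFrame, names):
    pl = truth[["pair_id", "mate", "replicon", "start", "strand"]].copy()
    pl["score"] = 100
    pl["nhits"] = 1
    pairs = pd.DataFrame({"pair_id": truth.pair_id.unique(), "paired": True})
    return PairTable(pl, pairs, list(names))


class TestRepliconDepths:
    def test_ratio_arithmetic(self):
        pt = pt_from_counts({"chr": 10_000, "pA": 1_000})
        df = replicon_depths(pt, {"chr": 1_000_000, "pA": 10_000}, "chr")
        d = df.set_index("replicon")
        assert d.loc["chr", "average_depth"] == pytest.approx(0.01)
        assert d.loc["pA", "average_depth"] == pytest.approx(0.1)
        assert d.loc["pA", "ratio_to_chromosome"] == pytest.approx(10.0)
        assert d.loc["chr", "ratio_to_chromosome"] == 1.0

    def test_multimapped_reads_split_weight(self):
        pl = pd.DataFrame(
            [
                (0, 1, "chr", 1, "+", 100, 2),
                (0, 1, "pA", 1, "+", 100, 2),
            ],
            columns=["pair_id", "mate", "replicon", "start", "strand", "score", "nhits"],
        )
        pairs = pd.DataFrame({"pair_id": [0], "paired": [True]})
        pt = PairTable(pl, pairs, ["chr", "pA"])
        df = replicon_depths(pt, {"chr": 100, "pA": 100}, "chr").set_index("replicon")
        assert df.loc["chr", "mapped_read_weight"] == pytest.approx(0.5)
        assert df.loc["pA", "mapped_read_weight"] == pytest.approx(0.5)

    def test_unique_weighting_drops_multireads(self):
        pl = pd.DataFrame(
            [
                (0, 1, "chr", 1, "+", 100, 2),
                (0, 1, "pA", 1, "+", 100, 2),
                (1, 1, "chr", 5, "+", 100, 1),
            ],
            columns=["pair_id", "mate", "replicon", "start", "strand", "score", "nhits"],
        )
        pairs = pd.DataFrame({"pair_id": [0, 1], "paired": True})
        pt = PairTable(pl, pairs, ["chr", "pA"])
        df = replicon_depths(pt, {"chr": 100, "pA": 100}, "chr", weighting="unique")
        d = df.set_index("replicon")
        assert d.loc["chr", "mapped_read_weight"] == 1.0
        assert d.loc["pA", "mapped_read_weight"] == 0.0

    def test_zero_chromosome_depth_rejected(self):
        pt = pt_from_counts({"pA": 10}, names=["chr", "pA"])
        with pytest.raises(ValueError, match="chromosome depth"):
            replicon_depths(pt, {"chr": 1_000, "pA": 100}, "chr")

    def test_estimate_converges_to_planted_copy_number(self):
        """Absolute error of the depth ratio falls monotonically with library
        size (seed-averaged, truth placements)."""
        specs = [
            RepliconSpec("chr", 30_000, 1.0, is_chromosome=True),
            RepliconSpec("pC", 6_000, 5.0),
        ]
        g = generate_genome(specs, [], seed=7)
        lengths = {"chr": 30_000, "pC": 6_000}
        errs = []
        for n in (1_000, 10_000, 100_000):
            e = []
            for seed in range(5):
                _, _, truth = simulate_matepairs(g, small_lib(n_pairs=n, seed=seed))
                pt = pt_from_truth(truth, lengths)
                df = replicon_depths(pt, lengths, "chr").set_index("replicon")
                e.append(abs(df.loc["pC", "ratio_to_chromosome"] - 5.0))
            errs.append(np.mean(e))
        assert errs[0] > errs[1] > errs[2]

    def test_ratio_invariant_under_subsampling(self):
        specs = [
            RepliconSpec("chr", 30_000, 1.0, is_chromosome=True),
            RepliconSpec("pC", 6_000, 5.0),
        ]
        g = generate_genome(specs, [], seed=9)
        lengths = {"chr": 30_000, "pC": 6_000}
        _, _, truth = simulate_matepairs(g, small_lib(n_pairs=50_000, seed=3))
        full = replicon_depths(pt_from_truth(truth, lengths), lengths, "chr")
        rng = np.random.default_rng(0)
        keep = rng.random(len(truth)) < 0.5
        half = replicon_depths(pt_from_truth(truth[keep], lengths), lengths, "chr")
        r_full = full.set_index("replicon").loc["pC", "ratio_to_chromosome"]
        r_half = half.set_index("replicon").loc["pC", "ratio_to_chromosome"]
        n_p = (truth[keep].replicon == "pC").sum()
        n_c = (truth[keep].replicon == "chr").sum()
        se = r_full * np.sqrt(1 / n_p + 1 / n_c)
        assert abs(r_half - r_full) < 3 * se


class TestCompareStrains:
    def test_identical_tables_fold_one(self):
        pt = pt_from_counts({"chr": 1_000, "pC": 500})
        d = replicon_depths(pt, {"chr": 10_000, "pC": 1_000}, "chr")
        fold = compare_strains(d, d).set_index("replicon")["fold_change"]
        assert (fold == 1.0).all()

    def test_fold_recovers_planted_change(self):
        specs_wt = [
            RepliconSpec("chr", 30_000, 1.0, is_chromosome=True),
            RepliconSpec("pC", 5_200, 5.0),
        ]
        specs_mut = [
            RepliconSpec("chr", 30_000, 1.0, is_chromosome=True),
            RepliconSpec("pC", 5_200, 50.0),
        ]
        lengths = {"chr": 30_000, "pC": 5_200}
        gw = generate_genome(specs_wt, [], seed=13)
        gm = generate_genome(specs_mut, [], seed=13)
        _, _, tw = simulate_matepairs(gw, small_lib(n_pairs=100_000, seed=1))
        _, _, tm = simulate_matepairs(gm, small_lib(n_pairs=100_000, seed=2))
        dw = replicon_depths(pt_from_truth(tw, lengths), lengths, "chr")
        dm = replicon_depths(pt_from_truth(tm, lengths), lengths, "chr")
        fold = compare_strains(dw, dm).set_index("replicon")["fold_change"]
        assert fold["chr"] == 1.0
        assert abs(fold["pC"] - 10.0) <= 2.0  # within 20%

    def test_missing_replicon_rejected(self):
        a = replicon_depths(pt_from_counts({"chr": 100, "pC": 50}),
                            {"chr": 1_000, "pC": 500}, "chr")
        b = replicon_depths(pt_from_counts({"chr": 100}), {"chr": 1_000}, "chr")
        with pytest.raises(KeyError):
            compare_strains(a, b)


class TestSignalRatio:
    def test_identical_groups_fold_one_p_one(self):
        g = (np.array([1.0, 1.1, 0.9]), np.array([1.0, 1.0, 1.0]))
        out = signal_ratio_test({"wt": g, "mut": g}, reference="wt")
        mut = next(q for q in out if q.group == "mut")
        assert mut.fold_vs_reference == pytest.approx(1.0)
        assert mut.p_value == pytest.approx(1.0)

    def test_degenerate_variance_reports_extreme_p_with_warning(self):
        groups = {
            "wt": (np.array([1.0, 1.0, 1.0]), np.array([1.0, 1.0, 1.0])),
            "mut": (np.array([3.0, 3.0, 3.0]), np.array([1.0, 1.0, 1.0])),
        }
        with pytest.warns(UserWarning, match="zero variance"):
            out = signal_ratio_test(groups, reference="wt")
        mut = next(q for q in out if q.group == "mut")
        assert mut.fold_vs_reference == pytest.approx(3.0)
        assert mut.p_value == 0.0

    def test_single_replicate_refuses_test_but_reports_ratio(self):
        groups = {
            "wt": (np.array([1.0, 1.2]), np.array([1.0, 1.0])),
            "mut": (np.array([2.0]), np.array([1.0])),
        }
        with pytest.warns(UserWarning, match="refused"):
            out = signal_ratio_test(groups, reference="wt")
        mut = next(q for q in out if q.group == "mut")
        assert np.isnan(mut.p_value) and mut.ratio == 2.0

    def test_p_values_uniform_under_null(self):
        """Permutation oracle: with group labels random, the t-test p-value
        distribution must be uniform (KS check)."""
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(200):
            pool = rng.lognormal(0.0, 0.3, size=10)
            denom = np.ones(5)
            perm = rng.permutation(pool)
            groups = {
                "a": (perm[:5], denom),
                "b": (perm[5:], denom),
            }
            out = signal_ratio_test(groups, reference="a")
            pvals.append(next(q for q in out if q.group == "b").p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
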