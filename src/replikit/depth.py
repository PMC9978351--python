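"""Replicon read depth, plasmid/chromosome depth ratios, strain comparison,
and two-probe blot signal quantification.

Average read depth of a replicon is the summed per-read weight mapped to it
divided by the replicon length; the ratio of plasmid depth to chromosome
depth estimates the plasmid copy number per chromosome copy.  Because
repeats shared between replicons would otherwise bias plasmid depth, a
multimapped read contributes weight 1 split equally across its tied-best
placements by default ("fractional"); the "unique" weighting counts only
uniquely placed reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import PairTable


def replicon_depths(pt: PairTable, lengths: dict[str, int],
                    chromosome: str, weighting: str = "fractional") -> pd.DataFrame:
    """DepthTable: per replicon mapped read weight, average depth, and the
    depth ratio to the chromosome."""
    if weighting not in ("fractional", "unique"):
        raise ValueError("weighting must be 'fractional' or 'unique'")
    for name in lengths.values():
        if name <= 0:
            raise ValueError("replicon lengths must be positive")
    pl = pt.placements
    if weighting == "fractional":
        w = 1.0 / pl["nhits"].to_numpy()
    else:
        w = (pl["nhits"].to_numpy() == 1).astype(float)
    weight = pd.Series(w, index=pl["replicon"].to_numpy()).groupby(level=0).sum()

    rows = []
    for name, ln in lengths.items():
        wt = float(weight.get(name, 0.0))
        rows.append((name, wt, ln, wt / ln))
    df = pd.DataFrame(rows, columns=["replicon", "mapped_read_weight", "length",
                                     "average_depth"])
    chrom_depth = float(df.loc[df["replicon"] == chromosome, "average_depth"].iloc[0])
    if chrom_depth == 0:
        raise ValueError("chromosome depth is zero; cannot form ratios")
    df["ratio_to_chromosome"] = df["average_depth"] / chrom_depth
    return df


def compare_strains(depth_a: pd.DataFrame, depth_b: pd.DataFrame) -> pd.DataFrame:
    """Per-replicon fold change of the depth ratio, strain B over strain A."""
    a = depth_a.set_index("replicon")["ratio_to_chromosome"]
    b = depth_b.set_index("replicon")["ratio_to_chromosome"]
    if set(a.index) != set(b.index):
        missing = set(a.index) ^ set(b.index)
        raise KeyError(f"replicon sets differ between strains: {sorted(missing)}")
    fold = (b / a).rename("fold_change")
    return fold.reset_index()


@dataclass
class SignalQuant:
    """Two-probe signal quantification for one group of replicates."""

    group: str
    n: int
    ratio: float              # mean(plasmid probe) / mean(chromosome probe)
    replicate_ratios: np.ndarray
    sem: float
    fold_vs_reference: float = np.nan
    t_statistic: float = np.nan
    p_value: float = np.nan


def signal_ratio_test(groups: dict[str, tuple[np.ndarray, np.ndarray]],
                      reference: str, equal_var: bool = True) -> list[SignalQuant]:
    """Quantify plasmid/chromosome probe signal ratios per group and test
    each group against the reference with an unpaired two-tailed t-test
    (classical Student's pooled-variance test by default; Welch optional)
    on the per-replicate ratios.
    """
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} missing")
    quants: dict[str, SignalQuant] = {}
    for name, (a, b) in groups.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"group {name}: probe replicate counts differ")
        rr = a / b
        quants[name] = SignalQuant(
            group=name, n=len(rr), ratio=float(a.mean() / b.mean()),
            replicate_ratios=rr,
            sem=float(rr.std(ddof=1) / np.sqrt(len(rr))) if len(rr) > 1 else np.nan,
        )
    ref = quants[reference]
    out = []
    for name, q in quants.items():
        q.fold_vs_reference = q.ratio / ref.ratio
        if name != reference:
            if q.n < 2 or ref.n < 2:
                warnings.warn(f"group {name}: <2 replicates; t-test refused")
            else:
                x, y = q.replicate_ratios, ref.replicate_ratios
                if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
                    warnings.warn(
                        f"group {name}: zero variance in both groups; "
                        "p-value degenerate"
                    )
                    q.t_statistic = np.inf if x.mean() != y.mean() else 0.0
                    q.p_value = 0.0 if x.mean() != y.mean() else 1.0
                else:
                    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
                    q.t_statistic = float(t)
                    q.p_value = float(p)
        out.append(q)
    return out
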