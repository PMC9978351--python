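"""Reciprocal anchored-pair detection of whole-plasmid integration.

The procedure mirrors the mate-pair analysis of plasmid cointegrates: select
read pairs in which one mate maps to the anchor plasmid, narrow to pairs
whose other mate maps to a different (target) replicon, repeat with anchor
and targets switched, and intersect the two subsets by pair identity.  The
surviving pairs' first positions form the scatter evidence; single-linkage
clustering of those positions calls fusion intervals.

Because fusion junctions sit inside repeats shared between replicons, a mate
"maps to" a replicon by default only if its unique best placement is there
(require_unique); the permissive policy (any tied-best placement) is kept for
comparison.  A crossover inside an identical repeat is positionally
unidentifiable within the repeat, so calls report junction *intervals*, and
are widened to the repeat copy when an annotation is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .mapping import PairTable


@dataclass(frozen=True)
class FusionCall:
    anchor_replicon: str
    anchor_interval: tuple[int, int]
    target_replicon: str
    target_interval: tuple[int, int]
    support: int
    within_repeat: bool = False
    repeat_family: str | None = None


def _maps_to_matrix(pt: PairTable, replicons: list[str],
                    require_unique: bool) -> np.ndarray:
    """(n_pairs, 2) boolean: does mate 1/2 of each pair map to any of
    ``replicons`` under the chosen ambiguity policy?"""
    n = pt.n_pairs()
    pl = pt.placements
    sel = pl["replicon"].isin(replicons)
    if require_unique:
        sel &= pl["nhits"] == 1
    hit = pl[sel]
    out = np.zeros((n, 2), dtype=bool)
    out[hit["pair_id"].to_numpy(), hit["mate"].to_numpy() - 1] = True
    return out


def _pairs_with_cross(pt: PairTable, side_a: str, targets: list[str],
                      require_unique: bool) -> np.ndarray:
    """Pair ids where one mate maps to side_a and the other mate maps to any
    replicon in ``targets``."""
    paired = pt.pairs["paired"].to_numpy()
    on_a = _maps_to_matrix(pt, [side_a], require_unique)
    on_t = _maps_to_matrix(pt, targets, require_unique)
    cross = paired & ((on_a[:, 0] & on_t[:, 1]) | (on_a[:, 1] & on_t[:, 0]))
    return np.flatnonzero(cross).astype(np.int64)


def select_anchor_pairs(pt: PairTable, anchor: str,
                        require_unique: bool = True) -> np.ndarray:
    """Pairs in which at least one mate maps to the anchor replicon."""
    if anchor not in pt.replicon_names:
        raise KeyError(f"unknown anchor replicon {anchor!r}")
    on_a = _maps_to_matrix(pt, [anchor], require_unique)
    paired = pt.pairs["paired"].to_numpy()
    return np.flatnonzero(paired & on_a.any(axis=1)).astype(np.int64)


def cross_replicon_pairs(pt: PairTable, anchor_set: np.ndarray, anchor: str,
                         targets: list[str] | None = None,
                         require_unique: bool = True) -> np.ndarray:
    """Narrow the anchored set to pairs whose other mate maps to a target."""
    targets = _default_targets(pt, anchor, targets)
    cross = _pairs_with_cross(pt, anchor, targets, require_unique)
    return np.intersect1d(np.asarray(anchor_set), cross)


def _default_targets(pt: PairTable, anchor: str, targets) -> list[str]:
    if targets is None:
        targets = [n for n in pt.replicon_names if n != anchor]
    if anchor in targets:
        raise ValueError("anchor cannot be one of the targets")
    return list(targets)


def reciprocal_intersect(pt: PairTable, anchor: str,
                         targets: list[str] | None = None,
                         require_unique: bool = True
                         ) -> tuple[np.ndarray, dict[str, int]]:
    """Full reciprocal procedure; returns (pair ids, set-size log).

    B  = anchored on the anchor, other mate on a target;
    B' = the same with references switched; C = B ∩ B' by pair identity.
    """
    if anchor not in pt.replicon_names:
        raise KeyError(f"unknown anchor replicon {anchor!r}")
    targets = _default_targets(pt, anchor, targets)
    A = select_anchor_pairs(pt, anchor, require_unique)
    B = cross_replicon_pairs(pt, A, anchor, targets, require_unique)
    # switched references: anchored on each target, other mate on the anchor
    Bp_ids = set()
    for t in targets:
        At = select_anchor_pairs(pt, t, require_unique)
        Bt = cross_replicon_pairs(pt, At, t, [anchor], require_unique)
        Bp_ids.update(Bt.tolist())
    Bp = np.array(sorted(Bp_ids), dtype=np.int64)
    C = np.intersect1d(B, Bp)
    sizes = {"A": len(A), "B": len(B), "B_switched": len(Bp), "C": len(C)}
    return C, sizes


def scatter_table(pt: PairTable, pair_ids: np.ndarray, anchor: str,
                  require_unique: bool = True) -> pd.DataFrame:
    """First-position scatter rows (anchor_pos, target_replicon, target_pos),
    one per pair — the plottable evidence for integration loci."""
    pl = pt.placements
    sel = pl[pl["pair_id"].isin(set(np.asarray(pair_ids).tolist()))]
    if require_unique:
        sel = sel[sel["nhits"] == 1]
    sel = sel.sort_values(["pair_id", "score", "start"],
                          ascending=[True, False, True])
    # one mate anchors, the other provides the target locus; if a mate had
    # tied placements on both sides, prefer higher score then lower position
    on_anchor = (
        sel[sel["replicon"] == anchor]
        .drop_duplicates("pair_id")[["pair_id", "mate", "start"]]
        .rename(columns={"mate": "anchor_mate", "start": "anchor_pos"})
    )
    off = sel[sel["replicon"] != anchor].merge(on_anchor, on="pair_id")
    off = off[off["mate"] != off["anchor_mate"]].drop_duplicates("pair_id")
    out = off[["pair_id", "anchor_pos", "replicon", "start"]].rename(
        columns={"replicon": "target_replicon", "start": "target_pos"}
    )
    return out.reset_index(drop=True)


def call_fusions(scatter: pd.DataFrame, anchor: str, insert_max: int,
                 min_support: int = 5, read_length: int = 150,
                 repeats: pd.DataFrame | None = None) -> list[FusionCall]:
    """Cluster scatter points (single linkage, distance <= insert_max on both
    axes) per target replicon and call one fusion interval per cluster with
    at least ``min_support`` supporting pairs."""
    calls: list[FusionCall] = []
    for target, grp in scatter.groupby("target_replicon"):
        a = grp["anchor_pos"].to_numpy()
        t = grp["target_pos"].to_numpy()
        m = len(grp)
        if m == 0:
            continue
        adj = (np.abs(a[:, None] - a[None, :]) <= insert_max) & (
            np.abs(t[:, None] - t[None, :]) <= insert_max
        )
        ncomp, labels = connected_components(csr_matrix(adj), directed=False)
        for comp in range(ncomp):
            sel = labels == comp
            support = int(sel.sum())
            if support < min_support:
                continue
            ai = (int(a[sel].min()), int(a[sel].max()) + read_length - 1)
            ti = (int(t[sel].min()), int(t[sel].max()) + read_length - 1)
            within = False
            family = None
            if repeats is not None and len(repeats):
                for row in repeats.itertuples():
                    if row.replicon == anchor and _overlaps(ai, (row.start, row.end)):
                        within = True
                        family = row.family
                        ai = (min(ai[0], row.start), max(ai[1], row.end))
                    if row.replicon == target and _overlaps(ti, (row.start, row.end)):
                        within = True
                        family = row.family
                        ti = (min(ti[0], row.start), max(ti[1], row.end))
            calls.append(FusionCall(anchor, ai, str(target), ti, support, within, family))
    calls.sort(key=lambda c: -c.support)
    return calls


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def calls_to_frame(calls: list[FusionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.anchor_replicon, c.anchor_interval[0], c.anchor_interval[1],
             c.target_replicon, c.target_interval[0], c.target_interval[1],
             c.support, c.within_repeat, c.repeat_family)
            for c in calls
        ],
        columns=["anchor", "anchor_start", "anchor_end", "target", "target_start",
                 "target_end", "support", "within_repeat", "repeat_family"],
    )
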