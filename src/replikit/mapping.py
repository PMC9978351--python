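"""Seed-and-extend read mapping against a multi-replicon reference.

The mapper reports *all tied-best placements* of a read instead of picking a
random one: fusion junctions sit inside repeats shared between replicons, and
downstream logic must be able to require uniqueness explicitly.  A placement
is accepted only if it satisfies both acceptance thresholds

* length fraction  = aligned read bases / read length      (default 0.8)
* similarity fraction = matches / aligned columns          (default 0.9)

Alignment is banded local (Smith-Waterman) extension around exact k-mer seed
diagonals, scored match +1 / mismatch -2 / gap -3 (linear gaps).  Circular
replicons are indexed across the origin; reported coordinates are 1-based,
leftmost forward-strand base of the alignment, modulo the replicon length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from ._seq import encode
from .reads import ReadSet

_SPACER = 200  # run of N codes between replicon blocks; > read length + band


@dataclass(frozen=True)
class MapperParams:
    k: int = 15
    length_fraction: float = 0.8
    similarity_fraction: float = 0.9
    match: int = 1
    mismatch: int = -2
    gap: int = -3
    band: int = 12
    seed_stride: int = 7
    max_kmer_hits: int = 16
    max_hits_per_read: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.length_fraction <= 1:
            raise ValueError("length_fraction must lie in (0, 1]")
        if not 0 < self.similarity_fraction <= 1:
            raise ValueError("similarity_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class Placement:
    replicon: str
    start: int        # 1-based leftmost aligned base on the forward reference
    strand: str       # '+' or '-'
    aligned_length: int  # read bases in the alignment
    identity: float   # matches / aligned columns (gaps count as columns)
    score: int


class ReferenceIndex:
    """Exact k-mer index over the forward strand of a concatenated reference.

    Circular replicons get their first ``extension`` bases appended after the
    end so reads spanning the origin still find seeds and align; positions in
    the extension fold back modulo the replicon length.
    """

    def __init__(self, replicons: list[tuple[str, str, bool]], k: int = 15,
                 extension: int | None = None):
        names = [n for n, _, _ in replicons]
        if len(set(names)) != len(names):
            raise ValueError("duplicate replicon names in reference")
        self.k = k
        self.names = names
        ext_default = 162 if extension is None else extension

        blocks = []
        starts = []
        lengths = []
        exts = []
        pos = _SPACER
        blocks.append(np.full(_SPACER, 4, dtype=np.uint8))
        for name, seq, circular in replicons:
            codes = encode(seq)
            L = len(codes)
            if L == 0:
                raise ValueError(f"replicon {name} is empty")
            if L < k:
                warnings.warn(f"replicon {name}: length {L} < k={k}; no k-mers indexed")
            ext = min(ext_default, L) if circular else 0
            block = np.concatenate([codes, codes[:ext]]) if ext else codes
            blocks.append(block)
            blocks.append(np.full(_SPACER, 4, dtype=np.uint8))
            starts.append(pos)
            lengths.append(L)
            exts.append(ext)
            pos += len(block) + _SPACER
        self.codes = np.concatenate(blocks)
        self.block_starts = np.asarray(starts, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        self.extensions = np.asarray(exts, dtype=np.int64)
        self.circular = np.asarray([c for _, _, c in replicons], dtype=bool)

        # build sorted k-mer table over every valid window of the concat
        valid = self.codes < 4
        if len(self.codes) >= k:
            win_valid = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
            windows = np.lib.stride_tricks.sliding_window_view(self.codes, k)
            powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
            kmers = (windows.astype(np.uint64) * powers[None, :]).sum(axis=1)
            idx = np.flatnonzero(win_valid)
            order = np.argsort(kmers[idx], kind="stable")
            self.kmer_sorted = kmers[idx][order]
            self.pos_sorted = idx[order].astype(np.int64)
        else:
            self.kmer_sorted = np.empty(0, dtype=np.uint64)
            self.pos_sorted = np.empty(0, dtype=np.int64)

    @classmethod
    def from_genome(cls, genome, k: int = 15, extension: int | None = None):
        reps = [(r.name, r.sequence, r.circular) for r in genome.replicons.values()]
        return cls(reps, k=k, extension=extension)

    def kmer_start_count(self, name: str) -> int:
        """Distinct forward k-mer start positions indexed for a replicon."""
        i = self.names.index(name)
        lo = self.block_starts[i]
        hi = lo + self.lengths[i] + self.extensions[i]
        in_block = (self.pos_sorted >= lo) & (self.pos_sorted <= hi - self.k)
        local = (self.pos_sorted[in_block] - lo) % self.lengths[i]
        return len(np.unique(local))

    def decode_position(self, gpos: int) -> tuple[int, int]:
        """Map a concat coordinate to (replicon index, 1-based local start)."""
        i = int(np.searchsorted(self.block_starts, gpos, side="right") - 1)
        local = int(gpos - self.block_starts[i])
        if local >= self.lengths[i]:
            local -= int(self.lengths[i])
        return i, local + 1


@njit(cache=False)
def _banded_sw(read, rlen, ref, ws, band, match, mismatch, gap, H, P):
    """Banded local alignment of read vs ref window starting at ws.

    Read base i (1-based) pairs near window position band+i; allowed window
    positions are i..i+2*band.  H and P are caller-provided DP buffers of
    shape (rlen+1, 2*band+1).  Returns (score, matches, columns, read_bases,
    leftmost-global-ref, read_start) of the best-scoring local path.
    """
    W = 2 * band + 1
    for c in range(W):
        H[0, c] = 0
        P[0, c] = 0
    best = 0
    bi = 0
    bc = 0
    nref = len(ref)
    for i in range(1, rlen + 1):
        rb = read[i - 1]
        for c in range(W):
            wj = i + c  # 1-based window position
            gp = ws + wj - 1
            if gp < 0 or gp >= nref:
                H[i, c] = 0
                P[i, c] = 0
                continue
            xb = ref[gp]
            if rb < 4 and rb == xb:
                sub = match
            else:
                sub = mismatch
            s = H[i - 1, c] + sub  # diagonal
            p = 1
            if c + 1 < W:
                alt = H[i - 1, c + 1] + gap  # gap in reference (consume read)
                if alt > s:
                    s = alt
                    p = 2
            if c > 0:
                alt = H[i, c - 1] + gap  # gap in read (consume ref)
                if alt > s:
                    s = alt
                    p = 3
            if s <= 0:
                s = 0
                p = 0
            H[i, c] = s
            P[i, c] = p
            if s > best:
                best = s
                bi = i
                bc = c
    if best <= 0:
        return 0, 0, 0, 0, -1, -1
    # traceback
    i = bi
    c = bc
    matches = 0
    cols = 0
    read_bases = 0
    min_wj = bi + bc
    read_start = bi
    while i > 0 and P[i, c] != 0:
        p = P[i, c]
        wj = i + c
        if p == 1:
            cols += 1
            read_bases += 1
            gp = ws + wj - 1
            if read[i - 1] < 4 and read[i - 1] == ref[gp]:
                matches += 1
            if wj < min_wj:
                min_wj = wj
            read_start = i
            i -= 1
            # c unchanged on diagonal
        elif p == 2:
            cols += 1
            read_bases += 1
            read_start = i
            i -= 1
            c += 1
        else:
            cols += 1
            if wj < min_wj:
                min_wj = wj
            c -= 1
    left_gp = ws + min_wj - 1
    return best, matches, cols, read_bases, left_gp, read_start - 1


@njit(cache=False)
def _map_batch_kernel(
    codes, lengths, ref, kmer_sorted, pos_sorted,
    k, stride, max_kmer_hits, band, match, mismatch, gap,
    length_fraction, similarity_fraction, max_hits,
    out_read, out_strand, out_pos, out_score, out_matches, out_cols,
    out_bases, out_rstart,
):
    n = codes.shape[0]
    powers = np.empty(k, dtype=np.uint64)
    p = np.uint64(1)
    for i in range(k - 1, -1, -1):
        powers[i] = p
        p *= np.uint64(4)
    nout = 0
    max_cand = 64
    cand_diag = np.empty(max_cand, dtype=np.int64)
    cand_strand = np.empty(max_cand, dtype=np.int8)
    sc = np.empty(max_hits * 8, dtype=np.int64)  # scratch placements
    st = np.empty(max_hits * 8, dtype=np.int8)
    sp = np.empty(max_hits * 8, dtype=np.int64)
    sm = np.empty(max_hits * 8, dtype=np.int64)
    sco = np.empty(max_hits * 8, dtype=np.int64)
    sb = np.empty(max_hits * 8, dtype=np.int64)
    srs = np.empty(max_hits * 8, dtype=np.int64)
    fwd = np.empty(codes.shape[1], dtype=np.uint8)
    rev = np.empty(codes.shape[1], dtype=np.uint8)
    Lmax = codes.shape[1]
    Hbuf = np.zeros((Lmax + 1, 2 * band + 1), dtype=np.int32)
    Pbuf = np.zeros((Lmax + 1, 2 * band + 1), dtype=np.uint8)

    for r in range(n):
        L = lengths[r]
        if L < k:
            continue
        for i in range(L):
            fwd[i] = codes[r, i]
            b = codes[r, L - 1 - i]
            rev[i] = 3 - b if b < 4 else 4
        ncand = 0
        for strand in range(2):
            seq = fwd if strand == 0 else rev
            off = 0
            while off <= L - k:
                km = np.uint64(0)
                ok = True
                for j in range(k):
                    b = seq[off + j]
                    if b > 3:
                        ok = False
                        break
                    km += powers[j] * np.uint64(b)
                if ok:
                    lo = np.searchsorted(kmer_sorted, km, side="left")
                    hi = np.searchsorted(kmer_sorted, km, side="right")
                    if hi - lo <= max_kmer_hits:
                        for t in range(lo, hi):
                            d = pos_sorted[t] - off
                            dup = False
                            for q in range(ncand):
                                if cand_strand[q] == strand and abs(cand_diag[q] - d) <= band:
                                    dup = True
                                    break
                            if not dup and ncand < max_cand:
                                cand_diag[ncand] = d
                                cand_strand[ncand] = strand
                                ncand += 1
                if off == L - k:
                    break
                off = min(off + stride, L - k)

        nplace = 0
        best_score = -1
        for q in range(ncand):
            strand = cand_strand[q]
            seq = fwd if strand == 0 else rev
            ws = cand_diag[q] - band
            score, matches, cols, bases, left_gp, rstart = _banded_sw(
                seq, L, ref, ws, band, match, mismatch, gap, Hbuf, Pbuf
            )
            if score <= 0 or cols == 0:
                continue
            if bases / L < length_fraction:
                continue
            if matches / cols < similarity_fraction:
                continue
            if nplace < sc.shape[0]:
                sc[nplace] = score
                st[nplace] = strand
                sp[nplace] = left_gp
                sm[nplace] = matches
                sco[nplace] = cols
                sb[nplace] = bases
                srs[nplace] = rstart
                nplace += 1
                if score > best_score:
                    best_score = score
        nkept = 0
        for q in range(nplace):
            if sc[q] == best_score and nkept < max_hits:
                out_read[nout] = r
                out_strand[nout] = st[q]
                out_pos[nout] = sp[q]
                out_score[nout] = sc[q]
                out_matches[nout] = sm[q]
                out_cols[nout] = sco[q]
                out_bases[nout] = sb[q]
                out_rstart[nout] = srs[q]
                nout += 1
                nkept += 1
    return nout


def map_batch(reads: ReadSet, index: ReferenceIndex,
              params: MapperParams = MapperParams()) -> pd.DataFrame:
    """Map every read of a batch; returns a long DataFrame of tied-best
    placements with columns read, replicon, start, strand, score, matches,
    columns, aligned_length, identity, nhits."""
    n = len(reads)
    cap = max(n * params.max_hits_per_read, 1)
    out = {k: np.empty(cap, dtype=np.int64) for k in
           ("read", "pos", "score", "matches", "cols", "bases", "rstart")}
    out_strand = np.empty(cap, dtype=np.int8)
    nout = _map_batch_kernel(
        reads.codes, reads.lengths.astype(np.int64), index.codes,
        index.kmer_sorted, index.pos_sorted,
        params.k, params.seed_stride, params.max_kmer_hits, params.band,
        params.match, params.mismatch, params.gap,
        params.length_fraction, params.similarity_fraction,
        params.max_hits_per_read,
        out["read"], out_strand, out["pos"], out["score"], out["matches"],
        out["cols"], out["bases"], out["rstart"],
    )
    read = out["read"][:nout]
    gpos = out["pos"][:nout]
    rep_idx = np.searchsorted(index.block_starts, gpos, side="right") - 1
    local = gpos - index.block_starts[rep_idx]
    fold = local >= index.lengths[rep_idx]
    local[fold] -= index.lengths[rep_idx][fold]
    df = pd.DataFrame(
        {
            "read": read,
            "replicon": np.asarray(index.names, dtype=object)[rep_idx],
            "start": local + 1,
            "strand": np.where(out_strand[:nout] == 0, "+", "-"),
            "score": out["score"][:nout],
            "matches": out["matches"][:nout],
            "columns": out["cols"][:nout],
            "aligned_length": out["bases"][:nout],
            "read_start": out["rstart"][:nout],
        }
    )
    # fold-duplicate placements (origin-spanning copies) collapse here
    df = df.drop_duplicates(subset=["read", "replicon", "start", "strand"])
    df["identity"] = df["matches"] / df["columns"]
    df["nhits"] = df.groupby("read")["read"].transform("size")
    return df.reset_index(drop=True)


def map_read(sequence: str, index: ReferenceIndex,
             params: MapperParams = MapperParams()) -> list[Placement]:
    """Map a single read; returns all tied-best placements (empty if none)."""
    if len(sequence) < params.k:
        raise ValueError(f"read shorter than k={params.k}")
    codes = encode(sequence)[None, :].copy()
    quals = np.zeros_like(codes)
    rs = ReadSet(codes, quals, np.array([len(sequence)], dtype=np.int32), ["r"])
    df = map_batch(rs, index, params)
    return [
        Placement(row.replicon, int(row.start), row.strand,
                  int(row.aligned_length), float(row.identity), int(row.score))
        for row in df.itertuples()
    ]


def map_pairs(mate1: ReadSet, mate2: ReadSet, index: ReferenceIndex,
              params: MapperParams = MapperParams(),
              keep1: np.ndarray | None = None,
              keep2: np.ndarray | None = None) -> "PairTable":
    """Map both mates of index-aligned read sets and join per pair.

    keep1/keep2 mark reads that survived trimming; a pair enters the pairing
    table only if both mates survived, but every surviving read is mapped (so
    depth estimation can use orphans).
    """
    if mate1.names != mate2.names:
        set2 = set(mate2.names)
        common = [nm for nm in mate1.names if nm in set2]
        n_orphan = (len(mate1) - len(common)) + (len(mate2) - len(common))
        warnings.warn(f"{n_orphan} orphan mates excluded from pairing")
        pos2 = {nm: i for i, nm in enumerate(mate2.names)}
        idx1 = np.array([i for i, nm in enumerate(mate1.names) if nm in set2],
                        dtype=np.int64)
        idx2 = np.array([pos2[nm] for nm in common], dtype=np.int64)
        mate1 = mate1.subset(idx1)
        mate2 = mate2.subset(idx2)
        if keep1 is not None:
            keep1 = np.asarray(keep1)[idx1]
        if keep2 is not None:
            keep2 = np.asarray(keep2)[idx2]
    n = len(mate1)
    keep1 = np.ones(n, dtype=bool) if keep1 is None else np.asarray(keep1, dtype=bool)
    keep2 = np.ones(n, dtype=bool) if keep2 is None else np.asarray(keep2, dtype=bool)

    frames = []
    for mate_no, (rs, keep) in enumerate(((mate1, keep1), (mate2, keep2)), start=1):
        idx = np.flatnonzero(keep & (rs.lengths >= params.k))
        df = map_batch(rs.subset(idx), index, params)
        df["pair_id"] = idx[df["read"].to_numpy()]
        df["mate"] = mate_no
        frames.append(df.drop(columns=["read"]))
    placements = pd.concat(frames, ignore_index=True)

    both = keep1 & keep2
    nh = placements.groupby(["pair_id", "mate"]).size().unstack(fill_value=0)
    n1 = np.zeros(n, dtype=np.int64)
    n2 = np.zeros(n, dtype=np.int64)
    if 1 in nh.columns:
        n1[nh.index.to_numpy()] = nh[1].to_numpy()
    if 2 in nh.columns:
        n2[nh.index.to_numpy()] = nh[2].to_numpy()
    pairs = pd.DataFrame(
        {
            "pair_id": np.arange(n),
            "paired": both,
            "n1": n1,
            "n2": n2,
            "unique1": n1 == 1,
            "unique2": n2 == 1,
        }
    )
    return PairTable(placements, pairs, list(index.names))


@dataclass
class PairTable:
    """Joined tied-best placements of both mates of every pair."""

    placements: pd.DataFrame  # long: pair_id, mate, replicon, start, strand, ...
    pairs: pd.DataFrame       # per pair: paired flag, hit counts, uniqueness
    replicon_names: list[str]

    def n_pairs(self) -> int:
        return len(self.pairs)


def write_sam(pt: PairTable, reads: tuple[ReadSet, ReadSet],
              index: ReferenceIndex, path) -> None:
    """Minimal SAM subset: @SQ header, mandatory fields, NM tag.  The CIGAR
    approximates the alignment as soft-clips around a single match block
    (indels are not spelled out)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": int(ln)} for n, ln in zip(index.names, index.lengths)],
    }
    name_to_tid = {n: i for i, n in enumerate(index.names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for row in pt.placements.itertuples():
            rs = reads[row.mate - 1]
            L = int(rs.lengths[row.pair_id])
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rs.names[row.pair_id]
            a.query_sequence = rs.sequence(row.pair_id)
            a.query_qualities = pysam.qualitystring_to_array(
                (rs.quals[row.pair_id, :L] + 33).tobytes().decode("ascii"))
            a.flag = (16 if row.strand == "-" else 0) | (256 if row.nhits > 1 else 0)
            a.reference_id = name_to_tid[row.replicon]
            a.reference_start = int(row.start) - 1
            a.mapping_quality = 0 if row.nhits > 1 else 60
            lead = int(row.read_start)
            aligned = int(row.aligned_length)
            tail = L - lead - aligned
            cig = []
            if row.strand == "-":
                lead, tail = tail, lead
            if lead:
                cig.append((4, lead))
            cig.append((0, aligned))
            if tail:
                cig.append((4, tail))
            a.cigartuples = cig
            a.set_tag("NM", int(row.columns - row.matches))
            fh.write(a)
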