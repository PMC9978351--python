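"""Synthetic multi-replicon genomes, cointegrate fusions, and mate-pair reads.

This module emulates the study system: a cyanobacterium-like genome made of a
large circular chromosome plus several circular plasmids at distinct copy
numbers, carrying >=1 kb repeat families (transposase/integrase homologs)
shared between replicons.  A single crossover through such a shared repeat
produces a cointegrate in which the entire donor plasmid sits inside the
acceptor, flanked by two repeat copies — the configuration detectable by
long-insert mate-pair sequencing.

Reads are simulated following the mate-pair protocol: 2–10 kb fragments are
circularised, one 150 nt read is taken from each fragment end, and a
configurable fraction of reads run through the circularisation point and
therefore contain the junction adapter followed by sequence from the opposite
fragment end.  Every read's true origin is recorded in a truth table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import decode, encode, revcomp_codes
from .reads import ReadSet

#: default circularisation-junction adapter: the public Nextera mate-pair
#: transposon 19-mer (any other constant can be configured instead).
DEFAULT_JUNCTION_ADAPTER = "CTGTCTCTTATACACATCT"


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class RepliconSpec:
    """One replicon of the genome to simulate.

    copy_number is the expected number of copies per chromosome copy; exactly
    one replicon per genome carries is_chromosome=True.
    """

    name: str
    length: int
    copy_number: float = 1.0
    is_chromosome: bool = False
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"replicon {self.name}: length must be positive")
        if self.copy_number <= 0:
            raise ValueError(f"replicon {self.name}: copy_number must be > 0")


@dataclass(frozen=True)
class RepeatPlacement:
    replicon: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad repeat placement interval {self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RepeatElement:
    """A repeat family; all placements carry the identical sequence."""

    family_id: str
    placements: tuple[RepeatPlacement, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "placements", tuple(self.placements))
        lens = {p.length for p in self.placements}
        if len(lens) > 1:
            raise ValueError(
                f"repeat family {self.family_id}: placements have unequal lengths {lens}"
            )


@dataclass(frozen=True)
class FusionEvent:
    """Single crossover between a donor plasmid and an acceptor replicon
    through one shared repeat family."""

    donor: str
    acceptor: str
    donor_repeat: RepeatPlacement
    acceptor_repeat: RepeatPlacement
    crossover_offset: int  # 0-based nt within the repeat, 0 <= c < repeat length


@dataclass(frozen=True)
class MatePairLibrarySpec:
    insert_min: int = 2_000
    insert_max: int = 10_000
    read_length: int = 150
    junction_adapter: str = DEFAULT_JUNCTION_ADAPTER
    error_rate: float = 0.005
    n_pairs: int = 50_000
    seed: int = 0
    junction_read_fraction: float = 0.1
    q_high: int = 38
    q_low: int = 12
    low_quality_tail_mean: float = 3.0

    def __post_init__(self) -> None:
        if self.insert_min <= 2 * self.read_length:
            raise ValueError("insert_min must exceed twice the read length")
        if self.insert_max < self.insert_min:
            raise ValueError("insert_max < insert_min")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must lie in [0, 0.1)")


# ---------------------------------------------------------------------------
# genome


@dataclass
class Replicon:
    name: str
    codes: np.ndarray  # uint8 base codes
    copy_number: float = 1.0
    is_chromosome: bool = False
    circular: bool = True

    @property
    def length(self) -> int:
        return int(len(self.codes))

    @property
    def sequence(self) -> str:
        return decode(self.codes)


@dataclass
class Genome:
    replicons: dict[str, Replicon]
    repeats: list[RepeatElement] = field(default_factory=list)

    @property
    def chromosome(self) -> Replicon:
        for rep in self.replicons.values():
            if rep.is_chromosome:
                return rep
        raise ValueError("genome has no chromosome")

    def total_length(self) -> int:
        return sum(r.length for r in self.replicons.values())

    def repeat_table(self) -> pd.DataFrame:
        rows = [
            (el.family_id, p.replicon, p.start, p.end, p.strand)
            for el in self.repeats
            for p in el.placements
        ]
        return pd.DataFrame(rows, columns=["family", "replicon", "start", "end", "strand"])


def _check_placements(specs: list[RepliconSpec], repeat_plan: list[RepeatElement],
                      min_repeat_length: int) -> None:
    lengths = {s.name: s.length for s in specs}
    placed: list[tuple[str, RepeatPlacement]] = []
    for el in repeat_plan:
        for p in el.placements:
            if p.replicon not in lengths:
                raise ValueError(f"repeat {el.family_id}: unknown replicon {p.replicon}")
            if p.end > lengths[p.replicon]:
                raise ValueError(
                    f"repeat {el.family_id} placement {p.replicon}:{p.start}-{p.end} "
                    f"extends past replicon end ({lengths[p.replicon]})"
                )
            if p.length < min_repeat_length:
                raise ValueError(
                    f"repeat {el.family_id}: placement length {p.length} below "
                    f"minimum {min_repeat_length}"
                )
            for fam, q in placed:
                if p.replicon == q.replicon and p.start <= q.end and q.start <= p.end:
                    raise ValueError(
                        f"overlapping repeat placements: {el.family_id} "
                        f"{p.replicon}:{p.start}-{p.end} overlaps {fam} "
                        f"{q.replicon}:{q.start}-{q.end}"
                    )
            placed.append((el.family_id, p))


def generate_genome(specs: list[RepliconSpec], repeat_plan: list[RepeatElement] | None = None,
                    seed: int = 0, min_repeat_length: int = 1_000) -> Genome:
    """Draw uniform-composition random replicons and plant identical repeat
    family copies at the requested placements.  Deterministic per seed."""
    repeat_plan = list(repeat_plan or [])
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("replicon names must be unique")
    if sum(s.is_chromosome for s in specs) != 1:
        raise ValueError("exactly one replicon must be the chromosome")
    _check_placements(specs, repeat_plan, min_repeat_length)

    rng = np.random.default_rng(seed)
    replicons: dict[str, Replicon] = {}
    for s in specs:
        codes = rng.integers(0, 4, size=s.length, dtype=np.uint8)
        replicons[s.name] = Replicon(s.name, codes, s.copy_number, s.is_chromosome, s.circular)
    for el in repeat_plan:
        fam_seq = rng.integers(0, 4, size=el.placements[0].length, dtype=np.uint8)
        for p in el.placements:
            copy = fam_seq if p.strand == "+" else revcomp_codes(fam_seq)
            replicons[p.replicon].codes[p.start - 1 : p.end] = copy
    return Genome(replicons, repeat_plan)


# ---------------------------------------------------------------------------
# cointegrate formation


@dataclass(frozen=True)
class FusionTruth:
    """Ground truth for one applied fusion.

    Junction coordinates are 1-based positions in the cointegrate: the first
    base of each junction-flanking repeat-derived segment downstream of the
    crossover.  Both fall inside a repeat copy of the cointegrate annotation;
    the crossover itself is positionally unidentifiable within the repeat.
    """

    event: FusionEvent
    cointegrate: str              # name of the fused replicon (the acceptor)
    junction_a: int               # acceptor->donor switch point
    junction_b: int               # donor->acceptor switch point
    donor_repeat: RepeatPlacement     # WT coordinates on the donor
    acceptor_repeat: RepeatPlacement  # WT coordinates on the acceptor


def apply_fusion(genome: Genome, event: FusionEvent) -> tuple[Genome, FusionTruth]:
    """Form a single-crossover cointegrate: the full donor replicon is
    inserted into the acceptor inside the shared repeat, and the donor is
    removed from the replicon list.  Total base content is conserved."""
    if event.donor == event.acceptor:
        raise ValueError("donor and acceptor must be distinct replicons")
    if event.donor not in genome.replicons or event.acceptor not in genome.replicons:
        raise ValueError("donor or acceptor not present in genome")

    family = None
    for el in genome.repeats:
        ps = set(el.placements)
        if event.donor_repeat in ps and event.acceptor_repeat in ps:
            family = el
            break
    if family is None:
        raise ValueError(
            "donor and acceptor repeat placements do not belong to one shared family"
        )
    rep_len = event.donor_repeat.length
    c = event.crossover_offset
    if not 0 < c < rep_len:
        raise ValueError(f"crossover_offset must lie strictly inside the repeat (0, {rep_len})")

    donor = genome.replicons[event.donor]
    acceptor = genome.replicons[event.acceptor]
    if not donor.circular:
        raise ValueError("donor must be circular to form a cointegrate")

    d = donor.codes
    drs = event.donor_repeat.start - 1  # 0-based
    if event.donor_repeat.strand != event.acceptor_repeat.strand:
        # flip the donor so the two repeat copies recombine in matching
        # orientation; coordinates of its repeat flip accordingly
        d = revcomp_codes(d)
        drs = len(d) - (event.donor_repeat.end - 1) - 1
    ld = len(d)
    rotated = np.concatenate([d[drs + c :], d[: drs + c]])

    a = acceptor.codes
    ars = event.acceptor_repeat.start - 1
    cut = ars + c
    fused_codes = np.concatenate([a[:cut], rotated, a[cut:]])

    new_replicons = {}
    for name, rep in genome.replicons.items():
        if name == event.donor:
            continue
        if name == event.acceptor:
            new_replicons[name] = Replicon(
                name, fused_codes, rep.copy_number, rep.is_chromosome, rep.circular
            )
        else:
            new_replicons[name] = dataclasses.replace(rep, codes=rep.codes.copy())

    # shift/remap repeat annotations onto the cointegrate
    new_repeats: list[RepeatElement] = []
    for el in genome.repeats:
        placements = []
        for p in el.placements:
            if p.replicon == event.acceptor:
                if p.start - 1 >= cut:
                    placements.append(dataclasses.replace(
                        p, start=p.start + ld, end=p.end + ld))
                elif p.end - 1 < cut:
                    placements.append(p)
                else:
                    # the acceptor repeat copy through which the crossover ran:
                    # it now flanks the junction as a full copy on each side
                    placements.append(p)
                    placements.append(dataclasses.replace(
                        p, start=p.start + ld, end=p.end + ld))
            elif p.replicon == event.donor:
                start0 = (p.start - 1 - (drs + c)) % ld
                placements.append(RepeatPlacement(
                    event.acceptor, cut + start0 + 1, cut + start0 + p.length, p.strand))
            else:
                placements.append(p)
        new_repeats.append(RepeatElement(el.family_id, tuple(placements)))

    truth = FusionTruth(
        event=event,
        cointegrate=event.acceptor,
        junction_a=cut + 1,
        junction_b=cut + ld + 1,
        donor_repeat=event.donor_repeat,
        acceptor_repeat=event.acceptor_repeat,
    )
    return Genome(new_replicons, new_repeats), truth


# ---------------------------------------------------------------------------
# mate-pair simulation


def _substitute(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return codes
    mask = rng.random(codes.shape) < rate
    shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
    out = codes.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def simulate_matepairs(
    genome: Genome, lib: MatePairLibrarySpec
) -> tuple[ReadSet, ReadSet, pd.DataFrame]:
    """Simulate a mate-pair library.

    Fragments are drawn with probability proportional to copy_number x length,
    insert sizes uniform on [insert_min, insert_max]; circular replicons may
    yield fragments spanning the origin.  Returns (mate1, mate2, truth) where
    truth records, per mate, the source replicon, the 1-based leftmost
    forward-strand coordinate, the strand, and whether the read carries the
    circularisation-junction adapter.
    """
    if lib.n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if not genome.replicons:
        raise ValueError("genome is empty")
    chrom = genome.chromosome
    if chrom.length < 10 * lib.insert_max:
        raise ValueError(
            f"chromosome length {chrom.length} below 10x the maximum insert "
            f"size {lib.insert_max}"
        )

    rng = np.random.default_rng(lib.seed)
    reps = list(genome.replicons.values())
    lens = np.array([r.length for r in reps], dtype=np.int64)
    weights = np.array([r.copy_number * r.length for r in reps])
    probs = weights / weights.sum()

    n = lib.n_pairs
    L = lib.read_length
    rep_idx = rng.choice(len(reps), size=n, p=probs)
    inserts = rng.integers(lib.insert_min, lib.insert_max + 1, size=n)
    # clamp inserts to replicon length; sample start positions (linear
    # replicons must fit without wrapping)
    rep_lens = lens[rep_idx]
    inserts = np.minimum(inserts, rep_lens)
    circular = np.array([r.circular for r in reps], dtype=bool)[rep_idx]
    starts = np.empty(n, dtype=np.int64)
    u = rng.random(n)
    starts[circular] = (u[circular] * rep_lens[circular]).astype(np.int64)
    room = rep_lens - inserts + 1
    starts[~circular] = (u[~circular] * room[~circular]).astype(np.int64)
    flip = rng.random(n) < 0.5  # fragment read from the reverse strand

    # per-read truth coordinates (leftmost forward-strand base, 0-based here)
    m1_off = np.where(flip, starts + inserts - L, starts)
    m2_off = np.where(flip, starts, starts + inserts - L)
    m1_strand = np.where(flip, "-", "+")
    m2_strand = np.where(flip, "+", "-")
    m1_off %= rep_lens
    m2_off %= rep_lens

    def _extract(offsets: np.ndarray) -> np.ndarray:
        out = np.empty((n, L), dtype=np.uint8)
        pos = (offsets[:, None] + np.arange(L)[None, :]) % rep_lens[:, None]
        for ri, rep in enumerate(reps):  # few replicons: loop is cheap
            sel = rep_idx == ri
            if sel.any():
                out[sel] = rep.codes[pos[sel]]
        return out

    m1 = _extract(m1_off)
    m2 = _extract(m2_off)
    # orient reads: mate1 reads the fragment 5'->3', mate2 the opposite end
    m1[flip] = 3 - m1[flip, ::-1]  # reverse complement (codes 0..3)
    m2[~flip] = 3 - m2[~flip, ::-1]

    # junction-adapter reads: a fraction of reads run through the
    # circularisation point: genuine prefix + adapter + opposite-end sequence
    adapter = encode(lib.junction_adapter)
    la = len(adapter)
    has_ad = np.zeros((2, n), dtype=bool)
    if lib.junction_read_fraction > 0 and la and L - la > 2:
        jmin = min(20, max(1, L - la - 1))
        for mi, mat in enumerate((m1, m2)):
            other = m2 if mi == 0 else m1
            sel = np.flatnonzero(rng.random(n) < lib.junction_read_fraction)
            has_ad[mi, sel] = True
            js = rng.integers(jmin, L - la + 1, size=len(sel))
            for s, j in zip(sel, js):
                tail = L - j - la
                mat[s, j : j + la] = adapter
                if tail > 0:
                    mat[s, j + la :] = other[s, :tail]

    m1 = _substitute(rng, m1, lib.error_rate)
    m2 = _substitute(rng, m2, lib.error_rate)

    def _quals() -> np.ndarray:
        q = np.full((n, L), lib.q_high, dtype=np.uint8)
        if lib.low_quality_tail_mean > 0:
            p = 1.0 / (1.0 + lib.low_quality_tail_mean)
            tails = np.minimum(rng.geometric(p, size=n) - 1, L)
            cols = np.arange(L)[None, :]
            q[cols >= (L - tails)[:, None]] = lib.q_low
        return q

    names = [f"pair{i:07d}" for i in range(n)]
    rs1 = ReadSet(m1, _quals(), np.full(n, L, dtype=np.int32), list(names))
    rs2 = ReadSet(m2, _quals(), np.full(n, L, dtype=np.int32), list(names))

    rep_names = np.array([r.name for r in reps])
    truth = pd.DataFrame(
        {
            "pair_id": np.repeat(np.arange(n), 2),
            "name": np.repeat(names, 2),
            "mate": np.tile([1, 2], n),
            "replicon": np.repeat(rep_names[rep_idx], 2),
            "start": np.stack([m1_off + 1, m2_off + 1], axis=1).ravel(),
            "strand": np.stack([m1_strand, m2_strand], axis=1).ravel(),
            "insert": np.repeat(inserts, 2),
            "has_adapter": has_ad.T.ravel(),
        }
    )
    return rs1, rs2, truth
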