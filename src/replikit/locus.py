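"""Strand-aware coordinate arithmetic for an mRNA/antisense-RNA plasmid
replication-control locus.

The locus comprises a short forward-strand ORF (the ssr7036-type gene, whose
transcript likely primes plasmid replication) and an abundant antisense RNA
transcribed from the reverse strand, both cleaved by RNase E.  This module
computes in vitro substrate lengths, predicts cleavage-fragment sizes,
classifies transcriptome-mapped processing sites (PSS) from differential
5'-monophosphate read counts, and performs in silico restriction digests and
primer/amplicon location.

Cleavage-site convention: a site coordinate is the 5'-terminal nucleotide of
the *downstream* cleavage product — the only convention consistent with the
printed in vitro fragment sizes and with 5'-monophosphate (TIER-seq) read-end
mapping.  Non-templated 5' residues (e.g. the three Gs left by T7 RNA
polymerase initiation) count toward the 5'-most fragment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from ._seq import revcomp

T7_LEADER = "TAATACGACTCACTATAGGG"


# ---------------------------------------------------------------------------
# types


@dataclass(frozen=True)
class TranscriptSubstrate:
    strand: str                # '+' or '-'
    five_prime_pos: int        # genome coordinate of the 5'-most templated nt
    three_prime_pos: int       # genome coordinate of the 3'-most templated nt
    extra5: int = 0            # non-templated 5' residues (e.g. T7 Gs)
    phospho_state: str = "triphosphate"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.strand == "-" and self.five_prime_pos <= self.three_prime_pos:
            raise ValueError("reverse-strand substrate needs five_prime_pos > three_prime_pos")
        if self.strand == "+" and self.five_prime_pos > self.three_prime_pos:
            raise ValueError("forward-strand substrate needs five_prime_pos <= three_prime_pos")
        if self.extra5 < 0:
            raise ValueError("extra5 must be >= 0")
        if self.phospho_state not in ("triphosphate", "monophosphate"):
            raise ValueError("phospho_state must be tri- or monophosphate")

    @property
    def templated_span(self) -> int:
        return abs(self.five_prime_pos - self.three_prime_pos) + 1


@dataclass(frozen=True)
class CleavageSite:
    """position = genome coordinate of the 5'-terminal nucleotide of the
    downstream cleavage product."""

    position: int
    strand: str


@dataclass(frozen=True)
class OrfSpan:
    start: int   # genome coordinates, inclusive of the stop codon
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class PSSRecord:
    position: int
    strand: str
    tu: str
    fc_wt_ts: float = math.nan
    padj_wt_ts: float = math.nan
    fc_wt_5p: float = math.nan
    padj_wt_5p: float = math.nan
    comment: str = ""


# ---------------------------------------------------------------------------
# arithmetic


def substrate_length(s: TranscriptSubstrate) -> int:
    """Total length in nt: templated span plus non-templated 5' residues."""
    return s.templated_span + s.extra5


def fragment_sizes(s: TranscriptSubstrate, cuts: list[CleavageSite | int]) -> list[int]:
    """Fragment lengths 5'->3' after cleaving the substrate at every site.

    Each cut position becomes the first nucleotide of its downstream
    fragment; lengths always sum to substrate_length(s).
    """
    offsets = []
    for cut in cuts:
        if isinstance(cut, CleavageSite):
            if cut.strand != s.strand:
                raise ValueError(f"cut at {cut.position} is on the opposite strand")
            pos = cut.position
        else:
            pos = int(cut)
        if s.strand == "+":
            i = pos - s.five_prime_pos
        else:
            i = s.five_prime_pos - pos
        if not 0 < i <= s.templated_span - 1:
            raise ValueError(
                f"cut position {pos} lies outside the templated span "
                f"({s.five_prime_pos}..{s.three_prime_pos}, strand {s.strand})"
            )
        offsets.append(s.extra5 + i)
    bounds = [0] + sorted(set(offsets)) + [substrate_length(s)]
    return [b - a for a, b in zip(bounds[:-1], bounds[1:])]


def orf_aa_count(o: OrfSpan) -> int:
    """Amino acids encoded by the reading frame, excluding the stop codon."""
    span = o.end - o.start + 1
    if span % 3 != 0:
        raise ValueError(f"ORF span {span} nt is not a multiple of 3")
    return span // 3 - 1


def tss_distance(pos_a: int, pos_b: int) -> int:
    """Distance in nt between two transcriptional start sites."""
    return abs(pos_a - pos_b)


# ---------------------------------------------------------------------------
# PSS classification

CATEGORIES = ("rnase_e_site", "stabilized_in_ts", "five_prime_sensing_dependent",
              "unclassified")


def classify_pss(record: PSSRecord, comparison: str, alpha: float = 0.05) -> str:
    """Classify a processing site from differential PSS read counts.

    comparison='wt_vs_ts': sites significantly *higher* in rne(WT) than in
    the temperature-inactivated rne(Ts) are RNase E cleavage sites; sites
    significantly higher in rne(Ts) were stabilised by RNase E loss, i.e.
    cut by another RNase whose product RNase E normally degrades.

    comparison='wt_vs_5p': significant differences between the native and
    the 5'-sensing-deficient enzyme flag sites whose processing depends on
    5' sensing (either direction; see methods note).
    """
    if comparison == "wt_vs_ts":
        fc, padj = record.fc_wt_ts, record.padj_wt_ts
        if math.isnan(fc) or math.isnan(padj) or padj > alpha:
            return "unclassified"
        return "rnase_e_site" if fc > 0 else "stabilized_in_ts"
    if comparison == "wt_vs_5p":
        fc, padj = record.fc_wt_5p, record.padj_wt_5p
        if math.isnan(fc) or math.isnan(padj) or padj > alpha or fc == 0:
            return "unclassified"
        return "five_prime_sensing_dependent"
    raise ValueError(f"unknown comparison {comparison!r}")


def load_pss_table() -> pd.DataFrame:
    """The packaged table of TIER-seq mapped processing sites of the locus
    (position, strand, TU, per-comparison log2 fold change and adjusted p)."""
    with resources.files("replikit.data").joinpath("table3_pss.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def load_locus_coords() -> dict[str, int]:
    with resources.files("replikit.data").joinpath("locus_coords.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["name"], df["value"].astype(int)))


def load_primers() -> pd.DataFrame:
    with resources.files("replikit.data").joinpath("primers.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def pss_records(df: pd.DataFrame | None = None) -> list[PSSRecord]:
    if df is None:
        df = load_pss_table()
    return [
        PSSRecord(
            position=int(r.position), strand=r.strand, tu=r.tu,
            fc_wt_ts=float(r.fc_wt_ts) if pd.notna(r.fc_wt_ts) else math.nan,
            padj_wt_ts=float(r.padj_wt_ts) if pd.notna(r.padj_wt_ts) else math.nan,
            fc_wt_5p=float(r.fc_wt_5p) if pd.notna(r.fc_wt_5p) else math.nan,
            padj_wt_5p=float(r.padj_wt_5p) if pd.notna(r.padj_wt_5p) else math.nan,
            comment=str(r.comment),
        )
        for r in df.itertuples()
    ]


def classify_table(df: pd.DataFrame | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Classified PSS table with one category column per comparison."""
    if df is None:
        df = load_pss_table()
    recs = pss_records(df)
    out = df.copy()
    out["category_wt_vs_ts"] = [classify_pss(r, "wt_vs_ts", alpha) for r in recs]
    out["category_wt_vs_5p"] = [classify_pss(r, "wt_vs_5p", alpha) for r in recs]
    return out


# ---------------------------------------------------------------------------
# restriction digest & primer location


def digest(sequence: str, recognition_site: str = "AAGCTT", circular: bool = False,
           cut_offset: int = 1) -> list[tuple[int, int, int]]:
    """In silico restriction digest by exact recognition-site matching.

    Returns (start, end, length) fragments, 1-based inclusive; the cut falls
    ``cut_offset`` nt into each site occurrence (1 for HindIII: A^AGCTT).
    Circular sequences yield a fragment spanning the origin; fragment lengths
    always sum to the sequence length.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    L = len(seq)
    search = seq + seq[: len(recognition_site) - 1] if circular else seq
    cuts = []
    pos = 0
    while True:
        hit = search.find(recognition_site.upper(), pos)
        if hit < 0 or hit >= L:
            break
        cuts.append((hit + cut_offset) % L)
        pos = hit + 1
    cuts = sorted(set(cuts))
    if not cuts:
        return [(1, L, L)]
    frags = []
    if circular:
        for c, nxt in zip(cuts, cuts[1:] + [cuts[0] + L]):
            length = nxt - c
            start = c + 1
            end = (c + length - 1) % L + 1
            frags.append((start, end, length))
    else:
        bounds = [0] + cuts + [L]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b > a:
                frags.append((a + 1, b, b - a))
    return frags


def locate_amplicon(sequence: str, fwd_primer: str, rev_primer: str,
                    t7_leader: str = T7_LEADER) -> tuple[int, int]:
    """Genomic span amplified by a primer pair (exact matching).

    Any T7 promoter leader is stripped from either primer before matching;
    the reverse primer is matched as its reverse complement.  Raises if a
    primer matches zero times or more than once.
    """
    fwd = _strip_t7(fwd_primer, t7_leader)
    rev = _strip_t7(rev_primer, t7_leader)
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be >= 15 nt after leader stripping")
    seq = sequence.upper()
    f_hits = _find_all(seq, fwd.upper())
    r_hits = _find_all(seq, revcomp(rev).upper())
    for name, hits in (("forward", f_hits), ("reverse", r_hits)):
        if len(hits) == 0:
            raise ValueError(f"{name} primer has no exact match")
        if len(hits) > 1:
            raise ValueError(f"{name} primer matches {len(hits)} times (ambiguous)")
    start = f_hits[0] + 1
    end = r_hits[0] + len(rev)
    if end < start:
        raise ValueError("primer orientation inconsistent with an amplicon")
    return start, end


def _strip_t7(primer: str, leader: str) -> str:
    p = primer.upper()
    return p[len(leader):] if leader and p.startswith(leader.upper()) else p


def _find_all(seq: str, sub: str) -> list[int]:
    hits = []
    pos = 0
    while True:
        hit = seq.find(sub, pos)
        if hit < 0:
            break
        hits.append(hit)
        pos = hit + 1
    return hits


def amplicon_fragment(fragments: list[tuple[int, int, int]],
                      span: tuple[int, int]) -> tuple[int, int, int]:
    """The digest fragment containing an amplicon span (e.g. to predict the
    band a hybridisation probe lights up on a blot)."""
    s, e = span
    for frag in fragments:
        fs, fe, _ = frag
        if fs <= fe:
            if fs <= s and e <= fe:
                return frag
        elif s >= fs or e <= fe:  # origin-spanning circular fragment
            return frag
    raise ValueError("amplicon does not lie within a single fragment")
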