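#!/usr/bin/env python
"""Coordinate arithmetic of the mRNA/antisense-RNA replication-control locus.

Builds the in vitro antisense-RNA substrate from the packaged locus
constants, predicts the RNase E cleavage-product lengths for the two mapped
reverse-strand sites, and derives the TSS spacing and the small protein's
size.  Writes results/locus_arithmetic.tsv.
"""

from pathlib import Path

import pandas as pd

from replikit.locus import (
    OrfSpan,
    TranscriptSubstrate,
    fragment_sizes,
    load_locus_coords,
    orf_aa_count,
    substrate_length,
    tss_distance,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    c = load_locus_coords()
    sub = TranscriptSubstrate("-", c["asrna1_substrate_five_prime"],
                              c["asrna1_three_prime"], extra5=3,
                              phospho_state="monophosphate")
    native = TranscriptSubstrate("-", c["asrna1_tss"], c["asrna1_three_prime"])
    up, down = c["invitro_cut_upstream"], c["invitro_cut_downstream"]

    rows = [
        ("native_asrna1_length_nt", substrate_length(native)),
        ("invitro_substrate_length_nt", substrate_length(sub)),
        ("fragments_cut_32426", fragment_sizes(sub, [up])),
        ("fragments_cut_32418", fragment_sizes(sub, [down])),
        ("fragments_both_cuts", fragment_sizes(sub, [up, down])),
        ("tss_spacing_nt", tss_distance(c["ssr7036_tss"], c["asrna1_tss"])),
        ("ssr7036_protein_aa", orf_aa_count(OrfSpan(c["ssr7036_orf_start"],
                                                    c["ssr7036_orf_end"]))),
    ]
    df = pd.DataFrame(rows, columns=["quantity", "value"])
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "locus_arithmetic.tsv", sep="\t", index=False)

    print("antisense RNA (native) length:", substrate_length(native), "nt")
    print("in vitro substrate (+3 T7 Gs):", substrate_length(sub), "nt")
    print(f"cleavage at {up}: fragments", fragment_sizes(sub, [up]), "nt")
    print(f"cleavage at {down}: fragments", fragment_sizes(sub, [down]), "nt")
    print("both cleavages:", fragment_sizes(sub, [up, down]), "nt")
    print("TSS spacing:", rows[5][1], "nt; protein:", rows[6][1], "aa")
    print("wrote", OUT / "locus_arithmetic.tsv")


if __name__ == "__main__":
    main()
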