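#!/usr/bin/env python
"""Classify the packaged TIER-seq processing sites of the locus.

Sites significantly more abundant in the RNase-E-overexpressing strain than
in the temperature-inactivated strain are direct RNase E cleavage sites;
sites going the other way are stabilised products of another RNase.  Writes
results/pss_classification.tsv and prints the per-TU tallies.
"""

from pathlib import Path

from replikit.locus import classify_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    t = classify_table(alpha=0.05)
    OUT.mkdir(exist_ok=True)
    t.to_csv(OUT / "pss_classification.tsv", sep="\t", index=False)

    n_sense = int(t.tu.isin(["TU7029", "TU7030"]).sum())
    n_anti = int((t.tu == "TU7031").sum())
    sig_anti = t[(t.tu == "TU7031") & (t.category_wt_vs_ts == "rnase_e_site")]
    print(f"processing sites in the sense precursor (TU7029/TU7030): {n_sense}")
    print(f"processing sites in the antisense RNA (TU7031): {n_anti}")
    print(
        "antisense sites called direct RNase E cleavages "
        f"(rne(WT) vs rne(Ts)): {len(sig_anti)} at positions "
        f"{sorted(sig_anti.position)}"
    )
    print(t[["position", "strand", "tu", "category_wt_vs_ts",
             "category_wt_vs_5p"]].to_string(index=False))
    print("wrote", OUT / "pss_classification.tsv")


if __name__ == "__main__":
    main()
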