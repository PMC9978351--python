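"""End-to-end orchestration: simulate -> trim -> map -> fusion/depth -> report.

A single config (dict, YAML or JSON) describes the genome, an optional
cointegrate fusion, the library, trimming, mapping and detection parameters.
Per-stage seeds are derived from the master seed with
``numpy.random.SeedSequence(seed).spawn`` in a fixed order (genome, library),
so a run is reproducible end to end and each stage is independently
re-runnable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import depth as depth_mod
from . import fusion as fusion_mod
from . import qc, synth
from .mapping import MapperParams, ReferenceIndex, map_pairs
from .reads import write_fastq


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    text = Path(path_or_dict).read_text()
    return yaml.safe_load(text)


def stage_seeds(master: int, n: int = 4) -> list[int]:
    """Fixed derivation scheme for per-stage seeds (documented contract)."""
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_all(config, outdir=None) -> dict:
    """Run the whole pipeline; returns (and writes) a machine-readable
    summary with selection-set sizes, fusion calls and depth ratios."""
    cfg = load_config(config)
    outdir = Path(outdir or cfg.get("outdir", "pipeline_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(cfg.get("seed", 0))
    seeds = stage_seeds(master)
    log: list[str] = []

    def stage(name):
        log.append(f"stage: {name}")

    # --- genome -----------------------------------------------------------
    try:
        stage("genome")
        specs = [synth.RepliconSpec(**r) for r in cfg["replicons"]]
        repeat_plan = [
            synth.RepeatElement(
                fam["family_id"],
                tuple(synth.RepeatPlacement(**p) for p in fam["placements"]),
            )
            for fam in cfg.get("repeats", [])
        ]
        genome = synth.generate_genome(
            specs, repeat_plan, seed=seeds[0],
            min_repeat_length=int(cfg.get("min_repeat_length", 1000)),
        )
        reference = genome  # reads are always mapped back to the WT reference
        write_genome_fasta(genome, outdir / "reference.fasta")
        genome.repeat_table().to_csv(outdir / "repeats.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("genome", e) from e

    # --- optional cointegrate fusion --------------------------------------
    fusion_truth = None
    try:
        if cfg.get("fusion"):
            stage("fusion")
            f = cfg["fusion"]
            event = synth.FusionEvent(
                donor=f["donor"], acceptor=f["acceptor"],
                donor_repeat=synth.RepeatPlacement(**f["donor_repeat"]),
                acceptor_repeat=synth.RepeatPlacement(**f["acceptor_repeat"]),
                crossover_offset=int(f["crossover_offset"]),
            )
            genome, fusion_truth = synth.apply_fusion(genome, event)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("fusion", e) from e

    # --- library ----------------------------------------------------------
    try:
        stage("library")
        lib = synth.MatePairLibrarySpec(
            **{**cfg.get("library", {}), "seed": seeds[1]}
        )
        m1, m2, truth = synth.simulate_matepairs(genome, lib)
        write_fastq(m1, outdir / "reads_R1.fastq")
        write_fastq(m2, outdir / "reads_R2.fastq")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("library", e) from e

    # --- trimming ---------------------------------------------------------
    try:
        stage("trim")
        policy = qc.TrimPolicy(
            adapter=lib.junction_adapter, **cfg.get("trim", {})
        )
        t1, keep1, counts1 = qc.trim_batch(m1, policy)
        t2, keep2, counts2 = qc.trim_batch(m2, policy)
        log.append(f"trim mate1: {counts1}")
        log.append(f"trim mate2: {counts2}")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("trim", e) from e

    # --- mapping ----------------------------------------------------------
    try:
        stage("map")
        params = MapperParams(**cfg.get("mapper", {}))
        index = ReferenceIndex.from_genome(reference, k=params.k)
        pt = map_pairs(t1, t2, index, params, keep1, keep2)
        pt.placements.to_csv(outdir / "placements.tsv", sep="\t", index=False)
        pt.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("map", e) from e

    # --- fusion detection -------------------------------------------------
    try:
        stage("detect")
        det = cfg.get("fusion_detect", {})
        anchor = det.get("anchor")
        calls = []
        sizes = {}
        if anchor:
            C, sizes = fusion_mod.reciprocal_intersect(
                pt, anchor, require_unique=det.get("require_unique", True)
            )
            scatter = fusion_mod.scatter_table(
                pt, C, anchor, require_unique=det.get("require_unique", True)
            )
            scatter.to_csv(outdir / "scatter.tsv", sep="\t", index=False)
            calls = fusion_mod.call_fusions(
                scatter, anchor, insert_max=lib.insert_max,
                min_support=int(det.get("min_support", 5)),
                read_length=lib.read_length,
                repeats=reference.repeat_table(),
            )
            fusion_mod.calls_to_frame(calls).to_csv(
                outdir / "fusion_calls.tsv", sep="\t", index=False
            )
            log.append(f"selection sizes: {sizes}")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("detect", e) from e

    # --- depth ------------------------------------------------------------
    try:
        stage("depth")
        lengths = {r.name: r.length for r in reference.replicons.values()}
        chrom = reference.chromosome.name
        depth = depth_mod.replicon_depths(
            pt, lengths, chrom, weighting=cfg.get("weighting", "fractional")
        )
        depth.to_csv(outdir / "depth.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("depth", e) from e

    summary = {
        "seed": master,
        "n_pairs": int(lib.n_pairs),
        "selection_sizes": {k: int(v) for k, v in sizes.items()},
        "fusion_calls": [
            dataclasses.asdict(c) for c in calls
        ],
        "depth_ratios": {
            row.replicon: round(float(row.ratio_to_chromosome), 6)
            for row in depth.itertuples()
        },
        "truth_fusion": (
            None if fusion_truth is None else {
                "donor": fusion_truth.event.donor,
                "acceptor": fusion_truth.event.acceptor,
                "junction_a": fusion_truth.junction_a,
                "junction_b": fusion_truth.junction_b,
            }
        ),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return summary


def write_genome_fasta(genome: synth.Genome, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(rep.sequence), id=rep.name,
            description=f"copy_number={rep.copy_number} "
                        f"circular={rep.circular} chromosome={rep.is_chromosome}",
        )
        for rep in genome.replicons.values()
    ]
    seqio_write(records, str(path), "fasta")


def read_genome_fasta(path, copy_numbers: dict[str, float] | None = None,
                      chromosome: str | None = None) -> synth.Genome:
    from Bio.SeqIO import parse

    from ._seq import encode

    replicons = {}
    for rec in parse(str(path), "fasta"):
        cn = (copy_numbers or {}).get(rec.id, 1.0)
        replicons[rec.id] = synth.Replicon(
            rec.id, encode(str(rec.seq)), cn,
            is_chromosome=(rec.id == chromosome), circular=True,
        )
    return synth.Genome(replicons)
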