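"""Pipeline orchestration: simulate -> reads -> detect -> foldback ->
invpairs -> barcode -> features, with one config and an auditable report.

Each stage's outputs are the next stage's inputs; the report aggregates
counts at every filter so read losses are traceable, and records the
fully resolved configuration for provenance.  Identical config and seed
reproduce an identical report.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import barcode as bc
from . import detect as det
from . import features as feat
from . import foldback as fb
from . import invpairs as inv
from . import io as bio
from .genome import default_genome
from .locus import build_locus
from .reads import FastqRead, merge_pair, quality_filter
from .simulate import SimConfig, make_pairs, simulate_reads

ALL_STAGES = ("simulate", "reads", "detect", "foldback", "invpairs", "barcode", "features")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str
    rng_seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    locus: dict = field(default_factory=dict)
    genome: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    reads: dict = field(default_factory=dict)
    detect: dict = field(default_factory=dict)
    foldback: dict = field(default_factory=lambda: {"min_copy": 5, "signature_len": 2})
    barcode: dict = field(default_factory=dict)
    features: dict = field(default_factory=lambda: {"n_iter": 200})
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages:
            for key in ("reads_r1", "reads_r2"):
                path = self.inputs.get(key)
                if not path:
                    raise ValueError(
                        f"input {key!r} required when the simulate stage is disabled"
                    )
                if not os.path.exists(path):
                    raise ValueError(f"input path does not exist: {path}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"stages": {}, "config": _resolved(config)}
    locus = build_locus(rng_seed=config.rng_seed, **config.locus)
    genome = default_genome(rng_seed=config.rng_seed + 1, **config.genome)
    design = bc.default_design()
    state: dict = {}

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            runner = _RUNNERS[stage]
            report["stages"][stage] = runner(config, locus, genome, design, state)
        except Exception as exc:  # halt with the failing stage named
            _write_report(report, config.outdir)
            raise PipelineError(stage, str(exc)) from exc
    _write_report(report, config.outdir)
    return report


def _resolved(config: RunConfig) -> dict:
    out = dataclasses.asdict(config)
    out["stages"] = list(config.stages)
    return out


def _write_report(report: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)


def _stage_simulate(config, locus, genome, design, state) -> dict:
    sim_cfg = SimConfig(rng_seed=config.rng_seed, **config.simulate)
    reads, truth = simulate_reads(locus, genome, sim_cfg, oligo=design)
    r1, r2 = make_pairs(reads, sim_cfg.read_len)
    out = config.outdir
    bio.write_fastq(r1, os.path.join(out, "reads_R1.fastq"))
    bio.write_fastq(r2, os.path.join(out, "reads_R2.fastq"))
    truth_out = truth.copy()
    for col in ("donor1_start", "donor2_start"):  # 1-based inclusive on disk
        truth_out[col] = truth_out[col].where(truth_out[col] < 0, truth_out[col] + 1)
    truth_out.to_csv(os.path.join(out, "truth.tsv"), sep="\t", index=False)
    bio.write_fasta({locus.locus_id: locus.sequence}, os.path.join(out, "locus.fa"))
    bio.write_genome(genome, out)
    state["pairs"] = (r1, r2)
    state["truth"] = truth
    counts = truth["event_class"].value_counts().to_dict()
    return {"n_reads": len(reads), "class_counts": counts}


def _stage_reads(config, locus, genome, design, state) -> dict:
    if "pairs" in state:
        r1, r2 = state["pairs"]
    else:
        r1 = bio.read_fastq(config.inputs["reads_r1"])
        r2 = bio.read_fastq(config.inputs["reads_r2"])
    opts = dict(config.reads)
    min_overlap = opts.pop("min_overlap", 10)
    max_mm = opts.pop("max_mismatch_frac", 0.1)
    min_mean_q = opts.pop("min_mean_q", 20.0)
    contaminants = opts.pop("contaminants", [])
    merged, unmerged = [], 0
    for a, b in zip(r1, r2):
        fa = a if isinstance(a, FastqRead) else FastqRead(a.read_id, a.sequence, a.quality)
        fb_ = b if isinstance(b, FastqRead) else FastqRead(b.read_id, b.sequence, b.quality)
        m = merge_pair(fa, fb_, min_overlap=min_overlap, max_mismatch_frac=max_mm)
        if m.merged_flag:
            merged.append(m)
        else:
            unmerged += 1
    kept, qc = quality_filter(merged, min_mean_q=min_mean_q, contaminant_seqs=contaminants)
    state["merged"] = kept
    bio.write_fastq(
        [FastqRead(m.read_id, m.sequence, m.qualities) for m in kept],
        os.path.join(config.outdir, "merged.fastq"),
    )
    stats = {"pairs_in": len(r1), "merged": len(merged), "unmerged": unmerged, **qc}
    pd.DataFrame([stats]).to_csv(
        os.path.join(config.outdir, "merge_stats.tsv"), sep="\t", index=False
    )
    return stats


def _merged_reads(config, state):
    if "merged" not in state:
        path = config.inputs.get("merged") or os.path.join(config.outdir, "merged.fastq")
        state["merged"] = bio.read_fastq(path)
    return state["merged"]


def _stage_detect(config, locus, genome, design, state) -> dict:
    reads = _merged_reads(config, state)
    events, counts = det.detect_insertions(reads, locus, genome, **config.detect)
    state["events"] = events
    rows = []
    for ev in events:
        rows.append(
            {
                "event_id": ev.event_id,
                "insert_seq": ev.insert_seq,
                "insert_len": len(ev.insert_seq),
                "read_support": ev.read_support,
                "donor_count": ev.donor_count,
                "category": ev.category,
                "mh_left": ev.mh_left,
                "mh_right": ev.mh_right,
                "donor_hits": ";".join(
                    f"{h.contig}:{h.start + 1}-{h.end}:{h.strand}" for h in ev.donor_hits
                ),
            }
        )
    pd.DataFrame(rows).to_csv(
        os.path.join(config.outdir, "events.tsv"), sep="\t", index=False
    )
    freq, dist = det.annotate_and_summarize(
        {"sample": (events, counts["reads"])}, genome, reference="sample"
    )
    freq.to_csv(os.path.join(config.outdir, "frequency.tsv"), sep="\t", index=False)
    dist.to_csv(os.path.join(config.outdir, "distributions.tsv"), sep="\t", index=False)
    return counts


def _stage_foldback(config, locus, genome, design, state) -> dict:
    reads = _merged_reads(config, state)
    opts = dict(config.foldback)
    min_copy = opts.pop("min_copy", 5)
    sig_len = opts.pop("signature_len", 2)
    seeds = fb.build_seeds(locus, min_copy=min_copy)
    events = fb.scan_for_foldbacks(reads, seeds, locus, **opts)
    sig_count = fb.count_short_signature(reads, locus, sig_len)
    pd.DataFrame(
        [
            {
                "event_id": ev.event_id,
                "copy_len": ev.copy_len,
                "mh_left": ev.mh_left,
                "loop_len": ev.loop_len,
                "seed_variant": ev.seed_variant,
                "read_support": ev.read_support,
            }
            for ev in events
        ]
    ).to_csv(os.path.join(config.outdir, "foldback.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{"signature_len": sig_len, "read_count": sig_count}]
    ).to_csv(os.path.join(config.outdir, "signature_counts.tsv"), sep="\t", index=False)
    return {"n_foldback_events": len(events), "signature_reads": sig_count}


def _stage_invpairs(config, locus, genome, design, state) -> dict:
    events = state.get("events", [])
    table = inv.pairs_table(events, genome, locus)
    table.to_csv(os.path.join(config.outdir, "pairs.tsv"), sep="\t", index=False)
    summary = inv.summarize_complex(events, genome)
    with open(os.path.join(config.outdir, "complex_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _stage_barcode(config, locus, genome, design, state) -> dict:
    reads = _merged_reads(config, state)
    flagged, _ = bc.recognize_oligo_reads(
        [(r.read_id, r.sequence) for r in reads], design
    )
    flagged_set = set(flagged)
    pairs, rows = [], []
    for r in reads:
        if r.read_id not in flagged_set:
            continue
        codes, malformed = bc.extract_barcodes(r.sequence, design)
        pairs.append(codes)
        rows.append(
            {
                "read_id": r.read_id,
                "barcodes": ",".join(codes),
                "n_barcodes": len(codes),
                "n_malformed": malformed,
            }
        )
    pd.DataFrame(rows).to_csv(
        os.path.join(config.outdir, "barcodes.tsv"), sep="\t", index=False
    )
    result: dict = {"flagged_reads": len(flagged)}
    two = [p for p in pairs if len(p) == 2]
    if two:
        summary = bc.classify_and_expect(
            pairs, design.barcode_len, rng_seed=config.rng_seed, **config.barcode
        )
        result.update(
            observed_identical_fraction=summary.observed_identical_fraction,
            analytic_expectation=summary.analytic_expectation,
            mc_mean=summary.mc_mean,
            exceeds_chance=summary.exceeds_chance,
        )
    return result


def _stage_features(config, locus, genome, design, state) -> dict:
    events = state.get("events", [])
    donors = [
        (h.contig, h.start, h.end)
        for ev in events
        for h in ev.donor_hits
        if h.contig in genome.contigs
    ]
    result: dict = {"n_donor_intervals": len(donors)}
    if donors:
        fs = feat.FeatureSet(tracks=genome.features, proximity_rules=feat.DEFAULT_RULES)
        table = feat.enrichment_test(
            donors,
            fs,
            genome.sizes,
            genome.masked,
            n_iter=config.features.get("n_iter", 200),
            rng_seed=config.rng_seed,
        )
        table.to_csv(
            os.path.join(config.outdir, "enrichment.tsv"), sep="\t", index=False
        )
        result["tracks"] = table.to_dict("records")
    return result


_RUNNERS = {
    "simulate": _stage_simulate,
    "reads": _stage_reads,
    "detect": _stage_detect,
    "foldback": _stage_foldback,
    "invpairs": _stage_invpairs,
    "barcode": _stage_barcode,
    "features": _stage_features,
}
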