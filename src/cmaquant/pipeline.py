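"""Config-driven orchestration of the analysis stages.

A single structured (YAML/JSON) config file governs which stages run
and with what parameters; every stochastic stage takes a seed, so a
rerun with the same config reproduces byte-identical tables.  Stages:

``simulate-quant``, ``simulate-seqs``, ``simulate-image`` (synthetic
inputs with truth sidecars), ``filter`` (quantification-table filter
cascade + regulation calls), ``scan`` (motif scan of a FASTA),
``breakdown`` (motif x regulation panels), ``puncta`` (per-cell puncta
counts from a 2-channel TIFF), ``compare`` (replicate-level t-test),
``export-string-list`` (gene lists for the STRING website).
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, motifs, puncta, silac, synthetic

STAGES = (
    "simulate-quant",
    "simulate-seqs",
    "simulate-image",
    "filter",
    "scan",
    "breakdown",
    "puncta",
    "compare",
    "export-string-list",
)

_TOP_KEYS = {"outdir", "seed", "stages"} | {s.replace("-", "_") for s in STAGES}

_STAGE_KEYS = {
    "simulate_quant": {
        "n_proteins", "frac_up", "frac_down", "n_replicates", "rep_sd",
        "seed", "treatment", "frac_high_confidence",
    },
    "simulate_seqs": {"n_per_class", "classes", "length", "seed"},
    "simulate_image": {
        "n_cells", "puncta_per_cell", "spot_sigma", "snr", "size", "seed",
    },
    "filter": {
        "table", "treatment", "column_map", "min_peptides", "max_p",
        "fold_threshold",
    },
    "scan": {"fasta", "fold_dual_into_parents"},
    "breakdown": {},
    "puncta": {
        "image", "nuclei_channel", "reporter_channel", "pre_smooth_sigma",
        "min_area", "max_area", "radius", "k", "r", "p", "q",
    },
    "compare": {"counts"},
    "export_string_list": {},
}


def validate_config(config: dict) -> dict:
    """Check the config against the schema; unknown keys raise with the
    offending key named."""
    for key in config:
        if key not in _TOP_KEYS:
            raise ValueError(f"unknown config key: {key!r}")
    stages = config.get("stages", [])
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage: {stage!r}")
        section = config.get(stage.replace("-", "_"), {}) or {}
        allowed = _STAGE_KEYS[stage.replace("-", "_")]
        for key in section:
            if key not in allowed:
                raise ValueError(f"unknown config key: {stage}.{key!r}")
    return config


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    return validate_config(config)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stages in order; returns paths and key
    numbers per stage and writes a structured run log."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)

    outdir = Path(config.get("outdir", "cmaquant_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    global_seed = int(config.get("seed", 0))
    stages = config.get("stages", [])
    if not stages:
        raise ValueError("config lists no stages")

    state: dict = {}
    log: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": global_seed,
        "stages": [],
    }
    report: dict = {}

    for stage in stages:
        params = dict(config.get(stage.replace("-", "_"), {}) or {})
        entry: dict = {"stage": stage, "params": dict(params)}

        if stage == "simulate-quant":
            params.setdefault("seed", global_seed)
            params.setdefault("n_proteins", 1000)
            table, truths = synthetic.gen_quant_table(**params)
            table_path = outdir / "quant_table.tsv"
            synthetic.write_quant_table(table, table_path)
            _dump_json([asdict(t) for t in truths], outdir / "quant_truth.json")
            state["quant_table"] = table_path
            state["quant_ids"] = list(table[table.columns[0]])
            entry["n_proteins"] = len(table)

        elif stage == "simulate-seqs":
            params.setdefault("seed", global_seed)
            if "quant_ids" in state:
                # Tie sequences to the simulated quantification table so
                # motif profiles and regulation calls join downstream.
                params.setdefault("protein_ids", state["quant_ids"])
            params.setdefault("n_per_class", 20)
            truths = synthetic.gen_motif_proteins(**params)
            fasta_path = outdir / "sequences.fasta"
            synthetic.write_fasta(truths, fasta_path)
            synthetic.write_sequence_truth(truths, outdir / "sequence_truth.json")
            state["fasta"] = fasta_path
            entry["n_sequences"] = len(truths)

        elif stage == "simulate-image":
            params.setdefault("seed", global_seed)
            params.setdefault("n_cells", 10)
            if "size" in params:
                params["size"] = tuple(params["size"])
            image, truth = synthetic.gen_cell_image(**params)
            image_path = outdir / "image.tif"
            synthetic.write_image_tiff(image, image_path)
            synthetic.write_image_truth(
                truth, outdir / "image_truth.json", outdir / "image_truth_labels.tif"
            )
            state["image"] = image_path
            entry["n_cells"] = len(truth.nuclei_centers)

        elif stage == "filter":
            table_path = params.pop("table", None) or state.get("quant_table")
            if table_path is None:
                raise ValueError("filter stage needs a table (run simulate-quant "
                                 "first or set filter.table)")
            treatment = params.pop("treatment", "")
            column_map = params.pop("column_map", None)
            criteria = silac.FilterCriteria(**params) if params else silac.FilterCriteria()
            read = silac.read_quant_table(table_path, column_map, treatment)
            kept = silac.apply_filters(read.records, criteria)
            calls = silac.call_all(kept, criteria)
            summary = silac.summarize_regulation(calls) if calls else {}
            silac.write_filtered_table(kept, outdir / "filtered.tsv")
            _dump_json(summary, outdir / "regulation_summary.json")
            state.update(records=read.records, kept=kept, calls=calls)
            entry.update(
                n_input=len(read.records), n_dropped=read.n_dropped,
                n_kept=len(kept), summary=summary,
            )
            report["regulation"] = summary

        elif stage == "scan":
            fasta = params.pop("fasta", None) or state.get("fasta")
            if fasta is None:
                raise ValueError("scan stage needs a FASTA (run simulate-seqs "
                                 "first or set scan.fasta)")
            sequences = motifs.read_fasta(fasta)
            hits, profiles = motifs.profile_sequences(sequences, **params)
            motifs.hits_to_table(hits).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
            motifs.profiles_to_table(profiles).to_csv(
                outdir / "motif_profiles.tsv", sep="\t", index=False
            )
            state["profiles"] = profiles
            entry.update(n_sequences=len(sequences), n_hits=len(hits))

        elif stage == "breakdown":
            profiles = state.get("profiles")
            calls = state.get("calls")
            if profiles is None or calls is None:
                raise ValueError("breakdown stage needs prior scan and filter stages")
            breakdown = motifs.motif_breakdown(profiles, calls)
            motifs.write_breakdown(breakdown, outdir / "motif_breakdown.json")
            entry["breakdown"] = breakdown
            report["motif_breakdown"] = breakdown

        elif stage == "puncta":
            image_path = params.pop("image", None) or state.get("image")
            if image_path is None:
                raise ValueError("puncta stage needs an image (run simulate-image "
                                 "first or set puncta.image)")
            import tifffile

            data = tifffile.imread(image_path)
            ph_keys = {k: params.pop(k) for k in ("radius", "k", "r", "p", "q")
                       if k in params}
            ph = puncta.PhansalkarParams(**ph_keys) if ph_keys else None
            result, segmentation = puncta.quantify_image(data, phansalkar=ph, **params)
            counts = pd.DataFrame(
                sorted(result.per_cell_counts.items()),
                columns=["cell_label", "puncta_count"],
            )
            counts.to_csv(outdir / "puncta_counts.tsv", sep="\t", index=False)
            summary = {
                "n_cells": segmentation.n_cells,
                "n_detected": result.n_detected,
                "discarded_background": result.discarded_background,
                "mean_puncta_per_cell": (
                    float(counts["puncta_count"].mean()) if len(counts) else None
                ),
            }
            _dump_json(summary, outdir / "puncta_summary.json")
            entry.update(summary)
            report["puncta"] = summary

        elif stage == "compare":
            counts = params.get("counts")
            if not counts:
                raise ValueError("compare stage needs compare.counts "
                                 "(condition -> per-replicate mean counts)")
            comparison = puncta.compare_conditions(counts)
            _dump_json(asdict(comparison), outdir / "comparison.json")
            entry["comparison"] = asdict(comparison)
            report["comparison"] = asdict(comparison)

        elif stage == "export-string-list":
            kept, calls = state.get("kept"), state.get("calls")
            if kept is None or calls is None:
                raise ValueError("export-string-list needs a prior filter stage")
            for direction in ("up", "down"):
                n = silac.export_string_list(
                    kept, calls, direction, outdir / f"string_{direction}.txt"
                )
                entry[f"n_{direction}"] = n

        log["stages"].append(entry)

    _dump_json(log, outdir / "run_log.json")
    report["outdir"] = str(outdir)
    return report
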