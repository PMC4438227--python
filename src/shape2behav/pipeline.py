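"""End-to-end study orchestration.

``run_study`` executes the full analysis from one configuration document:
render the stimulus set, compute the physical dissimilarity vectors,
generate (or load) the per-area spike tables and behavior logs, decode
every area, and compute the correspondence statistics and transformation
indices.  Every stage writes its outputs (PNGs, TSV/CSV tables, JSON
report) under the output directory, and all randomness flows from the
single configured seed, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import batch_consistency, performance_last_sessions
from .correspondence import MatchInput, permutation_pvalue, transformation_index
from .neural_decoding import (DecodingConfig, net_responses, resampled_decoding,
                              shuffled_label_threshold, write_spike_table)
from .physical_similarity import pixel_dissimilarity, rescale_unit, v1sim_dissimilarity
from .stimuli import bbox_width_deg, build_stimulus_set, default_specs, save_set
from .synthetic_data import AREAS, SyntheticStudyConfig, make_synthetic_study

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stimuli": {"mean_width_deg": 27.3, "luminance_tol": 0.01},
    "physical": {
        "fwhm_px": 20.0,
        "stride": 1,
        "compute_v1sim": True,
        "reference": "average",  # "pix" | "v1sim" | "average"
    },
    "synthetic": {},  # overrides for SyntheticStudyConfig fields
    "decoding": {
        "penalty": 0.5,
        "n_resample": 100,
        "n_cells": 63,
        "n_shuffle_outer": 100,
        "compute_chance": True,
    },
    "behavior": {"last_k": 4},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _deep_merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _dissim_csv(vec, path: Path) -> None:
    pd.DataFrame({
        "pair_n": [p[0] for p in vec.pair_index],
        "pair_m": [p[1] for p in vec.pair_index],
        "value": vec.values,
        "scale": vec.scale,
        "source": vec.source,
    }).to_csv(path, index=False)


def run_study(config: dict | str | Path | None = None,
              out_dir: str | Path = "results/study") -> dict:
    """Run every stage of the study and return the report dictionary."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = _deep_merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    seeds = np.random.SeedSequence(seed).generate_state(8) % (2 ** 31)

    report: dict = {
        "provenance": {
            "config_hash": config_hash(cfg),
            "seed": seed,
            "version": __version__,
        }
    }

    # --- stimuli ------------------------------------------------------------
    stim = build_stimulus_set(default_specs(cfg["stimuli"]["mean_width_deg"]),
                              luminance_tol=cfg["stimuli"]["luminance_tol"])
    save_set(stim, out / "stimuli")
    widths = [bbox_width_deg(s) for s in stim.shapes]
    report["stimuli"] = {
        "glyph_ids": stim.glyph_ids,
        "bbox_widths_deg": widths,
        "mean_bbox_width_deg": float(np.mean(widths)),
        "white_counts": [s.white_count for s in stim.shapes],
    }

    # --- physical dissimilarity --------------------------------------------
    pix = rescale_unit(pixel_dissimilarity(stim))
    _dissim_csv(pix, out / "pix.csv")
    phys = {"pix": pix.values.tolist()}
    reference = pix.values
    if cfg["physical"]["compute_v1sim"]:
        v1sim = v1sim_dissimilarity(stim, fwhm=cfg["physical"]["fwhm_px"],
                                    stride=int(cfg["physical"]["stride"]))
        _dissim_csv(v1sim, out / "v1sim.csv")
        phys["v1sim"] = v1sim.values.tolist()
        phys["pix_v1sim_r"] = float(np.corrcoef(pix.values, v1sim.values)[0, 1])
        if cfg["physical"]["reference"] == "average":
            reference = (pix.values + v1sim.values) / 2.0
        elif cfg["physical"]["reference"] == "v1sim":
            reference = v1sim.values
    phys["reference"] = reference.tolist()
    report["physical"] = phys

    # --- synthetic study ----------------------------------------------------
    synth_cfg = SyntheticStudyConfig(**cfg["synthetic"], seed=int(seeds[0]))
    study = make_synthetic_study(synth_cfg, stimulus_set=stim)
    for area, table in study.spike_tables.items():
        write_spike_table(table, out / f"spikes_{area}.tsv")
    study.behavior_log.to_csv(out / "behavior_log.csv", index=False)
    beh_positions = study.behavioral_pair_positions
    pairs6 = [tuple(p) for p in synth_cfg.behavioral_pairs]

    # --- decoding -----------------------------------------------------------
    dec_cfg_args = {k: cfg["decoding"][k] for k in
                    ("penalty", "n_resample", "n_cells", "n_shuffle_outer")}
    decoding_report: dict = {}
    neural6: dict[str, np.ndarray] = {}
    for i, area in enumerate(AREAS):
        dcfg = DecodingConfig(**dec_cfg_args)
        rng = np.random.default_rng(int(seeds[1]) + i)
        resp = net_responses(study.spike_tables[area])
        res = resampled_decoding(resp, dcfg, pairs=pairs6, rng=rng)
        entry = {
            "pair_labels": ["|".join(p) for p in res.pair_labels],
            "mean_accuracy": res.mean_accuracy.tolist(),
            "sem_accuracy": res.sem_accuracy.tolist(),
            "overall_mean": res.overall_mean,
            "n_cells": res.n_cells,
        }
        if cfg["decoding"]["compute_chance"]:
            entry["chance_threshold"] = shuffled_label_threshold(
                resp, dcfg, pairs=pairs6,
                rng=np.random.default_rng(int(seeds[2]) + i))
        decoding_report[area] = entry
        neural6[area] = res.mean_accuracy
        pd.DataFrame({"pair": entry["pair_labels"],
                      "accuracy": res.mean_accuracy,
                      "sem": res.sem_accuracy}).to_csv(
            out / f"decoding_{area}.csv", index=False)
    report["decoding"] = decoding_report

    # --- behavior -----------------------------------------------------------
    last_k = cfg["behavior"]["last_k"]
    log = study.behavior_log
    per_batch: dict[int, list[float]] = {}
    beh_report: dict = {"per_rat": {}}
    pooled: list[float] = []
    pair_labels6 = sorted(log["pair"].unique(),
                          key=lambda lab: pairs6.index(_label_to_pair(lab)))
    for lab in pair_labels6:
        sub = log[log["pair"] == lab]
        pooled_trials = []
        for batch in sorted(sub["batch"].unique()):
            rat_log = sub[sub["batch"] == batch]
            perf = performance_last_sessions(rat_log, k=last_k)
            beh_report["per_rat"][f"batch{batch}:{lab}"] = asdict(perf)
            per_batch.setdefault(batch, []).append(perf.proportion)
            pooled_trials.append(perf)
        n = sum(p.n_trials for p in pooled_trials)
        k_corr = sum(round(p.proportion * p.n_trials) for p in pooled_trials)
        pooled.append(k_corr / n)
    consistency = batch_consistency(per_batch[1], per_batch[2])
    beh_report["pooled_by_pair"] = dict(zip(pair_labels6, pooled))
    beh_report["batch_consistency"] = {"r": consistency.value,
                                       "p_perm": consistency.p_perm}
    report["behavior"] = beh_report
    beh6 = np.array(pooled)

    # --- correspondence -----------------------------------------------------
    ref6 = reference[beh_positions]
    corr_report: dict = {}
    for area in AREAS:
        o = neural6[area]
        entry = {}
        for name, e in (("phys", ref6), ("beh", beh6)):
            chi = permutation_pvalue(MatchInput(o, e), "chisq")
            pea = permutation_pvalue(MatchInput(o, e), "pearson")
            entry[f"chisq_{name}"] = {"value": chi.value, "p_perm": chi.p_perm}
            entry[f"pearson_{name}"] = {"value": pea.value, "p_perm": pea.p_perm}
        corr_report[area] = entry
    report["correspondence"] = corr_report

    ti_report = {}
    for mode in ("correlation", "chisquare"):
        ti = transformation_index(neural6["TO"], neural6["V1"], beh6, ref6, mode=mode)
        ti_report[mode] = {"H": ti.H, "null_threshold": ti.null_threshold,
                           "significant": ti.significant}
    report["transformation_index"] = ti_report

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _label_to_pair(label: str) -> tuple[int, int]:
    from .stimuli import GLYPH_IDS
    a, b = label.split("|")
    return (GLYPH_IDS.index(a), GLYPH_IDS.index(b))
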