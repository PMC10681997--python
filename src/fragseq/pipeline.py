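"""Configuration-driven orchestration of the analysis stages.

A run starts from a single YAML config (flat keys per stage section) and
executes demux → sorter → zonation/niche → stats → interactions on either
simulated data (the default) or user-supplied inputs, writing every stage
output as CSV plus a manifest with content hashes.  Identical config and
inputs give a byte-identical manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demux, sorter, stats, zonation
from .interactions import compare_groups, score_interactions, scores_to_frame
from .io import (
    FragmentExperiment,
    LRDatabase,
    LRInteraction,
    ValidationError,
    write_cell_annotation,
    write_count_matrix,
    write_fragment_table,
)
from .simulate import (
    LobuleSimConfig,
    simulate_hashing_counts,
    simulate_landmark_panel,
    simulate_lobule_experiment,
)

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "stages",
    "simulate",
    "demux",
    "sorter",
    "zonation",
    "stats",
    "interactions",
}
_STAGES = ("simulate", "demux", "sorter", "zonation", "stats", "interactions")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "fragseq_run"
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    simulate: dict = field(default_factory=dict)
    demux: dict = field(default_factory=dict)
    sorter: dict = field(default_factory=dict)
    zonation: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    interactions: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        unknown_stages = set(cfg.stages) - set(_STAGES)
        if unknown_stages:
            raise ValidationError(f"unknown stages: {sorted(unknown_stages)}")
        stages = {s: True for s in _STAGES}
        stages.update(cfg.stages)
        cfg.stages = stages
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log: dict = {"seed": config.seed, "stages": dict(config.stages)}

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, lineterminator="\n")
        written.append(path)

    sim_cfg = LobuleSimConfig(seed=config.seed, **config.simulate)
    log["simulate"] = {"n_fragments": sim_cfg.n_fragments, "seed": sim_cfg.seed}
    exp, truth = simulate_lobule_experiment(sim_cfg)
    if config.stages.get("simulate", True):
        write_count_matrix(
            exp.counts, out / "counts.mtx", out / "genes.tsv", out / "cells.tsv"
        )
        written += [out / "counts.mtx", out / "genes.tsv", out / "cells.tsv"]
        emit(
            pd.DataFrame({"zc_true": truth.zc, "proximity_true": truth.proximity}),
            "ground_truth.csv",
        )

    if config.stages.get("demux", True):
        hashing, truth = simulate_hashing_counts(truth, sim_cfg)
        result = demux.classify_cells(hashing)
        exp = demux.attach_fragments(result, exp)
        result.write_csv(out / "classification.csv")
        written.append(out / "classification.csv")
        write_cell_annotation(exp.cells, out / "cell_annotation.csv")
        written.append(out / "cell_annotation.csv")

    if config.stages.get("sorter", True):
        scfg = dict(config.sorter)
        bead_sizes = scfg.get("bead_sizes", [60.0, 125.0, 175.0])
        rng = np.random.default_rng(config.seed + 7)
        reps = scfg.get("readings_per_bead", 5)
        sizes = np.repeat(bead_sizes, reps)
        tof = sim_cfg.tof_slope * sizes + sim_cfg.tof_intercept + rng.normal(
            0, sim_cfg.tof_noise_sd, sizes.size
        )
        cal = sorter.fit_calibration(sizes, tof)
        cal.to_json(out / "calibration.json")
        written.append(out / "calibration.json")
        exp.fragments = sorter.size_from_tof(cal, exp.fragments)
        write_fragment_table(exp.fragments, out / "fragment_table.csv")
        written.append(out / "fragment_table.csv")

    zres = None
    if config.stages.get("zonation", True):
        zcfg = dict(config.zonation)
        panel = simulate_landmark_panel(sim_cfg)
        panel = zonation.filter_landmarks(panel)
        pb = zonation.fragment_pseudobulk(
            exp, zcfg.get("cell_type", "LEC"), min_cells=zcfg.get("min_cells", 5)
        )
        zres = zonation.compute_zc(pb, panel)
        zres = zonation.group_zone(zonation.bin_layers(zres))
        emit(zres, "zonation.csv")
        prox = zonation.assign_proximity(
            exp,
            min_cells_per_fragment=zcfg.get("min_cells", 5),
            min_landmark_cells_per_sample=zcfg.get("min_landmark_cells_per_sample", 20),
        )
        emit(prox, "proximity.csv")
        log["zonation"] = {"n_fragments_placed": int(len(zres))}

    if config.stages.get("stats", True) and zres is not None:
        pb_sum = zonation.fragment_pseudobulk(
            exp, config.stats.get("cell_type", "LEC"), min_cells=5, mode="sum"
        )
        shared = pb_sum.index.intersection(zres.index)
        pb_sum = stats.filter_low_expression(pb_sum.loc[shared])
        de = stats.zonated_de(
            pb_sum,
            layers=zres.loc[shared, "layer_merged"].astype(str),
            sample_ids=exp.fragments.loc[shared, "sample"],
        )
        emit(de, "zonated_de.csv")
        prox = zonation.assign_proximity(exp, min_landmark_cells_per_sample=0)
        ab = stats.abundance_test(exp.cells, prox["proximity"])
        emit(ab, "abundance.csv")

    if config.stages.get("interactions", True) and zres is not None:
        icfg = dict(config.interactions)
        db = _default_database(exp, icfg)
        sender = icfg.get("sender", "KC")
        receiver = icfg.get("receiver", "T")
        per_group = {}
        zone_of = zres["zone"]
        for group in ("central", "portal"):
            frags = zone_of.index[zone_of == group]
            cells = exp.cells[exp.cells["fragment"].isin(frags)]
            sub = FragmentExperiment(
                exp.counts.subset_cells(list(cells.index)),
                cells.copy(),
                exp.fragments.loc[exp.fragments.index.isin(frags)].copy(),
            ).recount_fragments()
            per_group[group] = score_interactions(
                sub,
                db,
                sender=sender,
                receiver=receiver,
                group=group,
                n_perm=icfg.get("n_perm", 200),
                seed=config.seed + 11,
            )
            emit(scores_to_frame(per_group[group]), f"lr_{group}.csv")
        emit(compare_groups(per_group["central"], per_group["portal"]), "lr_comparison.csv")

    manifest = {
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
        "log": log,
    }
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _default_database(exp: FragmentExperiment, icfg: dict) -> LRDatabase:
    if "database" in icfg:
        from .io import read_lr_database

        return read_lr_database(icfg["database"])
    genes = [g for g in exp.counts.genes if g.startswith("BG")]
    pairs = [
        LRInteraction(f"{genes[i]}_{genes[i + 1]}", [genes[i]], [genes[i + 1]])
        for i in range(0, min(len(genes) - 1, 6), 2)
    ]
    return LRDatabase(pairs)
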