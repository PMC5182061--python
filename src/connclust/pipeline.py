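"""End-to-end analysis pipeline.

``run`` executes, in order: input (load or simulate) -> adjacency ->
connectivity-similarity clustering of the neurosecretory-like target
neurons -> synapse-similarity clustering of the sensory afferents ->
circuit statistics -> JSON run report. All artifacts are plain text, all
outputs are deterministic given the configuration, and no stage mutates
its inputs, so running twice with the same configuration produces
byte-identical artifacts.

Defaults are the reference analysis parameters: C1 = 0.5, C2 = 1 for the
connectivity score; sigma = omega = 2000 nm for the synapse score;
dendrogram cuts at similarity 0.4 (connectivity) and 0.2 (synapse);
partner-inclusion threshold of 3 synapses (not applied to sensory
neurons); a separate display threshold of 2 synapses for the
sensory->focal matrix; DCV proximity radius 450 nm.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import stats as st
from .cluster import ClusterResult, adjusted_rand, average_linkage, cut_at_score
from .io import load_connectome_dir, save_connectome
from .model import Connectome
from .similarity import (
    ConnSimParams,
    SimilarityMatrix,
    SynSimParams,
    conn_sim_matrix,
    syn_sim_matrix,
)
from .synthetic import SynthConfig, generate, save_synthetic

__all__ = ["RunConfig", "run", "validate_report", "REPORT_SCHEMA"]

log = logging.getLogger("connclust")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    input_dir: Optional[str] = None  # load this export; else simulate
    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: Optional[int] = None  # overrides synth.seed when simulating
    conn_params: ConnSimParams = field(default_factory=ConnSimParams)
    syn_params: SynSimParams = field(default_factory=SynSimParams)
    cut_connectivity: float = 0.4
    cut_synapse: float = 0.2
    min_syn: int = 3
    sensory_display_min: int = 2
    dcv_radius: float = 450.0
    focal_classes: tuple[str, ...] = ("hugin",)
    sensory_classes: tuple[str, ...] = ("sensory",)
    target_classes: tuple[str, ...] = ("DH44", "DMS", "IPC")
    conn_direction: str = "incoming"

    def validate(self) -> None:
        for name in ("cut_connectivity", "cut_synapse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_syn < 0 or self.sensory_display_min < 0:
            raise ValueError("thresholds must be nonnegative")
        if self.dcv_radius <= 0:
            raise ValueError("dcv_radius must be positive")
        if self.conn_direction not in ("incoming", "outgoing", "combined"):
            raise ValueError(f"unknown direction {self.conn_direction!r}")


#: Minimal shape contract of the run report (key -> required type).
REPORT_SCHEMA: dict[str, type] = {
    "config": dict,
    "counts": dict,
    "connectivity_clustering": dict,
    "synapse_clustering": dict,
    "partner_filter": dict,
    "dcv_proximity_percent": dict,
}


def validate_report(report: dict) -> None:
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"run report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"run report key {key!r} must be {typ.__name__}")


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    return json.loads(json.dumps(echo))  # plain JSON types only


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-12s %.2fs", name, t1 - t0)
    return t1


def run(
    config: RunConfig,
    out_dir: Union[str, Path],
    connectome: Optional[Connectome] = None,
) -> dict:
    """Execute the full pipeline; write artifacts under ``out_dir``.

    A pre-built ``connectome`` bypasses the input stage. Returns the run
    report (also written to ``report.json``).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = time.perf_counter()

    gt = None
    if connectome is not None:
        c = connectome
    elif config.input_dir is not None:
        c = load_connectome_dir(config.input_dir)
    else:
        synth = config.synth
        if config.seed is not None:
            synth = dataclasses.replace(synth, seed=config.seed)
        c, gt = generate(synth)
        save_synthetic(c, gt, out / "input")
    t = _stage("input", t)

    all_ids = sorted(c.skeletons)
    focal = c.ids_by_class(config.focal_classes)
    sensory = c.ids_by_class(config.sensory_classes)
    targets = c.ids_by_class(config.target_classes)

    adj = st.build_adjacency(c, all_ids, all_ids)
    adj.to_csv(out / "adjacency.csv")
    t = _stage("adjacency", t)

    report: dict = {
        "config": _config_echo(config),
        "counts": {
            "n_skeletons": len(c.skeletons),
            "n_connectors": len(c.connectors),
            "n_post_links": int(sum(len(x.post_links) for x in c.connectors)),
            "n_dcvs": len(c.dcvs),
            "n_focal": len(focal),
            "n_sensory": len(sensory),
            "n_targets": len(targets),
        },
    }

    # --- connectivity-similarity clustering of target neurons -------------
    conn_block: dict = {"n_clusters": None, "sizes": [], "identities": None}
    if len(targets) >= 2:
        sim = conn_sim_matrix(adj, targets, config.conn_direction, config.conn_params)
        sim.to_csv(out / "conn_sim")
        sim.write_params_sidecar(
            out / "conn_sim", dataclasses.asdict(config.conn_params)
        )
        tree = average_linkage(sim)
        tree.save(out / "conn_tree")
        cut = cut_at_score(tree, config.cut_connectivity)
        cut.save(out / "conn_clusters.csv")
        conn_block["n_clusters"] = cut.n_clusters
        conn_block["sizes"] = cut.sizes()
        expected = {
            label: sum(1 for i in targets if c.skeletons[i].class_label == label)
            for label in config.target_classes
        }
        expected = {k: v for k, v in expected.items() if v > 0}
        try:
            identities = st.assign_identities(cut, expected)
            conn_block["identities"] = {str(k): v for k, v in sorted(identities.items())}
            labels = {lbl: n for n, lbl in enumerate(sorted(expected))}
            truth = {i: labels[c.skeletons[i].class_label] for i in targets}
            conn_block["ari_vs_annotation"] = adjusted_rand(cut.assignment, truth)
        except ValueError as exc:
            conn_block["identities"] = None
            conn_block["identity_error"] = str(exc)
    report["connectivity_clustering"] = conn_block
    t = _stage("connsim", t)

    # --- synapse-similarity clustering of sensory afferents ---------------
    syn_block: dict = {"n_clusters": None, "sizes": []}
    if len(sensory) >= 2:
        sim = syn_sim_matrix(sensory, c, config.syn_params)
        sim.to_csv(out / "syn_sim")
        sim.write_params_sidecar(out / "syn_sim", dataclasses.asdict(config.syn_params))
        tree = average_linkage(sim)
        tree.save(out / "syn_tree")
        cut = cut_at_score(tree, config.cut_synapse)
        cut.save(out / "syn_clusters.csv")
        syn_block["n_clusters"] = cut.n_clusters
        syn_block["sizes"] = cut.sizes()
    report["synapse_clustering"] = syn_block
    t = _stage("synsim", t)

    # --- circuit statistics -------------------------------------------------
    filt_block: dict = {}
    if focal:
        filt = st.filter_partners(c, focal, min_syn=config.min_syn)
        filt_block = {
            "n_included": len(filt.included),
            "n_excluded": len(filt.excluded),
            "coverage_pre_percent": filt.coverage_pre,
            "coverage_post_percent": filt.coverage_post,
        }
        if sensory and config.sensory_display_min >= 0:
            sens_adj = st.build_adjacency(c, sensory, focal)
            df = sens_adj.to_dataframe()
            df[df < config.sensory_display_min] = 0
            df.to_csv(out / "sensory_to_focal.csv")
        summary = st.class_connectivity(c, focal)
        summary.same_class_percent.to_csv(out / "same_class_percent.csv")
        filt_block["bilateral_ok_fraction"] = (
            float(np.mean(list(summary.bilateral_ok.values())))
            if summary.bilateral_ok
            else None
        )
    report["partner_filter"] = filt_block

    dcv_block: dict = {}
    for skid in focal:
        v = st.dcv_proximity(c, skid, radius=config.dcv_radius)
        dcv_block[str(skid)] = None if v != v else v
    report["dcv_proximity_percent"] = dcv_block
    t = _stage("stats", t)

    validate_report(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
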