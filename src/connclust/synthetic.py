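"""Synthetic connectome generator with known ground truth.

The generator emulates the structure of a bilaterally symmetric feeding
microcircuit so that every analysis stage has a recoverable answer:

* four (configurable) interneuron classes of bilaterally mirrored neuron
  pairs, each class wired onto a class-private pool of partner neurons —
  neurons of a class share partners with probability
  ``shared_partner_prob_within``, across classes ``..._across``;
* a set of medially unpaired neurosecretory-like target neurons organised
  in blocks (default sizes 3/2/7, labelled DH44/DMS/IPC), each block fed by
  its private pool of upstream partner pairs with the same within/across
  sharing probabilities;
* sensory-like afferents in spatial groups: each neuron places an isotropic
  Gaussian cloud of presynaptic sites around its group's centre and
  contacts the class neurons;
* polyadic connectors (1..``polyadic_max`` postsynaptic links each), link
  counts per planted edge drawn from a zero-truncated Poisson law whose
  *mean* is ``mean_links_per_edge``;
* dense-core vesicles placed within ``dcv_radius`` of each presynaptic site
  with probability ``dcv_prob``.

Wiring is generated for left-side (and medial) presynaptic neurons and then
mirrored across the sagittal plane ``x = midline_x``: every connector whose
presynaptic neuron is sided has an exact mirror image with homologous
participants. Sensory afferents are medially annotated so their spatial
groups are not smeared by reflection.

Everything is driven by one seeded generator, so equal configs produce
byte-identical saved output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.optimize import brentq

from .io import save_connectome
from .model import (
    Connectome,
    Connector,
    DcvRecord,
    NeuronSkeleton,
    RegionMask,
    SkeletonNode,
    mirror_position,
)

__all__ = [
    "SynthConfig",
    "SyntheticGroundTruth",
    "generate",
    "default_fixture",
    "DEFAULT_FIXTURE_SEED",
    "save_synthetic",
    "load_ground_truth",
]

HUGIN_CLASS_NAMES = ("hugin-PC", "hugin-VNC", "hugin-RG", "hugin-PH")

#: Documented seed of the shipped acceptance fixture.
DEFAULT_FIXTURE_SEED = 1799


class ConfigError(ValueError):
    """The generator configuration is internally impossible."""


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic connectome; lengths in nm, counts per side."""

    seed: int = DEFAULT_FIXTURE_SEED
    n_classes: int = 4
    neurons_per_class_per_side: int = 2
    partner_pool_per_class: int = 8
    shared_partner_prob_within: float = 0.9
    shared_partner_prob_across: float = 0.05
    mean_links_per_edge: float = 5.0
    n_sensory_groups: int = 7
    sensory_neurons_per_group: int = 10
    cloud_centers: Optional[tuple[tuple[float, float, float], ...]] = None
    cloud_sd: float = 2000.0
    synapses_per_sensory_neuron: int = 30
    polyadic_max: int = 3
    dcv_prob: float = 0.9
    dcv_radius: float = 450.0
    midline_x: float = 0.0
    target_block_sizes: tuple[int, ...] = (3, 2, 7)
    target_block_labels: tuple[str, ...] = ("DH44", "DMS", "IPC")
    partners_per_block: int = 30
    shared_input_prob: float = 0.3
    min_center_separation: float = 12000.0
    emit_regions: bool = True

    def validate(self) -> None:
        for name in (
            "shared_partner_prob_within",
            "shared_partner_prob_across",
            "dcv_prob",
            "shared_input_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {v}")
        if self.mean_links_per_edge <= 0:
            raise ConfigError("mean_links_per_edge must be positive")
        if self.polyadic_max < 1:
            raise ConfigError("polyadic_max must be at least 1")
        if self.cloud_sd <= 0 or self.dcv_radius <= 0:
            raise ConfigError("cloud_sd and dcv_radius must be positive")
        if len(self.target_block_sizes) != len(self.target_block_labels):
            raise ConfigError("one label per target block is required")
        if self.n_sensory_groups > 0 and (
            self.n_classes == 0 or self.neurons_per_class_per_side == 0
        ):
            raise ConfigError("sensory afferents need class neurons to contact")
        if self.cloud_centers is not None:
            centers = [tuple(map(float, c)) for c in self.cloud_centers]
            if len(set(centers)) != len(centers):
                raise ConfigError("cloud centers must be pairwise distinct")
            if len(centers) != self.n_sensory_groups:
                raise ConfigError("need one cloud center per sensory group")


@dataclass
class SyntheticGroundTruth:
    """Hidden labels and parameters of a generated connectome."""

    class_of: dict[int, str]
    group_of: dict[int, int]  # sensory id -> spatial group index
    block_of: dict[int, str]  # target id -> block label
    homolog_of: dict[int, Optional[int]]
    planted_edges: list[tuple[int, int, int]]  # independent draws, pre-mirror
    shared_input_partners: dict[str, list[int]]  # block label -> partner ids
    cloud_centers: list[tuple[float, float, float]]  # resolved group centres
    config: SynthConfig


def _zt_poisson_rate(mean: float) -> float:
    """Rate lambda such that the zero-truncated Poisson has the given mean."""
    if mean <= 1.0:
        raise ConfigError("zero-truncated Poisson mean must exceed 1")
    f = lambda lam: lam / (1.0 - np.exp(-lam)) - mean
    return brentq(f, 1e-9, mean)


def _zt_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    out = rng.poisson(lam, size)
    while np.any(out == 0):
        zeros = out == 0
        out[zeros] = rng.poisson(lam, int(zeros.sum()))
    return out


class _Builder:
    """Accumulates neurons/connectors and materializes skeleton nodes."""

    def __init__(self, midline_x: float):
        self.midline_x = midline_x
        self.skeletons: dict[int, NeuronSkeleton] = {}
        self.soma: dict[int, tuple[float, float, float]] = {}
        self.conn_specs: list[tuple[tuple[float, float, float], int, list[int]]] = []
        self._next_id = 1

    def add_neuron(
        self, name: str, class_label: str, side: str, soma, homolog_id=None
    ) -> int:
        skid = self._next_id
        self._next_id += 1
        soma = tuple(float(v) for v in soma)
        self.skeletons[skid] = NeuronSkeleton(
            skeleton_id=skid,
            name=name,
            class_label=class_label,
            side=side,
            homolog_id=homolog_id,
            nodes={1: SkeletonNode(1, None, soma)},
        )
        self.soma[skid] = soma
        return skid

    def pair(self, left_id: int, right_id: int) -> None:
        self.skeletons[left_id].homolog_id = right_id
        self.skeletons[right_id].homolog_id = left_id

    def homolog(self, skid: int) -> int:
        h = self.skeletons[skid].homolog_id
        return skid if h is None else h

    def add_connector(self, position, pre: int, posts: list[int]) -> None:
        self.conn_specs.append((tuple(float(v) for v in position), pre, list(posts)))

    def mirror_sided_connectors(self) -> None:
        """Append the mirror image of every connector with a sided pre."""
        mirrored = []
        for pos, pre, posts in self.conn_specs:
            if self.skeletons[pre].side == "medial":
                continue
            mirrored.append(
                (
                    mirror_position(pos, self.midline_x),
                    self.homolog(pre),
                    [self.homolog(t) for t in posts],
                )
            )
        self.conn_specs.extend(mirrored)

    def build_connectors(self) -> list[Connector]:
        next_node = {skid: 2 for skid in self.skeletons}

        def new_node(skid: int, pos) -> int:
            nid = next_node[skid]
            next_node[skid] += 1
            self.skeletons[skid].nodes[nid] = SkeletonNode(
                nid, 1, tuple(float(v) for v in pos)
            )
            return nid

        connectors = []
        for cid, (pos, pre, posts) in enumerate(self.conn_specs, start=1):
            pre_link = (pre, new_node(pre, pos))
            post_links = tuple((t, new_node(t, pos)) for t in posts)
            connectors.append(Connector(cid, pos, pre_link, post_links))
        return connectors


def _auto_centers(rng: np.random.Generator, cfg: SynthConfig) -> list[tuple]:
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < cfg.n_sensory_groups:
        cand = rng.uniform([-30000.0, 15000.0, 15000.0], [30000.0, 85000.0, 85000.0])
        if all(
            np.linalg.norm(cand - c) >= cfg.min_center_separation for c in centers
        ):
            centers.append(cand)
        attempts += 1
        if attempts > 100000:
            raise ConfigError(
                "cannot place sensory group centers at the requested separation"
            )
    return [tuple(float(v) for v in c) for c in centers]


def generate(config: SynthConfig) -> tuple[Connectome, SyntheticGroundTruth]:
    """Generate a connectome and its ground truth; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lam = (
        _zt_poisson_rate(config.mean_links_per_edge)
        if config.mean_links_per_edge > 1
        else None
    )
    b = _Builder(config.midline_x)

    def left_soma() -> np.ndarray:
        return rng.uniform([-40000.0, 10000.0, 10000.0], [-5000.0, 90000.0, 90000.0])

    def medial_soma() -> np.ndarray:
        jitter = rng.uniform([-2000.0, 10000.0, 10000.0], [2000.0, 90000.0, 90000.0])
        return jitter + np.array([config.midline_x, 0.0, 0.0])

    def add_pair(name: str, label: str) -> tuple[int, int]:
        soma = left_soma()
        lid = b.add_neuron(f"{name} left", label, "left", soma)
        rid = b.add_neuron(
            f"{name} right", label, "right", mirror_position(soma, config.midline_x)
        )
        b.pair(lid, rid)
        return lid, rid

    class_left: list[list[int]] = []
    pool_left: list[list[int]] = []
    for ci in range(config.n_classes):
        label = (
            HUGIN_CLASS_NAMES[ci]
            if ci < len(HUGIN_CLASS_NAMES)
            else f"hugin-{ci}"
        )
        class_left.append(
            [
                add_pair(f"{label} {k}", label)[0]
                for k in range(config.neurons_per_class_per_side)
            ]
        )
    for ci in range(config.n_classes):
        pool_left.append(
            [
                add_pair(f"partner c{ci}.{k}", "interneuron")[0]
                for k in range(config.partner_pool_per_class)
            ]
        )

    targets_by_block: dict[str, list[int]] = {}
    for label, size in zip(config.target_block_labels, config.target_block_sizes):
        targets_by_block[label] = [
            b.add_neuron(f"{label} {k}", label, "medial", medial_soma(), None)
            for k in range(size)
        ]
    block_pool_left: dict[str, list[int]] = {
        label: [
            add_pair(f"upstream {label}.{k}", "interneuron")[0]
            for k in range(config.partners_per_block)
        ]
        for label in config.target_block_labels
    }

    centers = (
        [tuple(map(float, c)) for c in config.cloud_centers]
        if config.cloud_centers is not None
        else _auto_centers(rng, config)
    )
    sensory_ids: list[int] = []
    group_of: dict[int, int] = {}
    for g in range(config.n_sensory_groups):
        for k in range(config.sensory_neurons_per_group):
            skid = b.add_neuron(
                f"sensory g{g}.{k}", f"sensory-{g}", "medial", medial_soma(), None
            )
            sensory_ids.append(skid)
            group_of[skid] = g

    # ---- planted edges (left/medial sources only) -------------------------
    planted: list[tuple[int, int, int]] = []

    def plant(source: int, target: int) -> None:
        count = (
            int(_zt_poisson(rng, lam, 1)[0])
            if lam is not None
            else max(1, int(rng.poisson(config.mean_links_per_edge)))
        )
        planted.append((source, target, count))

    for ci, members in enumerate(class_left):
        for h in members:
            for cj, pool in enumerate(pool_left):
                p_edge = (
                    config.shared_partner_prob_within
                    if ci == cj
                    else config.shared_partner_prob_across
                )
                for p in pool:
                    if rng.random() < p_edge:
                        plant(h, p)

    shared_input_partners: dict[str, list[int]] = {
        label: [] for label in config.target_block_labels
    }
    hugin_class0_left = class_left[0] if class_left else []
    for bi, label_i in enumerate(config.target_block_labels):
        for q in block_pool_left[label_i]:
            for bj, label_j in enumerate(config.target_block_labels):
                p_edge = (
                    config.shared_partner_prob_within
                    if bi == bj
                    else config.shared_partner_prob_across
                )
                for t in targets_by_block[label_j]:
                    if rng.random() < p_edge:
                        plant(q, t)
            # some upstream partners also feed the first class -> shared inputs
            if hugin_class0_left and rng.random() < config.shared_input_prob:
                shared_input_partners[label_i].append(q)
                for h in hugin_class0_left:
                    plant(q, h)

    # ---- realize planted edges as polyadic connectors ---------------------
    by_source: dict[int, list[int]] = {}
    for s, t, n in planted:
        by_source.setdefault(s, []).extend([t] * n)
    for s in sorted(by_source):
        posts = np.array(by_source[s])
        rng.shuffle(posts)
        i = 0
        while i < len(posts):
            k = int(rng.integers(1, config.polyadic_max + 1))
            chunk = posts[i : i + k].tolist()
            i += k
            pos = np.asarray(b.soma[s]) + rng.normal(0.0, 1500.0, 3)
            b.add_connector(pos, s, [int(t) for t in chunk])

    # ---- sensory afferent clouds ------------------------------------------
    all_class_ids = sorted(
        skid
        for skid, sk in b.skeletons.items()
        if sk.class_label.startswith("hugin")
    )
    for skid in sensory_ids:
        center = np.asarray(centers[group_of[skid]])
        for _ in range(config.synapses_per_sensory_neuron):
            pos = center + rng.normal(0.0, config.cloud_sd, 3)
            k = int(rng.integers(1, config.polyadic_max + 1))
            posts = [int(t) for t in rng.choice(all_class_ids, size=k)]
            b.add_connector(pos, skid, posts)

    b.mirror_sided_connectors()
    connectors = b.build_connectors()

    # ---- DCVs --------------------------------------------------------------
    dcvs: list[DcvRecord] = []
    for conn in connectors:
        if rng.random() < config.dcv_prob:
            direction = rng.normal(0.0, 1.0, 3)
            direction /= np.linalg.norm(direction)
            r = config.dcv_radius * rng.random() ** (1.0 / 3.0)
            pos = np.asarray(conn.position) + direction * r
            dcvs.append(DcvRecord(conn.pre_link[0], tuple(float(v) for v in pos)))

    regions: dict[str, RegionMask] = {}
    if config.emit_regions:
        regions = {
            "SEZ": RegionMask(
                "SEZ", (((-60000.0, 0.0, 0.0), (60000.0, 100000.0, 50000.0)),)
            ),
            "protocerebrum": RegionMask(
                "protocerebrum",
                (((-60000.0, 0.0, 50000.0), (60000.0, 100000.0, 100000.0)),),
            ),
        }

    c = Connectome(
        skeletons=b.skeletons, connectors=connectors, dcvs=dcvs, regions=regions
    )
    c.validate()
    gt = SyntheticGroundTruth(
        class_of={skid: sk.class_label for skid, sk in b.skeletons.items()},
        group_of=group_of,
        block_of={
            t: label for label, ts in targets_by_block.items() for t in ts
        },
        homolog_of={skid: sk.homolog_id for skid, sk in b.skeletons.items()},
        planted_edges=planted,
        shared_input_partners=shared_input_partners,
        cloud_centers=centers,
        config=config,
    )
    return c, gt


def default_fixture() -> tuple[Connectome, SyntheticGroundTruth]:
    """The shipped reference configuration at the documented seed.

    Seven sensory groups of 10 neurons with 30 presynaptic sites each,
    group centres pairwise >= 12000 nm apart (6 cloud standard deviations),
    and neurosecretory-like target blocks of sizes 3/2/7.
    """
    return generate(SynthConfig(seed=DEFAULT_FIXTURE_SEED))


def save_synthetic(
    c: Connectome, gt: SyntheticGroundTruth, out_dir: Union[str, Path]
) -> None:
    """Save the connectome in the standard flat-file layout plus a
    ``manifest.json`` (config, seed, summary counts) and
    ``ground_truth.json`` so labels round-trip."""
    out = Path(out_dir)
    save_connectome(c, out)
    manifest = {
        "config": asdict(gt.config),
        "seed": gt.config.seed,
        "counts": {
            "n_skeletons": len(c.skeletons),
            "n_connectors": len(c.connectors),
            "n_post_links": int(sum(len(x.post_links) for x in c.connectors)),
            "n_dcvs": len(c.dcvs),
            "n_planted_edges": len(gt.planted_edges),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    truth = {
        "class_of": {str(k): v for k, v in sorted(gt.class_of.items())},
        "group_of": {str(k): v for k, v in sorted(gt.group_of.items())},
        "block_of": {str(k): v for k, v in sorted(gt.block_of.items())},
        "homolog_of": {str(k): v for k, v in sorted(gt.homolog_of.items())},
        "planted_edges": [list(e) for e in gt.planted_edges],
        "shared_input_partners": {
            k: list(v) for k, v in sorted(gt.shared_input_partners.items())
        },
        "cloud_centers": [list(c) for c in gt.cloud_centers],
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_ground_truth(out_dir: Union[str, Path]) -> SyntheticGroundTruth:
    out = Path(out_dir)
    with open(out / "ground_truth.json") as fh:
        truth = json.load(fh)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg_dict = dict(manifest["config"])
    for key in ("cloud_centers",):
        if cfg_dict.get(key) is not None:
            cfg_dict[key] = tuple(tuple(x) for x in cfg_dict[key])
    for key in ("target_block_sizes", "target_block_labels"):
        cfg_dict[key] = tuple(cfg_dict[key])
    return SyntheticGroundTruth(
        class_of={int(k): v for k, v in truth["class_of"].items()},
        group_of={int(k): v for k, v in truth["group_of"].items()},
        block_of={int(k): v for k, v in truth["block_of"].items()},
        homolog_of={int(k): v for k, v in truth["homolog_of"].items()},
        planted_edges=[tuple(e) for e in truth["planted_edges"]],
        shared_input_partners={
            k: list(v) for k, v in truth["shared_input_partners"].items()
        },
        cloud_centers=[tuple(x) for x in truth["cloud_centers"]],
        config=SynthConfig(**cfg_dict),
    )
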