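"""Core connectome data model.

The unit of analysis is a :class:`Connectome`: neuron skeletons (SWC-style
node trees annotated with class, hemisphere side and bilateral homology),
polyadic connectors (one presynaptic link, one or more postsynaptic links,
a single 3-D position in nm), optional dense-core-vesicle (DCV) records and
named axis-aligned spatial regions.

Conventions
-----------
* Coordinates are right-handed, in nanometres; x is medial--lateral,
  y dorsal--ventral, z anterior--posterior.
* The connector position is the canonical coordinate of a synapse: one
  release site contacts many postsynaptic neurites, so every synapse record
  derived from a connector carries the connector's position.
* Each postsynaptic link counts as one synaptic connection; a connector with
  k postsynaptic links therefore yields k "post" records and at most one
  "pre" record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "ValidationError",
    "SkeletonNode",
    "NeuronSkeleton",
    "Connector",
    "SynapseRecord",
    "DcvRecord",
    "RegionMask",
    "Connectome",
    "mirror_position",
]

Vec3 = tuple[float, float, float]

SIDES = ("left", "right", "medial")
SIGNS = ("pre", "post")


class ValidationError(ValueError):
    """A structural invariant of the connectome model is violated."""


def _as_vec3(position: Sequence[float]) -> Vec3:
    x, y, z = (float(v) for v in position)
    for v in (x, y, z):
        if v != v or v in (float("inf"), float("-inf")):
            raise ValidationError(f"non-finite coordinate in position {position!r}")
    return (x, y, z)


@dataclass(frozen=True)
class SkeletonNode:
    """One treenode of a neuron skeleton; ``parent_id`` is None at the root."""

    node_id: int
    parent_id: Optional[int]
    position: Vec3
    radius: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", _as_vec3(self.position))


@dataclass
class NeuronSkeleton:
    """A reconstructed neuron: its node tree plus circuit annotations.

    ``homolog_id`` names the bilaterally mirrored partner neuron, or is None
    for medially unpaired neurons. The homolog relation is symmetric and
    class-preserving; both are enforced at the connectome level.
    """

    skeleton_id: int
    name: str
    class_label: str
    side: str
    homolog_id: Optional[int]
    nodes: dict[int, SkeletonNode] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValidationError(
                f"skeleton {self.skeleton_id}: side {self.side!r} not in {SIDES}"
            )

    @property
    def root_id(self) -> int:
        roots = [n.node_id for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise ValidationError(
                f"skeleton {self.skeleton_id}: expected exactly one root, found {len(roots)}"
            )
        return roots[0]

    def validate_tree(self) -> None:
        """Check single root, resolvable parents and acyclicity."""
        root = self.root_id  # raises unless exactly one
        for node in self.nodes.values():
            if node.parent_id is None:
                continue
            if node.parent_id not in self.nodes:
                raise ValidationError(
                    f"skeleton {self.skeleton_id}: node {node.node_id} references "
                    f"missing parent {node.parent_id}"
                )
        # Walk each node towards the root; revisiting a node on the current
        # path means a cycle, and every node must reach the root (connected).
        state: dict[int, int] = {}  # 0 = on current path, 1 = done
        for start in self.nodes:
            path = []
            cur: Optional[int] = start
            while cur is not None and state.get(cur) != 1:
                if state.get(cur) == 0:
                    raise ValidationError(
                        f"skeleton {self.skeleton_id}: cycle through node {cur}"
                    )
                state[cur] = 0
                path.append(cur)
                cur = self.nodes[cur].parent_id
            for n in path:
                state[n] = 1
        if state.get(root) != 1:  # pragma: no cover - root always walked
            raise ValidationError(f"skeleton {self.skeleton_id}: root unreachable")


@dataclass(frozen=True)
class Connector:
    """A polyadic synapse: one release site, ``post_links`` target neurites.

    Links are ``(skeleton_id, node_id)`` pairs; a skeleton_id may repeat in
    ``post_links`` when several postsynaptic neurites of the same neuron
    contact the site (each still counts as one connection).
    """

    connector_id: int
    position: Vec3
    pre_link: Optional[tuple[int, int]]
    post_links: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", _as_vec3(self.position))
        object.__setattr__(
            self, "post_links", tuple((int(s), int(n)) for s, n in self.post_links)
        )
        if self.pre_link is not None:
            object.__setattr__(
                self, "pre_link", (int(self.pre_link[0]), int(self.pre_link[1]))
            )


@dataclass(frozen=True)
class SynapseRecord:
    """One directed synaptic involvement of one neuron at one connector."""

    skeleton_id: int
    connector_id: int
    sign: str  # "pre" or "post"
    position: Vec3


@dataclass(frozen=True)
class DcvRecord:
    """A dense-core vesicle observed in a given neuron, position in nm."""

    skeleton_id: int
    position: Vec3

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", _as_vec3(self.position))


@dataclass(frozen=True)
class RegionMask:
    """A named region as a union of axis-aligned boxes ((min, max) in nm)."""

    region_name: str
    boxes: tuple[tuple[Vec3, Vec3], ...]

    def __post_init__(self) -> None:
        boxes = tuple((_as_vec3(lo), _as_vec3(hi)) for lo, hi in self.boxes)
        for lo, hi in boxes:
            if any(l > h for l, h in zip(lo, hi)):
                raise ValidationError(
                    f"region {self.region_name!r}: box min {lo} exceeds max {hi}"
                )
        object.__setattr__(self, "boxes", boxes)

    def contains(self, position: Sequence[float]) -> bool:
        x, y, z = position
        return any(
            lo[0] <= x <= hi[0] and lo[1] <= y <= hi[1] and lo[2] <= z <= hi[2]
            for lo, hi in self.boxes
        )


def mirror_position(position: Sequence[float], midline_x: float) -> Vec3:
    """Reflect a point across the sagittal plane x = midline_x."""
    x, y, z = position
    return (2.0 * midline_x - float(x), float(y), float(z))


@dataclass
class Connectome:
    """Skeletons, connectors, DCVs and regions of one reconstruction."""

    skeletons: dict[int, NeuronSkeleton] = field(default_factory=dict)
    connectors: list[Connector] = field(default_factory=list)
    dcvs: list[DcvRecord] = field(default_factory=list)
    regions: dict[str, RegionMask] = field(default_factory=dict)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Enforce every structural invariant; raise ValidationError if not.

        Violations are reported, never silently repaired.
        """
        for skel in self.skeletons.values():
            skel.validate_tree()
            if skel.homolog_id is not None:
                other = self.skeletons.get(skel.homolog_id)
                if other is None:
                    raise ValidationError(
                        f"skeleton {skel.skeleton_id}: homolog "
                        f"{skel.homolog_id} does not exist"
                    )
                if other.homolog_id != skel.skeleton_id:
                    raise ValidationError(
                        f"homolog relation not symmetric between "
                        f"{skel.skeleton_id} and {skel.homolog_id}"
                    )
                if other.class_label != skel.class_label:
                    raise ValidationError(
                        f"homologs {skel.skeleton_id}/{other.skeleton_id} have "
                        f"different classes {skel.class_label!r}/{other.class_label!r}"
                    )
        for conn in self.connectors:
            links = list(conn.post_links)
            if conn.pre_link is not None:
                links.append(conn.pre_link)
            for skid, node_id in links:
                skel = self.skeletons.get(skid)
                if skel is None:
                    raise ValidationError(
                        f"connector {conn.connector_id} references unknown "
                        f"skeleton {skid}"
                    )
                if node_id not in skel.nodes:
                    raise ValidationError(
                        f"connector {conn.connector_id} references unknown node "
                        f"{node_id} of skeleton {skid}"
                    )
        for dcv in self.dcvs:
            if dcv.skeleton_id not in self.skeletons:
                raise ValidationError(
                    f"DCV record references unknown skeleton {dcv.skeleton_id}"
                )

    # -- queries ------------------------------------------------------------

    def homolog_of(self, skeleton_id: int) -> int:
        """Mirror-image partner id; medially unpaired neurons map to self."""
        skel = self.skeletons[skeleton_id]
        return skel.homolog_id if skel.homolog_id is not None else skeleton_id

    def ids_by_class(self, classes: Iterable[str]) -> list[int]:
        """Sorted skeleton ids whose class label matches any given label.

        A label matches exactly or as a dash-separated prefix, so "sensory"
        selects "sensory-3" as well.
        """
        classes = set(classes)
        out = []
        for skid, skel in self.skeletons.items():
            if skel.class_label in classes or any(
                skel.class_label.startswith(c + "-") for c in classes
            ):
                out.append(skid)
        return sorted(out)

    def synapse_records(self, skeleton_id: int) -> list[SynapseRecord]:
        """All pre/post synapse records of one neuron, connector-ordered.

        One "post" record per postsynaptic link and one "pre" record per
        presynaptic link of the neuron; positions are connector positions.
        """
        if skeleton_id not in self.skeletons:
            raise KeyError(f"unknown skeleton {skeleton_id}")
        records: list[SynapseRecord] = []
        for conn in sorted(self.connectors, key=lambda c: c.connector_id):
            if conn.pre_link is not None and conn.pre_link[0] == skeleton_id:
                records.append(
                    SynapseRecord(skeleton_id, conn.connector_id, "pre", conn.position)
                )
            for skid, _node in conn.post_links:
                if skid == skeleton_id:
                    records.append(
                        SynapseRecord(
                            skeleton_id, conn.connector_id, "post", conn.position
                        )
                    )
        return records

    def presynaptic_positions(self, skeleton_id: int) -> list[Vec3]:
        return [r.position for r in self.synapse_records(skeleton_id) if r.sign == "pre"]

    def copy(self) -> "Connectome":
        return Connectome(
            skeletons={
                skid: replace(skel, nodes=dict(skel.nodes))
                for skid, skel in self.skeletons.items()
            },
            connectors=list(self.connectors),
            dcvs=list(self.dcvs),
            regions=dict(self.regions),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Connectome):
            return NotImplemented
        return (
            self.skeletons == other.skeletons
            and sorted(self.connectors, key=lambda c: c.connector_id)
            == sorted(other.connectors, key=lambda c: c.connector_id)
            and sorted(self.dcvs, key=lambda d: (d.skeleton_id, d.position))
            == sorted(other.dcvs, key=lambda d: (d.skeleton_id, d.position))
            and self.regions == other.regions
        )
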