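"""Flat-file I/O for connectome exports.

Formats
-------
* one SWC file per skeleton (standard 7 columns ``id type x y z radius
  parent``; coordinates nm; ``parent == -1`` marks the root; a radius of
  ``-1`` means unknown),
* ``annotations.csv`` with ``skeleton_id,name,class_label,side,homolog_id,
  swc_file`` binding each skeleton id to its SWC file,
* ``connectors.csv`` with ``connector_id,role,skeleton_id,node_id,x,y,z``;
  one row per link, role in {pre, post}; the position repeats on every row
  of a connector,
* optional ``dcvs.csv`` with ``skeleton_id,x,y,z``,
* optional ``regions.txt``, one ``name: x0 y0 z0 x1 y1 z1`` box per line
  (a name may repeat to build a multi-box region).

Saving is canonical: everything is sorted by id and floats are written with
round-tripping precision, so saving the same connectome twice produces
byte-identical files and ``load(save(c)) == c``.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .model import (
    Connectome,
    Connector,
    DcvRecord,
    NeuronSkeleton,
    RegionMask,
    SkeletonNode,
    ValidationError,
)

__all__ = ["LoadError", "load_connectome", "save_connectome", "load_connectome_dir"]

PathLike = Union[str, os.PathLike]

ANNOTATION_COLUMNS = ["skeleton_id", "name", "class_label", "side", "homolog_id", "swc_file"]
CONNECTOR_COLUMNS = ["connector_id", "role", "skeleton_id", "node_id", "x", "y", "z"]
DCV_COLUMNS = ["skeleton_id", "x", "y", "z"]


class LoadError(ValueError):
    """A file could not be parsed or failed referential validation."""


def _fmt(v: float) -> str:
    # repr() round-trips doubles exactly; integers render without exponent
    return repr(float(v))


def _require_columns(df: pd.DataFrame, expected: list[str], path: PathLike) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing} (found {list(df.columns)})")


def _read_swc(path: PathLike) -> dict[int, SkeletonNode]:
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            header=None,
            names=["id", "type", "x", "y", "z", "radius", "parent"],
            float_precision="round_trip",
        )
    except Exception as exc:  # malformed whitespace table
        raise LoadError(f"{path}: cannot parse SWC ({exc})") from exc
    if df.shape[1] != 7:
        raise LoadError(f"{path}: expected 7 SWC columns, found {df.shape[1]}")
    nodes: dict[int, SkeletonNode] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            node_id = int(row.id)
            parent = int(row.parent)
            radius = float(row.radius)
            node = SkeletonNode(
                node_id=node_id,
                parent_id=None if parent == -1 else parent,
                position=(float(row.x), float(row.y), float(row.z)),
                radius=None if radius < 0 else radius,
            )
        except (TypeError, ValueError, ValidationError) as exc:
            raise LoadError(f"{path}: line {i}: {exc}") from exc
        if node_id in nodes:
            raise LoadError(f"{path}: line {i}: duplicate node id {node_id}")
        nodes[node_id] = node
    return nodes


def load_connectome(
    skeleton_dir: PathLike,
    connector_table: PathLike,
    annotation_table: PathLike,
    dcv_table: Optional[PathLike] = None,
    region_config: Optional[PathLike] = None,
) -> Connectome:
    """Load and validate a connectome from its flat-file export.

    Raises :class:`LoadError` with file/line context for malformed rows and
    dangling references; structural invariants (tree shape, homolog
    symmetry) raise :class:`~connclust.model.ValidationError`.
    """
    skeleton_dir = Path(skeleton_dir)
    ann = pd.read_csv(annotation_table, dtype=str, keep_default_na=False)
    _require_columns(ann, ANNOTATION_COLUMNS, annotation_table)

    skeletons: dict[int, NeuronSkeleton] = {}
    for i, row in enumerate(ann.itertuples(index=False), start=2):
        try:
            skid = int(row.skeleton_id)
            homolog = None if row.homolog_id == "" else int(row.homolog_id)
            skel = NeuronSkeleton(
                skeleton_id=skid,
                name=row.name,
                class_label=row.class_label,
                side=row.side,
                homolog_id=homolog,
                nodes=_read_swc(skeleton_dir / row.swc_file),
            )
        except LoadError:
            raise
        except (TypeError, ValueError) as exc:
            raise LoadError(f"{annotation_table}: line {i}: {exc}") from exc
        if skid in skeletons:
            raise LoadError(f"{annotation_table}: line {i}: duplicate skeleton {skid}")
        skeletons[skid] = skel

    con = pd.read_csv(connector_table, dtype=str, keep_default_na=False)
    _require_columns(con, CONNECTOR_COLUMNS, connector_table)
    by_id: dict[int, dict] = {}
    for i, row in enumerate(con.itertuples(index=False), start=2):
        try:
            cid = int(row.connector_id)
            skid = int(row.skeleton_id)
            link = (skid, int(row.node_id))
            pos = (float(row.x), float(row.y), float(row.z))
            role = row.role
        except (TypeError, ValueError) as exc:
            raise LoadError(f"{connector_table}: line {i}: {exc}") from exc
        if role not in ("pre", "post"):
            raise LoadError(f"{connector_table}: line {i}: bad role {role!r}")
        if skid not in skeletons:
            raise LoadError(
                f"{connector_table}: line {i}: connector {cid} references "
                f"unknown skeleton {skid}"
            )
        entry = by_id.setdefault(cid, {"position": pos, "pre": None, "post": []})
        if entry["position"] != pos:
            raise LoadError(
                f"{connector_table}: line {i}: connector {cid} has inconsistent positions"
            )
        if role == "pre":
            if entry["pre"] is not None:
                raise LoadError(
                    f"{connector_table}: line {i}: connector {cid} has two pre links"
                )
            entry["pre"] = link
        else:
            entry["post"].append(link)
    connectors = [
        Connector(cid, e["position"], e["pre"], tuple(e["post"]))
        for cid, e in sorted(by_id.items())
    ]

    dcvs: list[DcvRecord] = []
    if dcv_table is not None and Path(dcv_table).exists():
        dv = pd.read_csv(dcv_table, dtype=str, keep_default_na=False)
        _require_columns(dv, DCV_COLUMNS, dcv_table)
        for i, row in enumerate(dv.itertuples(index=False), start=2):
            try:
                skid = int(row.skeleton_id)
                rec = DcvRecord(skid, (float(row.x), float(row.y), float(row.z)))
            except (TypeError, ValueError, ValidationError) as exc:
                raise LoadError(f"{dcv_table}: line {i}: {exc}") from exc
            if skid not in skeletons:
                raise LoadError(
                    f"{dcv_table}: line {i}: DCV references unknown skeleton {skid}"
                )
            dcvs.append(rec)

    regions: dict[str, RegionMask] = {}
    if region_config is not None and Path(region_config).exists():
        regions = _read_regions(region_config)

    c = Connectome(skeletons=skeletons, connectors=connectors, dcvs=dcvs, regions=regions)
    c.validate()
    return c


def _read_regions(path: PathLike) -> dict[str, RegionMask]:
    boxes: dict[str, list] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise LoadError(f"{path}: line {i}: expected 'name: six numbers'")
            name, rest = line.split(":", 1)
            vals = rest.split()
            if len(vals) != 6:
                raise LoadError(f"{path}: line {i}: expected 6 numbers, got {len(vals)}")
            try:
                nums = [float(v) for v in vals]
            except ValueError as exc:
                raise LoadError(f"{path}: line {i}: {exc}") from exc
            boxes.setdefault(name.strip(), []).append(
                (tuple(nums[:3]), tuple(nums[3:]))
            )
    return {
        name: RegionMask(name, tuple(blist)) for name, blist in sorted(boxes.items())
    }


def load_connectome_dir(directory: PathLike) -> Connectome:
    """Load a connectome from a directory laid out by :func:`save_connectome`."""
    directory = Path(directory)
    dcv = directory / "dcvs.csv"
    regions = directory / "regions.txt"
    return load_connectome(
        directory / "skeletons",
        directory / "connectors.csv",
        directory / "annotations.csv",
        dcv_table=dcv if dcv.exists() else None,
        region_config=regions if regions.exists() else None,
    )


def save_connectome(c: Connectome, out_dir: PathLike) -> None:
    """Write the canonical flat-file export of a connectome.

    Deterministic: all rows sorted by id, floats written with
    round-tripping precision; a connectome with no DCVs (regions) omits
    ``dcvs.csv`` (``regions.txt``).
    """
    out = Path(out_dir)
    (out / "skeletons").mkdir(parents=True, exist_ok=True)

    ann_rows = []
    for skid in sorted(c.skeletons):
        skel = c.skeletons[skid]
        swc_name = f"{skid}.swc"
        ann_rows.append(
            {
                "skeleton_id": skid,
                "name": skel.name,
                "class_label": skel.class_label,
                "side": skel.side,
                "homolog_id": "" if skel.homolog_id is None else skel.homolog_id,
                "swc_file": swc_name,
            }
        )
        with open(out / "skeletons" / swc_name, "w") as fh:
            for node_id in sorted(skel.nodes):
                n = skel.nodes[node_id]
                parent = -1 if n.parent_id is None else n.parent_id
                radius = -1.0 if n.radius is None else n.radius
                fh.write(
                    f"{n.node_id} 0 {_fmt(n.position[0])} {_fmt(n.position[1])} "
                    f"{_fmt(n.position[2])} {_fmt(radius)} {parent}\n"
                )
    pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS).to_csv(
        out / "annotations.csv", index=False
    )

    con_rows = []
    for conn in sorted(c.connectors, key=lambda x: x.connector_id):
        x, y, z = (_fmt(v) for v in conn.position)
        links = []
        if conn.pre_link is not None:
            links.append(("pre", conn.pre_link))
        links.extend(("post", l) for l in conn.post_links)
        for role, (skid, node_id) in links:
            con_rows.append(
                {
                    "connector_id": conn.connector_id,
                    "role": role,
                    "skeleton_id": skid,
                    "node_id": node_id,
                    "x": x,
                    "y": y,
                    "z": z,
                }
            )
    pd.DataFrame(con_rows, columns=CONNECTOR_COLUMNS).to_csv(
        out / "connectors.csv", index=False
    )

    if c.dcvs:
        dcv_rows = [
            {
                "skeleton_id": d.skeleton_id,
                "x": _fmt(d.position[0]),
                "y": _fmt(d.position[1]),
                "z": _fmt(d.position[2]),
            }
            for d in sorted(c.dcvs, key=lambda d: (d.skeleton_id, d.position))
        ]
        pd.DataFrame(dcv_rows, columns=DCV_COLUMNS).to_csv(out / "dcvs.csv", index=False)

    if c.regions:
        with open(out / "regions.txt", "w") as fh:
            for name in sorted(c.regions):
                for lo, hi in c.regions[name].boxes:
                    nums = " ".join(_fmt(v) for v in (*lo, *hi))
                    fh.write(f"{name}: {nums}\n")
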