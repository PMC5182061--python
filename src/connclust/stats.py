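"""Adjacency construction and derived circuit statistics.

Counting convention throughout: synapses are polyadic, and *each
postsynaptic neurite counts as one synaptic connection*. A connector with
presynaptic neuron A and postsynaptic links [B, B, C] therefore contributes
A->B = 2 and A->C = 1. "Incoming" links of a neuron are its postsynaptic
records, "outgoing" links are the postsynaptic links of connectors where it
is presynaptic.

Statistics that are undefined for a neuron (no links in the requested
direction, no presynaptic sites) return NaN rather than a misleading 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cluster import ClusterResult
from .model import Connectome

__all__ = [
    "AdjacencyMatrix",
    "PartnerFilterResult",
    "ClassConnectivitySummary",
    "build_adjacency",
    "filter_partners",
    "connection_fraction",
    "region_fraction",
    "class_connectivity",
    "axis_distribution",
    "dcv_proximity",
    "shared_input_profile",
    "assign_identities",
]

AXIS_INDEX = {"mediolateral": 0, "dorsoventral": 1, "anteroposterior": 2}


@dataclass
class AdjacencyMatrix:
    """Integer synaptic-link counts from ``source_ids`` to ``target_ids``."""

    source_ids: list[int]
    target_ids: list[int]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.source_ids), len(self.target_ids)):
            raise ValueError("counts shape does not match id lists")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("adjacency counts must be integers")
        if np.any(self.counts < 0):
            raise ValueError("adjacency counts must be nonnegative")
        self._srow = {s: i for i, s in enumerate(self.source_ids)}
        self._tcol = {t: j for j, t in enumerate(self.target_ids)}

    def count(self, source: int, target: int) -> int:
        return int(self.counts[self._srow[source], self._tcol[target]])

    def rows_for(self, ids: Sequence[int]) -> np.ndarray:
        """Outgoing partner-count vectors (one row per requested source)."""
        missing = [i for i in ids if i not in self._srow]
        if missing:
            raise KeyError(f"ids not among sources: {missing}")
        return self.counts[[self._srow[i] for i in ids], :]

    def cols_for(self, ids: Sequence[int]) -> np.ndarray:
        """Incoming partner-count vectors (one row per requested target)."""
        missing = [i for i in ids if i not in self._tcol]
        if missing:
            raise KeyError(f"ids not among targets: {missing}")
        return self.counts[:, [self._tcol[i] for i in ids]].T

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.source_ids, columns=self.target_ids)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path)


def build_adjacency(
    c: Connectome, sources: Sequence[int], targets: Sequence[int]
) -> AdjacencyMatrix:
    """Count postsynaptic links target-by-target for each presynaptic source."""
    sources = list(sources)
    targets = list(targets)
    for skid in set(sources) | set(targets):
        if skid not in c.skeletons:
            raise KeyError(f"unknown skeleton {skid}")
    srow = {s: i for i, s in enumerate(sources)}
    tcol = {t: j for j, t in enumerate(targets)}
    counts = np.zeros((len(sources), len(targets)), dtype=np.int64)
    for conn in c.connectors:
        if conn.pre_link is None:
            continue
        s = conn.pre_link[0]
        if s not in srow:
            continue
        for skid, _node in conn.post_links:
            if skid in tcol:
                counts[srow[s], tcol[skid]] += 1
    return AdjacencyMatrix(sources, targets, counts)


# ---------------------------------------------------------------------------
# partner inclusion filter
# ---------------------------------------------------------------------------

@dataclass
class PartnerFilterResult:
    """Outcome of the reconstruction-inclusion filter for partner neurons."""

    included: set[int]
    excluded: dict[int, str]  # id -> reason: "no_homolog" | "below_threshold"
    coverage_pre: float  # % of focal presynaptic links onto included partners
    coverage_post: float  # % of focal postsynaptic links from included partners


def _links_with_focal(c: Connectome, focal: set[int]) -> dict[int, int]:
    """Total link count (either direction) between each non-focal partner
    and the focal set."""
    totals: dict[int, int] = {}
    for conn in c.connectors:
        pre = conn.pre_link[0] if conn.pre_link is not None else None
        for skid, _ in conn.post_links:
            if pre in focal and skid not in focal:
                totals[skid] = totals.get(skid, 0) + 1
            elif skid in focal and pre is not None and pre not in focal:
                totals[pre] = totals.get(pre, 0) + 1
    return totals


def filter_partners(
    c: Connectome,
    focal: Iterable[int],
    min_syn: int = 3,
    exempt_classes: Iterable[str] = ("sensory",),
) -> PartnerFilterResult:
    """Apply the partner-inclusion rule used for full reconstruction.

    A candidate partner (any non-focal neuron exchanging >= 1 link with the
    focal set) is included iff

    a. a homologous neuron exists in the other hemisphere — satisfied by
       definition for medially unpaired neurons; and
    b. it or its homolog has at least ``min_syn`` total links to/from the
       focal set; classes in ``exempt_classes`` (matched exactly or as a
       dash-prefix, e.g. "sensory" matches "sensory-3") skip this criterion.

    Coverage is the percentage of the focal set's pre-/postsynaptic links
    exchanged with candidates that land on (come from) included partners;
    it is 100 when there are no candidate links at all.
    """
    focal = set(focal)
    for skid in focal:
        if skid not in c.skeletons:
            raise KeyError(f"unknown skeleton {skid}")
    exempt = set(exempt_classes)
    totals = _links_with_focal(c, focal)

    included: set[int] = set()
    excluded: dict[int, str] = {}
    for skid in sorted(totals):
        skel = c.skeletons[skid]
        has_homolog = skel.homolog_id is not None or skel.side == "medial"
        if not has_homolog:
            excluded[skid] = "no_homolog"
            continue
        is_exempt = skel.class_label in exempt or any(
            skel.class_label.startswith(e + "-") for e in exempt
        )
        pair_total = totals[skid]
        if skel.homolog_id is not None:
            pair_total = max(pair_total, totals.get(skel.homolog_id, 0))
        if is_exempt or pair_total >= min_syn:
            included.add(skid)
        else:
            excluded[skid] = "below_threshold"

    pre_num = pre_den = post_num = post_den = 0
    for conn in c.connectors:
        pre = conn.pre_link[0] if conn.pre_link is not None else None
        for skid, _ in conn.post_links:
            if pre in focal and skid not in focal:
                pre_den += 1
                pre_num += skid in included
            elif skid in focal and pre is not None and pre not in focal:
                post_den += 1
                post_num += pre in included
    coverage_pre = 100.0 * pre_num / pre_den if pre_den else 100.0
    coverage_post = 100.0 * post_num / post_den if post_den else 100.0
    return PartnerFilterResult(included, excluded, coverage_pre, coverage_post)


# ---------------------------------------------------------------------------
# fractions
# ---------------------------------------------------------------------------

def _directional_links(
    c: Connectome, neuron: int, direction: str
) -> list[tuple[Optional[int], tuple[float, float, float]]]:
    """(partner id, connector position) for each link of the neuron.

    For outgoing links the partner is the postsynaptic neuron; for incoming
    links the partner is the presynaptic neuron (None when unknown).
    """
    if neuron not in c.skeletons:
        raise KeyError(f"unknown skeleton {neuron}")
    if direction not in ("incoming", "outgoing"):
        raise ValueError(f"unknown direction {direction!r}")
    out = []
    for conn in c.connectors:
        pre = conn.pre_link[0] if conn.pre_link is not None else None
        if direction == "outgoing":
            if pre == neuron:
                out.extend((skid, conn.position) for skid, _ in conn.post_links)
        else:
            for skid, _ in conn.post_links:
                if skid == neuron:
                    out.append((pre, conn.position))
    return out


def connection_fraction(
    c: Connectome, neuron: int, partner_set: Iterable[int], direction: str
) -> float:
    """Percent of a neuron's directional links exchanged with a partner set.

    NaN when the neuron has no links in the direction.
    """
    partners = set(partner_set)
    links = _directional_links(c, neuron, direction)
    if not links:
        return float("nan")
    hits = sum(1 for partner, _pos in links if partner in partners)
    return 100.0 * hits / len(links)


def region_fraction(c: Connectome, neuron: int, region: str, direction: str) -> float:
    """Percent of a neuron's directional links placed inside a named region
    (connector position, box-boundary inclusive)."""
    if region not in c.regions:
        raise KeyError(f"unknown region {region!r}")
    mask = c.regions[region]
    links = _directional_links(c, neuron, direction)
    if not links:
        return float("nan")
    hits = sum(1 for _partner, pos in links if mask.contains(pos))
    return 100.0 * hits / len(links)


# ---------------------------------------------------------------------------
# class-level connectivity
# ---------------------------------------------------------------------------

@dataclass
class ClassConnectivitySummary:
    """Within-/across-class wiring of a neuron set, plus bilateral checks."""

    class_pair_totals: dict[tuple[str, str], int]
    same_class_percent: pd.DataFrame  # index id, columns incoming/outgoing (%)
    bilateral_ok: dict[tuple[int, int], bool]  # per connection with count >= 1


def class_connectivity(c: Connectome, ids: Iterable[int]) -> ClassConnectivitySummary:
    """Class-pair synapse totals, same-class link percentages per neuron and
    bilateral recapitulation of every connection inside the set.

    A connection (s, t) is bilaterally recapitulated when its mirror image
    (homolog(s), homolog(t)) — medial neurons mirroring to themselves —
    also has at least one link.
    """
    ids = sorted(set(ids))
    missing = [i for i in ids if i not in c.skeletons]
    if missing:
        raise KeyError(f"unknown skeletons: {missing}")
    adj = build_adjacency(c, ids, ids)
    label = {i: c.skeletons[i].class_label for i in ids}

    totals: dict[tuple[str, str], int] = {}
    for s in ids:
        for t in ids:
            n = adj.count(s, t)
            if n:
                key = (label[s], label[t])
                totals[key] = totals.get(key, 0) + n

    rows = []
    for i in ids:
        same = {j for j in ids if label[j] == label[i]}
        rows.append(
            {
                "id": i,
                "incoming": connection_fraction(c, i, same, "incoming"),
                "outgoing": connection_fraction(c, i, same, "outgoing"),
            }
        )
    same_class = pd.DataFrame(rows).set_index("id")

    bilateral: dict[tuple[int, int], bool] = {}
    idset = set(ids)
    for s in ids:
        for t in ids:
            if adj.count(s, t) < 1:
                continue
            hs, ht = c.homolog_of(s), c.homolog_of(t)
            if hs in idset and ht in idset:
                bilateral[(s, t)] = adj.count(hs, ht) >= 1
            else:
                bilateral[(s, t)] = False
    return ClassConnectivitySummary(totals, same_class, bilateral)


def axis_distribution(
    records: Sequence, axis: str, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of synapse positions along a body axis.

    Returns (bin_edges_nm, counts); counts sum to the number of records and
    the edges span the data range.
    """
    if axis not in AXIS_INDEX:
        raise ValueError(f"unknown axis {axis!r}; one of {sorted(AXIS_INDEX)}")
    if not len(records):
        raise ValueError("no synapse records to histogram")
    coords = np.array([r.position[AXIS_INDEX[axis]] for r in records], dtype=float)
    counts, edges = np.histogram(coords, bins=n_bins)
    return edges, counts


def dcv_proximity(c: Connectome, neuron: int, radius: float = 450.0) -> float:
    """Percent of a neuron's presynaptic sites with >= 1 of its own DCVs
    within ``radius`` nm (Euclidean distance to the connector position).

    NaN when the neuron has no presynaptic sites; 0 when it has no DCVs.
    """
    presites = np.array(c.presynaptic_positions(neuron), dtype=float).reshape(-1, 3)
    if not len(presites):
        return float("nan")
    dcv_pts = np.array(
        [d.position for d in c.dcvs if d.skeleton_id == neuron], dtype=float
    ).reshape(-1, 3)
    if not len(dcv_pts):
        return 0.0
    tree = cKDTree(dcv_pts)
    d, _ = tree.query(presites)
    return 100.0 * float(np.sum(d <= radius)) / len(presites)


def shared_input_profile(
    c: Connectome,
    reference_set: Iterable[int],
    target_groups: Mapping[str, Iterable[int]],
) -> pd.DataFrame:
    """Link counts of each upstream partner of a reference set onto that set
    and onto each (disjoint) target group.

    One row per presynaptic partner of the reference set (partners inside
    the reference set itself are not rows). Column ``shared_<group>`` flags
    partners with >= 1 link onto the group.
    """
    reference = set(reference_set)
    groups = {g: set(m) for g, m in target_groups.items()}
    if not reference or any(not m for m in groups.values()):
        raise ValueError("reference set and all target groups must be non-empty")
    names = sorted(groups)
    for i, g in enumerate(names):
        for h in names[i + 1 :]:
            overlap = groups[g] & groups[h]
            if overlap:
                raise ValueError(
                    f"target groups {g!r} and {h!r} overlap: {sorted(overlap)}"
                )

    partners = sorted(
        {
            conn.pre_link[0]
            for conn in c.connectors
            if conn.pre_link is not None
            and conn.pre_link[0] not in reference
            and any(skid in reference for skid, _ in conn.post_links)
        }
    )
    all_targets = sorted(reference | set().union(*groups.values()))
    adj = build_adjacency(c, partners, all_targets)
    rows = []
    for p in partners:
        row = {"partner": p}
        row["links_to_reference"] = int(sum(adj.count(p, t) for t in sorted(reference)))
        for g in names:
            n = int(sum(adj.count(p, t) for t in sorted(groups[g])))
            row[f"links_to_{g}"] = n
            row[f"shared_{g}"] = n >= 1
        rows.append(row)
    columns = (
        ["partner", "links_to_reference"]
        + [f"links_to_{g}" for g in names]
        + [f"shared_{g}" for g in names]
    )
    return pd.DataFrame(rows, columns=columns).set_index("partner")


def assign_identities(
    cluster: ClusterResult, expected_sizes: Mapping[str, int]
) -> dict[int, str]:
    """Map clusters to labels by matching cluster sizes to expected sizes.

    Requires the multiset of cluster sizes to equal the multiset of
    expected sizes, and every size to be unique (two labels expecting the
    same size would be ambiguous).
    """
    sizes: dict[int, int] = {}
    for _skid, cl in cluster.assignment.items():
        sizes[cl] = sizes.get(cl, 0) + 1
    got = sorted(sizes.values())
    want = sorted(expected_sizes.values())
    if got != want:
        raise ValueError(
            f"cluster sizes {got} do not match expected sizes {want}"
        )
    by_size: dict[int, list[str]] = {}
    for lbl, n in expected_sizes.items():
        by_size.setdefault(n, []).append(lbl)
    ambiguous = {n: lbls for n, lbls in by_size.items() if len(lbls) > 1}
    if ambiguous:
        raise ValueError(f"ambiguous expected sizes: {ambiguous}")
    label_of_cluster = {cl: by_size[n][0] for cl, n in sizes.items()}
    return {skid: label_of_cluster[cl] for skid, cl in cluster.assignment.items()}
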