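"""Connectivity- and synapse-placement similarity scores.

Two complementary notions of "these neurons are the same kind of element":

**Normalized connectivity similarity.** For neurons *i*, *j* with adjacency
vectors over common partners *k*, each partner contributes

    f(A_ik, A_jk) = min(A_ik, A_jk) - C1 * max(A_ik, A_jk) * exp(-C2 * min(A_ik, A_jk))

so a partner contacted by both neurons with similar weight scores ~min,
while a partner private to one of them is punished by -C1*max. The summed
score S is normalized against its attainable extremes, Smin = sum of
-C1*max and Smax = sum of max, giving (S - Smin)/(Smax - Smin) in [0, 1].
Self-connections and the direct i<->j connection are excluded from the sum.
Defaults C1 = 0.5, C2 = 1.

**Synapse similarity.** For each synapse *s* of neuron *i*, let *k* be the
nearest synapse of neuron *j* of the same sign (pre with pre, post with
post), d_sk their Euclidean distance, and n(is), n(jk) the number of
same-sign synapses of the owning neuron within radius omega of s and k
(counting the focal synapse itself). The per-synapse term

    f(is, jk) = exp(-d_sk^2 / (2 sigma^2)) * exp(-|n(is) - n(jk)| / (n(is) + n(jk)))

is averaged over all synapses s of i, rewarding co-located synapses with
comparable local density. The directional score S(i->j) is asymmetric; the
matrix used for clustering averages both directions. Defaults
sigma = omega = 2000 nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import Connectome, SynapseRecord

__all__ = [
    "ConnSimParams",
    "SynSimParams",
    "SimilarityMatrix",
    "conn_sim_term",
    "conn_sim",
    "conn_sim_matrix",
    "syn_sim_term",
    "syn_sim",
    "syn_sim_matrix",
]


@dataclass(frozen=True)
class ConnSimParams:
    """Weights of the connectivity-similarity kernel.

    c1 scales how strongly a partner private to one neuron is punished;
    c2 sets how fast that punishment decays once both neurons do contact
    the partner.
    """

    c1: float = 0.5
    c2: float = 1.0

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError(f"C1 and C2 must be nonnegative, got {self.c1}, {self.c2}")


@dataclass(frozen=True)
class SynSimParams:
    """Length scales (nm) of the synapse-similarity kernel.

    sigma is the distance at which two synapses stop counting as close;
    omega is the radius of the local-density count.
    """

    sigma: float = 2000.0
    omega: float = 2000.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.omega <= 0:
            raise ValueError(
                f"sigma and omega must be positive, got {self.sigma}, {self.omega}"
            )


@dataclass
class SimilarityMatrix:
    """A square pairwise similarity matrix with an explicit defined-mask.

    Entries where ``defined`` is False (the diagonal self-comparisons, and
    pairs for which the score has no value, e.g. two all-zero adjacency
    vectors) carry no information and must never be read as 0.
    """

    ids: list[int]
    values: np.ndarray
    kind: str  # "connectivity" or "synapse"
    defined: np.ndarray = field(default=None)  # bool mask, same shape
    symmetrized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if self.defined is None:
            self.defined = ~np.eye(n, dtype=bool)
        self.defined = np.asarray(self.defined, dtype=bool)
        ok = self.defined & np.isfinite(self.values)
        if np.any(self.values[ok] < -1e-9) or np.any(self.values[ok] > 1 + 1e-9):
            raise ValueError("defined similarity values must lie in [0, 1]")
        if self.symmetrized:
            v = np.where(self.defined, self.values, 0.0)
            if not (
                np.allclose(v, v.T, atol=1e-9)
                and np.array_equal(self.defined, self.defined.T)
            ):
                raise ValueError("symmetrized matrix is not symmetric")

    def value(self, id_a: int, id_b: int) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j]) if self.defined[i, j] else float("nan")

    def to_csv(self, path_prefix: Union[str, Path]) -> None:
        """Write ``<prefix>.csv`` (values), ``<prefix>.mask.csv`` and a
        ``<prefix>.params.json`` provenance sidecar (written by callers that
        know the parameters; here only values and mask)."""
        prefix = Path(path_prefix)
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            prefix.with_suffix(".csv")
        )
        pd.DataFrame(self.defined.astype(int), index=self.ids, columns=self.ids).to_csv(
            Path(str(prefix) + ".mask.csv")
        )

    @classmethod
    def from_csv(cls, path_prefix: Union[str, Path], kind: str = "connectivity"):
        """Read a matrix written by :meth:`to_csv` (values + mask files)."""
        prefix = Path(path_prefix)
        values = pd.read_csv(prefix.with_suffix(".csv"), index_col=0)
        mask = pd.read_csv(Path(str(prefix) + ".mask.csv"), index_col=0)
        ids = [int(i) for i in values.index]
        return cls(
            ids=ids,
            values=values.to_numpy(dtype=float),
            kind=kind,
            defined=mask.to_numpy(dtype=bool),
        )

    def write_params_sidecar(self, path_prefix: Union[str, Path], params: dict) -> None:
        with open(Path(str(path_prefix) + ".params.json"), "w") as fh:
            json.dump({"kind": self.kind, "symmetrized": self.symmetrized, **params},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# connectivity similarity
# ---------------------------------------------------------------------------

def conn_sim_term(a, b, params: ConnSimParams = ConnSimParams()):
    """Per-partner similarity term min(a,b) - C1*max(a,b)*exp(-C2*min(a,b)).

    Vectorized: ``a`` and ``b`` may be scalars or broadcastable arrays of
    nonnegative synapse counts.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("synapse counts must be nonnegative")
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    out = lo - params.c1 * hi * np.exp(-params.c2 * lo)
    return float(out) if out.ndim == 0 else out


def conn_sim(
    vec_i: Sequence[float],
    vec_j: Sequence[float],
    params: ConnSimParams = ConnSimParams(),
    ignore: Iterable[int] = (),
) -> float:
    """Normalized connectivity similarity of two partner-count vectors.

    ``ignore`` lists partner indices dropped from the sum (used to exclude
    the compared neurons themselves: self-connections and the direct i-j
    connection). Returns NaN when undefined, i.e. when both vectors are
    all-zero over the retained partners — no shared evidence either way.
    """
    vi = np.asarray(vec_i, dtype=float)
    vj = np.asarray(vec_j, dtype=float)
    if vi.shape != vj.shape or vi.ndim != 1:
        raise ValueError(f"vector shapes differ: {vi.shape} vs {vj.shape}")
    keep = np.ones(vi.shape[0], dtype=bool)
    for idx in ignore:
        keep[idx] = False
    vi, vj = vi[keep], vj[keep]
    hi = np.maximum(vi, vj)
    s_max = float(hi.sum())
    if s_max == 0.0:
        return float("nan")
    s = float(np.sum(conn_sim_term(vi, vj, params)))
    s_min = -params.c1 * s_max
    val = (s - s_min) / (s_max - s_min)
    return float(min(1.0, max(0.0, val)))


def conn_sim_matrix(
    adj: "AdjacencyMatrix",
    neuron_ids: Sequence[int],
    direction: str = "combined",
    params: ConnSimParams = ConnSimParams(),
) -> SimilarityMatrix:
    """Pairwise normalized connectivity similarity over a neuron set.

    direction
        ``"outgoing"`` compares rows of the adjacency (postsynaptic partner
        profiles), ``"incoming"`` compares columns (presynaptic partner
        profiles), ``"combined"`` averages the two directional normalized
        scores (a direction undefined for both neurons drops out; if both
        directions are undefined the pair is masked).

    Partner entries belonging to either compared neuron are excluded from
    every pairwise score.
    """
    if direction not in ("incoming", "outgoing", "combined"):
        raise ValueError(f"unknown direction {direction!r}")
    ids = list(neuron_ids)
    if direction == "combined":
        a = conn_sim_matrix(adj, ids, "incoming", params)
        b = conn_sim_matrix(adj, ids, "outgoing", params)
        num = np.zeros_like(a.values)
        den = np.zeros_like(a.values)
        for m in (a, b):
            num += np.where(m.defined, m.values, 0.0)
            den += m.defined
        defined = den > 0
        values = np.divide(num, den, out=np.zeros_like(num), where=defined)
        return SimilarityMatrix(ids, values, "connectivity", defined=defined)

    if direction == "outgoing":
        vectors, axis_ids = adj.rows_for(ids), adj.target_ids
    else:
        vectors, axis_ids = adj.cols_for(ids), adj.source_ids
    pos = {skid: k for k, skid in enumerate(axis_ids)}

    n = len(ids)
    values = np.zeros((n, n))
    defined = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            ignore = [pos[x] for x in (ids[i], ids[j]) if x in pos]
            val = conn_sim(vectors[i], vectors[j], params, ignore=ignore)
            if val == val:  # not NaN
                values[i, j] = values[j, i] = val
                defined[i, j] = defined[j, i] = True
    return SimilarityMatrix(ids, values, "connectivity", defined=defined)


# ---------------------------------------------------------------------------
# synapse similarity
# ---------------------------------------------------------------------------

def syn_sim_term(
    d: float, n_is: int, n_jk: int, params: SynSimParams = SynSimParams()
) -> float:
    """Distance kernel times local-density-mismatch penalty, in (0, 1]."""
    if n_is < 1 or n_jk < 1:
        raise ValueError("local synapse counts include the focal synapse and are >= 1")
    if d < 0:
        raise ValueError("distance must be nonnegative")
    return float(
        np.exp(-(d * d) / (2.0 * params.sigma**2))
        * np.exp(-abs(n_is - n_jk) / (n_is + n_jk))
    )


def _split_by_sign(records: Sequence[SynapseRecord]) -> dict[str, np.ndarray]:
    out = {}
    for sign in ("pre", "post"):
        pts = np.array(
            [r.position for r in records if r.sign == sign], dtype=float
        ).reshape(-1, 3)
        if len(pts):
            out[sign] = pts
    return out


def _directional_syn_sim(
    pts_i: dict[str, np.ndarray],
    pts_j: dict[str, np.ndarray],
    params: SynSimParams,
) -> float:
    terms: list[np.ndarray] = []
    for sign, pi in pts_i.items():
        pj = pts_j.get(sign)
        if pj is None:
            # no same-sign synapse in j: each s contributes 0
            terms.append(np.zeros(len(pi)))
            continue
        tree_i = cKDTree(pi)
        tree_j = cKDTree(pj)
        d, k_idx = tree_j.query(pi)
        n_is = np.array([len(x) for x in tree_i.query_ball_point(pi, params.omega)])
        n_jk = np.array(
            [len(x) for x in tree_j.query_ball_point(pj[k_idx], params.omega)]
        )
        terms.append(
            np.exp(-(d**2) / (2.0 * params.sigma**2))
            * np.exp(-np.abs(n_is - n_jk) / (n_is + n_jk))
        )
    all_terms = np.concatenate(terms)
    return float(all_terms.mean())


def syn_sim(
    neuron_i: Sequence[SynapseRecord],
    neuron_j: Sequence[SynapseRecord],
    params: SynSimParams = SynSimParams(),
    symmetrize: bool = True,
) -> float:
    """Synapse-placement similarity between two neurons' synapse clouds.

    With ``symmetrize=False`` returns the directional score S(i->j): the
    mean per-synapse term over all synapses of i, matching each to the
    nearest same-sign synapse of j. With ``symmetrize=True`` (default)
    returns (S(i->j) + S(j->i)) / 2.
    """
    if not len(neuron_i) or not len(neuron_j):
        raise ValueError("both neurons need at least one synapse record")
    pi, pj = _split_by_sign(neuron_i), _split_by_sign(neuron_j)
    s_ij = _directional_syn_sim(pi, pj, params)
    if not symmetrize:
        return s_ij
    s_ji = _directional_syn_sim(pj, pi, params)
    return 0.5 * (s_ij + s_ji)


def syn_sim_matrix(
    neuron_ids: Sequence[int],
    c: Connectome,
    params: SynSimParams = SynSimParams(),
    signs: Optional[Sequence[str]] = None,
) -> SimilarityMatrix:
    """Pairwise symmetrized synapse similarity over a neuron set.

    ``signs`` optionally restricts the records used (e.g. ``["pre"]`` to
    compare only presynaptic-site placement, as for sensory afferents).
    Neurons with no (retained) synapse records are reported together in a
    single error.
    """
    ids = list(neuron_ids)
    records = {}
    empty = []
    for skid in ids:
        recs = c.synapse_records(skid)
        if signs is not None:
            recs = [r for r in recs if r.sign in signs]
        if not recs:
            empty.append(skid)
        records[skid] = recs
    if empty:
        raise ValueError(f"neurons with zero synapse records: {sorted(empty)}")
    clouds = {skid: _split_by_sign(records[skid]) for skid in ids}

    n = len(ids)
    values = np.eye(n) * 0.0
    defined = ~np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            s_ij = _directional_syn_sim(clouds[ids[i]], clouds[ids[j]], params)
            s_ji = _directional_syn_sim(clouds[ids[j]], clouds[ids[i]], params)
            values[i, j] = values[j, i] = 0.5 * (s_ij + s_ji)
    return SimilarityMatrix(ids, values, "synapse", defined=defined)
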