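"""Cluster-mass permutation correction over the electrode array.

Channel-wise mixed-model Wald statistics are corrected for multiple
comparisons with a max-statistic permutation scheme: spatially contiguous
electrodes with uncorrected p below the cluster-forming threshold (0.005)
and a consistent effect direction are grouped into clusters of at least
three electrodes; the cluster mass is the sum of Wald statistics over the
cluster.  The outcome is then re-shuffled within participant-by-experiment
strata (5,000 permutations in the emulated study), the identical model and
clustering are applied to every shuffle, and the maximum absolute cluster
mass per permutation forms the null distribution.  Observed clusters are
significant when their mass exceeds the 95th percentile of that null;
corrected p-values use the standard +1 permutation correction
p = (1 + #{null >= mass}) / (1 + n_perm), which can never be exactly zero.

Positive and negative clusters are formed separately but compared against
the single max-|mass| null (a two-sided correction).  Electrodes whose fit
failed are treated as sub-threshold: they can neither seed nor join a
cluster, in the observed map and in every permutation alike.

The adjacency graph is a plain ``networkx.Graph`` whose nodes are the
channel labels; the construction method and parameters are stored in its
``graph`` attributes for provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .glme import ChannelwiseWaldEngine, ModelSpec
from .synthetic import SensorArray

__all__ = [
    "ClusterResult",
    "PermutationNull",
    "build_adjacency",
    "form_clusters",
    "permutation_null",
    "significant_clusters",
    "cluster_permutation_test",
]


@dataclass(frozen=True)
class ClusterResult:
    """A sign-consistent supra-threshold electrode set."""

    members: tuple[str, ...]
    sign: int  # +1 or -1
    mass: float
    corrected_p: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class PermutationNull:
    """Max-|cluster-mass| null distribution from stratified shuffles."""

    values: np.ndarray  # one max-|mass| per permutation (0 if no cluster)
    n_permutations: int
    seed: int | None
    strata: str

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if len(self.values) != self.n_permutations:
            raise ValueError("null length must equal n_permutations")
        if np.any(self.values < 0):
            raise ValueError("cluster masses are nonnegative")

    def percentile(self, q: float = 95.0) -> float:
        return float(np.percentile(self.values, q))


def build_adjacency(sensors: SensorArray, method: str = "delaunay",
                    threshold: float | None = None,
                    prune_quantile: float = 0.98) -> nx.Graph:
    """Electrode adjacency graph.

    ``delaunay`` (default): Delaunay triangulation of the 2-D azimuthal
    projection of the electrode positions, with edges longer than the given
    quantile of edge lengths pruned (guards against spurious long edges at
    the cap border).  ``distance``: connect electrodes closer than
    ``threshold`` (3-D Euclidean).
    """
    pos = sensors.positions
    if len(sensors) < 3:
        raise ValueError("need at least 3 sensors")
    if len(np.unique(pos.round(12), axis=0)) != len(pos):
        raise ValueError("duplicate sensor positions")
    g = nx.Graph()
    g.add_nodes_from(sensors.channel_labels)
    labels = sensors.channel_labels
    if method == "distance":
        if threshold is None:
            raise ValueError("distance method requires a threshold")
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        ii, jj = np.where((d <= threshold) & (d > 0))
        g.add_edges_from(
            (labels[i], labels[j]) for i, j in zip(ii, jj) if i < j
        )
    elif method == "delaunay":
        # azimuthal (polar) projection: distance from the cap vertex along
        # the sphere, preserving neighborhood structure of the cap
        r = np.linalg.norm(pos, axis=1)
        r[r == 0] = 1.0
        unit = pos / r[:, None]
        theta = np.arccos(np.clip(unit[:, 2], -1, 1))
        phi = np.arctan2(unit[:, 1], unit[:, 0])
        xy = np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])
        tri = Delaunay(xy)
        edges = set()
        for simplex in tri.simplices:
            for k in range(3):
                i, j = sorted((simplex[k], simplex[(k + 1) % 3]))
                edges.add((i, j))
        lengths = {e: np.linalg.norm(pos[e[0]] - pos[e[1]]) for e in edges}
        cut = np.quantile(list(lengths.values()), prune_quantile)
        g.add_edges_from(
            (labels[i], labels[j]) for (i, j), ln in lengths.items() if ln <= cut
        )
    else:
        raise ValueError(f"unknown adjacency method {method!r}")
    if not nx.is_connected(g):
        warnings.warn(
            f"adjacency graph has {nx.number_connected_components(g)} components"
        )
    g.graph["method"] = method
    g.graph["threshold"] = threshold
    g.graph["prune_quantile"] = prune_quantile if method == "delaunay" else None
    return g


def form_clusters(stats: pd.DataFrame, graph: nx.Graph,
                  p_thresh: float = 0.005, min_size: int = 3) -> list[ClusterResult]:
    """Connected, sign-homogeneous supra-threshold clusters with masses.

    ``stats`` is indexed by channel label with columns wald, pvalue, sign
    and (optionally) ok; channels flagged not-ok are sub-threshold by fiat.
    Components smaller than ``min_size`` are dropped.
    """
    ok = stats["ok"] if "ok" in stats else pd.Series(True, index=stats.index)
    out: list[ClusterResult] = []
    for s in (1, -1):
        mask = ok & (stats["pvalue"] < p_thresh) & (stats["sign"] == s)
        nodes = [ch for ch in stats.index[mask] if ch in graph]
        if not nodes:
            continue
        sub = graph.subgraph(nodes)
        for comp in nx.connected_components(sub):
            if len(comp) < min_size:
                continue
            members = tuple(sorted(comp))
            # summing in sorted member order keeps the mass bit-reproducible
            mass = float(stats.loc[list(members), "wald"].sum())
            out.append(ClusterResult(members=members, sign=s, mass=mass))
    out.sort(key=lambda c: -c.mass)
    return out


def _strata_codes(records: pd.DataFrame, strata: str) -> np.ndarray:
    if strata == "participant":
        key = records["participant_id"].astype(str)
    elif strata == "participant_experiment":
        key = (records["participant_id"].astype(str) + "|"
               + records["experiment"].astype(str))
    else:
        raise ValueError(f"unknown strata {strata!r}")
    codes, _ = pd.factorize(key)
    return codes


def _stratified_permutation(rng: np.random.Generator,
                            groups: list[np.ndarray], n: int) -> np.ndarray:
    perm = np.arange(n)
    for idx in groups:
        perm[idx] = idx[rng.permutation(len(idx))]
    return perm


def permutation_null(
    records: pd.DataFrame,
    features: pd.DataFrame,
    spec: ModelSpec,
    graph: nx.Graph,
    n_perm: int = 5000,
    strata: str = "participant_experiment",
    seed: int | None = None,
    p_thresh: float = 0.005,
    min_size: int = 3,
    term: str | None = None,
    engine: ChannelwiseWaldEngine | None = None,
) -> PermutationNull:
    """Max-|cluster-mass| null: shuffle the outcome within strata, re-run
    the identical channel-wise model, form clusters, keep the largest mass.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} gives an unstable null tail")
    eng = engine or ChannelwiseWaldEngine(records, features, spec, term=term)
    codes = _strata_codes(eng.records, strata)
    sizes = np.bincount(codes)
    if np.any(sizes < 2):
        warnings.warn(
            f"{int((sizes < 2).sum())} strata have a single observation and "
            "contribute nothing to the permutation null"
        )
    groups = [np.flatnonzero(codes == c) for c in range(codes.max() + 1)]
    rng = np.random.default_rng(seed)
    n = len(eng.records)
    null = np.zeros(n_perm)
    for i in range(n_perm):
        perm = _stratified_permutation(rng, groups, n)
        tab = eng.wald_table(perm)
        cands = form_clusters(tab, graph, p_thresh=p_thresh, min_size=min_size)
        if cands:
            null[i] = cands[0].mass  # already the max |mass| (signs separate)
    return PermutationNull(values=null, n_permutations=n_perm, seed=seed,
                           strata=strata)


def significant_clusters(candidates: list[ClusterResult], null: PermutationNull,
                         alpha: float = 0.05) -> list[ClusterResult]:
    """Attach permutation-corrected p-values; keep clusters with p < alpha."""
    if null.n_permutations == 0:
        raise ValueError("empty permutation null")
    out = []
    for c in candidates:
        p = (1 + int((null.values >= c.mass).sum())) / (1 + null.n_permutations)
        out.append(ClusterResult(c.members, c.sign, c.mass, corrected_p=p))
    return [c for c in out if c.corrected_p < alpha]


def cluster_permutation_test(
    records: pd.DataFrame,
    features: pd.DataFrame,
    spec: ModelSpec,
    graph: nx.Graph,
    n_perm: int = 5000,
    alpha: float = 0.05,
    p_thresh: float = 0.005,
    min_size: int = 3,
    strata: str = "participant_experiment",
    seed: int | None = None,
    term: str | None = None,
):
    """Full observed-vs-permuted cluster analysis for one model.

    Returns (significant clusters, all candidates with corrected p,
    per-channel statistics table, permutation null).
    """
    eng = ChannelwiseWaldEngine(records, features, spec, term=term)
    stats = eng.wald_table()
    candidates = form_clusters(stats, graph, p_thresh=p_thresh, min_size=min_size)
    null = permutation_null(
        records, features, spec, graph, n_perm=n_perm, strata=strata,
        seed=seed, p_thresh=p_thresh, min_size=min_size, term=term, engine=eng,
    )
    annotated = []
    for c in candidates:
        p = (1 + int((null.values >= c.mass).sum())) / (1 + null.n_permutations)
        annotated.append(ClusterResult(c.members, c.sign, c.mass, corrected_p=p))
    sig = [c for c in annotated if c.corrected_p < alpha]
    return sig, annotated, stats, null
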