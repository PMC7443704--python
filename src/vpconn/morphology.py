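"""Morphology similarity scoring, type clustering and compartment splitting.

Neurons are compared NBLAST-style: each skeleton is reduced to a cloud of
resampled points with local tangent vectors ("dotprops"), and a query is
scored against a target by summing, over query points, a kernel of the
nearest-target-point distance d and the absolute tangent alignment a.  The
default kernel is

    f(d, a) = exp(-d / sigma) * a,   sigma = 3000 nm,

which is smooth, has f(0, 1) = 1, and admits a closed-form oracle; published
tabulated (distance-bin x dot-bin) score tables can be supplied instead.
Scores are normalized by the query self-score and averaged forward/reverse,
giving a symmetric matrix with unit diagonal, which is then Ward-clustered on
the dissimilarity 1 - score and cut at a fixed dendrogram height to assign
morphological types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .core import Skeleton, Volume, points_in_volume

logger = logging.getLogger("vpconn")

DEFAULT_SIGMA_NM = 3000.0


class DegenerateMorphologyError(ValueError):
    """Skeleton too small to score (no edges, or zero self-similarity)."""


@dataclass
class DotProps:
    """Resampled point cloud with unit tangent vectors for one neuron."""

    points: np.ndarray            # (N, 3) nanometres
    tangents: np.ndarray          # (N, 3) unit vectors (sign meaningless)
    skeleton_id: str = ""
    resample_spacing: float = float("nan")

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.tangents = np.atleast_2d(np.asarray(self.tangents, float))
        if len(self.points) < 1 or self.points.shape != self.tangents.shape:
            raise DegenerateMorphologyError("empty or mismatched dotprops")
        norms = np.linalg.norm(self.tangents, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise DegenerateMorphologyError("tangents must be unit vectors")

    def mirrored(self, midline_x: float = 0.0) -> "DotProps":
        """Rigid sagittal reflection about the plane x = midline_x."""
        pts = self.points.copy()
        pts[:, 0] = 2.0 * midline_x - pts[:, 0]
        tg = self.tangents.copy()
        tg[:, 0] *= -1.0
        return DotProps(pts, tg, self.skeleton_id, self.resample_spacing)


def _segments(skeleton: Skeleton) -> list[list[int]]:
    """Unbranched node chains (root/branchpoint -> branchpoint/leaf)."""
    children = skeleton.children_map()
    root = skeleton.root
    breaks = {root} | {n for n, ch in children.items() if len(ch) > 1}
    segs = []
    for start in sorted(breaks):
        for ch in children[start]:
            seg = [start, ch]
            while len(children[seg[-1]]) == 1 and seg[-1] not in breaks:
                seg.append(children[seg[-1]][0])
            segs.append(seg)
    return segs


def to_dotprops(skeleton: Skeleton, spacing: float = 1000.0, k: int = 5) -> DotProps:
    """Resample a skeleton at fixed arclength spacing and attach tangents.

    The tangent at each resampled point is the first principal axis of its
    ``k`` nearest resampled neighbours (clamped to the cloud size); its sign
    is arbitrary and ignored downstream.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(skeleton.edges()) == 0:
        raise DegenerateMorphologyError(
            f"{skeleton.skeleton_id}: single-node skeleton has no morphology")
    pts = []
    for seg in _segments(skeleton):
        xyz = skeleton.coords(seg)
        d = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(d)])
        total = cum[-1]
        if total <= 0:
            pts.append(xyz[0])
            continue
        s = np.arange(0.0, total + spacing * 1e-9, spacing)
        if total - s[-1] > spacing * 1e-6:
            s = np.append(s, total)
        samp = np.column_stack([np.interp(s, cum, xyz[:, a]) for a in range(3)])
        pts.append(samp)
    cloud = np.vstack([np.atleast_2d(p) for p in pts])
    # dedupe points shared between adjoining segments (branchpoints)
    cloud = np.unique(np.round(cloud, 6), axis=0)
    n = len(cloud)
    kk = min(k, n)
    tree = cKDTree(cloud)
    _, idx = tree.query(cloud, k=kk)
    idx = np.atleast_2d(idx)
    tangents = np.empty_like(cloud)
    for i in range(n):
        nb = cloud[idx[i]]
        nb = nb - nb.mean(axis=0)
        if np.allclose(nb, 0.0):
            tangents[i] = (1.0, 0.0, 0.0)
            continue
        _, vecs = np.linalg.eigh(nb.T @ nb)
        tangents[i] = vecs[:, -1]
    return DotProps(cloud, tangents, skeleton.skeleton_id, spacing)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class ScoreTable:
    """Tabulated (distance-bin x |dot|-bin) scoring function.

    ``dist_edges`` (len D+1, nm) and ``dot_edges`` (len A+1, in [0, 1]) define
    the bins of ``values`` (D x A).  Out-of-range distances fall in the last
    bin.
    """

    dist_edges: np.ndarray
    dot_edges: np.ndarray
    values: np.ndarray

    def __call__(self, d: np.ndarray, a: np.ndarray) -> np.ndarray:
        di = np.clip(np.searchsorted(self.dist_edges, d, side="right") - 1,
                     0, self.values.shape[0] - 1)
        ai = np.clip(np.searchsorted(self.dot_edges, a, side="right") - 1,
                     0, self.values.shape[1] - 1)
        return self.values[di, ai]


def _kernel(d: np.ndarray, a: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-d / sigma) * a


def similarity(query: DotProps, target: DotProps, sigma: float = DEFAULT_SIGMA_NM,
               score_table: ScoreTable | None = None) -> float:
    """Raw directed similarity: sum over query points of f(d, a) at the
    nearest target point.  Nearest-neighbour ties resolve to the lowest
    target point index."""
    tree = cKDTree(target.points)
    d, idx = tree.query(query.points, k=1)
    a = np.abs(np.einsum("ij,ij->i", query.tangents, target.tangents[idx]))
    a = np.minimum(a, 1.0)
    if score_table is not None:
        return float(score_table(d, a).sum())
    return float(_kernel(d, a, sigma).sum())


def mean_normalized_score(q: DotProps, t: DotProps, sigma: float = DEFAULT_SIGMA_NM,
                          score_table: ScoreTable | None = None) -> float:
    """Self-normalized similarity, averaged forward and reverse; 1 at identity."""
    sqq = similarity(q, q, sigma, score_table)
    stt = similarity(t, t, sigma, score_table)
    if sqq == 0 or stt == 0:
        raise DegenerateMorphologyError("zero self-similarity")
    return 0.5 * (similarity(q, t, sigma, score_table) / sqq
                  + similarity(t, q, sigma, score_table) / stt)


def score_matrix(dotprops: dict[str, DotProps], sigma: float = DEFAULT_SIGMA_NM,
                 score_table: ScoreTable | None = None) -> pd.DataFrame:
    """All-by-all mean normalized scores; symmetric with unit diagonal."""
    ids = sorted(dotprops)
    m = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            s = mean_normalized_score(dotprops[a], dotprops[b], sigma, score_table)
            m.loc[a, b] = m.loc[b, a] = s
    return m


def read_score_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_score_matrix(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_types(scores: pd.DataFrame, cut_height: float = 0.8,
                  ) -> tuple[pd.Series, np.ndarray]:
    """Ward-cluster neurons on 1 - score and cut the dendrogram.

    Returns integer group labels per neuron id and the scipy linkage matrix.
    Scores are similarities in (-inf, 1]; the dissimilarity is clipped at 0.
    """
    arr = scores.to_numpy(float)
    if not np.isfinite(arr).all():
        raise ValueError("score matrix contains non-finite values")
    d = np.clip(1.0 - arr, 0.0, None)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    if len(scores) < 2:
        return pd.Series([1] * len(scores), index=scores.index, name="group"), \
            np.empty((0, 4))
    z = linkage(squareform(d, checks=False), method="ward")
    labels = fcluster(z, t=cut_height, criterion="distance")
    return pd.Series(labels, index=scores.index, name="group"), z


def linkage_to_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage dendrogram as a Newick string."""
    tree = to_tree(z)

    def rec(node) -> str:
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{node.dist:.6g}"
        return (f"({rec(node.left)},{rec(node.right)})"
                f":{node.dist:.6g}")

    return f"({rec(tree.left)},{rec(tree.right)});"


def match_contralateral(dotprops: dict[str, DotProps],
                        meta: dict, midline_x: float = 0.0,
                        sigma: float = DEFAULT_SIGMA_NM,
                        ) -> tuple[int, list[tuple[str, str]]]:
    """Count neurons whose best morphological match is their annotated
    contralateral partner, after rigidly mirroring one hemisphere.

    Left-hemisphere clouds are reflected about x = midline_x so all neurons
    live in one frame; a neuron "pairs" when its highest off-diagonal mean
    normalized score is its ``contralateral_partner``.  Neurons without a
    hemisphere label are excluded with a warning.
    """
    usable = {}
    for sid, dp in dotprops.items():
        m = meta.get(sid)
        hemi = getattr(m, "hemisphere", None) if m is not None else None
        if hemi not in ("R", "L"):
            logger.warning("match_contralateral: %s has no hemisphere; excluded", sid)
            continue
        usable[sid] = dp.mirrored(midline_x) if hemi == "L" else dp
    if not usable:
        return 0, []
    scores = score_matrix(usable, sigma)
    pairs = []
    for sid in scores.index:
        partner = getattr(meta.get(sid), "contralateral_partner", None)
        if partner is None or partner not in scores.columns:
            continue
        off = scores.loc[sid].drop(sid)
        if off.idxmax() == partner:
            pairs.append((sid, partner))
    return len(pairs), pairs


# ---------------------------------------------------------------------------
# Axon/dendrite splitting for Kenyon cells
# ---------------------------------------------------------------------------

def split_dendrites(kc_skeleton: Skeleton, calyx_volume: Volume) -> set[int]:
    """Flag the dendritic (claw) nodes of a KC inside the calyx.

    The main tract is the root-to-tip path maximizing total path length;
    dendrites are the nodes inside the calyx volume that lie on side branches
    off that path.  A KC that does not enter the calyx yields an empty set.
    """
    children = kc_skeleton.children_map()
    root = kc_skeleton.root
    coords = {int(n): kc_skeleton.coords([int(n)])[0] for n in kc_skeleton.nodes.index}
    # path length from root to every node (iterative DFS)
    dist = {root: 0.0}
    parent_of = {int(n): int(p) for n, p in
                 kc_skeleton.nodes["parent_id"].items() if p != -1}
    stack = [root]
    while stack:
        n = stack.pop()
        for ch in children[n]:
            dist[ch] = dist[n] + float(np.linalg.norm(coords[ch] - coords[n]))
            stack.append(ch)
    tip = max(dist, key=lambda n: dist[n])
    main_path = {tip}
    n = tip
    while n in parent_of:
        n = parent_of[n]
        main_path.add(n)
    inside = points_in_volume(np.array([coords[int(n)] for n in kc_skeleton.nodes.index]),
                              calyx_volume)
    inside_ids = {int(n) for n, i in zip(kc_skeleton.nodes.index, inside) if i}
    if not inside_ids:
        logger.warning("split_dendrites: %s does not intersect the calyx",
                       kc_skeleton.skeleton_id)
        return set()
    return inside_ids - main_path


def dendrite_branches(kc_skeleton: Skeleton, dendrite_nodes: set[int]) -> dict[int, set[int]]:
    """Group dendrite nodes into claws: connected components keyed by the
    branch root (the highest dendrite node of each side branch)."""
    parent_of = {int(n): int(p) for n, p in
                 kc_skeleton.nodes["parent_id"].items() if p != -1}
    out: dict[int, set[int]] = {}
    roots = {n for n in dendrite_nodes
             if parent_of.get(n) is None or parent_of[n] not in dendrite_nodes}
    for n in sorted(dendrite_nodes):
        m = n
        while parent_of.get(m) in dendrite_nodes:
            m = parent_of[m]
        out.setdefault(m, set()).add(n)
    for r in roots:
        out.setdefault(r, set()).add(r)
    return out
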