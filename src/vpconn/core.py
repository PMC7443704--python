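"""Domain types and I/O for sparse EM connectome data.

The data model follows the CATMAID-style representation used for manual
reconstruction in whole-brain EM volumes: neurons are rooted skeleton trees of
3-D nodes, and chemical synapses are *connectors* -- each continuous synaptic
cleft is one presynapse, and every opposing membrane in contact with that cleft
is one associated postsynapse.  Connectors are therefore polyadic: one
presynaptic link, one or more postsynaptic links.  Per-edge synaptic counts are
always derived from connectors, never stored.

All internal coordinates are nanometres (the FAFB convention).  Skeleton and
connector identifiers are opaque strings; SWC node identifiers are integers as
the format requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("vpconn")

NEURON_CLASSES = ("RN", "PN", "KC", "LHN", "DN", "other")

SYNAPSE_COLUMNS = [
    "connector_id", "x", "y", "z",
    "pre_skeleton", "pre_node", "post_skeleton", "post_node",
]

META_COLUMNS = [
    "skeleton_id", "neuron_class", "type_label", "hemisphere",
    "glomeruli", "lineage", "contralateral_partner",
]


class MalformedSkeletonError(ValueError):
    """Skeleton file or node table violates the rooted-tree contract."""


class MalformedSynapseError(ValueError):
    """Synapse table violates the one-pre/many-post connector contract."""


class InvalidVolumeError(ValueError):
    """Volume geometry is degenerate or not a closed surface."""


# ---------------------------------------------------------------------------
# Skeletons
# ---------------------------------------------------------------------------

@dataclass
class Skeleton:
    """A neuron morphology: a rooted tree of 3-D nodes with radii.

    ``nodes`` is indexed by integer node id with columns ``parent_id`` (-1 for
    the root), ``x``, ``y``, ``z`` (nanometres) and ``radius``.
    """

    skeleton_id: str
    nodes: pd.DataFrame
    soma_node: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nd = self.nodes
        if len(nd) == 0:
            raise MalformedSkeletonError(f"{self.skeleton_id}: empty skeleton")
        if not np.isfinite(nd[["x", "y", "z"]].to_numpy()).all():
            raise MalformedSkeletonError(f"{self.skeleton_id}: non-finite coordinates")
        roots = nd.index[nd["parent_id"] == -1]
        if len(roots) != 1:
            raise MalformedSkeletonError(
                f"{self.skeleton_id}: expected exactly one root, found {len(roots)}")
        parent_of = dict(zip(nd.index.to_numpy(), nd["parent_id"].to_numpy()))
        bad = [p for p in parent_of.values() if p != -1 and p not in parent_of]
        if bad:
            raise MalformedSkeletonError(
                f"{self.skeleton_id}: unresolved parent ids {sorted(set(bad))[:5]}")
        # parent pointers + single root + all-resolved: a cycle would be a set
        # of nodes from which the root is unreachable by parent ascent.
        reached: set[int] = {int(roots[0])}
        for nid in parent_of:
            chain = []
            n = int(nid)
            while n not in reached:
                chain.append(n)
                n = int(parent_of[n])
                if n in chain:
                    raise MalformedSkeletonError(f"{self.skeleton_id}: cycle at node {n}")
            reached.update(chain)

    @property
    def root(self) -> int:
        return int(self.nodes.index[self.nodes["parent_id"] == -1][0])

    def edges(self) -> np.ndarray:
        """(E, 2) array of (child, parent) node ids, root edge excluded."""
        nd = self.nodes
        child = nd.index[nd["parent_id"] != -1].to_numpy()
        parent = nd.loc[child, "parent_id"].to_numpy()
        return np.column_stack([child, parent]).astype(int)

    def coords(self, node_ids: Sequence[int] | None = None) -> np.ndarray:
        nd = self.nodes if node_ids is None else self.nodes.loc[list(node_ids)]
        return nd[["x", "y", "z"]].to_numpy(float)

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {int(n): [] for n in self.nodes.index}
        for child, parent in self.edges():
            out[int(parent)].append(int(child))
        return out


def read_swc(path: str | Path, unit_scale: float = 1000.0,
             skeleton_id: str | None = None) -> Skeleton:
    """Read a 7-column SWC file.

    SWC files conventionally carry micrometres; the default ``unit_scale`` of
    1000 converts to the internal nanometre frame.  Structure code 1 marks the
    soma node.
    """
    path = Path(path)
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise MalformedSkeletonError(f"{path}: bad SWC row {line!r}")
        rows.append(parts)
    if not rows:
        raise MalformedSkeletonError(f"{path}: no nodes")
    arr = pd.DataFrame(rows, columns=["id", "structure", "x", "y", "z", "radius", "parent"])
    nodes = pd.DataFrame({
        "parent_id": arr["parent"].astype(int).to_numpy(),
        "x": arr["x"].astype(float).to_numpy() * unit_scale,
        "y": arr["y"].astype(float).to_numpy() * unit_scale,
        "z": arr["z"].astype(float).to_numpy() * unit_scale,
        "radius": arr["radius"].astype(float).to_numpy() * unit_scale,
    }, index=pd.Index(arr["id"].astype(int), name="node_id"))
    if nodes.index.has_duplicates:
        raise MalformedSkeletonError(f"{path}: duplicate node ids")
    soma = arr.loc[arr["structure"].astype(int) == 1, "id"]
    soma_node = int(soma.iloc[0]) if len(soma) else None
    return Skeleton(skeleton_id or path.stem, nodes, soma_node)


def write_swc(skeleton: Skeleton, path: str | Path, unit_scale: float = 1000.0) -> None:
    """Write SWC; coordinates are divided by ``unit_scale`` on the way out."""
    lines = ["# id structure x y z radius parent"]
    for nid, row in skeleton.nodes.iterrows():
        struct = 1 if nid == skeleton.soma_node else 0
        lines.append(
            f"{int(nid)} {struct} {row.x / unit_scale:.17g} {row.y / unit_scale:.17g} "
            f"{row.z / unit_scale:.17g} {row.radius / unit_scale:.17g} {int(row.parent_id)}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Connectors (polyadic synapses)
# ---------------------------------------------------------------------------

@dataclass
class Connector:
    """One presynaptic site and its set of postsynaptic links."""

    connector_id: str
    location: np.ndarray            # (3,) nanometres
    pre: tuple[str, int]            # (skeleton_id, node_id)
    posts: list[tuple[str, int]]    # >= 1 (skeleton_id, node_id) links

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, float)
        if self.location.shape != (3,):
            raise MalformedSynapseError(f"{self.connector_id}: bad location")
        if not self.posts:
            raise MalformedSynapseError(f"{self.connector_id}: no postsynaptic links")
        if len(set(self.posts)) != len(self.posts):
            raise MalformedSynapseError(
                f"{self.connector_id}: duplicate postsynaptic link")


def read_synapse_table(path: str | Path) -> dict[str, Connector]:
    """Read a connector table (one row per (connector, postsynaptic link)).

    Rows sharing a ``connector_id`` merge into one polyadic :class:`Connector`;
    their presynaptic fields must agree.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"connector_id": str, "pre_skeleton": str,
                            "post_skeleton": str})
    missing = [c for c in SYNAPSE_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedSynapseError(f"{path}: missing columns {missing}")
    out: dict[str, Connector] = {}
    for cid, grp in df.groupby("connector_id", sort=True):
        pre = grp[["pre_skeleton", "pre_node", "x", "y", "z"]].drop_duplicates()
        if len(pre) != 1:
            raise MalformedSynapseError(f"connector {cid}: conflicting presynaptic links")
        row = pre.iloc[0]
        posts = [(str(s), int(n)) for s, n in
                 zip(grp["post_skeleton"], grp["post_node"])]
        out[str(cid)] = Connector(str(cid), np.array([row.x, row.y, row.z], float),
                                  (str(row.pre_skeleton), int(row.pre_node)), posts)
    return out


def write_synapse_table(connectors: Mapping[str, Connector], path: str | Path) -> None:
    rows = []
    for cid in sorted(connectors):
        c = connectors[cid]
        for ps, pn in c.posts:
            rows.append((c.connector_id, c.location[0], c.location[1], c.location[2],
                         c.pre[0], c.pre[1], ps, pn))
    pd.DataFrame(rows, columns=SYNAPSE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Neuron metadata
# ---------------------------------------------------------------------------

@dataclass
class NeuronMeta:
    """Class/type/side labels for one reconstructed neuron.

    ``glomeruli`` is ordered; the first entry is the primary glomerulus (the
    one the neuron innervates more than any other).
    """

    skeleton_id: str
    neuron_class: str = "other"
    type_label: str = ""
    hemisphere: str | None = None       # "R" or "L"
    glomeruli: tuple[str, ...] = ()
    lineage: str | None = None
    contralateral_partner: str | None = None

    def __post_init__(self) -> None:
        if self.neuron_class not in NEURON_CLASSES:
            raise ValueError(f"unknown neuron class {self.neuron_class!r}")
        if self.hemisphere not in (None, "R", "L"):
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")
        self.glomeruli = tuple(self.glomeruli)


def read_meta_table(path: str | Path) -> dict[str, NeuronMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = {}
    for _, r in df.iterrows():
        out[r.skeleton_id] = NeuronMeta(
            skeleton_id=r.skeleton_id,
            neuron_class=r.neuron_class or "other",
            type_label=r.type_label,
            hemisphere=r.hemisphere or None,
            glomeruli=tuple(g for g in r.glomeruli.split(";") if g),
            lineage=r.lineage or None,
            contralateral_partner=r.contralateral_partner or None,
        )
    return out


def write_meta_table(meta: Mapping[str, NeuronMeta], path: str | Path) -> None:
    rows = []
    for sid in sorted(meta):
        m = meta[sid]
        rows.append((m.skeleton_id, m.neuron_class, m.type_label, m.hemisphere or "",
                     ";".join(m.glomeruli), m.lineage or "",
                     m.contralateral_partner or ""))
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

@dataclass
class BoxVolume:
    """Axis-aligned box; the boundary counts as inside."""

    name: str
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, float)
        self.hi = np.asarray(self.hi, float)
        if self.lo.shape != (3,) or self.hi.shape != (3,):
            raise InvalidVolumeError(f"{self.name}: corners must be 3-vectors")
        if np.any(self.lo > self.hi):
            raise InvalidVolumeError(f"{self.name}: corners not ordered min<=max")


@dataclass
class MeshVolume:
    """Closed triangle mesh; containment by generalized winding number."""

    name: str
    vertices: np.ndarray   # (V, 3)
    faces: np.ndarray      # (F, 3) integer

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.faces = np.asarray(self.faces, int)
        if len(self.faces) == 0 or len(self.vertices) < 4:
            raise InvalidVolumeError(f"{self.name}: degenerate mesh")
        # closed + orientable: every undirected edge shared by exactly two
        # faces, once in each direction
        directed: dict[tuple[int, int], int] = {}
        for f in self.faces:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                directed[(int(a), int(b))] = directed.get((int(a), int(b)), 0) + 1
        for (a, b), n in directed.items():
            if n != 1 or directed.get((b, a), 0) != 1:
                raise InvalidVolumeError(f"{self.name}: mesh not closed/orientable")


Volume = BoxVolume | MeshVolume


def read_obj_volume(path: str | Path, name: str | None = None) -> MeshVolume:
    """Load a triangle mesh volume from a Wavefront OBJ file."""
    import trimesh
    mesh = trimesh.load_mesh(str(path), file_type="obj", process=False)
    return MeshVolume(name or Path(path).stem,
                      np.asarray(mesh.vertices, float), np.asarray(mesh.faces, int))


def _winding_numbers(points: np.ndarray, vol: MeshVolume) -> np.ndarray:
    """Generalized winding number of each point w.r.t. the closed mesh.

    Sums the signed solid angle of every triangle (van Oosterom & Strackee)
    and divides by 4*pi: ~1 inside, ~0 outside, ~0.5 on the surface.
    """
    tri = vol.vertices[vol.faces]                       # (F, 3, 3)
    w = np.zeros(len(points))
    for i, p in enumerate(points):
        a = tri[:, 0] - p
        b = tri[:, 1] - p
        c = tri[:, 2] - p
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(c, axis=1)
        num = np.einsum("ij,ij->i", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("ij,ij->i", a, b) * lc
               + np.einsum("ij,ij->i", b, c) * la
               + np.einsum("ij,ij->i", a, c) * lb)
        w[i] = np.arctan2(num, den).sum() / (2.0 * np.pi)
    return w


def points_in_volume(points: np.ndarray, volume: Volume) -> np.ndarray:
    """Vectorized membership test; boundary points count as inside."""
    points = np.atleast_2d(np.asarray(points, float))
    if not np.isfinite(points).all():
        raise ValueError("points must be finite")
    if isinstance(volume, BoxVolume):
        return np.all((points >= volume.lo) & (points <= volume.hi), axis=1)
    return _winding_numbers(points, volume) >= 0.5 - 1e-9


def point_in_volume(point: Sequence[float], volume: Volume) -> bool:
    return bool(points_in_volume(np.asarray(point, float)[None, :], volume)[0])


def cable_length_in_volume(skeleton: Skeleton, volume: Volume | None = None) -> float:
    """Total parent-child Euclidean cable, optionally volume-restricted.

    An edge contributes only when BOTH endpoints lie inside the volume; traced
    skeletons are bookkept at node resolution, so no edge clipping is done.
    """
    e = skeleton.edges()
    if len(e) == 0:
        return 0.0
    pa = skeleton.coords(e[:, 0])
    pb = skeleton.coords(e[:, 1])
    lengths = np.linalg.norm(pa - pb, axis=1)
    if volume is None:
        return float(lengths.sum())
    ina = points_in_volume(pa, volume)
    inb = points_in_volume(pb, volume)
    return float(lengths[ina & inb].sum())


# ---------------------------------------------------------------------------
# Connectome container
# ---------------------------------------------------------------------------

@dataclass
class Connectome:
    """All reconstructed data for one analysis: skeletons, connectors,
    metadata, named volumes, and optional bouton/claw annotation tables."""

    skeletons: dict[str, Skeleton] = field(default_factory=dict)
    connectors: dict[str, Connector] = field(default_factory=dict)
    meta: dict[str, NeuronMeta] = field(default_factory=dict)
    volumes: dict[str, Volume] = field(default_factory=dict)
    boutons: dict[str, int] = field(default_factory=dict)       # pn skid -> count
    claws: dict[str, list[int]] = field(default_factory=dict)   # kc skid -> branch roots

    def validate(self) -> None:
        known = set(self.skeletons)
        for c in self.connectors.values():
            if c.pre[0] not in known:
                raise MalformedSynapseError(
                    f"connector {c.connector_id}: unknown presynaptic skeleton {c.pre[0]}")
            for ps, _ in c.posts:
                if ps not in known:
                    raise MalformedSynapseError(
                        f"connector {c.connector_id}: unknown postsynaptic skeleton {ps}")
        for sid in list(self.boutons) + list(self.claws):
            if sid not in known:
                raise ValueError(f"annotation references unknown neuron {sid}")

    def class_of(self, skeleton_id: str) -> str:
        m = self.meta.get(skeleton_id)
        return m.type_label if m is not None and m.type_label else "unknown"


def write_connectome(conn: Connectome, outdir: str | Path) -> None:
    """Write a connectome as plain-text files (SWC dir + TSV tables + YAML)."""
    import yaml
    outdir = Path(outdir)
    swcdir = outdir / "skeletons"
    swcdir.mkdir(parents=True, exist_ok=True)
    # connectome bundles keep SWC in nanometres (unit_scale 1) so that the
    # write/read roundtrip is bit-exact
    for sid in sorted(conn.skeletons):
        write_swc(conn.skeletons[sid], swcdir / f"{sid}.swc", unit_scale=1.0)
    write_synapse_table(conn.connectors, outdir / "synapses.tsv")
    write_meta_table(conn.meta, outdir / "meta.tsv")
    vols = {}
    for name in sorted(conn.volumes):
        v = conn.volumes[name]
        if isinstance(v, BoxVolume):
            vols[name] = {"box": {"lo": [float(x) for x in v.lo],
                                  "hi": [float(x) for x in v.hi]}}
        else:
            vols[name] = {"mesh": {"vertices": v.vertices.tolist(),
                                   "faces": v.faces.tolist()}}
    (outdir / "volumes.yaml").write_text(yaml.safe_dump(vols, sort_keys=True))
    pd.DataFrame(sorted(conn.boutons.items()), columns=["skeleton_id", "boutons"]) \
        .to_csv(outdir / "boutons.tsv", sep="\t", index=False)
    rows = [(k, ";".join(map(str, v))) for k, v in sorted(conn.claws.items())]
    pd.DataFrame(rows, columns=["skeleton_id", "branch_roots"]) \
        .to_csv(outdir / "claws.tsv", sep="\t", index=False)


def read_connectome(indir: str | Path) -> Connectome:
    import yaml
    indir = Path(indir)
    conn = Connectome()
    for swc in sorted((indir / "skeletons").glob("*.swc")):
        sk = read_swc(swc, unit_scale=1.0)
        conn.skeletons[sk.skeleton_id] = sk
    conn.connectors = read_synapse_table(indir / "synapses.tsv")
    conn.meta = read_meta_table(indir / "meta.tsv")
    for name, spec in (yaml.safe_load((indir / "volumes.yaml").read_text()) or {}).items():
        if "box" in spec:
            conn.volumes[name] = BoxVolume(name, spec["box"]["lo"], spec["box"]["hi"])
        else:
            conn.volumes[name] = MeshVolume(name, np.array(spec["mesh"]["vertices"]),
                                            np.array(spec["mesh"]["faces"]))
    bt = pd.read_csv(indir / "boutons.tsv", sep="\t", dtype={"skeleton_id": str})
    conn.boutons = dict(zip(bt.skeleton_id, bt.boutons.astype(int)))
    cl = pd.read_csv(indir / "claws.tsv", sep="\t", dtype=str).fillna("")
    conn.claws = {r.skeleton_id: [int(x) for x in r.branch_roots.split(";") if x]
                  for _, r in cl.iterrows()}
    conn.validate()
    return conn
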