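"""Synthetic connectome generator.

Builds small connectomes with the statistical structure the downstream
analyses assume, so that every pipeline stage can be exercised and validated
against known ground truth without any EM data:

* ~7 ventroposterior (VP) glomeruli with per-hemisphere receptor-neuron (RN)
  counts on the scale reported for the fly antennal lobe;
* projection neurons (PNs) whose dendrites occupy glomerulus envelopes and
  whose axons visit higher neuropils (lACA, calyx, lateral horn);
* an lACA volume in which two designated "query" PNs supply the dominant
  share of PN presynapses (default 92%);
* a long-tailed partner-degree distribution downstream of the query PNs,
  planted exactly so sampling runs can be scored against truth;
* Kenyon cells (KCs) with claw-structured dendrites in the calyx whose inputs
  are drawn from PN bouton shares (optionally bias-multiplied).

Skeletons are biased random walks, not biologically realistic arbors.
Members of one morphological type are jittered copies of a shared prototype,
which gives the geometric separation the morphology stage needs; the type
structure, not the geometry, is the object under test.

Everything is driven by integer-seeded numpy generators (one spawned stream
per stage) so a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import (BoxVolume, Connectome, Connector, NeuronMeta, Skeleton,
                   cable_length_in_volume)


class ConfigError(ValueError):
    """Synthetic-generator configuration is infeasible or inconsistent."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

# Per-hemisphere RN counts per glomerulus, matching the reconstructed census
# scale (VP4 RNs are bilateral, 14 per side; VP1d pairs with VP5 counts).
DEFAULT_RN_COUNTS: dict[str, dict[str, int]] = {
    "VP1d": {"R": 9, "L": 7},
    "VP1l": {"R": 7, "L": 7},
    "VP1m": {"R": 7, "L": 7},
    "VP2": {"R": 3, "L": 4},
    "VP3": {"R": 4, "L": 5},
    "VP4": {"R": 14, "L": 14},
    "VP5": {"R": 9, "L": 7},
    "VC5": {"R": 8, "L": 8},
}

# Calyx bouton counts per PN class: olfactory classes carry most boutons,
# thermo/hygrosensory classes few -- the share vector the KC null model draws
# from.
DEFAULT_BOUTON_COUNTS: dict[str, int] = {
    "DM1 adPN": 100,
    "DP1m adPN": 80,
    "DA2 lPN": 60,
    "VA2 adPN": 60,
    "VC5+ adPN": 30,
    "VP1m+VP5 ilPN": 25,
    "VP3+ l2PN1": 20,
    "VP2 adPN": 10,
}

DEFAULT_VALENCES: dict[str, str] = {
    "DM1 adPN": "attractive",
    "VA2 adPN": "attractive",
    "DA2 lPN": "aversive",
    "DP1m adPN": "aversive",
    "VC5+ adPN": "unknown",
    "VP1m+VP5 ilPN": "unknown",
    "VP3+ l2PN1": "unknown",
    "VP2 adPN": "unknown",
}

GLOMERULI = ("VP1d", "VP1l", "VP1m", "VP2", "VP3", "VP4", "VP5", "VC5")


@dataclass
class PNSpec:
    """One PN morphological type for the generator."""

    type_label: str
    glomeruli: tuple[str, ...]
    targets: dict[str, int]        # volume base name -> presynapse budget
    is_query: bool = False
    bilateral: bool = True
    count: int = 1                 # members per hemisphere

    def __post_init__(self) -> None:
        self.glomeruli = tuple(self.glomeruli)


def default_pn_specs() -> list[PNSpec]:
    """The lACA-workflow PN population: two dominant query PNs plus the other
    conserved lACA-innervating types."""
    return [
        PNSpec("VP3 vPN", ("VP3",), {"lACA": 60, "CA": 15, "LH": 15}, is_query=True),
        PNSpec("VP2 adPN", ("VP2",), {"lACA": 40, "CA": 15, "LH": 15}, is_query=True),
        PNSpec("VP2+ adPN", ("VP2", "VC5"), {"lACA": 4, "CA": 15}),
        PNSpec("VP1m+VP5 ilPN", ("VP1m", "VP5"), {"lACA": 2, "CA": 20}),
        PNSpec("VP1m+VP2 lvPN1", ("VP1m", "VP2"), {"lACA": 2, "CA": 20, "LH": 10}),
        PNSpec("VC5+ adPN", ("VC5",), {"lACA": 1, "CA": 20}),
    ]


@dataclass
class SynthConfig:
    seed: int = 0
    rn_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {g: dict(c) for g, c in DEFAULT_RN_COUNTS.items()})
    pn_specs: list[PNSpec] = field(default_factory=default_pn_specs)
    laca_dominance: float = 0.92
    # (number of partners, connections each): long-tailed degree distribution
    # downstream of each query PN in the lACA
    partner_degrees: list[tuple[int, int]] = field(
        default_factory=lambda: [(3, 20), (2, 8), (200, 1)])
    n_kcs: int = 27
    claws_per_kc: int = 5
    inputs_per_claw: int = 1
    bouton_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BOUTON_COUNTS))
    bias: dict[str, float] | None = None
    noise: float = 100.0            # coordinate jitter sigma, nm
    rn_input_rate: float = 5e-4     # RN synapses per nm of PN dendrite cable
    min_syn: int = 5                # synapses per planted claw input

    def validate(self) -> None:
        if not (0.0 < self.laca_dominance <= 1.0):
            raise ConfigError("laca_dominance must be in (0, 1]")
        if any(n < 0 for c in self.rn_counts.values() for n in c.values()):
            raise ConfigError("negative RN count")
        if any(n < 0 or c < 0 for n, c in self.partner_degrees):
            raise ConfigError("negative partner degree entry")
        if self.n_kcs < 0 or self.inputs_per_claw < 0:
            raise ConfigError("negative KC spec entry")
        if self.n_kcs > 0 and self.claws_per_kc <= 0:
            raise ConfigError("KCs require at least one claw each")
        if any(b < 0 for b in self.bouton_counts.values()):
            raise ConfigError("negative bouton count")
        if (self.n_kcs * self.claws_per_kc * self.inputs_per_claw > 0
                and sum(self.bouton_counts.values()) == 0):
            raise ConfigError("claw inputs requested but all bouton counts are zero")
        if self.noise < 0:
            raise ConfigError("noise sigma must be >= 0")
        if not self.pn_specs and self.partner_degrees and any(
                n * c > 0 for n, c in self.partner_degrees):
            raise ConfigError("partner degrees given but no query PN specs")


def make_clustering_config(n_types: int = 2, members_per_type: int = 3,
                           seed: int = 0, noise: float = 300.0) -> SynthConfig:
    """Config for morphology-typing tests: each type is a jittered prototype
    confined to its own glomerulus envelope, with no shared axon targets, no
    lACA wiring and no KC population."""
    if n_types > len(GLOMERULI):
        raise ConfigError(f"at most {len(GLOMERULI)} well-separated envelopes")
    specs = [PNSpec(f"type{i} PN", (GLOMERULI[i],), {}, bilateral=False,
                    count=members_per_type) for i in range(n_types)]
    return SynthConfig(seed=seed, rn_counts={}, pn_specs=specs,
                       partner_degrees=[], n_kcs=0, inputs_per_claw=0,
                       bouton_counts={}, noise=noise, rn_input_rate=0.0)


def config_from_yaml(path: str | Path) -> SynthConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "pn_specs" in raw:
        raw["pn_specs"] = [PNSpec(type_label=s["type_label"],
                                  glomeruli=tuple(s["glomeruli"]),
                                  targets=dict(s.get("targets", {})),
                                  is_query=bool(s.get("is_query", False)),
                                  bilateral=bool(s.get("bilateral", True)),
                                  count=int(s.get("count", 1)))
                           for s in raw["pn_specs"]]
    if "partner_degrees" in raw:
        raw["partner_degrees"] = [tuple(x) for x in raw["partner_degrees"]]
    return SynthConfig(**raw)


def config_to_yaml(config: SynthConfig, path: str | Path) -> None:
    d = {
        "seed": config.seed,
        "rn_counts": config.rn_counts,
        "pn_specs": [{"type_label": s.type_label, "glomeruli": list(s.glomeruli),
                      "targets": s.targets, "is_query": s.is_query,
                      "bilateral": s.bilateral, "count": s.count}
                     for s in config.pn_specs],
        "laca_dominance": config.laca_dominance,
        "partner_degrees": [list(x) for x in config.partner_degrees],
        "n_kcs": config.n_kcs,
        "claws_per_kc": config.claws_per_kc,
        "inputs_per_claw": config.inputs_per_claw,
        "bouton_counts": config.bouton_counts,
        "bias": config.bias,
        "noise": config.noise,
        "rn_input_rate": config.rn_input_rate,
        "min_syn": config.min_syn,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# Geometry: synthetic brain layout (nanometres; midline at x = 0)
# ---------------------------------------------------------------------------

_AL_BOX = (np.array([20e3, 0.0, 0.0]), np.array([100e3, 80e3, 80e3]))
_NEUROPIL_BOXES = {
    "lACA": (np.array([120e3, 90e3, 40e3]), np.array([160e3, 130e3, 80e3])),
    "CA": (np.array([120e3, 140e3, 40e3]), np.array([200e3, 220e3, 120e3])),
    "LH": (np.array([210e3, 90e3, 40e3]), np.array([260e3, 140e3, 100e3])),
}


def _mirror_box(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo2 = lo.copy(); hi2 = hi.copy()
    lo2[0], hi2[0] = -hi[0], -lo[0]
    return lo2, hi2


def make_volumes() -> dict[str, BoxVolume]:
    """Named neuropil and glomerulus boxes for both hemispheres."""
    vols: dict[str, BoxVolume] = {}
    for base, (lo, hi) in {"AL": _AL_BOX, **_NEUROPIL_BOXES}.items():
        vols[f"{base}_R"] = BoxVolume(f"{base}_R", lo, hi)
        llo, lhi = _mirror_box(lo, hi)
        vols[f"{base}_L"] = BoxVolume(f"{base}_L", llo, lhi)
    # glomeruli: the 8 octants of the AL box, shrunk for clear separation
    lo, hi = _AL_BOX
    half = (hi - lo) / 2.0
    for i, g in enumerate(GLOMERULI):
        off = np.array([(i >> 2) & 1, (i >> 1) & 1, i & 1], float)
        glo = lo + off * half + 0.1 * half
        ghi = lo + (off + 1) * half - 0.1 * half
        vols[f"glom_{g}_R"] = BoxVolume(f"glom_{g}_R", glo, ghi)
        llo, lhi = _mirror_box(glo, ghi)
        vols[f"glom_{g}_L"] = BoxVolume(f"glom_{g}_L", llo, lhi)
    return vols


def _walk(rng: np.random.Generator, start: np.ndarray, box: BoxVolume,
          n: int, step: float) -> np.ndarray:
    """Biased random walk of ``n`` points inside a box, step length ``step``."""
    pts = np.empty((n, 3))
    pts[0] = np.clip(start, box.lo, box.hi)
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    for i in range(1, n):
        d = 0.7 * d + 0.6 * rng.standard_normal(3)
        d /= max(np.linalg.norm(d), 1e-12)
        p = pts[i - 1] + d * step
        p = np.clip(p, box.lo, box.hi)
        pts[i] = p
    return pts


def _line(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return a[None, :] * (1 - t) + b[None, :] * t


class _SkelBuilder:
    """Assemble a rooted tree skeleton from point paths."""

    def __init__(self) -> None:
        self.points: list[np.ndarray] = []
        self.parents: list[int] = []

    def add_path(self, pts: np.ndarray, parent: int = -1) -> list[int]:
        """Append a polyline; ``parent`` is the 0-based index it attaches to
        (-1 starts the root).  Returns the new 0-based indices."""
        idx = []
        for p in np.atleast_2d(pts):
            i = len(self.points)
            self.points.append(np.asarray(p, float))
            self.parents.append(parent)
            parent = i
            idx.append(i)
        return idx

    def build(self, skeleton_id: str, soma: int | None = 0,
              radius: float = 40.0) -> Skeleton:
        n = len(self.points)
        nodes = pd.DataFrame({
            "parent_id": [p + 1 if p >= 0 else -1 for p in self.parents],
            "x": [p[0] for p in self.points],
            "y": [p[1] for p in self.points],
            "z": [p[2] for p in self.points],
            "radius": [radius] * n,
        }, index=pd.Index(range(1, n + 1), name="node_id"))
        return Skeleton(skeleton_id, nodes,
                        soma_node=None if soma is None else soma + 1)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Sidecar truth tables for parameter-recovery tests."""

    queries: list[str]
    partner_degrees: dict[str, dict[str, int]]   # query -> partner -> count (lACA)
    claw_draws: pd.DataFrame                     # kc, claw, pn_class
    shares: pd.Series                            # effective class share vector
    type_labels: dict[str, str]
    laca_volume: str = "lACA_R"
    calyx_volume: str = "CA_R"


def effective_shares(bouton_counts: Mapping[str, int],
                     bias: Mapping[str, float] | None = None) -> pd.Series:
    """Bouton counts -> class probabilities, after multiplicative bias."""
    s = pd.Series({c: float(n) for c, n in bouton_counts.items()}).sort_index()
    if bias:
        for c, f in bias.items():
            if c in s.index:
                s[c] *= f
    tot = s.sum()
    if tot <= 0:
        raise ConfigError("all-zero bouton counts")
    return s / tot


def generate_kc_population(config: SynthConfig,
                           rng: np.random.Generator | None = None,
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Draw the per-claw PN-class inputs for a virtual KC population.

    Returns the draws as a long table (kc, claw, pn_class) together with the
    effective share vector they were drawn from (the ground truth).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    shares = effective_shares(config.bouton_counts, config.bias)
    classes = list(shares.index)
    rows = []
    for k in range(config.n_kcs):
        kc = f"kc_{k:03d}"
        for c in range(config.claws_per_kc):
            claw = f"claw_{c}"
            for _ in range(config.inputs_per_claw):
                cls = classes[rng.choice(len(classes), p=shares.to_numpy())]
                rows.append((kc, claw, cls))
    return pd.DataFrame(rows, columns=["kc", "claw", "pn_class"]), shares


def generate_connectome(config: SynthConfig) -> tuple[Connectome, GroundTruth]:
    """Build a full synthetic connectome plus its ground-truth sidecars."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_skel = np.random.default_rng(streams[0])
    rng_wire = np.random.default_rng(streams[1])
    rng_rn = np.random.default_rng(streams[2])
    rng_kc = np.random.default_rng(streams[3])
    rng_claw = np.random.default_rng(streams[4])

    conn = Connectome(volumes=make_volumes())
    type_labels: dict[str, str] = {}
    cid_counter = [0]

    def put(pre: tuple[str, int], posts: list[tuple[str, int]],
            loc: np.ndarray) -> None:
        cid_counter[0] += 1
        cid = f"c{cid_counter[0]:06d}"
        conn.connectors[cid] = Connector(cid, np.asarray(loc, float), pre, list(posts))

    # ---- receptor neurons -------------------------------------------------
    rns_by_glom: dict[tuple[str, str], list[str]] = {}
    for glom in sorted(config.rn_counts):
        for side in ("R", "L"):
            box = conn.volumes[f"glom_{glom}_{side}"]
            ids = []
            for i in range(config.rn_counts[glom].get(side, 0)):
                sid = f"rn_{glom}_{side}_{i:02d}"
                start = box.lo + (box.hi - box.lo) * rng_skel.uniform(0.2, 0.8, 3)
                b = _SkelBuilder()
                b.add_path(_walk(rng_skel, start, box, 25, 2500.0))
                conn.skeletons[sid] = b.build(sid)
                conn.meta[sid] = NeuronMeta(sid, "RN", f"{glom} RN", side, (glom,))
                type_labels[sid] = f"{glom} RN"
                ids.append(sid)
            rns_by_glom[(glom, side)] = ids

    # ---- projection neurons (prototype + jittered members, mirrored L) ----
    pn_members: dict[str, list[str]] = {}
    queries: list[str] = []
    pn_glom_nodes: dict[str, dict[str, list[int]]] = {}   # pn -> glom -> node ids
    pn_vol_nodes: dict[str, dict[str, list[int]]] = {}    # pn -> volume base -> node ids

    for spec in config.pn_specs:
        # prototype built once (RHS frame), members are jittered copies
        b = _SkelBuilder()
        glom_idx: dict[str, list[int]] = {}
        vol_idx: dict[str, list[int]] = {}
        soma = np.array([15e3, 40e3, 40e3])
        b.add_path(soma[None, :])
        attach = 0
        for g in spec.glomeruli:
            box = conn.volumes[f"glom_{g}_R"]
            start = box.lo + (box.hi - box.lo) * rng_skel.uniform(0.25, 0.75, 3)
            n = int(rng_skel.integers(20, 35))
            idx = b.add_path(_walk(rng_skel, start, box, n, 2200.0), parent=attach)
            glom_idx[g] = idx
        prev = attach
        cursor = soma
        for base in spec.targets:
            box = conn.volumes[f"{base}_R"]
            entry = (box.lo + box.hi) / 2.0
            link = b.add_path(_line(cursor, entry, 6)[1:], parent=prev)
            inner = b.add_path(_walk(rng_skel, entry, box, 15, 3000.0), parent=link[-1])
            vol_idx[base] = inner
            prev, cursor = inner[-1], b.points[inner[-1]]
        proto_pts = np.array(b.points)

        for side in (("R", "L") if spec.bilateral else ("R",)):
            for m in range(spec.count):
                label = spec.type_label if spec.count == 1 else f"{spec.type_label}#{m + 1}"
                sid = f"pn_{spec.type_label.replace(' ', '_').replace('+', 'p')}_{side}_{m}"
                pts = proto_pts + rng_skel.normal(0.0, max(config.noise, 1.0),
                                                  proto_pts.shape)
                if side == "L":
                    pts = pts.copy()
                    pts[:, 0] *= -1.0
                bb = _SkelBuilder()
                for p, parent in zip(pts, b.parents):
                    bb.add_path(p[None, :], parent=parent)
                conn.skeletons[sid] = bb.build(sid)
                conn.meta[sid] = NeuronMeta(sid, "PN", label, side, spec.glomeruli)
                # ground truth records the type, not the numbered individual
                type_labels[sid] = spec.type_label
                pn_members.setdefault(spec.type_label, []).append(sid)
                pn_glom_nodes[sid] = {g: [i + 1 for i in ix] for g, ix in glom_idx.items()}
                pn_vol_nodes[sid] = {v: [i + 1 for i in ix] for v, ix in vol_idx.items()}
                if spec.is_query and side == "R" and m == 0:
                    queries.append(sid)
        # annotate contralateral partners for unique bilateral members
        if spec.bilateral and spec.count == 1:
            r_id = pn_members[spec.type_label][-2]
            l_id = pn_members[spec.type_label][-1]
            conn.meta[r_id].contralateral_partner = l_id
            conn.meta[l_id].contralateral_partner = r_id

    # ---- RN -> PN synapses in glomeruli (drives the cable regression) -----
    for sid, gmap in pn_glom_nodes.items():
        side = conn.meta[sid].hemisphere
        sk = conn.skeletons[sid]
        for g, nodes in gmap.items():
            rns = rns_by_glom.get((g, side), [])
            if not rns:
                continue
            cable = cable_length_in_volume(sk, conn.volumes[f"glom_{g}_{side}"])
            n_in = int(round(config.rn_input_rate * cable
                             + rng_rn.normal(0.0, 2.0)))
            for _ in range(max(n_in, 0)):
                rn = rns[rng_rn.integers(len(rns))]
                rn_sk = conn.skeletons[rn]
                rn_node = int(rn_sk.nodes.index[rng_rn.integers(len(rn_sk.nodes))])
                pn_node = int(nodes[rng_rn.integers(len(nodes))])
                loc = rn_sk.coords([rn_node])[0] \
                    + rng_rn.normal(0.0, max(config.noise, 1.0), 3)
                put((rn, rn_node), [(sid, pn_node)], loc)

    # ---- lACA wiring: planted partner degrees downstream of each query ----
    truth: dict[str, dict[str, int]] = {}
    laca_box = conn.volumes["lACA_R"]
    partner_seq = [0]
    query_presyn = 0
    for q in queries:
        degs: list[tuple[str, int]] = []
        for n_partners, n_conn in config.partner_degrees:
            for _ in range(n_partners):
                pid = f"tgt_{partner_seq[0]:04d}"
                partner_seq[0] += 1
                npts = max(6, n_conn + 2)
                start = laca_box.lo + (laca_box.hi - laca_box.lo) \
                    * rng_wire.uniform(0.1, 0.9, 3)
                pb = _SkelBuilder()
                pb.add_path(_walk(rng_wire, start, laca_box, npts, 2000.0))
                conn.skeletons[pid] = pb.build(pid)
                conn.meta[pid] = NeuronMeta(pid, "other", f"target_{pid}", "R")
                type_labels[pid] = f"target_{pid}"
                degs.append((pid, n_conn))
        truth[q] = {pid: c for pid, c in degs if c > 0}
        events = [pid for pid, c in degs for _ in range(c)]
        rng_wire.shuffle(events)
        pre_nodes = pn_vol_nodes[q].get("lACA", [])
        if not pre_nodes:
            raise ConfigError(f"query {q} has no lACA axon nodes")
        i = 0
        sk_q = conn.skeletons[q]
        while i < len(events):
            size = int(rng_wire.integers(1, 4))
            chunk = events[i:i + size]
            i += len(chunk)
            pre_node = int(pre_nodes[rng_wire.integers(len(pre_nodes))])
            posts: list[tuple[str, int]] = []
            for pid in chunk:
                pk = conn.skeletons[pid]
                for _ in range(20):
                    node = int(pk.nodes.index[rng_wire.integers(len(pk.nodes))])
                    if (pid, node) not in posts:
                        posts.append((pid, node))
                        break
                else:
                    raise ConfigError(f"cannot place distinct post link on {pid}")
            loc = sk_q.coords([pre_node])[0] + rng_wire.normal(0.0, 200.0, 3)
            loc = np.clip(loc, laca_box.lo, laca_box.hi)
            put((q, pre_node), posts, loc)
            query_presyn += 1

    # ---- non-query lACA presynapses, capped to preserve query dominance ---
    d = config.laca_dominance
    allowed = int(np.floor(query_presyn * (1.0 - d) / d)) if query_presyn else 0
    others = [(s, s.targets.get("lACA", 0)) for s in config.pn_specs
              if not s.is_query and s.targets.get("lACA", 0) > 0]
    budget_total = sum(n for _, n in others)
    scale = min(1.0, allowed / budget_total) if budget_total else 0.0
    for spec, n in others:
        members = [m for m in pn_members[spec.type_label]
                   if conn.meta[m].hemisphere == "R"]
        if not members:
            continue
        sid = members[0]
        take = int(np.floor(n * scale))
        pre_nodes = pn_vol_nodes[sid].get("lACA", [])
        other_queries = queries or [sid]
        for _ in range(take):
            pre_node = int(pre_nodes[rng_wire.integers(len(pre_nodes))])
            # axo-axonic: posts onto a query PN's lACA axon
            tq = other_queries[rng_wire.integers(len(other_queries))]
            tq_nodes = pn_vol_nodes[tq].get("lACA", [])
            post_node = int(tq_nodes[rng_wire.integers(len(tq_nodes))])
            loc = conn.skeletons[sid].coords([pre_node])[0] \
                + rng_wire.normal(0.0, 200.0, 3)
            loc = np.clip(loc, laca_box.lo, laca_box.hi)
            put((sid, pre_node), [(tq, post_node)], loc)

    # ---- calyx PN classes (bouton carriers) -------------------------------
    ca_box = conn.volumes["CA_R"]
    class_pns: dict[str, str] = {}
    for cls in sorted(config.bouton_counts):
        sid = f"cpn_{cls.replace(' ', '_').replace('+', 'p')}"
        start = ca_box.lo + (ca_box.hi - ca_box.lo) * rng_kc.uniform(0.15, 0.85, 3)
        cb = _SkelBuilder()
        cb.add_path(_walk(rng_kc, start, ca_box, 30, 3500.0))
        conn.skeletons[sid] = cb.build(sid)
        conn.meta[sid] = NeuronMeta(sid, "PN", cls, "R")
        type_labels[sid] = cls
        conn.boutons[sid] = int(config.bouton_counts[cls])
        class_pns[cls] = sid

    # ---- Kenyon cells with claw-structured dendrites ----------------------
    shares = effective_shares(config.bouton_counts, config.bias) \
        if sum(config.bouton_counts.values()) else pd.Series(dtype=float)
    classes = list(shares.index)
    probs = shares.to_numpy() if len(shares) else None
    claw_rows = []
    for k in range(config.n_kcs):
        kc = f"kc_{k:03d}"
        soma = np.array([rng_kc.uniform(130e3, 190e3), 230e3, 80e3])
        mid = ca_box.lo + (ca_box.hi - ca_box.lo) * rng_kc.uniform(0.3, 0.7, 3)
        exitp = np.array([mid[0], ca_box.lo[1] - 60e3, mid[2]])
        kb = _SkelBuilder()
        kb.add_path(soma[None, :])
        tract = kb.add_path(np.vstack([_line(soma, mid, 15)[1:],
                                       _line(mid, exitp, 15)[1:]]), parent=0)
        inside = [i for i in tract
                  if np.all(kb.points[i] >= ca_box.lo) and np.all(kb.points[i] <= ca_box.hi)]
        claw_roots = []
        for c in range(config.claws_per_kc):
            att = inside[int(rng_kc.integers(len(inside)))]
            p0 = kb.points[att]
            claw_pts = _walk(rng_kc, p0 + rng_kc.normal(0, 800.0, 3), ca_box, 4, 1200.0)
            idx = kb.add_path(claw_pts, parent=att)
            claw_roots.append(idx[0] + 1)
            if probs is not None and config.inputs_per_claw > 0:
                for _ in range(config.inputs_per_claw):
                    cls = classes[rng_claw.choice(len(classes), p=probs)]
                    claw_rows.append((kc, claw_roots[-1], cls))
                    src = class_pns[cls]
                    src_sk = conn.skeletons[src]
                    for s in range(config.min_syn + 1):
                        pre_node = int(src_sk.nodes.index[rng_claw.integers(len(src_sk.nodes))])
                        post_node = int(idx[s % len(idx)] + 1)
                        loc = np.clip(claw_pts[s % len(idx)]
                                      + rng_claw.normal(0, 300.0, 3),
                                      ca_box.lo, ca_box.hi)
                        put((src, pre_node), [(kc, post_node)], loc)
                # sub-threshold distractor input from one other class
                if len(classes) > 1:
                    alt = classes[int(rng_claw.integers(len(classes)))]
                    src = class_pns[alt]
                    src_sk = conn.skeletons[src]
                    for s in range(2):
                        pre_node = int(src_sk.nodes.index[rng_claw.integers(len(src_sk.nodes))])
                        loc = np.clip(claw_pts[s] + rng_claw.normal(0, 300.0, 3),
                                      ca_box.lo, ca_box.hi)
                        put((src, pre_node), [(kc, int(idx[s] + 1))], loc)
        conn.skeletons[kc] = kb.build(kc)
        conn.meta[kc] = NeuronMeta(kc, "KC", "KCa'b'", "R")
        type_labels[kc] = "KCa'b'"
        conn.claws[kc] = claw_roots

    conn.validate()
    gt = GroundTruth(
        queries=queries,
        partner_degrees=truth,
        claw_draws=pd.DataFrame(claw_rows, columns=["kc", "claw", "pn_class"]),
        shares=shares,
        type_labels=type_labels,
    )
    return conn, gt


def write_ground_truth(gt: GroundTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [(q, p, c) for q in sorted(gt.partner_degrees)
            for p, c in sorted(gt.partner_degrees[q].items())]
    pd.DataFrame(rows, columns=["query", "partner", "connections"]) \
        .to_csv(outdir / "true_partner_degrees.tsv", sep="\t", index=False)
    gt.claw_draws.to_csv(outdir / "true_claw_draws.tsv", sep="\t", index=False)
    gt.shares.rename("share").to_csv(outdir / "true_shares.tsv", sep="\t")
    pd.DataFrame(sorted(gt.type_labels.items()),
                 columns=["skeleton_id", "type_label"]) \
        .to_csv(outdir / "true_types.tsv", sep="\t", index=False)
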