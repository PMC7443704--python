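"""Randomized downstream-synapse sampling with a saturation stopping rule.

The workflow mirrors sparse-EM circuit tracing: every postsynapse downstream
of a set of query neurons (optionally restricted to a neuropil volume) is
enumerated, then drawn uniformly at random without replacement.  Each draw
whose postsynaptic skeleton has not been seen before is a *novel hit*; when
the 10 most recent novel hits each total fewer than 5 connections with the
query set, the partner discovery process is considered saturated and sampling
stops.  The per-partner connection totals used by the rule are ground truth:
in the original workflow each hit was reconstructed and its connections
counted, here the simulator (or a full connectome) supplies them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Connectome, Volume, points_in_volume

DEFAULT_WINDOW = 10
DEFAULT_WEAK_THRESHOLD = 5

PoolEntry = tuple[str, str]   # (connector_id, post skeleton_id)


@dataclass
class SamplingState:
    """Full record of one sampling run."""

    pool: list[PoolEntry]
    sampled: list[PoolEntry] = field(default_factory=list)
    partner_tally: dict[str, int] = field(default_factory=dict)
    novel_history: list[tuple[str, int]] = field(default_factory=list)
    stopped: bool = False                 # True iff the saturation rule fired
    stop_reason: str = ""
    fraction_sampled: float = 0.0


def enumerate_postsynapses(connectome: Connectome, query_ids: Sequence[str],
                           volume: Volume | None = None) -> list[PoolEntry]:
    """All (connector, postsynaptic link) pairs downstream of the queries.

    A polyadic connector contributes one entry per postsynaptic link.  With a
    volume, only connectors whose location lies inside are kept.  Order is
    deterministic (connector id, then post skeleton id).
    """
    qset = set(query_ids)
    unknown = qset - set(connectome.skeletons)
    if unknown:
        raise KeyError(f"unknown query skeleton ids: {sorted(unknown)}")
    pool: list[PoolEntry] = []
    cids = sorted(connectome.connectors)
    if volume is not None:
        locs = np.array([connectome.connectors[c].location for c in cids]) \
            if cids else np.empty((0, 3))
        keep = points_in_volume(locs, volume) if cids else np.array([], bool)
    else:
        keep = np.ones(len(cids), bool)
    for cid, k in zip(cids, keep):
        c = connectome.connectors[cid]
        if not k or c.pre[0] not in qset:
            continue
        for ps, _pn in sorted(c.posts):
            pool.append((cid, ps))
    return pool


def true_connection_counts(connectome: Connectome, query_ids: Sequence[str],
                           volume: Volume | None = None) -> dict[str, int]:
    """Ground-truth total connections from the query set per downstream
    partner, within the given scope (the live-mode truth for the rule)."""
    counts: dict[str, int] = {}
    for _cid, ps in enumerate_postsynapses(connectome, query_ids, volume):
        counts[ps] = counts.get(ps, 0) + 1
    return counts


def sample_to_saturation(pool: Sequence[PoolEntry], truth: Mapping[str, int],
                         rng: np.random.Generator,
                         window: int = DEFAULT_WINDOW,
                         weak_threshold: int = DEFAULT_WEAK_THRESHOLD,
                         ) -> SamplingState:
    """Draw postsynapses uniformly without replacement until saturation.

    Stops when the last ``window`` novel hits all have true connection totals
    below ``weak_threshold`` (evaluated only once ``window`` novel hits
    exist).  If the pool empties first, the run ends with ``stopped=False``
    and reason ``"exhausted"``.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("empty postsynapse pool")
    missing = {ps for _c, ps in pool} - set(truth)
    if missing:
        raise KeyError(f"truth missing partners: {sorted(missing)[:5]}")
    state = SamplingState(pool=pool)
    order = rng.permutation(len(pool))
    for j in order:
        cid, ps = pool[j]
        state.sampled.append((cid, ps))
        novel = ps not in state.partner_tally
        state.partner_tally[ps] = state.partner_tally.get(ps, 0) + 1
        if novel:
            state.novel_history.append((ps, int(truth[ps])))
            if len(state.novel_history) >= window and all(
                    t < weak_threshold for _p, t in state.novel_history[-window:]):
                state.stopped = True
                state.stop_reason = "saturated"
                break
    else:
        state.stopped = False
        state.stop_reason = "exhausted"
    state.fraction_sampled = len(state.sampled) / len(pool)
    return state


def exhaustive_tally(pool: Sequence[PoolEntry]) -> dict[str, int]:
    """Partner tally with the stopping rule disabled and the pool fully
    consumed -- the enumeration oracle for adjacency checks."""
    out: dict[str, int] = {}
    for _c, ps in pool:
        out[ps] = out.get(ps, 0) + 1
    return out


def discovery_curve(state: SamplingState) -> pd.DataFrame:
    """Cumulative unique-partner count per draw (monotone non-decreasing)."""
    seen: set[str] = set()
    rows = []
    for i, (_c, ps) in enumerate(state.sampled, start=1):
        seen.add(ps)
        rows.append((i, len(seen)))
    return pd.DataFrame(rows, columns=["draws", "unique_partners"])
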