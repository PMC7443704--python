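"""Adjacency construction, threshold-based circuit membership, normalized
input budgets, and the receptor-neuron census bookkeeping.

Conventions, pinned by tests:

* a "connection" is one postsynaptic link, so a polyadic connector counts
  once per link;
* circuit membership from the lACA query PNs uses an inclusive threshold
  (at least 5 connections), while brain-wide strong targets use a strict one
  (more than 150 inputs);
* input-budget heatmaps drop cells of <= 2 synapses before renormalizing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Connectome, Volume, points_in_volume

CIRCUIT_THRESHOLD = 5          # inclusive: "at least 5 connections"
STRONG_THRESHOLD = 150         # strict: "> 150 inputs"
HEATMAP_MIN_SYNAPSES = 2       # cells must exceed this to survive


class UndefinedBudgetError(ValueError):
    """Input budget requested for a target with zero qualifying input."""


@dataclass
class AdjacencyTable:
    """Synaptic connection counts, sources (rows) x targets (columns)."""

    counts: pd.DataFrame
    volume: str | None = None
    compartment: str | None = None

    def pooled(self, source_groups: Mapping[str, Sequence[str]] | None = None,
               target_groups: Mapping[str, Sequence[str]] | None = None,
               ) -> "AdjacencyTable":
        """Pool rows/columns by group; a pooled cell is the member sum."""
        df = self.counts
        if source_groups:
            df = pd.concat({g: df.loc[[m for m in ms if m in df.index]].sum(axis=0)
                            for g, ms in source_groups.items()}, axis=1).T
        if target_groups:
            df = pd.concat({g: df[[m for m in ms if m in df.columns]].sum(axis=1)
                            for g, ms in target_groups.items()}, axis=1)
        return AdjacencyTable(df.astype(int), self.volume, self.compartment)


def build_adjacency(connectome: Connectome, sources: Sequence[str],
                    targets: Sequence[str], volume: Volume | None = None,
                    compartments: Mapping[str, set[int]] | None = None,
                    ) -> AdjacencyTable:
    """Count (connector, post-link) pairs from each source onto each target.

    ``compartments`` optionally restricts a target to an allowed node set
    (e.g., dendrite flags from :func:`vpconn.morphology.split_dendrites`); a
    post link onto a flagged neuron counts only if its node is allowed.
    """
    unknown = (set(sources) | set(targets)) - set(connectome.skeletons)
    if unknown:
        raise KeyError(f"unknown skeleton ids: {sorted(unknown)[:5]}")
    sset, tset = set(sources), set(targets)
    counts = pd.DataFrame(0, index=sorted(sset), columns=sorted(tset), dtype=int)
    for cid in sorted(connectome.connectors):
        c = connectome.connectors[cid]
        if c.pre[0] not in sset:
            continue
        if volume is not None and not points_in_volume(c.location[None, :], volume)[0]:
            continue
        for ps, pn in c.posts:
            if ps not in tset:
                continue
            if compartments is not None and ps in compartments \
                    and pn not in compartments[ps]:
                continue
            counts.loc[c.pre[0], ps] += 1
    return AdjacencyTable(counts,
                          volume=getattr(volume, "name", None),
                          compartment="restricted" if compartments else None)


def circuit_members(adjacency: AdjacencyTable,
                    threshold: int = CIRCUIT_THRESHOLD) -> set[str]:
    """Targets with at least ``threshold`` summed connections from the query
    set (boundary included): the lACA circuit-membership rule."""
    totals = adjacency.counts.sum(axis=0)
    return set(totals.index[totals >= threshold])


def strong_targets(adjacency: AdjacencyTable,
                   threshold: int = STRONG_THRESHOLD) -> set[str]:
    """Targets with strictly more than ``threshold`` summed inputs: the
    brain-wide strong-partner rule."""
    totals = adjacency.counts.sum(axis=0)
    return set(totals.index[totals > threshold])


def input_budget(column: pd.Series, mode: str = "vp",
                 categories: Mapping[str, str] | None = None) -> pd.Series:
    """Normalize one target's input column to fractions.

    mode "vp": drop cells of <= 2 synapses, then divide the survivors by the
    retained total (total VP-PN input = 1).  mode "identified": sum sources
    into categories (VP, VP+SEZ, gustatory, olfactory, visual, lACA targets,
    via the supplied source -> category map) and divide by the identified
    total.  Retained fractions sum to 1.
    """
    col = column.astype(float)
    if mode == "vp":
        kept = col[col > HEATMAP_MIN_SYNAPSES]
        total = kept.sum()
        if total <= 0:
            raise UndefinedBudgetError("no input above the heatmap threshold")
        return kept / total
    if mode == "identified":
        if categories is None:
            raise ValueError("mode 'identified' needs a source->category map")
        cat = col.groupby(col.index.map(lambda s: categories.get(s, "unknown"))).sum()
        cat = cat[cat > 0]
        total = cat.sum()
        if total <= 0:
            raise UndefinedBudgetError("no identified input")
        return cat / total
    raise ValueError(f"unknown mode {mode!r}")


def adjacency_to_graphml(adjacency: AdjacencyTable, path: str | Path,
                         min_count: int = 1) -> None:
    """Export the adjacency as a GraphML edge list with count attributes."""
    import networkx as nx
    g = nx.DiGraph()
    for s in adjacency.counts.index:
        for t in adjacency.counts.columns:
            n = int(adjacency.counts.loc[s, t])
            if n >= min_count:
                g.add_edge(s, t, count=n)
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# Census bookkeeping
# ---------------------------------------------------------------------------

def pooled_total(rhs: int, lhs: int) -> int:
    """Reconstructed totals pool across hemispheres by summation."""
    _check_nonneg(rhs, lhs)
    return rhs + lhs


def novel_type_count(total_types: int, previously_described: int,
                     previously_misassociated: int) -> int:
    """Novel types = all types minus those already described minus those
    reported before but associated with the wrong glomeruli."""
    out = total_types - previously_described - previously_misassociated
    _check_nonneg(total_types, previously_described, previously_misassociated, out)
    return out


def percent_complete(complete: int, sampled: int) -> float:
    """Share of sampled neurons that were fully reconstructed, one decimal."""
    _check_nonneg(complete, sampled)
    if sampled == 0:
        raise ValueError("no sampled neurons")
    return round(100.0 * complete / sampled, 1)


def chamber_assignment(vp4_total: int, vp5_count: int) -> tuple[int, int]:
    """Split a hemisphere's VP4 RNs between sacculus chambers.

    VP4 and VP5 RNs cohabit triad sensilla in chamber II, so the number of
    chamber-II VP4 RNs on a side equals that side's VP5 RN count; the
    remainder originate in chamber I.  Returns (chamber_ii, chamber_i).
    """
    chamber_i = vp4_total - vp5_count
    _check_nonneg(vp4_total, vp5_count, chamber_i)
    return vp5_count, chamber_i


def vp1d_vp4_total(vp4_total: int, vp5_count: int) -> int:
    """Combined VP1d + VP4 RN count for one side: VP1d RNs share the
    chamber-II triads with VP5, so the side's VP1d count equals its VP5
    count."""
    _check_nonneg(vp4_total, vp5_count)
    return vp4_total + vp5_count


def census(vp_pn_rhs: int = 52, vp_pn_lhs: int = 36,
           total_types: int = 38, previously_described: int = 9,
           previously_misassociated: int = 6,
           complete: int = 20, sampled: int = 42,
           vp4_per_side: Mapping[str, int] = None,
           vp5_per_side: Mapping[str, int] = None) -> dict:
    """Run the full census arithmetic and return the summary numbers."""
    vp4 = dict(vp4_per_side or {"R": 14, "L": 14})
    vp5 = dict(vp5_per_side or {"R": 9, "L": 7})
    out = {
        "vp_pn_total": pooled_total(vp_pn_rhs, vp_pn_lhs),
        "novel_types": novel_type_count(total_types, previously_described,
                                        previously_misassociated),
        "percent_complete": percent_complete(complete, sampled),
    }
    for side in sorted(vp4):
        ii, i = chamber_assignment(vp4[side], vp5[side])
        out[f"chamber_ii_vp4_{side}"] = ii
        out[f"chamber_i_vp4_{side}"] = i
        out[f"vp1d_vp4_total_{side}"] = vp1d_vp4_total(vp4[side], vp5[side])
    return out


def _check_nonneg(*values: int) -> None:
    if any(v < 0 for v in values):
        raise ValueError("negative intermediate in census arithmetic")
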