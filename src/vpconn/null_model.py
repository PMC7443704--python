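"""Kenyon-cell input-composition analysis with a bouton-share null model.

Each KC dendritic claw is scored for which PN classes feed it: a class is an
*observed input* to a claw when it contributes at least ``min_syn`` synapses
(default 5), all inputs weighted equally.  The null hypothesis is that claws
sample PN classes in proportion to each class's share of calyx boutons: a
virtual KC population with the same number of claws and inputs is drawn from
the bouton-share vector, repeated (default 1000 times) to give expected
per-class input counts.  Observed-vs-expected ratios plus empirical Monte
Carlo p-values, per class and rolled up by putative valence, quantify over-
and under-representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Connectome, Volume, points_in_volume
from .morphology import dendrite_branches, split_dendrites

logger = logging.getLogger("vpconn")

DEFAULT_MIN_SYN = 5
DEFAULT_REPS = 1000


@dataclass
class ClawInputTable:
    """Binary per-claw observed inputs: rows (kc, claw), columns PN classes."""

    table: pd.DataFrame          # MultiIndex (kc, claw) x class, 0/1 cells
    min_syn: int = DEFAULT_MIN_SYN

    def class_totals(self) -> pd.Series:
        return self.table.sum(axis=0).astype(int)

    @property
    def n_rows(self) -> int:
        return len(self.table)


def bouton_shares(bouton_counts: Mapping[str, float]) -> pd.Series:
    """Bouton counts per PN class -> draw probabilities (sum to 1)."""
    s = pd.Series({c: float(v) for c, v in bouton_counts.items()}).sort_index()
    if (s < 0).any():
        raise ValueError("negative bouton count")
    total = s.sum()
    if total <= 0:
        raise ValueError("all-zero bouton counts")
    return s / total


def observed_inputs(connectome: Connectome, kc_set: Sequence[str],
                    calyx_volume: Volume, min_syn: int = DEFAULT_MIN_SYN,
                    laca_volume: Volume | None = None,
                    laca_pn_ids: Sequence[str] = (),
                    ) -> ClawInputTable:
    """Build the per-claw observed-input table from a connectome.

    KC dendrites are flagged with :func:`split_dendrites` and grouped into
    claws (connected side branches).  A PN class is an input to a claw when
    its neurons contribute >= ``min_syn`` synapses onto the claw's nodes
    inside the calyx.  Inputs from lACA-associated PNs located inside the
    lACA volume are omitted.
    """
    laca_set = set(laca_pn_ids)
    counts: dict[tuple[str, int], dict[str, int]] = {}
    claw_of: dict[tuple[str, int], tuple[str, int]] = {}  # (kc, node) -> (kc, claw root)
    for kc in sorted(kc_set):
        sk = connectome.skeletons[kc]
        dend = split_dendrites(sk, calyx_volume)
        if not dend:
            logger.warning("observed_inputs: %s has no flagged dendrites; skipped", kc)
            continue
        for root, nodes in dendrite_branches(sk, dend).items():
            counts[(kc, root)] = {}
            for n in nodes:
                claw_of[(kc, n)] = (kc, root)
    for cid in sorted(connectome.connectors):
        c = connectome.connectors[cid]
        src = c.pre[0]
        src_meta = connectome.meta.get(src)
        if src_meta is None or src_meta.neuron_class != "PN":
            continue
        if src in laca_set and laca_volume is not None \
                and points_in_volume(c.location[None, :], laca_volume)[0]:
            continue
        for ps, pn in c.posts:
            key = claw_of.get((ps, pn))
            if key is None:
                continue
            cls = connectome.class_of(src)
            counts[key][cls] = counts[key].get(cls, 0) + 1
    classes = sorted({cls for d in counts.values() for cls in d})
    rows = sorted(counts)
    data = pd.DataFrame(0, index=pd.MultiIndex.from_tuples(rows, names=["kc", "claw"])
                        if rows else pd.MultiIndex.from_arrays([[], []], names=["kc", "claw"]),
                        columns=classes, dtype=int)
    for key in rows:
        for cls, n in counts[key].items():
            if n >= min_syn:
                data.loc[key, cls] = 1
    return ClawInputTable(data, min_syn)


def table_from_draws(draws: pd.DataFrame, min_syn: int = DEFAULT_MIN_SYN,
                     ) -> ClawInputTable:
    """Binary claw-input table from a long (kc, claw, pn_class) draw table
    (e.g., the generator's ground truth)."""
    if len(draws) == 0:
        return ClawInputTable(pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["kc", "claw"])), min_syn)
    binary = (draws.assign(v=1)
              .pivot_table(index=["kc", "claw"], columns="pn_class", values="v",
                           aggfunc="max", fill_value=0))
    binary.columns.name = None
    return ClawInputTable(binary.astype(int), min_syn)


@dataclass
class ExpectedInputs:
    """Monte Carlo expectation under the bouton-share null."""

    mean: pd.Series               # per-class mean input count over replicates
    se: pd.Series                 # Monte Carlo standard error (sd / sqrt(reps))
    replicates: pd.DataFrame      # reps x classes per-replicate counts
    total_inputs: int
    reps: int


def expected_inputs(n_rows: int, inputs_per_row: int | Sequence[int],
                    shares: pd.Series, reps: int = DEFAULT_REPS,
                    rng: np.random.Generator | None = None) -> ExpectedInputs:
    """Draw a virtual claw population ``reps`` times from the share vector.

    Every row (claw) draws ``inputs_per_row`` class labels independently with
    probabilities ``shares``; per-class counts are summed over rows and
    averaged over replicates.  ``inputs_per_row`` may be a constant or the
    observed per-row totals.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    per_row = (np.full(n_rows, int(inputs_per_row))
               if np.isscalar(inputs_per_row) else np.asarray(inputs_per_row, int))
    if len(per_row) != n_rows:
        raise ValueError("inputs_per_row length must match n_rows")
    total = int(per_row.sum())
    if total <= 0:
        raise ValueError("no inputs to draw")
    p = shares.to_numpy(float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("shares must be a probability vector")
    # independent per-input draws: row structure does not change class totals,
    # so each replicate's totals are one multinomial draw of size `total`
    draws = rng.multinomial(total, p, size=reps)
    rep = pd.DataFrame(draws, columns=shares.index)
    mean = rep.mean(axis=0)
    se = rep.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 \
        else pd.Series(0.0, index=shares.index)
    return ExpectedInputs(mean, se, rep, total, reps)


def _empirical_p(rep: np.ndarray, obs: float) -> float:
    """Two-sided Monte Carlo p with the +1 continuity correction."""
    r = len(rep)
    lo = (1 + np.sum(rep <= obs)) / (r + 1)
    hi = (1 + np.sum(rep >= obs)) / (r + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def enrichment_report(observed: ClawInputTable, expected: ExpectedInputs,
                      valence_map: Mapping[str, str] | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed vs expected input counts, per class and per valence.

    Returns (per_class, per_valence) tables with observed count, expected
    mean, obs/exp ratio and empirical two-sided Monte Carlo p-value.  Classes
    absent from the valence map are logged and rolled up as "unknown".
    """
    valence_map = dict(valence_map or {})
    obs = observed.class_totals()
    classes = expected.mean.index
    obs = obs.reindex(classes, fill_value=0)
    rows = []
    for cls in classes:
        rep = expected.replicates[cls].to_numpy()
        exp = expected.mean[cls]
        rows.append((cls, int(obs[cls]), float(exp),
                     float(obs[cls] / exp) if exp > 0 else np.inf,
                     _empirical_p(rep, obs[cls])))
    per_class = pd.DataFrame(rows, columns=["pn_class", "observed", "expected",
                                            "ratio", "p_value"]).set_index("pn_class")
    valences = {}
    for cls in classes:
        if cls not in valence_map:
            logger.info("enrichment_report: class %r missing from valence map; "
                        "assigned 'unknown'", cls)
        valences[cls] = valence_map.get(cls, "unknown")
    vrows = []
    for val in sorted(set(valences.values())):
        members = [c for c in classes if valences[c] == val]
        o = int(obs[members].sum())
        rep = expected.replicates[members].sum(axis=1).to_numpy()
        e = float(expected.mean[members].sum())
        vrows.append((val, o, e, float(o / e) if e > 0 else np.inf,
                      _empirical_p(rep, o)))
    per_valence = pd.DataFrame(vrows, columns=["valence", "observed", "expected",
                                               "ratio", "p_value"]).set_index("valence")
    return per_class, per_valence
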