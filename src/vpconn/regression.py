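"""Cable-length vs receptor-neuron-input regression for multiglomerular PNs.

For a PN innervating several glomeruli, each (PN, glomerulus) pair yields one
sample: dendritic cable length inside the glomerulus volume (nm) and the
number of synaptic connections received from that glomerulus's RNs.  An
ordinary least-squares line of input count on cable length summarizes how
strongly a PN's sampling of a glomerulus scales with the cable it invests
there; R-squared and the F-test p-value come from the standard linear-model
fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class CableInputFit:
    slope: float          # RN inputs per nm of cable
    intercept: float
    r_squared: float
    p_value: float        # F-test, (1, n-2) degrees of freedom
    n: int

    def summary(self) -> str:
        return (f"n={self.n}  slope={self.slope:.6g}/nm  "
                f"intercept={self.intercept:.4g}  R^2={self.r_squared:.4f}  "
                f"p={self.p_value:.4g}")


def fit_cable_vs_input(samples: pd.DataFrame) -> CableInputFit:
    """OLS of RN input count on cable length.

    ``samples`` needs columns ``cable_nm`` (>= 0) and ``rn_inputs``
    (non-negative integers).  Requires at least 3 samples and non-constant
    cable lengths.
    """
    x = np.asarray(samples["cable_nm"], float)
    y = np.asarray(samples["rn_inputs"], float)
    if len(x) < 3:
        raise ValueError("need at least 3 (PN, glomerulus) samples")
    if np.ptp(x) == 0:
        raise ValueError("cable lengths are all identical; slope undefined")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative cable length or input count")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return CableInputFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.f_pvalue),
        n=len(x),
    )


def glomerular_samples(connectome, pn_ids, rng_classes=None) -> pd.DataFrame:
    """Tabulate (PN, glomerulus) cable lengths and RN input counts.

    Cable is measured inside each ``glom_<name>_<side>`` volume; RN inputs
    are post links onto the PN from RNs whose primary glomerulus matches.
    """
    from .core import cable_length_in_volume
    rows = []
    for pn in pn_ids:
        meta = connectome.meta[pn]
        sk = connectome.skeletons[pn]
        for g in meta.glomeruli:
            vol = connectome.volumes.get(f"glom_{g}_{meta.hemisphere}")
            if vol is None:
                continue
            cable = cable_length_in_volume(sk, vol)
            n_in = 0
            for cid, c in connectome.connectors.items():
                src = connectome.meta.get(c.pre[0])
                if src is None or src.neuron_class != "RN" or \
                        not src.glomeruli or src.glomeruli[0] != g:
                    continue
                n_in += sum(1 for ps, _pn in c.posts if ps == pn)
            rows.append((pn, g, cable, n_in))
    return pd.DataFrame(rows, columns=["pn", "glomerulus", "cable_nm", "rn_inputs"])
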