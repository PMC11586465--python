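"""Correlating case-control t-maps with neurotransmitter density maps.

A per-region receptor density map (e.g. GABA-A availability from
flumazenil PET, parcellated to the same atlas) is compared to a
case-control t-map by Spearman correlation, with significance from the
spatial spin null so that shared smoothness cannot masquerade as
association. By default the correlation runs over all regions of the
contrast map under the hybrid null (cortex spun, subcortex shuffled);
restrict both maps to cortex for a purely rotational null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spin import SpinNull, spin_pvalue

__all__ = ["receptor_correlation"]


def receptor_correlation(tmap, receptor: pd.Series, spins: SpinNull) -> tuple[float, float]:
    """Spearman rho between a t-map and a receptor map, with spin p.

    ``tmap`` may be a CaseControlMap or a pandas Series indexed by
    region_id; the receptor map must cover the spin scope.
    """
    if hasattr(tmap, "table"):  # CaseControlMap
        t = pd.Series(tmap.table["t"].to_numpy(float), index=tmap.table["region_id"].to_numpy())
    else:
        t = pd.Series(tmap)
    scope = list(spins.region_ids)
    missing_t = [r for r in scope if r not in t.index]
    missing_r = [r for r in scope if r not in receptor.index]
    if missing_t or missing_r:
        raise ValueError("maps do not cover the spin scope")
    x = t.loc[scope].to_numpy(float)
    y = receptor.loc[scope].to_numpy(float)
    return spin_pvalue(x, y, spins, stat="spearman")
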