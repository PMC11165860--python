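"""CANAPE: categorical analysis of neo- and paleo-endemism.

Cells are classified from the randomization significance of phylogenetic
endemism on the observed tree (PE), on the equal-branch-length comparison
tree (PE_alt), and of their ratio (RPE):

1. *Candidate gate* — a cell is a candidate centre of endemism when PE or
   PE_alt is significantly high (one-tailed, ``alpha_candidate``); all other
   cells are ``not_significant``.
2. *Tails of RPE* — among candidates, significantly high RPE marks
   paleo-endemism (an excess of long, range-restricted branches), and
   significantly low RPE marks neo-endemism (short, range-restricted
   branches), at ``alpha_tail`` per tail.  Remaining candidates are
   ``mixed``, upgraded to ``super`` when both PE and PE_alt are high at the
   stricter ``alpha_super``.

The five labels partition the cells; the default thresholds (0.05, 0.025
per tail, 0.01) follow the original CANAPE protocol and are all exposed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LABELS = ("not_significant", "neo", "paleo", "mixed", "super")

#: map colours used by the interactive output
PALETTE = {
    "not_significant": "#ece8d8",  # beige
    "neo": "#d7191c",  # red
    "paleo": "#2c7bb6",  # blue
    "mixed": "#c2a5cf",  # light purple
    "super": "#6a3d9a",  # dark purple
}

_REQUIRED = ("pe_p_p_high", "pe_alt_p_p_high", "rpe_p_high", "rpe_p_low")


def classify(
    sig: pd.DataFrame,
    alpha_candidate: float = 0.05,
    alpha_tail: float = 0.025,
    alpha_super: float = 0.01,
) -> pd.Series:
    """CANAPE label per cell from a SignificanceTable."""
    missing = [c for c in _REQUIRED if c not in sig.columns]
    if missing:
        raise ValueError(f"significance table lacks columns: {missing}")

    pe_hi = sig["pe_p_p_high"].to_numpy()
    alt_hi = sig["pe_alt_p_p_high"].to_numpy()
    rpe_hi = sig["rpe_p_high"].to_numpy()
    rpe_lo = sig["rpe_p_low"].to_numpy()

    candidate = (pe_hi <= alpha_candidate) | (alt_hi <= alpha_candidate)

    labels = np.full(len(sig), "not_significant", dtype=object)
    paleo = candidate & (rpe_hi <= alpha_tail)
    neo = candidate & ~paleo & (rpe_lo <= alpha_tail)
    mixed = candidate & ~paleo & ~neo
    super_ = mixed & (pe_hi <= alpha_super) & (alt_hi <= alpha_super)
    labels[paleo] = "paleo"
    labels[neo] = "neo"
    labels[mixed & ~super_] = "mixed"
    labels[super_] = "super"

    out = pd.Series(
        pd.Categorical(labels, categories=list(LABELS)), index=sig.index, name="canape"
    )
    assert not out.isna().any()
    return out
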