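"""Summary and mediator-specific coarsenings of the 32 path-specific effects.

The summary natural path-specific effect of a path averages its 8 types with
weights proportional to how often each type appears among the 24
decompositions (6/24 for types 000 and 111, 2/24 for the other six).  The
four summaries themselves decompose the TCE exactly.  A weighted variance
about each summary quantifies how much the 8 types disagree -- zero exactly
when no interactions make them differ.

The mediator-specific (MS) effects coarsen to three components by merging
the through-both path with the through-M2 path (MS1: "all of the effect
through M2") or the through-M1 path (MS2: "all of the effect through M1");
each family has 12 effects and 6 exact three-way decompositions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import algebra
from .gcomp import CounterfactualTable, EffectTable


def _check_full(effects: EffectTable) -> None:
    missing = [
        c.name
        for c in algebra.enumerate_effects()
        if c.name not in set(effects.df["effect"])
    ]
    if missing:
        raise ValueError(f"effect table is missing estimands: {missing[:4]}...")


def summary_effects(effects: EffectTable) -> dict[str, float]:
    """SNDE, SNIE1, SNIE2, SNIE12: the weighted type averages per path."""
    _check_full(effects)
    weights = algebra.summary_weights()
    out = {}
    for path in algebra.PATHS:
        label = algebra.PATH_LABELS[path]
        out[f"S{label}"] = sum(
            float(w) * effects[f"{label}-{algebra.bits_str(bits)}"]
            for bits, w in weights.items()
        )
    return out


def effect_variability(effects: EffectTable) -> dict[str, float]:
    """Weighted variance of the 8 types about each path's summary effect.

    Uses the same 6/24-2/24 weights, reflecting that the summary sits closer
    to the 000 and 111 types than to the others; nonnegative, and zero only
    when all weighted types coincide.
    """
    _check_full(effects)
    weights = algebra.summary_weights()
    summaries = summary_effects(effects)
    out = {}
    for path in algebra.PATHS:
        label = algebra.PATH_LABELS[path]
        s = summaries[f"S{label}"]
        out[f"var-{label}"] = sum(
            float(w) * (effects[f"{label}-{algebra.bits_str(bits)}"] - s) ** 2
            for bits, w in weights.items()
        )
    return out


def mediator_specific_effects(table: CounterfactualTable) -> dict[str, float]:
    """All 24 MS estimates (12 per family) as cell-contrast means."""
    if table.reduced:
        raise ValueError("mediator-specific effects require the full (ordered) system")
    out = {}
    for family in ("MS1", "MS2"):
        for c in algebra.enumerate_ms_effects(family):
            out[c.name] = float(np.mean(table.cells[c.plus] - table.cells[c.minus]))
    return out


def mediator_specific_table(table: CounterfactualTable) -> pd.DataFrame:
    """MS estimates plus, per family, the 6 ordering sums and the TCE.

    Each family's 6 three-way orderings telescope to the TCE exactly on a
    shared counterfactual table.
    """
    est = mediator_specific_effects(table)
    tce = float(np.mean(table.cells[(1, 1, 1, 1)] - table.cells[(0, 0, 0, 0)]))
    rows = [
        {
            "family": c.family,
            "effect": c.name,
            "path": c.path,
            "type": algebra.bits_str(c.bits),
            "estimate": est[c.name],
        }
        for family in ("MS1", "MS2")
        for c in algebra.enumerate_ms_effects(family)
    ]
    df = pd.DataFrame(rows)
    df.attrs["tce"] = tce
    df.attrs["ordering_sums"] = {
        family: [
            sum(est[c.name] for c in comps)
            for comps in algebra.enumerate_ms_decompositions(family)
        ]
        for family in ("MS1", "MS2")
    }
    return df


def subset_decompositions(path: str, bits=(0, 0, 0)) -> pd.DataFrame:
    """The decompositions containing a chosen (path, type) — fixing a path of
    interest at its 000 type keeps 6 of the 24."""
    rows = []
    for d in algebra.decompositions_containing(path, bits):
        codes = d.codes
        rows.append(
            {
                "decomposition": d.table_row,
                "NDE": codes[0], "NIE1": codes[1],
                "NIE2": codes[2], "NIE12": codes[3],
            }
        )
    return pd.DataFrame(rows)
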