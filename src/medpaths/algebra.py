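"""Symbolic algebra of natural path-specific effects for two ordered mediators.

With a binary exposure ``X``, two causally ordered mediators ``M1 -> M2`` and
an outcome ``Y``, every natural path-specific estimand is a contrast of two
nested counterfactuals of the form ::

    Y(a0, M1(a1), M2(a2, M1(a3))),   (a0, a1, a2, a3) in {0, 1}^4

The four exposure arguments correspond to the four causal pathways: ``a0`` is
the direct path, ``a1`` the path through M1 alone, ``a2`` the path through M2
alone, and ``a3`` the path through both mediators (X -> M1 -> M2 -> Y).  An
effect switches exactly one argument from 0 to 1 while the other three are
fixed at a pattern of 0s and 1s called the effect's *type*; the number of
arguments fixed at 1 is its *level*.  This module enumerates the resulting
4 x 8 = 32 estimands, the 24 orderings in which the four arguments can be
switched 0 -> 1 (each ordering telescopes to the total causal effect, TCE),
and the coarser systems: the reduced system without the M1 -> M2 path, the
two mediator-specific (MS) merged systems, and the classical single-mediator
system.  Everything is verified against a brute-force telescoping oracle that
knows nothing about the generative orderings.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

#: The four pathways, in slot order (a0, a1, a2, a3).
PATHS: tuple[str, ...] = ("direct", "via_m1", "via_m2", "via_both")

#: Display names used in effect identifiers, by path.
PATH_LABELS: dict[str, str] = {
    "direct": "NDE",
    "via_m1": "NIE1",
    "via_m2": "NIE2",
    "via_both": "NIE12",
}

#: Table code scheme for the 8 types: 1=000, 2=100, 3=010, 4=001,
#: 5=110, 6=101, 7=011, 8=111.
TYPE_CODES: dict[tuple[int, ...], int] = {
    (0, 0, 0): 1,
    (1, 0, 0): 2,
    (0, 1, 0): 3,
    (0, 0, 1): 4,
    (1, 1, 0): 5,
    (1, 0, 1): 6,
    (0, 1, 1): 7,
    (1, 1, 1): 8,
}


def path_slot(path: str) -> int:
    """Slot index (position in (a0,a1,a2,a3)) varied by ``path``."""
    try:
        return PATHS.index(path)
    except ValueError:
        raise ValueError(f"unknown path {path!r}; expected one of {PATHS}") from None


def level(bits: Sequence[int]) -> int:
    """Level of an effect type: the number of fixed arguments set to 1."""
    return sum(bits)


def bits_str(bits: Sequence[int]) -> str:
    return "".join(str(b) for b in bits)


@dataclass(frozen=True)
class EffectContrast:
    """One natural path-specific estimand: E[Y(plus)] - E[Y(minus)].

    ``plus`` and ``minus`` are counterfactual indices (a0,a1,a2,a3); they
    differ only in the slot varied by ``path``, where plus holds 1.  The
    remaining slots carry ``bits``, listed in slot order with the varying
    slot removed.
    """

    path: str
    bits: tuple[int, int, int]
    plus: tuple[int, int, int, int]
    minus: tuple[int, int, int, int]

    @property
    def level(self) -> int:
        return level(self.bits)

    @property
    def type_code(self) -> int:
        return TYPE_CODES[self.bits]

    @property
    def name(self) -> str:
        return f"{PATH_LABELS[self.path]}-{bits_str(self.bits)}"

    @property
    def rho_free(self) -> bool:
        """True when neither half involves a cross-world mediator law.

        The joint law of (M1(0), M1(1)) is needed exactly when a1 != a3 in a
        counterfactual index, so an estimand is identified without the
        sensitivity parameter iff a1 == a3 in both halves.
        """
        return self.plus[1] == self.plus[3] and self.minus[1] == self.minus[3]


def effect_contrast(path: str, bits: Sequence[int]) -> EffectContrast:
    """The estimand varying ``path``'s argument with the others fixed at ``bits``."""
    bits = tuple(int(b) for b in bits)
    if len(bits) != 3 or any(b not in (0, 1) for b in bits):
        raise ValueError(f"type must be three bits, got {bits!r}")
    slot = path_slot(path)
    fixed = list(bits)
    plus = tuple(fixed[:slot] + [1] + fixed[slot:])
    minus = tuple(fixed[:slot] + [0] + fixed[slot:])
    return EffectContrast(path=path, bits=bits, plus=plus, minus=minus)


def enumerate_effects() -> list[EffectContrast]:
    """All 32 natural path-specific estimands (4 paths x 8 types)."""
    return [
        effect_contrast(path, bits)
        for path in PATHS
        for bits in itertools.product((0, 1), repeat=3)
    ]


@dataclass(frozen=True)
class Decomposition:
    """An exact additive split of the TCE into one type of each path effect.

    Generated by an ordering (permutation of the four paths) in which the
    exposure arguments are switched 0 -> 1; the component switching at
    position k has level k-1 and its fixed bits are 1 exactly on the slots
    switched earlier, so the four contrasts telescope from Y(0,0,0,0) to
    Y(1,1,1,1).
    """

    order: tuple[str, str, str, str]
    components: tuple[EffectContrast, ...]
    table_row: int | None = None

    @property
    def codes(self) -> tuple[int, int, int, int]:
        """Type codes in the fixed column order (NDE, NIE1, NIE2, NIE12)."""
        by_path = {c.path: c for c in self.components}
        return tuple(by_path[p].type_code for p in PATHS)

    def telescopes(self) -> bool:
        return _signed_sum(self.components) == _TCE_SUM_4


def _signed_sum(contrasts: Iterable[EffectContrast]) -> dict[tuple, int]:
    total: Counter = Counter()
    for c in contrasts:
        total[c.plus] += 1
        total[c.minus] -= 1
    return {k: v for k, v in total.items() if v != 0}


_TCE_SUM_4 = {(1, 1, 1, 1): 1, (0, 0, 0, 0): -1}


def decomposition_from_order(order: Sequence[str]) -> Decomposition:
    """Build the decomposition switching arguments 0 -> 1 in ``order``."""
    order = tuple(order)
    if sorted(order) != sorted(PATHS):
        raise ValueError(f"order must be a permutation of {PATHS}, got {order!r}")
    switched: set[int] = set()
    components = []
    for path in order:
        slot = path_slot(path)
        fixed = [1 if s in switched else 0 for s in range(4) if s != slot]
        components.append(effect_contrast(path, fixed))
        switched.add(slot)
    return Decomposition(order=order, components=tuple(components))


def enumerate_decompositions() -> list[Decomposition]:
    """All 24 decompositions of the TCE, sorted by their (NDE,NIE1,NIE2,NIE12)
    code row and numbered accordingly."""
    decomps = [decomposition_from_order(p) for p in itertools.permutations(PATHS)]
    decomps.sort(key=lambda d: d.codes)
    return [
        Decomposition(order=d.order, components=d.components, table_row=i + 1)
        for i, d in enumerate(decomps)
    ]


# ---------------------------------------------------------------------------
# Brute-force telescoping oracle (generic over slot systems)
# ---------------------------------------------------------------------------

def _generic_contrasts(n_slots: int, varying: int) -> list[tuple[tuple, tuple]]:
    """All (plus, minus) pairs varying one slot of an n-slot index."""
    out = []
    for fixed in itertools.product((0, 1), repeat=n_slots - 1):
        fixed = list(fixed)
        plus = tuple(fixed[:varying] + [1] + fixed[varying:])
        minus = tuple(fixed[:varying] + [0] + fixed[varying:])
        out.append((plus, minus))
    return out


def brute_force_valid_sums(n_slots: int = 4) -> int:
    """Count sums (one type per slot/path) that telescope to the TCE.

    Enumerates all ``(2^(n-1))^n`` ways of picking one fixed-bit pattern per
    varying slot, represents each candidate as an integer-weighted formal sum
    of counterfactual indices, and counts those cancelling exactly to
    ``+(1,...,1) - (0,...,0)``.  Independent of the ordering-based generator:
    this is the oracle that pins the 24 (n=4), 6 (n=3) and 2 (n=2) counts.
    """
    per_slot = [_generic_contrasts(n_slots, s) for s in range(n_slots)]
    target = {(1,) * n_slots: 1, (0,) * n_slots: -1}
    count = 0
    for choice in itertools.product(*per_slot):
        total: Counter = Counter()
        for plus, minus in choice:
            total[plus] += 1
            total[minus] -= 1
        if {k: v for k, v in total.items() if v != 0} == target:
            count += 1
    return count


def brute_force_valid_code_rows() -> list[tuple[int, int, int, int]]:
    """The telescoping sums of the full system as sorted type-code rows."""
    per_path = {
        path: [effect_contrast(path, bits) for bits in itertools.product((0, 1), repeat=3)]
        for path in PATHS
    }
    rows = []
    for choice in itertools.product(*(per_path[p] for p in PATHS)):
        if _signed_sum(choice) == _TCE_SUM_4:
            rows.append(tuple(c.type_code for c in choice))
    return sorted(rows)


# ---------------------------------------------------------------------------
# Reduced system (no M1 -> M2 effect): indices (a0, a1, a2)
# ---------------------------------------------------------------------------

REDUCED_PATHS: tuple[str, ...] = ("direct", "via_m1", "via_m2")


@dataclass(frozen=True)
class ReducedContrast:
    """Estimand of the 3-slot system Y(a0, M1(a1), M2(a2)) (unordered mediators)."""

    path: str
    bits: tuple[int, int]
    plus: tuple[int, int, int]
    minus: tuple[int, int, int]

    @property
    def level(self) -> int:
        return level(self.bits)

    @property
    def name(self) -> str:
        return f"{PATH_LABELS[self.path]}-{bits_str(self.bits)}"


def _reduced_contrast(path: str, bits: Sequence[int]) -> ReducedContrast:
    bits = tuple(int(b) for b in bits)
    slot = REDUCED_PATHS.index(path)
    fixed = list(bits)
    plus = tuple(fixed[:slot] + [1] + fixed[slot:])
    minus = tuple(fixed[:slot] + [0] + fixed[slot:])
    return ReducedContrast(path=path, bits=bits, plus=plus, minus=minus)


def enumerate_reduced_effects() -> list[ReducedContrast]:
    """The 12 estimands (3 paths x 4 types) when M1 does not affect M2."""
    return [
        _reduced_contrast(path, bits)
        for path in REDUCED_PATHS
        for bits in itertools.product((0, 1), repeat=2)
    ]


def enumerate_reduced_decompositions() -> list[tuple[ReducedContrast, ...]]:
    """The 6 orderings of the 3-slot system; each telescopes to the TCE."""
    out = []
    for order in itertools.permutations(REDUCED_PATHS):
        switched: set[int] = set()
        comps = []
        for path in order:
            slot = REDUCED_PATHS.index(path)
            fixed = [1 if s in switched else 0 for s in range(3) if s != slot]
            comps.append(_reduced_contrast(path, fixed))
            switched.add(slot)
        out.append(tuple(comps))
    return out


# ---------------------------------------------------------------------------
# Mediator-specific (MS) merged systems
# ---------------------------------------------------------------------------

MS_PATHS: tuple[str, ...] = ("direct", "via_m1", "via_m2")


@dataclass(frozen=True)
class MSEffectContrast:
    """Mediator-specific estimand on a merged 3-slot system.

    MS1 merges the through-both path into the through-M2 path: its varying
    "via_m2" argument sets a2 and a3 jointly, i.e. counterfactuals are
    Y(a0, M1(a1), M2(a, M1(a))) so a2 == a3 always.  MS2 merges through-both
    into through-M1: Y(a0, M1(a), M2(a2, M1(a))), so a1 == a3 always.
    ``plus``/``minus`` are embedded into the full 4-slot index so MS effects
    can be evaluated on the same 16-cell counterfactual table.
    """

    family: str  # "MS1" | "MS2"
    path: str
    bits: tuple[int, int]
    plus: tuple[int, int, int, int]
    minus: tuple[int, int, int, int]

    @property
    def level(self) -> int:
        return level(self.bits)

    @property
    def name(self) -> str:
        return f"{self.family}-{PATH_LABELS[self.path]}-{bits_str(self.bits)}"

    @property
    def rho_free(self) -> bool:
        return self.plus[1] == self.plus[3] and self.minus[1] == self.minus[3]


def _ms_embed(family: str, idx3: Sequence[int]) -> tuple[int, int, int, int]:
    """Map a merged 3-slot index into the full 4-slot index."""
    if family == "MS1":  # slots (a0, a1, a-merged) -> (a0, a1, a, a)
        a0, a1, a = idx3
        return (a0, a1, a, a)
    if family == "MS2":  # slots (a0, a-merged, a2) -> (a0, a, a2, a)
        a0, a, a2 = idx3
        return (a0, a, a2, a)
    raise ValueError(f"family must be 'MS1' or 'MS2', got {family!r}")


def _ms_contrast(family: str, path: str, bits: Sequence[int]) -> MSEffectContrast:
    bits = tuple(int(b) for b in bits)
    slot = MS_PATHS.index(path)
    fixed = list(bits)
    plus3 = tuple(fixed[:slot] + [1] + fixed[slot:])
    minus3 = tuple(fixed[:slot] + [0] + fixed[slot:])
    return MSEffectContrast(
        family=family,
        path=path,
        bits=bits,
        plus=_ms_embed(family, plus3),
        minus=_ms_embed(family, minus3),
    )


def enumerate_ms_effects(family: str) -> list[MSEffectContrast]:
    """The 12 mediator-specific estimands (3 paths x 4 types) of one family."""
    if family not in ("MS1", "MS2"):
        raise ValueError(f"family must be 'MS1' or 'MS2', got {family!r}")
    return [
        _ms_contrast(family, path, bits)
        for path in MS_PATHS
        for bits in itertools.product((0, 1), repeat=2)
    ]


def enumerate_ms_decompositions(family: str) -> list[tuple[MSEffectContrast, ...]]:
    """The 6 three-way orderings of one MS family; each telescopes to the TCE."""
    out = []
    for order in itertools.permutations(MS_PATHS):
        switched: set[int] = set()
        comps = []
        for path in order:
            slot = MS_PATHS.index(path)
            fixed = [1 if s in switched else 0 for s in range(3) if s != slot]
            comps.append(_ms_contrast(family, path, fixed))
            switched.add(slot)
        out.append(tuple(comps))
    return out


# ---------------------------------------------------------------------------
# Single-mediator system (review semantics): indices (a0, a1)
# ---------------------------------------------------------------------------

def enumerate_single_mediator_effects() -> dict[str, tuple[tuple, tuple]]:
    """PNDE/TNDE/PNIE/TNIE as (plus, minus) pairs of Y(a0, M(a1)) indices."""
    return {
        "PNDE": ((1, 0), (0, 0)),
        "TNDE": ((1, 1), (0, 1)),
        "PNIE": ((0, 1), (0, 0)),
        "TNIE": ((1, 1), (1, 0)),
    }


# ---------------------------------------------------------------------------
# Rho-free effects and summary weights
# ---------------------------------------------------------------------------

def rho_free_effects(include_ms: bool = True) -> list[str]:
    """Names of estimands identified without the cross-world sensitivity
    parameter, derived by the a1 == a3 predicate (never a hand list)."""
    names = [c.name for c in enumerate_effects() if c.rho_free]
    if include_ms:
        for family in ("MS1", "MS2"):
            names += [c.name for c in enumerate_ms_effects(family) if c.rho_free]
    return names


def type_appearance_counts(path: str = "direct") -> Counter:
    """How many of the 24 decompositions contain each type of ``path``'s effect."""
    counts: Counter = Counter()
    for d in enumerate_decompositions():
        by_path = {c.path: c for c in d.components}
        counts[by_path[path].bits] += 1
    return counts


def summary_weights() -> dict[tuple[int, int, int], Fraction]:
    """Weight of each effect type in the summary natural effects.

    The weight of a type is its number of appearances across the 24
    decompositions divided by 24; counted, not hard-coded.  Types 000 and 111
    appear 6 times each, the other six types twice, so the weights per path
    sum to 1.  The counts are identical for every path.
    """
    decomps = enumerate_decompositions()
    counts = type_appearance_counts("direct")
    return {bits: Fraction(c, len(decomps)) for bits, c in counts.items()}


def decompositions_containing(path: str, bits: Sequence[int]) -> list[Decomposition]:
    """Filter the 24 decompositions to those containing a given (path, type).

    Fixing e.g. the 000 type of one path of interest reduces the 24
    decompositions under consideration to 6.
    """
    bits = tuple(int(b) for b in bits)
    return [
        d
        for d in enumerate_decompositions()
        if any(c.path == path and c.bits == bits for c in d.components)
    ]


# ---------------------------------------------------------------------------
# Pretty-printers
# ---------------------------------------------------------------------------

def _index_str(idx: tuple[int, int, int, int]) -> str:
    a0, a1, a2, a3 = idx
    return f"Y({a0},M1({a1}),M2({a2},M1({a3})))"


def effects_table() -> pd.DataFrame:
    """The 32 estimands plus both MS families, one row per contrast."""
    rows = []
    for c in enumerate_effects():
        rows.append(
            {
                "effect": c.name,
                "path": c.path,
                "type": bits_str(c.bits),
                "level": c.level,
                "plus": _index_str(c.plus),
                "minus": _index_str(c.minus),
                "rho_free": c.rho_free,
            }
        )
    for family in ("MS1", "MS2"):
        for c in enumerate_ms_effects(family):
            rows.append(
                {
                    "effect": c.name,
                    "path": c.path,
                    "type": bits_str(c.bits),
                    "level": c.level,
                    "plus": _index_str(c.plus),
                    "minus": _index_str(c.minus),
                    "rho_free": c.rho_free,
                }
            )
    return pd.DataFrame(rows)


def decompositions_table() -> pd.DataFrame:
    """The 24 decompositions as code rows, columns NDE/NIE1/NIE2/NIE12."""
    rows = []
    for d in enumerate_decompositions():
        codes = d.codes
        rows.append(
            {
                "decomposition": d.table_row,
                "NDE": codes[0],
                "NIE1": codes[1],
                "NIE2": codes[2],
                "NIE12": codes[3],
                "order": " -> ".join(d.order),
            }
        )
    return pd.DataFrame(rows)


def format_tables_text() -> str:
    """Human-readable dump of the effect and decomposition listings."""
    eff = effects_table()
    dec = decompositions_table()
    lines = ["Natural path-specific effects", "=" * 29, eff.to_string(index=False), ""]
    lines += [
        "Decompositions of the TCE (codes: 1=000 2=100 3=010 4=001 5=110 6=101 7=011 8=111)",
        "=" * 48,
        dec.to_string(index=False),
    ]
    return "\n".join(lines)
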