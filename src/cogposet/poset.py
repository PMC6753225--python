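"""Identifiable partially-ordered classification models from a battery.

A cognitive profile assigns a level to each function (binary for ATT,
VF, CF, PS; ordinal 0-3 for episodic memory).  Each profile induces an
*ideal response vector* over the battery: 1 on the tests whose every
required function the profile holds at a high level, 0 elsewhere
(conjunctive response rule).  Profiles with identical ideal vectors
cannot be statistically distinguished by the battery; the equivalence
classes are the model's *states*.  States are partially ordered by
entrywise dominance of their ideal vectors, and the Hasse diagram is
the transitive reduction of that order.

Functions whose level varies across the profiles of a state are
*confounded* (undetermined) in that state: the battery only ever probes
them jointly with functions the state holds low, so their own level
leaves no signature in the ideal vector.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .battery import FUNCTIONS, BatterySpec, FunctionDomain, FULL_DOMAIN, TestSpec


@dataclass(frozen=True, order=True)
class Profile:
    """One assignment of levels to the functions: binary ATT/VF/CF/PS, ordinal EM."""

    att: int = 0
    em: int = 0
    vf: int = 0
    cf: int = 0
    ps: int = 0

    def __post_init__(self) -> None:
        for fn in ("att", "vf", "cf", "ps"):
            if getattr(self, fn) not in (0, 1):
                raise ValueError(f"{fn} must be 0 or 1")
        if self.em not in (0, 1, 2, 3):
            raise ValueError("em must be in 0..3")

    def indicator_vector(self) -> tuple[int, ...]:
        """Expand to (ATT, EM1, EM2, EM3, VF, CF, PS): EMj = 1 iff em >= j."""
        return (
            self.att,
            int(self.em >= 1),
            int(self.em >= 2),
            int(self.em >= 3),
            self.vf,
            self.cf,
            self.ps,
        )

    def dominates(self, other: "Profile") -> bool:
        """Componentwise >= with EM compared on its four-level scale."""
        return (
            self.att >= other.att
            and self.em >= other.em
            and self.vf >= other.vf
            and self.cf >= other.cf
            and self.ps >= other.ps
        )


def enumerate_profiles(domain: FunctionDomain = FULL_DOMAIN) -> list[Profile]:
    """Every profile of the domain exactly once.

    Canonical order: levels of excluded functions fixed at 0; included
    functions iterated in (att, em, vf, cf, ps) order, slowest first,
    levels ascending.  The full domain yields 64 profiles.
    """
    ranges = {
        "att": (0, 1) if "ATT" in domain.binary else (0,),
        "em": (0, 1, 2, 3) if domain.include_em else (0,),
        "vf": (0, 1) if "VF" in domain.binary else (0,),
        "cf": (0, 1) if "CF" in domain.binary else (0,),
        "ps": (0, 1) if "PS" in domain.binary else (0,),
    }
    return [
        Profile(att=a, em=e, vf=v, cf=c, ps=p)
        for a, e, v, c, p in itertools.product(
            ranges["att"], ranges["em"], ranges["vf"], ranges["cf"], ranges["ps"]
        )
    ]


def ideal_response(profile: Profile, battery: BatterySpec) -> tuple[int, ...]:
    """Binary vector over the battery: 1 iff the profile meets every requirement."""
    if len(battery) == 0:
        raise ValueError("battery must contain at least one test")
    out = []
    for t in battery:
        ok = (
            (not t.requires_att or profile.att == 1)
            and profile.em >= t.em_required
            and (not t.requires_vf or profile.vf == 1)
            and (not t.requires_cf or profile.cf == 1)
            and (not t.requires_ps or profile.ps == 1)
        )
        out.append(int(ok))
    return tuple(out)


@dataclass(frozen=True)
class State:
    """An equivalence class of profiles sharing one ideal response vector."""

    index: int
    members: frozenset[Profile]
    ideal: tuple[int, ...]
    determined: dict[str, int] = field(compare=False)
    undetermined: frozenset[str] = field(compare=False)

    @property
    def label_vector(self) -> tuple[int, ...]:
        """High indicators over FUNCTIONS; undetermined functions count as low."""
        return tuple(self.determined.get(fn, 0) for fn in FUNCTIONS)

    @property
    def n_high(self) -> int:
        return sum(self.label_vector)


def _class_summary(members: frozenset[Profile]) -> tuple[dict[str, int], frozenset[str]]:
    vectors = [m.indicator_vector() for m in members]
    determined: dict[str, int] = {}
    undetermined: set[str] = set()
    for j, fn in enumerate(FUNCTIONS):
        values = {v[j] for v in vectors}
        if len(values) == 1:
            determined[fn] = values.pop()
        else:
            undetermined.add(fn)
    return determined, frozenset(undetermined)


@dataclass(frozen=True)
class PosetModel:
    """States, their partial order and its Hasse diagram for one battery."""

    battery: BatterySpec
    states: tuple[State, ...]
    #: reflexive order as frozenset of (higher_index, lower_index) pairs
    order: frozenset[tuple[int, int]]
    #: transitive reduction, higher state -> lower state
    hasse_edges: tuple[tuple[int, int], ...]
    top_index: int | None
    bottom_index: int | None

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state(self, index: int) -> State:
        """State by its 1-based index."""
        return self.states[index - 1]

    def geq(self, i: int, j: int) -> bool:
        """True iff state i >= state j in the model order (1-based indices)."""
        return (i, j) in self.order

    def ideal_matrix(self):
        """n_states x n_tests 0/1 array of ideal response vectors."""
        import numpy as np

        return np.array([s.ideal for s in self.states], dtype=int)

    def high_indicator_matrix(self):
        """n_states x 7 array: determined-high indicators over FUNCTIONS."""
        import numpy as np

        return np.array([s.label_vector for s in self.states], dtype=int)


def build_model(battery: BatterySpec) -> PosetModel:
    """Group all profiles of the domain by ideal vector and order the classes.

    State indices are 1-based and form a linear extension of the order:
    states are sorted by their 7-function high-indicator vector
    (undetermined = low) in descending lexicographic order, ties broken
    by descending ideal vector.  This puts the all-high state first and
    the bottom class last and reproduces the published ADNI2/AIBL
    numbering.
    """
    if len(battery) == 0:
        raise ValueError("battery must contain at least one test")
    groups: dict[tuple[int, ...], set[Profile]] = {}
    for p in enumerate_profiles(battery.domain):
        groups.setdefault(ideal_response(p, battery), set()).add(p)

    raw = []
    for ideal, members in groups.items():
        determined, undetermined = _class_summary(frozenset(members))
        raw.append((ideal, frozenset(members), determined, undetermined))
    raw.sort(key=lambda r: (tuple(r[2].get(fn, 0) for fn in FUNCTIONS), r[0]),
             reverse=True)

    states = tuple(
        State(index=i, members=members, ideal=ideal,
              determined=determined, undetermined=undetermined)
        for i, (ideal, members, determined, undetermined) in enumerate(raw, start=1)
    )

    order = set()
    for s in states:
        for t in states:
            if all(a >= b for a, b in zip(s.ideal, t.ideal)):
                order.add((s.index, t.index))

    strict = nx.DiGraph((i, j) for i, j in order if i != j)
    strict.add_nodes_from(s.index for s in states)
    hasse = nx.transitive_reduction(strict)
    hasse_edges = tuple(sorted(hasse.edges()))

    maxima = [s.index for s in states if not any((t, s.index) in order and t != s.index
                                                 for t in (u.index for u in states))]
    minima = [s.index for s in states if not any((s.index, t) in order and t != s.index
                                                 for t in (u.index for u in states))]
    return PosetModel(
        battery=battery,
        states=states,
        order=frozenset(order),
        hasse_edges=hasse_edges,
        top_index=maxima[0] if len(maxima) == 1 else None,
        bottom_index=minima[0] if len(minima) == 1 else None,
    )


def detect_confounding(model: PosetModel) -> dict[int, frozenset[str]]:
    """Per state, the functions whose level varies across member profiles.

    The bottom class (all-zero ideal vector) is included with its full
    undetermined set here; reporting conventions (all-low) are applied
    by :func:`state_label`.
    """
    return {s.index: s.undetermined for s in model.states}


def state_label(state: State, model: PosetModel | None = None) -> list[str]:
    """Function names at a high level, starred when undetermined.

    The bottom class (ideal vector all zero) is reported with every
    function at a low level, the conservative published convention for
    states where nothing can be demonstrated.
    """
    if not any(state.ideal):
        return []
    label = []
    for fn in FUNCTIONS:
        if fn in state.undetermined:
            label.append(fn + "*")
        elif state.determined.get(fn, 0) == 1:
            label.append(fn)
    return label


def export_hasse(model: PosetModel) -> str:
    """Graphviz DOT digraph: one node per state, edges higher -> lower."""
    lines = ["digraph poset {", '  rankdir=TB;', '  node [shape=box];']
    for s in model.states:
        label = ", ".join(state_label(s)) or "(all low)"
        lines.append(f'  s{s.index} [label="{s.index}: {label}"];')
    for i, j in model.hasse_edges:
        lines.append(f"  s{i} -> s{j};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def state_table(model: PosetModel):
    """DataFrame mirroring the published state table: one row per state,
    one column per function indicator ('X' high, '*' undetermined, '' low)."""
    import pandas as pd

    rows = []
    for s in model.states:
        bottom = not any(s.ideal)
        row = {"state": s.index}
        for fn in FUNCTIONS:
            if bottom:
                row[fn] = ""
            elif fn in s.undetermined:
                row[fn] = "*"
            else:
                row[fn] = "X" if s.determined.get(fn, 0) == 1 else ""
        rows.append(row)
    return pd.DataFrame(rows).set_index("state")
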