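"""Enumeration and realization of splicing-intermediate states.

A splicing state records, for one transcript molecule, which introns are
still retained (bit 1) and which are already spliced out (bit 0), plus the
status of a trans-spliced 5' end (outron still attached vs. splice leader
added).  Realizing a state yields the concrete intermediate sequence that
an RT-PCR product or a sequencing read would derive from.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from intron_order.gene_model import GeneModel

OUTRON = "outron"
SPLICE_LEADER = "splice_leader"
NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True, order=True)
class SplicingState:
    """Per-transcript intron retention bit vector plus 5'-end status.

    ``retention[k]`` is 1 if intron ordinal ``k + 1`` is retained (most-5'
    intron first).
    """

    retention: tuple[int, ...]
    five_prime: str = NOT_APPLICABLE

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.retention):
            raise ValueError("retention bits must be 0 or 1")
        if self.five_prime not in (OUTRON, SPLICE_LEADER, NOT_APPLICABLE):
            raise ValueError(f"bad five_prime {self.five_prime!r}")

    def retained(self, ordinal: int) -> bool:
        return bool(self.retention[ordinal - 1])

    def bitstring(self) -> str:
        return "".join(str(b) for b in self.retention)

    def label(self) -> str:
        if self.five_prime == NOT_APPLICABLE:
            return self.bitstring()
        return f"{self.bitstring()}/{self.five_prime}"

    @classmethod
    def from_label(cls, label: str) -> "SplicingState":
        bits, _, tag = label.partition("/")
        return cls(tuple(int(b) for b in bits), tag or NOT_APPLICABLE)


@dataclass(frozen=True)
class StateConstraint:
    """Introns pinned retained (e.g. the RT-capture intron) or spliced."""

    forced_retained: frozenset[int] = frozenset()
    forced_spliced: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "forced_retained", frozenset(self.forced_retained))
        object.__setattr__(self, "forced_spliced", frozenset(self.forced_spliced))
        if self.forced_retained & self.forced_spliced:
            raise ValueError("forced_retained and forced_spliced must be disjoint")


_FIVE_PRIME_ORDER = (OUTRON, SPLICE_LEADER)


def enumerate_states(
    model: GeneModel, constraint: Optional[StateConstraint] = None
) -> list[SplicingState]:
    """All splicing states of ``model`` compatible with ``constraint``.

    2^k states over the k unconstrained introns, doubled over outron /
    splice-leader 5' ends when the model is trans-spliced.  Order is
    deterministic: lexicographic by retention bits (most-5' intron first),
    outron before splice leader.
    """
    constraint = constraint or StateConstraint()
    ordinals = set(range(1, model.n_introns + 1))
    for o in constraint.forced_retained | constraint.forced_spliced:
        if o not in ordinals:
            raise ValueError(f"constraint ordinal {o} not in model {model.name}")
    free = sorted(ordinals - constraint.forced_retained - constraint.forced_spliced)
    states = []
    for bits in itertools.product((0, 1), repeat=len(free)):
        retention = [0] * model.n_introns
        for o in constraint.forced_retained:
            retention[o - 1] = 1
        for o, b in zip(free, bits):
            retention[o - 1] = b
        if model.outron is not None:
            for tag in _FIVE_PRIME_ORDER:
                states.append(SplicingState(tuple(retention), tag))
        else:
            states.append(SplicingState(tuple(retention)))
    states.sort(key=lambda s: (s.retention, _sort_tag(s.five_prime)))
    return states


def _sort_tag(tag: str) -> int:
    return 0 if tag == NOT_APPLICABLE else _FIVE_PRIME_ORDER.index(tag)


def realize_with_junctions(
    model: GeneModel, state: SplicingState
) -> tuple[str, list[int]]:
    """Realize a state's sequence and return the splice-joint positions.

    Junctions are the boundaries between consecutive retained features in
    the realized sequence (exon/intron borders, splice points of excised
    introns, and the SL/outron joint), excluding sequence ends.
    """
    if len(state.retention) != model.n_introns:
        raise ValueError("state dimension does not match model intron count")
    if model.outron is None and state.five_prime != NOT_APPLICABLE:
        raise ValueError(f"{model.name} has no outron; five_prime must be not_applicable")
    if model.outron is not None and state.five_prime == NOT_APPLICABLE:
        raise ValueError(f"{model.name} is trans-spliced; five_prime must be set")

    parts: list[str] = []
    if model.outron is not None:
        if state.five_prime == OUTRON:
            s, e = model.outron
            parts.append(model.sequence[s:e])
        else:
            parts.append(model.splice_leader)

    features: list[tuple[int, int, bool]] = [(s, e, True) for s, e in model.exons]
    for iv in model.introns:
        features.append((iv.start, iv.end, state.retained(iv.ordinal)))
    features.sort()
    for s, e, keep in features:
        if keep:
            parts.append(model.sequence[s:e])
        else:
            parts.append("")  # spliced intron: a junction, no sequence

    junctions: list[int] = []
    pos = 0
    seq_parts: list[str] = []
    for part in parts:
        if seq_parts and pos not in junctions:
            junctions.append(pos)
        seq_parts.append(part)
        pos += len(part)
    junctions = [j for j in junctions if 0 < j < pos]
    return "".join(seq_parts), junctions


def realize_sequence(model: GeneModel, state: SplicingState) -> str:
    """The concrete intermediate sequence for one splicing state."""
    return realize_with_junctions(model, state)[0]


def state_table(
    model: GeneModel, constraint: Optional[StateConstraint] = None
) -> pd.DataFrame:
    """State space as a table: bitstring, 5' tag, realized length."""
    rows = []
    for st in enumerate_states(model, constraint):
        rows.append(
            {
                "state": st.bitstring(),
                "five_prime": st.five_prime,
                "length": len(realize_sequence(model, st)),
            }
        )
    return pd.DataFrame(rows)


def write_population(population: dict[SplicingState, int], path: str) -> None:
    """Serialize a state multiset as TSV (state, five_prime, count)."""
    rows = [
        {"state": st.bitstring(), "five_prime": st.five_prime, "count": n}
        for st, n in sorted(population.items())
    ]
    pd.DataFrame(rows, columns=["state", "five_prime", "count"]).to_csv(
        path, sep="\t", index=False
    )


def load_population(path: str) -> dict[SplicingState, int]:
    df = pd.read_csv(path, sep="\t", dtype={"state": str})
    pop: dict[SplicingState, int] = {}
    for r in df.itertuples(index=False):
        st = SplicingState(tuple(int(b) for b in r.state), str(r.five_prime))
        pop[st] = pop.get(st, 0) + int(r.count)
    return pop
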