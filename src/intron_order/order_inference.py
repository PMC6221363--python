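"""Category tallies to precedence statistics and a partial removal order.

Once reads are tallied per splicing state, the order questions become
category algebra: how many reads retain at least one conventional intron
while all nonconventional introns are still present (support for the
conventional-first principle), how many violate it, which of two introns
is more often the first to go, and which strict "i before j" relations the
pooled evidence supports.  Intermediate-flagged introns count under their
resolved operational category throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Optional, Sequence

from intron_order.gene_model import CONVENTIONAL, NONCONVENTIONAL, GeneModel


@dataclass
class CategoryTally:
    """Read counts per splicing state for one amplicon.

    ``counts`` is keyed by retention bitstring over all introns of the
    gene; ``analyzed_introns`` excludes the capture intron and anything
    downstream of it (those are retained by construction, not evidence).
    """

    amplicon_name: str
    gene: str
    capture_intron: int
    analyzed_introns: tuple[int, ...]
    intron_categories: dict[int, str]
    counts: dict[str, int]

    def __post_init__(self) -> None:
        n = len(self.intron_categories)
        for bits, count in self.counts.items():
            if count < 0:
                raise ValueError("counts must be >= 0")
            if len(bits) != n:
                raise ValueError(
                    f"state {bits!r} inconsistent with {n} annotated introns"
                )

    @classmethod
    def from_model(
        cls,
        model: GeneModel,
        amplicon_name: str,
        capture_intron: int,
        counts: Mapping[str, int],
    ) -> "CategoryTally":
        return cls(
            amplicon_name=amplicon_name,
            gene=model.name,
            capture_intron=capture_intron,
            analyzed_introns=tuple(range(1, capture_intron)),
            intron_categories=model.intron_categories(),
            counts=dict(counts),
        )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def retained(self, bits: str, ordinal: int) -> bool:
        return bits[ordinal - 1] == "1"

    def analyzed_of_category(self, category: str) -> tuple[int, ...]:
        return tuple(
            o for o in self.analyzed_introns if self.intron_categories[o] == category
        )


def write_tally(tally: CategoryTally, path: str) -> None:
    """Tally as TSV with a self-describing comment header."""
    cats = ",".join(
        f"{o}:{c}" for o, c in sorted(tally.intron_categories.items())
    )
    with open(path, "w") as fh:
        fh.write(f"#amplicon={tally.amplicon_name}\n")
        fh.write(f"#gene={tally.gene}\n")
        fh.write(f"#capture_intron={tally.capture_intron}\n")
        fh.write(f"#intron_categories={cats}\n")
        fh.write("state\tcount\n")
        for bits, count in sorted(tally.counts.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{bits}\t{count}\n")


def load_tally(path: str) -> CategoryTally:
    meta: dict[str, str] = {}
    counts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
            elif line and not line.startswith("state\t"):
                bits, count = line.split("\t")
                counts[bits] = counts.get(bits, 0) + int(count)
    categories = {
        int(tok.split(":")[0]): tok.split(":")[1]
        for tok in meta["intron_categories"].split(",")
    }
    capture = int(meta["capture_intron"])
    return CategoryTally(
        amplicon_name=meta["amplicon"],
        gene=meta["gene"],
        capture_intron=capture,
        analyzed_introns=tuple(range(1, capture)),
        intron_categories=categories,
        counts=counts,
    )


def percentages(tally: CategoryTally) -> dict[str, float]:
    """Per-category percentages of the accepted-read total, half-up to 2 dp."""
    total = tally.total
    if total == 0:
        raise ValueError("cannot compute percentages of an empty tally")
    out = {}
    for bits, count in tally.counts.items():
        pct = Decimal(100 * count) / Decimal(total)
        out[bits] = float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return out


# -- predicate algebra -------------------------------------------------------


class Predicate:
    """Composable predicate over intron presence within one tally.

    Built from the atom constructors below; supports ``&``, ``|`` and
    ``~``.  Atoms referencing explicit ordinals record them so queries can
    refuse predicates that touch the capture intron.
    """

    def __init__(
        self,
        fn: Callable[[str, CategoryTally], bool],
        referenced: frozenset[int] = frozenset(),
        description: str = "",
    ):
        self._fn = fn
        self.referenced = referenced
        self.description = description

    def __call__(self, bits: str, tally: CategoryTally) -> bool:
        return self._fn(bits, tally)

    def __and__(self, other: "Predicate") -> "Predicate":
        return Predicate(
            lambda b, t: self(b, t) and other(b, t),
            self.referenced | other.referenced,
            f"({self.description}) AND ({other.description})",
        )

    def __or__(self, other: "Predicate") -> "Predicate":
        return Predicate(
            lambda b, t: self(b, t) or other(b, t),
            self.referenced | other.referenced,
            f"({self.description}) OR ({other.description})",
        )

    def __invert__(self) -> "Predicate":
        return Predicate(
            lambda b, t: not self(b, t), self.referenced, f"NOT ({self.description})"
        )


def intron_present(ordinal: int) -> Predicate:
    return Predicate(
        lambda b, t: t.retained(b, ordinal),
        frozenset({ordinal}),
        f"intron {ordinal} present",
    )


def intron_absent(ordinal: int) -> Predicate:
    return Predicate(
        lambda b, t: not t.retained(b, ordinal),
        frozenset({ordinal}),
        f"intron {ordinal} absent",
    )


def at_least_of_type(category: str, k: int, present: bool = True) -> Predicate:
    def fn(bits: str, tally: CategoryTally) -> bool:
        ords = tally.analyzed_of_category(category)
        hits = sum(tally.retained(bits, o) == present for o in ords)
        return hits >= k

    word = "present" if present else "absent"
    return Predicate(fn, frozenset(), f">={k} {category} {word}")


def all_of_type(category: str, present: bool = True) -> Predicate:
    def fn(bits: str, tally: CategoryTally) -> bool:
        ords = tally.analyzed_of_category(category)
        return all(tally.retained(bits, o) == present for o in ords)

    word = "present" if present else "absent"
    return Predicate(fn, frozenset(), f"all {category} {word}")


ALWAYS = Predicate(lambda b, t: True, frozenset(), "TRUE")


def category_query(tally: CategoryTally, predicate: Predicate) -> int:
    """Total reads over states satisfying the predicate."""
    bad = predicate.referenced - set(tally.analyzed_introns)
    if bad:
        raise ValueError(
            f"predicate references non-analyzed intron(s) {sorted(bad)} "
            f"(capture intron {tally.capture_intron} is not evidence)"
        )
    return sum(
        count for bits, count in tally.counts.items() if predicate(bits, tally)
    )


# -- precedence statistics ---------------------------------------------------


@dataclass(frozen=True)
class PrecedenceCounts:
    n_i_first: int
    n_j_first: int
    n_both_present: int
    n_both_absent: int

    @property
    def total(self) -> int:
        return self.n_i_first + self.n_j_first + self.n_both_present + self.n_both_absent


def pairwise_precedence(tally: CategoryTally, i: int, j: int) -> PrecedenceCounts:
    """Partition reads by which of introns i and j is already removed."""
    if i == j:
        raise ValueError("pairwise precedence needs two distinct introns")
    for o in (i, j):
        if o not in tally.analyzed_introns:
            raise ValueError(f"intron {o} is not analyzed in {tally.amplicon_name}")
    n_i = n_j = n_both = n_neither = 0
    for bits, count in tally.counts.items():
        pi, pj = tally.retained(bits, i), tally.retained(bits, j)
        if not pi and pj:
            n_i += count
        elif pi and not pj:
            n_j += count
        elif pi and pj:
            n_both += count
        else:
            n_neither += count
    return PrecedenceCounts(n_i, n_j, n_both, n_neither)


def single_removal_counts(tally: CategoryTally) -> dict[int, int]:
    """Reads in which exactly one analyzed intron has been removed, per intron."""
    out = {o: 0 for o in tally.analyzed_introns}
    for bits, count in tally.counts.items():
        absent = [o for o in tally.analyzed_introns if not tally.retained(bits, o)]
        if len(absent) == 1:
            out[absent[0]] += count
    return out


def conventional_first_consistency(
    tally: CategoryTally,
) -> tuple[int, int, list[str]]:
    """Reads (in)consistent with conventional-before-nonconventional removal.

    A state is inconsistent iff some nonconventional intron is already
    absent while some conventional intron is still present.
    """
    n_consistent = n_inconsistent = 0
    offenders: list[str] = []
    conv = tally.analyzed_of_category(CONVENTIONAL)
    nonconv = tally.analyzed_of_category(NONCONVENTIONAL)
    for bits, count in tally.counts.items():
        some_nonconv_absent = any(not tally.retained(bits, o) for o in nonconv)
        some_conv_present = any(tally.retained(bits, o) for o in conv)
        if some_nonconv_absent and some_conv_present:
            n_inconsistent += count
            if count:
                offenders.append(bits)
        else:
            n_consistent += count
    return n_consistent, n_inconsistent, sorted(offenders)


# -- partial order -----------------------------------------------------------


@dataclass
class OrderReport:
    """Aggregated removal-order inference across amplicons."""

    percentages: dict[str, dict[str, float]]
    pairwise: dict[str, dict[str, dict]]
    relations: list[dict]
    type_level: dict

    def to_dict(self) -> dict:
        return {
            "percentages": self.percentages,
            "pairwise": self.pairwise,
            "relations": self.relations,
            "type_level": self.type_level,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_text(self) -> str:
        lines = ["Inferred intron-removal order", "=" * 31]
        for rel in self.relations:
            lines.append(
                f"  {rel['gene']}: intron {rel['i']} {rel['kind']} intron {rel['j']} "
                f"({rel['n_i_first']} vs {rel['n_j_first']} reads)"
            )
        t = self.type_level
        lines.append(
            f"  type level: conventional before nonconventional — "
            f"{t['support']} supporting reads, {t['counterexamples']} counterexamples"
        )
        return "\n".join(lines)


def infer_partial_order(tallies: Sequence[CategoryTally]) -> OrderReport:
    """Pool tallies into pairwise relations and a type-level conclusion.

    Within each gene, for every intron pair seen by at least one amplicon,
    a strict relation "i before j" is emitted only when intermediates with
    i removed and j retained exist while the reverse class is empty; when
    both classes are populated the relation is a graded preference with the
    count ratio.  Type level, the support is the number of reads retaining
    at least one conventional intron with every nonconventional intron
    still present, against the inconsistent reads as counterexamples.
    """
    if not tallies:
        raise ValueError("need at least one tally")

    pct = {t.amplicon_name: percentages(t) for t in tallies}

    by_gene: dict[str, list[CategoryTally]] = {}
    for t in tallies:
        by_gene.setdefault(t.gene, []).append(t)

    pairwise: dict[str, dict[str, dict]] = {}
    relations: list[dict] = []
    for gene, group in by_gene.items():
        pairs: dict[tuple[int, int], list[int]] = {}
        for t in group:
            for a in t.analyzed_introns:
                for b in t.analyzed_introns:
                    if a < b:
                        pc = pairwise_precedence(t, a, b)
                        acc = pairs.setdefault((a, b), [0, 0, 0, 0])
                        acc[0] += pc.n_i_first
                        acc[1] += pc.n_j_first
                        acc[2] += pc.n_both_present
                        acc[3] += pc.n_both_absent
        gene_table = {}
        for (a, b), (ni, nj, nboth, nnone) in sorted(pairs.items()):
            gene_table[f"{a},{b}"] = {
                "n_i_first": ni,
                "n_j_first": nj,
                "n_both_present": nboth,
                "n_both_absent": nnone,
            }
            if ni > 0 and nj == 0:
                kind, i, j, wi, wj = "before", a, b, ni, nj
            elif nj > 0 and ni == 0:
                kind, i, j, wi, wj = "before", b, a, nj, ni
            elif ni > 0 and nj > 0:
                if ni >= nj:
                    kind, i, j, wi, wj = "preferred_over", a, b, ni, nj
                else:
                    kind, i, j, wi, wj = "preferred_over", b, a, nj, ni
            else:
                continue
            relations.append(
                {
                    "gene": gene,
                    "i": i,
                    "j": j,
                    "kind": kind,
                    "n_i_first": wi,
                    "n_j_first": wj,
                }
            )
        pairwise[gene] = gene_table

    support = 0
    counterexamples = 0
    for t in tallies:
        if not t.analyzed_of_category(CONVENTIONAL) or not t.analyzed_of_category(
            NONCONVENTIONAL
        ):
            continue
        support += category_query(
            t,
            at_least_of_type(CONVENTIONAL, 1, present=True)
            & all_of_type(NONCONVENTIONAL, present=True),
        )
        counterexamples += conventional_first_consistency(t)[1]
    type_level = {
        "relation": "conventional_before_nonconventional",
        "support": support,
        "counterexamples": counterexamples,
    }
    return OrderReport(pct, pairwise, relations, type_level)
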