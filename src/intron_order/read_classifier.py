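"""Amplicon read classification by exhaustive candidate-isoform alignment.

Every splicing state compatible with the RT-capture constraint is realized
as an explicit candidate amplicon; each read is assigned to the candidate
with the smallest global edit distance (edlib, Needleman-Wunsch mode).
Acceptance filters mirror a curated long-read analysis: a read must be
flanked by both PCR primers (complete amplification), must not extend
beyond the primer binding sites, must align within a relative edit-distance
budget, must beat the runner-up candidate by a clear margin, and must have
no alignment edit within a small window of any splice junction of its best
candidate — edits there are indistinguishable from defective splicing and
are discarded rather than guessed.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import edlib
from Bio import SeqIO

from intron_order.gene_model import GeneModel, Primer, reverse_complement
from intron_order.isoform_space import (
    SplicingState,
    StateConstraint,
    realize_with_junctions,
)
from intron_order.order_inference import CategoryTally

logger = logging.getLogger(__name__)

OUTCOMES = (
    "assigned",
    "rejected_incomplete",
    "rejected_overextended",
    "rejected_junction_ambiguity",
    "rejected_distance",
    "rejected_tie",
    "malformed",
)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class ClassifierParams:
    """Acceptance thresholds for read classification.

    ``max_edit_fraction``: maximum edit distance / read length.
    ``junction_window``: nt on each side of every splice junction of the
    best candidate within which no alignment edit is tolerated.
    ``tie_margin``: minimum edit-distance gap between best and second-best
    candidate; closer calls are biologically ambiguous and rejected.
    ``primer_hamming``: per-primer mismatch tolerance at the read ends.
    ``max_overhang``: nt a read may extend past the longest candidate.
    """

    max_edit_fraction: float = 0.15
    junction_window: int = 6
    require_both_primers: bool = True
    tie_margin: int = 2
    primer_hamming: int = 1
    max_overhang: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.max_edit_fraction < 1:
            raise ValueError("max_edit_fraction must lie in [0, 1)")
        if self.junction_window < 0:
            raise ValueError("junction_window must be >= 0")
        if self.tie_margin < 1:
            raise ValueError("tie_margin must be >= 1")


@dataclass(frozen=True)
class ReadCall:
    read_id: str
    outcome: str
    state: Optional[SplicingState] = None
    edit_distance: Optional[int] = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if (self.state is not None) != (self.outcome == "assigned"):
            raise ValueError("state must be present iff the read was assigned")


@dataclass
class CandidateSet:
    """Realized candidate amplicons for one (gene, primer pair) design."""

    model: GeneModel
    forward_primer: Primer
    reverse_primer: Primer
    capture_intron: int
    states: list[SplicingState]
    sequences: dict[SplicingState, str]
    junctions: dict[SplicingState, tuple[int, ...]]

    @property
    def fwd_site(self) -> str:
        return self.forward_primer.site

    @property
    def rev_site(self) -> str:
        return self.reverse_primer.site

    @property
    def max_length(self) -> int:
        return max(len(s) for s in self.sequences.values())


def candidate_amplicons(
    model: GeneModel,
    fwd: Primer,
    rev_intron_ordinal: int,
    primer_length: Optional[int] = None,
    rev: Optional[Primer] = None,
) -> CandidateSet:
    """Realize one candidate amplicon per splicing state under RT capture.

    The capture intron — and every intron downstream of the reverse primer,
    which the amplicon cannot see — is forced retained, so candidates are
    enumerated only over the introns the amplicon actually interrogates.
    """
    from intron_order.synthetic_data import amplicon_of_state  # avoid cycle
    from intron_order.gene_model import design_primer

    model.intron(rev_intron_ordinal)
    if rev is None:
        length = primer_length or len(fwd.sequence)
        rev = design_primer(
            model, f"i{rev_intron_ordinal}R", "reverse",
            "intron", rev_intron_ordinal, -length, length,
        )
    forced = frozenset(
        o for o in range(rev_intron_ordinal, model.n_introns + 1)
    )
    constraint = StateConstraint(forced_retained=forced)
    from intron_order.isoform_space import enumerate_states

    states, seqs, juncs = [], {}, {}
    for st in enumerate_states(model, constraint):
        if st.five_prime not in ("not_applicable",):
            continue  # amplicon designs here are cis-spliced genes
        try:
            seq, junctions = amplicon_of_state(model, st, fwd, rev)
        except ValueError:
            logger.warning("primer does not frame state %s; candidate omitted", st.label())
            continue
        states.append(st)
        seqs[st] = seq
        juncs[st] = tuple(junctions)
    if not states:
        raise ValueError("no realizable candidate amplicons")
    return CandidateSet(model, fwd, rev, rev_intron_ordinal, states, seqs, juncs)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def alignment_edits(read: str, reference: str) -> tuple[int, list[tuple[str, int]]]:
    """Global alignment of read vs reference; edits as (kind, ref position).

    Mismatches and deletions (bases of the reference absent from the read)
    are located at reference base coordinates; insertions (read bases
    absent from the reference) at reference boundary coordinates.
    """
    res = edlib.align(read, reference, mode="NW", task="path")
    edits: list[tuple[str, int]] = []
    ref_pos = 0
    for count, op in _CIGAR_RE.findall(res["cigar"]):
        count = int(count)
        if op == "=":
            ref_pos += count
        elif op == "X":
            edits.extend(("mismatch", ref_pos + k) for k in range(count))
            ref_pos += count
        elif op == "D":  # reference base missing from the read
            edits.extend(("deletion", ref_pos + k) for k in range(count))
            ref_pos += count
        elif op == "I":  # read base absent from the reference
            edits.extend(("insertion", ref_pos) for _ in range(count))
    return res["editDistance"], edits


def classify_read(
    read_id: str,
    read: str,
    candidates: CandidateSet,
    params: Optional[ClassifierParams] = None,
) -> ReadCall:
    """Assign one read to a splicing state, or reject it with a reason."""
    params = params or ClassifierParams()
    if not read:
        raise ValueError("empty read")
    read = read.upper()

    if params.require_both_primers:
        fwd_site, rev_site = candidates.fwd_site, candidates.rev_site
        if len(read) < max(len(fwd_site), len(rev_site)):
            return ReadCall(read_id, "rejected_incomplete")
        if (
            _hamming(read[: len(fwd_site)], fwd_site) > params.primer_hamming
            or _hamming(read[-len(rev_site):], rev_site) > params.primer_hamming
        ):
            return ReadCall(read_id, "rejected_incomplete")

    if len(read) > candidates.max_length + params.max_overhang:
        return ReadCall(read_id, "rejected_overextended")

    distances = []
    for st in candidates.states:
        d = edlib.align(read, candidates.sequences[st], mode="NW", task="distance")
        distances.append((d["editDistance"], st))
    distances.sort(key=lambda t: (t[0], t[1]))
    best_d, best_state = distances[0]
    if best_d > params.max_edit_fraction * len(read):
        return ReadCall(read_id, "rejected_distance")
    if len(distances) > 1 and distances[1][0] - best_d < params.tie_margin:
        return ReadCall(read_id, "rejected_tie")

    if best_d > 0:
        from intron_order.synthetic_data import edit_near_junction

        _, edits = alignment_edits(read, candidates.sequences[best_state])
        junctions = candidates.junctions[best_state]
        for kind, pos in edits:
            if edit_near_junction(kind, pos, junctions, params.junction_window):
                return ReadCall(read_id, "rejected_junction_ambiguity")

    return ReadCall(read_id, "assigned", best_state, best_d)


@dataclass
class BatchResult:
    """Classification outcome for one read file."""

    tally: CategoryTally
    rejections: Counter
    calls: list[ReadCall]

    @property
    def n_reads(self) -> int:
        return len(self.calls)

    @property
    def n_assigned(self) -> int:
        return self.tally.total


def _iter_reads(path: str):
    fmt = "fastq"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    fmt = "fasta"
                break
    yield from SeqIO.parse(path, fmt)


def classify_batch(
    reads_path: str,
    model: GeneModel,
    fwd: Primer,
    rev_intron_ordinal: int,
    params: Optional[ClassifierParams] = None,
    amplicon_name: Optional[str] = None,
    rev: Optional[Primer] = None,
) -> BatchResult:
    """Classify every read in a FASTA/FASTQ file against the candidate space.

    Returns the per-state tally over assigned reads plus rejection counts;
    accepted + rejected always equals the number of input reads.
    """
    params = params or ClassifierParams()
    candidates = candidate_amplicons(model, fwd, rev_intron_ordinal, rev=rev)
    counts: Counter = Counter()
    rejections: Counter = Counter()
    calls: list[ReadCall] = []
    try:
        for rec in _iter_reads(reads_path):
            call = classify_read(rec.id, str(rec.seq), candidates, params)
            calls.append(call)
            if call.outcome == "assigned":
                counts[call.state.bitstring()] += 1
            else:
                rejections[call.outcome] += 1
    except ValueError as exc:
        logger.error("unparseable record in %s: %s", reads_path, exc)
        rejections["malformed"] += 1
        calls.append(ReadCall(f"malformed_{rejections['malformed']}", "malformed"))
    tally = CategoryTally.from_model(
        model,
        amplicon_name or f"{model.name}_i{rev_intron_ordinal}",
        rev_intron_ordinal,
        dict(counts),
    )
    return BatchResult(tally, rejections, calls)


def write_calls(calls: Iterable[ReadCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\toutcome\tstate\tedit_distance\n")
        for c in calls:
            state = c.state.bitstring() if c.state is not None else ""
            dist = "" if c.edit_distance is None else str(c.edit_distance)
            fh.write(f"{c.read_id}\t{c.outcome}\t{state}\t{dist}\n")
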