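"""Synthetic gene models, splicing kinetics, and amplicon read generation.

This module is the stand-in for the study system: *Euglena gracilis* tubA
(six introns: conventional at ordinals 1, 2 and 5 with lengths 52, 230 and
157 nt; nonconventional at 3 — an intermediate intron operationally treated
as nonconventional — 4 and 6) and gapC (four introns: an intermediate
intron treated as conventional at ordinal 1, nonconventional at 2–4), plus
an rbcS-style trans-spliced 5' end (outron + splice leader) with
nonconventional introns only.

The kinetic model encodes the two-machinery hypothesis under test:
conventional (spliceosomal) introns are removed co-transcriptionally, each
with its own exponential clock starting at t = 0; nonconventional introns
become removable only after an onset lag τ, and are then excised rapidly —
either all at once per transcript (coordinated) or independently.  An
RT-capture primer inside the last or penultimate intron restricts the
observable population to splicing intermediates still retaining that
intron, exactly as the wet-lab design excludes mature mRNA.

Reads are emitted as FASTQ with i.i.d. per-base mismatch/insertion/deletion
errors (CCS-like rates by default) alongside a ground-truth table, and
`generate_fixture` replays the published per-category read counts of the
three sequenced amplicons as error-free reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Union

import numpy as np

from intron_order.gene_model import (
    CONVENTIONAL,
    NONCONVENTIONAL,
    GeneModel,
    IntronAnnotation,
    Primer,
    design_primer,
)
from intron_order.isoform_space import (
    NOT_APPLICABLE,
    OUTRON,
    SPLICE_LEADER,
    SplicingState,
    realize_with_junctions,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ErrorModel:
    """Per-base i.i.d. sequencing error rates."""

    mismatch_rate: float = 0.005
    insertion_rate: float = 0.005
    deletion_rate: float = 0.005

    def __post_init__(self) -> None:
        for r in (self.mismatch_rate, self.insertion_rate, self.deletion_rate):
            if not 0 <= r < 1:
                raise ValueError("error rates must lie in [0, 1)")

    @property
    def total(self) -> float:
        return self.mismatch_rate + self.insertion_rate + self.deletion_rate

    def is_null(self) -> bool:
        return self.total == 0


ERROR_FREE = ErrorModel(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Kinetic and observation parameters for one simulated population.

    Rates are per unit time; a transcript is observed at a time drawn
    uniformly from ``sampling_window``.  ``conv_rates`` is either one rate
    shared by all conventional introns or a map ordinal -> rate.
    ``nonconv_onset_lag`` is the delay τ after transcript completion before
    nonconventional removal can begin; ``coordinated`` removes all
    nonconventional introns of a transcript in one event.
    """

    n_transcripts: int = 10_000
    conv_rates: Union[float, Mapping[int, float]] = 1.0
    nonconv_onset_lag: float = 8.0
    nonconv_rate: float = 5.0
    coordinated: bool = True
    trans_rate: float = 1.0
    capture_intron: Optional[int] = None
    sampling_window: tuple[float, float] = (0.0, 10.0)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            [self.conv_rates]
            if isinstance(self.conv_rates, (int, float))
            else list(self.conv_rates.values())
        )
        if any(r < 0 for r in rates):
            raise ValueError("conventional rates must be >= 0")
        if self.nonconv_rate < 0 or self.trans_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.nonconv_onset_lag < 0:
            raise ValueError("onset lag must be >= 0")
        if self.sampling_window[0] > self.sampling_window[1]:
            raise ValueError("sampling window must satisfy t_min <= t_max")
        if self.n_transcripts < 0:
            raise ValueError("n_transcripts must be >= 0")

    def conv_rate_for(self, ordinal: int) -> float:
        if isinstance(self.conv_rates, (int, float)):
            return float(self.conv_rates)
        return float(self.conv_rates[ordinal])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def generate_gene(
    n_introns: int,
    categories: Iterable[str],
    lengths: Iterable[int],
    exon_lengths: Iterable[int],
    seed: int,
    name: str = "synthetic_gene",
    intermediate: Iterable[int] = (),
    outron_length: Optional[int] = None,
    splice_leader_length: int = 26,
) -> GeneModel:
    """Random gene with the requested exon/intron architecture.

    ``categories`` and ``lengths`` are per-intron (5'->3');
    ``exon_lengths`` must have ``n_introns + 1`` entries; ``intermediate``
    lists ordinals carrying the intermediate-features flag.
    """
    categories = list(categories)
    lengths = [int(x) for x in lengths]
    exon_lengths = [int(x) for x in exon_lengths]
    if not len(categories) == len(lengths) == n_introns:
        raise ValueError("categories and lengths must have n_introns entries")
    if len(exon_lengths) != n_introns + 1:
        raise ValueError("need n_introns + 1 exon lengths")
    intermediate = set(intermediate)

    rng = np.random.default_rng(seed)
    parts: list[tuple[str, int]] = []  # (kind, length) in genomic order
    if outron_length:
        parts.append(("outron", outron_length))
    for i in range(n_introns):
        parts.append(("exon", exon_lengths[i]))
        parts.append(("intron", lengths[i]))
    parts.append(("exon", exon_lengths[-1]))

    seq_parts, exons, introns = [], [], []
    outron = None
    pos, intron_ordinal = 0, 0
    for kind, length in parts:
        seq_parts.append(_random_seq(rng, length))
        if kind == "exon":
            exons.append((pos, pos + length))
        elif kind == "intron":
            intron_ordinal += 1
            introns.append(
                IntronAnnotation(
                    ordinal=intron_ordinal,
                    start=pos,
                    end=pos + length,
                    category=categories[intron_ordinal - 1],
                    intermediate=intron_ordinal in intermediate,
                )
            )
        else:
            outron = (pos, pos + length)
        pos += length
    splice_leader = _random_seq(rng, splice_leader_length) if outron_length else None
    return GeneModel(
        name=name,
        sequence="".join(seq_parts),
        exons=exons,
        introns=introns,
        outron=outron,
        splice_leader=splice_leader,
    )


# -- presets ---------------------------------------------------------------

TUBA_INTRON_LENGTHS = (52, 230, 98, 104, 157, 92)
TUBA_CATEGORIES = (
    CONVENTIONAL, CONVENTIONAL, NONCONVENTIONAL,
    NONCONVENTIONAL, CONVENTIONAL, NONCONVENTIONAL,
)
TUBA_EXON_LENGTHS = (150, 140, 160, 180, 200, 170, 210)

GAPC_INTRON_LENGTHS = (96, 110, 88, 102)
GAPC_CATEGORIES = (
    CONVENTIONAL, NONCONVENTIONAL, NONCONVENTIONAL, NONCONVENTIONAL,
)
GAPC_EXON_LENGTHS = (160, 150, 190, 170, 200)

RBCS_INTRON_LENGTHS = (104, 96)
RBCS_EXON_LENGTHS = (100, 150, 180)


def tuba_like(seed: int = 101) -> GeneModel:
    """tubA architecture: 6 introns, conventional at 1/2/5 (52/230/157 nt),
    nonconventional at 3 (intermediate), 4 and 6."""
    return generate_gene(
        6, TUBA_CATEGORIES, TUBA_INTRON_LENGTHS, TUBA_EXON_LENGTHS,
        seed=seed, name="tubA_like", intermediate={3},
    )


def gapc_like(seed: int = 102) -> GeneModel:
    """gapC architecture: 4 introns, conventional (intermediate) at 1,
    nonconventional at 2-4."""
    return generate_gene(
        4, GAPC_CATEGORIES, GAPC_INTRON_LENGTHS, GAPC_EXON_LENGTHS,
        seed=seed, name="gapC_like", intermediate={1},
    )


def rbcs_like(seed: int = 103) -> GeneModel:
    """rbcS-style 5' end: outron + splice leader, nonconventional introns only."""
    return generate_gene(
        2,
        (NONCONVENTIONAL, NONCONVENTIONAL),
        RBCS_INTRON_LENGTHS,
        RBCS_EXON_LENGTHS,
        seed=seed,
        name="rbcS_like",
        outron_length=150,
    )


# -- kinetics ---------------------------------------------------------------


def simulate_population(model: GeneModel, config: SimulationConfig) -> Counter:
    """Draw a population of splicing states under the two-machinery model.

    Each transcript is observed at t ~ U(sampling window).  Conventional
    intron i is spliced iff an Exp(rate_i) waiting time is < t.
    Nonconventional introns can only be spliced once t exceeds the onset
    lag τ, then with probability 1 - exp(-rate (t - τ)) — all-or-none per
    transcript when coordinated, independently otherwise.  With an outron,
    trans-splicing (splice-leader addition) follows an Exp(trans_rate)
    clock like a conventional event.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    t_min, t_max = config.sampling_window
    t = rng.uniform(t_min, t_max, n)

    retention = np.ones((n, model.n_introns), dtype=np.int8)
    nonconv = [iv.ordinal for iv in model.introns if iv.category == NONCONVENTIONAL]

    for iv in model.introns:
        if iv.category != CONVENTIONAL:
            continue
        rate = config.conv_rate_for(iv.ordinal)
        if rate > 0:
            waits = rng.exponential(1.0 / rate, n)
            retention[waits < t, iv.ordinal - 1] = 0

    tau, r = config.nonconv_onset_lag, config.nonconv_rate
    if nonconv and r > 0:
        dt = np.clip(t - tau, 0.0, None)
        p = 1.0 - np.exp(-r * dt)
        if config.coordinated:
            hit = rng.random(n) < p
            for o in nonconv:
                retention[hit, o - 1] = 0
        else:
            for o in nonconv:
                hit = rng.random(n) < p
                retention[hit, o - 1] = 0

    if model.outron is not None:
        if config.trans_rate > 0:
            trans = rng.exponential(1.0 / config.trans_rate, n) < t
        else:
            trans = np.zeros(n, dtype=bool)
        tags = np.where(trans, SPLICE_LEADER, OUTRON)
    else:
        tags = np.full(n, NOT_APPLICABLE, dtype=object)

    population: Counter = Counter()
    for row, tag in zip(retention, tags):
        population[SplicingState(tuple(int(b) for b in row), str(tag))] += 1
    return population


def capture_and_amplify(
    population: Mapping[SplicingState, int],
    model: GeneModel,
    fwd: Primer,
    rev_intron_ordinal: int,
) -> Counter:
    """RT capture: keep only templates still retaining the primer-targeted intron."""
    model.intron(rev_intron_ordinal)
    kept: Counter = Counter()
    for st, count in population.items():
        if st.retained(rev_intron_ordinal):
            kept[st] += count
    return kept


# -- read emission ----------------------------------------------------------


def amplicon_of_state(
    model: GeneModel, state: SplicingState, fwd: Primer, rev: Primer
) -> tuple[str, list[int]]:
    """Realized amplicon (fwd 5' start .. rev 3' end) and its junction positions."""
    seq, junctions = realize_with_junctions(model, state)
    fpos = seq.find(fwd.site)
    rpos = seq.find(rev.site)
    if fpos < 0 or rpos < 0 or fpos >= rpos:
        raise ValueError(
            f"primers {fwd.name}/{rev.name} do not frame state {state.label()}"
        )
    start, end = fpos, rpos + len(rev.sequence)
    clipped = [j - start for j in junctions if start < j < end]
    return seq[start:end], clipped


def _inject_errors(
    seq: str, error_model: ErrorModel, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int]]]:
    """Apply i.i.d. per-base errors; return mutated sequence and edits.

    Edits are (kind, ref_position): mismatch/deletion at a reference base,
    insertion at a reference boundary (before that base; len(seq) = end).
    """
    if error_model.is_null():
        return seq, []
    n = len(seq)
    u = rng.random(n)
    ins = rng.random(n + 1) < error_model.insertion_rate
    m, d = error_model.mismatch_rate, error_model.deletion_rate
    out: list[str] = []
    edits: list[tuple[str, int]] = []
    for i in range(n + 1):
        if ins[i]:
            out.append(rng.choice(_BASES).decode())
            edits.append(("insertion", i))
        if i == n:
            break
        base = seq[i]
        if u[i] < d:
            edits.append(("deletion", i))
        elif u[i] < d + m:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(3)])
            edits.append(("mismatch", i))
        else:
            out.append(base)
    return "".join(out), edits


def edit_near_junction(
    kind: str, pos: int, junctions: Iterable[int], w: int
) -> bool:
    """Is an edit column within w nt of a splice junction?

    Junctions sit between reference bases.  A mismatch or deletion at base
    ``pos`` is near junction j when j - w <= pos < j + w; an insertion at
    boundary ``pos`` when |pos - j| <= w.
    """
    for j in junctions:
        if kind == "insertion":
            if abs(pos - j) <= w:
                return True
        elif j - w <= pos < j + w:
            return True
    return False


def emit_reads(
    states: Mapping[SplicingState, int],
    model: GeneModel,
    fwd: Primer,
    rev: Primer,
    error_model: ErrorModel,
    seed: int,
    fastq_path: str,
    truth_path: str,
    junction_window: int = 6,
    shuffle: bool = True,
) -> int:
    """Write error-injected amplicon reads (FASTQ) plus a ground-truth TSV.

    The truth table records each read's true state, whether any injected
    error fell within ``junction_window`` nt of a splice junction
    (``rejected_truth`` — such reads are expected to be discarded as
    junction-ambiguous downstream), and whether any error corrupted a
    primer site (``primer_error`` — such reads fail the completeness
    filter instead).  Returns the number of reads written.  Deterministic:
    same states + seed give byte-identical output.
    """
    rng = np.random.default_rng(seed)
    per_state = {
        st: amplicon_of_state(model, st, fwd, rev) for st in sorted(states)
    }
    order: list[SplicingState] = []
    for st in sorted(states):
        order.extend([st] * states[st])
    if shuffle and order:
        order = [order[i] for i in rng.permutation(len(order))]

    nf, nr = len(fwd.sequence), len(rev.sequence)
    n_written = 0
    with open(fastq_path, "w") as fq, open(truth_path, "w") as tt:
        tt.write(
            "read_id\tstate\tfive_prime\tlength\tn_errors\t"
            "rejected_truth\tprimer_error\n"
        )
        for idx, st in enumerate(order):
            amplicon, junctions = per_state[st]
            read, edits = _inject_errors(amplicon, error_model, rng)
            flagged = any(
                edit_near_junction(kind, pos, junctions, junction_window)
                for kind, pos in edits
            )
            in_primer = any(
                pos < nf or pos >= len(amplicon) - nr for _, pos in edits
            )
            read_id = f"read_{idx:06d}"
            fq.write(f"@{read_id}\n{read}\n+\n{'?' * len(read)}\n")
            tt.write(
                f"{read_id}\t{st.bitstring()}\t{st.five_prime}\t{len(read)}\t"
                f"{len(edits)}\t{str(flagged).lower()}\t{str(in_primer).lower()}\n"
            )
            n_written += 1
    return n_written


# -- amplicon designs and published tallies ---------------------------------


@dataclass(frozen=True)
class AmpliconDesign:
    """One sequenced amplicon: gene preset, forward primer, capture intron."""

    name: str
    model_factory: Callable[[], GeneModel]
    capture_intron: int
    primer_length: int = 20

    def model(self) -> GeneModel:
        return self.model_factory()

    def forward_primer(self, model: GeneModel) -> Primer:
        return design_primer(
            model, f"{self.name}_e1F", "forward", "exon", 1, 10, self.primer_length
        )

    def reverse_primer(self, model: GeneModel) -> Primer:
        # anneals flush with the capture-intron 3' end, so the amplicon
        # spans exon 1 through (almost) the whole capture intron
        return design_primer(
            model, f"{self.name}_i{self.capture_intron}R", "reverse",
            "intron", self.capture_intron, -self.primer_length, self.primer_length,
        )


AMPLICONS: dict[str, AmpliconDesign] = {
    "gapC": AmpliconDesign("gapC", gapc_like, capture_intron=4),
    "i6_tubA": AmpliconDesign("i6_tubA", tuba_like, capture_intron=6),
    "i5_tubA": AmpliconDesign("i5_tubA", tuba_like, capture_intron=5),
}

# Published per-category accepted-read counts for the three amplicons
# (bitstring = intron retention, most-5' intron first; the capture intron
# and any intron downstream of it are necessarily retained).
REFERENCE_COUNTS: dict[str, dict[str, int]] = {
    "gapC": {
        "0111": 11_293,  # first (conventional) intron spliced
        "1111": 3_650,   # all introns present
        "0001": 17,      # all analyzed introns spliced
    },
    "i6_tubA": {
        "001101": 2_782,  # I: all conventional out, nonconventional in
        "011101": 676,    # II: i1 and i5 out
        "111101": 399,    # III: only i5 out
        "111111": 322,    # IV: all present
        "001111": 136,    # V: i1 and i2 out
        "011111": 106,    # VI: only i1 out
        "101101": 60,     # VII: i2 and i5 out
        "000001": 9,      # VIII: all analyzed out
        "001001": 8,      # IX: only i3 (and capture i6) present
        "101111": 2,      # X: only i2 out
        "100001": 2,      # XI: i1 present, all other analyzed out
    },
    "i5_tubA": {
        "111111": 5_055,  # I: all present
        "011111": 756,    # II: i1 out
        "001111": 245,    # III: i1 and i2 out
        "101111": 26,     # IV: only i2 out
    },
}


@dataclass(frozen=True)
class Fixture:
    """A generated read set with its gene model and primers."""

    amplicon_name: str
    model: GeneModel
    forward_primer: Primer
    reverse_primer: Primer
    capture_intron: int
    fastq_path: str
    truth_path: str
    n_reads: int


def generate_fixture(
    amplicon_name: str,
    category_counts: Mapping[str, int],
    seed: int,
    fastq_path: str,
    truth_path: str,
) -> Fixture:
    """Emit exactly the requested number of error-free reads per category.

    ``category_counts`` maps retention bitstrings to read counts; each
    state must retain the amplicon's capture intron.  Used to replay the
    published tallies through the classifier.
    """
    design = AMPLICONS[amplicon_name]
    model = design.model()
    states: Counter = Counter()
    for bits, count in category_counts.items():
        st = SplicingState(tuple(int(b) for b in bits))
        if len(st.retention) != model.n_introns:
            raise ValueError(f"state {bits} has wrong dimension for {model.name}")
        if not st.retained(design.capture_intron):
            raise ValueError(
                f"state {bits} splices the capture intron {design.capture_intron}"
            )
        if count < 0:
            raise ValueError("category counts must be >= 0")
        states[st] += int(count)
    fwd = design.forward_primer(model)
    rev = design.reverse_primer(model)
    n = emit_reads(
        states, model, fwd, rev, ERROR_FREE, seed, fastq_path, truth_path
    )
    return Fixture(
        amplicon_name, model, fwd, rev, design.capture_intron,
        fastq_path, truth_path, n,
    )
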