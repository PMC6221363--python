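"""Read classification: candidate spaces, acceptance filters, oracles."""

from collections import Counter

import numpy as np
import pytest

from intron_order.gene_model import design_primer
from intron_order.read_classifier import (
    ClassifierParams,
    alignment_edits,
    candidate_amplicons,
    classify_batch,
    classify_read,
)
from intron_order.synthetic_data import (
    AMPLICONS,
    ERROR_FREE,
    ErrorModel,
    SimulationConfig,
    capture_and_amplify,
    emit_reads,
    generate_gene,
    simulate_population,
)


def _candidates(model, amplicon):
    design = AMPLICONS[amplicon]
    return candidate_amplicons(
        model, design.forward_primer(model), design.capture_intron,
        rev=design.reverse_primer(model),
    )


def edit_distance_dp(a: str, b: str) -> int:
    """Plain full-matrix Levenshtein oracle."""
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, 1):
        cur = np.empty(len(b) + 1, dtype=int)
        cur[0] = i
        for j, cb in enumerate(b, 1):
            cur[j] = min(
                prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)
            )
        prev = cur
    return int(prev[-1])


class TestCandidateSpace:
    def test_candidate_counts(self, tuba, gapc):
        assert len(_candidates(gapc, "gapC").states) == 8
        assert len(_candidates(tuba, "i6_tubA").states) == 32
        # the penultimate-intron amplicon cannot see intron 6, so it is
        # not enumerated: 2^4 candidates over introns 1-4
        assert len(_candidates(tuba, "i5_tubA").states) == 16

    def test_single_intron_gene_single_candidate(self):
        model = generate_gene(
            1, ["nonconventional"], [80], [120, 120], seed=5, name="mini"
        )
        fwd = design_primer(model, "e1F", "forward", "exon", 1, 0)
        cands = candidate_amplicons(model, fwd, 1)
        assert len(cands.states) == 1

    def test_candidate_sequences_distinct(self, tuba):
        cands = _candidates(tuba, "i6_tubA")
        assert len(set(cands.sequences.values())) == 32


class TestClassifyRead:
    @pytest.mark.parametrize("amplicon", ["gapC", "i6_tubA"])
    def test_exhaustive_error_free_assignment(self, amplicon, tuba, gapc):
        """Every error-free candidate amplicon maps back to its own state."""
        model = tuba if amplicon != "gapC" else gapc
        cands = _candidates(model, amplicon)
        for state in cands.states:
            call = classify_read("r", cands.sequences[state], cands)
            assert call.outcome == "assigned"
            assert call.state == state
            assert call.edit_distance == 0

    def test_mismatch_near_junction_rejected(self, tuba):
        cands = _candidates(tuba, "i6_tubA")
        state = cands.states[-1]  # fully retained
        seq = cands.sequences[state]
        j = cands.junctions[state][0]
        pos = j + 2  # within the default 6-nt window
        read = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1:]
        call = classify_read("r", read, cands)
        assert call.outcome == "rejected_junction_ambiguity"

    def test_mismatch_far_from_junctions_tolerated(self, tuba):
        cands = _candidates(tuba, "i6_tubA")
        state = cands.states[-1]
        seq = cands.sequences[state]
        junctions = cands.junctions[state]
        pos = next(
            p for p in range(40, len(seq) - 40)
            if all(abs(p - j) > 10 for j in junctions)
        )
        read = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1:]
        call = classify_read("r", read, cands)
        assert call.outcome == "assigned"
        assert call.state == state
        assert call.edit_distance == 1

    def test_missing_forward_primer_rejected(self, tuba):
        cands = _candidates(tuba, "i6_tubA")
        seq = cands.sequences[cands.states[-1]]
        call = classify_read("r", seq[10:], cands)
        assert call.outcome == "rejected_incomplete"

    def test_overextended_read_rejected(self, tuba):
        cands = _candidates(tuba, "i6_tubA")
        seq = cands.sequences[cands.states[-1]]
        mid = len(seq) // 2
        read = seq[:mid] + "ACGT" * 8 + seq[mid:]
        call = classify_read("r", read, cands)
        assert call.outcome == "rejected_overextended"

    def test_empty_read_rejected(self, tuba):
        cands = _candidates(tuba, "i6_tubA")
        with pytest.raises(ValueError):
            classify_read("r", "", cands)

    def test_edit_distance_matches_dp_oracle(self, gapc):
        """edlib distances equal a plain full-matrix DP on mutated reads."""
        cands = _candidates(gapc, "gapC")
        rng = np.random.default_rng(0)
        bases = "ACGT"
        short_states = sorted(cands.states)[:3]
        for state in short_states:
            seq = list(cands.sequences[state])
            for _ in range(8):
                p = rng.integers(len(seq))
                seq[p] = bases[rng.integers(4)]
            read = "".join(seq)
            for other in short_states:
                import edlib

                fast = edlib.align(
                    read, cands.sequences[other], mode="NW", task="distance"
                )["editDistance"]
                assert fast == edit_distance_dp(read, cands.sequences[other])

    def test_alignment_edit_positions(self):
        # reference AACCGGTT; read mutates position 2 and deletes position 5
        d, edits = alignment_edits("AATCGTT", "AACCGGTT")
        assert d == 2
        kinds = {k for k, _ in edits}
        assert kinds <= {"mismatch", "deletion", "insertion"}


class TestClassifyBatch:
    def _simulated_batch(self, tuba, tmp_path, error_model, n=400, seed=3):
        design = AMPLICONS["i6_tubA"]
        cfg = SimulationConfig(
            n_transcripts=n, nonconv_onset_lag=5.0, error_model=error_model,
            seed=seed,
        )
        pop = simulate_population(tuba, cfg)
        fwd, rev = design.forward_primer(tuba), design.reverse_primer(tuba)
        captured = capture_and_amplify(pop, tuba, fwd, 6)
        fq, tt = str(tmp_path / "r.fastq"), str(tmp_path / "t.tsv")
        emit_reads(captured, tuba, fwd, rev, error_model, seed, fq, tt)
        return fq, tt, fwd

    def test_read_conservation(self, tuba, tmp_path):
        fq, tt, fwd = self._simulated_batch(tuba, tmp_path, ErrorModel())
        result = classify_batch(fq, tuba, fwd, 6)
        n_input = sum(1 for line in open(fq) if line.startswith("@read_"))
        assert result.tally.total + sum(result.rejections.values()) == n_input

    def test_error_robustness_away_from_junctions(self, tuba, tmp_path):
        """>= 95% of reads whose errors avoid junction windows and primer
        sites are assigned to their true state at default CCS-like error
        rates."""
        fq, tt, fwd = self._simulated_batch(tuba, tmp_path, ErrorModel(), n=1000)
        truth = {}
        for line in open(tt).read().splitlines()[1:]:
            rid, bits, _, _, _, flagged, in_primer = line.split("\t")
            truth[rid] = (bits, flagged == "true" or in_primer == "true")
        result = classify_batch(fq, tuba, fwd, 6)
        clean = [c for c in result.calls if not truth[c.read_id][1]]
        assert len(clean) >= 30  # sanity: the comparison is not vacuous
        correct = sum(
            1
            for c in clean
            if c.outcome == "assigned" and c.state.bitstring() == truth[c.read_id][0]
        )
        assert correct / len(clean) >= 0.95

    def test_junction_flagged_reads_are_rejected(self, tuba, tmp_path):
        """Reads with a single mismatch planted 2 nt from a junction are
        all rejected for junction ambiguity."""
        design = AMPLICONS["i6_tubA"]
        fwd, rev = design.forward_primer(tuba), design.reverse_primer(tuba)
        cands = candidate_amplicons(tuba, fwd, 6, rev=rev)
        state = cands.states[-1]
        seq = cands.sequences[state]
        fq = tmp_path / "planted.fastq"
        with open(fq, "w") as fh:
            for i, j in enumerate(cands.junctions[state][:10] * 10):
                pos = j + 2
                read = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1:]
                fh.write(f"@planted_{i:03d}\n{read}\n+\n{'?' * len(read)}\n")
        result = classify_batch(str(fq), tuba, fwd, 6)
        assert result.rejections["rejected_junction_ambiguity"] == 100

    def test_empty_fastq(self, tuba, tmp_path):
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        design = AMPLICONS["i6_tubA"]
        result = classify_batch(str(fq), tuba, design.forward_primer(tuba), 6)
        assert result.tally.total == 0
        assert result.n_reads == 0

    def test_fasta_input_accepted(self, tuba, tmp_path):
        design = AMPLICONS["i6_tubA"]
        fwd, rev = design.forward_primer(tuba), design.reverse_primer(tuba)
        cands = candidate_amplicons(tuba, fwd, 6, rev=rev)
        state = cands.states[0]
        fa = tmp_path / "r.fasta"
        fa.write_text(f">r1\n{cands.sequences[state]}\n")
        result = classify_batch(str(fa), tuba, fwd, 6)
        assert result.tally.counts == {state.bitstring(): 1}
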