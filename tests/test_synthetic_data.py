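"""Kinetic simulator, error injection, fixture generation."""

import math

import numpy as np
import pytest

from intron_order.gene_model import CONVENTIONAL, NONCONVENTIONAL
from intron_order.isoform_space import SPLICE_LEADER, SplicingState
from intron_order.synthetic_data import (
    AMPLICONS,
    ERROR_FREE,
    REFERENCE_COUNTS,
    ErrorModel,
    SimulationConfig,
    amplicon_of_state,
    capture_and_amplify,
    emit_reads,
    generate_fixture,
    generate_gene,
    simulate_population,
    tuba_like,
)


def test_generate_gene_degenerate_intronless():
    model = generate_gene(0, [], [], [60], seed=1)
    assert model.n_introns == 0
    assert len(model.sequence) == 60


def test_generate_gene_mismatched_lists_rejected():
    with pytest.raises(ValueError):
        generate_gene(2, [CONVENTIONAL], [50, 60], [100, 100, 100], seed=1)


def test_presets_are_reproducible(tuba):
    assert tuba_like().sequence == tuba.sequence


class TestKinetics:
    def test_infinite_lag_freezes_nonconventional(self, tuba):
        cfg = SimulationConfig(
            n_transcripts=2000, nonconv_onset_lag=1e9, seed=7
        )
        pop = simulate_population(tuba, cfg)
        for state in pop:
            assert state.retained(3) and state.retained(4) and state.retained(6)

    def test_fast_conventional_long_lag_accumulates_signature_state(self, tuba):
        # high conventional rates + late nonconventional onset: the
        # population is dominated by conventional-spliced /
        # nonconventional-retained transcripts
        cfg = SimulationConfig(
            n_transcripts=5000,
            conv_rates=50.0,
            nonconv_onset_lag=9.5,
            sampling_window=(0.0, 10.0),
            seed=11,
        )
        pop = simulate_population(tuba, cfg)
        signature = SplicingState((0, 0, 1, 1, 0, 1))
        assert pop[signature] / cfg.n_transcripts > 0.85

    def test_conventional_marginals_match_closed_form(self, tuba):
        # at a fixed observation time t, P(intron i spliced) = 1 - exp(-r t)
        n = 10_000
        t = 1.3
        rates = {1: 1.5, 2: 0.5, 5: 2.0}
        cfg = SimulationConfig(
            n_transcripts=n, conv_rates=rates,
            sampling_window=(t, t), nonconv_onset_lag=1e9, seed=13,
        )
        pop = simulate_population(tuba, cfg)
        for ordinal, rate in rates.items():
            p = 1 - math.exp(-rate * t)
            observed = sum(
                c for s, c in pop.items() if not s.retained(ordinal)
            ) / n
            se = math.sqrt(p * (1 - p) / n)
            assert abs(observed - p) < 3 * se

    def test_nonconventional_marginal_matches_closed_form(self, tuba):
        n = 10_000
        t, tau, r = 9.0, 8.0, 5.0
        cfg = SimulationConfig(
            n_transcripts=n, conv_rates=1.0, nonconv_onset_lag=tau,
            nonconv_rate=r, sampling_window=(t, t), coordinated=True, seed=17,
        )
        pop = simulate_population(tuba, cfg)
        p = 1 - math.exp(-r * (t - tau))
        observed = sum(c for s, c in pop.items() if not s.retained(4)) / n
        se = math.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 3 * se

    def test_coordinated_removal_is_all_or_none(self, tuba):
        cfg = SimulationConfig(n_transcripts=3000, coordinated=True, seed=19)
        pop = simulate_population(tuba, cfg)
        nonconv = (3, 4, 6)
        for state in pop:
            bits = {state.retained(o) for o in nonconv}
            assert len(bits) == 1

    def test_lag_monotonically_favors_signature_class(self, tuba):
        freqs = []
        for tau in (0.0, 2.0, 5.0, 8.0):
            cfg = SimulationConfig(
                n_transcripts=4000, conv_rates=2.0, nonconv_onset_lag=tau,
                nonconv_rate=2.0, seed=23,
            )
            pop = simulate_population(tuba, cfg)
            conv_out_nonconv_in = sum(
                c
                for s, c in pop.items()
                if not any(s.retained(o) for o in (1, 2, 5))
                and all(s.retained(o) for o in (3, 4, 6))
            )
            freqs.append(conv_out_nonconv_in / cfg.n_transcripts)
        assert all(b >= a for a, b in zip(freqs, freqs[1:]))

    def test_capture_keeps_only_retaining_states(self, tuba):
        design = AMPLICONS["i6_tubA"]
        cfg = SimulationConfig(n_transcripts=5000, nonconv_onset_lag=2.0, seed=29)
        pop = simulate_population(tuba, cfg)
        fwd = design.forward_primer(tuba)
        captured = capture_and_amplify(pop, tuba, fwd, 6)
        assert all(s.retained(6) for s in captured)
        # surviving fraction matches the population marginal exactly
        marginal = sum(c for s, c in pop.items() if s.retained(6))
        assert sum(captured.values()) == marginal

    def test_capture_fraction_matches_analytic_value(self, tuba):
        # coordinated removal at fixed t: P(capture intron retained)
        # = exp(-r (t - tau))
        n, t, tau, r = 10_000, 8.5, 8.0, 5.0
        cfg = SimulationConfig(
            n_transcripts=n, nonconv_onset_lag=tau, nonconv_rate=r,
            sampling_window=(t, t), seed=31,
        )
        pop = simulate_population(tuba, cfg)
        design = AMPLICONS["i6_tubA"]
        captured = capture_and_amplify(pop, tuba, design.forward_primer(tuba), 6)
        p = math.exp(-r * (t - tau))
        observed = sum(captured.values()) / n
        se = math.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 3 * se


class TestEmitReads:
    def _setup(self, tuba):
        design = AMPLICONS["i6_tubA"]
        fwd, rev = design.forward_primer(tuba), design.reverse_primer(tuba)
        states = {
            SplicingState((1, 1, 1, 1, 1, 1)): 30,
            SplicingState((0, 0, 1, 1, 0, 1)): 30,
        }
        return design, fwd, rev, states

    def test_error_free_reads_equal_amplicons(self, tuba, tmp_path):
        design, fwd, rev, states = self._setup(tuba)
        fq, tt = str(tmp_path / "r.fastq"), str(tmp_path / "t.tsv")
        n = emit_reads(states, tuba, fwd, rev, ERROR_FREE, 1, fq, tt)
        assert n == 60
        amplicons = {
            st.bitstring(): amplicon_of_state(tuba, st, fwd, rev)[0]
            for st in states
        }
        truth = {}
        for line in open(tt).read().splitlines()[1:]:
            rid, bits, _, _, nerr, flagged, in_primer = line.split("\t")
            truth[rid] = bits
            assert nerr == "0" and flagged == "false" and in_primer == "false"
        reads = open(fq).read().splitlines()
        assert len(reads) == 4 * 60
        for i in range(0, len(reads), 4):
            rid = reads[i][1:]
            assert reads[i + 1] == amplicons[truth[rid]]

    def test_error_rate_matches_binomial_oracle(self, tuba, tmp_path):
        design, fwd, rev, _ = self._setup(tuba)
        state = SplicingState((1, 1, 1, 1, 1, 1))
        n_reads = 5000
        em = ErrorModel(0.005, 0.005, 0.005)
        fq, tt = str(tmp_path / "r.fastq"), str(tmp_path / "t.tsv")
        emit_reads({state: n_reads}, tuba, fwd, rev, em, 2, fq, tt)
        length = len(amplicon_of_state(tuba, state, fwd, rev)[0])
        errors = [
            int(line.split("\t")[4])
            for line in open(tt).read().splitlines()[1:]
        ]
        # insertions occur at length + 1 boundaries
        expected = length * (em.mismatch_rate + em.deletion_rate) + (
            length + 1
        ) * em.insertion_rate
        se = math.sqrt(expected / n_reads)  # Poisson-ish SE of the mean
        assert abs(np.mean(errors) - expected) < 3 * se
        assert len(errors) == n_reads

    def test_byte_identical_given_seed(self, tuba, tmp_path):
        design, fwd, rev, states = self._setup(tuba)
        em = ErrorModel()
        outs = []
        for tag in ("a", "b"):
            fq = str(tmp_path / f"{tag}.fastq")
            tt = str(tmp_path / f"{tag}.tsv")
            emit_reads(states, tuba, fwd, rev, em, 42, fq, tt)
            outs.append((open(fq, "rb").read(), open(tt, "rb").read()))
        assert outs[0] == outs[1]


class TestGenerateFixture:
    def test_reference_counts_sum_to_published_totals(self):
        assert sum(REFERENCE_COUNTS["gapC"].values()) == 14_960
        assert sum(REFERENCE_COUNTS["i6_tubA"].values()) == 4_502
        assert sum(REFERENCE_COUNTS["i5_tubA"].values()) == 6_082

    def test_fixture_emits_requested_counts(self, tmp_path):
        counts = {"0111": 5, "1111": 3, "0001": 2}
        fx = generate_fixture(
            "gapC", counts, 1, str(tmp_path / "r.fastq"), str(tmp_path / "t.tsv")
        )
        assert fx.n_reads == 10
        from collections import Counter

        truth = Counter(
            line.split("\t")[1]
            for line in open(fx.truth_path).read().splitlines()[1:]
        )
        assert dict(truth) == counts

    def test_state_splicing_capture_intron_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_fixture(
                "gapC", {"0110": 5}, 1,
                str(tmp_path / "r.fastq"), str(tmp_path / "t.tsv"),
            )

    def test_empty_counts_give_empty_fastq(self, tmp_path):
        fx = generate_fixture(
            "gapC", {}, 1, str(tmp_path / "r.fastq"), str(tmp_path / "t.tsv")
        )
        assert fx.n_reads == 0
        assert open(fx.fastq_path).read() == ""
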