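"""Error, dropout and dilution simulation; recovery-curve sweeps."""

import numpy as np
import pytest

import yycodec as yy
from yycodec.framing import FrameLayout
from yycodec.robustness import (
    ErrorModel,
    apply_dropout,
    apply_error_model,
    apply_indels,
    apply_substitutions,
    simulate_dilution,
    sweep_recovery,
)
from yycodec.rules import REFERENCE_SCHEME
from yycodec.synthetic import SyntheticSpec, gen_file


@pytest.fixture(scope="module")
def pool():
    rng = np.random.default_rng(0)
    return ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(400)]


class TestSubstitutions:
    def test_zero_rate_is_identity(self, pool):
        assert apply_substitutions(pool, ErrorModel(snv_rate=0.0), rng=1) == pool

    def test_rate_one_per_sequence_changes_exactly_one_base(self, pool):
        mutated = apply_substitutions(pool, ErrorModel(snv_rate=1.0), rng=1)
        for before, after in zip(pool, mutated):
            assert len(after) == len(before)
            diffs = sum(a != b for a, b in zip(before, after))
            assert diffs == 1

    def test_per_nucleotide_rate_matches_binomial_expectation(self, pool):
        rate = 0.05
        model = ErrorModel(snv_rate=rate, rate_semantics="per_nucleotide")
        mutated = apply_substitutions(pool, model, rng=2)
        changed = sum(
            sum(a != b for a, b in zip(s1, s2)) for s1, s2 in zip(pool, mutated)
        )
        n_bases = sum(len(s) for s in pool)
        se = np.sqrt(n_bases * rate * (1 - rate))
        assert abs(changed - n_bases * rate) < 4 * se


class TestIndels:
    def test_zero_rate_is_identity(self, pool):
        assert apply_indels(pool, ErrorModel(), rng=1) == pool

    def test_deletion_shortens_by_one(self, pool):
        mutated = apply_indels(pool, ErrorModel(del_rate=1.0), rng=3)
        assert all(len(m) == len(s) - 1 for m, s in zip(mutated, pool))

    def test_insertion_lengthens_by_one(self, pool):
        mutated = apply_indels(pool, ErrorModel(ins_rate=1.0), rng=3)
        assert all(len(m) == len(s) + 1 for m, s in zip(mutated, pool))


class TestDropout:
    def test_zero_loss_identity(self, pool):
        assert apply_dropout(pool, ErrorModel(loss_rate=0.0), rng=1) == pool

    def test_total_loss_empties_pool(self, pool):
        assert apply_dropout(pool, ErrorModel(loss_rate=1.0), rng=1) == []

    def test_exact_count_mode(self, pool):
        out = apply_dropout(pool, ErrorModel(loss_rate=0.1), rng=1)
        assert len(out) == 360

    def test_bernoulli_mode_within_tolerance(self, pool):
        model = ErrorModel(loss_rate=0.2, loss_mode="bernoulli")
        out = apply_dropout(pool, model, rng=4)
        se = np.sqrt(len(pool) * 0.2 * 0.8)
        assert abs((len(pool) - len(out)) - 0.2 * len(pool)) < 4 * se


class TestDilution:
    def test_amc_zero_loses_everything(self, pool):
        survivors, copies = simulate_dilution(pool, 0.0, seed=1)
        assert survivors == []
        assert not copies.any()

    def test_high_amc_keeps_everything(self, pool):
        survivors, _ = simulate_dilution(pool, 1e4, seed=1)
        assert len(survivors) == len(pool)

    def test_loss_fraction_matches_poisson_zero_class(self):
        """At AMC 0.7 about exp(-0.7) = 49.7% of oligos are lost."""
        big_pool = ["ACGT"] * 20_000
        survivors, _ = simulate_dilution(big_pool, 0.7, seed=5)
        lost_fraction = 1 - len(survivors) / len(big_pool)
        expected = np.exp(-0.7)
        se = np.sqrt(expected * (1 - expected) / len(big_pool))
        assert abs(lost_fraction - expected) < 4 * se

    def test_invalid_amc_rejected(self, pool):
        with pytest.raises(ValueError):
            simulate_dilution(pool, -1.0)


class TestModelValidation:
    def test_rates_out_of_range(self):
        with pytest.raises(ValueError):
            ErrorModel(snv_rate=1.5)
        with pytest.raises(ValueError):
            ErrorModel(rate_semantics="per_codon")
        with pytest.raises(ValueError):
            ErrorModel(loss_mode="sometimes")


@pytest.fixture(scope="module")
def encoded_30k():
    """30 KB pool without parity: the raw-codec robustness baseline."""
    data = gen_file(SyntheticSpec(30_000, seed=71))
    layout = FrameLayout(parity_group=0)
    return data, yy.encode_file(data, REFERENCE_SCHEME, layout=layout, seed=71)


class TestSweeps:
    def test_zero_perturbation_recovers_everything(self, encoded_30k):
        data, enc = encoded_30k
        rows = sweep_recovery(
            data, REFERENCE_SCHEME, [ErrorModel()], n_seeds=2, encoded=enc
        )
        assert rows[0].mean_recovery == 100.0

    def test_dropout_recovery_is_linear_in_loss(self, encoded_30k):
        """Without parity each lost sequence costs its two segments, so
        E[recovery] = 100 x (1 - loss): ~98% at 2% loss, ~90% at 10%."""
        data, enc = encoded_30k
        rows = sweep_recovery(
            data,
            REFERENCE_SCHEME,
            [ErrorModel(loss_rate=0.02), ErrorModel(loss_rate=0.10)],
            n_seeds=6,
            encoded=enc,
            rs_repair=False,
        )
        assert abs(rows[0].mean_recovery - 98.0) < 0.5
        assert abs(rows[1].mean_recovery - 90.0) < 0.8

    def test_recovery_monotone_in_dropout(self, encoded_30k):
        data, enc = encoded_30k
        rows = sweep_recovery(
            data,
            REFERENCE_SCHEME,
            [ErrorModel(loss_rate=r) for r in (0.0, 0.05, 0.2, 0.5)],
            n_seeds=4,
            encoded=enc,
        )
        means = [r.mean_recovery for r in rows]
        assert means == sorted(means, reverse=True)

    def test_substitution_cost_bounded_by_two_segments(self, encoded_30k):
        """Per-sequence corruption at rate r costs at most both segments of
        each corrupted sequence: recovery >= 100 x (1 - 2r)."""
        data, enc = encoded_30k
        rate = 0.05
        rows = sweep_recovery(
            data,
            REFERENCE_SCHEME,
            [ErrorModel(snv_rate=rate)],
            n_seeds=6,
            encoded=enc,
            rs_repair=False,
        )
        assert rows[0].mean_recovery >= 100 * (1 - 2 * rate)

    def test_rs_repair_restores_substitution_losses(self, encoded_30k):
        data, enc = encoded_30k
        with_repair = sweep_recovery(
            data, REFERENCE_SCHEME, [ErrorModel(snv_rate=0.05)],
            n_seeds=4, encoded=enc, rs_repair=True,
        )[0].mean_recovery
        without = sweep_recovery(
            data, REFERENCE_SCHEME, [ErrorModel(snv_rate=0.05)],
            n_seeds=4, encoded=enc, rs_repair=False,
        )[0].mean_recovery
        assert with_repair == 100.0
        assert without < 100.0

    def test_indels_frameshift_and_lose_segments(self, encoded_30k):
        data, enc = encoded_30k
        rows = sweep_recovery(
            data,
            REFERENCE_SCHEME,
            [ErrorModel(ins_rate=0.05, del_rate=0.05)],
            n_seeds=4,
            encoded=enc,
        )
        assert 75.0 < rows[0].mean_recovery < 100.0

    def test_error_model_composition(self, encoded_30k):
        _, enc = encoded_30k
        seqs = [s for _, s in enc.records]
        model = ErrorModel(loss_rate=0.1, snv_rate=0.05, amc=5.0)
        out = apply_error_model(seqs, model, rng=9)
        assert len(out) < len(seqs)
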