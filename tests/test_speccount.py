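"""Spectral-count quantification against independent exact-test oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from netconcord.simulate import generate_count_table
from netconcord.speccount import (
    differential_proteins,
    fisher_test,
    quantify,
    stepup_correct,
)
from netconcord.speccount import test_counts as run_count_tests


def make_counts(rows):
    return pd.DataFrame(rows, columns=["protein", "count_met", "count_par"])


def fisher_oracle(a, b, na, nb):
    """Two-sided Fisher exact p by enumerating all 2x2 tables at fixed margins.

    The margin row totals are (na, nb) and the protein-column total a + b;
    the p-value sums hypergeometric probabilities of every table no more
    likely than the observed one.
    """
    col = a + b

    def prob(x):
        # x successes in sample of size col from na marked of na+nb
        return (math.comb(na, x) * math.comb(nb, col - x)
                / math.comb(na + nb, col))

    p_obs = prob(a)
    lo, hi = max(0, col - nb), min(col, na)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def stepup_oracle(pvalues):
    """Literal step-up definition: from the largest p downward,
    p_(i) <- min(p_(i) * n / i, p_(i+1)-adjusted), clipped at 1."""
    p = list(pvalues)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        adj[i] = min(prev, 1.0)
    return adj


class TestQuantify:
    def test_equal_libraries_identity(self):
        tab = make_counts([("P1", 10, 5), ("P2", 90, 95)])
        q = quantify(tab)
        row = q.set_index("protein").loc["P1"]
        assert row["qvalue_met"] == 10 and row["qvalue_par"] == 5
        assert row["fold_change"] == 2.0

    def test_floor_at_one(self):
        tab = make_counts([("P1", 3, 0), ("P2", 97, 100)])
        row = quantify(tab).set_index("protein").loc["P1"]
        assert row["qvalue_par"] == 1.0
        assert row["fold_change"] == 3.0

    def test_mean_library_scaling(self):
        # libraries 200 vs 100 -> common target 150; (10, 10) -> (7.5, 15)
        tab = make_counts([("P1", 10, 10), ("P2", 190, 90)])
        row = quantify(tab).set_index("protein").loc["P1"]
        assert row["qvalue_met"] == pytest.approx(7.5)
        assert row["qvalue_par"] == pytest.approx(15.0)
        assert row["fold_change"] == pytest.approx(0.5)

    def test_all_zero_sample_is_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            quantify(make_counts([("P1", 5, 0), ("P2", 3, 0)]))

    def test_replicate_rows_pooled(self):
        tab = make_counts([("P1", 5, 2), ("p1", 5, 2), ("P2", 10, 16)])
        q = quantify(tab)
        assert len(q) == 2
        assert q.set_index("protein").loc["P1", "count_met"] == 10


class TestFisher:
    def test_identical_proportions(self):
        assert fisher_test((5, 5), (100, 100)) == 1.0

    def test_zero_counts(self):
        assert fisher_test((0, 0), (50, 50)) == 1.0

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            fisher_test((0, 0), (0, 50))

    def test_count_above_total_is_error(self):
        with pytest.raises(ValueError):
            fisher_test((60, 0), (50, 50))

    def test_example_against_enumeration(self):
        assert fisher_test((10, 0), (50, 50)) == pytest.approx(
            fisher_oracle(10, 0, 50, 50), abs=1e-12)

    def test_exhaustive_small_margins(self):
        for na in range(1, 11, 3):
            for nb in range(1, 11, 3):
                for a in range(na + 1):
                    for b in range(nb + 1):
                        assert fisher_test((a, b), (na, nb)) == pytest.approx(
                            fisher_oracle(a, b, na, nb), abs=1e-10)

    def test_random_tables_margins_to_40(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            na, nb = rng.integers(1, 41, size=2)
            a, b = rng.integers(0, na + 1), rng.integers(0, nb + 1)
            assert fisher_test((int(a), int(b)), (int(na), int(nb))) == \
                pytest.approx(fisher_oracle(int(a), int(b), int(na), int(nb)),
                              abs=1e-10)

    def test_swapping_samples_preserves_p(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            na, nb = rng.integers(5, 200, size=2)
            a, b = rng.integers(0, na + 1), rng.integers(0, nb + 1)
            p1 = fisher_test((int(a), int(b)), (int(na), int(nb)))
            p2 = fisher_test((int(b), int(a)), (int(nb), int(na)))
            assert p1 == pytest.approx(p2, rel=1e-9)


class TestStepUp:
    def test_single_p_unchanged(self):
        assert stepup_correct([0.03]) == pytest.approx([0.03])

    def test_textbook_vector(self):
        out = stepup_correct([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_constant_vector_unchanged(self):
        assert stepup_correct([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_range_check(self):
        with pytest.raises(ValueError):
            stepup_correct([0.5, 1.5])

    def test_against_literal_definition(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            n = int(rng.integers(1, 51))
            p = rng.uniform(size=n)
            assert stepup_correct(p) == pytest.approx(stepup_oracle(p),
                                                      abs=1e-12)


class TestDifferentialProteins:
    def test_corrected_p_controls_calls(self):
        quant = pd.DataFrame({
            "protein": ["SIG", "RAWONLY"],
            "fold_change": [3.0, 3.0],
            "p_adj": [0.01, 0.2],
        })
        ds = differential_proteins(quant)
        assert "SIG" in ds.up and "RAWONLY" not in ds.up

    def test_missing_p_adj_is_error(self):
        quant = pd.DataFrame({"protein": ["A"], "fold_change": [2.0]})
        with pytest.raises(ValueError, match="p_adj"):
            differential_proteins(quant)

    def test_sample_swap_inverts_folds_keeps_p(self):
        rng = np.random.default_rng(3)
        proteins = [f"P{i}" for i in range(40)]
        tab = generate_count_table(proteins, proteins[:5], [], rng,
                                   count_depth=2000)
        swapped = tab.rename(columns={"count_met": "count_par",
                                      "count_par": "count_met"})
        q1, q2 = run_count_tests(tab), run_count_tests(swapped)
        assert q1["pvalue"].to_numpy() == pytest.approx(
            q2["pvalue"].to_numpy(), rel=1e-9)
        assert q1["fold_change"].to_numpy() == pytest.approx(
            1.0 / q2["fold_change"].to_numpy(), rel=1e-9)

    def test_spiked_protein_recovery(self):
        """300 proteins, 20 spiked 5-fold at deep libraries: near-complete
        recovery with at most two false calls."""
        rng = np.random.default_rng(7)
        proteins = [f"P{i:03d}" for i in range(300)]
        spiked = proteins[:20]
        tab = generate_count_table(proteins, spiked, [], rng,
                                   count_depth=20000, spike_fold=5.0,
                                   dispersion=0.01)
        ds = differential_proteins(run_count_tests(tab), model="spiketest")
        recovered = len(ds.up & set(spiked))
        false_calls = len((ds.up | ds.down) - set(spiked))
        assert recovered >= 18
        assert false_calls <= 2
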