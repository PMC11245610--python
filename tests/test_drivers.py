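"""Founding-clone driver calls and the Freeman-Halton exact test."""

import itertools
from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from scipy.stats import fisher_exact

from phyloclone.drivers import (
    ContingencyTable,
    driver_status_table,
    founding_clone_genes,
    freeman_halton_test,
    gene_status,
    phylogeny_mutation_summary,
)
from phyloclone.simulate import MutationCall
from phyloclone.trees import ClonalTree


def _call(gene, clone):
    return MutationCall("A", gene, "1", 1, 10, 50, clone_index=clone)


class TestFoundingCloneGenes:
    def test_root_genes_collected(self):
        tree = ClonalTree("A", [-1, 0], [0.6, 0.4], [2, 1],
                          assignment=np.array([0, 0, 1]))
        calls = [_call("TP53", 0), _call("MUC6", 0), _call("CTNNB1", 1)]
        assert founding_clone_genes(tree, calls) == {"TP53", "MUC6"}

    def test_empty_root_warns(self):
        tree = ClonalTree("A", [-1, 0], [0.6, 0.4], [0, 1],
                          assignment=np.array([1]))
        with pytest.warns(UserWarning):
            assert founding_clone_genes(tree, [_call("TP53", 1)]) == set()

    def test_gene_in_root_and_subclone_counts_as_driver(self):
        tree = ClonalTree("A", [-1, 0], [0.6, 0.4], [1, 1],
                          assignment=np.array([0, 1]))
        calls = [_call("TP53", 0), _call("TP53", 1)]
        assert gene_status(tree, calls, "TP53") == "driver"

    def test_status_categories(self):
        tree = ClonalTree("A", [-1, 0], [0.6, 0.4], [1, 1],
                          assignment=np.array([0, 1]))
        calls = [_call("TP53", 0), _call("CTNNB1", 1)]
        assert gene_status(tree, calls, "TP53") == "driver"
        assert gene_status(tree, calls, "CTNNB1") == "not driver"
        assert gene_status(tree, calls, "ALB") == "no mutation"


class TestStatusTable:
    def test_direct_tabulation(self):
        statuses = {"s1": "driver", "s2": "driver", "s3": "no mutation",
                    "s4": "no mutation", "s5": "not driver", "s6": "not driver"}
        labels = {"s1": "linear", "s2": "linear", "s3": "deep", "s4": "deep",
                  "s5": "shallow", "s6": "shallow"}
        t = driver_status_table(statuses, labels)
        assert t.counts[1, 0] == 2  # driver x linear
        assert t.counts[0, 2] == 2  # no mutation x deep
        assert t.counts[2, 1] == 2  # not driver x shallow
        assert t.counts.sum() == 6

    def test_column_sums_are_class_counts(self):
        statuses = {f"s{i}": "no mutation" for i in range(5)}
        labels = {f"s{i}": ("linear" if i < 3 else "deep") for i in range(5)}
        t = driver_status_table(statuses, labels)
        assert list(t.counts.sum(axis=0)) == [3, 0, 2]

    def test_unresolved_labels_excluded_with_warning(self):
        statuses = {"a": "driver", "b": "driver"}
        labels = {"a": "linear", "b": "nonlinear-unresolved"}
        with pytest.warns(UserWarning):
            t = driver_status_table(statuses, labels)
        assert t.counts.sum() == 1


def brute_force_fh(tab):
    """Independent oracle: exact rational enumeration of all tables with
    the observed margins."""
    tab = np.asarray(tab)
    tab = tab[tab.sum(1) > 0][:, tab.sum(0) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return 1.0
    rows, cols = tab.sum(1), tab.sum(0)
    n = int(tab.sum())

    def prob(t):
        num = Fraction(1)
        for r in rows:
            num *= factorial(int(r))
        for c in cols:
            num *= factorial(int(c))
        den = Fraction(factorial(n))
        for x in np.asarray(t).flat:
            den *= factorial(int(x))
        return num / den

    p_obs = prob(tab)
    total = Fraction(0)
    ranges = [range(int(c) + 1) for c in cols]
    rowsets = {}
    for r in set(int(x) for x in rows):
        rowsets[r] = [v for v in itertools.product(*ranges) if sum(v) == r]

    def rec(i, col_rem, cells):
        nonlocal total
        if i == len(rows) - 1:
            if all(cr >= 0 for cr in col_rem):
                t = cells + [tuple(col_rem)]
                p = prob(t)
                if p <= p_obs:
                    total += p
            return
        for v in rowsets[int(rows[i])]:
            nc = [a - b for a, b in zip(col_rem, v)]
            if all(x >= 0 for x in nc):
                rec(i + 1, nc, cells + [v])

    rec(0, list(cols), [])
    return float(total)


class TestFreemanHalton:
    def test_identity_table_p_one(self):
        assert freeman_halton_test(np.eye(3, dtype=int)) == pytest.approx(1.0)

    def test_classical_fisher_2x2_value(self):
        tab = np.array([[3, 1], [1, 3]])
        assert freeman_halton_test(tab) == pytest.approx(0.4857, abs=1e-4)
        assert freeman_halton_test(tab) == pytest.approx(
            fisher_exact(tab)[1], abs=1e-10
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_reduces_to_fisher_on_random_2x2(self, seed):
        rng = np.random.default_rng(seed)
        tab = rng.integers(0, 12, size=(2, 2))
        tab[0, 0] += 1
        assert freeman_halton_test(tab) == pytest.approx(fisher_exact(tab)[1], abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_random_3x3(self, seed):
        rng = np.random.default_rng(100 + seed)
        tab = rng.integers(0, 5, size=(3, 3))
        tab[0, 0] += 1
        assert freeman_halton_test(tab) == pytest.approx(brute_force_fh(tab), abs=1e-10)

    def test_zero_row_removed_invariance(self):
        tab = np.array([[4, 1, 2], [0, 0, 0], [1, 3, 2]])
        red = np.array([[4, 1, 2], [1, 3, 2]])
        assert freeman_halton_test(tab) == pytest.approx(freeman_halton_test(red), abs=1e-12)

    def test_row_and_column_permutation_invariance(self):
        rng = np.random.default_rng(2)
        tab = rng.integers(0, 6, size=(3, 3)) + 1
        p = freeman_halton_test(tab)
        assert freeman_halton_test(tab[[2, 0, 1]]) == pytest.approx(p, abs=1e-12)
        assert freeman_halton_test(tab[:, [1, 2, 0]]) == pytest.approx(p, abs=1e-12)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            tab = rng.integers(0, 8, size=(3, 3))
            if tab.sum() == 0:
                continue
            p = freeman_halton_test(tab)
            assert 0 < p <= 1

    def test_cap_and_monte_carlo_fallback(self):
        big = np.full((3, 3), 30)  # total 270 > cap
        with pytest.raises(ValueError, match="monte_carlo"):
            freeman_halton_test(big)
        small = np.array([[8, 2, 1], [2, 7, 2], [1, 2, 8]])
        exact = freeman_halton_test(small)
        mc = freeman_halton_test(small, monte_carlo=True, n_samples=20_000,
                                 rng=np.random.default_rng(0))
        assert mc == pytest.approx(exact, abs=0.02)

    def test_contingency_table_wrapper(self):
        t = ContingencyTable(np.eye(3, dtype=int), ("a", "b", "c"), ("x", "y", "z"))
        assert freeman_halton_test(t) == pytest.approx(1.0)


class TestSummary:
    def test_ranking_and_frequencies(self):
        founding = {"s1": {"TP53", "ALB"}, "s2": {"TP53"}, "s3": {"CTNNB1"}}
        labels = {"s1": "deep", "s2": "deep", "s3": "linear"}
        df = phylogeny_mutation_summary(founding, labels)
        deep = df[df["class"] == "deep"]
        assert list(deep["gene"]) == ["TP53", "ALB"]  # frequency then alphabetical
        assert deep.iloc[0]["frequency"] == pytest.approx(1.0)
        assert (df["frequency"] <= 1).all() and (df["frequency"] >= 0).all()

    def test_empty_class_section(self):
        df = phylogeny_mutation_summary({"s1": {"TP53"}}, {"s1": "linear"})
        assert (df["class"] == "deep").sum() == 0
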