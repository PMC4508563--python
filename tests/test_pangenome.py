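import itertools
import math

import numpy as np
import pytest

from panbin.orthology import OrthologTable
from panbin.pangenome import (
    CORE,
    SHARED_NON_CORE,
    UNIQUE,
    PairwiseShared,
    accumulate,
    category_breakdown,
    fit_new_gene_curve,
    fit_power,
    partition,
)
from panbin.seqio import Proteome, SequenceRecord


def _table_from_presence(presence):
    """presence: list of per-family genome lists (len>=2 members)."""
    families = {}
    for i, genomes in enumerate(presence):
        families[f"F{i}"] = {(g, f"{g}|f{i}") for g in genomes}
    return OrthologTable(families=families, singletons=set())


class TestPartition:
    def test_thirteen_of_seventeen_is_core(self):
        table = _table_from_presence([[f"G{k}" for k in range(13)]])
        part = partition(table, 17)
        assert part.core_min_genomes == 13
        assert part.family_class["F0"] == CORE

    def test_single_genome_family_with_copies_is_unique(self):
        table = OrthologTable(
            families={"F0": {("G1", "a"), ("G1", "b"), ("G1", "c")}}, singletons=set()
        )
        part = partition(table, 17)
        assert part.family_class["F0"] == UNIQUE
        assert part.class_gene_counts()[UNIQUE] == 3

    def test_core_min_above_genome_count_is_an_error(self):
        table = _table_from_presence([["G1", "G2"]])
        with pytest.raises(ValueError):
            partition(table, 17, core_min_genomes=18)

    def test_default_threshold_scales_with_genome_count(self):
        table = _table_from_presence([["G1", "G2"]])
        assert partition(table, 8).core_min_genomes == math.ceil(13 / 17 * 8)

    def test_random_presence_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        genomes = [f"G{i}" for i in range(10)]
        presence = []
        for _ in range(40):
            k = rng.integers(2, 11)
            presence.append(list(rng.choice(genomes, size=k, replace=False)))
        table = _table_from_presence(presence)
        part = partition(table, 10, core_min_genomes=8)
        for fid, members in table.families.items():
            n = len({g for g, _ in members})
            expected = CORE if n >= 8 else (UNIQUE if n == 1 else SHARED_NON_CORE)
            assert part.family_class[fid] == expected
        counts = part.class_family_counts()
        assert sum(counts.values()) == 40


# three proteomes over mutually hostile alphabets: every cross-genome
# BLOSUM62 score is negative, so no qualifying hits exist at all
_ALPHABETS = {"A": "PG", "B": "WC", "C": "KD"}


def _disjoint_proteome(gid, n_genes, length=40, seed=0):
    rng = np.random.default_rng(seed)
    letters = np.array(list(_ALPHABETS[gid]))
    recs = [
        SequenceRecord(f"{gid}|g{i}", gid, "".join(rng.choice(letters, length)))
        for i in range(n_genes)
    ]
    return Proteome(gid, recs)


def _copy_proteome(gid, source):
    return Proteome(gid, [SequenceRecord(f"{gid}|{r.id.split('|')[1]}", gid, r.seq)
                          for r in source])


class TestAccumulate:
    def test_identical_proteomes_saturate_immediately(self):
        rng = np.random.default_rng(1)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        base = Proteome("A", [
            SequenceRecord(f"A|g{i}", "A", "".join(rng.choice(aa, 60))) for i in range(20)
        ])
        prots = [base, _copy_proteome("B", base), _copy_proteome("C", base)]
        curve = accumulate(prots, trials=100, seed=0)
        pan = curve.stats[curve.stats["stat"] == "pan"]
        assert (pan["raw_mean"] == 20).all()
        assert (pan["norm_mean"] == 1.0).all()
        new = curve.per_trial[(curve.per_trial["stat"] == "new") & (curve.per_trial["step"] > 1)]
        assert (new["raw"] == 0).all()

    def test_disjoint_proteomes_match_hand_enumeration(self):
        sizes = {"A": 80, "B": 100, "C": 120}
        prots = [_disjoint_proteome(g, n, seed=i) for i, (g, n) in enumerate(sizes.items())]
        curve = accumulate(prots, trials=100, seed=5)
        # exhaustion rule: 3! = 6 distinct orders
        assert curve.n_trials == 6
        assert len(set(curve.trial_orders)) == 6
        for t, order in enumerate(curve.trial_orders):
            sub = curve.per_trial[curve.per_trial["trial"] == t]
            for k in (1, 2, 3):
                included = [sizes[g] for g in order[:k]]
                median = float(np.median(included))
                row_new = sub[(sub["stat"] == "new") & (sub["step"] == k)].iloc[0]
                row_pan = sub[(sub["stat"] == "pan") & (sub["step"] == k)].iloc[0]
                assert row_new["raw"] == sizes[order[k - 1]]
                assert row_new["norm"] == pytest.approx(sizes[order[k - 1]] / median)
                assert row_pan["raw"] == sum(included)
            # shared curve: first genome shares nothing with disjoint genomes
            row_sh = sub[(sub["stat"] == "shared") & (sub["step"] == 3)].iloc[0]
            assert row_sh["raw"] == 0

    def test_pan_increments_equal_new_genes(self, small_set, small_hits):
        proteomes, _ = small_set
        pairwise = PairwiseShared(proteomes, hits_by_pair=small_hits)
        curve = accumulate(proteomes, trials=10, seed=2, pairwise=pairwise)
        for t in range(curve.n_trials):
            sub = curve.per_trial[curve.per_trial["trial"] == t]
            pans = sub[sub["stat"] == "pan"].sort_values("step")["raw"].to_numpy()
            news = sub[sub["stat"] == "new"].sort_values("step")["raw"].to_numpy()
            assert pans[0] == news[0]
            assert np.all(np.diff(pans) == news[1:])
            assert np.all(np.diff(pans) >= 0)

    def test_endpoint_is_order_invariant(self, small_set, small_hits):
        proteomes, _ = small_set
        pairwise = PairwiseShared(proteomes, hits_by_pair=small_hits)
        curve = accumulate(proteomes, trials=24, seed=3, pairwise=pairwise)
        last = curve.per_trial[
            (curve.per_trial["stat"] == "pan")
            & (curve.per_trial["step"] == len(proteomes))
        ]
        assert last["raw"].nunique() == 1

    def test_new_gene_labels_match_planted_truth(self, small_set, small_hits):
        proteomes, truth = small_set
        pairwise = PairwiseShared(proteomes, hits_by_pair=small_hits)
        added = proteomes[-1].genome_id
        prior = [p.genome_id for p in proteomes[:-1]]
        new = pairwise.new_genes(added, prior)
        fam = truth.gene_to_family
        present_elsewhere = {
            fam[r.id] for p in proteomes[:-1] for r in p if fam[r.id] != "UNIQUE"
        }
        expected = {
            r.id for r in proteomes[-1]
            if fam[r.id] == "UNIQUE" or fam[r.id] not in present_elsewhere
        }
        assert new == expected

    def test_needs_two_proteomes(self):
        with pytest.raises(ValueError):
            accumulate([_disjoint_proteome("A", 5)], trials=5, seed=0)


class TestFitPower:
    def test_exact_recovery(self):
        xs = np.arange(1, 8, dtype=float)
        fit = fit_power(xs, 5.0 * xs**0.3)
        assert fit.amplitude == pytest.approx(5.0, abs=1e-9)
        assert fit.exponent == pytest.approx(0.3, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_constant_series_has_zero_exponent(self):
        fit = fit_power([1, 2, 3, 4], [7, 7, 7, 7])
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)
        assert fit.amplitude == pytest.approx(7.0)

    def test_decaying_curve(self):
        xs = np.arange(1, 10, dtype=float)
        fit = fit_power(xs, 2.0 * xs**-0.8)
        assert fit.exponent == pytest.approx(-0.8, abs=1e-9)

    def test_nonpositive_value_named_by_index(self):
        with pytest.raises(ValueError, match="index 2"):
            fit_power([1, 2, 3], [4, 5, 0])

    def test_new_gene_fit_excludes_step_one_by_default(self):
        sizes = {"A": 80, "B": 100, "C": 120}
        prots = [_disjoint_proteome(g, n, seed=i) for i, (g, n) in enumerate(sizes.items())]
        curve = accumulate(prots, trials=100, seed=5)
        fit = fit_new_gene_curve(curve)
        assert fit.n_points == 2


class TestCategoryBreakdown:
    def _one_family_table(self, genes):
        return OrthologTable(
            families={"F0": {("G1", g) for g in genes}}, singletons=set()
        )

    def test_single_category_single_class(self):
        table = self._one_family_table(["a", "b", "c"])
        part = partition(table, 1, core_min_genomes=1)
        df = category_breakdown(part, table, {"a": "J", "b": "J", "c": "J"})
        assert df.loc["J", CORE] == 3

    def test_multi_category_counted_once(self):
        table = self._one_family_table(["a", "b"])
        part = partition(table, 1, core_min_genomes=1)
        df = category_breakdown(part, table, {"a": ["K", "L"], "b": "K"})
        assert df.loc["Multiple assignments", CORE] == 1
        assert df.loc["K", CORE] == 1
        assert "L" not in df.index

    def test_random_map_matches_bruteforce_tally(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(60)]
        table = OrthologTable(
            families={"F0": {("G1", g) for g in genes[:30]}},
            singletons={("G2", g) for g in genes[30:]},
        )
        part = partition(table, 2, core_min_genomes=1)
        cats = "JKLM"
        mapping = {}
        for g in genes:
            k = rng.integers(0, 4)
            mapping[g] = list(rng.choice(list(cats), size=k, replace=False))
        df = category_breakdown(part, table, mapping)
        n_multi = sum(1 for g in genes if len(mapping[g]) >= 2)
        n_none = sum(1 for g in genes if len(mapping[g]) == 0)
        assert df.loc["Multiple assignments", "Total"] == n_multi
        assert df.loc["Unassigned", "Total"] == n_none
        assert df.loc["Total", "Total"] == len(genes)  # every gene counted once

    def test_unknown_letter_bucketed_as_unassigned(self):
        table = self._one_family_table(["a", "b"])
        part = partition(table, 1, core_min_genomes=1)
        with pytest.warns(UserWarning, match="unknown category"):
            df = category_breakdown(part, table, {"a": "5", "b": "J"})
        assert df.loc["Unassigned", CORE] == 1
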