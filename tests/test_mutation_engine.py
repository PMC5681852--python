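"""Mutation budget, category apportionment and codon-level mutation."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hgtsim.genetic_code import DEFAULT_TABLE, translate
from hgtsim.mutation_engine import (
    FeasibilityError,
    GeneRecord,
    InfeasibleBudgetError,
    MutationPlan,
    aa_identity,
    apply_report,
    build_plan,
    mutate_gene,
    mutation_budget,
    nt_identity,
    parse_ratio,
    write_mutation_report,
)
from hgtsim.fixtures import generate_cds

_COSTS = (1, 1, 2, 3)


def make_gene(n_codons=100, seed=0, gene_id="g"):
    return generate_cds(n_codons, DEFAULT_TABLE, np.random.default_rng(seed), gene_id)


class TestBudget:
    @pytest.mark.parametrize(
        "length, level, expected",
        [
            (300, 10, 30),
            (300, 0, 0),
            (303, 5, 15),   # 15.15 rounds down
            (306, 2.5, 8),  # 7.65 rounds up
            (30, 5, 2),     # 1.5 rounds half away from zero -> 2
            (300, 100, 300),
        ],
    )
    def test_rounding(self, length, level, expected):
        assert mutation_budget(length, level) == expected

    def test_level_out_of_range(self):
        with pytest.raises(ValueError):
            mutation_budget(300, 101)
        with pytest.raises(ValueError):
            mutation_budget(300, -1)


class TestPlan:
    @pytest.mark.parametrize(
        "n, ratio, counts",
        [
            (7, (1, 1, 1, 1), (1, 1, 1, 1)),
            (0, (1, 1, 1, 1), (0, 0, 0, 0)),
            (9, (0, 0, 0, 1), (0, 0, 0, 3)),
            (14, (1, 1, 1, 1), (2, 2, 2, 2)),
            (10, (1, 0, 0, 0), (10, 0, 0, 0)),
            # residuals the active set cannot absorb are closed by borrowing
            # one cheap event, so the base budget holds for any gene length
            (10, (0, 0, 0, 1), (0, 1, 0, 3)),
            (11, (0, 0, 0, 1), (0, 0, 1, 3)),
            (5, (0, 0, 1, 0), (0, 1, 2, 0)),
        ],
    )
    def test_examples(self, n, ratio, counts):
        assert build_plan(n, ratio).counts == counts

    @pytest.mark.parametrize(
        "n, ratio",
        [(1, (0, 0, 0, 1)), (2, (0, 0, 0, 1)), (1, (0, 0, 1, 0)), (1, (0, 0, 1, 1))],
    )
    def test_budget_below_cheapest_event_is_infeasible(self, n, ratio):
        with pytest.raises(InfeasibleBudgetError):
            build_plan(n, ratio)

    def test_zero_ratio_categories_get_zero_events(self):
        plan = build_plan(30, (1, 0, 1, 1))
        assert plan.c2 == 0

    @given(
        n=st.integers(0, 500),
        ratio=st.tuples(*[st.integers(0, 5)] * 4).filter(lambda r: sum(r) > 0),
    )
    @settings(max_examples=200, deadline=None)
    def test_exact_base_budget_property(self, n, ratio):
        try:
            plan = build_plan(n, ratio)
        except InfeasibleBudgetError:
            # refused only when the budget is below the cheapest active event
            min_cost = min(c for c, r in zip(_COSTS, ratio) if r > 0)
            assert 0 < n < min_cost
            return
        assert sum(c * w for c, w in zip(plan.counts, _COSTS)) == n
        # a zero-ratio category hosts at most one borrowed residual event
        for r, c in zip(ratio, plan.counts):
            if r == 0:
                assert c <= 1

    def test_deterministic(self):
        assert build_plan(97, (2, 1, 3, 1)) == build_plan(97, (2, 1, 3, 1))

    def test_parse_ratio(self):
        assert parse_ratio("1:0:1:1") == (1, 0, 1, 1)
        with pytest.raises(ValueError):
            parse_ratio("1:1:1")
        with pytest.raises(ValueError):
            parse_ratio("0:0:0:0")


class TestGeneRecord:
    def test_rejects_out_of_frame(self):
        with pytest.raises(ValueError):
            GeneRecord("g", "ATGAAATA")

    def test_rejects_too_short(self):
        with pytest.raises(ValueError):
            GeneRecord("g", "ATGTAA")


class TestMutateGene:
    def test_zero_level_is_identity(self, rng):
        gene = make_gene(100)
        mutated, events = mutate_gene(gene, build_plan(0, (1, 1, 1, 1)), rng=rng)
        assert mutated == gene.seq
        assert events == []

    @pytest.mark.parametrize("ratio", [(1, 1, 1, 1), (1, 0, 1, 1), (0, 0, 0, 1)])
    def test_hamming_equals_budget(self, rng, ratio):
        gene = make_gene(150)
        n = mutation_budget(gene.length, 12)
        mutated, _ = mutate_gene(gene, build_plan(n, ratio), rng=rng)
        assert sum(a != b for a, b in zip(gene.seq, mutated)) == n
        assert len(mutated) == gene.length

    def test_silent_only_preserves_protein(self, rng):
        gene = make_gene(200)
        n = mutation_budget(gene.length, 8)
        mutated, _ = mutate_gene(gene, build_plan(n, (1, 0, 0, 0)), rng=rng)
        assert translate(mutated) == translate(gene.seq)
        assert aa_identity(gene.seq, mutated) == 100.0

    def test_c2_only_changes_exactly_that_many_residues(self, rng):
        gene = make_gene(200)
        plan = build_plan(10, (0, 1, 0, 0))
        mutated, _ = mutate_gene(gene, plan, rng=rng)
        p0, p1 = translate(gene.seq), translate(mutated)
        assert sum(a != b for a, b in zip(p0, p1)) == plan.c2

    def test_terminal_codons_never_touched(self, rng):
        gene = make_gene(60)
        for _ in range(10):
            mutated, events = mutate_gene(gene, build_plan(30, (1, 1, 1, 1)), rng=rng)
            assert mutated[:3] == gene.seq[:3]
            assert mutated[-3:] == gene.seq[-3:]
            assert all(0 < e.codon_index < gene.n_codons - 1 for e in events)

    def test_no_internal_stops_created(self, rng):
        gene = make_gene(120)
        mutated, _ = mutate_gene(gene, build_plan(60, (1, 1, 1, 1)), rng=rng)
        assert "*" not in translate(mutated)[:-1]

    def test_each_codon_mutated_at_most_once(self, rng):
        gene = make_gene(120)
        _, events = mutate_gene(gene, build_plan(80, (1, 1, 1, 1)), rng=rng)
        idx = [e.codon_index for e in events]
        assert len(idx) == len(set(idx))

    def test_nt_identity_is_exactly_level(self, rng):
        gene = make_gene(100)  # L = 300
        n = mutation_budget(gene.length, 10)
        mutated, _ = mutate_gene(gene, build_plan(n, (1, 1, 1, 1)), rng=rng)
        assert nt_identity(gene.seq, mutated) == pytest.approx(90.0)

    def test_determinism_under_seed(self):
        gene = make_gene(100)
        plan = build_plan(30, (1, 0, 1, 1))
        out = [
            mutate_gene(gene, plan, rng=np.random.default_rng(7)) for _ in range(2)
        ]
        assert out[0] == out[1]

    def test_feasibility_error_when_no_silent_neighbors(self, rng):
        # every internal codon is TGG (Trp): C1 has nowhere to go
        gene = GeneRecord("trp", "ATG" + "TGG" * 10 + "TAA")
        with pytest.raises(FeasibilityError, match="C1"):
            mutate_gene(gene, MutationPlan(2, 0, 0, 0, 2, (1, 0, 0, 0)), rng=rng)

    def test_excluded_internal_codons_are_skipped(self, rng):
        # internal GTG/TTG are start-like triplets, protected from mutation
        gene = GeneRecord("g", "ATG" + "GTG" + "AAA" * 8 + "TTG" + "TAA")
        for _ in range(20):
            mutated, _ = mutate_gene(gene, build_plan(5, (0, 1, 1, 1)), rng=rng)
            assert mutated[3:6] == "GTG"
            assert mutated[30:33] == "TTG"

    def test_selection_near_uniform_over_internal_codons(self):
        # chi-square over which internal codon hosts the single event
        from scipy import stats

        gene = GeneRecord("g", "ATG" + "AAA" * 20 + "TAA")
        rng = np.random.default_rng(99)
        counts = np.zeros(20)
        n_trials = 4000
        plan = build_plan(1, (0, 1, 0, 0))
        for _ in range(n_trials):
            _, events = mutate_gene(gene, plan, rng=rng)
            counts[events[0].codon_index - 1] += 1
        p = stats.chisquare(counts).pvalue
        assert p > 1e-4


class TestIdentity:
    def test_nt_identity_examples(self):
        assert nt_identity("ACGT", "ACGT") == 100.0
        assert nt_identity("ACGT", "ACGA") == 75.0
        assert nt_identity("", "") == 100.0
        with pytest.raises(ValueError):
            nt_identity("ACG", "AC")

    def test_aa_identity_examples(self):
        assert aa_identity("GCC", "ACC") == 0.0
        assert aa_identity("GCCAAA", "GCCAAA") == 100.0


class TestReport:
    def test_empty_report_is_header_only(self, tmp_path):
        path = tmp_path / "report.tsv"
        write_mutation_report([], path)
        assert path.read_text() == "gene_id\tposition\tref\talt\tcodon_index\tcategory\n"

    def test_c4_event_writes_three_rows(self, rng, tmp_path):
        gene = make_gene(50)
        _, events = mutate_gene(gene, build_plan(3, (0, 0, 0, 1)), rng=rng)
        path = tmp_path / "report.tsv"
        write_mutation_report(events, path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 3
        assert (df["category"] == "C4").all()

    @pytest.mark.parametrize("level", [5, 15, 30])
    def test_replay_reproduces_mutated_sequence(self, rng, tmp_path, level):
        gene = make_gene(150)
        n = mutation_budget(gene.length, level)
        mutated, events = mutate_gene(gene, build_plan(n, (1, 1, 1, 1)), rng=rng)
        path = tmp_path / "report.tsv"
        write_mutation_report(events, path)
        df = pd.read_csv(path, sep="\t")
        assert apply_report(gene.seq, df) == mutated
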