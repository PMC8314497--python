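import numpy as np
import pandas as pd
import pytest

from lncpath import (
    RankedGeneList,
    enrichment_score,
    leading_edge,
    permutation_null,
    run_preranked,
)
from lncpath.errors import ConfigError, DegenerateInputError, ValidationError
from lncpath.io import GeneSetCollection

from oracles import walk_enrichment, walk_leading_edge


def _ranked(genes, scores, metric="pearson"):
    return RankedGeneList(list(genes), np.asarray(scores, float), metric, "T", 10)


def _random_instance(gen, max_n=50):
    n = int(gen.integers(4, max_n + 1))
    scores = np.sort(gen.normal(size=n))[::-1]
    genes = [f"G{i:03d}" for i in range(n)]
    size = int(gen.integers(1, n))
    members = list(gen.choice(genes, size=size, replace=False))
    weight_p = float(gen.choice([0.0, 0.5, 1.0, 2.0]))
    return _ranked(genes, scores), members, weight_p


class TestEnrichmentScore:
    def test_unweighted_front_loaded_set(self):
        r = _ranked(["A", "B", "C", "D"], [4.0, 3.0, 2.0, 1.0])
        es, peak, rs = enrichment_score(r, {"A", "B"}, weight_p=0.0)
        assert es == 1.0
        assert peak == 1  # 0-based: after the second gene
        assert rs.tolist() == [0.5, 1.0, 0.5, 0.0]

    def test_all_members_degenerate(self):
        r = _ranked(["A", "B"], [1.0, 0.5])
        with pytest.raises(DegenerateInputError):
            enrichment_score(r, {"A", "B"})

    def test_empty_intersection(self):
        r = _ranked(["A", "B"], [1.0, 0.5])
        with pytest.raises(ValidationError):
            enrichment_score(r, {"X"})

    def test_zero_hit_weights_fall_back_to_uniform(self):
        r = _ranked(["A", "B", "C", "D"], [1.0, 0.0, 0.0, -1.0])
        es, peak, rs = enrichment_score(r, {"B", "C"}, weight_p=1.0)
        # hits have |score|^1 = 0: uniform 1/2 increments, misses -1/2
        assert rs.tolist() == pytest.approx([-0.5, 0.0, 0.5, 0.0])
        # |rs| ties at -0.5 (pos 0) and 0.5 (pos 2): first occurrence wins
        assert es == pytest.approx(-0.5)
        assert peak == 0

    def test_matches_literal_walk_on_random_instances(self):
        gen = np.random.default_rng(42)
        for _ in range(250):
            ranked, members, weight_p = _random_instance(gen)
            es, peak, rs = enrichment_score(ranked, members, weight_p)
            es_o, peak_o, rs_o = walk_enrichment(
                ranked.genes, ranked.scores, members, weight_p
            )
            assert es == pytest.approx(es_o, abs=1e-12)
            assert peak == peak_o
            assert np.allclose(rs, rs_o, atol=1e-12)

    def test_matches_external_gsea_engine(self):
        """Dual route: our ES vs the independent gseapy prerank engine."""
        import warnings

        import gseapy

        gen = np.random.default_rng(9)
        n = 200
        genes = [f"G{i:03d}" for i in range(n)]
        scores = np.sort(gen.normal(size=n))[::-1]
        ranked = _ranked(genes, scores)
        sets = {
            f"S{j:02d}": list(gen.choice(genes, size=15, replace=False))
            for j in range(8)
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ext = gseapy.prerank(
                rnk=pd.DataFrame({"gene": genes, "score": scores}),
                gene_sets=sets,
                permutation_num=10,
                min_size=3,
                max_size=500,
                weight=1.0,
                seed=1,
                threads=1,
                no_plot=True,
                outdir=None,
            ).res2d
        for name, members in sets.items():
            ours, _, _ = enrichment_score(ranked, members, 1.0)
            theirs = float(ext.loc[ext["Term"] == name, "ES"].iloc[0])
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_magnitude_bounded_by_one(self):
        gen = np.random.default_rng(11)
        for _ in range(100):
            ranked, members, weight_p = _random_instance(gen, max_n=30)
            es, _, _ = enrichment_score(ranked, members, weight_p)
            assert abs(es) <= 1.0 + 1e-12

    def test_es_one_iff_front_loaded_unweighted(self):
        gen = np.random.default_rng(13)
        for _ in range(50):
            ranked, members, _ = _random_instance(gen, max_n=20)
            es, _, _ = enrichment_score(ranked, members, weight_p=0.0)
            member_pos = sorted(
                i for i, g in enumerate(ranked.genes) if g in set(members)
            )
            front_loaded = member_pos[-1] == len(member_pos) - 1
            assert (es == pytest.approx(1.0)) == front_loaded

    def test_antisymmetry_unweighted(self):
        # reversing the list negates the running-sum profile, so |ES| is
        # preserved and the sign flips whenever the extreme is unique
        # (ties are broken by first occurrence, which reversal re-orders)
        gen = np.random.default_rng(17)
        for _ in range(50):
            ranked, members, _ = _random_instance(gen, max_n=30)
            es, _, rs = enrichment_score(ranked, members, weight_p=0.0)
            flipped = _ranked(ranked.genes[::-1], -ranked.scores[::-1])
            es_f, _, _ = enrichment_score(flipped, members, weight_p=0.0)
            assert abs(es_f) == pytest.approx(abs(es), abs=1e-12)
            unique_extreme = np.sum(np.abs(rs) >= np.abs(rs).max() - 1e-12) == 1
            if unique_extreme:
                assert es_f == pytest.approx(-es, abs=1e-12)


class TestLeadingEdge:
    def test_positive_es_members_before_peak(self):
        r = _ranked(["A", "B", "C", "D"], [4.0, 3.0, 2.0, 1.0])
        es, peak, _ = enrichment_score(r, {"A", "B"}, weight_p=0.0)
        assert leading_edge(r, {"A", "B"}, es, peak) == ["A", "B"]

    def test_member_after_positive_peak_excluded(self):
        r = _ranked(["A", "B", "C", "D", "E"], [4.0, 3.0, 2.0, 1.0, 0.5])
        es, peak, _ = enrichment_score(r, {"A", "E"}, weight_p=1.0)
        assert es > 0
        le = leading_edge(r, {"A", "E"}, es, peak)
        assert le == ["A"]

    def test_negative_es_matches_oracle_walk(self):
        gen = np.random.default_rng(23)
        genes = [f"G{i}" for i in range(10)]
        scores = np.linspace(2, -3, 10)
        r = _ranked(genes, scores)
        members = {"G7", "G8", "G9"}
        es, peak, _ = enrichment_score(r, members, 1.0)
        assert es < 0
        assert leading_edge(r, members, es, peak) == walk_leading_edge(
            genes, members, es, peak
        )

    def test_oracle_equivalence_random(self):
        gen = np.random.default_rng(29)
        for _ in range(100):
            ranked, members, weight_p = _random_instance(gen, max_n=40)
            es, peak, _ = enrichment_score(ranked, members, weight_p)
            assert leading_edge(ranked, members, es, peak) == walk_leading_edge(
                ranked.genes, members, es, peak
            )

    def test_bad_peak_index(self):
        r = _ranked(["A", "B"], [1.0, 0.0])
        with pytest.raises(ValidationError):
            leading_edge(r, {"A"}, 0.5, 7)


class TestPermutationNull:
    def test_deterministic_under_seed(self):
        gen = np.random.default_rng(31)
        ranked, _, _ = _random_instance(gen, max_n=30)
        a = permutation_null(ranked, 5, 1.0, 50, seed=7)
        b = permutation_null(ranked, 5, 1.0, 50, seed=7)
        assert np.array_equal(a, b)
        c = permutation_null(ranked, 5, 1.0, 50, seed=8)
        assert not np.array_equal(a, c)

    def test_two_gene_universe_enumeration(self):
        # set_size=1 on N=2: the only two subsets are {A} and {B}; their ES
        # values are equiprobable under uniform sampling
        r = _ranked(["A", "B"], [2.0, 1.0])
        es_a, _, _ = enrichment_score(r, {"A"})
        es_b, _, _ = enrichment_score(r, {"B"})
        null = permutation_null(r, 1, 1.0, 4000, seed=3)
        values, counts = np.unique(np.round(null, 12), return_counts=True)
        assert np.allclose(np.sort(values), np.sort([es_a, es_b]))
        # frequencies within 3 binomial SDs of 1/2
        sd = np.sqrt(0.25 / 4000)
        assert abs(counts[0] / 4000 - 0.5) < 3 * sd

    def test_nperm_zero_rejected(self):
        r = _ranked(["A", "B", "C"], [2.0, 1.0, 0.0])
        with pytest.raises(ConfigError):
            permutation_null(r, 1, 1.0, 0)

    def test_set_size_domain(self):
        r = _ranked(["A", "B", "C"], [2.0, 1.0, 0.0])
        for bad in (0, 3, 5):
            with pytest.raises(ConfigError):
                permutation_null(r, bad, 1.0, 10)

    def test_null_matches_single_instance_scores(self):
        # batch path must agree with the scalar enrichment_score path
        gen = np.random.default_rng(37)
        ranked, _, _ = _random_instance(gen, max_n=25)
        size = min(4, len(ranked) - 1)
        rng = np.random.default_rng(99)
        noise = rng.random((20, len(ranked)))
        idx = np.argpartition(noise, size - 1, axis=1)[:, :size]
        null = permutation_null(ranked, size, 1.0, 20, seed=99)
        for row, subset_idx in enumerate(idx):
            members = [ranked.genes[i] for i in subset_idx]
            es, _, _ = enrichment_score(ranked, members, 1.0)
            assert null[row] == pytest.approx(es, abs=1e-12)


def _collection(sets):
    return GeneSetCollection({k: ("", frozenset(v)) for k, v in sets.items()})


@pytest.fixture(scope="module")
def planted_run(small_cohort):
    from lncpath import analyze_target

    lnc, coding, sets, truth = small_cohort
    return (
        analyze_target(
            lnc, coding, sets, "LNC_TARGET", metric="gba", n_perm=500, seed=7
        ),
        truth,
    )


class TestRunPreranked:
    def test_planted_set_has_largest_nes_and_low_q(self, planted_run):
        run, truth = planted_run
        table = run.result.table
        planted = list(truth.planted_members)[0]
        assert table["nes"].abs().idxmax() == planted
        assert table.index[0] == planted
        assert table.loc[planted, "q_fdr"] < 0.05

    def test_leading_edge_consistent(self, planted_run):
        run, truth = planted_run
        planted = list(truth.planted_members)[0]
        le = run.result.table.loc[planted, "leading_edge"]
        members = set(truth.planted_members[planted])
        assert set(le) <= members
        positions = [run.ranked.gene_index[g] for g in le]
        assert positions == sorted(positions)

    def test_bh_is_monotone_in_p(self, planted_run):
        run, _ = planted_run
        t = run.result.table.sort_values("p_nominal")
        assert np.all(np.diff(t["q_fdr"]) >= -1e-12)

    def test_bh_matches_statsmodels_recomputation(self, planted_run):
        from statsmodels.stats.multitest import multipletests

        run, _ = planted_run
        t = run.result.table
        expected = multipletests(t["p_nominal"], method="fdr_bh")[1]
        assert np.allclose(t["q_fdr"], expected)

    def test_nes_sign_matches_es(self, planted_run):
        run, _ = planted_run
        t = run.result.table.dropna(subset=["nes"])
        assert np.all(np.sign(t["nes"]) == np.sign(t["es"]))

    def test_p_floor(self, planted_run):
        run, _ = planted_run
        t = run.result.table
        assert (t["p_nominal"] >= 1 / (t["n_perm_effective"] + 1) - 1e-15).all()

    def test_deterministic_result_tables(self, small_cohort, tmp_path):
        from lncpath import analyze_target

        lnc, coding, sets, _ = small_cohort
        paths = []
        for i in (1, 2):
            run = analyze_target(
                lnc, coding, sets, "LNC_TARGET", metric="dge", n_perm=200, seed=11
            )
            p = tmp_path / f"res{i}.tsv"
            run.result.to_tsv(p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_size_filter_and_skip_reporting(self):
        genes = [f"G{i:02d}" for i in range(40)]
        scores = np.linspace(3, -3, 40)
        ranked = _ranked(genes, scores)
        coll = _collection(
            {
                "TOO_SMALL": genes[:2],
                "ABSENT": ["X1", "X2", "X3"],
                "OK": genes[:10],
                "TOO_BIG": genes,
            }
        )
        res = run_preranked(ranked, coll, min_size=5, max_size=20, n_perm=50, seed=1)
        assert list(res.table.index) == ["OK"]
        assert set(res.skipped) == {"TOO_SMALL", "ABSENT", "TOO_BIG"}

    def test_no_set_passes_filter(self):
        ranked = _ranked(["A", "B", "C"], [1.0, 0.5, 0.0])
        with pytest.raises(ValidationError, match="size filter"):
            run_preranked(ranked, _collection({"S": ["A"]}), min_size=2, n_perm=10)

    def test_null_pool_independent_of_collection_order(self):
        genes = [f"G{i:02d}" for i in range(30)]
        scores = np.linspace(2, -2, 30)
        ranked = _ranked(genes, scores)
        a = _collection({"S1": genes[:8], "S2": genes[10:18]})
        b = _collection({"S2": genes[10:18], "S1": genes[:8]})
        res_a = run_preranked(ranked, a, min_size=3, n_perm=100, seed=5)
        res_b = run_preranked(ranked, b, min_size=3, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(
            res_a.table.sort_index(), res_b.table.sort_index()
        )

    def test_tsv_round_trip(self, planted_run, tmp_path):
        from lncpath import EnrichmentResult

        run, _ = planted_run
        p = tmp_path / "res.tsv"
        run.result.to_tsv(p)
        back = EnrichmentResult.from_tsv(p)
        assert list(back.table.index) == list(run.result.table.index)
        assert np.allclose(back.table["nes"], run.result.table["nes"], atol=1e-9)
        assert list(back.table["leading_edge"].iloc[0]) == list(
            run.result.table["leading_edge"].iloc[0]
        )
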