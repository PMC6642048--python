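"""Weighted running-sum enrichment: oracle equivalence, null, NES/FDR."""

import numpy as np
import pandas as pd
import pytest

from tmetargets.enrichment import (
    EnrichmentScore,
    RankedList,
    enrichment_score,
    normalize_and_fdr,
    permutation_null,
    preranked_gsea,
)
from tmetargets.io import GeneSet, GeneSetCollection


def quadratic_oracle_es(genes, scores, members, p):
    """Independent quadratic-time re-walk of the running-sum definition."""
    hits = [g in set(members) for g in genes]
    n, n_hits = len(genes), sum(hits)
    denom = sum(abs(s) ** p for s, h in zip(scores, hits) if h)
    best, best_abs = 0.0, 0.0
    running = 0.0
    for i in range(n):
        if hits[i]:
            running += (abs(scores[i]) ** p) / denom if denom > 0 else 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        # recompute from scratch up to i (quadratic, deliberately independent)
        check = 0.0
        for j in range(i + 1):
            if hits[j]:
                check += (abs(scores[j]) ** p) / denom if denom > 0 else 1.0 / n_hits
            else:
                check -= 1.0 / (n - n_hits)
        assert abs(check - running) < 1e-9
        if abs(running) > best_abs or (abs(running) == best_abs and running > best):
            best, best_abs = running, abs(running)
    return best


def make_ranked(rng, n):
    genes = np.array([f"G{i:03d}" for i in range(n)], dtype=object)
    scores = np.sort(rng.normal(0.2, 0.6, n))[::-1]
    return RankedList(genes, scores)


class TestEnrichmentScore:
    @pytest.mark.parametrize("p", [0.0, 1.0, 2.0])
    @pytest.mark.parametrize("k", [3, 10])
    def test_top_k_set_gives_one(self, rng, p, k):
        ranked = make_ranked(rng, 60)
        res = enrichment_score(ranked, list(ranked.genes[:k]), weight_exponent=p)
        assert res.es == pytest.approx(1.0, abs=1e-9)
        assert res.peak_index == k - 1

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_bottom_k_set_gives_minus_one(self, rng, p):
        ranked = make_ranked(rng, 60)
        res = enrichment_score(ranked, list(ranked.genes[-7:]), weight_exponent=p)
        assert res.es == pytest.approx(-1.0, abs=1e-9)

    def test_matches_quadratic_oracle_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 51))
            ranked = make_ranked(rng, n)
            size = int(rng.integers(1, max(2, n // 2)))
            members = list(rng.choice(ranked.genes, size, replace=False))
            p = float(rng.choice([0.0, 1.0, 1.5]))
            ours = enrichment_score(ranked, members, weight_exponent=p).es
            oracle = quadratic_oracle_es(ranked.genes, ranked.scores, members, p)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_reversed_list_negates_es_unweighted(self, rng):
        ranked = make_ranked(rng, 50)
        members = list(rng.choice(ranked.genes, 9, replace=False))
        fwd = enrichment_score(ranked, members, weight_exponent=0.0).es
        rev = RankedList(ranked.genes[::-1].copy(), -ranked.scores[::-1])
        bwd = enrichment_score(rev, members, weight_exponent=0.0).es
        assert bwd == pytest.approx(-fwd, abs=1e-9)

    def test_empty_intersection_rejected(self, rng):
        ranked = make_ranked(rng, 20)
        with pytest.raises(ValueError, match="no member"):
            enrichment_score(ranked, ["ABSENT"])

    def test_bounds_on_random_instances(self, rng):
        for _ in range(50):
            ranked = make_ranked(rng, int(rng.integers(5, 40)))
            size = int(rng.integers(1, len(ranked)))
            members = list(rng.choice(ranked.genes, size, replace=False))
            es = enrichment_score(ranked, members).es
            assert -1.0 <= es <= 1.0

    def test_matches_external_gsea_tool(self, rng):
        """Cross-check against the independent gseapy implementation."""
        gseapy = pytest.importorskip("gseapy")
        ranked = make_ranked(rng, 80)
        sets = {
            "A": list(rng.choice(ranked.genes, 15, replace=False)),
            "B": list(ranked.genes[:10]),
            "C": list(rng.choice(ranked.genes, 8, replace=False)),
        }
        df = pd.DataFrame({"gene": ranked.genes, "score": ranked.scores})
        res = gseapy.prerank(
            rnk=df, gene_sets=sets, permutation_num=4, min_size=2, max_size=70,
            outdir=None, seed=1, weight=1, threads=1, no_plot=True,
        ).res2d.set_index("Term")
        for name, members in sets.items():
            ours = enrichment_score(ranked, members, weight_exponent=1.0).es
            assert ours == pytest.approx(float(res.loc[name, "ES"]), abs=1e-6)


class TestPermutationNull:
    def test_size_bounds_and_determinism(self, rng):
        ranked = make_ranked(rng, 100)
        null_a = permutation_null(ranked, 10, 500, seed=7)
        null_b = permutation_null(ranked, 10, 500, seed=7)
        assert len(null_a) == 500
        assert np.all((null_a >= -1) & (null_a <= 1))
        np.testing.assert_array_equal(null_a, null_b)
        assert not np.array_equal(null_a, permutation_null(ranked, 10, 500, seed=8))

    def test_null_mean_stable_across_seeds(self, rng):
        ranked = make_ranked(rng, 200)
        means = []
        for seed in (1, 2):
            null = permutation_null(ranked, 15, 5000, seed=seed)
            means.append(np.abs(null[null > 0]).mean())
        assert means[0] == pytest.approx(means[1], abs=0.02)

    def test_invalid_args(self, rng):
        ranked = make_ranked(rng, 20)
        with pytest.raises(ValueError):
            permutation_null(ranked, 0, 10)
        with pytest.raises(ValueError):
            permutation_null(ranked, 5, 0)


class TestNormalizeAndFdr:
    def test_nes_one_at_null_mean(self):
        null = np.array([0.5, 0.3, -0.2, -0.4, 0.4])
        pos_mean = np.mean([0.5, 0.3, 0.4])
        obs = {"S": EnrichmentScore(es=pos_mean, peak_index=0, n_hits=5)}
        res = normalize_and_fdr(obs, {"S": null})[0]
        assert res.nes == pytest.approx(1.0, abs=1e-12)

    def test_zero_es_gives_zero_nes(self):
        null = np.array([0.5, -0.5, 0.2])
        obs = {"S": EnrichmentScore(es=0.0, peak_index=0, n_hits=3)}
        res = normalize_and_fdr(obs, {"S": null})[0]
        assert res.nes == 0.0

    def test_degenerate_same_sign_null_flagged_with_p_floor(self):
        null = np.array([0.1, 0.2, 0.3])  # no negative null values
        obs = {"S": EnrichmentScore(es=-0.5, peak_index=0, n_hits=3)}
        res = normalize_and_fdr(obs, {"S": null})[0]
        assert res.degenerate_null
        assert res.pval == pytest.approx(1.0 / 4)

    def test_pvalues_in_unit_interval_and_q_monotone(self, rng):
        ranked = make_ranked(rng, 120)
        obs, nulls = {}, {}
        for i in range(12):
            members = list(rng.choice(ranked.genes, 10, replace=False))
            name = f"S{i}"
            obs[name] = enrichment_score(ranked, members)
            nulls[name] = permutation_null(ranked, 10, 300, seed=i)
        results = normalize_and_fdr(obs, nulls)
        for r in results:
            assert 0 <= r.pval <= 1
            assert 0 <= r.fdr_q <= 1
        pos = sorted((r for r in results if r.nes >= 0), key=lambda r: -r.nes)
        assert all(a.fdr_q <= b.fdr_q + 1e-12 for a, b in zip(pos, pos[1:]))


class TestPrerankedGsea:
    def _ranked_and_sets(self, rng, n=150):
        ranked = make_ranked(rng, n)
        sets = GeneSetCollection(
            sets=[
                GeneSet("TOP", "planted", tuple(ranked.genes[:12])),
                GeneSet("RAND1", "", tuple(rng.choice(ranked.genes, 12, replace=False))),
                GeneSet("RAND2", "", tuple(rng.choice(ranked.genes, 15, replace=False))),
                GeneSet("TINY", "", tuple(ranked.genes[:2])),
            ]
        )
        return ranked, sets

    def test_top_set_ranks_first_and_small_sets_dropped(self, rng):
        ranked, sets = self._ranked_and_sets(rng)
        results = preranked_gsea(ranked, sets, n_perm=200, seed=3, min_size=5)
        assert results[0].name == "TOP"
        assert results[0].es == pytest.approx(1.0, abs=1e-9)
        assert "TINY" not in {r.name for r in results}
        nes = [r.nes for r in results]
        assert nes == sorted(nes, reverse=True)

    def test_shuffled_gmt_order_gives_identical_results(self, rng):
        ranked, sets = self._ranked_and_sets(rng)
        shuffled = GeneSetCollection(sets=list(reversed(sets.sets)))
        a = preranked_gsea(ranked, sets, n_perm=100, seed=5, min_size=5)
        b = preranked_gsea(ranked, shuffled, n_perm=100, seed=5, min_size=5)
        assert [(r.name, r.es, r.nes, r.pval, r.fdr_q) for r in a] == [
            (r.name, r.es, r.nes, r.pval, r.fdr_q) for r in b
        ]

    def test_no_surviving_sets_rejected(self, rng):
        ranked, _ = self._ranked_and_sets(rng)
        sets = GeneSetCollection(sets=[GeneSet("TINY", "", tuple(ranked.genes[:2]))])
        with pytest.raises(ValueError, match="no gene set"):
            preranked_gsea(ranked, sets, n_perm=10, min_size=5)

    def test_reads_rnk_and_gmt_files(self, rng, tmp_path):
        ranked, sets = self._ranked_and_sets(rng)
        rnk = tmp_path / "r.rnk"
        with open(rnk, "w") as fh:
            for g, s in zip(ranked.genes, ranked.scores):
                fh.write(f"{g}\t{float(s)!r}\n")
        from tmetargets.io import write_gmt

        gmt = tmp_path / "s.gmt"
        write_gmt(sets, gmt)
        results = preranked_gsea(rnk, gmt, n_perm=50, seed=1, min_size=5)
        assert results[0].name == "TOP"
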