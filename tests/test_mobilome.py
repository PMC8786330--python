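"""MGE keywords, viral/plasmid rules, pathways, Fisher/Hochberg, rank-sum."""
from math import comb

import numpy as np
import pandas as pd
import pytest

from maglow import mobilome as mb


class TestClassifyCmge:
    @pytest.mark.parametrize(
        "product,expected",
        [
            ("Tn3 family transposase", "transposon"),
            ("conjugal transfer protein TraG", "plasmid"),
            ("phage major capsid protein", "phage"),
            ("site-specific integrase", "other"),
            ("hypothetical protein", "none"),
            ("TRANSPOSASE (upper case)", "transposon"),
        ],
    )
    def test_keyword_classes(self, product, expected):
        assert mb.classify_cmge(product)[0] == expected

    def test_priority_order_is_fixed(self):
        # matches both transposon and phage lists; transposon wins
        assert mb.classify_cmge("phage transposase fusion")[0] == "transposon"


class TestMgeDensity:
    def test_per_mbp(self):
        calls = [mb.MgeCall(f"o{i}", "b", "transposon") for i in range(30)]
        assert mb.mge_density(calls, 3e6)["transposon"] == pytest.approx(10.0)

    def test_no_calls(self):
        assert mb.mge_density([], 1e6) == {c: 0.0 for c in mb.MGE_CLASSES}

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            mb.mge_density([], 0)


class TestDetectViral:
    @pytest.mark.parametrize(
        "length,cat,score,p,expected",
        [
            (6000, 1, None, None, True),
            (6000, None, 0.95, 0.005, True),
            (4000, 1, None, None, False),  # below 5 kb
            (6000, 3, None, None, False),  # category 3 does not qualify
            (6000, None, 0.95, 0.02, False),  # p not < .01
            (6000, None, 0.89, 0.005, False),  # score not >= 0.9
            (5000, 4, None, None, True),  # boundary length kept
        ],
    )
    def test_decision_table(self, length, cat, score, p, expected):
        assert mb.detect_viral(length, cat, score, p) is expected

    def test_monotone_in_evidence(self):
        base = mb.detect_viral(6000, None, 0.95, 0.005)
        with_cat = mb.detect_viral(6000, 1, 0.95, 0.005)
        assert with_cat >= base

    def test_intersection_mode(self):
        assert mb.detect_viral(6000, 1, None, None, combine="intersection") is False
        assert (
            mb.detect_viral(6000, 1, 0.95, 0.001, combine="intersection") is True
        )


@pytest.fixture(scope="module")
def circular_seq():
    rng = np.random.default_rng(5)
    body = "".join(rng.choice(list("ACGT"), size=15_000))
    return body + body[:500]  # terminal 500-bp exact repeat


class TestPlasmidDetection:
    def test_circular_fixture_detected(self, circular_seq):
        assert mb.is_circular(circular_seq)

    def test_linear_sequence_not_circular(self):
        rng = np.random.default_rng(6)
        assert not mb.is_circular("".join(rng.choice(list("ACGT"), size=15_000)))

    def test_unbinned_long_circular_is_plasmid(self, circular_seq):
        assert mb.detect_plasmid(circular_seq, binned=False)

    def test_binned_scaffold_never_plasmid(self, circular_seq):
        assert not mb.detect_plasmid(circular_seq, binned=True)

    def test_short_circular_not_plasmid(self):
        rng = np.random.default_rng(7)
        body = "".join(rng.choice(list("ACGT"), size=9_000))
        assert not mb.detect_plasmid(body + body[:200], binned=False)

    def test_length_only_requires_flag(self):
        assert mb.detect_plasmid(15_000, binned=False, circular=True)
        with pytest.raises(ValueError):
            mb.detect_plasmid(15_000, binned=False)


class TestViralTaxonomy:
    def _hits(self, families, bitscore=80):
        return pd.DataFrame(
            {
                "protein": [f"p{i}" for i in range(len(families))],
                "family": families,
                "bitscore": [bitscore] * len(families),
            }
        )

    def test_six_of_ten_assigns_family(self):
        hits = self._hits(["Siphoviridae"] * 6 + ["Myoviridae"] * 2)
        assert mb.assign_viral_taxonomy(hits, n_proteins=10) == "Siphoviridae"

    def test_exactly_half_is_unclassified(self):
        hits = self._hits(["Siphoviridae"] * 5)
        assert mb.assign_viral_taxonomy(hits, n_proteins=10) is None

    def test_weak_bitscores_discarded(self):
        hits = self._hits(["Siphoviridae"] * 9, bitscore=50)  # not > 50
        assert mb.assign_viral_taxonomy(hits, n_proteins=10) is None

    def test_best_hit_per_protein(self):
        hits = pd.DataFrame(
            {
                "protein": ["p0", "p0", "p1"],
                "family": ["Myoviridae", "Siphoviridae", "Siphoviridae"],
                "bitscore": [60, 90, 70],
            }
        )
        assert mb.assign_viral_taxonomy(hits, n_proteins=2) == "Siphoviridae"


class TestFilterHits:
    @pytest.mark.parametrize(
        "identity,coverage,db,kept",
        [
            (0.30, 0.70, "kegg", True),
            (0.29, 0.90, "kegg", False),
            (0.90, 0.69, "kegg", False),
            (0.95, 0.90, "card", True),
            (0.94, 0.95, "card", False),
            (0.99, 0.89, "card", False),
        ],
    )
    def test_boundaries(self, identity, coverage, db, kept):
        assert mb.filter_hits(identity, coverage, db) is kept

    def test_unknown_database_rejected(self):
        with pytest.raises(ValueError):
            mb.filter_hits(0.5, 0.5, "pfam")


class TestPathwayPresence:
    def test_two_thirds_boundary(self):
        defs = {"P1": {f"r{i}" for i in range(9)}}
        present_6 = mb.pathway_presence({f"r{i}" for i in range(6)}, defs)[0]
        present_5 = mb.pathway_presence({f"r{i}" for i in range(5)}, defs)[0]
        assert present_6.is_present  # 6/9 = 0.667 > 0.66
        assert not present_5.is_present  # 5/9 = 0.556

    def test_complete_pathway_present(self):
        defs = {"P1": {"a", "b"}}
        assert mb.pathway_presence({"a", "b"}, defs)[0].is_present

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            mb.pathway_presence(set(), {"P1": set()})


class TestFisherAndHochberg:
    def test_perfect_separation_closed_form(self):
        p = mb.fisher_one_sided([[10, 0], [0, 10]])
        assert p == pytest.approx(1 / comb(20, 10), rel=1e-9)

    def test_balanced_table_closed_form(self):
        assert mb.fisher_one_sided([[1, 1], [1, 1]]) == pytest.approx(5 / 6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mb.fisher_one_sided([[1, -1], [0, 2]])

    def test_equal_raw_ps_stay_unadjusted(self):
        tables = {
            "a": [[3, 7], [7, 3]],
            "b": [[7, 3], [3, 7]],
        }
        out = mb.enrichment({k: np.array(v) for k, v in tables.items()})
        # Hochberg with m p-values: identical ps keep the smallest multiplier
        raw = out.set_index("pathway")["p"]
        adj = out.set_index("pathway")["p_adjusted"]
        assert (adj >= raw - 1e-12).all()

    def test_hochberg_matches_step_up_algebra(self):
        rng = np.random.default_rng(8)
        raws = np.sort(rng.uniform(size=6))
        tables = {}
        # build tables indirectly is awkward; exercise the adjustment alone
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(raws, method="simes-hochberg")[1]
        # independent step-up oracle
        m = len(raws)
        expected = np.empty(m)
        running = 1.0
        for i in range(m - 1, -1, -1):
            running = min(running, (m - i) * raws[i])
            expected[i] = running
        assert np.allclose(adj, expected)


class TestRankSum:
    def test_complete_tie_has_p_one(self):
        stat, p = mb.rank_sum([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_full_separation_matches_exact_enumeration(self):
        x = [10.0, 11.0, 12.0, 13.0]
        y = [1.0, 2.0, 3.0]
        _, p = mb.rank_sum(x, y)
        # all x above all y: two-sided exact p = 2 / C(7, 4)
        assert p == pytest.approx(2 / comb(7, 4))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mb.rank_sum([], [1.0])


class TestCompareTiers:
    def test_pairwise_results_shape(self):
        rng = np.random.default_rng(9)
        frame = pd.DataFrame(
            {
                "transposon": rng.uniform(size=12),
                "plasmid": rng.uniform(size=12),
                "phage": rng.uniform(size=12),
                "other": rng.uniform(size=12),
                "tier": ["high"] * 4 + ["low"] * 4 + ["extra-low"] * 4,
            }
        )
        out = mb.compare_tiers(frame)
        assert len(out) == 4 * 3  # 4 classes x 3 tier pairs
        assert ((out["p"] > 0) & (out["p"] <= 1)).all()

    def test_sparse_tier_rejected(self):
        frame = pd.DataFrame(
            {"transposon": [1.0, 2.0, 3.0, 4.0], "plasmid": [1, 2, 3, 4],
             "phage": [1, 2, 3, 4], "other": [1, 2, 3, 4],
             "tier": ["high", "high", "high", "low"]}
        )
        with pytest.raises(ValueError):
            mb.compare_tiers(frame)
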