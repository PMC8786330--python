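"""The generator must plant exactly what the estimators later recover."""
import numpy as np
import pytest

from maglow import popgen, seqfeatures as sf, synthetic as syn
from maglow.records import ScaffoldRecord


def _tiny_spec(**overrides):
    base = dict(
        n_genomes=2, genome_length_range=(30_000, 40_000), total_bases=1e9, seed=7
    )
    base.update(overrides)
    return syn.CommunitySpec(**base)


class TestGenerateGenomes:
    def test_same_seed_is_byte_identical(self):
        g1, t1 = syn.generate_genomes(_tiny_spec())
        g2, t2 = syn.generate_genomes(_tiny_spec())
        assert g1 == g2
        assert t1.tag_catalog == t2.tag_catalog
        assert [t.ori for t in t1.genomes.values()] == [
            t.ori for t in t2.genomes.values()
        ]

    def test_zero_sigma_gives_equal_abundances(self):
        _, truth = syn.generate_genomes(_tiny_spec(n_genomes=3, abundance_sigma=0.0))
        for t in truth.genomes.values():
            assert t.abundance == pytest.approx(1 / 3)

    def test_abundances_sum_to_one(self, small_community):
        _, truth = small_community
        assert sum(t.abundance for t in truth.genomes.values()) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_gc_hits_target_within_one_percent(self):
        genomes, truth = syn.generate_genomes(_tiny_spec(gc_range=(0.5, 0.5)))
        for gid, seq in genomes.items():
            assert 0.49 <= sf.compute_gc(seq) <= 0.51

    def test_each_marker_tag_planted_exactly_once(self, small_community):
        genomes, truth = small_community
        for gid, seq in genomes.items():
            for marker, tag in list(truth.tag_catalog.items())[::25]:
                assert seq.count(tag) == 1
                assert seq.find(tag) == truth.genomes[gid].scg_positions[marker]

    def test_skew_trough_at_planted_ori(self, small_community):
        genomes, truth = small_community
        for gid, seq in genomes.items():
            t = truth.genomes[gid]
            profile = sf.cumulative_gc_skew(seq, 1000)
            err = abs(
                (profile.ori_position - t.ori + t.length / 2) % t.length
                - t.length / 2
            )
            assert err <= 2000

    def test_orfs_are_in_frame_sense_codons(self, small_community):
        genomes, truth = small_community
        for gid, t in truth.genomes.items():
            for orf in t.orfs[::10]:
                n, s = popgen.codon_opportunities(genomes[gid][orf.start : orf.end])
                assert n + s == 3 * orf.length

    @pytest.mark.parametrize(
        "overrides",
        [
            {"abundance_sigma": -0.5},
            {"genome_length_range": (0, 1000)},
            {"n_scg": 0},
            {"total_bases": -1.0},
            {"ptr_range": (0.5, 2.0)},
        ],
    )
    def test_invalid_specs_rejected(self, overrides):
        with pytest.raises(ValueError):
            syn.generate_genomes(_tiny_spec(**overrides))


class TestFragmentGenomes:
    def test_fixed_fragments_partition_exactly(self):
        genomes, truth = syn.generate_genomes(
            _tiny_spec(
                n_genomes=1,
                genome_length_range=(10_000, 10_000),
                n_scg=5,
                mge_keyword_counts={"transposon": 1},
            )
        )
        frags = syn.fragment_genomes(genomes, truth, 2000)
        assert [f.length for f in frags] == [2000] * 5

    def test_concatenation_reproduces_genome(self, small_community, small_scaffolds):
        genomes, truth = small_community
        for gid, seq in genomes.items():
            parts = sorted(
                (f for f in small_scaffolds if f.genome == gid), key=lambda f: f.start
            )
            assert "".join(p.sequence for p in parts) == seq

    def test_uniform_model_conserves_total_length(self, small_community):
        genomes, truth = small_community
        frags = syn.fragment_genomes(genomes, truth, ("uniform", 2000, 5000))
        for gid, seq in genomes.items():
            total = sum(f.length for f in frags if f.genome == gid)
            assert total == len(seq)

    def test_oversized_fragment_gives_single_scaffold(self):
        genomes, truth = syn.generate_genomes(
            _tiny_spec(n_genomes=1, genome_length_range=(30_000, 30_000))
        )
        frags = syn.fragment_genomes(genomes, truth, 1_000_000)
        assert len(frags) == 1

    def test_short_fragment_model_rejected(self, small_community):
        genomes, truth = small_community
        with pytest.raises(ValueError):
            syn.fragment_genomes(genomes, truth, 400)


class TestSimulateDepth:
    def test_flat_profile_mean_matches_closed_form(self):
        genomes, truth = syn.generate_genomes(
            _tiny_spec(
                n_genomes=1,
                genome_length_range=(40_000, 40_000),
                ptr_range=(1.0, 1.0),
            )
        )
        sc = [ScaffoldRecord("g00", genomes["g00"], "g00", 0)]
        # abundance 1, total 2e8 over 40 kb -> 5000x; SE per window ~ sqrt(D/w)
        table = syn.simulate_depth(sc, truth, total_bases=2e8, window=1000)
        expected = 2e8 / 40_000
        se = np.sqrt(expected / 1000) / np.sqrt(len(table))
        assert table["depth"].mean() == pytest.approx(expected, abs=3 * se)

    def test_ptr_one_has_no_gradient(self):
        genomes, truth = syn.generate_genomes(
            _tiny_spec(
                n_genomes=1,
                genome_length_range=(40_000, 40_000),
                ptr_range=(1.0, 1.0),
            )
        )
        sc = [ScaffoldRecord("g00", genomes["g00"], "g00", 0)]
        table = syn.simulate_depth(sc, truth, total_bases=1e9, window=1000)
        d = table["depth"].to_numpy()
        assert d.max() / d.min() < 1.1

    def test_planted_ptr_realized_at_ori_and_ter(self):
        genomes, truth = syn.generate_genomes(
            _tiny_spec(
                n_genomes=1,
                genome_length_range=(100_000, 100_000),
                ptr_range=(2.0, 2.0),
            )
        )
        t = truth.genomes["g00"]
        sc = [ScaffoldRecord("g00", genomes["g00"], "g00", 0)]
        ratios = []
        for rep in range(50):
            table = syn.simulate_depth(
                sc, truth, total_bases=1e9, window=1000, seed=rep
            )
            d = table["depth"].to_numpy()
            ratios.append(d[t.ori // 1000] / d[t.ter // 1000])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_invalid_inputs_rejected(self, small_community, small_scaffolds):
        _, truth = small_community
        with pytest.raises(ValueError):
            syn.simulate_depth(small_scaffolds, truth, total_bases=0)
        with pytest.raises(ValueError):
            syn.simulate_depth(small_scaffolds, truth, window=50)


class TestSimulatePileups:
    def test_zero_density_zero_error_is_all_reference(self):
        genomes, truth = syn.generate_genomes(
            _tiny_spec(n_genomes=1, snp_density_range=(0.0, 0.0))
        )
        sim = syn.simulate_pileups(genomes, truth, mean_depth=10)
        seq = genomes["g00"]
        for site in sim.sites():
            if site.pos >= 2000:
                break
            assert (site.bases == seq[site.pos]).all()

    def test_planted_site_count_matches_density(self):
        genomes, truth = syn.generate_genomes(
            _tiny_spec(
                n_genomes=1,
                genome_length_range=(100_000, 100_000),
                snp_density_range=(2.0, 2.0),
            )
        )
        sim = syn.simulate_pileups(genomes, truth, mean_depth=10)
        assert sim.planted["g00"].n_sites == 200

    def test_neutral_plant_matches_opportunity_ratio(self):
        genomes, truth = syn.generate_genomes(
            _tiny_spec(
                n_genomes=1,
                genome_length_range=(100_000, 100_000),
                snp_density_range=(20.0, 20.0),
                dnds_per_genome=1.0,
            )
        )
        sim = syn.simulate_pileups(genomes, truth, mean_depth=5)
        plants = sim.planted["g00"]
        exp_n = exp_s = 0
        for orf in truth.genomes["g00"].orfs:
            n, s = popgen.codon_opportunities(genomes["g00"][orf.start : orf.end])
            exp_n += n
            exp_s += s
        observed = plants.n_nonsynonymous / plants.n_synonymous
        expected = exp_n / exp_s
        assert observed == pytest.approx(expected, rel=0.15)

    def test_mean_depth_below_one_rejected(self, small_community):
        genomes, truth = small_community
        with pytest.raises(ValueError):
            syn.simulate_pileups(genomes, truth, mean_depth=0.5)


class TestEmitAnnotations:
    def test_planted_mge_keyword_counts_exact(self, small_community):
        from maglow import mobilome

        genomes, truth = small_community
        ann = syn.emit_annotations(truth)
        calls = mobilome.classify_cmge_table(ann)
        for gid, t in truth.genomes.items():
            found = {}
            for c in calls:
                if c.bin == gid and c.mge_class != "none":
                    found[c.mge_class] = found.get(c.mge_class, 0) + 1
            assert found == t.mge_counts

    def test_rrna_and_trna_features_present(self, small_community):
        _, truth = small_community
        ann = syn.emit_annotations(truth)
        one = ann[ann["genome"] == "g00"]
        assert (one["type"] == "tRNA").sum() == truth.genomes["g00"].trna_count
        for r in ("5S", "16S", "23S"):
            assert (one["type"] == f"rRNA_{r}").sum() == 1

    def test_zero_mge_plant_yields_zero_calls(self):
        from maglow import mobilome

        genomes, truth = syn.generate_genomes(
            _tiny_spec(mge_keyword_counts={"transposon": 0})
        )
        calls = mobilome.classify_cmge_table(syn.emit_annotations(truth))
        assert all(c.mge_class == "none" for c in calls)

    def test_excess_keyword_request_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_genomes(_tiny_spec(mge_keyword_counts={"phage": 10_000}))
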