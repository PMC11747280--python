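import numpy as np
import pytest
from dataclasses import replace

from breakscape import junctions as jx
from breakscape.model import ValidationError, find_asisi_sites
from breakscape.simulate import (
    ChipParams,
    GenomeParams,
    SimulationConfig,
    build_layout,
    junction_params_for,
    simulate_chip,
    simulate_contacts,
    simulate_junctions,
)
from breakscape.stats import welch_t


class TestBuildLayout:
    def test_deterministic(self, small_config):
        b1, b2 = build_layout(small_config), build_layout(small_config)
        assert [t.interval for t in b1.tads] == [t.interval for t in b2.tads]
        assert [s.cut for s in b1.sites] == [s.cut for s in b2.sites]
        assert b1.truth.cut_ids == b2.truth.cut_ids
        assert b1.truth.site_intensity == b2.truth.site_intensity

    def test_tads_tile_each_chromosome(self, small_bundle):
        for chrom in small_bundle.layout.chrom_names:
            tads = [t for t in small_bundle.tads if t.interval.chrom == chrom]
            assert tads[0].interval.start == 0
            assert tads[-1].interval.end == small_bundle.layout.chrom_lengths[chrom]
            for a, b in zip(tads[:-1], tads[1:]):
                assert a.interval.end == b.interval.start

    def test_cut_spacing_respected(self, small_bundle, small_config):
        spacing = small_config.genome.min_cut_spacing
        for chrom in small_bundle.layout.chrom_names:
            cuts = sorted(
                s.midpoint for s in small_bundle.cut_sites if s.chrom == chrom
            )
            for a, b in zip(cuts[:-1], cuts[1:]):
                assert b - a >= spacing

    def test_n_cut_exceeding_n_asisi_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(seed=1, genome=GenomeParams(n_asisi=4, n_cut=5))

    def test_infeasible_spacing_reports_suggestion(self):
        with pytest.raises(ValidationError, match="reduce n_cut"):
            build_layout(
                SimulationConfig(
                    seed=1,
                    genome=GenomeParams(
                        n_chrom=1,
                        chrom_length=5_000_000,
                        n_asisi=8,
                        n_cut=8,
                        n_baits=1,
                        min_cut_spacing=2_400_000,
                    ),
                )
            )

    def test_damaged_domains_cover_cuts(self, small_bundle):
        for site in small_bundle.cut_sites:
            assert any(
                d.interval.chrom == site.chrom
                and d.interval.contains(site.midpoint)
                for d in small_bundle.truth.damaged_domains
            )

    def test_planted_sequence_matches_site_list(self):
        cfg = SimulationConfig(
            seed=3,
            genome=GenomeParams(
                n_chrom=1,
                chrom_length=3_000_000,
                n_asisi=3,
                n_cut=2,
                n_baits=1,
                min_cut_spacing=900_000,
                with_sequence=True,
            ),
        )
        bundle = build_layout(cfg)
        scanned = find_asisi_sites(bundle.layout)
        assert {s.cut.start for s in scanned} == {
            s.cut.start for s in bundle.sites
        }


class TestSimulateChip:
    def test_deterministic(self, small_bundle, small_config):
        t1, _ = simulate_chip(small_bundle, "WT", "DSB", small_config)
        t2, _ = simulate_chip(small_bundle, "WT", "DSB", small_config)
        for factor in t1:
            for chrom in t1[factor].values:
                np.testing.assert_array_equal(
                    t1[factor].values[chrom], t2[factor].values[chrom]
                )

    def test_mre11_flat_without_damage(self, small_bundle, small_config):
        tracks, _ = simulate_chip(small_bundle, "WT", "NT", small_config)
        background = small_config.chip.background
        for chrom, v in tracks["MRE11"].values.items():
            assert v.mean() == pytest.approx(background, rel=0.1)
            # no bin anywhere near peak height
            assert v.max() < small_config.chip.mre11_height / 2

    def test_unknown_genotype_rejected(self, small_bundle, small_config):
        with pytest.raises(ValidationError):
            simulate_chip(small_bundle, "XYZ", "DSB", small_config)

    def test_null_enrichment_inside_equals_outside(self, small_config):
        cfg = replace(
            small_config,
            chip=ChipParams(anchor_fc={"WT": 1.0}),
        )
        bundle = build_layout(cfg)
        tracks, peaks = simulate_chip(bundle, "WT", "DSB", cfg)
        tracks_nt, _ = simulate_chip(bundle, "WT", "NT", cfg)
        from breakscape.enrichment import call_anchor_sites

        anchors = call_anchor_sites(peaks["RAD21"], peaks["CTCF"])
        inside, outside = _fold_changes(
            anchors, bundle, tracks["RAD21"], tracks_nt["RAD21"]
        )
        # two-sided test must not reject at the 1% level under the null
        assert welch_t(inside, outside, tails="two").p_value > 0.01


def _fold_changes(anchors, bundle, treated, untreated):
    from breakscape.enrichment import peak_fold_change

    inside, outside = [], []
    for a in anchors:
        fc = peak_fold_change(a, treated, untreated)[2]
        if any(
            d.interval.chrom == a.chrom and d.interval.contains(a.summit)
            for d in bundle.truth.damaged_domains
        ):
            inside.append(fc)
        else:
            outside.append(fc)
    return np.array(inside), np.array(outside)


class TestSimulateContacts:
    def test_deterministic(self, small_bundle, small_config):
        c1 = simulate_contacts(small_bundle, "WT", "DSB", small_config)
        c2 = simulate_contacts(small_bundle, "WT", "DSB", small_config)
        for key in c1:
            np.testing.assert_array_equal(c1[key].counts, c2[key].counts)

    def test_intra_matrices_symmetric(self, small_bundle, small_config):
        contacts = simulate_contacts(small_bundle, "WT", "NT", small_config)
        for (a, b), m in contacts.items():
            if a == b:
                np.testing.assert_array_equal(m.counts, m.counts.T)

    def test_null_oe_within_tads_near_one(self):
        from breakscape import hic
        from breakscape.simulate import HicParams

        cfg = SimulationConfig(
            seed=11,
            genome=GenomeParams(
                n_chrom=1, chrom_length=20_000_000, n_asisi=4, n_cut=2,
                n_baits=1, min_cut_spacing=2_400_000,
            ),
            hic=HicParams(depth=1e6, tad_boost=1.0, intra_damage_fc={}, gamma={}),
        )
        bundle = build_layout(cfg)
        m = simulate_contacts(bundle, "WT", "DSB", cfg)[("chr1", "chr1")]
        oe = hic.oe_normalize(m)
        scores = [
            hic.intra_domain_score(oe, t).score
            for t in bundle.tads
            if t.interval.width >= 2 * cfg.hic.resolution
        ]
        assert 0.95 <= np.mean(scores) <= 1.05

    def test_cohesin_depletion_lowers_intra_tad_oe(self, small_bundle, small_config):
        from breakscape import hic

        wt = simulate_contacts(small_bundle, "WT", "NT", small_config)
        dep = simulate_contacts(small_bundle, "RAD21-", "NT", small_config)
        for chrom in small_bundle.layout.chrom_names:
            oe_wt = hic.oe_normalize(wt[(chrom, chrom)])
            oe_dep = hic.oe_normalize(dep[(chrom, chrom)])
            tads = [
                t
                for t in small_bundle.tads
                if t.interval.chrom == chrom
                and t.interval.width >= 2 * small_config.hic.resolution
            ]
            s_wt = np.mean([hic.intra_domain_score(oe_wt, t).score for t in tads])
            s_dep = np.mean([hic.intra_domain_score(oe_dep, t).score for t in tads])
            assert s_dep < s_wt


class TestSimulateJunctions:
    def test_deterministic(self, small_bundle, small_config):
        contacts = simulate_contacts(small_bundle, "WT", "DSB", small_config)
        bait = small_bundle.truth.bait_ids[0]
        r1 = simulate_junctions(small_bundle, contacts, bait, small_config)
        r2 = simulate_junctions(small_bundle, contacts, bait, small_config)
        assert r1 == r2

    def test_replicates_differ(self, small_bundle, small_config):
        contacts = simulate_contacts(small_bundle, "WT", "DSB", small_config)
        bait = small_bundle.truth.bait_ids[0]
        r1 = simulate_junctions(small_bundle, contacts, bait, small_config)
        r2 = simulate_junctions(
            small_bundle, contacts, bait, small_config, replicate=1
        )
        assert r1 != r2

    def test_degenerate_mh_p_one(self, small_bundle, small_config):
        contacts = simulate_contacts(small_bundle, "WT", "DSB", small_config)
        params = replace(small_config.junctions, mh_geometric_p=1.0)
        records = simulate_junctions(
            small_bundle, contacts, small_bundle.truth.bait_ids[0],
            small_config, params,
        )
        assert all(
            jx.microhomology_length(r.bait_flank, r.prey_flank) == 0
            for r in records
        )

    def test_flanks_embed_drawn_microhomology(self, small_bundle, small_config):
        contacts = simulate_contacts(small_bundle, "WT", "DSB", small_config)
        params = replace(small_config.junctions, mh_geometric_p=0.4)
        records = simulate_junctions(
            small_bundle, contacts, small_bundle.truth.bait_ids[0],
            small_config, params,
        )
        lengths = [
            jx.microhomology_length(r.bait_flank, r.prey_flank) for r in records
        ]
        # geometric(0.4) mean = 1.5 (capped tail shifts it only slightly)
        assert 1.3 <= np.mean(lengths) <= 1.7

    def test_all_bait_proximal_removed_by_filter(self, small_bundle, small_config):
        contacts = simulate_contacts(small_bundle, "WT", "DSB", small_config)
        params = replace(small_config.junctions, bait_proximal_fraction=1.0)
        bait_id = small_bundle.truth.bait_ids[0]
        records = simulate_junctions(
            small_bundle, contacts, bait_id, small_config, params
        )
        bait = small_bundle.site_by_id(bait_id)
        kept, removed = jx.filter_bait_proximal(records, bait)
        assert kept == [] and len(removed) == len(records)

    def test_non_cut_bait_rejected(self, small_bundle, small_config):
        contacts = simulate_contacts(small_bundle, "WT", "DSB", small_config)
        uncut = next(
            s.id for s in small_bundle.sites
            if s.id not in small_bundle.truth.cut_ids
        )
        with pytest.raises(ValidationError):
            simulate_junctions(small_bundle, contacts, uncut, small_config)

    def test_genotype_params_table(self, small_config):
        p = junction_params_for("RAD21-", small_config.junctions)
        assert p.trans_multiplier == pytest.approx(4.3)
        assert p.cis_multiplier == pytest.approx(6.0)
        with pytest.raises(ValidationError):
            junction_params_for("nonsense", small_config.junctions)
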