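"""Generator contracts: determinism, planted structure, truth recovery."""

import numpy as np
import pytest

from cicerkit import divergence_dating as dd
from cicerkit import genome_topography as gt
from cicerkit.synthetic_data import (
    GenomeSimConfig,
    simulate_allele_counts,
    simulate_cds_pairs,
    simulate_expression,
    simulate_genome,
    simulate_hits,
)


class TestGenome:
    def test_same_seed_gives_byte_identical_output(self):
        cfg = GenomeSimConfig(
            n_linkage_groups=1, arm_length_bp=400_000, core_length_bp=300_000,
            seed=5,
        )
        r1 = simulate_genome(cfg)
        r2 = simulate_genome(cfg)
        assert [x.residues for x in r1[0]] == [x.residues for x in r2[0]]
        assert [m.marker_id for m in r1[3]] == [m.marker_id for m in r2[3]]

    def test_different_seeds_give_different_marker_ids(self):
        base = dict(
            n_linkage_groups=1, arm_length_bp=400_000, core_length_bp=300_000
        )
        m1 = simulate_genome(GenomeSimConfig(**base, seed=1))[3]
        m2 = simulate_genome(GenomeSimConfig(**base, seed=2))[3]
        assert {m.marker_id for m in m1}.isdisjoint(m.marker_id for m in m2)

    def test_core_repeat_coverage_exceeds_arm(self, single_chromosome_sim):
        cfg, records, _, repeats, _, truth = single_chromosome_sim
        sid = truth.scaffold_order["LG1"][0][0]
        c0, c1 = truth.cores["LG1"]
        ivals = gt.repeat_intervals(repeats, sid)
        core_cov = gt.window_density(ivals, [(c0, c1)], "covered_fraction")
        arm_cov = gt.window_density(ivals, [(1, c0 - 1)], "covered_fraction")
        assert core_cov.windows[0][2] > arm_cov.windows[0][2] + 0.3

    def test_marker_spacing_tracks_configured_rate(self):
        cfg = GenomeSimConfig(
            n_linkage_groups=1, arm_length_bp=2_000_000,
            core_length_bp=1_000_000, marker_spacing_cm=1.0, seed=4,
        )
        _, _, _, markers, _ = simulate_genome(cfg)
        arm = [m for m in markers if m.bp <= cfg.arm_length_bp]
        gaps = np.diff([m.bp for m in arm])
        # arm configured at 193 kb/cM with 1 cM spacing
        assert np.allclose(gaps, 193_000, rtol=0.05)

    def test_overpacked_density_is_an_error(self):
        with pytest.raises(ValueError, match="density"):
            GenomeSimConfig(gene_density_arm=25.0)

    def test_genes_do_not_overlap_within_a_scaffold(self, multi_scaffold_sim):
        _, _, genes, _, _, _ = multi_scaffold_sim
        by_seq = {}
        for g in genes:
            by_seq.setdefault(g.seq_id, []).append(g.span)
        for spans in by_seq.values():
            spans.sort()
            for a, b in zip(spans, spans[1:]):
                assert a[1] < b[0]

    def test_truth_references_emitted_entities(self, multi_scaffold_sim):
        _, records, _, _, markers, truth = multi_scaffold_sim
        ids = {r.id for r in records}
        for order in truth.scaffold_order.values():
            assert {sid for sid, _ in order} <= ids
        assert set(truth.unanchored) <= ids
        assert {m.seq_id for m in markers} <= ids


class TestExpression:
    def test_planted_specific_genes_have_single_nonzero_tissue(self):
        gene_ids = [f"g{i}" for i in range(100)]
        mx, truth = simulate_expression(gene_ids, ["a", "b", "c"], seed=2)
        frame = mx.to_frame()
        for tissue, genes in truth.specific.items():
            for g in genes:
                row = frame.loc[g]
                assert row[tissue] > 0
                assert (row.drop(tissue) == 0).all()

    def test_planted_preferential_margin_is_at_least_four_fold(self):
        gene_ids = [f"g{i}" for i in range(100)]
        mx, truth = simulate_expression(gene_ids, ["a", "b", "c"], seed=2)
        rpm = mx.counts / mx.library_sizes[None, :] * 1e6
        idx = {g: i for i, g in enumerate(mx.gene_ids)}
        for tissue, genes in truth.preferential.items():
            t = mx.tissue_ids.index(tissue)
            for g in genes:
                row = rpm[idx[g]]
                others = np.delete(row, t)
                assert row[t] >= 4 * others.max()

    def test_library_scaling_leaves_rpm_proportional_to_counts(self):
        mx, _ = simulate_expression(["g0", "g1"], ["a", "b"], 0, 0, seed=1)
        rpm = mx.counts / mx.library_sizes[None, :] * 1e6
        col = mx.counts[:, 0] / mx.library_sizes[0] * 1e6
        assert np.allclose(rpm[:, 0], col)

    def test_fewer_than_two_tissues_is_an_error(self):
        with pytest.raises(ValueError):
            simulate_expression(["g0"], ["only"], seed=0)


class TestCdsPairs:
    def test_target_zero_gives_identical_pair(self):
        pairs, _ = simulate_cds_pairs(1, 200, [0.0], seed=0)
        a, b = pairs[0]
        assert a.residues == b.residues

    def test_generator_hits_target_within_ten_percent(self):
        pairs, truth = simulate_cds_pairs(2, 5000, [0.002], seed=1)
        for a, b in pairs:
            ks = dd.ks_ng86(a, b).ks
            target = truth.ks_targets[(a.id, b.id)]
            assert abs(ks - target) <= 0.10 * target

    def test_pairs_differ_only_synonymously(self):
        pairs, _ = simulate_cds_pairs(1, 1000, [0.01], seed=3)
        a, b = pairs[0]
        for i in range(0, len(a.residues), 3):
            ca, cb = a.residues[i : i + 3], b.residues[i : i + 3]
            assert dd.CODON_TO_AA[ca] == dd.CODON_TO_AA[cb]

    def test_unreachable_target_advises_longer_genes(self):
        with pytest.raises(ValueError, match="longer genes"):
            simulate_cds_pairs(1, 50, [0.0001], seed=0)


class TestHits:
    def test_planted_categories_are_disjoint_and_sized(self):
        gene_ids = [f"g{i}" for i in range(60)]
        hits, truth = simulate_hits(gene_ids, 10, 15, seed=0)
        assert len(truth.orphan) == 10
        assert len(truth.species_specific) == 15
        assert truth.orphan.isdisjoint(truth.species_specific)
        sig = {h.query_id for h in hits if h.evalue < 1e-5}
        assert sig.isdisjoint(truth.orphan)


class TestAlleleCounts:
    def test_positives_have_unique_alt_at_depth_three_or_more(
        self, multi_scaffold_sim
    ):
        _, records, _, _, _, _ = multi_scaffold_sim
        sites, truth = simulate_allele_counts(records, 20, seed=9)
        keyed = {(s.seq_id, s.pos, s.group_id): s for s in sites}
        for group, planted in truth.snp_sites.items():
            for sid, pos, alt in planted:
                s = keyed[(sid, pos, group)]
                alts = {
                    b: d
                    for b, d in s.depth_by_base.items()
                    if b != s.ref_base and d > 0
                }
                assert list(alts) == [alt]
                assert alts[alt] >= 3

    def test_three_negative_classes_present(self, multi_scaffold_sim):
        _, records, _, _, _, _ = multi_scaffold_sim
        sites, truth = simulate_allele_counts(
            records, 5, n_negatives_per_class=4, seed=9
        )
        neg = [
            s
            for s in sites
            if (s.seq_id, s.pos) in truth.snp_negatives[s.group_id]
        ]
        classes = {"low_depth": 0, "two_alt": 0, "ref_only": 0}
        for s in neg:
            alts = {
                b: d
                for b, d in s.depth_by_base.items()
                if b != s.ref_base and d > 0
            }
            if not alts:
                classes["ref_only"] += 1
            elif len(alts) == 2:
                classes["two_alt"] += 1
            elif max(alts.values()) < 3:
                classes["low_depth"] += 1
        assert all(v == 8 for v in classes.values())  # 4 per class x 2 groups

    def test_bad_depth_range_is_an_error(self, multi_scaffold_sim):
        _, records, _, _, _, _ = multi_scaffold_sim
        with pytest.raises(ValueError):
            simulate_allele_counts(records, 5, depth_range=(0, 10), seed=0)
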