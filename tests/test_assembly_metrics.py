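"""Assembly statistics: filtering, N50, composition, anchoring."""

import numpy as np
import pytest

from cicerkit import assembly_metrics as am
from cicerkit.io_core import MarkerRecord, SequenceRecord


def n50_oracle(lengths):
    """Brute-force prefix scan over the descending-sorted lengths."""
    srt = sorted(lengths, reverse=True)
    total = sum(srt)
    for k in range(1, len(srt) + 1):
        if sum(srt[:k]) >= total / 2:
            return srt[k - 1], k


def _rec(i, n, base="A"):
    return SequenceRecord(f"s{i}", base * n)


class TestFilterShort:
    def test_boundary_length_survives(self):
        records = [_rec(0, 999), _rec(1, 1000), _rec(2, 1001)]
        kept = am.filter_short(records, 1000)
        assert [len(r) for r in kept] == [1000, 1001]

    def test_min_len_zero_is_identity(self):
        records = [_rec(i, 10 + i) for i in range(5)]
        assert am.filter_short(records, 0) == records

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        records = [_rec(i, int(n)) for i, n in enumerate(rng.integers(1, 50, 30))]
        kept = am.filter_short(records, 25)
        removed = [r for r in records if len(r) < 25]
        assert len(kept) + len(removed) == len(records)
        assert all(len(r) >= 25 for r in kept)


class TestN50:
    def test_single_scaffold(self):
        assert am.n50([10]) == (10, 1)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            am.n50([])

    def test_matches_brute_force_oracle_on_random_multisets(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            lengths = rng.integers(1, 10_000, rng.integers(1, 60)).tolist()
            assert am.n50(lengths) == n50_oracle(lengths)

    def test_n50_invariants(self):
        rng = np.random.default_rng(7)
        lengths = rng.integers(1, 5000, 40).tolist()
        length, idx = am.n50(lengths)
        srt = sorted(lengths, reverse=True)
        assert length in lengths
        assert sum(srt[:idx]) >= sum(lengths) / 2
        assert sum(srt[: idx - 1]) < sum(lengths) / 2


class TestComposition:
    def test_pure_gc(self):
        s = am.composition([SequenceRecord("s", "GGCC")])
        assert s.gc_fraction == 1.0 and s.n_fraction == 0.0

    def test_n_excluded_from_gc_denominator(self):
        s = am.composition([SequenceRecord("s", "ANNT")])
        assert s.gc_fraction == 0.0 and s.n_fraction == 0.5

    def test_all_n_reports_missing_gc(self):
        s = am.composition([SequenceRecord("s", "NNNN")])
        assert s.gc_fraction is None

    def test_pooling_equals_concatenation(self):
        a = SequenceRecord("a", "ACGTNNGC")
        b = SequenceRecord("b", "GGGCCCAT")
        pooled = am.composition([a, b])
        merged = am.composition([SequenceRecord("m", a.residues + b.residues)])
        assert pooled.gc_fraction == merged.gc_fraction
        assert pooled.n_fraction == merged.n_fraction


def _marker(i, lg, cm, sid, bp):
    return MarkerRecord(f"m{i}", lg, cm, sid, bp)


class TestAnchoring:
    def test_scaffolds_ordered_by_mean_cm(self):
        records = [_rec(0, 1000), _rec(1, 1000)]
        markers = [
            _marker(0, "LG1", 10.0, "s0", 100),
            _marker(1, "LG1", 5.0, "s1", 100),
        ]
        pseudos, plan, _ = am.anchor_scaffolds(records, markers)
        order = [r.component_id for r in plan if r.kind == "W"]
        assert order == ["s1", "s0"]

    def test_anticorrelated_markers_give_minus_orientation(self):
        records = [_rec(0, 1000)]
        markers = [
            _marker(0, "LG1", 1.0, "s0", 900),
            _marker(1, "LG1", 2.0, "s0", 500),
            _marker(2, "LG1", 3.0, "s0", 100),
        ]
        _, plan, _ = am.anchor_scaffolds(records, markers)
        assert plan[0].orientation == "-"

    def test_marker_beyond_scaffold_is_an_error(self):
        with pytest.raises(Exception, match="beyond"):
            am.anchor_scaffolds(
                [_rec(0, 100)], [_marker(0, "LG1", 1.0, "s0", 200)]
            )

    def test_gap_convention_in_pseudomolecule(self):
        records = [_rec(0, 1000, "A"), _rec(1, 1000, "C")]
        markers = [
            _marker(0, "LG1", 1.0, "s0", 100),
            _marker(1, "LG1", 2.0, "s1", 100),
        ]
        pseudos, plan, _ = am.anchor_scaffolds(records, markers)
        (p,) = pseudos
        assert len(p) == 2100
        assert p.residues[1000:1100] == "N" * 100

    def test_truth_set_recovery_on_simulated_genome(self, multi_scaffold_sim):
        _, records, _, _, markers, truth = multi_scaffold_sim
        pseudos, plan, unanchored = am.anchor_scaffolds(records, markers)
        got = {}
        for row in plan:
            if row.kind == "W":
                got.setdefault(row.object_id, []).append(
                    (row.component_id, row.orientation)
                )
        for lg, order in truth.scaffold_order.items():
            assert got[f"pseudo_{lg}"] == order
        assert sorted(r.id for r in unanchored) == sorted(truth.unanchored)

    def test_anchoring_is_input_order_invariant(self, multi_scaffold_sim):
        _, records, _, _, markers, _ = multi_scaffold_sim
        p1, plan1, _ = am.anchor_scaffolds(records, markers)
        p2, plan2, _ = am.anchor_scaffolds(records[::-1], markers[::-1])
        assert [r.residues for r in p1] == [r.residues for r in p2]
        assert plan1 == plan2


class TestAnchoredFraction:
    def test_complement_property(self, multi_scaffold_sim):
        _, records, _, _, markers, _ = multi_scaffold_sim
        _, plan, unanchored = am.anchor_scaffolds(records, markers)
        total = sum(len(r) for r in records)
        frac = am.anchored_fraction(plan, total)
        assert frac == pytest.approx(
            1 - sum(len(r) for r in unanchored) / total
        )

    def test_everything_anchored_gives_exactly_one(self):
        records = [_rec(0, 500), _rec(1, 700)]
        markers = [
            _marker(0, "LG1", 1.0, "s0", 10),
            _marker(1, "LG1", 2.0, "s1", 10),
        ]
        _, plan, _ = am.anchor_scaffolds(records, markers)
        assert am.anchored_fraction(plan, 1200) == 1.0
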