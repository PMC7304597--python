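"""Protein alignment, stringency filters, tandem grouping and collapse."""

from __future__ import annotations

import numpy as np
import pytest

from fntdcscan.homology import (
    AlignmentError,
    SETTINGS,
    align_pair,
    collapse,
    passes_setting,
    read_hits,
    tandem_groups,
    window_hits,
    write_hits,
)
from fntdcscan.synthetic_data import hamming_identity, mutate_protein, random_protein

from conftest import make_gene

RNG = np.random.default_rng(1234)


class TestAlignPair:
    def test_identical_sequences(self):
        seq = random_protein(300, RNG)
        hit = align_pair(seq, seq, "a", "b")
        assert hit.identity_pct == 100.0
        assert hit.align_len == 300
        assert hit.ratio_q == hit.ratio_s == 1.0
        assert (hit.q_start, hit.q_end) == (1, 300)

    def test_self_alignment_matches_identical_pair(self):
        seq = random_protein(200, RNG)
        hit_self = align_pair(seq, seq)
        hit_copy = align_pair(seq, str(seq))
        assert hit_self.identity_pct == hit_copy.identity_pct == 100.0
        assert hit_self.score == hit_copy.score

    def test_identity_matches_column_count_oracle(self):
        """120 substitutions in the interior of a 300-aa sequence: the
        aligner's identity must equal the direct column count over the
        known mutation mask (conserved termini keep the local alignment
        full length, so the denominators agree)."""
        rng = np.random.default_rng(5)
        a = random_protein(300, rng)
        b = list(a)
        positions = rng.choice(np.arange(10, 290), size=120, replace=False)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for i in positions:
            b[i] = rng.choice(aas[aas != b[i]])
        b = "".join(b)
        hit = align_pair(a, b)
        oracle = 100.0 * sum(x == y for x, y in zip(a, b)) / 300
        assert hit.align_len == 300
        assert hit.identity_pct == pytest.approx(oracle, abs=1e-9)

    def test_symmetry_of_identity_and_lengths(self):
        a = random_protein(250, RNG)
        b = mutate_protein(a, 0.8, RNG)
        fwd = align_pair(a, b)
        rev = align_pair(b, a)
        assert fwd.identity_pct == pytest.approx(rev.identity_pct)
        assert fwd.align_len == rev.align_len

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError, match="empty"):
            align_pair("", "MKT")

    def test_invalid_residues_rejected(self):
        with pytest.raises(AlignmentError):
            align_pair("MKT1", "MKT")

    def test_trailing_stop_tolerated(self):
        hit = align_pair("MKTAYIAKQRQISFVKSHFSRQL*", "MKTAYIAKQRQISFVKSHFSRQL")
        assert hit.identity_pct == 100.0

    @pytest.mark.parametrize("rate", [0.05, 0.1, 0.2])
    def test_measured_identity_tracks_mutation_rate(self, rate):
        """Per-site mutation at rate m leaves ~100*(1 - m*19/20)% identity
        (a redrawn residue never matches, alternatives exclude the
        original) within 3 points on 300-aa sequences."""
        rng = np.random.default_rng(int(rate * 1000))
        a = random_protein(300, rng)
        b = mutate_protein(a, 1.0 - rate, rng)
        hit = align_pair(a, b)
        assert hit.identity_pct == pytest.approx(100.0 * (1 - rate), abs=3.0)


class TestPassesSetting:
    def test_paper_thresholds(self):
        hit = _mk_hit(75.0, 0.95, 0.92)
        assert passes_setting(hit, SETTINGS["setting_1"])
        assert passes_setting(hit, SETTINGS["setting_2"])
        assert not passes_setting(hit, SETTINGS["setting_3"])
        assert not passes_setting(hit, SETTINGS["setting_4"])

    def test_perfect_hit_passes_all(self):
        hit = _mk_hit(100.0, 1.0, 1.0)
        assert all(passes_setting(hit, s) for s in SETTINGS.values())

    def test_low_coverage_fails_strict_presets(self):
        hit = _mk_hit(95.0, 0.5, 1.0)
        assert passes_setting(hit, SETTINGS["setting_1"])
        for name in ("setting_2", "setting_3", "setting_4"):
            assert not passes_setting(hit, SETTINGS[name])

    def test_stricter_pass_implies_looser_pass(self):
        rng = np.random.default_rng(9)
        order = ["setting_4", "setting_3", "setting_2", "setting_1"]
        for _ in range(200):
            hit = _mk_hit(rng.uniform(0, 100), rng.uniform(0.05, 1.0),
                          rng.uniform(0.05, 1.0))
            results = [passes_setting(hit, SETTINGS[n]) for n in order]
            # once a stricter preset passes, every looser one must
            for strict, loose in zip(results, results[1:]):
                assert not strict or loose


def _mk_hit(identity, rq, rs, query_id="a", subject_id="b"):
    from fntdcscan.homology import AlignmentHit

    q_len = 100
    return AlignmentHit(
        query_id=query_id, subject_id=subject_id, identity_pct=identity,
        align_len=int(round(rq * q_len)), align_len_nogap=int(round(rq * q_len)),
        mismatches=0, gap_openings=0, q_start=1, q_end=100, s_start=1,
        s_end=100, q_len=q_len, s_len=int(round(rq * q_len / rs)),
        score=100.0, bit_score=40.0, evalue=1e-10,
    )


class TestTandemGroups:
    def _genes(self, n):
        seqs = [random_protein(200, RNG) for _ in range(n)]
        return [
            make_gene(f"g{i}", start=1 + 10_000 * i, protein=seqs[i])
            for i in range(n)
        ]

    def test_single_linkage_transitive_closure(self):
        genes = self._genes(3)
        # (g0,g1) and (g1,g2) pass; (g0,g2) absent -> one group of three
        hits = [_mk_hit(95.0, 1.0, 1.0, a, b)
                for a, b in [("g0", "g1"), ("g1", "g2")]]
        groups = tandem_groups(genes, hits, SETTINGS["setting_2"])
        assert len(groups) == 1
        assert groups[0].members == {"g0", "g1", "g2"}

    def test_no_passing_pairs_yields_no_groups(self):
        genes = self._genes(3)
        hits = [_mk_hit(30.0, 1.0, 1.0, "g0", "g1")]
        assert tandem_groups(genes, hits, SETTINGS["setting_2"]) == []

    def test_representative_is_first_by_coordinate(self):
        genes = self._genes(3)
        hits = [_mk_hit(99.0, 1.0, 1.0, a, b)
                for a, b in [("g0", "g1"), ("g0", "g2"), ("g1", "g2")]]
        groups = tandem_groups(genes, hits, SETTINGS["setting_2"])
        assert groups[0].representative == "g0"


class TestCollapse:
    def test_counts(self):
        genes = [make_gene(f"g{i}", start=1 + 10_000 * i) for i in range(8)]
        hits = [_mk_hit(99.0, 1.0, 1.0, a, b)
                for a, b in [("g2", "g3"), ("g3", "g4")]]
        groups = tandem_groups(genes, hits, SETTINGS["setting_2"])
        retained, removed = collapse(genes, groups)
        assert len(retained) == 6
        assert removed == ["g3", "g4"]

    def test_no_groups_is_identity(self):
        genes = [make_gene(f"g{i}", start=1 + 10_000 * i) for i in range(4)]
        retained, removed = collapse(genes, [])
        assert retained == genes
        assert removed == []

    def test_idempotent(self):
        genes = [make_gene(f"g{i}", start=1 + 10_000 * i) for i in range(5)]
        hits = [_mk_hit(99.0, 1.0, 1.0, "g1", "g2")]
        groups = tandem_groups(genes, hits, SETTINGS["setting_2"])
        once, removed_once = collapse(genes, groups)
        groups2 = tandem_groups(once, hits, SETTINGS["setting_2"])
        twice, removed_twice = collapse(once, groups2)
        assert twice == once
        assert removed_twice == []


class TestWindowHits:
    def test_tandem_pairs_found_and_random_pairs_mostly_silent(self):
        rng = np.random.default_rng(11)
        base = random_protein(300, rng)
        genes = [
            make_gene("t0", start=1, protein=base),
            make_gene("t1", start=10_001, protein=mutate_protein(base, 0.95, rng)),
            make_gene("r0", start=20_001, protein=random_protein(300, rng)),
            make_gene("r1", start=30_001, protein=random_protein(300, rng)),
        ]
        hits = window_hits(genes)
        pairs = {(h.query_id, h.subject_id) for h in hits}
        assert ("t0", "t1") in pairs
        t_hit = next(h for h in hits if (h.query_id, h.subject_id) == ("t0", "t1"))
        assert t_hit.identity_pct > 90.0
        assert t_hit.evalue <= 10.0

    def test_removed_count_non_increasing_with_looser_stringency(self):
        rng = np.random.default_rng(21)
        base = random_protein(250, rng)
        genes = [
            make_gene(f"g{i}", start=1 + 10_000 * i,
                      protein=mutate_protein(base, ident, rng))
            for i, ident in enumerate([1.0, 0.97, 0.85, 0.6, 0.45])
        ]
        hits = window_hits(genes)
        removed_counts = []
        for name in ("setting_1", "setting_2", "setting_3", "setting_4"):
            groups = tandem_groups(genes, hits, SETTINGS[name])
            _, removed = collapse(genes, groups)
            removed_counts.append(len(removed))
        assert removed_counts == sorted(removed_counts, reverse=True)

    def test_genes_without_protein_never_grouped(self):
        genes = [
            make_gene("g0", start=1, protein=None),
            make_gene("g1", start=10_001, protein=None),
        ]
        assert window_hits(genes) == []


class TestHitIO:
    def test_tsv_round_trip_preserves_filter_fields(self, tmp_path):
        rng = np.random.default_rng(31)
        a = random_protein(220, rng)
        hit = align_pair(a, mutate_protein(a, 0.9, rng), "qq", "ss")
        path = tmp_path / "hits.tsv"
        write_hits([hit], path)
        (back,) = read_hits(path)
        assert back.query_id == "qq" and back.subject_id == "ss"
        assert back.identity_pct == pytest.approx(hit.identity_pct, abs=0.01)
        assert back.align_len == hit.align_len
        assert back.q_len == hit.q_len
        assert back.align_len_nogap == hit.align_len_nogap
        for setting in SETTINGS.values():
            assert passes_setting(back, setting) == passes_setting(hit, setting)


class TestMutationIdentityLaw:
    def test_identity_near_theory_across_seeds(self):
        """Aligner-measured identity of pairs mutated at rate m stays
        within 3 points of 100*(1-m) for at least 95% of seeds."""
        m = 0.10
        ok = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            a = random_protein(300, rng)
            b = mutate_protein(a, 1.0 - m, rng)
            hit = align_pair(a, b)
            ok += abs(hit.identity_pct - 100.0 * (1 - m)) <= 3.0
        assert ok >= 38
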