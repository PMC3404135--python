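import math

import numpy as np
import pytest

import qmotif as qm
from qmotif.errors import ParameterError
from qmotif.tfbs import (
    estimate_background,
    phase1_select,
    phase2_sites,
    uniform_background,
    write_candidates_tsv,
    write_sites_tsv,
)

UNIFORM = uniform_background(qm.DNA)


class TestExpectedMatchCount:
    def test_d_equals_l_counts_all_windows(self):
        assert qm.expected_match_count("ACG", 10, UNIFORM, 3) == pytest.approx(8.0)

    def test_single_position(self):
        assert qm.expected_match_count("A", 1, UNIFORM, 0) == pytest.approx(0.25)

    def test_two_positions_one_mismatch(self):
        # exhaustive over all 16 windows: P(<=1 mismatch) = (1 + 2*3)/16
        assert qm.expected_match_count("AC", 2, UNIFORM, 1) == pytest.approx(7 / 16)

    def test_matches_exhaustive_enumeration(self, rng):
        import itertools

        for _ in range(5):
            l = int(rng.integers(1, 5))
            d = int(rng.integers(0, l + 1))
            motif = "".join(rng.choice(list("ACGT"), l))
            hits = sum(
                sum(a != b for a, b in zip(motif, w)) <= d
                for w in itertools.product("ACGT", repeat=l)
            )
            expected = hits / 4**l
            got = qm.expected_match_count(motif, l, UNIFORM, d)
            assert got == pytest.approx(expected)

    def test_biased_background(self):
        bg = np.array([0.7, 0.1, 0.1, 0.1])
        assert qm.expected_match_count("AA", 2, bg, 0) == pytest.approx(0.49)

    def test_monte_carlo_agreement(self, rng):
        # 100k random windows under the background, fixed seed, 3 SE band
        nsamp = 100_000
        for d in (0, 1, 2):
            motif = "".join(rng.choice(list("ACGT"), 6))
            samples = rng.integers(0, 4, size=(nsamp, 6))
            codes = qm.DNA.encode(motif)
            mism = (samples != codes).sum(axis=1)
            phat = float((mism <= d).mean())
            se = math.sqrt(max(phat * (1 - phat), 1e-12) / nsamp)
            p_exact = qm.expected_match_count(motif, 6, UNIFORM, d)
            assert abs(p_exact - phat) <= 3 * se + 1e-12

    def test_validation(self):
        with pytest.raises(ParameterError):
            qm.expected_match_count("ACG", 2, UNIFORM, 1)  # seq shorter than motif
        with pytest.raises(ParameterError):
            qm.expected_match_count("ACG", 5, np.array([0.5, 0.5, 0.5, 0.5]), 1)


class TestSequenceSpecificity:
    def test_single_sequence(self):
        seqs = qm.SequenceSet.from_strings(["ACGTACGT"])
        got = qm.sequence_specificity("ACG", seqs, 1, UNIFORM)
        assert got == pytest.approx(
            math.log(qm.expected_match_count("ACG", 8, UNIFORM, 1))
        )

    def test_d_equals_l_window_count(self):
        seqs = qm.SequenceSet.from_strings(["ACGTACGT", "TTTTTT"])
        got = qm.sequence_specificity("ACG", seqs, 3, UNIFORM)
        assert got == pytest.approx(math.log(6) + math.log(4))

    def test_additivity_for_identical_sequences(self):
        one = qm.SequenceSet.from_strings(["ACGTACGTAA"])
        two = qm.SequenceSet.from_strings(["ACGTACGTAA", "ACGTACGTAA"])
        s1 = qm.sequence_specificity("ACGT", one, 1, UNIFORM)
        s2 = qm.sequence_specificity("ACGT", two, 1, UNIFORM)
        assert s2 == pytest.approx(2 * s1)

    def test_default_background_estimated(self):
        seqs = qm.SequenceSet.from_strings(["AAAAAAAACG", "AAAAAAACGA"])
        bg = estimate_background(seqs)
        assert bg[0] > 0.5
        assert qm.sequence_specificity("ACG", seqs, 0) == pytest.approx(
            sum(
                math.log(qm.expected_match_count("ACG", 10, bg, 0))
                for _ in range(2)
            )
        )


class TestPhase1:
    def test_finds_planted_motif_in_grid(self):
        inst = qm.generate_planted_instance(n=8, m=60, l=8, d=1, q=8, seed=21)
        cands = phase1_select(
            inst.seqs, l_min=7, l_max=9, q=8, backend="qpms7",
            time_budget=120.0, log=lambda m: None,
        )
        assert any(
            c.motif == inst.motif or qm.hamming(c.motif, inst.motif) <= 1
            for c in cands
            if c.l == 8
        ) or any(c.motif in inst.motif for c in cands if c.l == 7)
        assert cands  # non-empty

    def test_stops_at_first_nonempty_d(self):
        # an exact common l-mer exists -> found at d=0, inner loop stops
        seqs = qm.SequenceSet.from_strings(
            ["AACGTACGGT", "CACGTACGTT", "TACGTACGCC"]
        )
        cands = phase1_select(
            seqs, l_min=7, l_max=7, q=3, backend="qpmsprune",
            time_budget=60.0, log=lambda m: None,
        )
        assert cands and all(c.d == 0 for c in cands)
        assert {c.motif for c in cands} == {"ACGTACG"}

    def test_zero_budget_clean_empty(self):
        seqs = qm.SequenceSet.from_strings(["ACGTACGT", "ACGTACGT"])
        cands = phase1_select(
            seqs, l_min=4, l_max=5, q=2, time_budget=0.0, log=lambda m: None
        )
        assert cands == []

    def test_budget_abort_moves_to_next_l(self):
        inst = qm.generate_planted_instance(n=6, m=50, l=6, d=0, q=6, seed=22)
        events = []
        cands = phase1_select(
            inst.seqs, l_min=5, l_max=6, q=6, backend="qpms7",
            time_budget=1e-9, log=events.append,
        )
        assert cands == []
        assert any("budget" in e for e in events)


class TestPhase2:
    def test_exact_plant_coordinates_at_d_site_zero(self):
        inst = qm.generate_planted_instance(n=8, m=80, l=10, d=0, q=8, seed=23)
        cand = qm.ScoredMotif(
            motif=inst.motif, l=10, d=0,
            score=qm.sequence_specificity(inst.motif, inst.seqs, 0),
        )
        sites = phase2_sites(inst.seqs, [cand], k_top=1, d_site=0)
        got = {(s.seq_id, s.offset) for s in sites}
        expected = {(f"seq{i + 1}", off) for i, off in inst.plant_coords}
        assert got == expected
        assert all(s.distance == 0 and s.window == inst.motif for s in sites)

    def test_k_top_larger_than_candidates(self, toy_seqs):
        cands = [qm.ScoredMotif("ACG", 3, 1, -1.0)]
        sites = phase2_sites(toy_seqs, cands, k_top=10)
        assert {s.seq_id for s in sites} == set(toy_seqs.ids)

    def test_d_site_defaults_to_candidate_d(self, toy_seqs):
        cands = [qm.ScoredMotif("ACG", 3, 1, -1.0)]
        with_d1 = phase2_sites(toy_seqs, cands)
        with_d0 = phase2_sites(toy_seqs, cands, d_site=0)
        keys = lambda sites: {(s.seq_id, s.offset) for s in sites}
        assert keys(with_d0) < keys(with_d1)
        assert max(s.distance for s in with_d1) == 1

    def test_deterministic_tie_break(self, toy_seqs):
        cands = [
            qm.ScoredMotif("CGT", 3, 0, 5.0),
            qm.ScoredMotif("ACG", 3, 0, 5.0),
        ]
        a = phase2_sites(toy_seqs, cands, k_top=1)
        b = phase2_sites(toy_seqs, cands, k_top=1)
        assert a == b
        assert all(s.motif == "ACG" for s in a)  # lexicographic tie-break

    def test_empty_candidates(self, toy_seqs):
        assert phase2_sites(toy_seqs, [], k_top=3) == []

    def test_site_invariant_distance_within_threshold(self, rng):
        inst = qm.generate_planted_instance(n=5, m=40, l=6, d=1, q=5, seed=24)
        cand = qm.ScoredMotif(inst.motif, 6, 1, 0.0)
        for site in phase2_sites(inst.seqs, [cand]):
            assert site.distance <= 1
            assert qm.hamming(site.window, inst.motif) == site.distance


class TestRankingProperty:
    def test_planted_motif_ranks_first_in_most_replicates(self):
        # uniform background; candidates at the planted (l, d); the plant
        # should top the specificity ranking in >= 90% of seeded replicates
        wins = 0
        total = 50
        for seed in range(total):
            inst = qm.generate_planted_instance(
                n=8, m=60, l=7, d=1, q=8, seed=1000 + seed
            )
            res = qm.qpms7_search(inst.seqs, qm.SearchParams(7, 1, 8))
            cands = [
                qm.ScoredMotif(
                    m, 7, 1,
                    qm.sequence_specificity(m, inst.seqs, 1, UNIFORM),
                )
                for m in res.motifs
            ]
            ranked = sorted(cands, key=lambda c: (c.score, c.motif))
            if ranked and ranked[0].motif == inst.motif:
                wins += 1
        assert wins >= 0.9 * total


class TestTsvWriters:
    def test_sites_tsv_format(self, toy_seqs, tmp_path):
        cands = [qm.ScoredMotif("ACG", 3, 1, -1.0)]
        sites = phase2_sites(toy_seqs, cands, d_site=0)
        path = tmp_path / "sites.tsv"
        write_sites_tsv(sites, path, header_lines=["hello"])
        lines = path.read_text().splitlines()
        body = [ln.split("\t") for ln in lines if not ln.startswith("#")]
        assert body[0] == ["seq_id", "start", "end", "motif", "distance", "window"]
        assert ["seq1", "0", "3", "ACG", "0", "ACG"] in body

    def test_candidates_tsv_sorted_by_score(self, tmp_path):
        cands = [qm.ScoredMotif("TTT", 3, 1, 2.0), qm.ScoredMotif("AAA", 3, 1, 1.0)]
        path = tmp_path / "cands.tsv"
        write_candidates_tsv(cands, path)
        body = [
            ln.split("\t")
            for ln in path.read_text().splitlines()
            if not ln.startswith("#")
        ][1:]
        assert [r[0] for r in body] == ["AAA", "TTT"]
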