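import numpy as np
import pytest

import paraconv as pc
from paraconv.app import make_fixture


def zero_length_tree():
    return pc.parse_newick("((A:0,B:0)X:0,(C:0,D:0)Y:0)R;")


class TestSimulateRecord:
    def test_zero_branch_lengths_copy_root(self, jtt_q):
        rec = pc.simulate_record(zero_length_tree(), jtt_q, 1.0, 30, jtt_q.pi, seed=4)
        root_seq = rec.sequences["R"]
        assert all(s == root_seq for s in rec.sequences.values())

    def test_deterministic_per_seed(self, jtt_q):
        tree = pc.parse_newick("((A:0.2,B:0.1)X:0.1,C:0.3)R;")
        a = pc.simulate_record(tree, jtt_q, 1.0, 50, jtt_q.pi, seed=9)
        b = pc.simulate_record(tree, jtt_q, 1.0, 50, jtt_q.pi, seed=9)
        c = pc.simulate_record(tree, jtt_q, 1.0, 50, jtt_q.pi, seed=10)
        assert a.sequences == b.sequences
        assert a.sequences != c.sequences

    def test_long_branch_reaches_stationary_composition(self, jtt_q):
        # after distance 50 the child composition is multinomial around pi
        tree = pc.parse_newick("(A:50)R;")
        L = 20000
        rec = pc.simulate_record(tree, jtt_q, 1.0, L, jtt_q.pi, seed=2)
        counts = np.array([rec.sequences["A"].count(a) for a in pc.AMINO_ACIDS])
        se = np.sqrt(jtt_q.pi * (1 - jtt_q.pi) * L)
        assert np.all(np.abs(counts - L * jtt_q.pi) <= 3 * se + 1)

    def test_site_rate_scaling(self, jtt_q):
        # rate 0-free: tiny rates barely change sequences, big rates scramble
        tree = pc.parse_newick("(A:1)R;")
        quiet = pc.simulate_record(tree, jtt_q, 1e-6, 500, jtt_q.pi, seed=3)
        noisy = pc.simulate_record(tree, jtt_q, 20.0, 500, jtt_q.pi, seed=3)
        diff_quiet = sum(a != b for a, b in zip(quiet.sequences["R"], quiet.sequences["A"]))
        diff_noisy = sum(a != b for a, b in zip(noisy.sequences["R"], noisy.sequences["A"]))
        assert diff_quiet < 5 < diff_noisy

    def test_missing_length_rejected(self, jtt_q):
        tree = pc.parse_newick("((A:1,B),C)R;")
        with pytest.raises(ValueError, match="length"):
            pc.simulate_record(tree, jtt_q, 1.0, 10, jtt_q.pi, seed=0)

    def test_rate_count_mismatch_rejected(self, jtt_q):
        tree = pc.parse_newick("(A:1,B:1)R;")
        with pytest.raises(ValueError, match="rates"):
            pc.simulate_record(tree, jtt_q, [1.0, 1.0], 3, jtt_q.pi, seed=0)


class TestSimulationExpectation:
    def test_zero_lengths_zero_expectation(self, jtt_q):
        rec = pc.simulate_record(zero_length_tree(), jtt_q, 1.0, 20, jtt_q.pi, seed=1)
        exp = pc.expected_counts_simulation(rec, jtt_q, n_replicates=5, seed=1)
        assert all(v == 0 for v in exp.e_parallel.values())
        assert all(v == 0 for v in exp.e_convergent.values())

    def test_fixed_seed_reproducible(self, jtt_q, tmp_path):
        rp, _, _ = make_fixture(3, 5, 30, outdir=tmp_path)
        rec = pc.read_ancestral_record(rp)
        a = pc.expected_counts_simulation(rec, jtt_q, n_replicates=10, seed=7)
        b = pc.expected_counts_simulation(rec, jtt_q, n_replicates=10, seed=7)
        assert a.e_parallel == b.e_parallel and a.e_convergent == b.e_convergent

    def test_keys_match_identification(self, jtt_q, tmp_path):
        rp, _, _ = make_fixture(4, 6, 30, outdir=tmp_path)
        rec = pc.read_ancestral_record(rp)
        exp = pc.expected_counts_simulation(rec, jtt_q, n_replicates=3, seed=1)
        counts, _ = pc.identify_events(rec)
        assert exp.pairs == {c.pair for c in counts}


class TestAnalyticExpectation:
    def test_zero_lengths_zero_expectation(self, jtt_q):
        rec = pc.simulate_record(zero_length_tree(), jtt_q, 1.0, 20, jtt_q.pi, seed=1)
        exp = pc.expected_counts_analytic(rec, jtt_q)
        assert all(v == 0 for v in exp.e_parallel.values())
        assert all(v == 0 for v in exp.e_convergent.values())

    def test_two_letter_closed_form(self, two_state_q):
        # one site, both ancestors 'A', t1 = t2 = 0.5, r = 1:
        # lambda_P = (P_AB(0.5))^2 with P_AB(d) = (1 - e^{-2d})/2; no third
        # state exists, so lambda_C = 0 everywhere
        tree = pc.parse_newick("((A:0.5,B:0.5)X:0.5,C:0.5)R;")
        rec = pc.AncestralRecord(
            tree=tree,
            site_rates=(1.0,),
            sequences={"R": "A", "X": "A", "A": "A", "B": "A", "C": "A"},
        )
        exp = pc.expected_counts_analytic(rec, two_state_q)
        lam = ((1 - np.exp(-1)) / 2) ** 2
        pair_ac = pc.BranchPair.of("A", "C")
        assert exp.e_parallel[pair_ac] == pytest.approx(lam, abs=1e-9)
        assert exp.e_parallel[pair_ac] == pytest.approx(0.0998941, abs=1e-6)
        assert all(v == 0 for v in exp.e_convergent.values())

    def test_monotone_in_branch_length_two_letter(self, two_state_q):
        # lambda_P grows with either branch length on [0, 1] for the
        # symmetric 2-letter chain
        pair = pc.BranchPair.of("A", "C")
        last = -1.0
        for t in np.linspace(0.0, 1.0, 11):
            tree = pc.parse_newick(f"((A:{t},B:0.5)X:0.5,C:0.5)R;")
            rec = pc.AncestralRecord(
                tree=tree,
                site_rates=(1.0,),
                sequences={"R": "A", "X": "A", "A": "A", "B": "A", "C": "A"},
            )
            lam = pc.expected_counts_analytic(rec, two_state_q).e_parallel[pair]
            assert lam >= last - 1e-12
            last = lam

    def test_conditional_mc_oracle_small(self, jtt_q, tmp_path):
        # resample only the two descendant states from their ancestors
        rp, _, _ = make_fixture(11, 5, 20, outdir=tmp_path)
        rec = pc.read_ancestral_record(rp)
        exp = pc.expected_counts_analytic(rec, jtt_q)
        rng = np.random.default_rng(0)
        n = 20000
        index = {a: i for i, a in enumerate(pc.AMINO_ACIDS)}
        for pair in sorted(exp.pairs)[:3]:
            t1 = rec.tree.nodes[pair.first].length
            t2 = rec.tree.nodes[pair.second].length
            p1 = rec.tree.nodes[pair.first].parent
            p2 = rec.tree.nodes[pair.second].parent
            tot_p = np.zeros(n)
            tot_c = np.zeros(n)
            for i, r in enumerate(rec.site_rates):
                a1 = index[rec.sequences[p1][i]]
                a2 = index[rec.sequences[p2][i]]
                P1 = pc.transition_matrix(jtt_q, r * t1)
                P2 = pc.transition_matrix(jtt_q, r * t2)
                d1 = rng.choice(20, size=n, p=P1[a1])
                d2 = rng.choice(20, size=n, p=P2[a2])
                hit = (d1 != a1) & (d2 != a2) & (d1 == d2)
                if a1 == a2:
                    tot_p += hit
                else:
                    tot_c += hit
            for total, expect_lam in ((tot_p, exp.e_parallel[pair]), (tot_c, exp.e_convergent[pair])):
                se = total.std(ddof=1) / np.sqrt(n)
                assert abs(total.mean() - expect_lam) <= 3 * se + 1e-9

    def test_missing_length_rejected(self, jtt_q):
        tree = pc.parse_newick("((A:1,B)X:1,C:1)R;")
        rec = pc.AncestralRecord(
            tree=tree,
            site_rates=(1.0,),
            sequences={n: "A" for n in tree.nodes},
        )
        with pytest.raises(ValueError, match="length"):
            pc.expected_counts_analytic(rec, jtt_q)
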