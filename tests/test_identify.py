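import numpy as np
import pytest

import paraconv as pc
from paraconv.app import make_fixture

from conftest import brute_force_events


class TestBranchReplacements:
    def test_single_difference(self, worked_record):
        # X = KKT, A = RRT: replacements at sites 1 and 2
        repl = pc.branch_replacements(worked_record, worked_record.tree.branch("A"))
        assert repl == [(1, "K", "R"), (2, "K", "R")]

    def test_identical_sequences_empty(self, worked_record):
        assert pc.branch_replacements(worked_record, worked_record.tree.branch("B")) == []

    def test_count_equals_hamming_distance(self, tmp_path):
        rp, _, _ = make_fixture(5, 7, 60, outdir=tmp_path)
        rec = pc.read_ancestral_record(rp)
        for br in rec.tree.branches():
            ham = sum(
                a != b for a, b in zip(rec.sequences[br.parent], rec.sequences[br.child])
            )
            assert len(pc.branch_replacements(rec, br)) == ham


class TestIdentifyEvents:
    def test_worked_example(self, worked_record):
        counts, events = pc.identify_events(worked_record)
        by_pair = {str(c.pair): (c.n_parallel, c.n_convergent) for c in counts}
        assert len(by_pair) == 8  # all comparable pairs present, zeros included
        assert by_pair["A-C"] == (1, 1)
        assert all(v == (0, 0) for k, v in by_pair.items() if k != "A-C")
        assert [(e.category, e.site) for e in events] == [("P", 1), ("C", 2)]
        assert events[0].r1 == ("K", "R") and events[0].r2 == ("K", "R")
        assert events[1].r1 == ("K", "R") and events[1].r2 == ("T", "R")

    def test_identical_sequences_no_events(self, worked_record):
        rec = pc.AncestralRecord(
            tree=worked_record.tree,
            site_rates=worked_record.site_rates,
            sequences={k: "KKT" for k in worked_record.sequences},
        )
        counts, events = pc.identify_events(rec)
        assert events == []
        assert all(c.n_parallel == 0 and c.n_convergent == 0 for c in counts)

    def test_matches_brute_force_on_fixture_records(self, tmp_path):
        for seed in range(10):
            rp, _, _ = make_fixture(seed, 8, 60, outdir=tmp_path / str(seed))
            rec = pc.read_ancestral_record(rp)
            counts, events = pc.identify_events(rec)
            oracle_counts, oracle_events = brute_force_events(rec)
            assert {c.pair: (c.n_parallel, c.n_convergent) for c in counts} == oracle_counts
            assert [
                (e.category, e.site, e.pair, e.r1, e.r2) for e in events
            ] == oracle_events

    def test_count_conservation(self, tmp_path):
        rp, _, _ = make_fixture(17, 9, 80, outdir=tmp_path)
        rec = pc.read_ancestral_record(rp)
        counts, events = pc.identify_events(rec)
        assert sum(c.n_parallel for c in counts) == sum(1 for e in events if e.category == "P")
        assert sum(c.n_convergent for c in counts) == sum(1 for e in events if e.category == "C")
        pair_set = pc.comparable_pairs(rec.tree)
        assert {c.pair for c in counts} == pair_set
        assert all(e.pair in pair_set for e in events)
        assert len({(e.pair, e.site) for e in events}) == len(events)

    def test_relabeling_invariance(self, tmp_path):
        rp, _, _ = make_fixture(23, 7, 50, outdir=tmp_path)
        rec = pc.read_ancestral_record(rp)
        mapping = {name: f"z_{name}" for name in rec.tree.nodes}
        nodes = {
            mapping[n.name]: pc.phylo.TreeNode(
                mapping[n.name],
                None if n.parent is None else mapping[n.parent],
                tuple(mapping[c] for c in n.children),
                n.length,
            )
            for n in rec.tree.nodes.values()
        }
        relabeled = pc.AncestralRecord(
            tree=pc.Tree(root=mapping[rec.tree.root], nodes=nodes),
            site_rates=rec.site_rates,
            sequences={mapping[k]: v for k, v in rec.sequences.items()},
        )
        orig = {
            (c.pair.first, c.pair.second): (c.n_parallel, c.n_convergent)
            for c in pc.identify_events(rec)[0]
        }
        new = {
            (c.pair.first.removeprefix("z_"), c.pair.second.removeprefix("z_")): (
                c.n_parallel,
                c.n_convergent,
            )
            for c in pc.identify_events(relabeled)[0]
        }
        assert orig == new


class TestTsvOutput:
    def test_details_rows(self, worked_record, tmp_path):
        _, events = pc.identify_events(worked_record)
        path = tmp_path / "details.tsv"
        pc.write_details_tsv(events, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "category\tposition\tpair\tr1\tr2"
        assert lines[1] == "P\t1\tA-C\tK->R\tK->R"
        assert lines[2] == "C\t2\tA-C\tK->R\tT->R"

    def test_empty_events_header_only(self, tmp_path):
        path = tmp_path / "details.tsv"
        pc.write_details_tsv([], path)
        assert path.read_text() == "category\tposition\tpair\tr1\tr2\n"

    def test_counts_file_totals(self, worked_record, tmp_path):
        counts, events = pc.identify_events(worked_record)
        path = tmp_path / "counts.tsv"
        pc.write_counts_tsv(counts, path)
        rows = [l.split("\t") for l in path.read_text().splitlines()[1:]]
        assert sum(int(r[1]) for r in rows) == sum(1 for e in events if e.category == "P")
        assert sum(int(r[2]) for r in rows) == sum(1 for e in events if e.category == "C")
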