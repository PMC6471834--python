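import itertools

import numpy as np
import pytest

import paraconv as pc


@pytest.fixture(scope="session")
def jtt_model():
    return pc.load_jtt()


@pytest.fixture(scope="session")
def jtt_q(jtt_model):
    return pc.build_rate_matrix(jtt_model)


@pytest.fixture(scope="session")
def two_state_q():
    """Symmetric 2-letter model: Q = [[-1, 1], [1, -1]], pi uniform."""
    model = pc.EmpiricalModel("toy2", np.array([[0.0, 1.0], [1.0, 0.0]]), np.array([0.5, 0.5]))
    return pc.build_rate_matrix(model)


@pytest.fixture()
def worked_record():
    """4-leaf record with one parallel and one convergent event on pair A-C."""
    tree = pc.parse_newick("((A:1,B:1)X:1,(C:1,D:1)Y:1)R;")
    seqs = {"R": "KKT", "X": "KKT", "Y": "KTT", "A": "RRT", "B": "KKT", "C": "RRT", "D": "KTT"}
    return pc.AncestralRecord(tree=tree, site_rates=(1.0, 1.0, 1.0), sequences=seqs)


# --- independent oracles shared between unit and acceptance tests -----------


def root_path(tree: pc.Tree, name: str) -> list[str]:
    """Node names from the root down to (and including) ``name``."""
    path = [name]
    while tree.nodes[path[-1]].parent is not None:
        path.append(tree.nodes[path[-1]].parent)
    return path[::-1]


def brute_force_pairs(tree: pc.Tree) -> set[pc.BranchPair]:
    """Literal double loop applying the sibling and shared-path exclusions."""
    names = [n for n in tree.nodes if tree.nodes[n].parent is not None]
    out = set()
    for a, b in itertools.combinations(sorted(names), 2):
        if tree.nodes[a].parent == tree.nodes[b].parent:
            continue
        if a in root_path(tree, b) or b in root_path(tree, a):
            continue
        out.add(pc.BranchPair.of(a, b))
    return out


def brute_force_events(record: pc.AncestralRecord):
    """Rescan of every comparable pair x site with the literal definition."""
    counts = {}
    events = []
    for pair in brute_force_pairs(record.tree):
        n_p = n_c = 0
        p1 = record.tree.nodes[pair.first].parent
        p2 = record.tree.nodes[pair.second].parent
        for i in range(record.length):
            a1, d1 = record.sequences[p1][i], record.sequences[pair.first][i]
            a2, d2 = record.sequences[p2][i], record.sequences[pair.second][i]
            if a1 != d1 and a2 != d2 and d1 == d2:
                if a1 == a2:
                    n_p += 1
                    events.append(("P", i + 1, pair, (a1, d1), (a2, d2)))
                else:
                    n_c += 1
                    events.append(("C", i + 1, pair, (a1, d1), (a2, d2)))
        counts[pair] = (n_p, n_c)
    return counts, sorted(events, key=lambda e: (e[2], e[1]))
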