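"""Expected parallel/convergent counts under a null substitution model.

Two routes to the per-pair expectations lambda_P and lambda_C:

* **simulation** — evolve replicate alignments along the record's tree
  (root drawn from alignment frequencies, each branch a continuous-time
  Markov step with per-site distance ``d = r_i * t``), keep the true
  simulated ancestral states, rescan each replicate for events, and
  average the counts;

* **analytic** — condition on the record's inferred ancestral states: for
  each pair {b1, b2} with states a1, a2 above the two branches at site i,

      lambda_P = sum_i [a1 == a2] sum_{c != a1}        P_{a1,c}(r_i t1) P_{a2,c}(r_i t2)
      lambda_C = sum_i [a1 != a2] sum_{c not in {a1,a2}} P_{a1,c}(r_i t1) P_{a2,c}(r_i t2)

  i.e. the probability, independently per branch given its ancestor, that
  both branches replace their state and land on the same residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .identify import identify_events
from .models import RateMatrix, estimate_frequencies, transition_matrix
from .phylo import BranchPair, Tree, comparable_pairs
from .seqio import AMINO_ACIDS, AncestralRecord, trim_alignment

__all__ = [
    "Expectation",
    "simulate_record",
    "expected_counts_simulation",
    "expected_counts_analytic",
    "write_expectation_tsv",
]


@dataclass(frozen=True)
class Expectation:
    """Per-pair expected parallel/convergent counts under the null model."""

    e_parallel: dict[BranchPair, float]
    e_convergent: dict[BranchPair, float]
    method: str  # "simulation" or "analytic"
    n_replicates: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        assert set(self.e_parallel) == set(self.e_convergent)
        assert all(v >= 0 and np.isfinite(v) for v in self.e_parallel.values())
        assert all(v >= 0 and np.isfinite(v) for v in self.e_convergent.values())

    @property
    def pairs(self) -> set[BranchPair]:
        return set(self.e_parallel)


def _require_lengths(tree: Tree) -> None:
    for name, node in tree.nodes.items():
        if node.parent is not None and node.length is None:
            raise ValueError(f"branch above {name!r} has no length; expectations need lengths")


def _alphabet_for(q: RateMatrix) -> tuple[str, ...]:
    if q.n == len(AMINO_ACIDS):
        return AMINO_ACIDS
    return tuple(AMINO_ACIDS[: q.n])  # small test alphabets use a prefix


def simulate_record(
    tree: Tree,
    q: RateMatrix,
    site_rates: float | list[float] | tuple[float, ...],
    length: int,
    root_freqs: np.ndarray,
    seed: int,
) -> AncestralRecord:
    """Evolve one alignment along ``tree``, retaining all ancestral states.

    The root sequence is i.i.d. from ``root_freqs``; each child sequence is
    sampled site-by-site from row ``parent_state`` of ``P(r_i * t)``.
    Bit-reproducible for a fixed seed.
    """
    _require_lengths(tree)
    if np.isscalar(site_rates):
        rates = np.full(length, float(site_rates))
    else:
        rates = np.asarray(site_rates, float)
        if len(rates) != length:
            raise ValueError(f"{len(rates)} site rates for length {length}")
    if np.any(rates <= 0):
        raise ValueError("site rates must be positive")
    root_freqs = np.asarray(root_freqs, float)
    if len(root_freqs) != q.n:
        raise ValueError("root frequency vector does not match alphabet size")

    rng = np.random.default_rng(seed)
    alphabet = _alphabet_for(q)
    # group sites sharing a rate: one transition matrix per (rate, branch length)
    uniq_rates, rate_idx = np.unique(rates, return_inverse=True)

    states: dict[str, np.ndarray] = {}
    states[tree.root] = rng.choice(q.n, size=length, p=root_freqs / root_freqs.sum())
    for name in tree.preorder():
        node = tree.nodes[name]
        if node.parent is None:
            continue
        parent_states = states[node.parent]
        t = node.length
        child = np.empty(length, dtype=np.int64)
        u = rng.random(length)
        for k, r in enumerate(uniq_rates):
            mask = rate_idx == k
            cum = np.cumsum(transition_matrix(q, r * t), axis=1)
            rows = cum[parent_states[mask]]
            child[mask] = np.minimum(
                (rows < u[mask, None]).sum(axis=1), q.n - 1
            )
        states[name] = child

    sequences = {
        name: "".join(alphabet[s] for s in arr) for name, arr in states.items()
    }
    return AncestralRecord(tree=tree, site_rates=tuple(rates), sequences=sequences)


def expected_counts_simulation(
    record: AncestralRecord,
    q: RateMatrix,
    n_replicates: int = 100,
    seed: int = 0,
    root_freqs: np.ndarray | None = None,
) -> Expectation:
    """Mean per-pair event counts over simulated replicates of the record.

    Tree, branch lengths, site rates and sequence length come from the
    record; root frequencies default to those of the record's (trimmed) tip
    alignment, falling back to the model's stationary frequencies when the
    tips carry no usable data.  Each replicate is scanned with the true
    simulated ancestors.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    _require_lengths(record.tree)
    if root_freqs is None:
        trimmed, _ = trim_alignment(record.tip_alignment())
        if trimmed.width > 0 and q.n == len(AMINO_ACIDS):
            root_freqs = estimate_frequencies(trimmed)
        else:
            root_freqs = q.pi

    pairs = sorted(comparable_pairs(record.tree))
    tot_p = {p: 0.0 for p in pairs}
    tot_c = {p: 0.0 for p in pairs}
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_replicates)
    for rep_seed in seeds:
        rep = simulate_record(
            record.tree, q, record.site_rates, record.length, root_freqs, int(rep_seed)
        )
        counts, _ = identify_events(rep)
        for row in counts:
            tot_p[row.pair] += row.n_parallel
            tot_c[row.pair] += row.n_convergent
    return Expectation(
        e_parallel={p: tot_p[p] / n_replicates for p in pairs},
        e_convergent={p: tot_c[p] / n_replicates for p in pairs},
        method="simulation",
        n_replicates=n_replicates,
        seed=seed,
    )


def expected_counts_analytic(record: AncestralRecord, q: RateMatrix) -> Expectation:
    """Closed-form expectations conditioning on the record's ancestral states."""
    _require_lengths(record.tree)
    alphabet = _alphabet_for(q)
    index = {a: i for i, a in enumerate(alphabet)}
    rates = np.asarray(record.site_rates)
    uniq_rates, rate_idx = np.unique(rates, return_inverse=True)

    # cache transition matrices per (branch, unique rate)
    P_cache: dict[tuple[str, int], np.ndarray] = {}

    def P_for(branch_child: str, k: int) -> np.ndarray:
        key = (branch_child, k)
        if key not in P_cache:
            t = record.tree.nodes[branch_child].length
            P_cache[key] = transition_matrix(q, uniq_rates[k] * t)
        return P_cache[key]

    pairs = sorted(comparable_pairs(record.tree))
    e_p: dict[BranchPair, float] = {}
    e_c: dict[BranchPair, float] = {}
    for pair in pairs:
        p1 = record.tree.nodes[pair.first].parent
        p2 = record.tree.nodes[pair.second].parent
        seq1 = record.sequences[p1]
        seq2 = record.sequences[p2]
        lam_p = lam_c = 0.0
        for i in range(record.length):
            a1 = index[seq1[i]]
            a2 = index[seq2[i]]
            k = rate_idx[i]
            P1 = P_for(pair.first, k)
            P2 = P_for(pair.second, k)
            # sum over shared descendants c excluding both ancestral states
            dot = float(P1[a1] @ P2[a2])
            if a1 == a2:
                lam_p += dot - P1[a1, a1] * P2[a2, a1]
            else:
                lam_c += dot - P1[a1, a1] * P2[a2, a1] - P1[a1, a2] * P2[a2, a2]
        e_p[pair] = max(lam_p, 0.0)
        e_c[pair] = max(lam_c, 0.0)
    return Expectation(e_parallel=e_p, e_convergent=e_c, method="analytic")


def write_expectation_tsv(exp: Expectation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair\te_parallel\te_convergent\tmethod\tn_replicates\tseed\n")
        for pair in sorted(exp.pairs):
            nr = "" if exp.n_replicates is None else exp.n_replicates
            sd = "" if exp.seed is None else exp.seed
            fh.write(
                f"{pair}\t{exp.e_parallel[pair]:.6f}\t{exp.e_convergent[pair]:.6f}"
                f"\t{exp.method}\t{nr}\t{sd}\n"
            )
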