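"""Poisson tail test of observed vs expected replacement counts.

The observed number of parallel (or convergent) replacements for a branch
pair is modeled as Poisson with mean equal to its expectation lambda.  The
reported tail is chosen by the side of the discrepancy: the lower tail
P(X <= k) when the observed count k falls below lambda, otherwise the
upper tail P(X >= k + 1) (strictly greater; equality of k and lambda uses
the upper tail).  When both k and lambda are zero no test is defined and
the p-value is reported as N/A; lambda == 0 with k > 0 yields p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .expect import Expectation
from .identify import PairCounts
from .phylo import BranchPair

__all__ = ["TestResult", "poisson_tail_p", "detect", "write_tests_tsv"]


@dataclass(frozen=True)
class TestResult:
    pair: BranchPair
    category: str  # 'P' or 'C'
    observed: int
    expected: float
    p: float | None  # None encodes N/A
    significance: str  # '', '*' (p <= 0.05) or '**' (p <= 0.01)


def poisson_tail_p(observed: int, expected: float) -> float | None:
    """Tail probability of ``observed`` under Poisson(``expected``).

    Returns ``None`` (N/A) when both arguments are zero.  Lower tail
    P(X <= k) when k < lambda, else upper tail P(X >= k + 1); values
    clipped to [0, 1].
    """
    if observed < 0 or expected < 0:
        raise ValueError("observed and expected must be non-negative")
    if expected == 0:
        return None if observed == 0 else 0.0
    if observed < expected:
        p = sstats.poisson.cdf(observed, expected)
    else:
        p = sstats.poisson.sf(observed, expected)  # P(X > k) = P(X >= k+1)
    return float(min(max(p, 0.0), 1.0))


def _stars(p: float | None) -> str:
    if p is None:
        return ""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def detect(
    observed: list[PairCounts],
    expected: Expectation,
    correction: str = "none",
) -> list[TestResult]:
    """Test every branch pair in both categories against its expectation.

    ``correction`` is "none" (the default, matching the convention of
    reporting uncorrected p-values), "bonferroni" or "bh"
    (Benjamini-Hochberg); a correction is applied jointly across all
    non-N/A p-values of both categories, and the significance flags then
    refer to the corrected values.
    """
    if correction not in ("none", "bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    obs_map = {row.pair: row for row in observed}
    if set(obs_map) != expected.pairs:
        raise ValueError("observed and expected tables cover different branch pairs")

    results: list[TestResult] = []
    for pair in sorted(expected.pairs):
        row = obs_map[pair]
        for category, k, lam in (
            ("P", row.n_parallel, expected.e_parallel[pair]),
            ("C", row.n_convergent, expected.e_convergent[pair]),
        ):
            p = poisson_tail_p(k, lam)
            results.append(TestResult(pair, category, k, lam, p, _stars(p)))

    if correction != "none":
        idx = [i for i, r in enumerate(results) if r.p is not None]
        if idx:
            method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[correction]
            _, adj, _, _ = multipletests([results[i].p for i in idx], method=method)
            for i, p_adj in zip(idx, adj):
                r = results[i]
                results[i] = TestResult(
                    r.pair, r.category, r.observed, r.expected, float(p_adj), _stars(float(p_adj))
                )
    return results


def write_tests_tsv(results: list[TestResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair\tcategory\tobserved\texpected\tp\tsignificance\n")
        for r in sorted(results, key=lambda x: (x.pair, x.category)):
            p_str = "N/A" if r.p is None else f"{r.p:.4f}"
            fh.write(
                f"{r.pair}\t{r.category}\t{r.observed}\t{r.expected:.6f}\t{p_str}\t{r.significance}\n"
            )
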