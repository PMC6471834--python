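"""Pipeline orchestration and synthetic fixture generation.

``run_pipeline`` chains the whole method on a ready ancestral record:
identification of observed events, expectation under a null model
(simulation or analytic), and the Poisson tail test, writing the four
result TSVs plus a manifest.  External alignment/reconstruction programs
are not wrapped: the record file is the contract.  Users who run their own
reconstruction (e.g. CODEML or RAxML) convert its output into the record
layout documented in :mod:`paraconv.seqio` — a guide-tree line, a rate
line, and one name/sequence line per node — and feed that file in.

``make_fixture`` builds fully synthetic inputs (Yule tree, simulated
sequences with true ancestors) so every stage can be exercised offline.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .expect import (
    expected_counts_analytic,
    expected_counts_simulation,
    simulate_record,
    write_expectation_tsv,
)
from .identify import identify_events, write_counts_tsv, write_details_tsv
from .models import build_rate_matrix, load_jtt, read_paml_dat
from .phylo import Tree, TreeNode, label_unnamed_internals, write_newick
from .seqio import read_ancestral_record, write_ancestral_record, write_fasta
from .stats import detect, write_tests_tsv

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_fixture", "random_yule_tree"]

logger = logging.getLogger("paraconv")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    record_path: str | Path
    model_path: str | Path | None = None  # None -> bundled JTT
    method: str = "analytic"  # "analytic" | "simulation"
    n_replicates: int = 100
    seed: int | None = None
    outdir: str | Path = "."
    correction: str = "none"

    def __post_init__(self) -> None:
        if self.method not in ("analytic", "simulation"):
            raise ValueError(f"unknown expectation method {self.method!r}")
        if self.method == "simulation" and self.seed is None:
            raise ValueError("a seed is required when method == 'simulation'")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Identify -> expect -> test; returns a manifest of output paths.

    Re-running with an identical config reproduces byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(name, exc) from exc
        timings[name] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", name, timings[name])
        return result

    record = stage("read", lambda: read_ancestral_record(config.record_path))
    model = stage(
        "model",
        lambda: load_jtt() if config.model_path is None else read_paml_dat(config.model_path),
    )
    q = build_rate_matrix(model)

    counts, events = stage("identify", lambda: identify_events(record))
    if config.method == "simulation":
        expectation = stage(
            "expect",
            lambda: expected_counts_simulation(
                record, q, n_replicates=config.n_replicates, seed=config.seed
            ),
        )
    else:
        expectation = stage("expect", lambda: expected_counts_analytic(record, q))
    results = stage("test", lambda: detect(counts, expectation, config.correction))

    paths = {
        "counts": outdir / "counts.tsv",
        "details": outdir / "details.tsv",
        "expectation": outdir / "expectation.tsv",
        "tests": outdir / "tests.tsv",
    }
    write_counts_tsv(counts, paths["counts"])
    write_details_tsv(events, paths["details"])
    write_expectation_tsv(expectation, paths["expectation"])
    write_tests_tsv(results, paths["tests"])

    manifest = {
        "version": __version__,
        "record": str(config.record_path),
        "model": "JTT (bundled)" if config.model_path is None else str(config.model_path),
        "method": config.method,
        "n_replicates": config.n_replicates if config.method == "simulation" else None,
        "seed": config.seed,
        "correction": config.correction,
        "outputs": {k: str(v) for k, v in paths.items()},
        "sha256": {k: _sha256(v) for k, v in paths.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", manifest_path)
    return {**manifest["outputs"], "manifest": str(manifest_path)}


# --- synthetic fixtures ------------------------------------------------------


def random_yule_tree(
    rng: np.random.Generator, n_leaves: int, mean_branch: float = 0.1
) -> Tree:
    """Random rooted bifurcating tree: Yule splits, exponential branch lengths.

    Tips are named t1..tn in order of creation; internals are labeled N<k>
    in preorder.  Branch lengths are i.i.d. exponential with the given mean
    (expected replacements per site).
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    # grow by repeatedly splitting a uniformly chosen tip
    children: dict[int, list[int]] = {0: []}
    parent: dict[int, int | None] = {0: None}
    tips = [0]
    next_id = 1
    while len(tips) < n_leaves:
        k = int(rng.integers(len(tips)))
        node = tips.pop(k)
        for _ in range(2):
            children[next_id] = []
            parent[next_id] = node
            children[node].append(next_id)
            tips.append(next_id)
            next_id += 1

    tip_ids = sorted(t for t in parent if not children[t])
    names = {t: f"t{i + 1}" for i, t in enumerate(tip_ids)}
    lengths = {nid: float(rng.exponential(mean_branch)) for nid in parent if parent[nid] is not None}

    def build_name(nid: int) -> str:
        return names.get(nid, f"\x00{nid}")

    nodes = {
        build_name(nid): TreeNode(
            build_name(nid),
            None if parent[nid] is None else build_name(parent[nid]),
            tuple(build_name(c) for c in children[nid]),
            lengths.get(nid),
        )
        for nid in parent
    }
    return label_unnamed_internals(Tree(root=build_name(0), nodes=nodes))


def make_fixture(
    seed: int,
    n_leaves: int = 8,
    length: int = 200,
    model_path: str | Path | None = None,
    mean_branch: float = 0.1,
    outdir: str | Path = ".",
) -> tuple[Path, Path, Path]:
    """Generate a synthetic ancestral record, tip FASTA and Newick tree.

    A Yule tree with exponential branch lengths (mean 0.1 replacements per
    site) is simulated under the requested model (bundled JTT by default)
    with unit site rates and model-stationary root frequencies; the
    simulation's true ancestral sequences populate the record.
    Deterministic per seed.
    """
    if n_leaves < 3 or length < 1:
        raise ValueError("need n_leaves >= 3 and length >= 1")
    rng = np.random.default_rng(seed)
    tree = random_yule_tree(rng, n_leaves, mean_branch)
    model = load_jtt() if model_path is None else read_paml_dat(model_path)
    q = build_rate_matrix(model)
    record = simulate_record(
        tree, q, 1.0, length, q.pi, seed=int(rng.integers(2**31 - 1))
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record_path = outdir / "record.tsv"
    fasta_path = outdir / "tips.fasta"
    tree_path = outdir / "tree.nwk"
    write_ancestral_record(record, record_path)
    write_fasta(record.tip_alignment(), fasta_path)
    tree_path.write_text(write_newick(tree) + "\n")
    return record_path, fasta_path, tree_path
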