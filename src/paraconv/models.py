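"""Empirical reversible amino-acid substitution models.

A model is a symmetric exchangeability matrix ``S`` plus stationary
frequencies ``pi`` (read from a PAML ``.dat`` file, lower triangle followed
by frequencies, residue order A R N D C Q E G H I L K M F P S T W Y V).
The generator is ``Q_ij = S_ij * pi_j`` with rows summing to zero,
normalized so the mean replacement rate ``-sum_i pi_i Q_ii`` equals one;
branch lengths are then expected replacements per site.  Transition
probabilities ``P(d) = expm(Q d)`` are obtained through the symmetric
eigendecomposition of ``Pi^{1/2} Q Pi^{-1/2}``, which is exact for
reversible generators and numerically stable at any distance.

All operations are generic in alphabet size ``n >= 2``, so small-alphabet
closed forms can serve as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .seqio import AMINO_ACIDS, Alignment

__all__ = [
    "EmpiricalModel",
    "RateMatrix",
    "ModelFormatError",
    "read_paml_dat",
    "load_jtt",
    "build_rate_matrix",
    "transition_matrix",
    "estimate_frequencies",
]


class ModelFormatError(ValueError):
    """Malformed PAML .dat input or invalid model parameters."""


@dataclass(frozen=True)
class EmpiricalModel:
    """Exchangeabilities ``S`` (symmetric, zero diagonal) and frequencies ``pi``."""

    name: str
    S: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        S, pi = np.asarray(self.S, float), np.asarray(self.pi, float)
        n = len(pi)
        if S.shape != (n, n):
            raise ModelFormatError(f"S shape {S.shape} does not match {n} frequencies")
        if not np.allclose(S, S.T):
            raise ModelFormatError("S is not symmetric")
        if np.any(np.diag(S) != 0):
            raise ModelFormatError("S diagonal must be zero")
        if np.any(S < 0) or np.any(pi <= 0):
            raise ModelFormatError("exchangeabilities must be >= 0 and frequencies > 0")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ModelFormatError(f"frequencies sum to {pi.sum()}, not 1")

    @property
    def n(self) -> int:
        return len(self.pi)


@dataclass(frozen=True)
class RateMatrix:
    """Normalized generator ``Q`` (mean rate one) with its stationary ``pi``."""

    Q: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        Q, pi = np.asarray(self.Q, float), np.asarray(self.pi, float)
        off = Q[~np.eye(len(pi), dtype=bool)]
        if np.any(off < 0):
            raise ModelFormatError("off-diagonal rates must be >= 0")
        if np.any(np.abs(Q.sum(axis=1)) > 1e-10):
            raise ModelFormatError("generator rows must sum to 0")
        if abs(-(pi * np.diag(Q)).sum() - 1.0) > 1e-10:
            raise ModelFormatError("generator not normalized to mean rate 1")

    @property
    def n(self) -> int:
        return len(self.pi)


def read_paml_dat(path: str | Path, name: str | None = None) -> EmpiricalModel:
    """Read an empirical model from a PAML-format ``.dat`` file.

    Expects the n(n-1)/2 lower-triangle entries of ``S`` (whitespace- and
    line-break-separated; n inferred, default 20) followed by the n
    frequencies; any trailing commentary after the frequency block is
    ignored.  Frequencies within 1e-4 of summing to 1 are renormalized.
    """
    tokens: list[float] = []
    for tok in Path(path).read_text().split():
        try:
            tokens.append(float(tok))
        except ValueError:
            break  # first non-numeric token starts the trailing commentary

    # infer n: total numeric tokens >= n(n-1)/2 + n
    n = None
    for cand in range(2, 40):
        if cand * (cand - 1) // 2 + cand == len(tokens):
            n = cand
            break
    if n is None:
        # allow trailing numeric commentary only for the default alphabet
        need = 20 * 19 // 2 + 20
        if len(tokens) >= need:
            n, tokens = 20, tokens[:need]
        else:
            raise ModelFormatError(
                f"{path}: {len(tokens)} numeric entries do not form a triangle+frequency block"
            )

    tri, freqs = tokens[: n * (n - 1) // 2], tokens[n * (n - 1) // 2 :]
    S = np.zeros((n, n))
    k = 0
    for i in range(1, n):
        for j in range(i):
            S[i, j] = S[j, i] = tri[k]
            k += 1
    pi = np.array(freqs)
    if np.any(pi < 0) or np.any(S < 0):
        raise ModelFormatError(f"{path}: negative entries")
    if abs(pi.sum() - 1.0) > 1e-4:
        raise ModelFormatError(f"{path}: frequencies sum to {pi.sum():.6f}, far from 1")
    pi = pi / pi.sum()
    return EmpiricalModel(name=name or Path(path).stem.upper(), S=S, pi=pi)


def load_jtt() -> EmpiricalModel:
    """The bundled JTT model (Jones, Taylor & Thornton 1992)."""
    with resources.as_file(resources.files("paraconv").joinpath("data/jtt.dat")) as p:
        return read_paml_dat(p, name="JTT")


def build_rate_matrix(model: EmpiricalModel, pi_override: np.ndarray | None = None) -> RateMatrix:
    """Assemble the mean-rate-one generator ``Q_ij = S_ij pi_j`` (i != j).

    ``pi_override`` swaps in alternative stationary frequencies (e.g.
    alignment-estimated ones) while keeping the model's exchangeabilities.
    """
    pi = model.pi if pi_override is None else np.asarray(pi_override, float)
    if pi_override is not None:
        if len(pi) != model.n or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-6:
            raise ModelFormatError("pi_override must be positive and sum to 1")
        pi = pi / pi.sum()
    Q = model.S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    if mu <= 0:
        raise ModelFormatError("degenerate model: zero mean rate")
    return RateMatrix(Q=Q / mu, pi=pi)


def transition_matrix(q: RateMatrix, d: float) -> np.ndarray:
    """Transition probabilities ``P(d) = expm(Q d)`` at distance ``d >= 0``.

    Computed via the symmetric form ``B = Pi^{1/2} Q Pi^{-1/2}`` whose real
    eigendecomposition gives ``P(d) = Pi^{-1/2} U e^{L d} U' Pi^{1/2}``.
    Rows sum to 1 within 1e-9; tiny negative round-off (>= -1e-12) is
    clipped to 0.
    """
    if d < 0:
        raise ValueError(f"negative distance {d}")
    if d == 0:
        return np.eye(q.n)
    sqrt_pi = np.sqrt(q.pi)
    B = (sqrt_pi[:, None] * q.Q) / sqrt_pi[None, :]
    B = (B + B.T) / 2  # enforce exact symmetry before eigh
    lam, U = np.linalg.eigh(B)
    P = (U * np.exp(lam * d)) @ U.T
    P = P / sqrt_pi[:, None] * sqrt_pi[None, :]
    if P.min() < -1e-12:
        raise FloatingPointError(f"transition probability {P.min()} below tolerance")
    return np.clip(P, 0.0, 1.0)


def estimate_frequencies(aln: Alignment, alphabet: tuple[str, ...] = AMINO_ACIDS) -> np.ndarray:
    """Observed residue proportions of a trimmed alignment.

    Zero counts are floored at 1e-6 (avoiding absorbing states when the
    vector seeds a simulation) and the vector renormalized.
    """
    if not aln.entries or aln.width == 0:
        raise ValueError("cannot estimate frequencies from an empty alignment")
    index = {a: i for i, a in enumerate(alphabet)}
    counts = np.zeros(len(alphabet))
    for _, seq in aln.entries:
        for ch in seq:
            try:
                counts[index[ch]] += 1
            except KeyError:
                raise ValueError(f"residue {ch!r} outside alphabet; trim the alignment first")
    freqs = counts / counts.sum()
    freqs = np.maximum(freqs, 1e-6)
    return freqs / freqs.sum()
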