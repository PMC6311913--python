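"""Profile-derived features: frequency matrix, consensus sequence, 87 features.

A position-specific scoring matrix (PSSM) holds per-position log-odds scores
s_ij. The pipeline is:

1. exponentiate: s'_ij = 2^(0.1 * s_ij) (always positive);
2. row-normalise s' to the frequency matrix (FM), each row summing to one;
3. consensus sequence (CS): per-position argmax over the four nucleotide
   columns (the gap column never wins; ties go to the lowest alphabet index);
4. features: nucleotide composition of the CS (NCCS, 4), its Shannon entropy
   (ECS, 1), the mean per-position entropy of the FM (EFM, 1), CS dimer and
   trimer relative frequencies (16 + 64), and CS GC content (1) — 87 in all.

All logarithms are natural. Because a constant additive shift of the scores
multiplies every exponentiated entry by the same factor, the FM — and hence
all 87 features — is invariant to such shifts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import PSSM, RNA_ALPHABET, RnaRecord

logger = logging.getLogger(__name__)

_IDX = {c: i for i, c in enumerate(RNA_ALPHABET)}

DIMERS = ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=2)]
TRIMERS = ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=3)]

#: Frozen 87-name layout of the profile block.
PROFILE_FEATURE_NAMES: list[str] = (
    [f"psi.nccs.{c}" for c in RNA_ALPHABET]
    + ["psi.ecs", "psi.efm"]
    + [f"psi.dimer.{d}" for d in DIMERS]
    + [f"psi.trimer.{t}" for t in TRIMERS]
    + ["psi.gc"]
)
assert len(PROFILE_FEATURE_NAMES) == 87


@dataclass(frozen=True)
class FrequencyMatrix:
    """Row-stochastic L x 5 matrix derived from an exponentiated PSSM."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if np.any(v < 0) or not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequency matrix rows must be non-negative and sum to 1")


def transform_scores(pssm: PSSM) -> np.ndarray:
    """Exponentiate integer scores: each entry becomes 2^(0.1 * s_ij) > 0."""
    return np.exp2(0.1 * pssm.scores.astype(float))


def to_frequency_matrix(transformed: np.ndarray) -> FrequencyMatrix:
    sums = transformed.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):  # impossible after exponentiation; guard anyway
        raise ValueError("zero row encountered during normalisation")
    return FrequencyMatrix(transformed / sums)


def consensus(fm: FrequencyMatrix) -> str:
    """Per-position argmax nucleotide over the 4 nucleotide columns.

    The gap column (index 4) is excluded; ties resolve to the lowest
    alphabet index (A < C < G < U), which np.argmax provides.
    """
    idx = np.argmax(fm.values[:, :4], axis=1)
    return "".join(RNA_ALPHABET[j] for j in idx)


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0*ln(0) := 0 convention."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def nccs_and_ecs(cs: str) -> tuple[np.ndarray, float]:
    """Nucleotide composition of the consensus and its entropy.

    NCCS(j) = n(j)/L over the four nucleotides; ECS is the Shannon entropy of
    that composition in nats (so ECS is in [0, ln 4]).
    """
    if not cs:
        raise ValueError("empty consensus sequence")
    counts = np.array([cs.count(c) for c in RNA_ALPHABET], dtype=float)
    nccs = counts / len(cs)
    return nccs, _entropy(nccs)


def efm(fm: FrequencyMatrix) -> float:
    """Mean per-position entropy of the frequency matrix, in [0, ln 5]."""
    return _entropy(fm.values.ravel()) / fm.values.shape[0]


def consensus_kmers(cs: str) -> np.ndarray:
    """Relative dimer (16) and trimer (64) frequencies of the consensus.

    Dimers are counted over the L-1 sliding windows, trimers over L-2;
    each block sums to one. Frequencies (not raw counts) keep the features
    comparable across the 60-130 nt length range.
    """
    L = len(cs)
    if L < 3:
        raise ValueError(f"consensus too short for trimers: L={L}")
    dimer_counts = np.zeros(16)
    trimer_counts = np.zeros(64)
    for i in range(L - 1):
        a, b = _IDX[cs[i]], _IDX[cs[i + 1]]
        dimer_counts[4 * a + b] += 1
    for i in range(L - 2):
        a, b, c = _IDX[cs[i]], _IDX[cs[i + 1]], _IDX[cs[i + 2]]
        trimer_counts[16 * a + 4 * b + c] += 1
    return np.concatenate([dimer_counts / (L - 1), trimer_counts / (L - 2)])


def gc_content(cs: str) -> float:
    if not cs:
        raise ValueError("empty consensus sequence")
    return (cs.count("G") + cs.count("C")) / len(cs)


def profile_block(pssm: PSSM) -> np.ndarray:
    """The full 87-value profile feature block, in the frozen name order."""
    fm = to_frequency_matrix(transform_scores(pssm))
    cs = consensus(fm)
    nccs, ecs = nccs_and_ecs(cs)
    kmers = consensus_kmers(cs)
    out = np.concatenate([nccs, [ecs, efm(fm)], kmers, [gc_content(cs)]])
    assert out.shape == (87,)
    return out


def pseudo_pssm(seq: RnaRecord, match: int = 5, mismatch: int = -5) -> PSSM:
    """One-hot stand-in PSSM for a sequence with no profile available.

    The matching nucleotide scores ``match``, all other columns (including the
    gap) score ``mismatch``; the consensus then reproduces the sequence
    exactly. Used so extraction degrades gracefully; callers log its use.
    """
    L = len(seq)
    scores = np.full((L, 5), mismatch, dtype=np.int64)
    for i, c in enumerate(seq.sequence):
        scores[i, _IDX[c]] = match
    logger.debug("synthesised pseudo-PSSM for %s", seq.id)
    return PSSM(scores, seq)


def raw_sequence_kmers(seq: RnaRecord) -> np.ndarray:
    """Dimer+trimer frequencies of the raw sequence (for user comparisons)."""
    return consensus_kmers(seq.sequence)
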