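"""Download-free synthetic corpora with the statistical structure the
pipeline assumes.

Positives are planted hairpins: a random 5' arm, a short loop, the arm's
reverse complement, and random flanks; the matching dot-bracket marks the
planted stem. Negatives are dinucleotide-preserving (Altschul-Erickson)
shuffles of positives, so mono- and dinucleotide composition — and hence
plain k-mer features — carry essentially no class signal and any separation
must come from structure and sequence order. This mirrors the hard-negative
design of pseudo-hairpin benchmarks, where negatives match true precursors
in length and composition.

Profiles are Dirichlet-perturbed one-hot frequency rows converted to
integer log-odds scores against a uniform background (10 * ln ratio,
rounded toward zero). Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import (
    DotBracket,
    PSSM,
    RNA_ALPHABET,
    RnaRecord,
    write_dotbracket,
    write_fasta,
    write_labels,
    write_pssm,
)
from .structure_features import fold_fallback

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: Per-position target frequencies for a noise-free profile: the matching
#: nucleotide dominates, the three others and the gap share the remainder.
_MATCH_FREQ = 0.92
_OFF_FREQ = 0.02
_BACKGROUND = 0.2  # uniform over the 5 PSSM columns
_FREQ_FLOOR = 1e-4


@dataclass(frozen=True)
class SynthConfig:
    """Corpus geometry and noise settings; ``seed`` drives all randomness."""

    n_pos: int = 50
    n_neg: int = 50
    length_range: tuple[int, int] = (60, 130)
    stem_len: int = 25
    loop_range: tuple[int, int] = (4, 8)
    pssm_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        min_core = 2 * self.stem_len + self.loop_range[0]
        if self.stem_len < 3 or self.loop_range[0] < 3:
            raise ValueError("need stem_len >= 3 and loop >= 3")
        if min_core > hi:
            raise ValueError(
                f"stem {self.stem_len} + loop {self.loop_range[0]} cannot fit "
                f"in max length {hi}"
            )


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def make_hairpin(
    config: SynthConfig, rng: np.random.Generator, rec_id: str = "hairpin"
) -> tuple[RnaRecord, DotBracket]:
    """One planted-stem hairpin and its dot-bracket."""
    lo, hi = config.length_range
    loop_len = int(rng.integers(config.loop_range[0], config.loop_range[1] + 1))
    core = 2 * config.stem_len + loop_len
    total = int(rng.integers(max(lo, core), hi + 1))
    n_flank = total - core
    left = int(rng.integers(0, n_flank + 1))
    right = n_flank - left

    def rand_nt(n: int) -> str:
        return "".join(rng.choice(list(RNA_ALPHABET), size=n))

    arm = rand_nt(config.stem_len)
    seq = rand_nt(left) + arm + rand_nt(loop_len) + reverse_complement(arm) + rand_nt(right)
    db = (
        "." * left
        + "(" * config.stem_len
        + "." * loop_len
        + ")" * config.stem_len
        + "." * right
    )
    return RnaRecord(rec_id, seq), DotBracket(db)


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (Altschul-Erickson)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random sequence with the exact dinucleotide multiset of ``seq``.

    Altschul-Erickson algorithm: view the sequence as an Eulerian walk on the
    dinucleotide multigraph, draw random last-exit edges forming a tree
    toward the final letter, shuffle the remaining out-edges, and rebuild.
    """
    if len(seq) < 3:
        return seq
    letters = sorted(set(seq))
    edges: dict[str, list[str]] = {c: [] for c in letters}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]

    non_terminal = [c for c in letters if c != last and edges[c]]
    while True:
        last_exit = {c: edges[c][int(rng.integers(len(edges[c])))] for c in non_terminal}
        # the chosen last-exit edges must lead every vertex to `last`
        ok = True
        for c in non_terminal:
            cur, hops = c, 0
            while cur != last:
                if cur not in last_exit or hops > len(letters):
                    ok = False
                    break
                cur = last_exit[cur]
                hops += 1
            if not ok:
                break
        if ok:
            break

    out_edges: dict[str, list[str]] = {}
    for c in letters:
        rest = list(edges[c])
        if c in last_exit:
            rest.remove(last_exit[c])
        rng.shuffle(rest)
        if c in last_exit:
            rest.append(last_exit[c])
        out_edges[c] = rest

    walk = [seq[0]]
    ptr = {c: 0 for c in letters}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = out_edges[cur][ptr[cur]]
        ptr[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def make_negative(
    positive: RnaRecord, rng: np.random.Generator, rec_id: str = "neg"
) -> RnaRecord:
    """Length- and composition-matched shuffle of a positive sequence."""
    return RnaRecord(rec_id, dinucleotide_shuffle(positive.sequence, rng))


# ---------------------------------------------------------------------------
# Synthetic profiles
# ---------------------------------------------------------------------------

def make_pssm(
    seq: RnaRecord, config: SynthConfig, rng: np.random.Generator
) -> PSSM:
    """Dirichlet-perturbed one-hot profile as integer log-odds scores.

    Target row frequencies put _MATCH_FREQ on the sequence's nucleotide and
    _OFF_FREQ elsewhere (gap included); with ``pssm_noise > 0`` the row is
    drawn from Dirichlet(target / pssm_noise), so noise -> 0 recovers the
    one-hot limit and the consensus equals the sequence. Scores are
    trunc(10 * ln(f / 0.2)).
    """
    idx = {c: i for i, c in enumerate(RNA_ALPHABET)}
    L = len(seq)
    freqs = np.full((L, 5), _OFF_FREQ)
    for i, c in enumerate(seq.sequence):
        freqs[i, idx[c]] = _MATCH_FREQ
    if config.pssm_noise > 0:
        freqs = np.vstack(
            [rng.dirichlet(row / config.pssm_noise) for row in freqs]
        )
    freqs = np.maximum(freqs, _FREQ_FLOOR)
    scores = np.trunc(10.0 * np.log(freqs / _BACKGROUND)).astype(np.int64)
    return PSSM(scores, seq)


# ---------------------------------------------------------------------------
# Full corpus
# ---------------------------------------------------------------------------

def make_benchmark(config: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete labelled corpus; returns the paths written.

    Layout: ``sequences.fasta``, ``structures.txt`` (planted folds for
    positives, base-pair-maximisation folds for negatives), ``labels.tsv``
    and one profile per record under ``pssms/``.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    (out / "pssms").mkdir(parents=True, exist_ok=True)

    records: list[RnaRecord] = []
    structures: list[tuple[RnaRecord, DotBracket]] = []
    labels: dict[str, int] = {}

    positives: list[tuple[RnaRecord, DotBracket]] = []
    for i in range(config.n_pos):
        rec, db = make_hairpin(config, rng, rec_id=f"pos{i + 1:03d}")
        positives.append((rec, db))
        records.append(rec)
        structures.append((rec, db))
        labels[rec.id] = 1
    for i in range(config.n_neg):
        if i < len(positives):
            template = positives[i][0]
        else:  # more negatives than positives: draw fresh hairpins to shuffle
            template, _ = make_hairpin(config, rng, rec_id=f"tmpl{i}")
        rec = make_negative(template, rng, rec_id=f"neg{i + 1:03d}")
        records.append(rec)
        structures.append((rec, fold_fallback(rec)))
        labels[rec.id] = 0

    paths = {
        "fasta": out / "sequences.fasta",
        "structures": out / "structures.txt",
        "labels": out / "labels.tsv",
        "pssm_dir": out / "pssms",
    }
    write_fasta(records, paths["fasta"])
    write_dotbracket(structures, paths["structures"])
    write_labels(pd.Series(labels), paths["labels"])
    for rec in records:
        write_pssm(make_pssm(rec, config, rng), paths["pssm_dir"] / f"{rec.id}.tsv")
    return paths
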