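"""Readers and writers for every external representation the pipeline touches.

Formats supported:

* FASTA (via Biopython), with DNA->RNA transliteration on read;
* PSI-BLAST ASCII PSSM files and a simple headered TSV fallback dialect;
* Vienna-style dot-bracket structure files;
* TSV feature tables (first column = sequence id, optional ``label`` column);
* JSON-serialised trained models (see :mod:`stemloop.classify`).

Coordinates are 0-based internally; user-facing position reports are 1-based,
matching PSSM file conventions.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = "ACGU"
#: PSSM column order: the four nucleotides plus the gap symbol.
PSSM_COLUMNS = ("A", "C", "G", "U", "-")

_VALID_INPUT_LETTERS = set("ACGUTacgut")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class RnaRecord:
    """A named RNA sequence with an optional two-class label."""

    id: str
    sequence: str
    label: int | None = None  # 1 = positive, 0 = negative

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("record id must be non-empty")
        if len(self.sequence) < 4:
            raise FormatError(f"record {self.id!r}: sequence shorter than 4 nt")
        bad = set(self.sequence) - set(RNA_ALPHABET)
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid letters {sorted(bad)}; "
                f"expected alphabet {{A,C,G,U}}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DotBracket:
    """A balanced dot-bracket secondary structure aligned to a sequence."""

    structure: str

    def __post_init__(self) -> None:
        validate_dotbracket(self.structure)

    def __len__(self) -> int:
        return len(self.structure)

    def pairs(self) -> list[tuple[int, int]]:
        """Return 0-based (i, j) base pairs, i < j, from the bracket matching."""
        stack: list[int] = []
        out: list[tuple[int, int]] = []
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                out.append((stack.pop(), i))
        return sorted(out)


def validate_dotbracket(structure: str) -> None:
    """Reject unbalanced or non-{(,),.} structures, reporting 1-based positions."""
    depth = 0
    for i, c in enumerate(structure):
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(
                    f"unbalanced ')' at position {i + 1} in structure"
                )
        elif c != ".":
            raise FormatError(
                f"invalid structure character {c!r} at position {i + 1}"
            )
    if depth != 0:
        raise FormatError(f"{depth} unmatched '(' in structure")


def _clean_sequence(raw: str, rec_id: str) -> str:
    bad = set(raw) - _VALID_INPUT_LETTERS
    if bad:
        raise FormatError(
            f"record {rec_id!r}: invalid sequence letters {sorted(bad)}"
        )
    return raw.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[RnaRecord]:
    """Read RNA records from FASTA; T is transliterated to U, case is upper-cased.

    Raises :class:`FormatError` on an empty file, duplicate ids, or letters
    outside {A,C,G,U,T} (case-insensitive), naming the offending record.
    """
    records: list[RnaRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(RnaRecord(rec.id, _clean_sequence(str(rec.seq), rec.id)))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[RnaRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSSM:
    """Position-specific scoring matrix: L x 5 integer scores over (A,C,G,U,-).

    Scores are 10 * ln(observed / background frequency), rounded to integer,
    as produced by iterative profile search tools.
    """

    scores: np.ndarray  # shape (L, 5), integer dtype
    sequence: RnaRecord

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        if s.ndim != 2 or s.shape[1] != 5:
            raise FormatError(f"PSSM must be L x 5, got shape {s.shape}")
        if s.shape[0] != len(self.sequence):
            raise FormatError(
                f"PSSM for {self.sequence.id!r}: {s.shape[0]} rows but "
                f"sequence length {len(self.sequence)}"
            )
        if not np.issubdtype(s.dtype, np.integer):
            raise FormatError("PSSM scores must be integers")


def _pssm_from_rows(
    rec_id: str, letters: list[str], rows: list[list[int]]
) -> PSSM:
    seq = _clean_sequence("".join(letters), rec_id)
    arr = np.asarray(rows, dtype=np.int64)
    if arr.shape[1] == 4:
        # Gap column absent: fill with the row minimum as a sentinel so the
        # gap never wins downstream normalisation.
        arr = np.hstack([arr, arr.min(axis=1, keepdims=True)])
    if arr.shape[1] != 5:
        raise FormatError(
            f"PSSM {rec_id!r}: expected 4 or 5 score columns, got {arr.shape[1]}"
        )
    return PSSM(arr, RnaRecord(rec_id, seq))


def read_pssm(path: str | Path, rec_id: str | None = None) -> PSSM:
    """Read a PSI-BLAST ASCII PSSM or the TSV fallback dialect.

    The dialect is sniffed from the first non-blank line: a line starting with
    ``pos`` (tab-separated header) selects the TSV fallback; anything else is
    parsed as the PSI-BLAST ``-out_ascii_pssm`` layout (free-text header line,
    a column-label line, then one row per position: index, letter, scores).
    """
    path = Path(path)
    if rec_id is None:
        rec_id = path.stem
    text = path.read_text()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if first.lower().startswith("pos"):
        return _read_pssm_tsv(text, rec_id)
    return _read_pssm_psiblast(text, rec_id)


def _read_pssm_tsv(text: str, rec_id: str) -> PSSM:
    df = pd.read_csv(io.StringIO(text), sep="\t")
    letters = [str(x) for x in df.iloc[:, 1]]
    scores = df.iloc[:, 2:].to_numpy()
    if not np.issubdtype(scores.dtype, np.integer):
        if not np.all(scores == np.floor(scores)):
            raise FormatError(f"PSSM {rec_id!r}: non-integer score value")
        scores = scores.astype(np.int64)
    return _pssm_from_rows(rec_id, letters, scores.tolist())


def _read_pssm_psiblast(text: str, rec_id: str) -> PSSM:
    letters: list[str] = []
    rows: list[list[int]] = []
    row_re = re.compile(r"^\s*(\d+)\s+([A-Za-z])((?:\s+-?\d+)+)")
    for line in text.splitlines():
        m = row_re.match(line)
        if not m:
            continue
        letters.append(m.group(2))
        try:
            scores = [int(tok) for tok in m.group(3).split()]
        except ValueError as exc:  # pragma: no cover - regex guarantees ints
            raise FormatError(f"PSSM {rec_id!r}: non-integer score") from exc
        # -out_ascii_pssm repeats the alphabet twice (scores then percentages);
        # keep the first block only.
        rows.append(scores[:5] if len(scores) >= 5 else scores[:4])
    if not rows:
        raise FormatError(f"no PSSM rows found for {rec_id!r}")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise FormatError(f"PSSM {rec_id!r}: ragged score rows")
    return _pssm_from_rows(rec_id, letters, rows)


def write_pssm(pssm: PSSM, path: str | Path) -> None:
    """Write a PSSM in the TSV fallback dialect (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("pos\tbase\t" + "\t".join(PSSM_COLUMNS) + "\n")
        for i, (letter, row) in enumerate(
            zip(pssm.sequence.sequence, pssm.scores), start=1
        ):
            fh.write(f"{i}\t{letter}\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Dot-bracket structure files
# ---------------------------------------------------------------------------

def read_dotbracket(path: str | Path) -> list[tuple[RnaRecord, DotBracket]]:
    """Read Vienna-style structure files.

    Accepts either ``>id`` / sequence / structure triplets or alternating
    sequence / structure line pairs (ids auto-numbered ``seq1``, ``seq2``...).
    Any trailing free-energy annotation after the structure is ignored.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"empty structure file {path}")
    out: list[tuple[RnaRecord, DotBracket]] = []
    i = 0
    n_anon = 0
    while i < len(lines):
        if lines[i].startswith(">"):
            if i + 2 >= len(lines):
                raise FormatError(f"truncated entry {lines[i]!r}")
            rec_id = lines[i][1:].split()[0]
            seq_line, db_line = lines[i + 1], lines[i + 2]
            i += 3
        else:
            if i + 1 >= len(lines):
                raise FormatError("dangling sequence line without structure")
            n_anon += 1
            rec_id = f"seq{n_anon}"
            seq_line, db_line = lines[i], lines[i + 1]
            i += 2
        structure = db_line.split()[0]
        rec = RnaRecord(rec_id, _clean_sequence(seq_line, rec_id))
        if len(structure) != len(rec):
            raise FormatError(
                f"record {rec_id!r}: structure length {len(structure)} != "
                f"sequence length {len(rec)}"
            )
        out.append((rec, DotBracket(structure)))
    return out


def write_dotbracket(
    entries: Iterable[tuple[RnaRecord, DotBracket]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for rec, db in entries:
            fh.write(f">{rec.id}\n{rec.sequence}\n{db.structure}\n")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Per-sequence feature vectors with a frozen column order.

    ``values`` is indexed by sequence id; ``labels`` (optional) is an integer
    series aligned to the same index (1 = positive, 0 = negative).
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise FormatError("feature table contains missing values")
        if self.labels is not None and not self.values.index.equals(
            self.labels.index
        ):
            raise FormatError("labels index does not match feature rows")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.values.copy()
    if table.labels is not None:
        df["label"] = table.labels
    df.to_csv(path, sep="\t", index_label="id", float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col="id", float_precision="round_trip")
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").astype(int)
    return FeatureTable(df, labels)


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV (id, label) into an integer series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(int)


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").to_csv(path, sep="\t", index_label="id")
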