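"""Reading, writing, filtering, encoding, and subsampling of A3M/FASTA alignments.

The central object is :class:`Msa`, an aligned sequence collection whose first
row is the query. A3M conventions apply throughout: uppercase letters and ``-``
are match columns defined by the query; lowercase letters are insertions
relative to the query and are ignored by every column-wise operation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import ArgumentError, FormatError

#: One-hot alphabet: the 20 standard amino acids, the gap symbol, and a single
#: "unknown" slot that absorbs every other character (B, J, O, U, X, Z, ...).
ALPHABET = "ACDEFGHIKLMNPQRSTVWY-X"
ALPHABET_SIZE = len(ALPHABET)

_UNKNOWN_INDEX = ALPHABET.index("X")
_CHAR_LUT = np.full(256, _UNKNOWN_INDEX, dtype=np.int64)
for _i, _c in enumerate(ALPHABET):
    _CHAR_LUT[ord(_c)] = _i


def match_columns(aligned_seq: str) -> str:
    """Drop lowercase insertion characters, keeping match columns only."""
    return "".join(c for c in aligned_seq if not c.islower())


@dataclass(frozen=True)
class Msa:
    """An alignment with a distinguished query row.

    Parameters
    ----------
    rows:
        Ordered ``(id, aligned_seq)`` pairs. The first row is the query; its
        non-lowercase characters define the match columns, so it may not
        contain gaps. Every other row must have exactly ``match_length``
        characters once insertions are removed.
    """

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ArgumentError("an Msa needs at least a query row")
        qid, qseq = self.rows[0]
        qmatch = match_columns(qseq)
        if "-" in qmatch:
            raise FormatError(f"query row {qid!r} contains gap characters")
        if not qmatch:
            raise FormatError(f"query row {qid!r} has no match columns")
        seen: set[str] = set()
        for rid, seq in self.rows:
            if rid in seen:
                raise FormatError(f"duplicate row id {rid!r}")
            seen.add(rid)
            if len(match_columns(seq)) != len(qmatch):
                raise FormatError(
                    f"row {rid!r} has {len(match_columns(seq))} match columns, "
                    f"expected {len(qmatch)}"
                )

    @property
    def query_id(self) -> str:
        return self.rows[0][0]

    @property
    def query_seq(self) -> str:
        return self.rows[0][1]

    @property
    def match_length(self) -> int:
        return len(match_columns(self.query_seq))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def _parse_fasta_text(text: str, source: str) -> Msa:
    # '#' lines (ColabFold complex headers / comments) are not plain records.
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    records = list(SeqIO.parse(io.StringIO("\n".join(lines)), "fasta"))
    if not records:
        raise FormatError(f"{source}: no FASTA records found")
    rows = tuple((rec.id, str(rec.seq)) for rec in records)
    if not rows[0][1]:
        raise FormatError(f"{source}: first record is empty")
    return Msa(rows)


def read_a3m(path: str | Path) -> Msa:
    """Read an A3M/aligned-FASTA file into an :class:`Msa`.

    Lowercase characters are retained as insertions; the first record is the
    query and defines the match length; ids are FASTA headers up to the first
    whitespace. Rows whose de-inserted length disagrees with the query raise
    :class:`FormatError` naming the offending row.
    """
    path = Path(path)
    return _parse_fasta_text(path.read_text(), str(path))


def read_a3m_text(text: str) -> Msa:
    """Parse A3M content from a string (convenience for tests and pipelines)."""
    return _parse_fasta_text(text, "<string>")


def write_a3m(msa: Msa, path: str | Path) -> None:
    """Write an :class:`Msa` as A3M; ``read_a3m`` round-trips it exactly."""
    path = Path(path)
    with path.open("w") as fh:
        for rid, seq in msa.rows:
            fh.write(f">{rid}\n{seq}\n")


def filter_by_gap_fraction(msa: Msa, max_gap: float = 0.25) -> Msa:
    """Drop rows with strictly more than ``max_gap`` gaps in match columns.

    The query is always retained. A non-query row survives iff
    ``gaps / match_length <= max_gap`` — i.e. "more than 25% gaps" removes,
    exactly 25% keeps. Insertions do not count as alignment columns. Row
    order is preserved; the operation is idempotent.
    """
    if not 0.0 <= max_gap <= 1.0:
        raise ArgumentError(f"max_gap must be in [0, 1], got {max_gap}")
    length = msa.match_length
    kept = [msa.rows[0]]
    for rid, seq in msa.rows[1:]:
        if match_columns(seq).count("-") / length <= max_gap:
            kept.append((rid, seq))
    return Msa(tuple(kept))


def encode_onehot(msa: Msa) -> np.ndarray:
    """One-hot encode match columns over a 22-letter alphabet.

    Returns a float array of shape ``(n_rows, match_length * 22)``; row order
    matches the Msa. Each match column maps to exactly one hot position, so
    every row sums to ``match_length`` and the squared Euclidean distance
    between two rows equals twice their Hamming distance over match columns.
    """
    length = msa.match_length
    out = np.zeros((msa.n_rows, length, ALPHABET_SIZE), dtype=np.float64)
    rowidx = np.arange(length)
    for r, (_rid, seq) in enumerate(msa.rows):
        codes = np.frombuffer(match_columns(seq).encode("ascii"), dtype=np.uint8)
        out[r, rowidx, _CHAR_LUT[codes]] = 1.0
    return out.reshape(msa.n_rows, length * ALPHABET_SIZE)


def subsample_random(msa: Msa, size: int, seed: int) -> Msa:
    """Uniformly subsample to ``size`` rows, always keeping the query.

    The remaining ``size - 1`` rows are drawn without replacement from the
    non-query rows; if fewer are available the input is returned unchanged.
    Sampled rows keep their original relative order. Deterministic per seed.
    """
    if size < 1:
        raise ArgumentError(f"size must be >= 1, got {size}")
    n_extra = msa.n_rows - 1
    if size >= msa.n_rows:
        return msa
    rng = np.random.default_rng(seed)
    picked = rng.choice(n_extra, size=size - 1, replace=False)
    picked.sort()
    rows = (msa.rows[0],) + tuple(msa.rows[1 + i] for i in picked)
    return Msa(rows)


def subsample_maxmsa(
    msa: Msa, max_seq: int, extra_seq: int, seed: int
) -> tuple[Msa, Msa]:
    """Depth-limiting split used by max-MSA style subsampling baselines.

    Returns ``(cluster_part, extra_part)``: a random partition of the
    non-query rows where ``cluster_part`` holds at most ``max_seq`` rows
    (query included as row 0) and ``extra_part`` at most ``extra_seq``
    non-query rows (the query is repeated as its row 0 so both parts are
    valid alignments). The two parts share no non-query row.
    """
    if max_seq < 1:
        raise ArgumentError(f"max_seq must be >= 1, got {max_seq}")
    if extra_seq < 0:
        raise ArgumentError(f"extra_seq must be >= 0, got {extra_seq}")
    n_extra = msa.n_rows - 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_extra)
    first = np.sort(order[: max_seq - 1])
    second = np.sort(order[max_seq - 1 : max_seq - 1 + extra_seq])
    cluster_part = Msa((msa.rows[0],) + tuple(msa.rows[1 + i] for i in first))
    extra_part = Msa((msa.rows[0],) + tuple(msa.rows[1 + i] for i in second))
    return cluster_part, extra_part
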