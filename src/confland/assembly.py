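"""Assembly of prediction-ready multi-chain alignments.

Unpaired complex alignments are built by *diagonal padding*: each chain's
rows are placed in their own column span with gaps everywhere else, so no
cross-chain pairing is asserted. The merged query (row 0) is the one fully
paired row, since predictors require a complete query sequence. Homooligomer
sampling duplicates a single chain's span; paired mode concatenates
explicitly paired rows. Assemblies serialize to the ColabFold complex-A3M
dialect (``#len1,len2<TAB>copies1,copies2`` header line).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .clustering import SequenceCluster
from .errors import ArgumentError, FormatError
from .msa import Msa, match_columns, read_a3m_text

_COPY_SUFFIX = "_copy"


@dataclass(frozen=True)
class ChainSpec:
    """One chain of a complex: its id, aligned query, and copy count."""

    chain_id: str
    query_seq: str
    copies: int = 1

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ArgumentError(f"copies must be >= 1, got {self.copies}")

    @property
    def match_length(self) -> int:
        return len(match_columns(self.query_seq))


@dataclass(frozen=True)
class ComplexMsa:
    """A multi-chain alignment with per-chain-copy column spans.

    ``rows[0]`` is the merged query (every chain's query concatenated, fully
    paired). Every row's de-inserted length equals the total match length,
    which is the sum over chain copies of each chain's match length.
    """

    chain_specs: tuple[ChainSpec, ...]
    rows: tuple[tuple[str, str], ...]
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.chain_specs:
            raise ArgumentError("a ComplexMsa needs at least one chain")
        if not self.rows:
            raise ArgumentError("a ComplexMsa needs at least the query row")
        total = self.total_match_length
        seen: set[str] = set()
        for rid, seq in self.rows:
            if rid in seen:
                raise FormatError(f"duplicate row id {rid!r}")
            seen.add(rid)
            got = len(match_columns(seq))
            if got != total:
                raise FormatError(
                    f"row {rid!r} has {got} match columns, expected {total}"
                )
        if "-" in match_columns(self.rows[0][1]):
            raise FormatError("merged query row may not contain gaps")

    @property
    def total_match_length(self) -> int:
        return sum(c.match_length * c.copies for c in self.chain_specs)

    @property
    def spans(self) -> tuple[tuple[int, int, int, int], ...]:
        """``(start, end, chain_index, copy_index)`` per chain copy, in order."""
        out = []
        offset = 0
        for ci, spec in enumerate(self.chain_specs):
            for copy in range(spec.copies):
                out.append((offset, offset + spec.match_length, ci, copy))
                offset += spec.match_length
        return tuple(out)

    @property
    def n_chain_copies(self) -> int:
        return sum(c.copies for c in self.chain_specs)


def _members_of(source: Msa | SequenceCluster) -> tuple[Msa, int | None]:
    if isinstance(source, SequenceCluster):
        return source.members, source.label
    return source, None


def _merged_query_id(ids: Sequence[str]) -> str:
    return "+".join(ids)


def pad_concat_unpaired(
    receptor: Msa | SequenceCluster, ligand: Msa
) -> ComplexMsa:
    """Concatenate receptor and ligand alignments without pairing rows.

    Row 0 is the merged query. Each receptor row is padded with gaps over
    the ligand span and vice versa, so all evolutionary signal stays
    chain-local. Chain order is receptor then ligand; row counts of both
    inputs are preserved.
    """
    rec, label = _members_of(receptor)
    lr, ll = rec.match_length, ligand.match_length
    specs = (
        ChainSpec(rec.query_id, rec.query_seq, 1),
        ChainSpec(ligand.query_id, ligand.query_seq, 1),
    )
    rows = [(
        _merged_query_id([rec.query_id, ligand.query_id]),
        rec.query_seq + ligand.query_seq,
    )]
    rows += [(rid, seq + "-" * ll) for rid, seq in rec.rows[1:]]
    rows += [(rid, "-" * lr + seq) for rid, seq in ligand.rows[1:]]
    return ComplexMsa(specs, tuple(rows), label=label)


def pair_concat(
    receptor: Msa,
    ligand: Msa,
    pairing: Sequence[tuple[str, str]],
) -> ComplexMsa:
    """Concatenate explicitly paired rows (the paired-MSA control mode).

    Each ``(receptor_row_id, ligand_row_id)`` pair yields one concatenated
    row; rows not mentioned in the pairing are excluded. Unknown ids raise
    :class:`ArgumentError`.
    """
    rec_by_id = dict(receptor.rows)
    lig_by_id = dict(ligand.rows)
    specs = (
        ChainSpec(receptor.query_id, receptor.query_seq, 1),
        ChainSpec(ligand.query_id, ligand.query_seq, 1),
    )
    rows = [(
        _merged_query_id([receptor.query_id, ligand.query_id]),
        receptor.query_seq + ligand.query_seq,
    )]
    for rid, lid in pairing:
        if rid not in rec_by_id:
            raise ArgumentError(f"unknown receptor row id {rid!r} in pairing")
        if lid not in lig_by_id:
            raise ArgumentError(f"unknown ligand row id {lid!r} in pairing")
        rows.append((_merged_query_id([rid, lid]), rec_by_id[rid] + lig_by_id[lid]))
    return ComplexMsa(specs, tuple(rows))


def duplicate_homooligomer(
    unit: Msa | SequenceCluster, copies: int
) -> ComplexMsa:
    """Duplicate a single chain's alignment into a homooligomer assembly.

    Every non-query source row appears once per copy span in diagonal-padded
    form (gaps on every other span); the merged query repeats the chain
    query ``copies`` times. ``copies == 1`` reduces to the input alignment.
    """
    if copies < 1:
        raise ArgumentError(f"copies must be >= 1, got {copies}")
    msa, label = _members_of(unit)
    spec = ChainSpec(msa.query_id, msa.query_seq, copies)
    if copies == 1:
        return ComplexMsa((spec,), msa.rows, label=label)
    length = msa.match_length
    rows = [(msa.query_id, msa.query_seq * copies)]
    for copy in range(copies):
        left = "-" * (copy * length)
        right = "-" * ((copies - 1 - copy) * length)
        for rid, seq in msa.rows[1:]:
            rows.append((f"{rid}{_COPY_SUFFIX}{copy + 1}", left + seq + right))
    return ComplexMsa((spec,), tuple(rows), label=label)


def _crop_row(seq: str, start: int, end: int) -> str:
    """Crop a diagonal-padded row to one span's match columns.

    Lowercase insertions are kept wherever they occur: in a diagonally
    padded row they can only belong to the row's single source span.
    """
    out = []
    consumed = 0
    for ch in seq:
        if ch.islower():
            out.append(ch)
        else:
            if start <= consumed < end:
                out.append(ch)
            consumed += 1
    return "".join(out)


def split_unpaired(cmsa: ComplexMsa) -> list[Msa]:
    """Invert diagonal-padded assembly: one :class:`Msa` per chain copy.

    Each non-query row is assigned to the unique span covering all of its
    non-gap match columns (rows spanning several spans mean the assembly is
    paired and cannot be split; this raises :class:`ArgumentError`). Copy
    suffixes added by :func:`duplicate_homooligomer` are stripped, and each
    chain's query is restored as row 0, so splitting recovers the assembly
    inputs exactly.
    """
    spans = cmsa.spans
    per_span: list[list[tuple[str, str]]] = [[] for _ in spans]
    for rid, seq in cmsa.rows[1:]:
        cols = match_columns(seq)
        occupied = [i for i, c in enumerate(cols) if c != "-"]
        if not occupied:
            continue  # an all-gap row belongs to no chain
        home = None
        for si, (start, end, _ci, _copy) in enumerate(spans):
            if start <= occupied[0] and occupied[-1] < end:
                home = si
                break
        if home is None:
            raise ArgumentError(
                f"row {rid!r} crosses chain boundaries; not an unpaired assembly"
            )
        start, end, ci, _copy = spans[home]
        out_id = rid
        if cmsa.chain_specs[ci].copies > 1:
            stem, sep, tail = rid.rpartition(_COPY_SUFFIX)
            if sep and tail.isdigit():
                out_id = stem
        per_span[home].append((out_id, _crop_row(seq, start, end)))
    result = []
    for si, (start, end, ci, _copy) in enumerate(spans):
        spec = cmsa.chain_specs[ci]
        result.append(Msa(((spec.chain_id, spec.query_seq),) + tuple(per_span[si])))
    return result


# ---------------------------------------------------------------------------
# serialization


def write_complex_a3m(cmsa: ComplexMsa, path: str | Path) -> None:
    """Write the ColabFold complex-A3M dialect (# length/copies header)."""
    lengths = ",".join(str(c.match_length) for c in cmsa.chain_specs)
    copies = ",".join(str(c.copies) for c in cmsa.chain_specs)
    with Path(path).open("w") as fh:
        fh.write(f"#{lengths}\t{copies}\n")
        for rid, seq in cmsa.rows:
            fh.write(f">{rid}\n{seq}\n")


def read_complex_a3m(path: str | Path, label: int | None = None) -> ComplexMsa:
    """Read a complex A3M written by :func:`write_complex_a3m`."""
    text = Path(path).read_text()
    header = text.splitlines()[0] if text else ""
    if not header.startswith("#"):
        raise FormatError(f"{path}: missing '#' complex header line")
    try:
        lengths_s, copies_s = header[1:].split("\t")
        lengths = [int(x) for x in lengths_s.split(",")]
        copies = [int(x) for x in copies_s.split(",")]
    except ValueError as exc:
        raise FormatError(f"{path}: malformed complex header {header!r}") from exc
    msa = read_a3m_text(text)
    merged_query = msa.query_seq
    specs = []
    offset = 0
    for i, (length, ncopy) in enumerate(zip(lengths, copies)):
        qpart = _crop_match(merged_query, offset, offset + length)
        specs.append(ChainSpec(f"chain{i}", qpart, ncopy))
        offset += length * ncopy
    return ComplexMsa(tuple(specs), msa.rows, label=label)


def _crop_match(seq: str, start: int, end: int) -> str:
    return _crop_row(seq, start, end)


# ---------------------------------------------------------------------------
# job fan-out


def emit_prediction_jobs(
    clusters: Sequence[SequenceCluster],
    partner: Msa | None,
    copies: int,
    outdir: str | Path,
    num_models: int = 1,
    num_recycles: int = 3,
) -> dict:
    """Write one complex A3M per cluster plus a JSON job manifest.

    With a ``partner`` alignment each job is an unpaired receptor-ligand
    assembly; without one, each job is a ``copies``-mer homooligomer
    assembly of the cluster itself. Predictor settings default to a single
    model with three recycling steps.
    """
    if not clusters:
        raise ArgumentError("need at least one cluster")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    jobs = []
    for cluster in clusters:
        if partner is not None:
            cmsa = pad_concat_unpaired(cluster, partner)
        else:
            cmsa = duplicate_homooligomer(cluster, copies)
        path = outdir / f"cluster_{cluster.label:03d}.a3m"
        write_complex_a3m(cmsa, path)
        jobs.append(
            {
                "cluster": cluster.label,
                "path": str(path),
                "chains": [
                    {
                        "chain_id": c.chain_id,
                        "match_length": c.match_length,
                        "copies": c.copies,
                    }
                    for c in cmsa.chain_specs
                ],
            }
        )
    manifest = {
        "predictor": {"num_models": num_models, "num_recycles": num_recycles},
        "jobs": jobs,
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_manifest(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return json.load(fh)
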