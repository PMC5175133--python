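"""Sequence and alignment I/O with a strict amino-acid alphabet.

Every downstream stage (redundancy removal, feature extraction, phylogeny)
assumes sequences over the 20 canonical amino-acid letters. Public-database
entries routinely contain ambiguity codes (B, Z, J), the rare residues U
(selenocysteine) and O (pyrrolysine), and placeholders (X, ``*``), so reading
always passes through :func:`sanitize_sequence` with a configurable policy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: Conventional substitutions for ambiguity/rare codes: B (Asx) -> N,
#: Z (Glx) -> Q, U (Sec) -> C, O (Pyl) -> K, J (Xle) -> L.
AMBIGUITY_MAP = {"B": "N", "Z": "Q", "U": "C", "O": "K", "J": "L"}

SANITIZE_POLICIES = ("error", "drop-residue", "map-common")

GAP = "-"


class SequenceError(ValueError):
    """Raised for malformed sequence data (bad alphabet, duplicate ids, ...)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single sanitized protein sequence.

    Attributes
    ----------
    id : str
        Non-empty identifier, unique within a dataset.
    sequence : str
        Uppercase string over the 20 canonical amino-acid letters.
    description : str
        Free-text remainder of the FASTA header (may be empty).
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceError(f"invalid record id: {self.id!r}")
        if not self.sequence:
            raise SequenceError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _CANONICAL_SET
        if bad:
            raise SequenceError(
                f"record {self.id!r} contains non-canonical residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Alignment:
    """A rectangular protein alignment (rows over the 20 letters plus '-')."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise SequenceError("ids and rows length mismatch")
        if len(self.rows) < 2:
            raise SequenceError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise SequenceError(f"ragged alignment: row lengths {sorted(lengths)}")
        if next(iter(lengths)) < 1:
            raise SequenceError("alignment has zero columns")
        if len(set(self.ids)) != len(self.ids):
            raise SequenceError("duplicate ids in alignment")
        allowed = _CANONICAL_SET | {GAP}
        for name, row in zip(self.ids, self.rows):
            bad = set(row) - allowed
            if bad:
                raise SequenceError(
                    f"alignment row {name!r} contains invalid symbols: {sorted(bad)}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def columns(self) -> "list[str]":
        return ["".join(row[j] for row in self.rows) for j in range(self.n_cols)]


def sanitize_sequence(raw: str, policy: str = "map-common") -> str:
    """Normalise a raw amino-acid string to the canonical 20-letter alphabet.

    Policies:

    ``error``
        raise on any non-canonical letter;
    ``drop-residue``
        delete every non-canonical letter;
    ``map-common``
        apply the conventional substitutions B->N, Z->Q, U->C, O->K, J->L,
        then drop whatever remains non-canonical (X, ``*``).

    Whitespace is always stripped and case is folded to upper before the
    policy applies. Raises :class:`SequenceError` if the result is empty.
    """
    if policy not in SANITIZE_POLICIES:
        raise ValueError(f"unknown sanitize policy {policy!r}")
    seq = re.sub(r"\s+", "", raw).upper()
    if not seq:
        raise SequenceError("empty sequence")
    if policy == "error":
        bad = set(seq) - _CANONICAL_SET
        if bad:
            raise SequenceError(f"non-canonical residues {sorted(bad)} under policy=error")
        out = seq
    else:
        if policy == "map-common":
            seq = seq.translate(str.maketrans(AMBIGUITY_MAP))
        out = "".join(c for c in seq if c in _CANONICAL_SET)
    if not out:
        raise SequenceError("sequence empty after sanitization")
    return out


def _header_to_id_desc(header: str) -> tuple[str, str]:
    parts = header.split(None, 1)
    return parts[0], (parts[1] if len(parts) > 1 else "")


def read_fasta(path: str | Path, policy: str = "map-common") -> list[ProteinRecord]:
    """Read a protein FASTA file into sanitized :class:`ProteinRecord` objects.

    The record id is the first whitespace-delimited token of the header.
    Raises :class:`SequenceError` on empty files, empty sequences and
    duplicate ids (the offending id is named in the message).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise SequenceError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)
        raw = str(rec.seq)
        if not raw:
            raise SequenceError(f"record {rid!r} in {path} has an empty sequence")
        _, desc = _header_to_id_desc(rec.description or rid)
        records.append(ProteinRecord(id=rid, sequence=sanitize_sequence(raw, policy), description=desc))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_alignment(path: str | Path, dialect: str = "aligned-fasta") -> Alignment:
    """Read a rectangular protein alignment.

    ``dialect`` is ``aligned-fasta`` or ``clustal`` (a CLUSTAL ``.aln`` file).
    Rows are returned in file order; rectangularity is enforced.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "aligned-fasta":
        fmt = "fasta"
    elif dialect == "clustal":
        fmt = "clustal"
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    if fmt == "fasta":
        # Parse record-by-record so ragged inputs raise our error, not Biopython's.
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
    else:
        aln = AlignIO.read(str(path), fmt)
        ids = [r.id for r in aln]
        rows = [str(r.seq).upper() for r in aln]
    if len(rows) < 2:
        raise SequenceError(f"alignment in {path} has fewer than 2 rows")
    return Alignment(ids=tuple(ids), rows=tuple(rows))


def write_alignment(aln: Alignment, path: str | Path, dialect: str = "aligned-fasta") -> None:
    """Write an alignment as aligned FASTA or CLUSTAL."""
    recs = [SeqRecord(Seq(row), id=name, description="") for name, row in zip(aln.ids, aln.rows)]
    if dialect == "aligned-fasta":
        SeqIO.write(recs, str(path), "fasta")
    elif dialect == "clustal":
        from Bio.Align import MultipleSeqAlignment

        AlignIO.write(MultipleSeqAlignment(recs), str(path), "clustal")
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


def _newick_label(name: str) -> str:
    if _NEWICK_UNSAFE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def tree_to_newick(tree) -> str:
    """Serialise a :class:`profam.phylo.PhyloTree` to a Newick string.

    Branch lengths are always written; bootstrap supports, when present,
    appear as internal node labels. Leaf names containing Newick
    metacharacters are single-quoted.
    """

    def render(node) -> str:
        if node.is_leaf():
            label = _newick_label(node.name)
        else:
            inner = ",".join(render(c) for c in node.children)
            label = f"({inner})"
            if node.support is not None:
                label += format(node.support, "g")
        if node.length is not None:
            label += f":{node.length:.10g}"
        return label

    root = tree.root
    if sum(1 for _ in root.iter_leaves()) < 2:
        raise ValueError("tree must have at least 2 leaves")
    inner = ",".join(render(c) for c in root.children)
    label = f"({inner})"
    if root.support is not None:
        label += format(root.support, "g")
    return label + ";"


def write_newick(tree, path: str | Path) -> None:
    """Write a tree to ``path`` in Newick format (see :func:`tree_to_newick`)."""
    Path(path).write_text(tree_to_newick(tree) + "\n")
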