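"""Sequence data model: containers, alignments, FASTA and Newick I/O.

Sequence sets come in two flavours: :class:`Container` (entries of arbitrary
lengths) and :class:`Alignment` (rectangular, one length for all entries).
Each entry carries a population label (a non-negative integer ``group``) and
an outgroup flag, encoded in FASTA headers with a trailing ``@k`` (group
``k``) or ``@#`` (outgroup).  A header without a tag means group 0, ingroup.

Sequences are DNA over ``{A, C, G, T}`` plus the missing-data symbols
``{N, ?, -}``; input is upper-cased, ``U`` is rejected.  Column indices are
0-based and intervals half-open throughout.

Phylogenetic trees are rooted, with optional node labels and non-negative
branch lengths (coalescent time units), read and written as Newick.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SequenceEntry",
    "Container",
    "Alignment",
    "Tree",
    "TreeNode",
    "SeqDataError",
    "NewickError",
    "read_fasta",
    "write_fasta",
    "extract",
    "concatenate",
    "parse_newick",
    "write_newick",
]

ALPHABET = frozenset("ACGT")
MISSING = frozenset("N?-")
VALID_CHARS = ALPHABET | MISSING

OUTGROUP_TAG = "#"


class SeqDataError(ValueError):
    """Malformed sequence data or invalid operation on a sequence set."""


@dataclass
class SequenceEntry:
    """One named sequence with its population label.

    Parameters
    ----------
    name : str
        Non-empty label (the FASTA header, minus the group tag).
    sequence : str
        Characters over ``{A,C,G,T,N,?,-}``; may be empty.
    group : int
        Non-negative population label; 0 by default.
    is_outgroup : bool
        Whether the entry is an outgroup sequence (used to polarise
        ancestral/derived alleles in diversity analyses).
    """

    name: str
    sequence: str
    group: int = 0
    is_outgroup: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise SeqDataError("sequence entry name must be non-empty")
        if self.group < 0:
            raise SeqDataError(f"group label must be >= 0, got {self.group}")
        seq = self.sequence.upper()
        bad = set(seq) - VALID_CHARS
        if bad:
            raise SeqDataError(
                f"record {self.name!r}: invalid character(s) "
                f"{''.join(sorted(bad))!r} (alphabet is ACGT plus N?-)"
            )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def tagged_name(self) -> str:
        """Name with the group/outgroup tag re-attached (FASTA dialect)."""
        tag = OUTGROUP_TAG if self.is_outgroup else str(self.group)
        return f"{self.name}@{tag}"


class Container:
    """Ordered collection of sequences of (possibly) unequal lengths."""

    def __init__(self, entries: Iterable[SequenceEntry] = ()) -> None:
        self._entries: list[SequenceEntry] = list(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[SequenceEntry]:
        return iter(self._entries)

    def __getitem__(self, index: int) -> SequenceEntry:
        return self._entries[index]

    def add(self, entry: SequenceEntry) -> None:
        self._entries.append(entry)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self._entries]

    @property
    def groups(self) -> list[int]:
        return [e.group for e in self._entries]

    def ingroup(self) -> list[SequenceEntry]:
        return [e for e in self._entries if not e.is_outgroup]

    def outgroup(self) -> list[SequenceEntry]:
        return [e for e in self._entries if e.is_outgroup]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Container):
            return NotImplemented
        return self._entries == other._entries

    def __repr__(self) -> str:
        return f"<{type(self).__name__}: {len(self)} entries>"


class Alignment(Container):
    """Rectangular sequence set: every entry has the same length."""

    def __init__(self, entries: Iterable[SequenceEntry] = ()) -> None:
        super().__init__(entries)
        self._check_rectangular()

    def _check_rectangular(self) -> None:
        lengths = {len(e) for e in self._entries}
        if len(lengths) > 1:
            raise SeqDataError(
                f"alignment entries have unequal lengths: {sorted(lengths)}"
            )

    def add(self, entry: SequenceEntry) -> None:
        if self._entries and len(entry) != self.length:
            raise SeqDataError(
                f"entry {entry.name!r} has length {len(entry)}, "
                f"alignment length is {self.length}"
            )
        super().add(entry)

    @property
    def length(self) -> int:
        """Number of columns (0 for an empty alignment)."""
        return len(self._entries[0]) if self._entries else 0

    def column(self, index: int) -> str:
        """Characters of one column, in entry order."""
        if not 0 <= index < self.length:
            raise IndexError(f"column {index} out of range [0, {self.length})")
        return "".join(e.sequence[index] for e in self._entries)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

PathOrStream = Union[str, os.PathLike, TextIO]


def _parse_header(header: str) -> tuple[str, int, bool]:
    """Split a FASTA header into (name, group, is_outgroup).

    The tag is the part after the last '@'; it must be a non-negative
    integer or '#'.  Anything else is part of the name.
    """
    name = header.strip()
    if "@" in name:
        stem, _, tag = name.rpartition("@")
        if stem:
            if tag == OUTGROUP_TAG:
                return stem, 0, True
            if tag.isdigit():
                return stem, int(tag), False
    return name, 0, False


def read_fasta(source: PathOrStream, alignment: bool = False) -> Container:
    """Read a FASTA file or stream into a :class:`Container` or :class:`Alignment`.

    Parameters
    ----------
    source : path or text stream
        FASTA input; group labels are taken from trailing ``@k`` / ``@#``
        header tags.
    alignment : bool
        If True, require equal sequence lengths and return an
        :class:`Alignment`; otherwise return a :class:`Container`.

    Raises
    ------
    SeqDataError
        On empty input, characters outside the alphabet (naming the
        offending record), or unequal lengths in alignment mode.
    """
    if hasattr(source, "read"):
        records = list(SimpleFastaParser(source))
    else:
        with open(source) as fh:
            records = list(SimpleFastaParser(fh))
    if not records:
        raise SeqDataError("empty FASTA input")
    entries = []
    for header, seq in records:
        name, group, is_out = _parse_header(header)
        entries.append(
            SequenceEntry(name=name, sequence=seq.replace(" ", ""),
                          group=group, is_outgroup=is_out)
        )
    if alignment:
        return Alignment(entries)
    return Container(entries)


def write_fasta(data: Container, sink: PathOrStream, line_width: int = 60) -> None:
    """Write a sequence set as FASTA, wrapping sequence lines at *line_width*.

    Headers always carry the group tag (``@k`` or ``@#``) so that
    ``read_fasta(write_fasta(x))`` reproduces names, groups, outgroup flags
    and sequences exactly.
    """
    if len(data) == 0:
        raise SeqDataError("refusing to write an empty sequence set")
    if line_width < 1:
        raise ValueError("line_width must be >= 1")

    def _dump(fh: TextIO) -> None:
        for entry in data:
            fh.write(f">{entry.tagged_name}\n")
            seq = entry.sequence
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")
            if not seq:
                fh.write("\n")

    if hasattr(sink, "write"):
        _dump(sink)
    else:
        with open(sink, "w") as fh:
            _dump(fh)


def fasta_str(data: Container, line_width: int = 60) -> str:
    """FASTA text of a sequence set (convenience wrapper)."""
    buf = io.StringIO()
    write_fasta(data, buf, line_width)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Alignment editing
# ---------------------------------------------------------------------------

def extract(aln: Alignment, columns: Sequence[int]) -> Alignment:
    """New alignment made of the requested columns, in the requested order.

    Names, groups and outgroup flags are preserved.  Indices are 0-based;
    an out-of-range index raises :class:`IndexError`.
    """
    length = aln.length
    for c in columns:
        if not 0 <= c < length:
            raise IndexError(f"column index {c} out of range [0, {length})")
    return Alignment(
        SequenceEntry(
            name=e.name,
            sequence="".join(e.sequence[c] for c in columns),
            group=e.group,
            is_outgroup=e.is_outgroup,
        )
        for e in aln
    )


def concatenate(alns: Sequence[Alignment]) -> Alignment:
    """Concatenate alignments locus by locus, matching entries by name.

    Every alignment must contain exactly the same multiset of names; the
    result's length is the sum of input lengths.  Group labels are taken
    from the first alignment.
    """
    if not alns:
        raise SeqDataError("nothing to concatenate")
    first = alns[0]
    ref_names = sorted(first.names)
    for k, aln in enumerate(alns[1:], start=2):
        if sorted(aln.names) != ref_names:
            missing = set(ref_names) ^ set(aln.names)
            raise SeqDataError(
                f"alignment {k} does not share the same names "
                f"(mismatch on {sorted(missing)})"
            )
    # index each alignment by name; duplicate names are consumed in order
    pools = []
    for aln in alns:
        pool: dict[str, list[SequenceEntry]] = {}
        for e in aln:
            pool.setdefault(e.name, []).append(e)
        pools.append(pool)
    out = []
    seen: dict[str, int] = {}
    for e in first:
        i = seen.get(e.name, 0)
        seen[e.name] = i + 1
        seq = "".join(pool[e.name][i].sequence for pool in pools)
        out.append(SequenceEntry(e.name, seq, e.group, e.is_outgroup))
    return Alignment(out)


# ---------------------------------------------------------------------------
# Trees and Newick
# ---------------------------------------------------------------------------

class NewickError(ValueError):
    """Newick syntax error; carries the character position."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass
class TreeNode:
    """Node of a rooted tree: optional label, optional branch length."""

    label: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        """Pre-order traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


@dataclass
class Tree:
    """Rooted tree with optional branch lengths (coalescent time units)."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label or "" for n in self.leaves()]

    def total_length(self) -> float:
        """Sum of all defined branch lengths."""
        return sum(n.length or 0.0 for n in self.root.walk())

    def depth(self) -> float:
        """Maximum root-to-leaf path length (TMRCA for ultrametric trees)."""

        def _d(node: TreeNode) -> float:
            own = node.length or 0.0
            return own + max((_d(c) for c in node.children), default=0.0)

        return max((_d(c) for c in self.root.children), default=0.0)


_NEWICK_SPECIALS = "(),:;"


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Supports nested groups, node labels, and ``:length`` suffixes; requires a
    terminating ``;``.  Errors report the offending character position.
    """
    pos = 0
    n = len(text)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def parse_label() -> str | None:
        nonlocal pos
        start = pos
        while pos < n and text[pos] not in _NEWICK_SPECIALS and not text[pos].isspace():
            pos += 1
        return text[start:pos] or None

    def parse_length() -> float | None:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == ":":
            pos += 1
            skip_ws()
            start = pos
            while pos < n and (text[pos] in "+-.eE" or text[pos].isdigit()):
                pos += 1
            try:
                value = float(text[start:pos])
            except ValueError:
                raise NewickError("invalid branch length", start) from None
            if value < 0:
                raise NewickError("negative branch length", start)
            return value
        return None

    def parse_node() -> TreeNode:
        nonlocal pos
        skip_ws()
        node = TreeNode()
        if pos < n and text[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            skip_ws()
            while pos < n and text[pos] == ",":
                pos += 1
                node.children.append(parse_node())
                skip_ws()
            if pos >= n or text[pos] != ")":
                raise NewickError("unbalanced parenthesis", pos)
            pos += 1
            skip_ws()
        node.label = parse_label()
        node.length = parse_length()
        return node

    skip_ws()
    if pos >= n:
        raise NewickError("empty input", 0)
    root = parse_node()
    skip_ws()
    if pos >= n or text[pos] != ";":
        raise NewickError("missing terminating ';'", pos)
    pos += 1
    skip_ws()
    if pos != n:
        raise NewickError("trailing characters after ';'", pos)
    return Tree(root)


def _format_length(x: float) -> str:
    return format(x, ".12g")


def write_newick(tree: Tree) -> str:
    """Serialise a :class:`Tree` to canonical Newick (ends with ';')."""

    def fmt(node: TreeNode) -> str:
        if node.children:
            inner = ",".join(fmt(c) for c in node.children)
            s = f"({inner})" + (node.label or "")
        else:
            s = node.label or ""
        if node.length is not None:
            s += ":" + _format_length(node.length)
        return s

    return fmt(tree.root) + ";"
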