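"""Sequence and structure containers, plus readers and writers.

Conventions used throughout the package:

* coordinates are 1-based inclusive;
* RNA sequences are uppercase strings over ``{A, C, G, U}`` (``T`` and
  lowercase input are normalized transparently);
* secondary structures are sets of base pairs split into two bracket
  layers of extended dot-bracket notation — ROUND (``(...)``) holds the
  first core stem, its extensions and all hairpins, SQUARE (``[...]``)
  holds the second core stem and its extensions.  Pairs within a layer
  must be mutually non-crossing; pairs of different layers may cross,
  which is what lets a pseudoknot be written unambiguously.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

from Bio import SeqIO

__all__ = [
    "Layer",
    "RnaSequence",
    "SecondaryStructure",
    "StructureFormatError",
    "parse_sequence",
    "read_fasta",
    "parse_dotbracket",
    "render_dotbracket",
    "write_bpseq",
]

_ALPHABET = set("ACGU")
_INPUT_ALPHABET = set("ACGUTacgut")


class StructureFormatError(ValueError):
    """Raised for malformed dot-bracket strings or invalid structures."""


class Layer(enum.Enum):
    """Bracket layer of a base pair in extended dot-bracket notation."""

    ROUND = "()"
    SQUARE = "[]"


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over {A, C, G, U}."""

    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty RNA sequence")
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)}; expected A/C/G/U")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def base(self, i: int) -> str:
        """Residue at 1-based position ``i``."""
        if not 1 <= i <= len(self.residues):
            raise IndexError(f"position {i} outside 1..{len(self.residues)}")
        return self.residues[i - 1]

    def __str__(self) -> str:
        return self.residues


@dataclass
class SecondaryStructure:
    """A set of base pairs on a sequence of given length, split into layers.

    ``pairs`` maps each pair ``(open, close)`` (1-based, open < close) to its
    :class:`Layer`.  Invariants — each index in at most one pair, and no
    crossing within a layer — are enforced on construction.
    """

    length: int
    pairs: Dict[Tuple[int, int], Layer] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("structure length must be >= 1")
        seen: Set[int] = set()
        for (i, j) in self.pairs:
            if not (1 <= i < j <= self.length):
                raise StructureFormatError(f"pair ({i},{j}) outside 1..{self.length}")
            if i in seen or j in seen:
                raise StructureFormatError(f"index reused by pair ({i},{j})")
            seen.update((i, j))
        for layer in Layer:
            members = sorted(p for p, lay in self.pairs.items() if lay is layer)
            for a in range(len(members)):
                i, j = members[a]
                for b in range(a + 1, len(members)):
                    k, l = members[b]
                    if i < k < j < l:
                        raise StructureFormatError(
                            f"crossing pairs ({i},{j}) and ({k},{l}) in layer {layer.name}"
                        )

    @property
    def pair_set(self) -> Set[Tuple[int, int]]:
        """The base pairs irrespective of layer."""
        return set(self.pairs)

    def layer_pairs(self, layer: Layer) -> List[Tuple[int, int]]:
        return sorted(p for p, lay in self.pairs.items() if lay is layer)

    def paired_positions(self) -> Set[int]:
        out: Set[int] = set()
        for i, j in self.pairs:
            out.update((i, j))
        return out

    def __len__(self) -> int:
        return self.length


def parse_sequence(text) -> RnaSequence:
    """Normalize raw text, a FASTA chunk, or a Bio.SeqRecord into an RnaSequence.

    DNA-style ``T`` is converted to ``U`` and lowercase to uppercase.
    Characters outside ``{A,C,G,U,T}`` (either case) are rejected.
    """
    if hasattr(text, "seq"):  # Bio.SeqRecord.SeqRecord
        text = str(text.seq)
    if not isinstance(text, str):
        raise TypeError("expected a string or a SeqRecord")
    text = text.strip()
    if text.startswith(">"):
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if not records:
            raise ValueError("no FASTA record found")
        text = str(records[0].seq)
    text = "".join(text.split())
    if not text:
        raise ValueError("empty sequence input")
    bad = set(text) - _INPUT_ALPHABET
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} in sequence input")
    return RnaSequence(text.upper().replace("T", "U"))


def read_fasta(path, all_records: bool = False):
    """Read one (default) or all RNA sequences from a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if all_records:
        return [parse_sequence(r) for r in records]
    return parse_sequence(records[0])


def render_dotbracket(structure: SecondaryStructure) -> str:
    """Render a structure as extended dot-bracket (ROUND → ``()``, SQUARE → ``[]``)."""
    chars = ["."] * structure.length
    for (i, j), layer in structure.pairs.items():
        open_ch, close_ch = layer.value
        chars[i - 1] = open_ch
        chars[j - 1] = close_ch
    return "".join(chars)


def parse_dotbracket(text: str, length: int | None = None) -> SecondaryStructure:
    """Parse extended dot-bracket text back into a :class:`SecondaryStructure`.

    Inverse of :func:`render_dotbracket`; unbalanced or unknown characters
    raise :class:`StructureFormatError`.
    """
    text = text.strip()
    if length is not None and len(text) != length:
        raise StructureFormatError(f"expected length {length}, got {len(text)}")
    if not text:
        raise StructureFormatError("empty dot-bracket string")
    pairs: Dict[Tuple[int, int], Layer] = {}
    stacks = {Layer.ROUND: [], Layer.SQUARE: []}
    opener = {"(": Layer.ROUND, "[": Layer.SQUARE}
    closer = {")": Layer.ROUND, "]": Layer.SQUARE}
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        if ch in opener:
            stacks[opener[ch]].append(pos)
        elif ch in closer:
            layer = closer[ch]
            if not stacks[layer]:
                raise StructureFormatError(f"unmatched '{ch}' at position {pos}")
            pairs[(stacks[layer].pop(), pos)] = layer
        else:
            raise StructureFormatError(f"unknown character '{ch}' at position {pos}")
    for layer, stack in stacks.items():
        if stack:
            raise StructureFormatError(
                f"unmatched '{layer.value[0]}' at position {stack[-1]}"
            )
    return SecondaryStructure(length=len(text), pairs=pairs)


def write_bpseq(seq: RnaSequence, structure: SecondaryStructure, handle) -> None:
    """Write a BPSEQ view: one line per base, ``index base partner`` (0 = unpaired)."""
    if structure.length != seq.length:
        raise ValueError("sequence/structure length mismatch")
    partner = {i: 0 for i in range(1, seq.length + 1)}
    for i, j in structure.pairs:
        partner[i] = j
        partner[j] = i
    own = isinstance(handle, (str, bytes)) or hasattr(handle, "__fspath__")
    fh = open(handle, "w") if own else handle
    try:
        for i in range(1, seq.length + 1):
            fh.write(f"{i} {seq.base(i)} {partner[i]}\n")
    finally:
        if own:
            fh.close()
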