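"""Protein sequences, point mutations, and mutant records.

The whole toolkit works on fixed-length protein sequences over the 20
canonical amino acids.  Mutations are substitutions only (no indels) and
are written in standard mutation notation, e.g. ``"K2A"`` for lysine at
position 2 replaced by alanine.  Positions are 1-based everywhere a user
sees them; conversion to 0-based array indices happens once, inside this
module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino-acid one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
#: Index of each residue letter in :data:`AMINO_ACIDS`.
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class SequenceError(ValueError):
    """Invalid residue string or sequence identifier."""


class MutationError(ValueError):
    """Invalid mutation token or mutation inapplicable to its parent."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identified protein sequence over the canonical 20-letter alphabet.

    Noncanonical letters (X, B, Z, U, O, gaps, stops) are rejected outright:
    every downstream model in the toolkit assumes the 20-letter alphabet, so
    silently mapping them would only defer the failure.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r}: noncanonical residues {sorted(bad)}; "
                f"only {AMINO_ACIDS} are accepted"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, position: int) -> str:
        """Residue at 1-based ``position``."""
        if not 1 <= position <= len(self.residues):
            raise MutationError(
                f"position {position} out of range 1..{len(self.residues)}"
            )
        return self.residues[position - 1]


@dataclass(frozen=True, order=True)
class Mutation:
    """A single substitution: ``wt_residue`` at 1-based ``position`` → ``new_residue``."""

    position: int
    wt_residue: str
    new_residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise MutationError(f"position must be >= 1, got {self.position}")
        for name, aa in (("wt", self.wt_residue), ("new", self.new_residue)):
            if aa not in _AA_SET:
                raise MutationError(f"{name} residue {aa!r} is not a canonical amino acid")
        if self.wt_residue == self.new_residue:
            raise MutationError(
                f"no-op mutation at position {self.position}: "
                f"{self.wt_residue} -> {self.new_residue}"
            )

    def __str__(self) -> str:
        return format_mutation(self)


@dataclass
class MutantRecord:
    """One GA individual: a mutated sequence plus its provenance and scores.

    ``mutations`` is always relative to the parent (in a GA run, the original
    wild type) and kept sorted by position; the mutation count therefore
    equals the Hamming distance to the parent.
    """

    parent_id: str
    mutations: tuple[Mutation, ...]
    sequence: ProteinSequence
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mutations = tuple(sorted(self.mutations))
        positions = [m.position for m in self.mutations]
        if len(set(positions)) != len(positions):
            raise MutationError(f"duplicate mutated positions: {positions}")

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)


def parse_mutation_string(text: str) -> Mutation:
    """Parse a token like ``"K2A"`` into a :class:`Mutation`."""
    m = _MUTATION_RE.match(text.strip())
    if m is None:
        raise MutationError(f"malformed mutation token {text!r}; expected e.g. 'K2A'")
    wt, pos, new = m.group(1), int(m.group(2)), m.group(3)
    return Mutation(position=pos, wt_residue=wt, new_residue=new)


def format_mutation(m: Mutation) -> str:
    """Format a :class:`Mutation` as ``<wt><position><new>``, e.g. ``"G10P"``."""
    return f"{m.wt_residue}{m.position}{m.new_residue}"


def parse_mutation_list(text: str) -> tuple[Mutation, ...]:
    """Parse a comma-joined mutation list such as ``"M1A,T3S"``."""
    text = text.strip()
    if not text:
        return ()
    return tuple(sorted(parse_mutation_string(tok) for tok in text.split(",")))


def format_mutation_list(mutations: Iterable[Mutation]) -> str:
    return ",".join(format_mutation(m) for m in sorted(mutations))


def apply_mutations(
    parent: ProteinSequence, mutations: Sequence[Mutation], *, child_id: str | None = None
) -> ProteinSequence:
    """Apply substitutions to ``parent``, returning a new sequence.

    Every mutation must reference a distinct in-range position and its
    ``wt_residue`` must match the parent there.
    """
    residues = list(parent.residues)
    seen: set[int] = set()
    for m in mutations:
        if not 1 <= m.position <= len(residues):
            raise MutationError(
                f"mutation {m}: position out of range 1..{len(residues)}"
            )
        if m.position in seen:
            raise MutationError(f"duplicate mutation position {m.position}")
        seen.add(m.position)
        actual = residues[m.position - 1]
        if actual != m.wt_residue:
            raise MutationError(
                f"mutation {m}: parent {parent.id!r} has {actual} at "
                f"position {m.position}, not {m.wt_residue}"
            )
        residues[m.position - 1] = m.new_residue
    if child_id is None:
        suffix = format_mutation_list(mutations) or "wt"
        child_id = f"{parent.id}|{suffix}"
    return ProteinSequence(id=child_id, residues="".join(residues))


def mutations_between(parent: ProteinSequence, child: ProteinSequence) -> tuple[Mutation, ...]:
    """Recover the sorted substitution set turning ``parent`` into ``child``."""
    if len(parent) != len(child):
        raise MutationError(
            f"length mismatch: {len(parent)} vs {len(child)} "
            f"({parent.id!r} vs {child.id!r})"
        )
    return tuple(
        Mutation(position=i + 1, wt_residue=a, new_residue=b)
        for i, (a, b) in enumerate(zip(parent.residues, child.residues))
        if a != b
    )


def hamming_distance(a: ProteinSequence | str, b: ProteinSequence | str) -> int:
    """Number of differing positions between two equal-length sequences."""
    sa = a.residues if isinstance(a, ProteinSequence) else a
    sb = b.residues if isinstance(b, ProteinSequence) else b
    if len(sa) != len(sb):
        raise MutationError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return sum(x != y for x, y in zip(sa, sb))


def make_mutant_record(
    wild_type: ProteinSequence, sequence: ProteinSequence, scores: dict[str, float] | None = None
) -> MutantRecord:
    """Build a :class:`MutantRecord` for ``sequence`` relative to ``wild_type``."""
    return MutantRecord(
        parent_id=wild_type.id,
        mutations=mutations_between(wild_type, sequence),
        sequence=sequence,
        scores=dict(scores or {}),
    )


# --- FASTA I/O -------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a (possibly multi-record) FASTA file of protein sequences.

    Line wrapping is arbitrary on read.  Ids must be unique within the file.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            ProteinSequence(
                id=rec.id,
                residues=str(rec.seq).upper(),
                description=rec.description,
            )
        )
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write sequences as FASTA wrapped at 60 columns."""
    recs = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description or "")
        for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(recs)
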