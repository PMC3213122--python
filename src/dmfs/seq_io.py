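"""FASTA input/output, alphabets and strand operations.

Sequences are plain Python strings over a declared alphabet (DNA or
protein).  Class labels are binary: 1 for the positive class, 0 for the
negative class.  The two-file convention used throughout the package is
one FASTA file per class.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

POSITIVE = 1
NEGATIVE = 0

_PROTEIN_SYMBOLS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Alphabet:
    """Residue alphabet over which sequences and motifs are defined.

    ``complementable`` is true only for DNA, where reverse-complement
    (strand) operations are meaningful.
    """

    name: str
    symbols: tuple[str, ...]
    complementable: bool

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def valid_residues(self) -> frozenset[str]:
        # N is tolerated on input for DNA (ambiguity), never in motifs.
        extra = ("N",) if self.complementable else ()
        return frozenset(self.symbols + extra)


DNA = Alphabet("DNA", ("A", "C", "G", "T"), complementable=True)
PROTEIN = Alphabet("PROTEIN", _PROTEIN_SYMBOLS, complementable=False)

_ALPHABETS = {"dna": DNA, "protein": PROTEIN}


def get_alphabet(name: str | Alphabet) -> Alphabet:
    """Resolve an alphabet from its name (case-insensitive) or pass through."""
    if isinstance(name, Alphabet):
        return name
    try:
        return _ALPHABETS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown alphabet {name!r}; expected 'dna' or 'protein'") from None


_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA_CHARS = frozenset("ACGTN")


def reverse_complement(s: str) -> str:
    """Reverse complement of a DNA string; N maps to N.

    Raises ``ValueError`` for non-DNA residues, so calling this on a
    protein sequence fails loudly rather than silently corrupting it.
    """
    if not _DNA_CHARS.issuperset(s):
        bad = sorted(set(s) - _DNA_CHARS)
        raise ValueError(f"reverse_complement is a DNA operation; found non-DNA residues {bad}")
    return s.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LabeledSequence:
    """A sequence with its binary class label."""

    id: str
    residues: str
    label: int

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"sequence {self.id!r}: label must be 0 or 1")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Dataset:
    """Labelled sequences over a common alphabet, with unique ids."""

    sequences: list[LabeledSequence]
    alphabet: Alphabet = field(default=DNA)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate sequence id {dup!r} in dataset")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    @property
    def labels(self) -> list[int]:
        return [s.label for s in self.sequences]

    @property
    def residues(self) -> list[str]:
        return [s.residues for s in self.sequences]

    def class_size(self, label: int) -> int:
        return sum(1 for s in self.sequences if s.label == label)

    def subset(self, ids: Iterable[str]) -> "Dataset":
        """Sub-dataset restricted to ``ids``, preserving input order."""
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"ids not in dataset: {sorted(missing)[:5]}")
        return Dataset([s for s in self.sequences if s.id in wanted], self.alphabet)

    def require_both_classes(self) -> None:
        if self.class_size(POSITIVE) == 0 or self.class_size(NEGATIVE) == 0:
            raise ValueError("dataset must contain at least one sequence of each class")


def _validate_residues(record_id: str, residues: str, alphabet: Alphabet) -> None:
    valid = alphabet.valid_residues()
    if not valid.issuperset(residues):
        bad = sorted(set(residues) - valid)
        raise ValueError(
            f"record {record_id!r}: residues {bad} not in {alphabet.name} alphabet"
        )


def read_fasta(path: str | Path, label: int, alphabet: Alphabet | str = DNA) -> list[LabeledSequence]:
    """Read one FASTA file, assigning every record the same class label.

    Residues are uppercased at read time (no soft-masking semantics).
    Records with residues outside the alphabet (other than N for DNA)
    raise a validation error naming the offending record.
    """
    alphabet = get_alphabet(alphabet)
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise ValueError(f"{path}: malformed FASTA (does not start with '>')")
    out: list[LabeledSequence] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        residues = str(rec.seq).upper()
        if not rec.id:
            raise ValueError(f"{path}: record with empty id")
        if not residues:
            raise ValueError(f"{path}: record {rec.id!r} has no residues")
        _validate_residues(rec.id, residues, alphabet)
        out.append(LabeledSequence(rec.id, residues, label))
    return out


def write_fasta(path: str | Path, sequences: Sequence[LabeledSequence]) -> None:
    """Write sequences to FASTA (id and residues round-trip exactly)."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def load_two_class(pos_path: str | Path, neg_path: str | Path,
                   alphabet: Alphabet | str = DNA) -> Dataset:
    """Load the positive/negative FASTA pair into a single dataset."""
    alphabet = get_alphabet(alphabet)
    seqs = read_fasta(pos_path, POSITIVE, alphabet) + read_fasta(neg_path, NEGATIVE, alphabet)
    return Dataset(seqs, alphabet)
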