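"""Degenerate-primer model: IUPAC matching and mismatch-counting semantics.

Every downstream module (virtual PCR, coverage statistics, synthetic data)
relies on the semantics fixed here:

* two IUPAC codes *match* iff the nucleotide sets they encode intersect,
  so an ``N`` in the subject sequence never counts as a mismatch
  (permissive, ecoPCR-style convention);
* mismatch counting is pure Hamming distance over that matching relation
  — no indels, no 3'-end weighting;
* input is case-insensitive and ``U`` is normalized to ``T``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

__all__ = [
    "IUPAC_SETS",
    "Primer",
    "PrimerSet",
    "iupac_match",
    "count_mismatches",
    "reverse_complement",
    "normalize_sequence",
    "load_primer_sets",
    "published_primer_sets",
]

#: IUPAC degenerate nucleotide alphabet -> the set of concrete bases encoded.
IUPAC_SETS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def normalize_sequence(seq: str) -> str:
    """Uppercase ``seq``, map U->T and validate every character.

    Raises
    ------
    ValueError
        If the sequence is empty or contains a character outside the
        IUPAC nucleotide alphabet; the message names the offender.
    """
    if not isinstance(seq, str):
        raise TypeError(f"sequence must be a string, got {type(seq).__name__}")
    out = seq.upper().replace("U", "T")
    if not out:
        raise ValueError("sequence must be non-empty")
    for ch in out:
        if ch not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC nucleotide code: {ch!r}")
    return out


def iupac_match(primer_base: str, sequence_base: str) -> bool:
    """True iff the base sets encoded by the two IUPAC codes intersect."""
    try:
        a = IUPAC_SETS[primer_base.upper().replace("U", "T")]
        b = IUPAC_SETS[sequence_base.upper().replace("U", "T")]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC nucleotide code: {exc.args[0]!r}") from None
    return bool(a & b)


def count_mismatches(primer: "Primer | str", window: str) -> int:
    """Hamming mismatch count of a primer against an equal-length window.

    A position mismatches iff :func:`iupac_match` is false there.  Indels
    are not modeled.
    """
    pseq = primer.sequence if isinstance(primer, Primer) else normalize_sequence(primer)
    wseq = normalize_sequence(window)
    if len(pseq) != len(wseq):
        raise ValueError(
            f"window length {len(wseq)} != primer length {len(pseq)}"
        )
    return sum(
        1 for p, w in zip(pseq, wseq) if not (IUPAC_SETS[p] & IUPAC_SETS[w])
    )


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string, degenerate codes included."""
    s = normalize_sequence(seq)
    return "".join(_COMPLEMENT[c] for c in reversed(s))


@dataclass(frozen=True)
class Primer:
    """A degenerate oligonucleotide, stored 5'->3'."""

    name: str
    sequence: str
    role: Literal["forward", "reverse"] = "forward"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"role must be 'forward' or 'reverse', got {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerSet:
    """A forward/reverse primer pair defining one assay."""

    name: str
    forward: Primer
    reverse: Primer

    def __post_init__(self) -> None:
        if self.forward.role != "forward":
            raise ValueError(f"forward primer {self.forward.name} has role {self.forward.role!r}")
        if self.reverse.role != "reverse":
            raise ValueError(f"reverse primer {self.reverse.name} has role {self.reverse.role!r}")

    @classmethod
    def from_sequences(cls, name: str, forward_seq: str, reverse_seq: str,
                       forward_name: str | None = None,
                       reverse_name: str | None = None) -> "PrimerSet":
        return cls(
            name=name,
            forward=Primer(forward_name or f"{name}-F", forward_seq, "forward"),
            reverse=Primer(reverse_name or f"{name}-R", reverse_seq, "reverse"),
        )


def load_primer_sets(path: str | Path) -> dict[str, PrimerSet]:
    """Read primer sets from a CSV/TSV.

    Expected columns: ``set_name, forward_name, forward_seq, reverse_name,
    reverse_seq``.  The delimiter is sniffed between comma and tab.
    """
    path = Path(path)
    text = path.read_text()
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    sets: dict[str, PrimerSet] = {}
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    required = {"set_name", "forward_name", "forward_seq", "reverse_name", "reverse_seq"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        missing = required - set(reader.fieldnames or [])
        raise ValueError(f"primer table missing columns: {sorted(missing)}")
    for row in reader:
        name = row["set_name"].strip()
        if name in sets:
            raise ValueError(f"duplicate primer set name: {name}")
        sets[name] = PrimerSet.from_sequences(
            name,
            row["forward_seq"].strip(),
            row["reverse_seq"].strip(),
            forward_name=row["forward_name"].strip(),
            reverse_name=row["reverse_name"].strip(),
        )
    return sets


def published_primer_sets() -> dict[str, PrimerSet]:
    """The three B-ARISA primer sets commonly evaluated in the field.

    Sequences are transcribed from the original publications describing
    1406f/23Sr, ITSF/ITSReub and S-D-Bact-1522-b-S-20/L-D-Bact-132-a-A-18;
    they ship as package data and are never hard-coded in the pipeline.
    """
    ref = resources.files("barisa").joinpath("data/primer_sets.csv")
    with resources.as_file(ref) as path:
        return load_primer_sets(path)
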