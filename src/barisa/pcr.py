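"""Virtual PCR engine.

Finds primer-pair binding sites within a per-primer mismatch budget on
both strands of each reference sequence and emits amplicons.  Matching is
bitmask-based: every IUPAC code is a 4-bit set over {A,C,G,T} and two
codes match iff their masks intersect, so the per-window mismatch profile
of a primer against a sequence is a short vectorized loop over primer
positions rather than a per-window scan.

Coordinates are 0-based half-open and always reported on the + strand;
the ``strand`` field records the orientation the product was found in.
The reverse primer is given 5'->3' and the engine searches for its
reverse complement downstream of a forward-primer site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .primers import IUPAC_SETS, Primer, PrimerSet, normalize_sequence, reverse_complement

__all__ = [
    "ReferenceRecord",
    "Amplicon",
    "AmplificationResult",
    "encode_iupac",
    "mismatch_profile",
    "find_primer_sites",
    "amplify_record",
    "amplify_database",
    "DEFAULT_LENGTH_BOUNDS",
]

#: Default full-product length filter: the ~100-1500 bp intergenic spacer
#: plus both primer footprints, left loose so no plausible product is hidden.
DEFAULT_LENGTH_BOUNDS: tuple[int, int] = (100, 2000)

_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_MASKS = {code: sum(_BASE_BITS[b] for b in bases) for code, bases in IUPAC_SETS.items()}

_LUT = np.zeros(256, dtype=np.uint8)
for _code, _mask in _CODE_MASKS.items():
    _LUT[ord(_code)] = _mask
    _LUT[ord(_code.lower())] = _mask
_LUT[ord("U")] = _BASE_BITS["T"]
_LUT[ord("u")] = _BASE_BITS["T"]


def encode_iupac(seq: str) -> np.ndarray:
    """Encode an IUPAC string as a uint8 array of 4-bit base-set masks."""
    try:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError:
        raise ValueError("sequence contains non-ASCII characters") from None
    masks = _LUT[raw]
    if masks.size and not masks.all():
        bad = seq[int(np.argmin(masks != 0))]
        raise ValueError(f"invalid IUPAC nucleotide code: {bad!r}")
    return masks


def mismatch_profile(seq_masks: np.ndarray, primer_masks: np.ndarray) -> np.ndarray:
    """Mismatch count of the primer against every window of the sequence.

    Returns an int array of length ``len(seq) - len(primer) + 1`` (empty if
    the primer is longer than the sequence).
    """
    n = seq_masks.size - primer_masks.size + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    for j in range(primer_masks.size):
        counts += (seq_masks[j : j + n] & primer_masks[j]) == 0
    return counts


def find_primer_sites(
    seq: str, primer: Primer | str, max_mismatch: int
) -> list[tuple[int, int, int]]:
    """All windows where the primer binds within the mismatch budget.

    Returns ``(start, end, mismatches)`` tuples in ascending start order,
    with 0-based half-open coordinates.  A primer longer than the sequence
    yields an empty list.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    pseq = primer.sequence if isinstance(primer, Primer) else normalize_sequence(primer)
    counts = mismatch_profile(encode_iupac(seq), encode_iupac(pseq))
    hits = np.flatnonzero(counts <= max_mismatch)
    plen = len(pseq)
    return [(int(s), int(s) + plen, int(counts[s])) for s in hits]


@dataclass(frozen=True)
class ReferenceRecord:
    """A database sequence, optionally tied to a taxonomy lineage."""

    record_id: str
    sequence: str
    lineage: object = None  # coverage.Lineage; kept loose to avoid a cycle

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))


@dataclass(frozen=True)
class Amplicon:
    """One virtual PCR product.

    All coordinates are 0-based half-open on the + strand.  ``fwd_*`` is
    the forward-primer footprint and ``rev_*`` the (reverse-complemented)
    reverse-primer footprint; for a ``-`` strand product the forward
    footprint therefore lies to the *right* of the reverse footprint in +
    coordinates.  ``inner_length`` counts the bases strictly between the
    two footprints (the spacer-borne length heterogeneity); ``full_length``
    includes both footprints.
    """

    record_id: str
    strand: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    inner_length: int
    full_length: int
    fwd_mismatches: int
    rev_mismatches: int
    primary: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        flen = self.fwd_end - self.fwd_start
        rlen = self.rev_end - self.rev_start
        if flen <= 0 or rlen <= 0:
            raise ValueError("primer footprints must have positive length")
        if self.strand == "+" and self.fwd_end > self.rev_start:
            raise ValueError("forward footprint overlaps reverse footprint")
        if self.strand == "-" and self.rev_end > self.fwd_start:
            raise ValueError("forward footprint overlaps reverse footprint")
        if self.full_length != self.inner_length + flen + rlen:
            raise ValueError("full_length != inner_length + primer footprints")


@dataclass
class AmplificationResult:
    """Per-database hit table for one primer set at one mismatch budget."""

    primer_set: str
    mismatch_budget: int
    amplicons: list[Amplicon] = field(default_factory=list)

    @property
    def amplified_record_ids(self) -> set[str]:
        return {a.record_id for a in self.amplicons}

    def primary_amplicons(self) -> dict[str, Amplicon]:
        """Per record, the amplicon flagged primary (shortest full product)."""
        return {a.record_id: a for a in self.amplicons if a.primary}

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "record_id", "strand", "fwd_start", "fwd_end", "rev_start", "rev_end",
            "inner_length", "full_length", "fwd_mismatches", "rev_mismatches", "primary",
        ]
        rows = [[getattr(a, c) for c in cols] for a in self.amplicons]
        df = pd.DataFrame(rows, columns=cols)
        df.insert(0, "mismatch_budget", self.mismatch_budget)
        df.insert(0, "primer_set", self.primer_set)
        return df


def _pair_sites_oriented(
    seq: str,
    n: int,
    strand: str,
    record_id: str,
    fwd_primer: Primer,
    rev_rc: str,
    max_mismatch: int,
    min_full: int,
    max_full: int,
) -> list[Amplicon]:
    """Pair forward sites with downstream reverse-complement sites on one
    orientation, mapping coordinates back to the + strand."""
    masks = encode_iupac(seq)
    fmasks = encode_iupac(fwd_primer.sequence)
    rmasks = encode_iupac(rev_rc)
    fcounts = mismatch_profile(masks, fmasks)
    rcounts = mismatch_profile(masks, rmasks)
    fhits = np.flatnonzero(fcounts <= max_mismatch)
    rhits = np.flatnonzero(rcounts <= max_mismatch)
    if fhits.size == 0 or rhits.size == 0:
        return []
    flen, rlen = len(fmasks), len(rmasks)
    out: list[Amplicon] = []
    for fs in fhits:
        fe = int(fs) + flen
        for rs in rhits:
            if rs < fe:
                continue
            re_ = int(rs) + rlen
            full = re_ - int(fs)
            if full < min_full:
                continue
            if full > max_full:
                break  # rhits ascending: all later pairs are longer
            inner = int(rs) - fe
            if strand == "+":
                coords = (int(fs), fe, int(rs), re_)
            else:
                coords = (n - fe, n - int(fs), n - re_, n - int(rs))
            out.append(
                Amplicon(
                    record_id=record_id,
                    strand=strand,
                    fwd_start=coords[0],
                    fwd_end=coords[1],
                    rev_start=coords[2],
                    rev_end=coords[3],
                    inner_length=inner,
                    full_length=full,
                    fwd_mismatches=int(fcounts[fs]),
                    rev_mismatches=int(rcounts[rs]),
                )
            )
    return out


def amplify_record(
    record: ReferenceRecord,
    primers: PrimerSet,
    max_mismatch: int,
    min_full_length: int = DEFAULT_LENGTH_BOUNDS[0],
    max_full_length: int = DEFAULT_LENGTH_BOUNDS[1],
) -> list[Amplicon]:
    """All amplicons of a primer set on one record, both strands searched.

    Every (forward site, downstream reverse-complemented reverse site) pair
    whose full length falls within bounds yields one amplicon; duplicates
    arising from palindromic degenerate hits are removed by the
    ``(record_id, strand, fwd_start, rev_end)`` key.
    """
    if not 0 < min_full_length <= max_full_length:
        raise ValueError("need 0 < min_full_length <= max_full_length")
    seq = record.sequence
    n = len(seq)
    rev_rc = reverse_complement(primers.reverse.sequence)
    amplicons: list[Amplicon] = []
    for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
        amplicons.extend(
            _pair_sites_oriented(
                oriented, n, strand, record.record_id,
                primers.forward, rev_rc, max_mismatch,
                min_full_length, max_full_length,
            )
        )
    seen: set[tuple] = set()
    unique: list[Amplicon] = []
    for a in amplicons:
        key = (a.record_id, a.strand, a.fwd_start, a.rev_end)
        if key not in seen:
            seen.add(key)
            unique.append(a)
    unique.sort(key=lambda a: (min(a.fwd_start, a.rev_start), a.full_length, a.strand))
    return unique


def _flag_primary(amps: list[Amplicon]) -> list[Amplicon]:
    """Flag the shortest full-length amplicon (ties: leftmost, + first)."""
    if not amps:
        return amps
    best = min(
        range(len(amps)),
        key=lambda i: (amps[i].full_length, min(amps[i].fwd_start, amps[i].rev_start),
                       amps[i].strand),
    )
    return [replace(a, primary=(i == best)) for i, a in enumerate(amps)]


def amplify_database(
    db: Iterable[ReferenceRecord],
    primers: PrimerSet,
    budgets: Sequence[int],
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> dict[int, AmplificationResult]:
    """Run virtual PCR over a database at each mismatch budget.

    Streams over records; each record is scanned once at the largest budget
    and its hits filtered down, so relaxing the budget can only add hits
    (amplified-record sets are nested across budgets).  Raises on duplicate
    record ids.
    """
    budgets = sorted(set(int(b) for b in budgets))
    if not budgets:
        raise ValueError("budgets must be non-empty")
    if budgets[0] < 0:
        raise ValueError("budgets must be >= 0")
    min_full, max_full = length_bounds
    results = {b: AmplificationResult(primers.name, b) for b in budgets}
    seen_ids: set[str] = set()
    for rec in db:
        if rec.record_id in seen_ids:
            raise ValueError(f"duplicate record_id: {rec.record_id}")
        seen_ids.add(rec.record_id)
        amps = amplify_record(rec, primers, budgets[-1], min_full, max_full)
        for b in budgets:
            sel = [a for a in amps if a.fwd_mismatches <= b and a.rev_mismatches <= b]
            results[b].amplicons.extend(_flag_primary(sel))
    return results
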