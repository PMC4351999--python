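"""File formats: FASTA references, taxonomy TSV, fingerprint and result
tables.

FASTA goes through Biopython; tabular formats through pandas.  The
taxonomy table is a TSV with columns ``record_id, phylum, class, order,
family, genus, species`` — cells may be empty below the deepest assigned
rank.  Fingerprints are long-format CSV: ``sample_id, fragment_length,
abundance``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .community import Fingerprint
from .coverage import RANKS, Lineage
from .pcr import AmplificationResult, ReferenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_taxonomy",
    "write_taxonomy",
    "load_reference_db",
    "write_reference_db",
    "read_fingerprints",
    "write_fingerprints",
    "read_groups",
    "write_amplicon_table",
]

_TAXONOMY_COLS = ["record_id", *RANKS]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (record_id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[ReferenceRecord | tuple[str, str]], path: str | Path) -> None:
    seqrecords = []
    for rec in records:
        if isinstance(rec, ReferenceRecord):
            rid, seq = rec.record_id, rec.sequence
        else:
            rid, seq = rec
        seqrecords.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seqrecords, str(path), "fasta")


def read_taxonomy(path: str | Path) -> dict[str, Lineage]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_TAXONOMY_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
    out: dict[str, Lineage] = {}
    for _, row in df.iterrows():
        rid = row["record_id"]
        if rid in out:
            raise ValueError(f"duplicate record_id in taxonomy: {rid}")
        out[rid] = Lineage.from_labels([row[r] or None for r in RANKS])
    return out


def write_taxonomy(taxonomy: Mapping[str, Lineage], path: str | Path) -> None:
    rows = [
        {"record_id": rid, **{r: lab or "" for r, lab in zip(RANKS, lin.labels())}}
        for rid, lin in taxonomy.items()
    ]
    pd.DataFrame(rows, columns=_TAXONOMY_COLS).to_csv(path, sep="\t", index=False)


def load_reference_db(
    fasta_path: str | Path, taxonomy_path: str | Path
) -> tuple[list[ReferenceRecord], dict[str, Lineage]]:
    """Load a FASTA + taxonomy TSV pair into annotated reference records."""
    taxonomy = read_taxonomy(taxonomy_path)
    records = [
        ReferenceRecord(rid, seq, taxonomy.get(rid))
        for rid, seq in read_fasta(fasta_path)
    ]
    return records, taxonomy


def write_reference_db(
    records: Sequence[ReferenceRecord],
    taxonomy: Mapping[str, Lineage],
    fasta_path: str | Path,
    taxonomy_path: str | Path,
) -> None:
    write_fasta(records, fasta_path)
    write_taxonomy(taxonomy, taxonomy_path)


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    df = pd.read_csv(path)
    required = {"sample_id", "fragment_length", "abundance"}
    if not required.issubset(df.columns):
        raise ValueError(f"fingerprint table missing columns: {sorted(required - set(df.columns))}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        peaks = list(zip(grp["fragment_length"].astype(float), grp["abundance"].astype(float)))
        out.append(Fingerprint(str(sid), peaks))
    return out


def write_fingerprints(fingerprints: Iterable[Fingerprint], path: str | Path) -> None:
    rows = [
        {"sample_id": fp.sample_id, "fragment_length": length, "abundance": abundance}
        for fp in fingerprints
        for length, abundance in fp.peaks
    ]
    pd.DataFrame(rows, columns=["sample_id", "fragment_length", "abundance"]).to_csv(
        path, index=False
    )


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a sample -> group TSV (columns sample_id, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(df.columns):
        raise ValueError("groups table needs columns: sample_id, group")
    return dict(zip(df["sample_id"], df["group"]))


def write_amplicon_table(
    results: Mapping[int, AmplificationResult] | AmplificationResult,
    path: str | Path,
) -> None:
    """Write one or several budgets' amplicon tables to a single CSV."""
    if isinstance(results, AmplificationResult):
        frames = [results.to_frame()]
    else:
        frames = [results[b].to_frame() for b in sorted(results)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
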