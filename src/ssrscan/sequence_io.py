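"""Reading, validating and writing CDS FASTA datasets.

A dataset is a list of :class:`SequenceRecord` — one full-length coding
sequence per gene, keyed by the first whitespace-delimited token of the FASTA
header.  The summed length of all records (not only the SSR-containing ones)
is the denominator for every per-Mbp density computed downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger("ssrscan")

#: Letters accepted in input sequences.  Ambiguity codes are retained but act
#: as hard breaks for repeat detection: no reported tract ever contains one.
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")


@dataclass(frozen=True)
class SequenceRecord:
    """One CDS: identifier plus validated, uppercase nucleotide string."""

    seq_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.seq_id or any(c.isspace() for c in self.seq_id):
            raise ValueError(f"invalid sequence identifier: {self.seq_id!r}")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"empty sequence for record {self.seq_id!r}")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"record {self.seq_id!r} contains non-nucleotide "
                f"characters: {sorted(bad)!r}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        """Sequence length in bp."""
        return len(self.sequence)


def read_cds_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record CDS FASTA file.

    Multi-line sequence bodies are concatenated, lowercase is mapped to
    uppercase, and records are returned in file order.  Duplicate record IDs
    and empty sequences raise ``ValueError``; an empty file yields an empty
    list with a logged warning.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    # FASTA requires the first non-blank line to be a header.
    with p.open() as fh:
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{p}: sequence data before first FASTA header"
                    )
                break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(p), "fasta"):
        seq_id = rec.id
        if seq_id in seen:
            raise ValueError(f"{p}: duplicate record ID {seq_id!r}")
        seen.add(seq_id)
        records.append(SequenceRecord(seq_id, str(rec.seq)))
    if not records:
        logger.warning("no FASTA records found in %s", p)
    return records


def write_cds_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as wrapped multi-FASTA (round-trips with the reader)."""
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def total_length_bp(records: Sequence[SequenceRecord]) -> int:
    """Total dataset length in bp, the per-Mbp normalization denominator."""
    return sum(rec.length for rec in records)
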