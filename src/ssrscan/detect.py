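"""Maximal perfect tandem-repeat detection and class I / class II assignment.

A perfect SSR tract is an uninterrupted repetition of a primitive motif of
period 1-10.  The scanner reports each tract once, at its smallest period,
with a whole-unit repeat count: the left end is character-maximal (the
character immediately left of the tract does not continue the period) and the
count is the floor of the character-maximal extent in whole units, so a
trailing partial unit neither counts nor extends the tract.  Non-ACGT letters
(N and IUPAC ambiguity codes) are hard breaks - no tract contains or spans
one.

Class assignment uses per-period minimum whole-repeat counts.  Class I
(nominally >= 20 bp of tract) is tested first; a run that misses the class I
minimum but meets the class II minimum (nominally 12-19 bp) is class II; runs
below both are dropped.  The default tables:

==========  =======  ========
period      class I  class II
==========  =======  ========
1 monomer   20       12
2 dimer     10       6
3 trimer    7        4
4 tetramer  5        3
5 pentamer  4        3
6 hexamer   4        2
7 heptamer  3        2
8 octamer   3        2
9 nonamer   3        2
10 decamer  2        (none)
==========  =======  ========

Decamers have no class II entry, so they never appear in class II output.
"""

from __future__ import annotations

import csv
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np

from .motifs import canonical_motif, richness, smallest_period
from .sequence_io import SequenceRecord

CLASS_I_MIN_REPEATS: Mapping[int, int] = MappingProxyType(
    {1: 20, 2: 10, 3: 7, 4: 5, 5: 4, 6: 4, 7: 3, 8: 3, 9: 3, 10: 2}
)
CLASS_II_MIN_REPEATS: Mapping[int, int] = MappingProxyType(
    {1: 12, 2: 6, 3: 4, 4: 3, 5: 3, 6: 2, 7: 2, 8: 2, 9: 2}
)


@dataclass(frozen=True)
class ThresholdTable:
    """Minimum whole-repeat counts per motif period for one SSR class.

    A period absent from ``min_repeats`` is not searched for that class.
    """

    ssr_class: str
    min_repeats: Mapping[int, int]

    def __post_init__(self) -> None:
        if self.ssr_class not in ("I", "II"):
            raise ValueError(f"unknown SSR class {self.ssr_class!r}")
        table = dict(self.min_repeats)
        for k, v in table.items():
            if not 1 <= int(k) <= 10:
                raise ValueError(f"motif period {k} outside 1..10")
            if int(v) < 2:
                raise ValueError(
                    f"minimum repeat count for period {k} must be >= 2"
                )
        object.__setattr__(
            self,
            "min_repeats",
            MappingProxyType({int(k): int(v) for k, v in table.items()}),
        )


CLASS_I = ThresholdTable("I", CLASS_I_MIN_REPEATS)
CLASS_II = ThresholdTable("II", CLASS_II_MIN_REPEATS)


class Run(NamedTuple):
    """A maximal perfect repeat run, before class assignment."""

    start: int
    period: int
    repeat_count: int
    motif: str


@dataclass(frozen=True)
class SSRLocus:
    """A detected perfect repeat tract on one sequence.

    Coordinates are 0-based half-open on the input strand; ``motif`` is the
    first repeat unit as it appears in the sequence, ``canonical_motif`` its
    class representative under rotation and reverse complement.
    """

    seq_id: str
    start: int
    end: int
    motif: str
    period: int
    repeat_count: int
    tract_length: int
    ssr_class: str
    canonical_motif: str
    richness: str


_A, _C, _G, _T = (ord(b) for b in "ACGT")


def _runs_in_array(
    a: np.ndarray,
    text: str,
    k_range: Iterable[int],
    min_units: Optional[Mapping[int, int]],
) -> list[Run]:
    """Vectorized maximal-run scan over a uint8 view of ``text``."""
    n = int(a.size)
    if n == 0:
        return []
    valid = (a == _A) | (a == _C) | (a == _G) | (a == _T)
    out: list[Run] = []
    for k in sorted(set(int(k) for k in k_range)):
        if not 1 <= k <= 10:
            raise ValueError(f"motif period {k} outside 1..10")
        need = 2 if min_units is None else max(2, int(min_units.get(k, 2)))
        if n < k * need:
            continue
        # m[p] == True  <=>  positions p and p+k match and are plain ACGT
        m = (a[k:] == a[:-k]) & valid[k:] & valid[:-k]
        if not m.any():
            continue
        pad = np.zeros(m.size + 2, dtype=np.int8)
        pad[1:-1] = m
        edges = np.diff(pad)
        starts = np.flatnonzero(edges == 1)
        lens = np.flatnonzero(edges == -1) - starts
        keep = lens >= (need - 1) * k
        for s0, true_len in zip(starts[keep].tolist(), lens[keep].tolist()):
            count = true_len // k + 1
            motif = text[s0 : s0 + k]
            if smallest_period(motif) != k:
                continue  # reported at its primitive period instead
            out.append(Run(s0, k, count, motif))
    out.sort(key=lambda r: (r.start, r.period))
    return out


def find_maximal_runs(
    sequence: str,
    k_range: Iterable[int] = range(1, 11),
    min_units: Optional[Mapping[int, int]] = None,
) -> list[Run]:
    """All maximal perfect runs with primitive period in ``k_range``.

    Every returned run has a whole-unit ``repeat_count`` of at least 2 (or at
    least ``min_units[k]`` when given, a pruning device for threshold-aware
    scans); runs are reported in ascending start order.  The empty sequence
    yields an empty list.
    """
    if not sequence:
        return []
    a = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _runs_in_array(a, sequence, k_range, min_units)


def classify_repeat(
    period: int,
    repeat_count: int,
    class1: ThresholdTable = CLASS_I,
    class2: ThresholdTable = CLASS_II,
) -> Optional[str]:
    """Class of a run under the two threshold tables, or None if below both.

    Class I takes precedence, mirroring the redundancy filtering of a class II
    search that also retrieves class I hits.
    """
    m1 = class1.min_repeats.get(period)
    if m1 is not None and repeat_count >= m1:
        return "I"
    m2 = class2.min_repeats.get(period)
    if m2 is not None and repeat_count >= m2:
        return "II"
    return None


def _combined_scan_params(
    class1: ThresholdTable, class2: ThresholdTable
) -> tuple[list[int], dict[int, int]]:
    ks = sorted(set(class1.min_repeats) | set(class2.min_repeats))
    big = 10**9
    mins = {
        k: min(class1.min_repeats.get(k, big), class2.min_repeats.get(k, big))
        for k in ks
    }
    return ks, mins


def _locus(seq_id: str, run: Run, ssr_class: str, offset: int = 0) -> SSRLocus:
    start = run.start - offset
    return SSRLocus(
        seq_id=seq_id,
        start=start,
        end=start + run.period * run.repeat_count,
        motif=run.motif,
        period=run.period,
        repeat_count=run.repeat_count,
        tract_length=run.period * run.repeat_count,
        ssr_class=ssr_class,
        canonical_motif=canonical_motif(run.motif),
        richness=richness(run.motif),
    )


def detect_ssrs(
    record: SequenceRecord,
    class1: ThresholdTable = CLASS_I,
    class2: ThresholdTable = CLASS_II,
) -> list[SSRLocus]:
    """Detect and classify all perfect SSR loci in one record.

    Each physical tract appears at most once; class I takes precedence over
    class II.  Runs below both class minima are dropped.
    """
    ks, mins = _combined_scan_params(class1, class2)
    loci = []
    for run in find_maximal_runs(record.sequence, ks, mins):
        cls = classify_repeat(run.period, run.repeat_count, class1, class2)
        if cls is not None:
            loci.append(_locus(record.seq_id, run, cls))
    return loci


def detect_in_records(
    records: Sequence[SequenceRecord],
    class1: ThresholdTable = CLASS_I,
    class2: ThresholdTable = CLASS_II,
) -> list[SSRLocus]:
    """Detect loci across a dataset in one pass.

    Equivalent to concatenating per-record :func:`detect_ssrs` calls but scans
    a single joined string ('N' separators keep tracts from crossing record
    boundaries), which is substantially faster on many short records.
    """
    if not records:
        return []
    big = "N".join(rec.sequence for rec in records)
    offsets = [0]
    for rec in records:
        offsets.append(offsets[-1] + rec.length + 1)
    ks, mins = _combined_scan_params(class1, class2)
    loci = []
    for run in find_maximal_runs(big, ks, mins):
        cls = classify_repeat(run.period, run.repeat_count, class1, class2)
        if cls is None:
            continue
        idx = bisect_right(offsets, run.start) - 1
        loci.append(_locus(records[idx].seq_id, run, cls, offset=offsets[idx]))
    return loci


LOCUS_TSV_COLUMNS = (
    "seq_id",
    "start0",
    "end0",
    "motif",
    "period",
    "repeats",
    "length_bp",
    "ssr_class",
    "canonical_motif",
    "richness",
)


def loci_to_tsv(loci: Iterable[SSRLocus], path: str | Path) -> None:
    """Write loci as TSV with 0-based half-open coordinates."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(LOCUS_TSV_COLUMNS)
        for l in loci:
            writer.writerow(
                (
                    l.seq_id,
                    l.start,
                    l.end,
                    l.motif,
                    l.period,
                    l.repeat_count,
                    l.tract_length,
                    l.ssr_class,
                    l.canonical_motif,
                    l.richness,
                )
            )


def loci_to_gff3(loci: Iterable[SSRLocus], path: str | Path) -> None:
    """Write loci as GFF3 microsatellite features (1-based inclusive)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for l in loci:
            attrs = (
                f"motif={l.motif};repeats={l.repeat_count};"
                f"ssr_class={l.ssr_class};canonical_motif={l.canonical_motif}"
            )
            fh.write(
                "\t".join(
                    (
                        l.seq_id,
                        "ssrscan",
                        "microsatellite",
                        str(l.start + 1),
                        str(l.end),
                        ".",
                        "+",
                        ".",
                        attrs,
                    )
                )
                + "\n"
            )
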