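"""Synthetic CDS datasets with planted, ground-truthed SSR tracts.

The generator emulates gene-model FASTA inputs: gene-sized records drawn from
an i.i.d. nucleotide background with a configurable GC fraction, with perfect
SSR tracts of known motif, repeat count and position spliced in.  Planting
mutates up to one flanking base per side ("guard" bases) so the tract is not
extendable in either direction, and the whole dataset is reconciled against
the detector until the planted truth is exactly the detected locus set -
background that happens to contain a thresholded repeat is locally resampled,
so precision and recall against truth are 1.0 by construction.  Everything is
deterministic given the seed.

The background model is i.i.d. with a GC knob and no codon structure; it
captures repeat presence/absence and composition, which is what the
downstream density and heterogeneity analyses consume.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .detect import (
    CLASS_I,
    CLASS_II,
    SSRLocus,
    ThresholdTable,
    classify_repeat,
    detect_in_records,
)
from .motifs import is_primitive
from .sequence_io import SequenceRecord, write_cds_fasta

_BASE_BYTES = tuple(b"ACGT")  # (65, 67, 71, 84)


@dataclass(frozen=True)
class TruthRecord:
    """A planted SSR tract, for detector recovery scoring."""

    seq_id: str
    start: int
    end: int
    motif: str
    period: int
    repeat_count: int
    intended_class: Optional[str]

    @property
    def key(self) -> tuple[str, int, int, int]:
        return (self.seq_id, self.start, self.end, self.period)


@dataclass(frozen=True)
class PlantInstruction:
    """Plant ``motif`` x ``repeat_count`` into ``n_genes`` distinct spots."""

    motif: str
    repeat_count: int
    n_genes: int


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for one synthetic dataset.

    ``gene_length`` is a uniform (min, max) range in bp; ``codon_aligned``
    places every tract at a position divisible by 3 for clean amino-acid
    profiling; the seed fully determines the output.
    """

    n_genes: int
    gene_length: tuple[int, int] = (400, 1200)
    gc: float = 0.5
    plants: tuple[PlantInstruction, ...] = ()
    codon_aligned: bool = False
    seed: int = 0
    dataset_name: str = "synthetic"


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return np.array(_BASE_BYTES, dtype=np.uint8)[rng.choice(4, size=n, p=p)]


def _other_base(byte: int, rng: Optional[np.random.Generator]) -> int:
    choices = [b for b in _BASE_BYTES if b != byte]
    if rng is None:
        return choices[0]
    return int(choices[int(rng.integers(len(choices)))])


def _splice_plant(
    arr: np.ndarray,
    pos: int,
    motif: str,
    repeat_count: int,
    rng: Optional[np.random.Generator] = None,
) -> None:
    """Write motif x repeat_count at ``pos`` and fix guard bases in place.

    The base left of the tract must not continue the period backwards
    (it may not equal the motif's last base) and the base right of the tract
    must not start a partial extra unit (it may not equal the first base).
    """
    unit = motif.encode("ascii")
    tract = np.frombuffer(unit * repeat_count, dtype=np.uint8)
    arr[pos : pos + tract.size] = tract
    if pos >= 1 and arr[pos - 1] == unit[-1]:
        arr[pos - 1] = _other_base(unit[-1], rng)
    j = pos + tract.size
    if j < arr.size and arr[j] == unit[0]:
        arr[j] = _other_base(unit[0], rng)


def generate_background(
    length: int,
    gc: float,
    seed: int,
    class1: ThresholdTable = CLASS_I,
    class2: ThresholdTable = CLASS_II,
    max_rounds: int = 60,
) -> str:
    """An SSR-free i.i.d. nucleotide string with expected GC = ``gc``.

    Tracts that happen to meet either class threshold are resampled locally
    until the detector finds nothing; configurations that cannot converge
    raise ``RuntimeError`` after ``max_rounds`` passes.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be strictly between 0 and 1")
    if length < 0:
        raise ValueError("length must be non-negative")
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    arr = _random_bases(rng, length, gc)
    for _ in range(max_rounds):
        rec = SequenceRecord("bg", arr.tobytes().decode("ascii"))
        loci = detect_in_records([rec], class1, class2)
        if not loci:
            return rec.sequence
        for locus in loci:
            arr[locus.start : locus.end] = _random_bases(
                rng, locus.tract_length, gc
            )
    raise RuntimeError(
        f"background (length={length}, gc={gc}) still contains SSRs "
        f"after {max_rounds} resampling rounds"
    )


def plant_ssr(
    sequence: str,
    motif: str,
    repeat_count: int,
    position: int,
    seq_id: str = "",
    class1: ThresholdTable = CLASS_I,
    class2: ThresholdTable = CLASS_II,
    reserved: Sequence[tuple[int, int]] = (),
) -> tuple[str, TruthRecord]:
    """Splice a perfect tract into ``sequence`` at ``position``.

    The motif must be primitive and the tract must fit with at least one
    guard base on each side; ``reserved`` intervals (existing planted tracts,
    0-based half-open) may not be overlapped.  Guard bases are mutated
    deterministically if they would extend the tract.
    """
    motif = motif.upper()
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    if repeat_count < 2:
        raise ValueError("repeat_count must be >= 2")
    tract_len = len(motif) * repeat_count
    if position < 1 or position + tract_len > len(sequence) - 1:
        raise ValueError("tract does not fit with one-base guard flanks")
    end = position + tract_len
    for s, e in reserved:
        if position - 1 < e and s < end + 1:
            raise ValueError("tract overlaps an existing planted tract")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    _splice_plant(arr, position, motif, repeat_count)
    truth = TruthRecord(
        seq_id,
        position,
        end,
        motif,
        len(motif),
        repeat_count,
        classify_repeat(len(motif), repeat_count, class1, class2),
    )
    return arr.tobytes().decode("ascii"), truth


def _validate_config(config: GeneratorConfig) -> None:
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = config.gene_length
    if not 0 < lo <= hi:
        raise ValueError("gene_length must satisfy 0 < min <= max")
    if not 0 < config.gc < 1:
        raise ValueError("gc must be strictly between 0 and 1")
    for inst in config.plants:
        motif = inst.motif.upper()
        if not is_primitive(motif):
            raise ValueError(f"plant motif {motif!r} is not primitive")
        if inst.n_genes < 0:
            raise ValueError("plant n_genes must be >= 0")
        if classify_repeat(len(motif), inst.repeat_count) is None:
            raise ValueError(
                f"plant {motif}x{inst.repeat_count} is below both class "
                "thresholds and would be undetectable"
            )


def _build_gene(
    rng: np.random.Generator,
    seq_id: str,
    length: int,
    plants: Sequence[tuple[str, int]],
    config: GeneratorConfig,
) -> tuple[np.ndarray, list[TruthRecord]]:
    arr = _random_bases(rng, length, config.gc)
    rows: list[TruthRecord] = []
    if not plants:
        return arr, rows
    block = length // len(plants)
    for j, (motif, count) in enumerate(plants):
        tract_len = len(motif) * count
        lo = j * block + 1
        hi = (j + 1) * block - tract_len - 1
        if hi < lo + 3:
            raise ValueError(
                f"infeasible packing: gene of {length} bp cannot hold "
                f"{len(plants)} tract(s) of {tract_len} bp with guards"
            )
        pos = int(rng.integers(lo, hi + 1))
        if config.codon_aligned:
            pos -= pos % 3
            if pos < lo:
                pos += 3
        _splice_plant(arr, pos, motif, count, rng)
        rows.append(
            TruthRecord(
                seq_id,
                pos,
                pos + tract_len,
                motif,
                len(motif),
                count,
                classify_repeat(len(motif), count),
            )
        )
    return arr, rows


def generate_dataset(
    config: GeneratorConfig,
    fasta_path: Optional[str | Path] = None,
    truth_path: Optional[str | Path] = None,
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Generate a dataset whose complete SSR content is the planted truth.

    Plants are distributed over randomly chosen genes (several per gene when
    instructions outnumber genes), and the dataset is reconciled against
    :func:`ssrscan.detect.detect_in_records` under the default threshold
    tables: spurious background repeats are resampled and genes whose planted
    tracts were disturbed are rebuilt, until detection equals truth exactly.
    Deterministic per seed; optionally writes FASTA and truth TSV.
    """
    _validate_config(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    lo, hi = config.gene_length
    lengths = [int(v) for v in rng.integers(lo, hi + 1, size=n)]
    ids = [f"g{i + 1:06d}" for i in range(n)]

    instances: list[tuple[str, int]] = []
    for inst in config.plants:
        instances.extend([(inst.motif.upper(), inst.repeat_count)] * inst.n_genes)
    order = [int(v) for v in rng.permutation(n)]
    gene_plants: dict[int, list[tuple[str, int]]] = {}
    for idx, item in enumerate(instances):
        gene_plants.setdefault(order[idx % n], []).append(item)

    arrays: list[np.ndarray] = []
    truths: dict[int, list[TruthRecord]] = {}
    for i in range(n):
        arr, rows = _build_gene(
            rng, ids[i], lengths[i], gene_plants.get(i, []), config
        )
        arrays.append(arr)
        truths[i] = rows

    idx_of = {sid: i for i, sid in enumerate(ids)}
    for _ in range(50):
        records = [
            SequenceRecord(ids[i], arrays[i].tobytes().decode("ascii"))
            for i in range(n)
        ]
        detected = detect_in_records(records)
        det_keys = {(l.seq_id, l.start, l.end, l.period) for l in detected}
        truth_keys = {t.key for rows in truths.values() for t in rows}
        extras = sorted(det_keys - truth_keys)
        missing = sorted(truth_keys - det_keys)
        if not extras and not missing:
            break
        rebuild = {idx_of[k[0]] for k in missing}
        for sid, s, e, _k in extras:
            i = idx_of[sid]
            if i in rebuild:
                continue
            protected = np.zeros(arrays[i].size, dtype=bool)
            for t in truths[i]:
                protected[max(0, t.start - 1) : t.end + 1] = True
            span = np.arange(s, e)
            free = span[~protected[s:e]]
            if free.size == 0:
                rebuild.add(i)
                continue
            arrays[i][free] = _random_bases(rng, free.size, config.gc)
        for i in sorted(rebuild):
            arrays[i], truths[i] = _build_gene(
                rng, ids[i], lengths[i], gene_plants.get(i, []), config
            )
    else:
        raise RuntimeError(
            "could not reconcile generated dataset with planted truth"
        )

    truth_list = sorted(
        (t for rows in truths.values() for t in rows),
        key=lambda t: (t.seq_id, t.start),
    )
    if fasta_path is not None:
        write_cds_fasta(records, fasta_path)
    if truth_path is not None:
        write_truth_tsv(truth_list, truth_path)
    return records, truth_list


TRUTH_TSV_COLUMNS = (
    "seq_id",
    "start0",
    "end0",
    "motif",
    "period",
    "repeat_count",
    "intended_class",
)


def write_truth_tsv(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_TSV_COLUMNS)
        for t in truth:
            writer.writerow(
                (
                    t.seq_id,
                    t.start,
                    t.end,
                    t.motif,
                    t.period,
                    t.repeat_count,
                    t.intended_class or "",
                )
            )


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    out = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                TruthRecord(
                    row["seq_id"],
                    int(row["start0"]),
                    int(row["end0"]),
                    row["motif"],
                    int(row["period"]),
                    int(row["repeat_count"]),
                    row["intended_class"] or None,
                )
            )
    return out


@dataclass(frozen=True)
class RecoveryReport:
    """Exact-interval scoring of detected loci against planted truth."""

    precision: float
    recall: float
    n_truth: int
    n_detected: int
    n_matched: int
    confusion: dict[tuple[str, str], int] = field(hash=False)


def recovery_report(
    truth: Sequence[TruthRecord], detected: Sequence[SSRLocus]
) -> RecoveryReport:
    """Match on (seq_id, start, end, period); precision = matched/detected,
    recall = matched/truth (1.0 for empty denominators).  The confusion map
    counts matched pairs by (intended class, detected class)."""
    tmap = {t.key: t for t in truth}
    dmap = {(l.seq_id, l.start, l.end, l.period): l for l in detected}
    matched = tmap.keys() & dmap.keys()
    confusion: dict[tuple[str, str], int] = {}
    for key in matched:
        pair = (tmap[key].intended_class or "-", dmap[key].ssr_class)
        confusion[pair] = confusion.get(pair, 0) + 1
    precision = len(matched) / len(dmap) if dmap else 1.0
    recall = len(matched) / len(tmap) if tmap else 1.0
    return RecoveryReport(
        precision, recall, len(tmap), len(dmap), len(matched), confusion
    )
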