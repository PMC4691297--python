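"""Dataset-level aggregation: gene tallies, per-Mbp densities, canonical
class tables, richness partitions, nucleotide differentials and amino-acid
repeat profiles.

The headline "SSR counts per Mbp" of a class excludes mononucleotide loci by
default (``include_monomers`` restores them): monomer runs are hard to assay
reliably and most repeat surveys drop them from everything except the
by-period density table, which here always carries every searched period so
the monomer row remains visible.  Nucleotide differentials count ONE motif
copy per locus, not the whole tract, so per class they sum to the sum of
periods over loci.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .detect import SSRLocus
from .motifs import RICHNESS_CATEGORIES, motif_nucleotide_counts
from .sequence_io import SequenceRecord, total_length_bp

SSR_CLASSES = ("I", "II")


def counts_per_mbp(n: float, total_bp: int) -> float:
    """Loci (or any count) per megabase pair of analyzed sequence."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    return n / (total_bp / 1e6)


@dataclass(frozen=True)
class AminoAcidProfile:
    """Per-class amino-acid tallies of codons fully inside SSR tracts.

    ``counts`` maps SSR class to {one-letter code: count}; stop codons are
    tallied separately in ``stops`` and excluded from the amino-acid maps.
    """

    counts: Mapping[str, Mapping[str, int]]
    stops: Mapping[str, int]


def amino_acid_profile(
    records: Sequence[SequenceRecord], loci: Sequence[SSRLocus]
) -> AminoAcidProfile:
    """Translate the codons lying entirely within each tract, in the gene's
    frame (anchored at sequence position 0), and tally occurrences per class.

    Loci shorter than one in-frame codon contribute nothing.
    """
    seq_by_id = {rec.seq_id: rec.sequence for rec in records}
    counts = {cls: Counter() for cls in SSR_CLASSES}
    stops = {cls: 0 for cls in SSR_CLASSES}
    for locus in loci:
        try:
            seq = seq_by_id[locus.seq_id]
        except KeyError:
            raise ValueError(f"locus references unknown record {locus.seq_id!r}")
        first_codon = -(-locus.start // 3) * 3  # next frame-0 boundary
        n_codons = (locus.end - first_codon) // 3
        if n_codons <= 0:
            continue
        aa = str(Seq(seq[first_codon : first_codon + 3 * n_codons]).translate())
        for ch in aa:
            if ch == "*":
                stops[locus.ssr_class] += 1
            else:
                counts[locus.ssr_class][ch] += 1
    return AminoAcidProfile(
        {cls: dict(counts[cls]) for cls in SSR_CLASSES}, dict(stops)
    )


@dataclass(frozen=True)
class ClassSummary:
    """Aggregates for one SSR class within one dataset."""

    ssr_class: str
    n_loci: int
    n_loci_with_monomers: int
    n_genes_with_ssr: int
    density: float
    mean_tract_length: float
    sd_tract_length: float
    counts_per_mbp_by_period: Mapping[int, float]
    counts_per_mbp_by_canonical: Mapping[int, Mapping[str, float]]
    richness_density: Mapping[str, float]
    nt_differential_density: Mapping[str, float]
    aa_tally: Mapping[str, int]
    stop_codon_tally: int
    tract_lengths: tuple[int, ...] = field(repr=False)


@dataclass(frozen=True)
class SpeciesSummary:
    """Per-dataset tables: gene counts, densities, composition, amino acids."""

    dataset_name: str
    n_genes: int
    total_bp: int
    include_monomers: bool
    per_class: Mapping[str, ClassSummary]
    n_genes_with_both_classes: int


def _mean_sd(values: Sequence[int]) -> tuple[float, float]:
    if not values:
        return (math.nan, math.nan)
    mean = sum(values) / len(values)
    var = sum((v - mean) ** 2 for v in values) / len(values)  # population SD
    return (mean, math.sqrt(var))


def canonical_density_table(
    loci: Iterable[SSRLocus],
    total_bp: int,
    period: int,
    descending: bool = False,
) -> dict[str, float]:
    """Counts per Mbp for each canonical class of one period.

    Classes with zero loci are omitted; ``descending`` orders the mapping by
    density (ties broken alphabetically).
    """
    if not 1 <= period <= 10:
        raise ValueError("period must be in 1..10")
    tally = Counter(
        l.canonical_motif for l in loci if l.period == period
    )
    items = [(canon, counts_per_mbp(c, total_bp)) for canon, c in tally.items()]
    if descending:
        items.sort(key=lambda kv: (-kv[1], kv[0]))
    else:
        items.sort()
    return dict(items)


def summarize_dataset(
    records: Sequence[SequenceRecord],
    loci: Sequence[SSRLocus],
    dataset_name: str = "dataset",
    include_monomers: bool = False,
) -> SpeciesSummary:
    """Aggregate detected loci into a :class:`SpeciesSummary`.

    A gene is counted once per class regardless of how many loci it carries;
    ``n_genes_with_both_classes`` counts genes with at least one locus of each
    class.  Headline tallies (n_loci, density, tract-length statistics,
    richness, nucleotide differentials, canonical tables, amino acids) exclude
    monomer loci unless ``include_monomers`` is set;
    ``counts_per_mbp_by_period`` always includes every searched period.
    """
    ids = {rec.seq_id for rec in records}
    if len(ids) != len(records):
        raise ValueError("duplicate seq_ids in records")
    for locus in loci:
        if locus.seq_id not in ids:
            raise ValueError(
                f"locus references unknown record {locus.seq_id!r}"
            )
    total_bp = total_length_bp(records)

    per_class = {}
    genes_by_class = {}
    for cls in SSR_CLASSES:
        cls_all = [l for l in loci if l.ssr_class == cls]
        sel = (
            cls_all
            if include_monomers
            else [l for l in cls_all if l.period > 1]
        )
        genes_by_class[cls] = {l.seq_id for l in sel}

        def dens(n: float) -> float:
            return counts_per_mbp(n, total_bp) if total_bp > 0 else 0.0

        by_period = {
            k: dens(c)
            for k, c in sorted(Counter(l.period for l in cls_all).items())
        }
        by_canonical: dict[int, dict[str, float]] = {}
        for k in sorted({l.period for l in sel}):
            by_canonical[k] = canonical_density_table(sel, total_bp, k)
        richness_density = {cat: 0.0 for cat in RICHNESS_CATEGORIES}
        for cat, c in Counter(l.richness for l in sel).items():
            richness_density[cat] = dens(c)
        nt = Counter()
        for l in sel:
            nt.update(motif_nucleotide_counts(l.motif))
        nt_density = {base: dens(nt.get(base, 0)) for base in "ACGT"}
        lengths = tuple(l.tract_length for l in sel)
        mean_len, sd_len = _mean_sd(lengths)
        profile = amino_acid_profile(records, sel)
        per_class[cls] = ClassSummary(
            ssr_class=cls,
            n_loci=len(sel),
            n_loci_with_monomers=len(cls_all),
            n_genes_with_ssr=len(genes_by_class[cls]),
            density=dens(len(sel)),
            mean_tract_length=mean_len,
            sd_tract_length=sd_len,
            counts_per_mbp_by_period=by_period,
            counts_per_mbp_by_canonical=by_canonical,
            richness_density=richness_density,
            nt_differential_density=nt_density,
            aa_tally=profile.counts[cls],
            stop_codon_tally=profile.stops[cls],
            tract_lengths=lengths,
        )

    return SpeciesSummary(
        dataset_name=dataset_name,
        n_genes=len(records),
        total_bp=total_bp,
        include_monomers=include_monomers,
        per_class=per_class,
        n_genes_with_both_classes=len(
            genes_by_class["I"] & genes_by_class["II"]
        ),
    )


def summary_to_dict(summary: SpeciesSummary) -> dict:
    """JSON-serializable form of a summary (full numeric precision)."""
    out = {
        "dataset_name": summary.dataset_name,
        "n_genes": summary.n_genes,
        "total_bp": summary.total_bp,
        "include_monomers": summary.include_monomers,
        "n_genes_with_both_classes": summary.n_genes_with_both_classes,
        "per_class": {},
    }
    for cls, cs in summary.per_class.items():
        out["per_class"][cls] = {
            "n_loci": cs.n_loci,
            "n_loci_with_monomers": cs.n_loci_with_monomers,
            "n_genes_with_ssr": cs.n_genes_with_ssr,
            "density": cs.density,
            "mean_tract_length": cs.mean_tract_length,
            "sd_tract_length": cs.sd_tract_length,
            "counts_per_mbp_by_period": {
                str(k): v for k, v in cs.counts_per_mbp_by_period.items()
            },
            "counts_per_mbp_by_canonical": {
                str(k): dict(v)
                for k, v in cs.counts_per_mbp_by_canonical.items()
            },
            "richness_density": dict(cs.richness_density),
            "nt_differential_density": dict(cs.nt_differential_density),
            "aa_tally": dict(cs.aa_tally),
            "stop_codon_tally": cs.stop_codon_tally,
        }
    return out


def write_summary_json(summary: SpeciesSummary, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(summary_to_dict(summary), fh, indent=2, allow_nan=True)
        fh.write("\n")


def write_summary_tables(summary: SpeciesSummary, outdir: str | Path) -> None:
    """Emit the survey-style TSV tables (densities at one decimal)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.1f"

    headline = pd.DataFrame(
        {
            cls: {
                "n_genes_with_ssr": cs.n_genes_with_ssr,
                "n_loci": cs.n_loci,
                "mean_tract_length_bp": cs.mean_tract_length,
                "sd_tract_length_bp": cs.sd_tract_length,
                "counts_per_mbp": cs.density,
            }
            for cls, cs in summary.per_class.items()
        }
    )
    headline.to_csv(outdir / "headline.tsv", sep="\t", float_format=fmt)

    periods = range(1, 11)
    by_period = pd.DataFrame(
        {
            f"class_{cls}": [
                cs.counts_per_mbp_by_period.get(k, 0.0) for k in periods
            ]
            for cls, cs in summary.per_class.items()
        },
        index=pd.Index(periods, name="period"),
    )
    by_period.to_csv(outdir / "density_by_period.tsv", sep="\t", float_format=fmt)

    for k, stem in ((3, "trimer"), (6, "hexamer")):
        frames = {}
        for cls, cs in summary.per_class.items():
            frames[f"class_{cls}"] = pd.Series(
                cs.counts_per_mbp_by_canonical.get(k, {}), dtype=float
            )
        table = pd.DataFrame(frames).fillna(0.0)
        table.index.name = "canonical_motif"
        table.sort_index().to_csv(
            outdir / f"density_{stem}_canonical.tsv", sep="\t", float_format=fmt
        )

    comp_rows = {}
    for cls, cs in summary.per_class.items():
        col = dict(cs.richness_density)
        col.update(
            {f"nt_{b}": v for b, v in cs.nt_differential_density.items()}
        )
        comp_rows[f"class_{cls}"] = col
    pd.DataFrame(comp_rows).to_csv(
        outdir / "richness_nucleotides.tsv", sep="\t", float_format=fmt
    )

    aa_rows = {
        f"class_{cls}": pd.Series(cs.aa_tally, dtype=float)
        for cls, cs in summary.per_class.items()
    }
    aa = pd.DataFrame(aa_rows).fillna(0).astype(int)
    aa.index.name = "amino_acid"
    aa.sort_index().to_csv(outdir / "amino_acid_profile.tsv", sep="\t")
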