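"""Comparative statistics: the equal-expectation chi-square heterogeneity
test on per-Mbp counts, the Welch two-sample t-test on tract lengths, and the
two-dataset comparison battery.

The heterogeneity test asks whether k density values are consistent with one
common value: the expectation is their mean e, the statistic is
sum_i (v_i - e)^2 / e with k-1 degrees of freedom, and the p-value is the
upper chi-square tail.  No continuity correction is applied.  The statistic
is homogeneous of degree one in the inputs: scaling all densities by c scales
the statistic by c, so it is sensitive to the absolute scale of the per-Mbp
counts, as intended for count densities.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .summarize import SpeciesSummary, SSR_CLASSES


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float


def chi_square_heterogeneity(values: Sequence[float]) -> ChiSquareResult:
    """Equal-expectation goodness-of-fit chi-square on k >= 2 densities.

    Raises ``ValueError`` for fewer than two values, negative values, or
    all-zero input.  A perfectly homogeneous input gives statistic 0 and
    p-value 1.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if np.any(v < 0) or np.any(~np.isfinite(v)):
        raise ValueError("values must be finite and non-negative")
    if not np.any(v > 0):
        raise ValueError("all values are zero")
    expected = v.mean()
    statistic = float(((v - expected) ** 2 / expected).sum())
    df = int(v.size - 1)
    return ChiSquareResult(statistic, df, float(sps.chi2.sf(statistic, df)))


def welch_t_test(
    lengths_a: Sequence[float], lengths_b: Sequence[float]
) -> TTestResult:
    """Two-sided Welch (unequal-variance) t-test on per-locus tract lengths."""
    a = np.asarray(list(lengths_a), dtype=float)
    b = np.asarray(list(lengths_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        # Degenerate but well-defined: no evidence of a difference.
        return TTestResult(0.0, float(a.size + b.size - 2), 1.0,
                           float(a.mean()), float(b.mean()))
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        float(res.statistic),
        float(res.df),
        float(res.pvalue),
        float(a.mean()),
        float(b.mean()),
    )


@dataclass(frozen=True)
class ComparisonRow:
    """One labeled test in a two-dataset comparison report."""

    label: str
    ssr_class: str
    test: str
    statistic: float
    df: float
    p_value: float


def compare_datasets(
    summary_a: SpeciesSummary, summary_b: SpeciesSummary
) -> list[ComparisonRow]:
    """The full comparison battery between two dataset summaries.

    Per class: between-dataset density heterogeneity; within-dataset
    trimer-vs-hexamer, AT-rich-vs-GC-rich and (A+T)-vs-(G+C) differential
    heterogeneity; and the between-dataset tract-length t-test.  Tests whose
    inputs are all zero (no loci in either cell) are skipped.  Both summaries
    must have been computed with the same monomer flag.
    """
    if summary_a.include_monomers != summary_b.include_monomers:
        raise ValueError("summaries computed with mismatched configuration")
    rows: list[ComparisonRow] = []

    def chi_row(label: str, cls: str, values: Sequence[float]) -> None:
        if not any(v > 0 for v in values):
            return
        res = chi_square_heterogeneity(values)
        rows.append(
            ComparisonRow(label, cls, "chi2", res.statistic, res.df, res.p_value)
        )

    for cls in SSR_CLASSES:
        ca = summary_a.per_class[cls]
        cb = summary_b.per_class[cls]
        chi_row("density_between_datasets", cls, [ca.density, cb.density])
        for name, cs in (
            (summary_a.dataset_name, ca),
            (summary_b.dataset_name, cb),
        ):
            bp = cs.counts_per_mbp_by_period
            chi_row(
                f"trimer_vs_hexamer[{name}]",
                cls,
                [bp.get(3, 0.0), bp.get(6, 0.0)],
            )
            rd = cs.richness_density
            chi_row(
                f"at_rich_vs_gc_rich[{name}]",
                cls,
                [rd.get("AT_RICH", 0.0), rd.get("GC_RICH", 0.0)],
            )
            nt = cs.nt_differential_density
            chi_row(
                f"at_vs_gc_nucleotides[{name}]",
                cls,
                [nt["A"] + nt["T"], nt["G"] + nt["C"]],
            )
        if len(ca.tract_lengths) >= 2 and len(cb.tract_lengths) >= 2:
            t = welch_t_test(ca.tract_lengths, cb.tract_lengths)
            rows.append(
                ComparisonRow(
                    "tract_length_between_datasets",
                    cls,
                    "welch_t",
                    t.statistic,
                    t.df,
                    t.p_value,
                )
            )
    return rows


def comparison_to_tsv(rows: Iterable[ComparisonRow], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ("comparison_label", "ssr_class", "test", "statistic", "df", "p_value")
        )
        for r in rows:
            writer.writerow(
                (r.label, r.ssr_class, r.test,
                 f"{r.statistic:.6g}", f"{r.df:.6g}", f"{r.p_value:.6g}")
            )
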