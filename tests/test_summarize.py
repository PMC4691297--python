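import math

import pytest

from ssrscan import (
    SequenceRecord,
    amino_acid_profile,
    canonical_density_table,
    counts_per_mbp,
    detect_in_records,
    summarize_dataset,
    summary_to_dict,
)


_SQUARE_FREE = None


def pad(n):
    """Neutral filler: prefix of Thue's square-free ternary word mapped to
    C/T/G.  Square-freeness means it contains no tandem repeat of any period,
    and the absence of A keeps it from extending A-containing motifs."""
    global _SQUARE_FREE
    if _SQUARE_FREE is None or len(_SQUARE_FREE) < max(n, 1):
        s = "0"
        sub = {"0": "012", "1": "02", "2": "1"}
        while len(s) < max(n, 600_000):
            s = "".join(sub[c] for c in s)
        _SQUARE_FREE = s.translate(str.maketrans("012", "CTG"))
    return _SQUARE_FREE[:n]


def make_record(seq_id, *parts, total=None):
    seq = "".join(parts)
    if total is not None:
        seq += pad(total - len(seq))
    return SequenceRecord(seq_id, seq)


class TestCountsPerMbp:
    def test_identities(self):
        assert counts_per_mbp(0, 10**6) == 0.0
        assert counts_per_mbp(55, 10**6) == 55.0
        assert counts_per_mbp(240, int(4.39e6)) == pytest.approx(54.67, abs=0.01)

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            counts_per_mbp(1, 0)


class TestSummarizeDataset:
    def test_gene_and_locus_tallies(self):
        # one gene with a class I and a class II locus; one with two class II
        g1 = make_record("g1", pad(10), "AT" * 10, pad(10), "AGC" * 5, pad(10))
        g2 = make_record("g2", pad(10), "AACGGT" * 2, pad(10), "AGC" * 4, pad(8))
        g3 = make_record("g3", pad(60))
        records = [g1, g2, g3]
        loci = detect_in_records(records)
        s = summarize_dataset(records, loci)
        assert s.n_genes == 3
        assert s.per_class["I"].n_genes_with_ssr == 1
        assert s.per_class["I"].n_loci == 1
        assert s.per_class["II"].n_genes_with_ssr == 2
        assert s.per_class["II"].n_loci == 3
        assert s.n_genes_with_both_classes == 1

    def test_monomer_flag(self):
        rec = make_record("g1", pad(5), "A" * 14, pad(5), "AGC" * 5, pad(5))
        records = [rec]
        loci = detect_in_records(records)
        assert {(l.period, l.ssr_class) for l in loci} == {(1, "II"), (3, "II")}
        headline = summarize_dataset(records, loci)
        assert headline.per_class["II"].n_loci == 1  # monomer excluded
        assert headline.per_class["II"].n_loci_with_monomers == 2
        # by-period table always carries the monomer row
        assert 1 in headline.per_class["II"].counts_per_mbp_by_period
        inclusive = summarize_dataset(records, loci, include_monomers=True)
        assert inclusive.per_class["II"].n_loci == 2

    def test_headline_density_is_by_period_sum_minus_monomers(self):
        rec = make_record("g1", pad(5), "A" * 14, pad(5), "AGC" * 5, pad(5),
                          "AACGGT" * 2, pad(5))
        records = [rec]
        s = summarize_dataset(records, detect_in_records(records))
        cs = s.per_class["II"]
        total = sum(cs.counts_per_mbp_by_period.values())
        monomer = cs.counts_per_mbp_by_period.get(1, 0.0)
        assert cs.density == pytest.approx(total - monomer)
        mbp = s.total_bp / 1e6
        assert total == pytest.approx(cs.n_loci_with_monomers / mbp)

    def test_richness_and_nt_conservation(self, small_planted_dataset):
        _, (records, _) = small_planted_dataset
        loci = detect_in_records(records)
        s = summarize_dataset(records, loci)
        for cls in ("I", "II"):
            cs = s.per_class[cls]
            assert sum(cs.richness_density.values()) == pytest.approx(cs.density)
            mbp = s.total_bp / 1e6
            nt_total = sum(cs.nt_differential_density.values()) * mbp
            period_sum = sum(
                l.period for l in loci if l.ssr_class == cls and l.period > 1
            )
            assert nt_total == pytest.approx(period_sum)

    def test_tract_length_stats_population_sd(self):
        g = make_record("g1", pad(5), "AT" * 10, pad(5), "AT" * 12, pad(5))
        records = [g]
        s = summarize_dataset(records, detect_in_records(records))
        cs = s.per_class["I"]
        assert cs.mean_tract_length == pytest.approx(22.0)
        assert cs.sd_tract_length == pytest.approx(2.0)  # population, not sample

    def test_unknown_seq_id_raises(self):
        g = make_record("g1", pad(5), "AT" * 10, pad(5))
        loci = detect_in_records([g])
        with pytest.raises(ValueError, match="unknown record"):
            summarize_dataset([make_record("g2", pad(30))], loci)

    def test_summary_round_trips_to_dict(self, small_planted_dataset):
        _, (records, _) = small_planted_dataset
        s = summarize_dataset(records, detect_in_records(records))
        d = summary_to_dict(s)
        assert d["n_genes"] == 100
        assert set(d["per_class"]) == {"I", "II"}
        assert math.isfinite(d["per_class"]["II"]["density"])


class TestCanonicalDensityTable:
    def test_empty(self):
        records = [make_record("g1", pad(100))]
        assert canonical_density_table(detect_in_records(records), 10**6, 3) == {}

    def test_planted_densities_and_rotation_aggregation(self):
        # 10 AGG-class (mixed rotations/complements) + 5 ACG-class trimers in 1 Mbp
        parts = []
        for i, m in enumerate(["AGG", "GGA", "CCT", "AGG", "GGA"] * 2):
            parts += [pad(7), m * 5]
        for m in ["ACG", "CGA", "GAC", "ACG", "CGT"]:
            parts += [pad(7), m * 5]
        records = [
            make_record("g1", *parts, total=500_000),
            make_record("g2", pad(500_000)),
        ]
        loci = detect_in_records(records)
        table = canonical_density_table(loci, 10**6, 3, descending=True)
        assert table == {"AGG": pytest.approx(10.0), "ACG": pytest.approx(5.0)}
        assert list(table) == ["AGG", "ACG"]


class TestAminoAcidProfile:
    def test_in_frame_trimer_tract(self):
        # (GAA)7 starting at a codon boundary encodes polyglutamate
        rec = make_record("g1", "CTG", "GAA" * 7, "CTT")
        loci = detect_in_records([rec])
        assert [(l.start, l.period) for l in loci] == [(3, 3)]
        profile = amino_acid_profile([rec], loci)
        assert profile.counts["I"] == {"E": 7}

    def test_out_of_frame_trimer_tract(self):
        # (GAA)7 starting at position 2: six full in-frame codons, all AAG (Lys)
        rec = make_record("g1", "CT", "GAA" * 7, "CTT")
        loci = detect_in_records([rec])
        assert [(l.start, l.end) for l in loci] == [(2, 23)]
        profile = amino_acid_profile([rec], loci)
        assert profile.counts["I"] == {"K": 6}

    def test_in_frame_hexamer(self):
        # (AACGGT)4 in frame: Asn,Gly x4 each; 4 repeats = class I hexamer
        rec = make_record("g1", "CTG", "AACGGT" * 4, "CTT")
        loci = detect_in_records([rec])
        profile = amino_acid_profile([rec], loci)
        assert profile.counts["I"] == {"N": 4, "G": 4}

    def test_stop_codons_tallied_separately(self):
        rec = make_record("g1", "CTG", "TAA" * 5, "CTT")
        loci = detect_in_records([rec])
        assert [(l.period, l.ssr_class) for l in loci] == [(3, "II")]
        profile = amino_acid_profile([rec], loci)
        assert profile.counts["II"] == {}
        assert profile.stops["II"] == 5

    def test_short_locus_contributes_nothing(self):
        # a 2-unit dimer tract out of frame holds no full codon
        rec = make_record("g1", "CT", "AT" * 2, "CCCTT")
        loci = detect_in_records(
            [rec],
        )
        assert loci == []  # below thresholds anyway; use profile directly
        profile = amino_acid_profile([rec], loci)
        assert profile.counts["I"] == {} and profile.counts["II"] == {}

    def test_total_bounded_by_codon_capacity(self, small_planted_dataset):
        _, (records, _) = small_planted_dataset
        loci = detect_in_records(records)
        profile = amino_acid_profile(records, loci)
        total = sum(
            sum(c.values()) for c in profile.counts.values()
        ) + sum(profile.stops.values())
        capacity = sum(l.tract_length // 3 for l in loci)
        assert total <= capacity
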