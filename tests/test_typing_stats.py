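import itertools
import math
import random
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from markerscan import typing_stats as ts
from markerscan.errors import LengthMismatchError, UndefinedStatisticError
from markerscan.refdata import REFERENCE_LOCUS_TABLE

SENSE = [c for c in ts.ALL_CODONS if c not in ts.STOP_CODONS]


# ---------------------------------------------------------------------------
# allele calling
# ---------------------------------------------------------------------------


class TestCallAlleles:
    def test_exact_identity_defines_alleles(self):
        table = ts.call_alleles({"s1": "ACGT", "s2": "acgt", "s3": "ACGA"})
        assert table.n_alleles == 2
        assert table.counts == {1: 2, 2: 1}
        assert table.N == 3
        assert table.assignment == {"s1": 1, "s2": 1, "s3": 2}

    def test_monomorphic_panel_single_allele(self):
        table = ts.call_alleles({f"s{i}": "ACGTAA" for i in range(21)})
        assert table.n_alleles == 1

    def test_empty_input_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ts.call_alleles({})

    def test_length_mismatch_names_strains(self):
        with pytest.raises(LengthMismatchError, match="sA"):
            ts.call_alleles({"sA": "ACGT", "sB": "ACG"})

    def test_zero_intra_divergence_gives_one_allele_per_species(self):
        from markerscan import synthetic_data as sd

        cfg = sd.default_config(seed=3, scale=0.2)
        cfg.p_intra = 0.0
        cfg.loci = [
            sd.LocusSpec(s.name, s.length_bp, s.coding, s.p_inter, 0.0)
            for s in cfg.loci
        ]
        cfg.planted_windows = []
        panel, truth = sd.generate_panel(cfg)
        for locus in panel.loci:
            table = ts.call_alleles(panel.locus_seqs(locus))
            assert table.n_alleles == len(cfg.species)


# ---------------------------------------------------------------------------
# polymorphic sites
# ---------------------------------------------------------------------------


def _brute_polymorphic(seqs):
    cols = zip(*seqs.values())
    count = 0
    for col in cols:
        if any(c not in "ACGT" for c in col):
            continue
        if len(set(col)) >= 2:
            count += 1
    return count


class TestPolymorphicSites:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            ({"a": "ACGT", "b": "ACGT"}, 0),
            ({"a": "ACGT", "b": "ACGA", "c": "TCGA"}, 2),
            ({"a": "ANGT", "b": "ACGA"}, 1),  # N column skipped entirely
            ({"a": "A-GT", "b": "ACGT"}, 0),
        ],
    )
    def test_examples(self, seqs, expected):
        assert ts.count_polymorphic_sites(seqs) == expected

    def test_matches_columnwise_recount_on_random_panels(self):
        rng = random.Random(42)
        for _ in range(50):
            seqs = {
                f"s{i}": "".join(rng.choice("ACGTN-") for _ in range(30))
                for i in range(5)
            }
            assert ts.count_polymorphic_sites(seqs) == _brute_polymorphic(seqs)


# ---------------------------------------------------------------------------
# typing efficiency and discriminatory power
# ---------------------------------------------------------------------------


class TestTypingEfficiency:
    def test_reproduces_reference_column_for_all_loci(self):
        for locus, ref in REFERENCE_LOCUS_TABLE.items():
            te = ts.typing_efficiency(ref.n_alleles, ref.n_polymorphic_sites)
            assert round(te, 3) == ref.te, locus

    def test_monomorphic_locus_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            ts.typing_efficiency(5, 0)


def _brute_dp(counts):
    """Fraction of unordered strain pairs with differing alleles."""
    alleles = list(
        itertools.chain.from_iterable([aid] * n for aid, n in counts.items())
    )
    pairs = list(itertools.combinations(alleles, 2))
    differing = sum(1 for a, b in pairs if a != b)
    return Fraction(differing, len(pairs))


class TestDiscriminatoryPower:
    def test_all_singletons(self):
        table = ts.AlleleTable("x", {f"s{i}": i + 1 for i in range(5)},
                               {i + 1: 1 for i in range(5)}, 5)
        assert ts.discriminatory_power(table) == 1.0

    def test_single_allele(self):
        table = ts.AlleleTable("x", {f"s{i}": 1 for i in range(4)}, {1: 4}, 4)
        assert ts.discriminatory_power(table) == 0.0

    def test_mixed_counts_match_pair_enumeration(self):
        counts = {1: 3, 2: 2, 3: 1, 4: 1}
        table = ts.AlleleTable("x", {}, counts, 7)
        dp = ts.discriminatory_power(table)
        assert dp == pytest.approx(1 - Fraction(8, 42), abs=1e-15)
        assert dp == pytest.approx(_brute_dp(counts), abs=1e-15)

    def test_requires_two_strains(self):
        with pytest.raises(UndefinedStatisticError):
            ts.discriminatory_power(ts.AlleleTable("x", {"s": 1}, {1: 1}, 1))

    @given(st.lists(st.integers(min_value=1, max_value=6), min_size=1, max_size=8))
    def test_equals_pair_counting_oracle(self, sizes):
        n = sum(sizes)
        if n < 2:
            return
        counts = {i + 1: c for i, c in enumerate(sizes)}
        dp = ts.discriminatory_power(ts.AlleleTable("x", {}, counts, n))
        oracle = _brute_dp(counts)
        same = sum(c * (c - 1) for c in counts.values())
        assert Fraction(same, n * (n - 1)) + oracle == 1  # exact rational identity
        assert dp == pytest.approx(float(oracle), abs=1e-12)


# ---------------------------------------------------------------------------
# Nei–Gojobori machinery
# ---------------------------------------------------------------------------


def oracle_sites(codon):
    """Independent per-codon site enumeration."""
    s = 0.0
    for pos in range(3):
        syn = sum(
            1
            for alt in "ACGT"
            if alt != codon[pos]
            and ts.CODON_AA[codon[:pos] + alt + codon[pos + 1:]] == ts.CODON_AA[codon]
            and ts.CODON_AA[codon] != "*"
            and ts.CODON_AA[codon[:pos] + alt + codon[pos + 1:]] != "*"
        )
        s += syn / 3
    return s, 3 - s


def oracle_pathways(c1, c2):
    """Average syn/nonsyn step counts over all orderings of the differing
    positions (the 2- and 3-difference cases average 2 and 6 orderings)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd = c1, 0, 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if ts.CODON_AA[cur] == ts.CODON_AA[nxt] and ts.CODON_AA[cur] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd))
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestNeiGojobori:
    def test_phenylalanine_sites(self):
        s, n = ts.nei_gojobori_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_methionine_sites(self):
        assert ts.nei_gojobori_sites("ATG") == (0.0, 3.0)

    def test_site_conservation_all_sense_codons(self):
        for codon in SENSE:
            s, n = ts.nei_gojobori_sites(codon)
            assert s + n == pytest.approx(3.0)
            assert (s, n) == pytest.approx(oracle_sites(codon))

    def test_stop_and_ambiguous_codons_flagged(self):
        with pytest.raises(UndefinedStatisticError):
            ts.nei_gojobori_sites("TAA")
        with pytest.raises(UndefinedStatisticError):
            ts.nei_gojobori_sites("ANG")

    def test_pathway_tables_match_oracle_on_random_pairs(self):
        rng = random.Random(0)
        for _ in range(300):
            c1, c2 = rng.choice(SENSE), rng.choice(SENSE)
            i, j = ts.codon_index(c1), ts.codon_index(c2)
            assert (ts._SD[i, j], ts._ND[i, j]) == pytest.approx(
                oracle_pathways(c1, c2)
            )


class TestPairwiseDnds:
    def test_identical_sequences(self):
        assert ts.pairwise_dnds("TTTATG", "TTTATG") == (0.0, 0.0)

    def test_single_synonymous_difference(self):
        # one Phe codon flips TTT→TTC in a 10-codon context: purely synonymous
        a, b = "GCT" * 9 + "TTT", "GCT" * 9 + "TTC"
        i, j = ts.codon_index("TTT"), ts.codon_index("TTC")
        assert (ts._SD[i, j], ts._ND[i, j]) == (1.0, 0.0)
        dn, ds = ts.pairwise_dnds(a, b)
        assert dn == 0.0
        assert ds > 0.0

    def test_single_codon_synonymous_pair_saturates(self):
        # at toy scale pS = Sd/S = 1/(1/3) ≥ 3/4, so the correction is
        # undefined and flagged as NaN while dN stays 0
        dn, ds = ts.pairwise_dnds("TTT", "TTC")
        assert dn == 0.0
        assert math.isnan(ds)

    def test_single_nonsynonymous_difference(self):
        dn, ds = ts.pairwise_dnds("ATG", "ATA")  # Met → Ile
        assert ds == 0.0
        assert dn > 0.0

    def test_ambiguous_codons_skipped_pairwise(self):
        # masking a codon with Ns must reproduce the shorter comparison
        dn_skip, ds_skip = ts.pairwise_dnds("GCT" * 9 + "TTT" + "NNN",
                                            "GCT" * 9 + "TTC" + "GGG")
        dn_ref, ds_ref = ts.pairwise_dnds("GCT" * 9 + "TTT", "GCT" * 9 + "TTC")
        assert (dn_skip, ds_skip) == (dn_ref, ds_ref)

    def test_length_mismatch_rejected(self):
        with pytest.raises(LengthMismatchError):
            ts.pairwise_dnds("TTT", "TTTTTT")


class TestLocusDnds:
    def test_all_synonymous_variation_gives_zero(self):
        base = "GCT" * 20  # poly-Ala; third positions are fourfold degenerate
        seqs = {"a": base, "b": base[:-3] + "GCC", "c": base[:-3] + "GCA"}
        assert ts.locus_dnds(seqs) == 0.0

    def test_identical_panel_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            ts.locus_dnds({"a": "TTTATG", "b": "TTTATG"})


# ---------------------------------------------------------------------------
# summaries and ranking
# ---------------------------------------------------------------------------


class TestSummarizeLoci:
    def test_monomorphic_locus_row(self):
        from markerscan.seqio import SeqEntry, StrainPanel

        panel = StrainPanel(
            strains=[("s1", "A"), ("s2", "B")],
            loci=["x"],
            sequences={
                ("s1", "x"): SeqEntry("s1", "ATGATG"),
                ("s2", "x"): SeqEntry("s2", "ATGATG"),
            },
        )
        (row,) = ts.summarize_loci(panel)
        assert row.te is None
        assert row.dp == 0.0
        assert row.dnds is None

    def test_strain_order_invariance(self, small_panel):
        panel, _ = small_panel
        stats1 = ts.summarize_loci(panel, coding_loci=set(panel.loci) - {"rrs"})
        import copy

        shuffled = copy.deepcopy(panel)
        shuffled.strains = shuffled.strains[::-1]
        stats2 = ts.summarize_loci(shuffled, coding_loci=set(panel.loci) - {"rrs"})
        for r1, r2 in zip(stats1, stats2):
            assert (r1.locus, r1.n_alleles, r1.n_polymorphic_sites) == (
                r2.locus, r2.n_alleles, r2.n_polymorphic_sites
            )
            assert r1.dp == pytest.approx(r2.dp, abs=1e-12)
            assert (r1.dnds or 0) == pytest.approx(r2.dnds or 0, abs=1e-9)

    def test_formatted_table_has_na_and_mean_footer(self):
        stats = [
            ts.LocusStats("x", 600, 1, 0, None, None, 0.0),
            ts.LocusStats("y", 600, 4, 10, 0.5, 0.4, 0.8),
        ]
        df = ts.format_locus_table(stats)
        assert df.iloc[0]["te"] == "NA"
        assert df.iloc[-1]["locus"] == "mean"
        assert df.iloc[-1]["dnds"] == "0.5000"


class TestRankMarkers:
    def _stats_from_reference(self):
        return [
            ts.LocusStats(loc, r.length_bp, r.n_alleles, r.n_polymorphic_sites,
                          r.dnds, r.te, r.dp)
            for loc, r in REFERENCE_LOCUS_TABLE.items()
        ]

    def test_reference_table_top_is_pycA(self):
        stats = self._stats_from_reference()
        identity = {s.locus: 80.0 for s in stats}
        identity["aroE"] = 67.0  # lowest published inter-species homology
        ranking = ts.rank_markers(stats, identity)
        assert ranking["by_polymorphism"][0] == "pycA"
        assert ranking["candidates"]["most_polymorphic"] == "pycA"
        assert ranking["candidates"]["lowest_identity"] == "aroE"

    def test_tied_stats_fall_back_to_name_order(self):
        stats = [
            ts.LocusStats(loc, 100, 5, 10, None, 0.5, 0.9) for loc in ["b", "c", "a"]
        ]
        ranking = ts.rank_markers(stats, {s.locus: 80.0 for s in stats})
        assert ranking["by_polymorphism"] == ["a", "b", "c"]

    def test_elevated_divergence_locus_tops_identity_ranking(self):
        from markerscan import synthetic_data as sd
        from markerscan import identity_phylo as ip

        cfg = sd.default_config(seed=11, scale=0.15)
        cfg.planted_windows = []
        cfg.loci = [
            sd.LocusSpec(s.name, s.length_bp, s.coding,
                         0.5 if s.name == "gmk" else s.p_inter, s.p_intra)
            for s in cfg.loci
            if s.name in {"adk", "gmk", "pyrE"}
        ]
        panel, _ = sd.generate_panel(cfg)
        stats = ts.summarize_loci(panel)
        ranking = ts.rank_markers(stats, ip.min_between_identity(panel))
        assert ranking["by_identity"][0] == "gmk"

    def test_empty_input_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ts.rank_markers([], {})
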