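"""Trait-variant genotyping, risk haplotypes/index, group comparison and
mtDNA haplotype assignment."""

import itertools
import math

import numpy as np
import pytest

from conftest import RISK_COUNTS, RISK_FREQS, TABLE2_COUNTS, TABLE2_FREQS

from rohkit import (
    MISSING,
    GenotypeCounts,
    allele_frequency,
    compare_group_frequencies,
    genotype_counts,
    haplotype_dose,
    load_mtdna_table,
    load_risk_loci,
    load_trait_variants,
    locus_genotype_counts,
    mtdna_haplotype,
    risk_index,
)
from rohkit.traits import DEFAULT_RISK_RULE, TraitVariantDef, find_site


@pytest.fixture(scope="module")
def defs():
    return {v.label: v for v in load_trait_variants()}


@pytest.fixture(scope="module")
def loci():
    return {l.label: l for l in load_risk_loci()}


class TestGenotypeCounts:
    @pytest.mark.parametrize("label", sorted(TABLE2_COUNTS))
    def test_counts_match_cohort_table(self, table2_matrix, defs, label):
        c = genotype_counts(table2_matrix, defs[label])
        assert c.present
        assert (c.n_refref, c.n_refalt, c.n_altalt) == TABLE2_COUNTS[label]
        assert c.n_called + c.n_missing == 33

    def test_absent_variant_reported_not_zero(self, table2_matrix):
        ghost = TraitVariantDef("ghost", "t", "o", "g", "1", 12345, "A", "G")
        c = genotype_counts(table2_matrix, ghost)
        assert not c.present

    def test_counts_match_per_sample_loop(self, table2_matrix, defs):
        v = defs["SOD1_c118GA"]
        j = find_site(table2_matrix, v)
        tally = {0: 0, 1: 0, 2: 0, MISSING: 0}
        for si in range(table2_matrix.n_samples):
            tally[int(table2_matrix.calls[si, j])] += 1
        c = genotype_counts(table2_matrix, v)
        assert (c.n_refref, c.n_refalt, c.n_altalt, c.n_missing) == \
            (tally[0], tally[1], tally[2], tally[MISSING])


class TestAlleleFrequency:
    @pytest.mark.parametrize("label", sorted(TABLE2_FREQS))
    def test_frequencies_reproduce_published_values(self, table2_matrix,
                                                    defs, label):
        c = genotype_counts(table2_matrix, defs[label])
        assert round(allele_frequency(c), 3) == TABLE2_FREQS[label]

    def test_fixation_and_undefined(self):
        assert allele_frequency(GenotypeCounts(0, 0, 10)) == 1.0
        with pytest.raises(ValueError):
            allele_frequency(GenotypeCounts(0, 0, 0, n_missing=5))

    def test_equals_direct_allele_tally(self, table2_matrix, defs):
        for v in defs.values():
            j = find_site(table2_matrix, v)
            col = table2_matrix.calls[:, j]
            called = col[col != MISSING]
            direct = called.sum() / (2 * called.size)
            c = genotype_counts(table2_matrix, v)
            assert allele_frequency(c) == pytest.approx(direct)


class TestHaplotypeDose:
    @pytest.mark.parametrize("label", sorted(RISK_COUNTS))
    def test_cohort_dose_aggregation(self, table2_matrix, loci, label):
        """Per-sample consensus doses aggregate to the published genotype
        classes and haplotype frequency."""
        c = locus_genotype_counts(table2_matrix, loci[label])
        assert (c.n_refref, c.n_refalt, c.n_altalt) == RISK_COUNTS[label]
        assert round(allele_frequency(c), 3) == RISK_FREQS[label]

    def test_unanimous_and_het(self, table2_matrix, loci):
        locus = loci["chr11_41Mb"]
        dose, disc = haplotype_dose(table2_matrix, locus, "D01")  # all 0
        assert (dose, disc) == (0, 0.0)
        dose, disc = haplotype_dose(table2_matrix, locus, "D03")  # all het
        assert (dose, disc) == (1, 0.0)
        dose, disc = haplotype_dose(table2_matrix, locus, "D33")  # all hom-alt
        assert (dose, disc) == (2, 0.0)

    def test_under_half_genotyped_is_missing(self, table2_matrix, loci):
        m = table2_matrix
        locus = loci["chr14_11Mb"]
        si = m.sample_index("D05")
        m2_calls = m.calls.copy()
        pos = m.sites["pos"].to_numpy()
        chrom = m.sites["chrom"].to_numpy()
        hit = np.isin(pos, locus.defining_positions) & (chrom == locus.chrom)
        # strictly more than half missing -> fewer than half genotyped
        idx = np.flatnonzero(hit)[: math.ceil(len(locus.defining_positions) / 2) + 1]
        m2_calls[si, idx] = MISSING
        from rohkit import GenotypeMatrix
        m2 = GenotypeMatrix(m.samples, m.sites, m2_calls)
        dose, disc = haplotype_dose(m2, locus, "D05")
        assert dose is None and math.isnan(disc)

    def test_discordance_reported(self, table2_matrix, loci):
        m = table2_matrix
        locus = loci["chr5_33Mb"]
        calls = m.calls.copy()
        si = m.sample_index("D33")  # all hom-alt at this locus
        pos = m.sites["pos"].to_numpy()
        j = np.flatnonzero(np.isin(pos, locus.defining_positions)
                           & (m.sites["chrom"].to_numpy() == locus.chrom))[0]
        calls[si, j] = 0
        from rohkit import GenotypeMatrix
        dose, disc = haplotype_dose(GenotypeMatrix(m.samples, m.sites, calls),
                                    locus, "D33")
        assert dose == 2
        assert disc == pytest.approx(1 / len(locus.defining_positions))


class TestRiskIndex:
    def test_extremes(self):
        assert risk_index([0, 0, 0, 0]) == "A"
        assert risk_index([2, 2, 2, 2]) == "C"

    def test_missing_dose_missing_index(self):
        assert risk_index([2, None, 0, 1]) is None

    def test_monotone_over_all_dose_vectors(self):
        """Raising any single locus dose never moves the index towards A —
        checked exhaustively over all 3^4 dose vectors."""
        order = {"A": 0, "B": 1, "C": 2}
        for doses in itertools.product((0, 1, 2), repeat=4):
            base = order[risk_index(list(doses))]
            for i in range(4):
                if doses[i] < 2:
                    bumped = list(doses)
                    bumped[i] += 1
                    assert order[risk_index(bumped)] >= base

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            risk_index([0, 0, 0, 0], rule={"A": (0, 3), "B": (5, 8)})  # hole
        with pytest.raises(ValueError):
            risk_index([0, 0, 0, 0], rule={"C": (0, 4), "A": (5, 8)})  # not monotone


def fisher_two_sided_oracle(a, b, c, d):
    """Enumerate all tables with the observed margins; two-sided p is the
    total probability of tables no more likely than the observed one."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def table_prob(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    p_obs = table_prob(a)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        px = table_prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestGroupComparison:
    def test_published_between_continent_contrast(self):
        """Risk-allele table (35,7 | 13,11) reproduces the printed group
        frequencies 0.833 and 0.542."""
        f1, f2, odds, p = compare_group_frequencies((35, 7), (13, 11))
        assert round(f1, 3) == 0.833
        assert round(f2, 3) == 0.542
        assert p == pytest.approx(fisher_two_sided_oracle(35, 7, 13, 11),
                                  rel=1e-6)

    def test_identical_frequencies_balanced_table(self):
        _, _, _, p = compare_group_frequencies((10, 10), (10, 10))
        assert p == 1.0

    @pytest.mark.parametrize("table", [(3, 2, 1, 4), (8, 1, 2, 7),
                                       (5, 5, 4, 6), (12, 0, 3, 9)])
    def test_fisher_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        _, _, _, p = compare_group_frequencies((a, b), (c, d))
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-6)

    def test_empty_margin(self):
        with pytest.warns(UserWarning, match="empty margin"):
            _, _, _, p = compare_group_frequencies((0, 0), (3, 4))
        assert p == 1.0


class TestMtdnaHaplotype:
    @pytest.fixture(scope="class")
    def table(self):
        return load_mtdna_table()

    def test_exact_match(self, table):
        assignment = mtdna_haplotype(set(table["A22"]), table)
        assert assignment.label == "A22"
        assert assignment.unexplained == ()

    def test_extra_coding_variant_listed_unexplained(self, table):
        profile = set(table["A22"]) | {(4378, "G")}
        assignment = mtdna_haplotype(profile, table)
        assert assignment.label == "A22"
        assert assignment.unexplained == ((4378, "G"),)

    def test_empty_profile_unassigned(self, table):
        assignment = mtdna_haplotype(set(), table)
        assert assignment.label == "unassigned"

    def test_partial_match_reported(self, table):
        profile = set(list(table["A2"])[:2])
        assignment = mtdna_haplotype(profile, table)
        assert assignment.label == "unassigned"
        assert assignment.best_partial == "A2"
        assert 0 < assignment.best_partial_fraction < 1

    def test_tie_reports_all(self):
        table = {"H1": {(1, "A")}, "H2": {(1, "A"), (2, "C")}}
        assignment = mtdna_haplotype({(1, "A"), (2, "C")}, table)
        assert assignment.haplotypes == ("H1", "H2")
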