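"""Mendelian exclusion rules, exclusion ratios, parentage and sex labels.

The published diploid-trio and sexed-triploid-trio exclusion tables are
hard-coded here verbatim as the oracle; the package derives its rules by
enumerating parental gamete/chromatid contributions, so any change to the
rule logic breaks these tests.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from tricall.containers import GenotypeMatrix
from tricall.pedigree import (
    DuoStats,
    ParentageModel,
    assign_parents,
    compute_duo_stats,
    compute_trio_stats,
    detect_duplicates,
    duo_exclusion,
    exclusion_table,
    mother_exclusion,
    predict_parent_sex,
    trio_exclusion,
)
from tricall.simulate import SimConfig, simulate_dataset

NA = None

# Published diploid-offspring trio exclusions: (P1, P2) -> excluded offspring
# dosages, with genotypes coded as A-allele counts (BB=0, AB=1, AA=2).
DIPLOID_TABLE = {
    (NA, 2): (0,),
    (NA, 0): (2,),
    (2, NA): (0,),
    (0, NA): (2,),
    (2, 0): (0, 2),
    (0, 2): (0, 2),
    (2, 2): (0, 1),
    (0, 0): (1, 2),
    (1, 2): (0,),
    (1, 0): (2,),
    (2, 1): (0,),
    (0, 1): (2,),
}

# Published triploid-offspring trio exclusions, (Mother, Father) -> excluded
# dosages (BBB=0 ... AAA=3).
TRIPLOID_TABLE = {
    (0, NA): (2, 3),
    (2, NA): (0, 1),
    (NA, 2): (0,),
    (NA, 0): (3,),
    (2, 0): (0, 1, 3),
    (0, 2): (0, 2, 3),
    (2, 2): (0, 1, 2),
    (0, 0): (1, 2, 3),
    (2, 1): (0, 1),
    (0, 1): (2, 3),
    (1, 2): (0,),
    (1, 0): (3,),
}


class TestExclusionTables:
    def test_diploid_table_reproduced_exactly(self):
        table = exclusion_table(2)
        derived = {
            (r.parent1, r.parent2): r.excluded_offspring
            for r in table.itertuples(index=False)
        }
        assert derived == DIPLOID_TABLE
        assert len(table) == 12

    def test_triploid_sexed_table_reproduced_exactly(self):
        table = exclusion_table(3, sexed=True)
        derived = {
            (r.parent1, r.parent2): r.excluded_offspring
            for r in table.itertuples(index=False)
        }
        assert derived == TRIPLOID_TABLE
        assert len(table) == 12

    def test_unsexed_triploid_uses_symmetric_rows_only(self):
        # opposing homozygotes: excluded under either parental-sex ordering
        assert trio_exclusion(0, 2, 0, 3, sexed=False)
        assert trio_exclusion(3, 2, 0, 3, sexed=False)
        # mother-specific row must NOT apply without sexes
        assert trio_exclusion(1, 2, 1, 3, sexed=True)
        assert not trio_exclusion(1, 2, 1, 3, sexed=False)

    @pytest.mark.parametrize("ploidy", [2, 3])
    def test_gamete_enumeration_oracle(self, ploidy):
        """Independent re-derivation: enumerate explicit allele draws."""
        for p1, p2 in itertools.product([NA, 0, 1, 2], repeat=2):
            p1_alleles = [(0, 0), (0, 1), (1, 1)][p1] if p1 is not NA else None
            p2_alleles = [(0, 0), (0, 1), (1, 1)][p2] if p2 is not NA else None
            possible = set()
            p1_opts = [p1_alleles] if p1_alleles is not None else [(0, 0), (0, 1), (1, 1)]
            p2_opts = [p2_alleles] if p2_alleles is not None else [(0, 0), (0, 1), (1, 1)]
            for a1 in p1_opts:
                for a2 in p2_opts:
                    if ploidy == 2:
                        possible |= {x + y for x in a1 for y in a2}
                    else:
                        # mother passes a chromatid pair: both copies of either
                        # haplotype, or (post-crossover) one of each
                        pairs = {2 * a1[0], 2 * a1[1], a1[0] + a1[1]}
                        possible |= {m + y for m in pairs for y in a2}
            for o in range(ploidy + 1):
                assert trio_exclusion(o, p1, p2, ploidy) == (o not in possible)


class TestDuoAndMotherExclusions:
    @pytest.mark.parametrize(
        "off,cand,ploidy,expected",
        [
            (3, 0, 3, True),   # candidate BB, offspring AAA
            (2, 1, 3, False),  # heterozygous candidate never excluded
            (1, 2, 2, False),  # AA parent with AB offspring is fine
            (0, 2, 2, True),
        ],
    )
    def test_duo_examples(self, off, cand, ploidy, expected):
        assert duo_exclusion(off, cand, ploidy) is expected

    @pytest.mark.parametrize("ploidy", [2, 3])
    def test_duo_allele_relabel_symmetry(self, ploidy):
        for off in range(ploidy + 1):
            for cand in range(3):
                assert duo_exclusion(off, cand, ploidy) == duo_exclusion(
                    ploidy - off, 2 - cand, ploidy
                )

    def test_mother_exclusion_truth_table(self):
        expected_true = {(1, 2), (0, 2), (3, 0), (2, 0)}
        cells = {
            (off, cand)
            for off in range(4)
            for cand in range(3)
            if mother_exclusion(off, cand)
        }
        assert cells == expected_true


class TestDuoStats:
    def test_er_arithmetic(self):
        stats = DuoStats("o", "c", n_compared=10_000, n_exclusions=5,
                         n_mother_exclusions=8)
        assert stats.er == pytest.approx(0.0005)
        assert stats.mother_er == pytest.approx(0.0008)

    def test_missing_genotypes_do_not_count(self):
        off = np.array([0.0, np.nan, 3.0, 2.0])
        cand = np.array([2.0, 2.0, np.nan, 0.0])
        stats = compute_duo_stats(off, cand, ploidy=3)
        assert stats.n_compared == 2
        assert stats.n_exclusions == 1  # only (off=0, cand=AA)

    def test_true_child_has_zero_er_without_errors(self, rng):
        p = rng.uniform(0.1, 0.5, 2000)
        mother = rng.binomial(2, p).astype(float)
        father = rng.binomial(2, p).astype(float)
        # triploid child: duplicated maternal haplotype plus one paternal allele
        m_hap = np.where(mother == 1, rng.integers(0, 2, 2000), mother / 2)
        f_hap = np.where(father == 1, rng.integers(0, 2, 2000), father / 2)
        child = 2 * m_hap + f_hap
        stats = compute_duo_stats(child, mother, 3)
        assert stats.n_exclusions == 0
        stats = compute_duo_stats(child, father, 3)
        assert stats.n_exclusions == 0

    def test_unrelated_duo_er_matches_enumerated_expectation(self):
        """With no crossovers, P(offspring BBB) = q^2 and P(AAA) = p^2, so an
        independent HWE candidate expects ER = mean(2 p^2 q^2)."""
        cfg = SimConfig(
            n_markers=10_000, n_mothers=2, n_fathers=2, offspring_per_cross=1,
            maf_low=0.1, maf_high=0.5, crossover_rate=0.0,
            genotype_error_rate=0.0, seed=77,
        )
        sim = simulate_dataset(cfg)
        rng = np.random.default_rng(78)
        p = sim.allele_freqs
        candidate = rng.binomial(2, p).astype(float)
        expected = 2 * p**2 * (1 - p) ** 2
        off = sim.offspring_truth.dosages[:, 0]
        stats = compute_duo_stats(off, candidate, 3)
        se = np.sqrt(np.sum(expected * (1 - expected))) / len(p)
        assert abs(stats.er - expected.mean()) < 3 * se


class TestAssignmentRules:
    def _stats(self, ers):
        return [
            DuoStats("o", f"c{i}", 10_000, int(round(er * 10_000)), 0)
            for i, er in enumerate(ers)
        ]

    def test_threshold_is_strict(self):
        assigned, conflict = assign_parents(self._stats([0.0003, 0.0008, 0.004]))
        assert assigned == ["c0", "c1"] and not conflict
        assigned, _ = assign_parents(self._stats([0.002]))
        assert assigned == []  # exactly at the threshold is NOT assigned

    def test_three_candidates_flag_conflict(self):
        assigned, conflict = assign_parents(self._stats([0.0, 0.0001, 0.0005]))
        assert len(assigned) == 3 and conflict

    def test_sex_labels_and_boundary(self):
        stats = [
            DuoStats("o", "mum", 1000, 0, 10),   # mother.ER 0.01
            DuoStats("o", "dad", 1000, 0, 20),   # mother.ER 0.02 exactly
        ]
        labels, conflict = predict_parent_sex(stats)
        assert labels == {"mum": "mother", "dad": "father"}
        assert not conflict

    def test_two_mothers_flag_conflict(self):
        stats = [
            DuoStats("o", "a", 1000, 0, 1),
            DuoStats("o", "b", 1000, 0, 2),
        ]
        _, conflict = predict_parent_sex(stats)
        assert conflict


class TestTrioStats:
    def test_trio_er_decreases_to_zero_with_error_rate(self):
        ers = []
        for eps in (0.02, 0.005, 0.0):
            cfg = SimConfig(
                n_markers=1500, n_mothers=4, n_fathers=4, offspring_per_cross=2,
                cross_design="paired", genotype_error_rate=eps, seed=31,
            )
            sim = simulate_dataset(cfg)
            stats = compute_trio_stats(
                sim.offspring_observed, sim.parent_observed, sim.pedigree
            )
            ers.append(stats["er"].mean())
        assert ers[0] > ers[1] > ers[2]
        assert ers[2] == 0.0  # no errors -> no Mendelian exclusions

    def test_mother_er_separates_sexes(self):
        cfg = SimConfig(
            n_markers=2500, n_mothers=5, n_fathers=5, offspring_per_cross=2,
            cross_design="paired", genotype_error_rate=0.005, seed=13,
        )
        sim = simulate_dataset(cfg)
        results = ParentageModel(sim.offspring_observed, sim.parent_observed).fit()
        duos = results.duo_stats.set_index(["offspring_id", "candidate_id"])
        for trio in sim.pedigree.itertuples(index=False):
            m_er = duos.loc[(trio.offspring_id, trio.mother_id), "mother_er"]
            f_er = duos.loc[(trio.offspring_id, trio.father_id), "mother_er"]
            assert m_er < f_er


class TestDuplicates:
    def test_exact_copy_reported_and_independents_not(self, rng):
        p = rng.uniform(0.1, 0.5, 5000)
        a = rng.binomial(2, p).astype(float)
        b = rng.binomial(2, p).astype(float)
        gm = GenotypeMatrix(
            2, [f"m{i}" for i in range(5000)], ["a", "copy", "b"],
            np.column_stack([a, a, b]),
        )
        pairs = detect_duplicates(gm)
        assert [(x, y) for x, y, _ in pairs] == [("a", "copy")]

    def test_pairs_without_shared_markers_skipped(self):
        gm = GenotypeMatrix(
            2, ["m1", "m2"], ["a", "b"],
            np.array([[1.0, np.nan], [np.nan, 2.0]]),
        )
        assert detect_duplicates(gm) == []
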