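"""Mendelian exclusion tables, exclusion ratios and parentage assignment.

Diploid offspring receive one allele from each parent.  Pressure-shock
induced triploids retain the second polar body: the mother contributes a
sister-chromatid pair (identical except distal to crossovers, so a
heterozygous mother can pass AA, AB or BB) and the father one allele.
Enumerating those contributions yields, for every parent-genotype
configuration, the offspring genotypes that are impossible under
Mendelian inheritance ("exclusions").

The exclusion ratio ER of an offspring-candidate duo is the number of
opposing-homozygote exclusions divided by the number of markers called in
both.  Mother-specific exclusions add the configurations impossible only
for a mother (who contributes two alleles): a candidate AA cannot mother
an ABB or BBB offspring, a candidate BB cannot mother an AAA or AAB
offspring.  mother.ER built from these separates true mothers (low) from
true fathers (high).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DuoStats",
    "ParentageModel",
    "ParentageResults",
    "assign_parents",
    "compute_duo_stats",
    "compute_trio_stats",
    "detect_duplicates",
    "duo_exclusion",
    "exclusion_table",
    "mother_exclusion",
    "possible_offspring_dosages",
    "predict_parent_sex",
    "trio_exclusion",
]


# -- Mendelian enumeration -------------------------------------------------

def _maternal_pair_contributions(dosage: int) -> set[int]:
    """A-allele counts a triploid offspring can receive from its mother.

    The retained chromatid pair duplicates one maternal haplotype (hom
    state) or carries one allele of each (het state), so a heterozygous
    mother can contribute 0, 1 or 2 copies of A; homozygous mothers always
    contribute two identical alleles.
    """
    return {0, 1, 2} if dosage == 1 else {dosage}


def _gamete_contributions(dosage: int) -> set[int]:
    """A-allele counts in a single gamete of a diploid parent."""
    return {0, 1} if dosage == 1 else {dosage // 2}


def possible_offspring_dosages(
    p1: int | None, p2: int | None, ploidy: int, sexed: bool = True
) -> set[int]:
    """Offspring dosages compatible with the parental genotypes.

    For triploids ``p1`` is the mother and ``p2`` the father when
    ``sexed``; a ``None`` parent is unconstrained.  For diploids both
    parents contribute one allele and ``sexed`` is irrelevant.
    """
    if ploidy == 2:
        c1 = {0, 1} if p1 is None else _gamete_contributions(p1)
        c2 = {0, 1} if p2 is None else _gamete_contributions(p2)
        return {a + b for a in c1 for b in c2}
    if ploidy == 3:
        if not sexed:
            return possible_offspring_dosages(p1, p2, 3, True) | \
                possible_offspring_dosages(p2, p1, 3, True)
        cm = {0, 1, 2} if p1 is None else _maternal_pair_contributions(p1)
        cf = {0, 1} if p2 is None else _gamete_contributions(p2)
        return {a + b for a in cm for b in cf}
    raise ValueError("ploidy must be 2 or 3")


def exclusion_table(ploidy: int, sexed: bool = True) -> pd.DataFrame:
    """All parent configurations with non-empty exclusion sets.

    Reproduces, by enumeration, the published diploid-trio and sexed
    triploid-trio exclusion tables (12 rows each).
    """
    rows = []
    for p1, p2 in itertools.product([None, 0, 1, 2], repeat=2):
        if p1 is None and p2 is None:
            continue
        possible = possible_offspring_dosages(p1, p2, ploidy, sexed)
        excluded = sorted(set(range(ploidy + 1)) - possible)
        if excluded:
            rows.append(
                {"parent1": p1, "parent2": p2, "excluded_offspring": tuple(excluded)}
            )
    # object dtype keeps the None (missing-parent) codes intact
    return pd.DataFrame(rows, dtype=object)


def trio_exclusion(
    offspring: int,
    p1: int | None,
    p2: int | None,
    ploidy: int,
    sexed: bool = True,
) -> bool:
    """True iff the trio configuration is Mendelian-impossible.

    For sexed triploid trios ``p1`` must be the mother.  Unsexed triploid
    trios use only the configurations excluded under both sex orderings.
    """
    return offspring not in possible_offspring_dosages(p1, p2, ploidy, sexed)


def duo_exclusion(offspring: int, candidate: int, ploidy: int) -> bool:
    """Opposing homozygotes: the minimal sex-agnostic duo exclusion."""
    return (candidate == 2 and offspring == 0) or (
        candidate == 0 and offspring == ploidy
    )


def mother_exclusion(offspring: int, candidate: int) -> bool:
    """Triploid offspring genotypes impossible for a candidate *mother*.

    The mother contributes two alleles, so a candidate AA is excluded for
    offspring ABB/BBB and a candidate BB for offspring AAA/AAB (this
    includes the opposing-homozygote cells).
    """
    return (candidate == 2 and offspring <= 1) or (candidate == 0 and offspring >= 2)


# -- exclusion ratios ------------------------------------------------------

@dataclass
class DuoStats:
    """Exclusion statistics for one offspring-candidate pair."""

    offspring_id: str
    candidate_id: str
    n_compared: int
    n_exclusions: int
    n_mother_exclusions: int

    @property
    def er(self) -> float:
        return self.n_exclusions / self.n_compared if self.n_compared else np.nan

    @property
    def mother_er(self) -> float:
        return self.n_mother_exclusions / self.n_compared if self.n_compared else np.nan


def compute_duo_stats(
    offspring: np.ndarray,
    candidate: np.ndarray,
    ploidy: int,
    offspring_id: str = "offspring",
    candidate_id: str = "candidate",
) -> DuoStats:
    """Exclusion counts over the markers called in both vectors."""
    off = np.asarray(offspring, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    if off.shape != cand.shape:
        raise ValueError("offspring and candidate vectors must be aligned")
    both = np.isfinite(off) & np.isfinite(cand)
    o, c = off[both], cand[both]
    n_excl = int(((c == 2) & (o == 0)).sum() + ((c == 0) & (o == ploidy)).sum())
    if ploidy == 3:
        n_mother = int(((c == 2) & (o <= 1)).sum() + ((c == 0) & (o >= 2)).sum())
    else:
        n_mother = n_excl
    return DuoStats(offspring_id, candidate_id, int(both.sum()), n_excl, n_mother)


def assign_parents(
    duo_stats: list[DuoStats], er_threshold: float = 0.002
) -> tuple[list[str], bool]:
    """Candidates with ER strictly below the threshold, plus a conflict
    flag when more than two qualify (possible duplicates or wrong ploidy)."""
    usable = [d for d in duo_stats if d.n_compared > 0]
    assigned = [d.candidate_id for d in usable if d.er < er_threshold]
    return assigned, len(assigned) > 2


def predict_parent_sex(
    assigned_stats: list[DuoStats], mother_er_threshold: float = 0.02
) -> tuple[dict[str, str], bool]:
    """Label assigned parents: mother.ER < threshold -> mother, else father.

    Two mothers or two fathers for one offspring flag a conflict."""
    labels = {
        d.candidate_id: ("mother" if d.mother_er < mother_er_threshold else "father")
        for d in assigned_stats
    }
    values = list(labels.values())
    conflict = values.count("mother") > 1 or values.count("father") > 1
    return labels, conflict


# -- panel-level model -----------------------------------------------------

class ParentageModel:
    """Exclusion-ratio parentage assignment of candidates to offspring.

    Parameters
    ----------
    offspring : GenotypeMatrix
        Called offspring genotypes (ploidy 2 or 3), QC-filtered upstream
        (the published procedure used dICL > 150 with parent marker call
        rates > 95%).
    candidates : GenotypeMatrix
        Diploid candidate-parent genotypes on the same markers (the marker
        intersection is used).
    """

    def __init__(self, offspring: GenotypeMatrix, candidates: GenotypeMatrix) -> None:
        if candidates.ploidy != 2:
            raise ValueError("candidate parents must be diploid")
        shared = [m for m in offspring.marker_ids if m in set(candidates.marker_ids)]
        if not shared:
            raise ValueError("offspring and candidates share no markers")
        self.offspring = offspring.select_markers(shared)
        self.candidates = candidates.select_markers(shared)
        self.ploidy = offspring.ploidy

    def fit(self) -> "ParentageResults":
        off = self.offspring.dosages
        cand = self.candidates.dosages
        off_called = np.isfinite(off)
        cand_called = np.isfinite(cand)

        def crosscount(cand_mask: np.ndarray, off_mask: np.ndarray) -> np.ndarray:
            return cand_mask.astype(float).T @ off_mask.astype(float)

        n_compared = crosscount(cand_called, off_called)
        c_aa, c_bb = cand == 2, cand == 0
        o_lo, o_hi = off == 0, off == self.ploidy
        n_excl = crosscount(c_aa, o_lo) + crosscount(c_bb, o_hi)
        if self.ploidy == 3:
            n_mother = crosscount(c_aa, off <= 1) + crosscount(c_bb, off >= 2)
        else:
            n_mother = n_excl

        pairs = pd.DataFrame(
            {
                "offspring_id": np.repeat(self.offspring.sample_ids,
                                          len(self.candidates.sample_ids)),
                "candidate_id": np.tile(self.candidates.sample_ids,
                                        len(self.offspring.sample_ids)),
                "n_compared": n_compared.T.ravel().astype(int),
                "n_exclusions": n_excl.T.ravel().astype(int),
                "n_mother_exclusions": n_mother.T.ravel().astype(int),
            }
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            pairs["er"] = pairs["n_exclusions"] / pairs["n_compared"]
            pairs["mother_er"] = pairs["n_mother_exclusions"] / pairs["n_compared"]
        dropped = int((pairs["n_compared"] == 0).sum())
        if dropped:
            logger.warning("%d duos share no called markers; dropped", dropped)
        pairs = pairs[pairs["n_compared"] > 0].reset_index(drop=True)
        return ParentageResults(self, pairs)


class ParentageResults:
    """Duo statistics plus threshold-based assignment and sex prediction."""

    def __init__(self, model: ParentageModel, duo_stats: pd.DataFrame) -> None:
        self.model = model
        self.duo_stats = duo_stats

    def assignments(self, er_threshold: float = 0.002) -> pd.DataFrame:
        """Per offspring: candidates with ER < threshold and a conflict flag."""
        rows = []
        for off_id, grp in self.duo_stats.groupby("offspring_id", sort=False):
            hit = grp[grp["er"] < er_threshold]
            rows.append(
                {
                    "offspring_id": off_id,
                    "assigned": tuple(hit["candidate_id"]),
                    "n_assigned": len(hit),
                    "conflict": len(hit) > 2,
                }
            )
        return pd.DataFrame(rows)

    def predict_sex(
        self,
        er_threshold: float = 0.002,
        mother_er_threshold: float = 0.02,
    ) -> pd.DataFrame:
        """Sex labels for assigned parents (mother.ER < threshold -> mother)."""
        rows = []
        for off_id, grp in self.duo_stats.groupby("offspring_id", sort=False):
            hit = grp[grp["er"] < er_threshold]
            for _, duo in hit.iterrows():
                rows.append(
                    {
                        "offspring_id": off_id,
                        "candidate_id": duo["candidate_id"],
                        "mother_er": duo["mother_er"],
                        "sex": "mother"
                        if duo["mother_er"] < mother_er_threshold
                        else "father",
                    }
                )
        out = pd.DataFrame(
            rows, columns=["offspring_id", "candidate_id", "mother_er", "sex"]
        )
        if len(out):
            sex_counts = out.groupby("offspring_id")["sex"].value_counts().unstack(
                fill_value=0
            )
            conflicted = sex_counts.index[(sex_counts > 1).any(axis=1)]
            out["conflict"] = out["offspring_id"].isin(conflicted)
        else:
            out["conflict"] = pd.Series(dtype=bool)
        return out

    def third_lowest_er(self) -> float:
        """Diagnostic for threshold choice: the minimum, over offspring, of
        each offspring's third-lowest duo ER (the closest non-parent)."""
        thirds = [
            grp["er"].nsmallest(3).iloc[-1]
            for _, grp in self.duo_stats.groupby("offspring_id", sort=False)
            if len(grp) >= 3
        ]
        return float(np.min(thirds)) if thirds else np.nan

    def summary(self, er_threshold: float = 0.002) -> str:
        assign = self.assignments(er_threshold)
        n_by = assign["n_assigned"].value_counts().sort_index()
        return "\n".join(
            [
                f"Parentage: {assign.shape[0]} offspring x "
                f"{self.duo_stats['candidate_id'].nunique()} candidates, "
                f"ER threshold {er_threshold}",
                "offspring by number of assigned parents: "
                + ", ".join(f"{k}:{v}" for k, v in n_by.items()),
                f"conflicts: {int(assign['conflict'].sum())}",
                f"min third-lowest ER: {self.third_lowest_er():.5f}",
            ]
        )


def _trio_exclusion_lookup(ploidy: int, sexed: bool) -> np.ndarray:
    """Boolean lookup[p1_code, p2_code, offspring] with parent code 3 = NA."""
    table = np.zeros((4, 4, ploidy + 1), dtype=bool)
    for c1, c2 in itertools.product(range(4), repeat=2):
        p1 = None if c1 == 3 else c1
        p2 = None if c2 == 3 else c2
        for o in range(ploidy + 1):
            table[c1, c2, o] = trio_exclusion(o, p1, p2, ploidy, sexed)
    return table


def compute_trio_stats(
    offspring: GenotypeMatrix,
    parents: GenotypeMatrix,
    trios: pd.DataFrame,
    sexed: bool = True,
) -> pd.DataFrame:
    """Per-trio exclusion counts using the full trio exclusion tables.

    ``trios`` needs columns offspring_id, mother_id, father_id (for
    unsexed diploid trios the two parent columns are interchangeable).
    A marker enters the denominator when the offspring and at least one
    parent have called genotypes.
    """
    lookup = _trio_exclusion_lookup(offspring.ploidy, sexed)
    shared = [m for m in offspring.marker_ids if m in set(parents.marker_ids)]
    off_gm = offspring.select_markers(shared)
    par_gm = parents.select_markers(shared)
    rows = []
    for trio in trios.itertuples(index=False):
        o = off_gm.sample_vector(trio.offspring_id)
        m = par_gm.sample_vector(trio.mother_id)
        f = par_gm.sample_vector(trio.father_id)
        o_ok = np.isfinite(o)
        m_code = np.where(np.isfinite(m), m, 3).astype(int)
        f_code = np.where(np.isfinite(f), f, 3).astype(int)
        informative = o_ok & ((m_code != 3) | (f_code != 3))
        excl = lookup[m_code[informative], f_code[informative],
                      o[informative].astype(int)]
        rows.append(
            {
                "offspring_id": trio.offspring_id,
                "mother_id": trio.mother_id,
                "father_id": trio.father_id,
                "n_compared": int(informative.sum()),
                "n_exclusions": int(excl.sum()),
            }
        )
    out = pd.DataFrame(rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["er"] = out["n_exclusions"] / out["n_compared"]
    return out


def detect_duplicates(
    genotypes: GenotypeMatrix, r_threshold: float = 0.99
) -> list[tuple[str, str, float]]:
    """Sample pairs whose dosage correlation over mutually called markers
    exceeds the threshold (likely duplicated or contaminated samples)."""
    if genotypes.n_samples < 2:
        return []
    frame = genotypes.to_frame()
    corr = frame.corr(min_periods=2)
    out = []
    ids = list(corr.columns)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and r > r_threshold:
                out.append((a, b, float(r)))
    return out
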