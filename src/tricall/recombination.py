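"""Maternal recombination mapping from sexed triploid trios.

At markers where the father is homozygous, the paternal allele in a
triploid offspring is known, so the maternal two-allele contribution can
be deduced by subtraction.  Where the mother is additionally heterozygous
(an *informative* trio), the deduced contribution is heterozygous exactly
when a crossover occurred between the locus and the centromere in the
retained chromatid pair.  The per-marker fraction of heterozygous
maternal contributions therefore traces the gene-centromere
recombination profile along each chromosome: near zero at the centromere
(where recombination is suppressed) and rising with distance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MarkerMap

logger = logging.getLogger(__name__)

__all__ = [
    "build_profile",
    "infer_maternal_states",
    "is_informative",
    "maternal_contribution",
    "segment_crossovers",
]


def maternal_contribution(offspring_dosage: int, father_dosage: int) -> str:
    """Deduce the maternal pair at a locus with a homozygous father.

    Returns 'hom', 'het' or 'inconsistent' (Mendelian-impossible, i.e. a
    genotype error).  A heterozygous father is not informative and raises.
    """
    if father_dosage not in (0, 2):
        raise ValueError("not informative: father must be homozygous")
    maternal_a = offspring_dosage - (1 if father_dosage == 2 else 0)
    if maternal_a == 1:
        return "het"
    if maternal_a in (0, 2):
        return "hom"
    return "inconsistent"


def is_informative(mother_dosage: int, father_dosage: int) -> bool:
    """Heterozygous mother with homozygous father."""
    return mother_dosage == 1 and father_dosage in (0, 2)


def _deduce_states(
    off: np.ndarray, mother: np.ndarray, father: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised deduction: (informative, het, inconsistent) masks."""
    called = np.isfinite(off) & np.isfinite(mother) & np.isfinite(father)
    informative = called & (mother == 1) & ((father == 0) | (father == 2))
    maternal_a = off - (father == 2)
    het = informative & (maternal_a == 1)
    inconsistent = informative & ((maternal_a < 0) | (maternal_a > 2))
    return informative, het, inconsistent


def build_profile(
    offspring: GenotypeMatrix,
    parents: GenotypeMatrix,
    trios: pd.DataFrame,
    marker_map: MarkerMap,
    min_trios: int = 50,
    delta_icl_min: float | None = 50.0,
    offspring_call_rate_min: float | None = 0.80,
    parent_call_rate_min: float | None = 0.95,
) -> pd.DataFrame:
    """Per-marker maternal heterozygous-inheritance profile.

    ``trios`` needs columns offspring_id, mother_id, father_id with sexes
    already assigned.  Markers pass QC (dICL strictly above
    ``delta_icl_min`` using the offspring QC table, offspring marker call
    rate >= 0.80, parent marker call rate >= 0.95 by default; pass None to
    skip a filter), must appear in the marker map, and need at least
    ``min_trios`` informative, Mendelian-consistent trios.  Inconsistent
    trios are dropped from numerator and denominator and tallied.
    """
    shared = [m for m in offspring.marker_ids if m in set(parents.marker_ids)]
    off_gm = offspring.select_markers(shared)
    par_gm = parents.select_markers(shared)

    keep = pd.Series(True, index=shared)
    if delta_icl_min is not None:
        if off_gm.qc is None or "delta_icl" not in off_gm.qc.columns:
            raise ValueError("offspring matrix lacks delta_icl QC")
        keep &= off_gm.qc["delta_icl"] > delta_icl_min
    if offspring_call_rate_min is not None:
        keep &= off_gm.marker_call_rates() >= offspring_call_rate_min - 1e-12
    if parent_call_rate_min is not None:
        keep &= par_gm.marker_call_rates() >= parent_call_rate_min - 1e-12
    kept = [m for m in shared if keep[m]]
    off_gm = off_gm.select_markers(kept)
    par_gm = par_gm.select_markers(kept)

    n_markers = len(kept)
    n_informative = np.zeros(n_markers, dtype=int)
    n_het = np.zeros(n_markers, dtype=int)
    n_inconsistent = np.zeros(n_markers, dtype=int)
    for trio in trios.itertuples(index=False):
        o = off_gm.sample_vector(trio.offspring_id)
        m = par_gm.sample_vector(trio.mother_id)
        f = par_gm.sample_vector(trio.father_id)
        informative, het, bad = _deduce_states(o, m, f)
        n_informative += (informative & ~bad).astype(int)
        n_het += het.astype(int)
        n_inconsistent += bad.astype(int)

    out = pd.DataFrame(
        {
            "marker_id": kept,
            "n_informative": n_informative,
            "n_het_maternal": n_het,
            "n_inconsistent": n_inconsistent,
        }
    )
    mapped = marker_map.table[["marker_id", "chromosome", "position"]]
    unmapped = set(out["marker_id"]) - set(mapped["marker_id"])
    if unmapped:
        logger.warning("%d markers absent from the map; dropped", len(unmapped))
    out = out.merge(mapped, on="marker_id", how="inner")
    out = out[out["n_informative"] >= min_trios].copy()
    out["het_fraction"] = out["n_het_maternal"] / out["n_informative"]
    out = out.sort_values(["chromosome", "position"], kind="mergesort")
    return out[
        [
            "marker_id", "chromosome", "position",
            "n_informative", "n_het_maternal", "het_fraction", "n_inconsistent",
        ]
    ].reset_index(drop=True)


def infer_maternal_states(
    offspring: GenotypeMatrix,
    parents: GenotypeMatrix,
    trios: pd.DataFrame,
    marker_map: MarkerMap,
) -> pd.DataFrame:
    """Long table of deduced maternal het/hom states at informative loci,
    ordered along chromosomes, one row per (trio, marker)."""
    shared = [m for m in offspring.marker_ids if m in set(parents.marker_ids)]
    off_gm = offspring.select_markers(shared)
    par_gm = parents.select_markers(shared)
    order = marker_map.sorted()
    order = order[order["marker_id"].isin(shared)]
    pos_of = {m: i for i, m in enumerate(shared)}
    idx = [pos_of[m] for m in order["marker_id"]]
    rows = []
    for trio in trios.itertuples(index=False):
        o = off_gm.sample_vector(trio.offspring_id)[idx]
        m = par_gm.sample_vector(trio.mother_id)[idx]
        f = par_gm.sample_vector(trio.father_id)[idx]
        informative, het, bad = _deduce_states(o, m, f)
        use = informative & ~bad
        rows.append(
            pd.DataFrame(
                {
                    "offspring_id": trio.offspring_id,
                    "mother_id": trio.mother_id,
                    "marker_id": order["marker_id"].to_numpy()[use],
                    "chromosome": order["chromosome"].to_numpy()[use],
                    "position": order["position"].to_numpy()[use],
                    "het": het[use],
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["offspring_id", "mother_id", "marker_id", "chromosome",
                 "position", "het"]
    )


def segment_crossovers(states: pd.DataFrame, min_run: int = 5) -> pd.DataFrame:
    """Per-offspring crossover intervals by run-length segmentation.

    ``states`` is the output of :func:`infer_maternal_states`.  Runs of
    identical het/hom state shorter than ``min_run`` informative markers
    are absorbed into their neighbours; each retained state change is
    reported as an interval between the flanking informative markers.
    This simple deterministic changepoint report is an extension beyond
    the count profile, not a genetic-map estimate.
    """
    events = []
    for (off_id, chrom), grp in states.groupby(["offspring_id", "chromosome"]):
        grp = grp.sort_values("position", kind="mergesort")
        het = grp["het"].to_numpy()
        pos = grp["position"].to_numpy()
        if het.size < 2 * min_run:
            continue
        # run-length encode, then drop runs below the minimum length
        change = np.flatnonzero(np.diff(het.astype(int)) != 0) + 1
        bounds = np.concatenate([[0], change, [het.size]])
        runs = [
            (het[a], a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b - a >= min_run
        ]
        merged = [runs[0]] if runs else []
        for state, a, b in runs[1:]:
            if state == merged[-1][0]:
                merged[-1] = (state, merged[-1][1], b)
            else:
                merged.append((state, a, b))
        for (s1, a1, b1), (s2, a2, b2) in zip(merged[:-1], merged[1:]):
            events.append(
                {
                    "offspring_id": off_id,
                    "chromosome": chrom,
                    "left_position": int(pos[b1 - 1]),
                    "right_position": int(pos[a2]),
                    "transition": f"{'het' if s1 else 'hom'}->"
                                  f"{'het' if s2 else 'hom'}",
                }
            )
    return pd.DataFrame(
        events,
        columns=["offspring_id", "chromosome", "left_position",
                 "right_position", "transition"],
    )
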