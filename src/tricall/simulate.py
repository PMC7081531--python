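"""Synthetic allele-signal, pedigree and truth-set simulator.

Emulates the statistical structure the calling method assumes: genotype
clusters of contrast values centred near the reference means with
marker-specific shifts and (optionally heteroscedastic) noise,
Hardy-Weinberg diploid parents, triploid offspring formed by
second-polar-body retention, and maternal crossovers whose distance from
the centromere drives the heterozygosity of the retained chromatid pair.

The meiosis model is a deliberately simple switch-process half-tetrad
model with no chiasma interference: per arm the chiasma count is
Poisson(``crossover_rate``) with positions uniform on the arm, and each
chiasma between the centromere and a locus flips the retained pair's
het/hom state independently with probability ``chromatid_switch_prob``.
Its closed-form het fraction at centromere distance d on an arm of
length L,

    y(d) = (1 - exp(-2 * rate * switch_prob * d / L)) / 2,

is the ground truth the recombination profile must recover.

All randomness flows from ``numpy.random.default_rng`` (PCG64); a fixed
seed fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ContrastMatrix, GenotypeMatrix, MarkerMap, ReferenceMeans

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_parents",
    "simulate_signals",
    "simulate_triploid_offspring",
    "true_het_fraction",
]


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults give a desk-scale panel with the cluster geometry and noise
    the method was designed for: reference-mean cluster centres,
    marker-specific shifts of SD 0.15 contrast units, cluster SDs drawn
    from [0.08, 0.25] (half the markers with per-cluster SDs), a 0.5%
    dosage-level genotype error rate, and one crossover per chromosome
    arm per meiosis on average.
    """

    n_markers: int = 1000
    n_mothers: int = 10
    n_fathers: int = 10
    offspring_per_cross: int = 3
    offspring_ploidy: int = 3
    cross_design: str = "factorial"  # or "paired": mother i with father i
    maf_low: float = 0.05
    maf_high: float = 0.5
    marker_shift_sd: float = 0.15
    cluster_sd_low: float = 0.08
    cluster_sd_high: float = 0.25
    heteroscedastic_fraction: float = 0.5
    noisy_marker_fraction: float = 0.0
    noisy_marker_sd: float = 0.6
    signal_size: float = 2000.0
    genotype_error_rate: float = 0.005
    error_mode: str = "dosage"  # or "signal": errors as signal outliers
    n_chromosomes: int = 5
    chromosome_length_bp: int = 100_000_000
    centromere_position_bp: int = 40_000_000
    crossover_rate: float = 1.0
    chromatid_switch_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("heteroscedastic_fraction", "noisy_marker_fraction",
                     "genotype_error_rate", "chromatid_switch_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.maf_low <= self.maf_high <= 1.0:
            raise ValueError("need 0 < maf_low <= maf_high <= 1")
        if min(self.cluster_sd_low, self.cluster_sd_high,
               self.noisy_marker_sd, self.marker_shift_sd) < 0:
            raise ValueError("SDs must be non-negative")
        if self.offspring_ploidy not in (2, 3):
            raise ValueError("offspring ploidy must be 2 or 3")
        if self.cross_design not in ("factorial", "paired"):
            raise ValueError("cross_design must be 'factorial' or 'paired'")


@dataclass
class SimulatedDataset:
    """Simulation outputs plus the truth needed to test every stage."""

    config: SimConfig
    marker_map: MarkerMap
    parent_truth: GenotypeMatrix  # diploid, error-free
    offspring_truth: GenotypeMatrix  # error-free
    parent_observed: GenotypeMatrix  # after dosage-level error injection
    offspring_observed: GenotypeMatrix
    parent_signals: ContrastMatrix
    offspring_signals: ContrastMatrix
    parent_ab: tuple[np.ndarray, np.ndarray]
    offspring_ab: tuple[np.ndarray, np.ndarray]
    pedigree: pd.DataFrame  # offspring_id, mother_id, father_id
    maternal_het_state: np.ndarray | None  # markers x offspring booleans
    crossovers: pd.DataFrame | None  # offspring_id, chromosome, arm, position, active
    marker_class: pd.Series  # "clean" or "noisy" per marker
    allele_freqs: np.ndarray


# -- pieces ----------------------------------------------------------------

def simulate_parents(
    config: SimConfig, rng: np.random.Generator, allele_freqs: np.ndarray | None = None
) -> tuple[GenotypeMatrix, GenotypeMatrix, np.ndarray]:
    """Hardy-Weinberg diploid parents: (mothers, fathers, A-allele freqs)."""
    p = (
        rng.uniform(config.maf_low, config.maf_high, config.n_markers)
        if allele_freqs is None
        else np.asarray(allele_freqs)
    )
    mother_ids = [f"M{i:03d}" for i in range(config.n_mothers)]
    father_ids = [f"F{i:03d}" for i in range(config.n_fathers)]
    mothers = rng.binomial(2, p[:, None], (config.n_markers, config.n_mothers))
    fathers = rng.binomial(2, p[:, None], (config.n_markers, config.n_fathers))
    markers = [f"SNP{i:05d}" for i in range(config.n_markers)]
    return (
        GenotypeMatrix(2, markers, mother_ids, mothers.astype(float)),
        GenotypeMatrix(2, markers, father_ids, fathers.astype(float)),
        p,
    )


def make_marker_map(config: SimConfig, marker_ids: list[str]) -> MarkerMap:
    """Markers spread evenly over equal-length chromosomes."""
    n = len(marker_ids)
    per = int(np.ceil(n / config.n_chromosomes))
    chroms, positions = [], []
    for i in range(n):
        c, j = divmod(i, per)
        n_on = min(per, n - c * per)
        chroms.append(f"chr{c + 1:02d}")
        positions.append(int((j + 1) * config.chromosome_length_bp / (n_on + 1)))
    return MarkerMap(
        pd.DataFrame(
            {"marker_id": marker_ids, "chromosome": chroms, "position": positions}
        )
    )


def _phase(dosages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random phasing of diploid dosages -> haplotype array (markers, 2)."""
    n = dosages.shape[0]
    h = np.zeros((n, 2), dtype=np.int8)
    h[dosages == 2] = 1
    het = dosages == 1
    which = rng.integers(0, 2, het.sum())
    h[np.flatnonzero(het), which] = 1
    return h


def _meiosis_states(
    positions: np.ndarray,
    arm: np.ndarray,
    dist: np.ndarray,
    arm_lengths: dict[int, float],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, float, bool]]]:
    """Het/hom state of the retained chromatid pair at each locus of one
    chromosome for one meiosis, plus the chiasma list (arm, position, active)."""
    state = np.zeros(positions.size, dtype=bool)
    chiasmata = []
    for a, length in arm_lengths.items():
        if length <= 0:
            continue
        k = rng.poisson(config.crossover_rate)
        if k == 0:
            continue
        d = rng.uniform(0, length, k)
        active = rng.random(k) < config.chromatid_switch_prob
        for dd, act in zip(d, active):
            chiasmata.append((a, float(dd), bool(act)))
        on_arm = arm == a
        flips = (
            (d[None, :] < dist[on_arm][:, None]) & active[None, :]
        ).sum(axis=1)
        state[on_arm] = flips % 2 == 1
    return state, chiasmata


def true_het_fraction(
    positions: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Closed-form maternal het fraction y(d) at the given bp positions."""
    c = config.centromere_position_bp
    length = config.chromosome_length_bp
    pos = np.asarray(positions, dtype=float)
    dist = np.abs(pos - c)
    arm_len = np.where(pos < c, c, length - c).astype(float)
    lam = 2.0 * config.crossover_rate * config.chromatid_switch_prob
    return 0.5 * (1.0 - np.exp(-lam * dist / np.maximum(arm_len, 1.0)))


def simulate_triploid_offspring(
    mothers: GenotypeMatrix,
    fathers: GenotypeMatrix,
    pedigree: pd.DataFrame,
    marker_map: MarkerMap,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, np.ndarray, pd.DataFrame]:
    """Triploid offspring by second-polar-body retention.

    Per meiosis and chromosome the mother passes a chromatid pair whose
    het/hom state follows the switch-process model; at het loci the pair
    carries one allele of each maternal haplotype, at hom loci two copies
    of one haplotype.  The father contributes one haplotype allele per
    chromosome.  Returns (offspring truth, het-state matrix, crossovers).
    """
    table = marker_map.table
    marker_to_row = {m: i for i, m in enumerate(mothers.marker_ids)}
    order = [marker_to_row[m] for m in table["marker_id"]]
    chrom_codes, chrom_index = pd.factorize(table["chromosome"])
    positions = table["position"].to_numpy(float)
    c = config.centromere_position_bp
    dist = np.abs(positions - c)
    arm = (positions >= c).astype(int)  # 0 = p-arm, 1 = q-arm
    arm_lengths = {0: float(c), 1: float(config.chromosome_length_bp - c)}

    n_markers = mothers.n_markers
    n_off = len(pedigree)
    dosages = np.zeros((n_markers, n_off), dtype=np.int8)
    het_state = np.zeros((n_markers, n_off), dtype=bool)
    xo_rows = []

    mother_haps = {
        s: _phase(mothers.sample_vector(s).astype(int), rng)
        for s in mothers.sample_ids
    }
    father_haps = {
        s: _phase(fathers.sample_vector(s).astype(int), rng)
        for s in fathers.sample_ids
    }

    for j, trio in enumerate(pedigree.itertuples(index=False)):
        mh = mother_haps[trio.mother_id]
        fh = father_haps[trio.father_id]
        for ci in range(len(chrom_index)):
            on = chrom_codes == ci
            rows = np.asarray(order)[on]
            state, chiasmata = _meiosis_states(
                positions[on], arm[on], dist[on], arm_lengths, config, rng
            )
            base = rng.integers(0, 2)  # duplicated haplotype at hom loci
            maternal = np.where(
                state, mh[rows, 0] + mh[rows, 1], 2 * mh[rows, base]
            )
            paternal = fh[rows, rng.integers(0, 2)]
            dosages[rows, j] = maternal + paternal
            het_state[rows, j] = state
            for a, d, act in chiasmata:
                xo_rows.append(
                    {
                        "offspring_id": trio.offspring_id,
                        "chromosome": chrom_index[ci],
                        "arm": "p" if a == 0 else "q",
                        "distance_bp": d,
                        "active": act,
                    }
                )

    offspring_ids = list(pedigree["offspring_id"])
    gm = GenotypeMatrix(3, list(mothers.marker_ids), offspring_ids,
                        dosages.astype(float))
    xo = pd.DataFrame(
        xo_rows, columns=["offspring_id", "chromosome", "arm", "distance_bp", "active"]
    )
    return gm, het_state, xo


def simulate_diploid_offspring(
    mothers: GenotypeMatrix,
    fathers: GenotypeMatrix,
    pedigree: pd.DataFrame,
    marker_map: MarkerMap,
    config: SimConfig,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Diploid offspring: one random parental haplotype per chromosome."""
    table = marker_map.table
    marker_to_row = {m: i for i, m in enumerate(mothers.marker_ids)}
    order = [marker_to_row[m] for m in table["marker_id"]]
    chrom_codes, chrom_index = pd.factorize(table["chromosome"])
    n_off = len(pedigree)
    dosages = np.zeros((mothers.n_markers, n_off), dtype=np.int8)
    mother_haps = {
        s: _phase(mothers.sample_vector(s).astype(int), rng)
        for s in mothers.sample_ids
    }
    father_haps = {
        s: _phase(fathers.sample_vector(s).astype(int), rng)
        for s in fathers.sample_ids
    }
    for j, trio in enumerate(pedigree.itertuples(index=False)):
        mh, fh = mother_haps[trio.mother_id], father_haps[trio.father_id]
        for ci in range(len(chrom_index)):
            rows = np.asarray(order)[chrom_codes == ci]
            dosages[rows, j] = (
                mh[rows, rng.integers(0, 2)] + fh[rows, rng.integers(0, 2)]
            )
    return GenotypeMatrix(
        2, list(mothers.marker_ids), list(pedigree["offspring_id"]),
        dosages.astype(float),
    )


def _inject_dosage_errors(
    dosages: np.ndarray, ploidy: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Replace a fraction of dosages by a uniformly different dosage."""
    out = dosages.copy()
    hit = rng.random(out.shape) < rate
    if hit.any():
        offsets = rng.integers(1, ploidy + 1, hit.sum())
        out[hit] = (out[hit] + offsets) % (ploidy + 1)
    return out


def simulate_signals(
    dosages: np.ndarray,
    ploidy: int,
    config: SimConfig,
    rng: np.random.Generator,
    marker_class: np.ndarray | None = None,
    shifts: np.ndarray | None = None,
    cluster_sds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contrast and (A, B) signal matrices for a dosage matrix.

    Per marker a common shift ~ N(0, marker_shift_sd) moves all cluster
    centres; cluster SDs are shared or per-cluster depending on the
    marker's heteroscedasticity draw, and "noisy" markers use
    ``noisy_marker_sd`` for every cluster.  Signals are reconstructed from
    the contrast with a fixed total ``signal_size`` = A + B.
    """
    n_markers, n_samples = dosages.shape
    ref = ReferenceMeans.defaults(ploidy).means
    if shifts is None:
        shifts = rng.normal(0.0, config.marker_shift_sd, n_markers)
    if cluster_sds is None:
        hetero = rng.random(n_markers) < config.heteroscedastic_fraction
        cluster_sds = np.where(
            hetero[:, None],
            rng.uniform(config.cluster_sd_low, config.cluster_sd_high,
                        (n_markers, ploidy + 1)),
            rng.uniform(config.cluster_sd_low, config.cluster_sd_high,
                        (n_markers, 1)),
        )
        if marker_class is not None:
            cluster_sds = np.where(
                (marker_class == "noisy")[:, None], config.noisy_marker_sd,
                cluster_sds,
            )
    d = dosages.astype(int)
    means = ref[d] + shifts[:, None]
    sds = np.take_along_axis(cluster_sds, d, axis=1)
    contrast = rng.normal(means, sds)
    if config.error_mode == "signal":
        hit = rng.random(contrast.shape) < config.genotype_error_rate
        contrast = np.where(
            hit, rng.uniform(ref[0] - 1.0, ref[-1] + 1.0, contrast.shape), contrast
        )
    ratio = np.exp2(contrast)
    a = config.signal_size * ratio / (1.0 + ratio)
    b = config.signal_size / (1.0 + ratio)
    return contrast, a, b


def _make_pedigree(config: SimConfig) -> pd.DataFrame:
    mother_ids = [f"M{i:03d}" for i in range(config.n_mothers)]
    father_ids = [f"F{i:03d}" for i in range(config.n_fathers)]
    rows = []
    if config.cross_design == "factorial":
        crosses = [(m, f) for m in mother_ids for f in father_ids]
    else:
        if config.n_mothers != config.n_fathers:
            raise ValueError("paired design needs equal mother/father counts")
        crosses = list(zip(mother_ids, father_ids))
    k = 0
    for m, f in crosses:
        for _ in range(config.offspring_per_cross):
            rows.append({"offspring_id": f"O{k:04d}", "mother_id": m, "father_id": f})
            k += 1
    return pd.DataFrame(rows)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full study simulation: parents, offspring, truth and signals."""
    rng = np.random.default_rng(config.seed)
    mothers, fathers, p = simulate_parents(config, rng)
    markers = list(mothers.marker_ids)
    marker_map = make_marker_map(config, markers)
    pedigree = _make_pedigree(config)

    if config.offspring_ploidy == 3:
        offspring, het_state, crossovers = simulate_triploid_offspring(
            mothers, fathers, pedigree, marker_map, config, rng
        )
    else:
        offspring = simulate_diploid_offspring(
            mothers, fathers, pedigree, marker_map, config, rng
        )
        het_state, crossovers = None, None

    n_noisy = int(round(config.noisy_marker_fraction * config.n_markers))
    marker_class = np.array(["clean"] * config.n_markers, dtype=object)
    if n_noisy:
        marker_class[rng.choice(config.n_markers, n_noisy, replace=False)] = "noisy"
    marker_class = pd.Series(marker_class, index=markers, name="marker_class")

    parent_dosages = np.hstack([mothers.dosages, fathers.dosages])
    parent_ids = mothers.sample_ids + fathers.sample_ids
    parent_truth = GenotypeMatrix(2, markers, parent_ids, parent_dosages)

    if config.error_mode == "dosage" and config.genotype_error_rate > 0:
        parent_obs = _inject_dosage_errors(
            parent_truth.dosages, 2, config.genotype_error_rate, rng
        )
        off_obs = _inject_dosage_errors(
            offspring.dosages, config.offspring_ploidy,
            config.genotype_error_rate, rng,
        )
    else:
        parent_obs = parent_truth.dosages.copy()
        off_obs = offspring.dosages.copy()
    parent_observed = GenotypeMatrix(2, markers, parent_ids, parent_obs)
    offspring_observed = GenotypeMatrix(
        config.offspring_ploidy, markers, list(offspring.sample_ids), off_obs
    )

    # shared per-marker shift so parent and offspring panels are consistent
    shifts = rng.normal(0.0, config.marker_shift_sd, config.n_markers)
    pc, pa, pb = simulate_signals(
        parent_obs, 2, config, rng, marker_class.to_numpy(), shifts=shifts
    )
    oc, oa, ob = simulate_signals(
        off_obs, config.offspring_ploidy, config, rng,
        marker_class.to_numpy(), shifts=shifts,
    )
    return SimulatedDataset(
        config=config,
        marker_map=marker_map,
        parent_truth=parent_truth,
        offspring_truth=offspring,
        parent_observed=parent_observed,
        offspring_observed=offspring_observed,
        parent_signals=ContrastMatrix(markers, parent_ids, pc),
        offspring_signals=ContrastMatrix(markers, list(offspring.sample_ids), oc),
        parent_ab=(pa, pb),
        offspring_ab=(oa, ob),
        pedigree=pedigree,
        maternal_het_state=het_state,
        crossovers=crossovers,
        marker_class=marker_class,
        allele_freqs=p,
    )
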