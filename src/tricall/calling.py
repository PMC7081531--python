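"""Per-marker model selection and genotype calling.

For every marker, all candidate mixtures ({1..ploidy+1} clusters x {E, V}
variance modes) are fitted and scored by ICL.  The best cluster count
classifies the samples; clusters map to allele dosages either by rank
(when all ploidy+1 clusters are present, the lowest-contrast cluster is
the all-B genotype) or by nearest reference contrast mean (when fewer
clusters are present).  Two clusters mapping to the same reference mean
make the whole locus a no-call.  A sample call whose membership
uncertainty (1 minus the winning posterior) exceeds the threshold is a
no-call; the threshold default 0.15 is applied strictly ("exceeds", so a
call at exactly 0.15 is kept).

Marker quality is summarised by dICL (ICL difference between the two
most likely cluster counts; +inf when only one count is feasible) and the
marker call rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ContrastMatrix, GenotypeMatrix, ReferenceMeans
from .mixture import (
    EMConfig,
    MarkerMixture,
    MarkerMixtureResults,
    enumerate_candidate_models,
    estimate_initial_partition,
)

logger = logging.getLogger(__name__)

LOCUS_NOCALL = "locus_nocall"

__all__ = [
    "CallingConfig",
    "GenotypeCallingModel",
    "GenotypeCallingResults",
    "MarkerCall",
    "call_marker",
    "call_samples",
    "filter_markers",
    "map_clusters_to_dosage",
    "sample_call_rates",
    "select_best_model",
]


@dataclass
class CallingConfig:
    uncertainty_threshold: float = 0.15
    em: EMConfig = field(default_factory=EMConfig)


@dataclass
class MarkerCall:
    """Calling outcome for one marker."""

    marker_id: str
    n_clusters: int
    variance_mode: str
    icl: float
    delta_icl: float
    cluster_means: np.ndarray
    cluster_to_dosage: dict[int, int] | None  # None -> locus no-call
    dosages: np.ndarray  # per sample, NaN missing
    uncertainties: np.ndarray  # per sample, NaN where contrast missing
    call_rate: float
    failed: bool = False

    @property
    def locus_nocall(self) -> bool:
        return self.cluster_to_dosage is None and not self.failed


def select_best_model(
    fits: list[MarkerMixtureResults],
) -> tuple[MarkerMixtureResults, float]:
    """Pick the max-ICL fit; dICL against the runner-up cluster count.

    Per cluster count only the better variance mode competes.  Ties in ICL
    break toward the smaller cluster count.  With a single feasible
    cluster count dICL is +inf.
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fits")
    best_by_g: dict[int, MarkerMixtureResults] = {}
    for f in converged:
        cur = best_by_g.get(f.g)
        if cur is None or f.icl > cur.icl:
            best_by_g[f.g] = f
    ranked = sorted(best_by_g.values(), key=lambda f: (-f.icl, f.g))
    best = ranked[0]
    delta = math.inf if len(ranked) == 1 else best.icl - ranked[1].icl
    return best, delta


def map_clusters_to_dosage(
    fit: MarkerMixtureResults, reference: ReferenceMeans
) -> dict[int, int] | None:
    """Map ascending clusters to dosages; None marks the locus a no-call.

    With all ploidy+1 clusters present the mapping is by rank.  Otherwise
    each cluster mean maps to the dosage of the nearest reference mean;
    any collision voids the locus.
    """
    ploidy = reference.ploidy
    if fit.g == ploidy + 1:
        return {k: k for k in range(fit.g)}
    nearest = np.abs(fit.means[:, None] - reference.means[None, :]).argmin(axis=1)
    if len(set(nearest.tolist())) < fit.g:
        return None
    return {k: int(d) for k, d in enumerate(nearest)}


def call_samples(
    fit: MarkerMixtureResults,
    mapping: dict[int, int],
    uncertainty_threshold: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify the fitted observations; no-call where uncertainty exceeds
    the threshold.  Posterior ties go to the lower-contrast cluster."""
    resp = fit.responsibilities
    winner = resp.argmax(axis=1)  # argmax returns the first (lowest) on ties
    uncertainty = 1.0 - resp[np.arange(resp.shape[0]), winner]
    dosages = np.array([float(mapping[k]) for k in winner])
    # strict "exceeds"; the ulp guard keeps exact-boundary calls (e.g. a
    # posterior of 0.85 under the default 0.15) from flipping on rounding
    dosages[uncertainty > uncertainty_threshold + 1e-12] = np.nan
    return dosages, uncertainty


def call_marker(
    contrasts: np.ndarray,
    ploidy: int,
    reference: ReferenceMeans | None = None,
    config: CallingConfig | None = None,
    marker_id: str = "",
) -> MarkerCall:
    """Full calling procedure for one marker's contrast vector.

    NaN contrasts stay missing.  Markers with fewer than two usable
    observations, or where every candidate fit fails, are flagged failed
    (100% no-call).
    """
    config = config or CallingConfig()
    reference = reference or ReferenceMeans.defaults(ploidy)
    x = np.asarray(contrasts, dtype=float)
    obs_mask = np.isfinite(x)
    n_obs = int(obs_mask.sum())
    n_samples = x.size

    def _failed() -> MarkerCall:
        return MarkerCall(
            marker_id, 0, "", np.nan, np.nan, np.array([]), None,
            np.full(n_samples, np.nan), np.full(n_samples, np.nan), 0.0,
            failed=True,
        )

    if n_obs < 2:
        return _failed()

    fits: list[MarkerMixtureResults] = []
    for g, mode in enumerate_candidate_models(ploidy):
        if g > n_obs:
            continue
        try:
            init = estimate_initial_partition(x, ploidy, g, reference.means)
            fits.append(
                MarkerMixture(x, g, mode, init=init, config=config.em).fit()
            )
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover
            logger.debug("marker %s g=%d mode=%s failed: %s", marker_id, g, mode, exc)
    try:
        best, delta_icl = select_best_model(fits)
    except ValueError:
        logger.warning("marker %s: no converged mixture fit", marker_id)
        return _failed()

    mapping = map_clusters_to_dosage(best, reference)
    dosages = np.full(n_samples, np.nan)
    uncertainties = np.full(n_samples, np.nan)
    if mapping is not None:
        called, unc = call_samples(best, mapping, config.uncertainty_threshold)
        dosages[obs_mask] = called
        uncertainties[obs_mask] = unc
    call_rate = float(np.isfinite(dosages).mean()) if n_samples else 0.0
    return MarkerCall(
        marker_id=marker_id,
        n_clusters=best.g,
        variance_mode=best.variance_mode,
        icl=best.icl,
        delta_icl=delta_icl,
        cluster_means=best.means,
        cluster_to_dosage=mapping,
        dosages=dosages,
        uncertainties=uncertainties,
        call_rate=call_rate,
    )


class GenotypeCallingModel:
    """Mixture-model genotype caller for a contrast matrix.

    Parameters
    ----------
    contrasts : ContrastMatrix
        markers x samples log2 signal ratios.
    ploidy : int
        Ploidy of the genotyped individuals (2 or 3 supported end to end).
    reference_means : ReferenceMeans, optional
        Per-dosage reference contrast means; defaults to the published
        calibration estimates for the given ploidy.
    """

    def __init__(
        self,
        contrasts: ContrastMatrix,
        ploidy: int,
        reference_means: ReferenceMeans | None = None,
        config: CallingConfig | None = None,
    ) -> None:
        self.contrasts = contrasts
        self.ploidy = int(ploidy)
        self.reference_means = reference_means or ReferenceMeans.defaults(ploidy)
        self.config = config or CallingConfig()

    def fit(self) -> "GenotypeCallingResults":
        calls = [
            call_marker(
                self.contrasts.contrast[i],
                self.ploidy,
                self.reference_means,
                self.config,
                marker_id=marker,
            )
            for i, marker in enumerate(self.contrasts.marker_ids)
        ]
        return GenotypeCallingResults(self, calls)


class GenotypeCallingResults:
    """Called genotypes plus per-marker QC for a panel."""

    def __init__(self, model: GenotypeCallingModel, calls: list[MarkerCall]) -> None:
        self.model = model
        self.calls = calls
        cm = model.contrasts
        dosages = np.vstack([c.dosages for c in calls]) if calls else np.empty((0, cm.n_samples))
        self.qc = pd.DataFrame(
            {
                "n_clusters": [c.n_clusters for c in calls],
                "variance_mode": [c.variance_mode for c in calls],
                "icl": [c.icl for c in calls],
                "delta_icl": [c.delta_icl for c in calls],
                "call_rate": [c.call_rate for c in calls],
                "locus_nocall_flag": [c.locus_nocall for c in calls],
                "failed": [c.failed for c in calls],
            },
            index=pd.Index(cm.marker_ids, name="marker_id"),
        )
        self.genotypes = GenotypeMatrix(
            model.ploidy, list(cm.marker_ids), list(cm.sample_ids), dosages, self.qc
        )

    def filter_markers(
        self, delta_icl_min: float = 0.0, marker_call_rate_min: float = 0.0
    ) -> GenotypeMatrix:
        gm, _ = filter_markers(self.genotypes, delta_icl_min, marker_call_rate_min)
        return gm

    def estimate_reference_means(self) -> ReferenceMeans:
        """Reference means recomputed from this panel: per-dosage average of
        fitted cluster means across markers showing all ploidy+1 clusters."""
        full = [
            c.cluster_means for c in self.calls
            if c.n_clusters == self.model.ploidy + 1
        ]
        if not full:
            raise ValueError("no marker shows all clusters; cannot calibrate")
        return ReferenceMeans(self.model.ploidy, np.vstack(full).mean(axis=0))

    def summary(self) -> str:
        qc = self.qc
        counts = qc["n_clusters"].value_counts().sort_index()
        lines = [
            f"Genotype calling: {len(self.calls)} markers x "
            f"{self.genotypes.n_samples} samples, ploidy {self.model.ploidy}",
            "markers per selected cluster count: "
            + ", ".join(f"{g}:{c}" for g, c in counts.items()),
            f"locus no-calls: {int(qc['locus_nocall_flag'].sum())}, "
            f"failed markers: {int(qc['failed'].sum())}",
            f"mean marker call rate: {qc['call_rate'].mean():.4f}",
        ]
        return "\n".join(lines)


def filter_markers(
    matrix: GenotypeMatrix,
    delta_icl_min: float,
    marker_call_rate_min: float,
) -> tuple[GenotypeMatrix, int]:
    """Retain markers with delta_icl strictly above and call rate at least
    the thresholds; returns (subset, number of removed markers).

    The dICL comparison is strict (a marker at exactly the threshold is
    removed); the call-rate comparison is >= with an ulp tolerance.
    """
    if matrix.qc is None or "delta_icl" not in matrix.qc.columns:
        raise ValueError("genotype matrix lacks QC fields")
    qc = matrix.qc
    keep = (qc["delta_icl"] > delta_icl_min) & (
        qc["call_rate"] >= marker_call_rate_min - 1e-12
    )
    kept_ids = [m for m, k in zip(matrix.marker_ids, keep.to_numpy()) if k]
    return matrix.select_markers(kept_ids), int(len(matrix.marker_ids) - len(kept_ids))


def sample_call_rates(matrix: GenotypeMatrix) -> pd.Series:
    """Called markers / total markers, per sample."""
    return matrix.sample_call_rates()
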