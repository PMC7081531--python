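"""Univariate finite normal mixtures for genotype-cluster fitting.

A marker's contrast values are modelled as a mixture of G normal
components, one per genotype cluster, with either a shared variance
('E' model) or per-cluster variances ('V' model).  Fitting is MAP-EM:
cluster means carry a normal prior centred on the means of the
left-to-right initial partition, with precision equivalent to ``kappa``
pseudo-observations at the initial within-block variance.  The anchor
steers early iterations toward the allele-frequency informed
initialisation but is swamped by the data precision once clusters
tighten, so converged means on well-populated clusters are unbiased.
Variances and weights are unpenalized.

Model scoring uses the "larger is better" conventions

    BIC = 2*loglik - n_params*log(n)
    ICL = BIC - 2*entropy,   entropy = -sum_i sum_g z_ig log z_ig

so that ICL <= BIC always, with equality under hard classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

__all__ = [
    "EMConfig",
    "InitialPartition",
    "MarkerMixture",
    "MarkerMixtureResults",
    "enumerate_candidate_models",
    "estimate_initial_partition",
    "fit_mixture",
    "score_fit",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class EMConfig:
    """EM settings.

    tolerance: relative change of the log posterior declaring convergence.
    variance_floor: lower bound on cluster variances (contrast units^2),
        preventing degenerate spikes on duplicated values.
    kappa: pseudo-observation strength of the normal prior on cluster means.
    """

    tolerance: float = 1e-6
    max_iterations: int = 500
    variance_floor: float = 1e-4
    kappa: float = 1.0


@dataclass
class InitialPartition:
    """Left-to-right initial clustering: block sizes and block means."""

    cluster_sizes: np.ndarray
    cluster_means: np.ndarray

    def __post_init__(self) -> None:
        self.cluster_sizes = np.asarray(self.cluster_sizes, dtype=int)
        self.cluster_means = np.asarray(self.cluster_means, dtype=float)
        if (self.cluster_sizes < 1).any():
            raise ValueError("every initial cluster must hold at least one observation")


def enumerate_candidate_models(ploidy: int) -> list[tuple[int, str]]:
    """All (cluster count, variance mode) candidates: {1..ploidy+1} x {E, V}.

    8 candidates for triploids, 6 for diploids.
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    return [(g, mode) for g in range(1, ploidy + 2) for mode in ("E", "V")]


def estimate_initial_partition(
    contrasts: np.ndarray,
    ploidy: int,
    g: int,
    reference_means: np.ndarray,
) -> InitialPartition:
    """Allele-frequency informed left-to-right initial clustering.

    Each observation is hard-assigned to the nearest reference contrast
    mean, giving a rough per-dosage occupancy and an allele-frequency
    estimate ``p = mean dosage / ploidy`` (clipped to [1/(2n), 1-1/(2n)]).
    The g dosage classes with the largest occupancy are retained (ties
    broken by binomial mass, then by lower dosage), expected proportions
    are the renormalised Binomial(ploidy, p) masses of those classes, and
    block sizes follow by largest-remainder rounding with a minimum of one
    observation per cluster.  Block means are means of the contrast-sorted
    blocks.
    """
    x = np.asarray(contrasts, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if not 1 <= g <= ploidy + 1:
        raise ValueError(f"g must be in 1..{ploidy + 1}")
    if n < g:
        raise ValueError(f"insufficient observations: {n} < g={g}")
    ref = np.asarray(reference_means, dtype=float)

    hard_dosage = np.abs(x[:, None] - ref[None, :]).argmin(axis=1)
    p_hat = float(np.clip(hard_dosage.mean() / ploidy, 1 / (2 * n), 1 - 1 / (2 * n)))
    mass = binom.pmf(np.arange(ploidy + 1), ploidy, p_hat)
    counts = np.bincount(hard_dosage, minlength=ploidy + 1)

    # classes ranked by observed occupancy, then binomial mass, then low dosage
    order = sorted(range(ploidy + 1), key=lambda d: (-counts[d], -mass[d], d))
    chosen = sorted(order[:g])
    props = mass[chosen]
    total = props.sum()
    props = props / total if total > 0 else np.full(g, 1.0 / g)

    sizes = _largest_remainder(props, n)
    x_sorted = np.sort(x)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    means = np.array(
        [x_sorted[bounds[k]:bounds[k + 1]].mean() for k in range(g)]
    )
    return InitialPartition(sizes, means)


def _largest_remainder(props: np.ndarray, n: int) -> np.ndarray:
    """Integer block sizes summing to n, each >= 1."""
    raw = props * n
    sizes = np.floor(raw).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(raw - sizes), kind="stable")
    for k in order[:remainder]:
        sizes[k] += 1
    # enforce the minimum of one by borrowing from the largest block
    while (sizes < 1).any():
        sizes[sizes.argmin()] += 1
        sizes[sizes.argmax()] -= 1
    return sizes


@dataclass
class MarkerMixtureResults:
    """A fitted univariate normal mixture for one marker."""

    g: int
    variance_mode: str
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    n_params: int
    converged: bool
    responsibilities: np.ndarray
    n_obs: int
    n_iter: int = 0
    bic: float = field(default=np.nan)
    icl: float = field(default=np.nan)
    objective_trace: np.ndarray | None = None

    def entropy(self) -> float:
        z = self.responsibilities
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(z > 0, z * np.log(z), 0.0)
        return float(-t.sum())

    def summary(self) -> str:
        lines = [
            f"Normal mixture, G={self.g}, mode={self.variance_mode}, "
            f"n={self.n_obs}, converged={self.converged} ({self.n_iter} iter)",
            f"loglik={self.loglik:.4f}  BIC={self.bic:.4f}  ICL={self.icl:.4f}  "
            f"params={self.n_params}",
            "cluster    weight      mean  variance",
        ]
        for k in range(self.g):
            lines.append(
                f"{k:7d}  {self.weights[k]:8.4f}  {self.means[k]:8.4f}"
                f"  {self.variances[k]:8.5f}"
            )
        return "\n".join(lines)


class MarkerMixture:
    """Model object for one marker's contrast mixture.

    Parameters
    ----------
    contrasts : array
        Non-missing contrast observations (NaN entries are dropped).
    g : int
        Number of genotype clusters to fit.
    variance_mode : {'E', 'V'}
        Shared ('E') or per-cluster ('V') variances.
    init : InitialPartition, optional
        Left-to-right initial clustering; required unless ``ploidy`` and
        ``reference_means`` are given, in which case it is estimated.
    """

    def __init__(
        self,
        contrasts,
        g: int,
        variance_mode: str = "E",
        init: InitialPartition | None = None,
        ploidy: int | None = None,
        reference_means=None,
        config: EMConfig | None = None,
    ) -> None:
        x = np.asarray(contrasts, dtype=float)
        self.x = x[np.isfinite(x)]
        if variance_mode not in ("E", "V"):
            raise ValueError("variance_mode must be 'E' or 'V'")
        if g < 1 or self.x.size < g:
            raise ValueError(f"need at least g={g} non-missing observations")
        self.g = int(g)
        self.variance_mode = variance_mode
        self.config = config or EMConfig()
        if init is None:
            if ploidy is None or reference_means is None:
                raise ValueError("provide init, or ploidy with reference_means")
            init = estimate_initial_partition(self.x, ploidy, g, reference_means)
        self.init = init

    # -- internals ---------------------------------------------------------

    def _log_prior(self, means: np.ndarray, prior_var: np.ndarray) -> float:
        """Quadratic mean penalty: kappa pseudo-observations at the fixed
        initial within-block scale (normalisation dropped; variances and
        weights are unpenalized)."""
        kappa = self.config.kappa
        m0 = self.init.cluster_means
        return float(-0.5 * kappa * np.sum((means - m0) ** 2 / prior_var))

    def _log_density(self, weights, means, variances) -> np.ndarray:
        x = self.x[:, None]
        return (
            np.log(weights)[None, :]
            - 0.5 * (_LOG_2PI + np.log(variances))[None, :]
            - 0.5 * (x - means[None, :]) ** 2 / variances[None, :]
        )

    def fit(self) -> MarkerMixtureResults:
        cfg = self.config
        n, g = self.x.size, self.g
        sizes = self.init.cluster_sizes
        if sizes.sum() != n or sizes.size != g:
            raise ValueError("initial partition inconsistent with data")

        # parameters from the hard left-to-right blocks
        x_sorted = np.sort(self.x)
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        means = self.init.cluster_means.copy()
        if self.variance_mode == "V":
            variances = np.array([
                max(x_sorted[bounds[k]:bounds[k + 1]].var(), cfg.variance_floor)
                for k in range(g)
            ])
        else:
            pooled = sum(
                ((x_sorted[bounds[k]:bounds[k + 1]] - means[k]) ** 2).sum()
                for k in range(g)
            ) / n
            variances = np.full(g, max(pooled, cfg.variance_floor))
        weights = sizes / n

        m0 = self.init.cluster_means
        kappa = cfg.kappa
        # prior precision is fixed at the initial within-block scale, so the
        # anchor fades once the data precision nk/sigma^2 grows past it
        prior_prec = kappa / np.maximum(variances.copy(), cfg.variance_floor)
        converged = False
        collapsed = False
        objective = -np.inf
        trace = []
        loglik = np.nan
        resp = np.full((n, g), 1.0 / g)
        it = 0
        for it in range(1, cfg.max_iterations + 1):
            # E-step
            logdens = self._log_density(weights, means, variances)
            norm = logsumexp(logdens, axis=1)
            loglik = float(norm.sum())
            resp = np.exp(logdens - norm[:, None])

            new_objective = loglik + self._log_prior(means, kappa / prior_prec)
            trace.append(new_objective)
            rel = abs(new_objective - objective) / (abs(new_objective) + 1e-12)
            if it > 1 and rel < cfg.tolerance:
                converged = True
                break
            objective = new_objective

            # M-step: coordinate ascent -- weights, then variances given the
            # old means (unpenalized MLE), then the penalized mean update.
            nk = resp.sum(axis=0)
            if nk.min() < 1e-3:
                collapsed = True
                break
            weights = nk / n
            sq = np.einsum("ik,ik->k", resp, (self.x[:, None] - means[None, :]) ** 2)
            if self.variance_mode == "V":
                variances = np.maximum(sq / nk, cfg.variance_floor)
            else:
                variances = np.full(g, max(sq.sum() / n, cfg.variance_floor))
            data_prec = nk / variances
            means = (data_prec * (resp.T @ self.x) / nk + prior_prec * m0) / (
                data_prec + prior_prec
            )

        # relabel so means are ascending
        order = np.argsort(means, kind="stable")
        weights, means, variances = weights[order], means[order], variances[order]
        resp = resp[:, order]

        n_params = 2 * g if self.variance_mode == "E" else 3 * g - 1
        results = MarkerMixtureResults(
            g=g,
            variance_mode=self.variance_mode,
            weights=weights,
            means=means,
            variances=variances,
            loglik=loglik,
            n_params=n_params,
            converged=converged and not collapsed,
            responsibilities=resp,
            n_obs=n,
            n_iter=it,
            objective_trace=np.array(trace),
        )
        score_fit(results, n)
        return results


def fit_mixture(
    contrasts,
    g: int,
    variance_mode: str,
    init: InitialPartition,
    config: EMConfig | None = None,
) -> MarkerMixtureResults:
    """Functional wrapper around :class:`MarkerMixture`."""
    return MarkerMixture(contrasts, g, variance_mode, init=init, config=config).fit()


def score_fit(fit: MarkerMixtureResults, n: int) -> tuple[float, float]:
    """Attach BIC and ICL (larger is better) to a fit and return them."""
    fit.bic = 2.0 * fit.loglik - fit.n_params * np.log(n)
    fit.icl = fit.bic - 2.0 * fit.entropy()
    return fit.bic, fit.icl
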