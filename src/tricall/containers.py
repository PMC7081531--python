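"""Core in-memory containers shared across the package.

Allele-signal data are reduced to a single dimension per cell, the
*contrast* ``log2(A_signal / B_signal)``; genotypes are stored as allele
dosages, i.e. the count of A alleles (0..ploidy, so diploid BB=0, AB=1,
AA=2 and triploid BBB=0 ... AAA=3).  Missing values are ``NaN`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Per-dosage reference contrast means estimated on a large calibration
#: panel (BB, AB, AA for diploids; BBB, ABB, AAB, AAA for triploids).
#: Used to label clusters at markers showing fewer than ploidy+1 clusters.
DIPLOID_REFERENCE_MEANS = (-1.76, 0.16, 1.94)
TRIPLOID_REFERENCE_MEANS = (-1.97, -0.50, 0.75, 2.14)


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} identifiers are not unique")
    return ids


@dataclass
class ReferenceMeans:
    """Ascending per-dosage reference contrast means, one per dosage 0..ploidy."""

    ploidy: int
    means: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.means.shape != (self.ploidy + 1,):
            raise ValueError(
                f"expected {self.ploidy + 1} reference means, got {self.means.size}"
            )
        if not np.all(np.diff(self.means) > 0):
            raise ValueError("reference means must be strictly increasing")

    @classmethod
    def defaults(cls, ploidy: int) -> "ReferenceMeans":
        """Published default reference means for ploidy 2 or 3."""
        if ploidy == 2:
            return cls(2, np.array(DIPLOID_REFERENCE_MEANS))
        if ploidy == 3:
            return cls(3, np.array(TRIPLOID_REFERENCE_MEANS))
        raise ValueError("default reference means exist only for ploidy 2 and 3")


@dataclass
class ContrastMatrix:
    """markers x samples matrix of log2 allele-signal ratios (NaN = missing)."""

    marker_ids: list[str]
    sample_ids: list[str]
    contrast: np.ndarray

    def __post_init__(self) -> None:
        self.marker_ids = _check_unique(self.marker_ids, "marker")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.contrast.shape != (len(self.marker_ids), len(self.sample_ids)):
            raise ValueError("contrast shape does not match marker/sample ids")

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.contrast)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.contrast, index=self.marker_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ContrastMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))


@dataclass
class GenotypeMatrix:
    """markers x samples allele dosages with a missing (NaN) mask.

    ``qc`` optionally carries per-marker quality statistics (columns such as
    ``n_clusters``, ``delta_icl``, ``call_rate``) indexed like ``marker_ids``.
    """

    ploidy: int
    marker_ids: list[str]
    sample_ids: list[str]
    dosages: np.ndarray
    qc: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.marker_ids = _check_unique(self.marker_ids, "marker")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.marker_ids), len(self.sample_ids)):
            raise ValueError("dosage shape does not match marker/sample ids")
        called = self.dosages[np.isfinite(self.dosages)]
        if called.size and ((called < 0).any() or (called > self.ploidy).any()):
            bad = np.argwhere(
                np.isfinite(self.dosages)
                & ((self.dosages < 0) | (self.dosages > self.ploidy))
            )[0]
            raise ValueError(
                f"dosage out of range 0..{self.ploidy} at marker "
                f"{self.marker_ids[bad[0]]}, sample {self.sample_ids[bad[1]]}"
            )
        if called.size and not np.allclose(called, np.round(called)):
            raise ValueError("dosages must be integers (or NaN)")

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.dosages)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.marker_ids, columns=self.sample_ids)

    def marker_call_rates(self) -> pd.Series:
        """Fraction of called samples per marker."""
        if self.n_samples == 0:
            return pd.Series(np.nan, index=self.marker_ids, name="call_rate")
        rates = np.isfinite(self.dosages).mean(axis=1)
        return pd.Series(rates, index=self.marker_ids, name="call_rate")

    def sample_call_rates(self) -> pd.Series:
        """Fraction of called markers per sample."""
        if self.n_markers == 0:
            return pd.Series(dtype=float, name="call_rate")
        rates = np.isfinite(self.dosages).mean(axis=0)
        return pd.Series(rates, index=self.sample_ids, name="call_rate")

    def select_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {m: i for i, m in enumerate(self.marker_ids)}
        rows = [index[m] for m in marker_ids]
        qc = self.qc.loc[list(marker_ids)] if self.qc is not None else None
        return GenotypeMatrix(
            self.ploidy, list(marker_ids), list(self.sample_ids),
            self.dosages[rows, :], qc,
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return GenotypeMatrix(
            self.ploidy, list(self.marker_ids), list(sample_ids),
            self.dosages[:, cols], self.qc,
        )

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.dosages[:, self.sample_ids.index(sample_id)]


@dataclass
class MarkerMap:
    """Marker positions: columns marker_id, chromosome, position (1-based bp)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker_id", "chromosome", "position"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"marker map requires columns {sorted(required)}")
        if (self.table["position"] < 0).any():
            raise ValueError("marker positions must be non-negative")
        self.table = self.table.astype(
            {"marker_id": str, "chromosome": str, "position": np.int64}
        )

    def sorted(self) -> pd.DataFrame:
        return self.table.sort_values(["chromosome", "position"], kind="mergesort")
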