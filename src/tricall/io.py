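"""Readers and writers for allele-signal files and genotype tables.

Three signal dialects are supported:

* the Axiom ``AxiomGT1.normalized-summary.txt`` dialect: tab-delimited,
  ``#`` comment lines, two rows per probeset whose identifiers end in
  ``-A`` and ``-B``, one column per sample;
* a long CSV with columns ``marker,sample,a_signal,b_signal``;
* a wide contrast CSV/TSV (markers x samples, first column marker id).

The contrast transform is ``log2(A_signal / B_signal)``; cells with
non-positive or non-finite signals become missing (NaN), never an error.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContrastMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

MISSING_SENTINEL = "NA"


def compute_contrast(a_signal, b_signal):
    """log2 ratio of A to B signal; NaN for non-positive/non-finite input.

    Accepts scalars or arrays.  ``compute_contrast(a, b) == -compute_contrast(b, a)``
    wherever both are defined.
    """
    a = np.asarray(a_signal, dtype=float)
    b = np.asarray(b_signal, dtype=float)
    valid = np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0)
    out = np.full(np.broadcast(a, b).shape, np.nan)
    if not valid.all():
        logger.debug("%d signal cells invalid, set missing", (~valid).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(valid, np.log2(a) - np.log2(b), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def read_normalized_summary(path: str | Path) -> ContrastMatrix:
    """Read an Axiom normalized-summary file into a ContrastMatrix.

    Probesets with only one of the ``-A``/``-B`` rows are skipped with a
    warning; any cell that does not parse as a number becomes missing.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    frame = frame.apply(pd.to_numeric, errors="coerce")
    a_rows = {idx[:-2]: idx for idx in frame.index if str(idx).endswith("-A")}
    b_rows = {idx[:-2]: idx for idx in frame.index if str(idx).endswith("-B")}
    markers = [m for m in a_rows if m in b_rows]
    for m in sorted(set(a_rows) ^ set(b_rows)):
        logger.warning("probeset %s has only one of the -A/-B rows; skipped", m)
    sample_ids = list(frame.columns)
    a = frame.loc[[a_rows[m] for m in markers]].to_numpy(dtype=float)
    b = frame.loc[[b_rows[m] for m in markers]].to_numpy(dtype=float)
    contrast = compute_contrast(a, b).reshape(len(markers), len(sample_ids))
    return ContrastMatrix(markers, sample_ids, contrast)


def write_normalized_summary(
    path: str | Path,
    marker_ids,
    sample_ids,
    a_signal: np.ndarray,
    b_signal: np.ndarray,
) -> None:
    """Write per-allele signal matrices in the normalized-summary dialect."""
    with open(path, "w") as fh:
        fh.write("#%%normalized-summary, written by tricall\n")
        fh.write("probeset_id\t" + "\t".join(map(str, sample_ids)) + "\n")
        for i, marker in enumerate(marker_ids):
            for suffix, mat in (("-A", a_signal), ("-B", b_signal)):
                cells = "\t".join(
                    MISSING_SENTINEL if not np.isfinite(v) else format(v, ".8g")
                    for v in mat[i]
                )
                fh.write(f"{marker}{suffix}\t{cells}\n")


def read_long_csv(path: str | Path) -> ContrastMatrix:
    """Read a long CSV (marker,sample,a_signal,b_signal) into a ContrastMatrix."""
    frame = pd.read_csv(path)
    required = {"marker", "sample", "a_signal", "b_signal"}
    if not required.issubset(frame.columns):
        raise ValueError(f"long signal CSV requires columns {sorted(required)}")
    frame["contrast"] = compute_contrast(
        frame["a_signal"].to_numpy(), frame["b_signal"].to_numpy()
    )
    wide = frame.pivot(index="marker", columns="sample", values="contrast")
    return ContrastMatrix.from_frame(wide)


def read_wide_contrast(path: str | Path, sep: str = ",") -> ContrastMatrix:
    frame = pd.read_csv(path, sep=sep, index_col=0, na_values=[MISSING_SENTINEL])
    frame = frame.apply(pd.to_numeric, errors="coerce")
    return ContrastMatrix.from_frame(frame)


def write_wide_contrast(cm: ContrastMatrix, path: str | Path, sep: str = ",") -> None:
    cm.to_frame().to_csv(path, sep=sep, na_rep=MISSING_SENTINEL, float_format="%.8g")


def read_genotypes(path: str | Path, ploidy: int, sep: str = "\t") -> GenotypeMatrix:
    """Read a markers x samples dosage table (codes 0..ploidy, NA missing).

    A dosage outside 0..ploidy raises a ValueError naming marker and sample.
    An empty file yields an empty matrix.
    """
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, na_values=[MISSING_SENTINEL])
    except pd.errors.EmptyDataError:
        return GenotypeMatrix(ploidy, [], [], np.empty((0, 0)))
    frame = frame.apply(pd.to_numeric, errors="coerce")
    return GenotypeMatrix(
        ploidy, list(frame.index.astype(str)), list(frame.columns), frame.to_numpy()
    )


def write_genotypes(gm: GenotypeMatrix, path: str | Path, sep: str = "\t") -> None:
    frame = gm.to_frame()
    # integer text codes so that a round trip is bit-exact
    frame.to_csv(
        path, sep=sep, na_rep=MISSING_SENTINEL,
        float_format=lambda v: format(int(round(v)), "d"),
    )


def write_qc(qc: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    qc.to_csv(path, sep=sep, na_rep=MISSING_SENTINEL, index_label="marker_id")


def read_marker_map(path: str | Path, sep: str = "\t"):
    from .containers import MarkerMap

    return MarkerMap(pd.read_csv(path, sep=sep))


def write_marker_map(marker_map, path: str | Path, sep: str = "\t") -> None:
    marker_map.table.to_csv(path, sep=sep, index=False)
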