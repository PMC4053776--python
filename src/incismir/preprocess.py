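"""Normalization and per-locus summarization of the three data layers.

Expression: log2 array intensities are normalized per sample by subtracting
the sample's 90th percentile across miRNAs, after removing miRNAs detected
in fewer than 10% of samples.  Methylation: when several probes represent a
locus, the per-sample median beta is used.  Copy number: log2 ratios are
centered per sample (median by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyMatrixError, MatrixFormatError
from .matrix import BETA, LocusSampleMatrix


@dataclass
class NormalizationConfig:
    """Expression normalization parameters.

    percentile: per-sample quantile subtracted from every miRNA (0.90).
    detection_fraction: minimum fraction of samples a miRNA must be
    detected in to be retained (0.10, strict "less than" excluded).
    """

    percentile: float = 0.90
    detection_fraction: float = 0.10

    def __post_init__(self):
        if not (0.0 < self.percentile < 1.0):
            raise ValueError(f"percentile must be in (0,1), got {self.percentile}")
        if not (0.0 < self.detection_fraction < 1.0):
            raise ValueError(
                f"detection_fraction must be in (0,1), got {self.detection_fraction}"
            )


def normalize_mirna_expression(
    raw: LocusSampleMatrix,
    detected: pd.DataFrame | None = None,
    cfg: NormalizationConfig | None = None,
) -> LocusSampleMatrix:
    """Detection-filter then 90th-percentile normalize a log2 expression matrix.

    Rows detected in fewer than ``cfg.detection_fraction`` of samples are
    removed first; then each sample column has its ``cfg.percentile``
    quantile (type-7 linear interpolation over non-missing, retained rows)
    subtracted, so the column's percentile of the output is 0.

    ``detected`` is a boolean matrix congruent with ``raw``; when absent,
    non-missing stands in for detected.
    """
    cfg = cfg or NormalizationConfig()
    data = raw.data
    if detected is None:
        detected = data.notna()
    else:
        detected = detected.reindex(index=data.index, columns=data.columns)
        if detected.isna().any().any():
            raise MatrixFormatError("detection matrix not congruent with expression matrix")
        detected = detected.astype(bool)
    frac = detected.mean(axis=1)
    keep = frac >= cfg.detection_fraction
    filtered = data.loc[keep]
    if filtered.shape[0] == 0:
        raise EmptyMatrixError("detection filter removed every miRNA")
    if filtered.isna().all(axis=0).any():
        col = filtered.columns[filtered.isna().all(axis=0)][0]
        raise EmptyMatrixError(f"sample {col!r} has no non-missing values to normalize")
    # np.nanquantile default is the type-7 linear-interpolation estimator
    q = filtered.apply(lambda col: np.nanquantile(col.to_numpy(), cfg.percentile), axis=0)
    return LocusSampleMatrix(filtered.sub(q, axis=1), raw.kind)


def summarize_locus_methylation(
    beta: LocusSampleMatrix, assignments: list
) -> LocusSampleMatrix:
    """Median beta over each locus's assigned probes, per sample.

    Single-probe loci pass through unchanged.  A locus whose probes are all
    missing for a sample yields a missing entry.
    """
    missing_probes = {
        pid for a in assignments for pid in a.probe_ids if pid not in beta.data.index
    }
    if missing_probes:
        raise MatrixFormatError(
            f"probes absent from beta matrix: {sorted(missing_probes)[:5]}"
        )
    rows = {}
    for a in assignments:
        sub = beta.data.loc[list(a.probe_ids)]
        rows[a.locus_id] = sub.median(axis=0, skipna=True)
    out = pd.DataFrame(rows).T.reindex(columns=beta.data.columns)
    out.index.name = "locus_id"
    return LocusSampleMatrix(out, BETA)


def center_log_ratios(
    cn: LocusSampleMatrix, statistic: str = "median"
) -> LocusSampleMatrix:
    """Center each sample's copy-number log2 ratios (median by default)."""
    if statistic not in ("median", "mean"):
        raise ValueError(f"unknown centering statistic {statistic!r}")
    if cn.data.isna().all(axis=0).any():
        col = cn.data.columns[cn.data.isna().all(axis=0)][0]
        raise EmptyMatrixError(f"sample {col!r} is entirely missing; cannot center")
    center = cn.data.median(axis=0) if statistic == "median" else cn.data.mean(axis=0)
    return LocusSampleMatrix(cn.data.sub(center, axis=1), cn.kind)


def average_replicate_arrays(arrays: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean-of-replicates utility for samples profiled on several arrays."""
    if not arrays:
        raise EmptyMatrixError("no replicate arrays supplied")
    stacked = pd.concat(arrays)
    return stacked.groupby(level=0).mean()
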