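"""The pipeline's common currency: a features x samples numeric matrix.

Three kinds of matrix flow through the pipeline, all with the same shape
contract: log2 expression intensities, CpG methylation beta values in [0, 1],
and copy-number log2 ratios.  Rows are feature identifiers (mature miRNA ids,
locus ids or probe ids), columns are sample identifiers.  Missing entries are
NaN and propagate; nothing is ever imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MatrixFormatError

EXPRESSION = "expression_log2"
BETA = "beta"
CN_LOGRATIO = "cn_logratio"

_KINDS = (EXPRESSION, BETA, CN_LOGRATIO)


@dataclass
class LocusSampleMatrix:
    """A features x samples matrix with a declared measurement kind.

    Parameters
    ----------
    data:
        DataFrame with unique row index (features) and unique columns
        (samples); values numeric, NaN for missing.
    kind:
        One of ``expression_log2``, ``beta``, ``cn_logratio``.  Beta
        matrices are validated to lie in [0, 1].
    """

    data: pd.DataFrame
    kind: str = field(default=EXPRESSION)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise MatrixFormatError(f"unknown matrix kind: {self.kind!r}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise MatrixFormatError(f"duplicate feature id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise MatrixFormatError(f"duplicate sample id: {dup!r}")
        self.data = self.data.astype(float)
        if self.kind == BETA:
            vals = self.data.to_numpy()
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise MatrixFormatError(
                    "beta values must lie in [0, 1]; "
                    f"observed range [{finite.min():g}, {finite.max():g}]"
                )

    # -- convenience -------------------------------------------------------
    @property
    def row_ids(self):
        return list(self.data.index)

    @property
    def col_ids(self):
        return list(self.data.columns)

    @property
    def shape(self):
        return self.data.shape

    def subset_rows(self, row_ids) -> "LocusSampleMatrix":
        return LocusSampleMatrix(self.data.loc[list(row_ids)], self.kind)

    def subset_cols(self, col_ids) -> "LocusSampleMatrix":
        return LocusSampleMatrix(self.data[list(col_ids)], self.kind)


def read_matrix(path, kind: str) -> LocusSampleMatrix:
    """Read a tab-separated matrix: first column feature id, header of sample ids.

    Missing values are encoded as ``NA``.  Raises :class:`MatrixFormatError`
    with the offending identifier on duplicates, or on out-of-range beta.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise MatrixFormatError(f"{path}: line 1: no sample columns found")
    samples = header[1:]
    dups = {s for s in samples if samples.count(s) > 1}
    if dups:
        raise MatrixFormatError(
            f"{path}: line 1: duplicate sample id: {sorted(dups)[0]!r}"
        )
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    try:
        return LocusSampleMatrix(df, kind)
    except MatrixFormatError as exc:
        raise MatrixFormatError(f"{path}: {exc}") from exc


def write_matrix(matrix: LocusSampleMatrix, path) -> None:
    """Write a matrix in the tab-separated dialect read by :func:`read_matrix`."""
    out = matrix.data.copy()
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.8g")
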