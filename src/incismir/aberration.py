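"""Categorical aberration calling for methylation and copy number.

Methylation states are called against a normal-tissue reference: a tumor is
hypermethylated at a locus when beta exceeds m + k*SD of the normals (k=2
by default), hypomethylated when beta falls below m - k*SD.  A threshold
that leaves the [0, 1] beta range is degenerate and the corresponding call
is not assessed (observed in practice when normal-tissue variability is
large).  Copy-number states use fixed cutoffs on segmented log2 ratios:
gain above +0.1, loss below -0.1, strict at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import LocusSampleMatrix

log = logging.getLogger(__name__)

CN_STATES = ("loss", "neutral", "gain", "missing")
METH_STATES = ("hypo", "normal", "hyper", "missing")


@dataclass
class NormalReference:
    """Per-locus normal-tissue beta summary and derived calling thresholds."""

    locus_id: str
    m: float
    sd: float
    k: float
    n_normals: int
    usable: bool = True

    @property
    def hi(self) -> float:
        return self.m + self.k * self.sd

    @property
    def lo(self) -> float:
        return self.m - self.k * self.sd

    @property
    def hypo_assessable(self) -> bool:
        return self.usable and self.lo >= 0.0

    @property
    def hyper_assessable(self) -> bool:
        return self.usable and self.hi <= 1.0


@dataclass
class CallingThresholds:
    gain_cutoff: float = 0.1
    loss_cutoff: float = -0.1

    def __post_init__(self):
        if not (self.gain_cutoff > 0.0 > self.loss_cutoff):
            raise ValueError("require gain_cutoff > 0 > loss_cutoff")


@dataclass
class AberrationMatrix:
    """Loci x samples categorical states on the two aberration axes."""

    cn_state: pd.DataFrame
    meth_state: pd.DataFrame

    def __post_init__(self):
        for df, states in ((self.cn_state, CN_STATES), (self.meth_state, METH_STATES)):
            bad = set(np.unique(df.to_numpy().astype(str))) - set(states)
            if bad:
                raise ValueError(f"invalid aberration states: {sorted(bad)}")
        if not self.cn_state.index.equals(self.meth_state.index) or not (
            self.cn_state.columns.equals(self.meth_state.columns)
        ):
            raise ValueError("cn and methylation state layers must be congruent")

    @property
    def loci(self):
        return list(self.cn_state.index)

    @property
    def samples(self):
        return list(self.cn_state.columns)


def fit_normal_reference(
    normal_beta: LocusSampleMatrix, k: float = 2.0
) -> list[NormalReference]:
    """Per-locus median and sample SD (n-1) of normal beta, with thresholds.

    Loci with fewer than two non-missing normals are marked unusable and
    excluded from methylation calling (logged).
    """
    refs = []
    for locus_id, row in normal_beta.data.iterrows():
        vals = row.dropna().to_numpy()
        if vals.size < 2:
            log.warning(
                "locus %s: %d usable normal(s); methylation calling disabled",
                locus_id, vals.size,
            )
            refs.append(NormalReference(locus_id, np.nan, np.nan, k, vals.size, usable=False))
            continue
        refs.append(
            NormalReference(
                locus_id,
                m=float(np.median(vals)),
                sd=float(np.std(vals, ddof=1)),
                k=k,
                n_normals=int(vals.size),
            )
        )
    return refs


def call_methylation_state(
    tumor_beta: LocusSampleMatrix, refs: list[NormalReference]
) -> pd.DataFrame:
    """Meth-state layer: hyper iff beta > m + k*SD, hypo iff beta < m - k*SD.

    Strict inequalities; degenerate thresholds (lo < 0 or hi > 1) disable
    the corresponding call; missing beta or absent reference => missing.
    """
    ref_by_locus = {r.locus_id: r for r in refs}
    out = pd.DataFrame(
        "missing", index=tumor_beta.data.index, columns=tumor_beta.data.columns
    )
    for locus_id, row in tumor_beta.data.iterrows():
        ref = ref_by_locus.get(locus_id)
        if ref is None or not ref.usable:
            if ref is None:
                log.warning("locus %s has no normal reference; states missing", locus_id)
            continue
        vals = row.to_numpy()
        states = np.where(np.isnan(vals), "missing", "normal").astype(object)
        if ref.hyper_assessable:
            states[vals > ref.hi] = "hyper"
        if ref.hypo_assessable:
            states[vals < ref.lo] = "hypo"
        out.loc[locus_id] = states
    return out


def call_copy_number_state(
    locus_cn: LocusSampleMatrix, thresholds: CallingThresholds | None = None
) -> pd.DataFrame:
    """CN-state layer: gain iff value > gain_cutoff, loss iff < loss_cutoff.

    Boundary values (exactly at a cutoff) are neutral; missing propagates.
    """
    thresholds = thresholds or CallingThresholds()
    vals = locus_cn.data.to_numpy()
    states = np.where(np.isnan(vals), "missing", "neutral").astype(object)
    states[vals > thresholds.gain_cutoff] = "gain"
    states[vals < thresholds.loss_cutoff] = "loss"
    return pd.DataFrame(states, index=locus_cn.data.index, columns=locus_cn.data.columns)


_CN_CODE = {"loss": "L", "neutral": ".", "gain": "G", "missing": "?"}
_METH_CODE = {"hypo": "h", "normal": ".", "hyper": "H", "missing": "?"}


def write_aberration_matrix(ab: AberrationMatrix, path, legend_path=None) -> None:
    """Compact two-character export (CN code + methylation code) plus legend."""
    codes = ab.cn_state.replace(_CN_CODE) + ab.meth_state.replace(_METH_CODE)
    codes.index.name = "locus_id"
    codes.to_csv(path, sep="\t")
    if legend_path is not None:
        with open(legend_path, "w") as fh:
            fh.write("position 1 (copy number): L=loss .=neutral G=gain ?=missing\n")
            fh.write("position 2 (methylation): h=hypo .=normal H=hyper ?=missing\n")


def aberration_long_format(ab: AberrationMatrix) -> pd.DataFrame:
    """Long-format view: one row per (locus, sample, axis, state)."""
    frames = []
    for axis, df in (("copy_number", ab.cn_state), ("methylation", ab.meth_state)):
        melted = df.reset_index(names="locus_id").melt(
            id_vars="locus_id", var_name="sample", value_name="state"
        )
        melted.insert(2, "axis", axis)
        frames.append(melted)
    return pd.concat(frames, ignore_index=True)
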