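"""Synthetic tumor cohorts with planted in-cis structure.

The generator emulates the data model of an integrative breast-tumor study:
tumors plus a normal-tissue methylation reference, piecewise-constant
copy-number probe tracks, Beta-like CpG methylation values, log2 miRNA
expression coupled in-cis to planted aberrations, multi-locus seed families
with complementary altered-sample sets, mRNA genes correlated to candidate
miRNAs, and a clinical table with planted subgroup and survival effects.
Every planted effect is recorded in a truth table so pipeline recovery can
be scored exactly.  Two cohorts drawn from one shared design (same loci,
mechanisms and families, independent samples and noise) exercise the
replication logic realistically.

Beta noise is a clipped Gaussian rather than a Beta distribution: the
2-SD calling rule then has a transparent false-call rate.  Mechanism
defaults mirror the target study's scale: 100 tumors, 17 normals, 500 loci,
a 1.5 log2 expression shift in 30% of samples, +/-0.3 copy-number segment
shifts over 0.15-SD probe noise, and +/-0.2 beta shifts over 0.02-SD noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .locus_model import (
    GenomicInterval,
    MirnaLocusAnnotation,
    ProbeAnnotation,
    group_families,
    read_annotation,
    read_probe_annotation,
    write_annotation,
    write_probe_annotation,
)
from .matrix import BETA, CN_LOGRATIO, EXPRESSION, LocusSampleMatrix, read_matrix, write_matrix

MECHANISMS = ("none", "gain", "loss", "hypo", "hyper", "combined")

_RNA = np.array(list("ACGU"))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort (or a cohort pair)."""

    n_tumors: int = 100
    n_normals: int = 17
    n_chromosomes: int = 5
    probes_per_chrom: int = 2000
    n_loci: int = 500
    n_families_multilocus: int = 5
    n_gain_driven: int = 10
    n_loss_driven: int = 10
    n_hypo_driven: int = 10
    n_hyper_driven: int = 10
    n_combined: int = 10
    effect_size_expr: float = 1.5     # log2 expression shift in altered samples
    altered_fraction: float = 0.3     # fraction of tumors altered per planted locus
    cn_segment_shift: float = 0.3     # log2 shift of planted copy-number segments
    cn_noise_sd: float = 0.15
    beta_noise_sd: float = 0.02
    beta_shift: float = 0.2
    expr_noise_sd: float = 0.5
    n_mrna_genes: int = 150
    n_corr_genes_per_candidate: int = 5
    corr_gene_slope: float = 0.8
    mrna_noise_sd: float = 0.5
    clinical_effect_size: float = 1.0
    survival_hazard_ratio: float = 2.0  # hazard multiplier per SD of low expression
    survival_baseline: float = 5.0      # mean event time at average expression
    censor_time: float = 10.0
    n_undetected_mirnas: int = 5
    frac_host_promoter: float = 0.08
    frac_nearest: float = 0.07
    chrom_length: int = 100_000_000
    cn_window_bp: int = 2_000_000       # half-width of planted copy-number segments
    seed: int = 0

    def __post_init__(self):
        if self.n_planted > self.n_loci:
            raise ValueError(
                f"planted loci ({self.n_planted}) exceed n_loci ({self.n_loci})"
            )
        if not (0.0 < self.altered_fraction < 0.5):
            raise ValueError("altered_fraction must be in (0, 0.5) for disjoint families")
        if self.n_families_multilocus > min(self.n_gain_driven, self.n_hypo_driven):
            raise ValueError("n_families_multilocus exceeds available gain/hypo loci")

    @property
    def n_planted(self) -> int:
        return (
            self.n_gain_driven + self.n_loss_driven + self.n_hypo_driven
            + self.n_hyper_driven + self.n_combined
        )


@dataclass
class TruthTable:
    """Ground truth for one cohort: what was planted where."""

    mechanism: dict                      # locus_id -> mechanism
    altered: pd.DataFrame                # loci x tumors boolean (expression-affecting)
    cn_altered: pd.DataFrame             # loci x tumors boolean (copy-number axis)
    meth_altered: pd.DataFrame           # loci x tumors boolean (methylation axis)
    clinical_targets: list = field(default_factory=list)  # dicts: locus_id, variable, direction
    survival_locus: str = ""
    corr_pairs: list = field(default_factory=list)        # (mature_id, gene, sign)
    families: dict = field(default_factory=dict)          # family_id -> [locus_id, ...]

    @property
    def planted_loci(self) -> set:
        return {l for l, m in self.mechanism.items() if m != "none"}


@dataclass
class CohortBundle:
    """All inputs the pipeline needs for one cohort, plus the truth table."""

    name: str
    annotations: list
    probes: list
    mature_expression: LocusSampleMatrix
    detected: pd.DataFrame
    cn_probes: LocusSampleMatrix
    cn_probe_positions: pd.DataFrame
    tumor_beta: LocusSampleMatrix
    normal_beta: LocusSampleMatrix
    clinical: pd.DataFrame
    mrna: LocusSampleMatrix
    truth: TruthTable


# ---------------------------------------------------------------------------
# Shared design (identical across a discovery/replication pair)
# ---------------------------------------------------------------------------

class _Design:
    """Loci, sequences, probes, mechanisms and planted targets."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
        self.chroms = chroms

        # copy-number probes: evenly spaced along each chromosome
        step = cfg.chrom_length / (cfg.probes_per_chrom + 1)
        self.cn_positions = pd.DataFrame(
            [
                {"probe_id": f"cnp_{c}_{i:05d}", "chrom": c, "pos": int((i + 1) * step)}
                for c in chroms
                for i in range(cfg.probes_per_chrom)
            ]
        ).set_index("probe_id")

        # locus placement: round-robin over chromosomes, random positions
        n_total = cfg.n_loci
        locus_chrom = [chroms[i % len(chroms)] for i in range(n_total)]
        locus_pos = rng.integers(2_000_000, cfg.chrom_length - 2_000_000, size=n_total)

        # mechanisms; copy-number-planted loci kept well separated on a chromosome
        mech_list = (
            ["gain"] * cfg.n_gain_driven + ["loss"] * cfg.n_loss_driven
            + ["hypo"] * cfg.n_hypo_driven + ["hyper"] * cfg.n_hyper_driven
            + ["combined"] * cfg.n_combined
        )
        order = rng.permutation(n_total)
        self.mechanism = ["none"] * n_total
        cn_mechs = {"gain", "loss", "combined"}
        placed: dict = {c: [] for c in chroms}
        queue = list(mech_list)
        for idx in order:
            if not queue:
                break
            mech = queue[0]
            if mech in cn_mechs:
                pos, chrom = locus_pos[idx], locus_chrom[idx]
                if any(abs(pos - p) < 2.5 * cfg.cn_window_bp for p in placed[chrom]):
                    continue
                placed[chrom].append(pos)
            self.mechanism[idx] = queue.pop(0)
        if queue:  # rare: could not separate all CN plants; place anywhere free
            for idx in order:
                if not queue:
                    break
                if self.mechanism[idx] == "none":
                    self.mechanism[idx] = queue.pop(0)

        # mature miRNAs: family members share one mature sequence (two loci);
        # a few extra null matures are multi-locus to exercise expansion
        gain_idx = [i for i, m in enumerate(self.mechanism) if m == "gain"]
        hypo_idx = [i for i, m in enumerate(self.mechanism) if m == "hypo"]
        self.family_pairs = [
            (gain_idx[k], hypo_idx[k]) for k in range(cfg.n_families_multilocus)
        ]
        paired = {i for pair in self.family_pairs for i in pair}
        null_idx = [i for i, m in enumerate(self.mechanism) if m == "none" and i not in paired]
        extra_pairs = [
            (null_idx[2 * k], null_idx[2 * k + 1]) for k in range(min(5, len(null_idx) // 2))
        ]
        self.mature_of = {}
        seqs: dict = {}
        seen_seeds: set = set()

        def _fresh_sequence():
            while True:
                seq = "".join(rng.choice(_RNA, size=22))
                if seq[1:8] not in seen_seeds:
                    seen_seeds.add(seq[1:8])
                    return seq

        mature_n = 0
        for pair in self.family_pairs + extra_pairs:
            mid = f"mir-{mature_n + 1}"
            mature_n += 1
            seqs[mid] = _fresh_sequence()
            for i in pair:
                self.mature_of[i] = mid
        for i in range(n_total):
            if i in self.mature_of:
                continue
            mid = f"mir-{mature_n + 1}"
            mature_n += 1
            seqs[mid] = _fresh_sequence()
            self.mature_of[i] = mid
        self.mature_sequences = seqs

        # annotation objects; locus ids encode mature id + copy index
        counts: dict = {}
        self.annotations = []
        for i in range(n_total):
            mid = self.mature_of[i]
            counts[mid] = counts.get(mid, 0) + 1
            self.annotations.append(
                MirnaLocusAnnotation(
                    locus_id=f"{mid}_L{counts[mid]}",
                    mature_id=mid,
                    mimat_id=f"MIMAT{i + 1:07d}",
                    interval=GenomicInterval(
                        locus_chrom[i], int(locus_pos[i]), int(locus_pos[i]) + 21, "+"
                    ),
                    mature_sequence=seqs[mid],
                )
            )
        self.families = group_families(self.annotations)
        self.locus_ids = [a.locus_id for a in self.annotations]
        self.mechanism_by_locus = dict(zip(self.locus_ids, self.mechanism))

        # undetected (dim) matures: extra single-locus annotations
        self.dim_matures = []
        for k in range(cfg.n_undetected_mirnas):
            mid = f"mir-dim{k + 1}"
            seq = _fresh_sequence()
            pos = int(rng.integers(2_000_000, cfg.chrom_length - 2_000_000))
            self.annotations.append(
                MirnaLocusAnnotation(
                    locus_id=f"{mid}_L1",
                    mature_id=mid,
                    mimat_id=f"MIMAT{n_total + k + 1:07d}",
                    interval=GenomicInterval(chroms[k % len(chroms)], pos, pos + 21, "+"),
                    mature_sequence=seq,
                )
            )
            self.dim_matures.append(mid)

        # methylation probe tiers: planted-methylation loci always designated
        meth_planted = {
            self.locus_ids[i]
            for i, m in enumerate(self.mechanism)
            if m in ("hypo", "hyper", "combined")
        }
        tier_draw = rng.random(len(self.annotations))
        self.probes = []
        self.probes_of_locus: dict = {}
        gene_n = 0
        mu = rng.uniform(0.15, 0.75, size=len(self.annotations))
        self.beta_mu = dict(zip([a.locus_id for a in self.annotations], mu))
        self.probe_offset: dict = {}
        for j, ann in enumerate(self.annotations):
            u = tier_draw[j]
            start = ann.interval.start
            if ann.locus_id in meth_planted or u >= cfg.frac_host_promoter + cfg.frac_nearest:
                n_probes = int(rng.integers(1, 5))
                ids = []
                for k in range(n_probes):
                    pid = f"mp_{ann.locus_id}_{k}"
                    pos = max(1, start - int(rng.integers(1, 1500)))
                    self.probes.append(
                        ProbeAnnotation(
                            pid, GenomicInterval(ann.interval.chrom, pos, pos),
                            "TSS1500", frozenset({ann.locus_id}),
                        )
                    )
                    ids.append(pid)
                self.probes_of_locus[ann.locus_id] = ids
            elif u < cfg.frac_host_promoter:
                gene_n += 1
                gene = f"GENE{gene_n}"
                ann.intronic = True
                ann.host_gene = gene
                ids = []
                for k in range(2):
                    pid = f"mp_{ann.locus_id}_host{k}"
                    pos = max(1, start - 5000 - int(rng.integers(1, 1500)))
                    self.probes.append(
                        ProbeAnnotation(
                            pid, GenomicInterval(ann.interval.chrom, pos, pos),
                            "TSS1500", frozenset(), frozenset({gene}),
                        )
                    )
                    ids.append(pid)
                self.probes_of_locus[ann.locus_id] = ids
            else:
                # nearest-tier locus: no probes of its own
                self.probes_of_locus[ann.locus_id] = []
        for p in self.probes:
            self.probe_offset[p.probe_id] = float(rng.normal(0.0, 0.01))

        # expression baselines (raw log2 intensity scale) and mRNA baselines
        self.expr_base = {
            mid: float(rng.uniform(4.0, 10.0)) for mid in list(seqs) + self.dim_matures
        }
        self.genes = [f"GENE_EXPR_{g + 1}" for g in range(cfg.n_mrna_genes)]

        # planted downstream targets, drawn from planted loci of suitable mechanism
        def _first(mech, skip=()):
            for i, m in enumerate(self.mechanism):
                lid = self.locus_ids[i]
                if m == mech and lid not in skip:
                    return lid
            return None

        self.tp53_locus = _first("hypo", skip={self.locus_ids[i] for i in hypo_idx[: cfg.n_families_multilocus]})
        self.grade_locus = _first("gain", skip={self.locus_ids[i] for i in gain_idx[: cfg.n_families_multilocus]})
        self.er_locus = _first("hyper")
        self.survival_locus = _first("hyper", skip={self.er_locus})
        self.clinical_targets = [
            {"locus_id": self.tp53_locus, "variable": "tp53", "direction": "up in mutant"},
            {"locus_id": self.grade_locus, "variable": "grade", "direction": "increasing with grade"},
            {"locus_id": self.er_locus, "variable": "er", "direction": "up in pos"},
        ]
        candidates = [
            _first("gain"), _first("hypo"), self.er_locus, _first("combined")
        ]
        mature_of_locus = {a.locus_id: a.mature_id for a in self.annotations}
        self.corr_pairs = []
        g = 0
        for c in candidates:
            if c is None:
                continue
            for k in range(cfg.n_corr_genes_per_candidate):
                sign = 1 if k % 2 == 0 else -1
                self.corr_pairs.append((mature_of_locus[c], self.genes[g], sign))
                g += 1


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def _draw_cohort(design: _Design, cfg: SimulationConfig, rng: np.random.Generator, name: str) -> CohortBundle:
    n = cfg.n_tumors
    tumors = [f"{name}T{i + 1:03d}" for i in range(n)]
    normals = [f"{name}N{i + 1:02d}" for i in range(cfg.n_normals)]
    loci = design.locus_ids
    n_alt = max(1, round(cfg.altered_fraction * n))

    cn_altered = pd.DataFrame(False, index=loci, columns=tumors)
    meth_altered = pd.DataFrame(False, index=loci, columns=tumors)

    family_members = {i for pair in design.family_pairs for i in pair}
    # family pairs draw disjoint altered sets; other planted loci draw freely
    for gi, hi in design.family_pairs:
        pick = rng.choice(n, size=2 * n_alt, replace=False)
        cn_altered.loc[loci[gi], [tumors[s] for s in pick[:n_alt]]] = True
        meth_altered.loc[loci[hi], [tumors[s] for s in pick[n_alt:]]] = True
    for i, mech in enumerate(design.mechanism):
        if mech == "none" or i in family_members:
            continue
        lid = loci[i]
        pick = [tumors[s] for s in rng.choice(n, size=n_alt, replace=False)]
        if mech in ("gain", "loss"):
            cn_altered.loc[lid, pick] = True
        elif mech in ("hypo", "hyper"):
            meth_altered.loc[lid, pick] = True
        else:  # combined: half the altered samples by gain, half by hypomethylation
            half = n_alt // 2
            cn_altered.loc[lid, pick[:half]] = True
            meth_altered.loc[lid, pick[half:]] = True
    altered = cn_altered | meth_altered

    # --- copy-number probe tracks -----------------------------------------
    pos_df = design.cn_positions
    cn_vals = rng.normal(0.0, cfg.cn_noise_sd, size=(len(pos_df), n))
    probe_pos = pos_df["pos"].to_numpy()
    probe_chrom = pos_df["chrom"].to_numpy()
    ann_by_locus = {a.locus_id: a for a in design.annotations}
    for i, mech in enumerate(design.mechanism):
        if mech not in ("gain", "loss", "combined"):
            continue
        lid = loci[i]
        ann = ann_by_locus[lid]
        in_window = (probe_chrom == ann.interval.chrom) & (
            np.abs(probe_pos - ann.interval.start) <= cfg.cn_window_bp
        )
        shift = cfg.cn_segment_shift if mech != "loss" else -cfg.cn_segment_shift
        cols = np.flatnonzero(cn_altered.loc[lid].to_numpy())
        if cols.size:
            cn_vals[np.ix_(in_window, cols)] += shift
    cn_probes = LocusSampleMatrix(
        pd.DataFrame(cn_vals, index=pos_df.index, columns=tumors), CN_LOGRATIO
    )

    # --- methylation ------------------------------------------------------
    probe_ids = [p.probe_id for p in design.probes]
    locus_of_probe: dict = {}
    for lid, pids in design.probes_of_locus.items():
        for pid in pids:
            locus_of_probe.setdefault(pid, lid)
    t_beta = np.empty((len(probe_ids), n))
    n_beta = np.empty((len(probe_ids), cfg.n_normals))
    for r, pid in enumerate(probe_ids):
        lid = locus_of_probe.get(pid)
        mu = design.beta_mu[lid] + design.probe_offset[pid] if lid else 0.5
        t_beta[r] = mu + rng.normal(0.0, cfg.beta_noise_sd, size=n)
        n_beta[r] = mu + rng.normal(0.0, cfg.beta_noise_sd, size=cfg.n_normals)
        if lid is None:
            continue
        mech = design.mechanism_by_locus.get(lid, "none")
        if mech in ("hypo", "combined"):
            t_beta[r, meth_altered.loc[lid].to_numpy()] -= cfg.beta_shift
        elif mech == "hyper":
            t_beta[r, meth_altered.loc[lid].to_numpy()] += cfg.beta_shift
    tumor_beta = LocusSampleMatrix(
        pd.DataFrame(np.clip(t_beta, 0.0, 1.0), index=probe_ids, columns=tumors), BETA
    )
    normal_beta = LocusSampleMatrix(
        pd.DataFrame(np.clip(n_beta, 0.0, 1.0), index=probe_ids, columns=normals), BETA
    )

    # --- clinical ---------------------------------------------------------
    er = np.where(rng.random(n) < 0.65, "pos", "neg")
    sub_u = rng.random(n)
    subtype = np.where(
        (er == "pos") & (sub_u < 0.9) | (er == "neg") & (sub_u < 0.15), "luminal", "basal"
    )
    clinical = pd.DataFrame(
        {
            "sample_id": tumors,
            "er": er,
            "her2": np.where(rng.random(n) < 0.2, "pos", "neg"),
            "grade": rng.choice([1, 2, 3], size=n, p=[0.15, 0.45, 0.4]),
            "tp53": np.where(rng.random(n) < 0.35, "mutant", "wildtype"),
            "subtype": subtype,
        }
    ).set_index("sample_id", drop=False)

    # --- expression -------------------------------------------------------
    sign_of = {"gain": 1, "hypo": 1, "combined": 1, "loss": -1, "hyper": -1}
    mature_ids = sorted({a.mature_id for a in design.annotations})
    expr = pd.DataFrame(
        rng.normal(0.0, cfg.expr_noise_sd, size=(len(mature_ids), n)),
        index=mature_ids, columns=tumors,
    )
    for mid in mature_ids:
        expr.loc[mid] += design.expr_base[mid]
    for i, mech in enumerate(design.mechanism):
        if mech == "none":
            continue
        mid = design.mature_of[i]
        expr.loc[mid] += (
            sign_of[mech] * cfg.effect_size_expr * altered.loc[loci[i]].to_numpy()
        )
    # planted clinical effects, on top of in-cis effects
    mature_of_locus = {a.locus_id: a.mature_id for a in design.annotations}
    if design.tp53_locus:
        expr.loc[mature_of_locus[design.tp53_locus]] += cfg.clinical_effect_size * (
            clinical["tp53"] == "mutant"
        ).to_numpy(dtype=float)
    if design.grade_locus:
        expr.loc[mature_of_locus[design.grade_locus]] += (
            0.6 * cfg.clinical_effect_size * (clinical["grade"].to_numpy(dtype=float) - 2.0)
        )
    if design.er_locus:
        expr.loc[mature_of_locus[design.er_locus]] += cfg.clinical_effect_size * (
            clinical["er"] == "pos"
        ).to_numpy(dtype=float)

    # survival: low expression of the prognostic locus raises the hazard
    surv_mid = mature_of_locus.get(design.survival_locus, None)
    if surv_mid is not None:
        z = expr.loc[surv_mid]
        z = (z - z.mean()) / (z.std(ddof=1) or 1.0)
        rate = (1.0 / cfg.survival_baseline) * np.power(
            cfg.survival_hazard_ratio, -z.to_numpy()
        )
        event_time = rng.exponential(1.0 / rate)
        censor = rng.uniform(0.0, cfg.censor_time, size=n)
        clinical["rfs_time"] = np.minimum(event_time, censor)
        clinical["rfs_event"] = (event_time <= censor).astype(int)
    else:
        clinical["rfs_time"] = np.nan
        clinical["rfs_event"] = np.nan

    # dim matures: raw intensities near background, rarely detected
    for mid in design.dim_matures:
        expr.loc[mid] = rng.normal(1.0, 0.3, size=n)
    detected = pd.DataFrame(True, index=expr.index, columns=tumors)
    for mid in design.dim_matures:
        detected.loc[mid] = rng.random(n) < 0.05

    # --- mRNA -------------------------------------------------------------
    mrna = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(design.genes), n)),
        index=design.genes, columns=tumors,
    )
    for mid, gene, sign in design.corr_pairs:
        centered = expr.loc[mid] - expr.loc[mid].mean()
        mrna.loc[gene] = sign * cfg.corr_gene_slope * centered + rng.normal(
            0.0, cfg.mrna_noise_sd, size=n
        )

    truth = TruthTable(
        mechanism=dict(design.mechanism_by_locus),
        altered=altered,
        cn_altered=cn_altered,
        meth_altered=meth_altered,
        clinical_targets=[dict(t) for t in design.clinical_targets if t["locus_id"]],
        survival_locus=design.survival_locus or "",
        corr_pairs=list(design.corr_pairs),
        families={
            fid: sorted(m)
            for fid, m in design.families.items()
            if len(m) > 1
        },
    )
    return CohortBundle(
        name=name,
        annotations=design.annotations,
        probes=design.probes,
        mature_expression=LocusSampleMatrix(expr, EXPRESSION),
        detected=detected,
        cn_probes=cn_probes,
        cn_probe_positions=pos_df[["chrom", "pos"]],
        tumor_beta=tumor_beta,
        normal_beta=normal_beta,
        clinical=clinical,
        mrna=LocusSampleMatrix(mrna, EXPRESSION),
        truth=truth,
    )


def generate_cohort(cfg: SimulationConfig | None = None) -> CohortBundle:
    """Generate a single cohort; deterministic given ``cfg.seed``."""
    cfg = cfg or SimulationConfig()
    design = _Design(cfg, np.random.default_rng([cfg.seed, 0]))
    return _draw_cohort(design, cfg, np.random.default_rng([cfg.seed, 1]), "D")


def generate_cohort_pair(
    cfg: SimulationConfig | None = None,
) -> tuple[CohortBundle, CohortBundle]:
    """Discovery and replication cohorts sharing one design (loci, mechanisms,
    families) with independent sample draws and noise."""
    cfg = cfg or SimulationConfig()
    design = _Design(cfg, np.random.default_rng([cfg.seed, 0]))
    discovery = _draw_cohort(design, cfg, np.random.default_rng([cfg.seed, 1]), "D")
    replication = _draw_cohort(design, cfg, np.random.default_rng([cfg.seed, 2]), "R")
    return discovery, replication


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

_FILES = {
    "annotation": "annotation.tsv",
    "probes": "probe_annotation.tsv",
    "expression": "expression_mature.tsv",
    "detected": "detected.tsv",
    "cn_probes": "cn_probes.tsv",
    "cn_positions": "cn_probe_positions.tsv",
    "tumor_beta": "tumor_beta.tsv",
    "normal_beta": "normal_beta.tsv",
    "clinical": "clinical.tsv",
    "mrna": "mrna.tsv",
    "truth": "truth.json",
}


def write_fixture(bundle: CohortBundle, directory) -> None:
    """Write every cohort layer in its documented text format."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_annotation(bundle.annotations, d / _FILES["annotation"])
    write_probe_annotation(bundle.probes, d / _FILES["probes"])
    write_matrix(bundle.mature_expression, d / _FILES["expression"])
    det = bundle.detected.astype(int)
    det.index.name = "feature_id"
    det.to_csv(d / _FILES["detected"], sep="\t")
    write_matrix(bundle.cn_probes, d / _FILES["cn_probes"])
    pos = bundle.cn_probe_positions.copy()
    pos.index.name = "probe_id"
    pos.to_csv(d / _FILES["cn_positions"], sep="\t")
    write_matrix(bundle.tumor_beta, d / _FILES["tumor_beta"])
    write_matrix(bundle.normal_beta, d / _FILES["normal_beta"])
    cols = ["sample_id", "er", "her2", "grade", "tp53", "subtype", "rfs_time", "rfs_event"]
    bundle.clinical[cols].to_csv(d / _FILES["clinical"], sep="\t", index=False, na_rep="")
    write_matrix(bundle.mrna, d / _FILES["mrna"])
    truth = bundle.truth
    payload = {
        "name": bundle.name,
        "mechanism": truth.mechanism,
        "altered": {l: truth.altered.columns[truth.altered.loc[l]].tolist() for l in truth.altered.index},
        "cn_altered": {l: truth.cn_altered.columns[truth.cn_altered.loc[l]].tolist() for l in truth.cn_altered.index},
        "meth_altered": {l: truth.meth_altered.columns[truth.meth_altered.loc[l]].tolist() for l in truth.meth_altered.index},
        "clinical_targets": truth.clinical_targets,
        "survival_locus": truth.survival_locus,
        "corr_pairs": [list(p) for p in truth.corr_pairs],
        "families": truth.families,
        "samples": list(truth.altered.columns),
    }
    with open(d / _FILES["truth"], "w") as fh:
        json.dump(payload, fh, indent=1)


def read_fixture(directory) -> CohortBundle:
    """Read a fixture directory written by :func:`write_fixture`."""
    d = Path(directory)
    annotations = read_annotation(d / _FILES["annotation"])
    probes = read_probe_annotation(d / _FILES["probes"])
    expression = read_matrix(d / _FILES["expression"], EXPRESSION)
    detected = pd.read_csv(d / _FILES["detected"], sep="\t", index_col=0).astype(bool)
    cn_probes = read_matrix(d / _FILES["cn_probes"], CN_LOGRATIO)
    cn_positions = pd.read_csv(d / _FILES["cn_positions"], sep="\t", index_col=0)
    tumor_beta = read_matrix(d / _FILES["tumor_beta"], BETA)
    normal_beta = read_matrix(d / _FILES["normal_beta"], BETA)
    clinical = pd.read_csv(d / _FILES["clinical"], sep="\t", dtype={"sample_id": str}).set_index(
        "sample_id", drop=False
    )
    mrna = read_matrix(d / _FILES["mrna"], EXPRESSION)
    with open(d / _FILES["truth"]) as fh:
        payload = json.load(fh)
    samples = payload["samples"]
    loci = list(payload["mechanism"])

    def _flags(key):
        df = pd.DataFrame(False, index=loci, columns=samples)
        for l, cols in payload[key].items():
            df.loc[l, cols] = True
        return df

    truth = TruthTable(
        mechanism=payload["mechanism"],
        altered=_flags("altered"),
        cn_altered=_flags("cn_altered"),
        meth_altered=_flags("meth_altered"),
        clinical_targets=payload["clinical_targets"],
        survival_locus=payload["survival_locus"],
        corr_pairs=[tuple(p) for p in payload["corr_pairs"]],
        families=payload["families"],
    )
    return CohortBundle(
        name=payload.get("name", "D"),
        annotations=annotations,
        probes=probes,
        mature_expression=expression,
        detected=detected,
        cn_probes=cn_probes,
        cn_probe_positions=cn_positions,
        tumor_beta=tumor_beta,
        normal_beta=normal_beta,
        clinical=clinical,
        mrna=mrna,
        truth=truth,
    )
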