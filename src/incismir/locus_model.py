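"""miRNA genomic loci, seed families and methylation-probe assignment.

A mature miRNA may be encoded at several genomic loci; expression arrays
measure the mature transcript, so per-locus analyses expand each mature
measurement to all of its loci.  Nucleotides 2-8 of the mature sequence form
the seed; loci with identical seeds belong to one family and share target
repertoires.  Methylation probes are tied to loci by a three-tier rule:
designated promoter probes first, the host gene's promoter probes for
intronic loci without designated probes, and otherwise the single nearest
probe on the same chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import InvalidAnnotationError, UnassignableLocusError
from .matrix import LocusSampleMatrix

log = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: 450k-style probe feature classes that count as proximal promoter:
#: within 1,500 bp upstream of the TSS, in the 5' UTR, or in the first exon.
PROMOTER_FEATURES = frozenset({"TSS1500", "5UTR", "FirstExon"})
FEATURE_CLASSES = frozenset(
    {"TSS1500", "5UTR", "FirstExon", "Body", "3UTR", "Intergenic"}
)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 1:
            raise InvalidAnnotationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise InvalidAnnotationError(
                f"end ({self.end}) precedes start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise InvalidAnnotationError(f"strand must be '+' or '-', got {self.strand!r}")


def extract_seed(mature_sequence: str) -> str:
    """Return the 7-nt seed: positions 2-8 (1-based) of the mature sequence.

    The sequence must be RNA (A/C/G/U, case-insensitive) and at least 8 nt.
    """
    seq = str(mature_sequence).upper()
    if len(seq) < 8:
        raise InvalidAnnotationError(
            f"mature sequence shorter than 8 nt: {mature_sequence!r}"
        )
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise InvalidAnnotationError(
            f"invalid character(s) {sorted(bad)} in mature sequence {mature_sequence!r}"
        )
    return seq[1:8]


@dataclass
class MirnaLocusAnnotation:
    """One genomic copy of a mature miRNA."""

    locus_id: str
    mature_id: str
    mimat_id: str
    interval: GenomicInterval
    mature_sequence: str
    host_gene: Optional[str] = None
    intronic: bool = False
    family_id: Optional[str] = None
    seed: str = field(default="", repr=False)

    def __post_init__(self):
        derived = extract_seed(self.mature_sequence)
        if self.seed and self.seed != derived:
            raise InvalidAnnotationError(
                f"{self.locus_id}: stored seed {self.seed!r} != derived {derived!r}"
            )
        self.seed = derived
        self.mature_sequence = self.mature_sequence.upper()


@dataclass(frozen=True)
class ProbeAnnotation:
    """A methylation probe interrogating one CpG site."""

    probe_id: str
    position: GenomicInterval  # single CpG: start == end
    feature_class: str = "Intergenic"
    designated_locus_ids: frozenset = frozenset()
    promoter_gene_ids: frozenset = frozenset()

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise InvalidAnnotationError(
                f"{self.probe_id}: unknown feature class {self.feature_class!r}"
            )
        object.__setattr__(self, "designated_locus_ids", frozenset(self.designated_locus_ids))
        object.__setattr__(self, "promoter_gene_ids", frozenset(self.promoter_gene_ids))

    @property
    def is_promoter(self) -> bool:
        return self.feature_class in PROMOTER_FEATURES


@dataclass(frozen=True)
class ProbeAssignment:
    locus_id: str
    probe_ids: tuple
    tier: str  # designated | host_promoter | nearest

    def __post_init__(self):
        if self.tier not in ("designated", "host_promoter", "nearest"):
            raise InvalidAnnotationError(f"unknown assignment tier {self.tier!r}")
        if not self.probe_ids:
            raise InvalidAnnotationError(f"{self.locus_id}: empty probe assignment")
        if self.tier == "nearest" and len(self.probe_ids) != 1:
            raise InvalidAnnotationError(
                f"{self.locus_id}: nearest-tier assignment must hold exactly one probe"
            )


def _check_unique_loci(annotations: Iterable[MirnaLocusAnnotation]):
    seen = set()
    for ann in annotations:
        if ann.locus_id in seen:
            raise InvalidAnnotationError(f"duplicate locus_id {ann.locus_id!r}")
        seen.add(ann.locus_id)


def group_families(annotations: list) -> dict:
    """Group loci into seed families: identical seed <=> same family.

    The family id is the seed followed by the lexicographically smallest
    member mature_id, making ids deterministic under input reordering.
    Singleton families are allowed.  Side effect: each annotation's
    ``family_id`` is filled in.
    """
    _check_unique_loci(annotations)
    by_seed: dict = {}
    for ann in annotations:
        by_seed.setdefault(ann.seed, []).append(ann)
    families = {}
    for seed, members in by_seed.items():
        fam_id = f"{seed}/{min(m.mature_id for m in members)}"
        families[fam_id] = {m.locus_id for m in members}
        for m in members:
            m.family_id = fam_id
    return families


def expand_to_loci(mature_matrix: LocusSampleMatrix, annotations: list) -> LocusSampleMatrix:
    """Expand a mature-miRNA expression matrix to one row per genomic locus.

    Each locus row is a verbatim copy of its mature miRNA's row; mature ids
    without any annotated locus are dropped with a warning.  Column order is
    preserved.
    """
    loci_by_mature: dict = {}
    for ann in annotations:
        loci_by_mature.setdefault(ann.mature_id, []).append(ann)
    rows = []
    index = []
    for mature_id in mature_matrix.row_ids:
        loci = loci_by_mature.get(mature_id)
        if not loci:
            log.warning("mature miRNA %s has no annotated locus; row dropped", mature_id)
            continue
        for ann in loci:
            rows.append(mature_matrix.data.loc[mature_id])
            index.append(ann.locus_id)
    expanded = pd.DataFrame(rows, index=index, columns=mature_matrix.data.columns)
    return LocusSampleMatrix(expanded, mature_matrix.kind)


def collapse_to_mature(locus_matrix: LocusSampleMatrix, annotations: list) -> LocusSampleMatrix:
    """Inverse of :func:`expand_to_loci`: keep one row per mature miRNA."""
    mature_of = {a.locus_id: a.mature_id for a in annotations}
    first_locus: dict = {}
    for locus_id in locus_matrix.row_ids:
        mature = mature_of[locus_id]
        first_locus.setdefault(mature, locus_id)
    data = locus_matrix.data.loc[list(first_locus.values())]
    data.index = list(first_locus.keys())
    return LocusSampleMatrix(data, locus_matrix.kind)


def assign_methylation_probes(annotations: list, probes: list) -> list:
    """Assign every locus its methylation probes by the three-tier hierarchy.

    Tier 1 (``designated``): all promoter-class probes naming the locus in
    their designated set.  Tier 2 (``host_promoter``): for intronic loci with
    no designated probes, the host gene's promoter probes.  Tier 3
    (``nearest``): the single closest probe (any class) on the locus's
    chromosome, distance measured to the locus start; equidistant ties break
    toward the lower coordinate, then lexicographic probe id.

    Raises :class:`UnassignableLocusError` listing loci on chromosomes with
    zero probes.
    """
    _check_unique_loci(annotations)
    designated: dict = {}
    host_promoter: dict = {}
    by_chrom: dict = {}
    for p in probes:
        by_chrom.setdefault(p.position.chrom, []).append(p)
        if p.is_promoter:
            for locus_id in p.designated_locus_ids:
                designated.setdefault(locus_id, []).append(p)
            for gene in p.promoter_gene_ids:
                host_promoter.setdefault(gene, []).append(p)

    def _ordered(ps):
        return tuple(
            q.probe_id for q in sorted(ps, key=lambda q: (q.position.start, q.probe_id))
        )

    assignments = []
    unassignable = []
    for ann in annotations:
        tier1 = designated.get(ann.locus_id)
        if tier1:
            assignments.append(ProbeAssignment(ann.locus_id, _ordered(tier1), "designated"))
            continue
        if ann.intronic and ann.host_gene:
            tier2 = host_promoter.get(ann.host_gene)
            if tier2:
                assignments.append(
                    ProbeAssignment(ann.locus_id, _ordered(tier2), "host_promoter")
                )
                continue
        candidates = by_chrom.get(ann.interval.chrom, [])
        if not candidates:
            unassignable.append(ann.locus_id)
            continue
        nearest = min(
            candidates,
            key=lambda q: (abs(q.position.start - ann.interval.start), q.position.start, q.probe_id),
        )
        assignments.append(ProbeAssignment(ann.locus_id, (nearest.probe_id,), "nearest"))
    if unassignable:
        raise UnassignableLocusError(unassignable)
    return assignments


# ---------------------------------------------------------------------------
# Annotation I/O (tab-separated; BED6 export uses 0-based half-open intervals)
# ---------------------------------------------------------------------------

_ANNOT_COLS = [
    "locus_id", "mature_id", "mimat_id", "chrom", "start", "end",
    "strand", "sequence", "host_gene", "intronic",
]


def write_annotation(annotations: list, path) -> None:
    rows = [
        {
            "locus_id": a.locus_id, "mature_id": a.mature_id, "mimat_id": a.mimat_id,
            "chrom": a.interval.chrom, "start": a.interval.start, "end": a.interval.end,
            "strand": a.interval.strand, "sequence": a.mature_sequence,
            "host_gene": a.host_gene or "", "intronic": int(a.intronic),
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_ANNOT_COLS).to_csv(path, sep="\t", index=False)


def read_annotation(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"host_gene": str}, keep_default_na=False)
    missing = set(_ANNOT_COLS) - set(df.columns)
    if missing:
        raise InvalidAnnotationError(f"{path}: missing columns {sorted(missing)}")
    anns = [
        MirnaLocusAnnotation(
            locus_id=r.locus_id, mature_id=r.mature_id, mimat_id=r.mimat_id,
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end), r.strand),
            mature_sequence=r.sequence,
            host_gene=r.host_gene or None, intronic=bool(int(r.intronic)),
        )
        for r in df.itertuples()
    ]
    group_families(anns)
    return anns


def write_annotation_bed(annotations: list, path) -> None:
    """BED6 export: 0-based half-open coordinates."""
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(
                f"{a.interval.chrom}\t{a.interval.start - 1}\t{a.interval.end}\t"
                f"{a.locus_id}\t0\t{a.interval.strand}\n"
            )


def write_probe_annotation(probes: list, path) -> None:
    rows = [
        {
            "probe_id": p.probe_id, "chrom": p.position.chrom, "pos": p.position.start,
            "feature_class": p.feature_class,
            "gene": ";".join(sorted(p.promoter_gene_ids)),
            "designated_locus_ids": ";".join(sorted(p.designated_locus_ids)),
        }
        for p in probes
    ]
    pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "feature_class", "gene", "designated_locus_ids"]
    ).to_csv(path, sep="\t", index=False)


def read_probe_annotation(path) -> list:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    probes = []
    for r in df.itertuples():
        pos = int(r.pos)
        probes.append(
            ProbeAnnotation(
                probe_id=r.probe_id,
                position=GenomicInterval(str(r.chrom), pos, pos),
                feature_class=r.feature_class,
                designated_locus_ids=frozenset(
                    x for x in str(r.designated_locus_ids).split(";") if x
                ),
                promoter_gene_ids=frozenset(x for x in str(r.gene).split(";") if x),
            )
        )
    return probes
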