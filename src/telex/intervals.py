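"""Gene/TE annotation parsing and positional classification of TE loci.

A transposable-element (TE) locus is classified by where it sits relative
to annotated gene models: overlapping a start codon, stop codon, exon, or
intron, or lying between genes (intergenic).  Loci fully covered by the
exonic sequence of a single gene are discarded, since reads from such loci
cannot be distinguished from ordinary host-gene transcription.

Coordinates are 0-based half-open internally.  GTF input (1-based,
inclusive) is converted on read; BED input is taken as-is.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

TE_CLASSES = frozenset({"DNA", "LINE", "LTR", "SINE"})

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals on the same chromosome (0 if
        overlapping or abutting)."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def merge_intervals(ivals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/abutting intervals (strand ignored)."""
    ivals = sorted(ivals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivals:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    body: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    start_codon: Optional[GenomicInterval] = None
    stop_codon: Optional[GenomicInterval] = None

    def covered_union(self) -> list[GenomicInterval]:
        """Merged union of exons plus start/stop codons of this gene."""
        parts = list(self.exons)
        if self.start_codon:
            parts.append(self.start_codon)
        if self.stop_codon:
            parts.append(self.stop_codon)
        return merge_intervals(parts)


@dataclass(frozen=True)
class TELocus:
    te_id: str
    subfamily: str
    family: str
    te_class: str
    locus: GenomicInterval

    @classmethod
    def from_fields(
        cls, chrom: str, start: int, end: int, subfamily: str, family: str,
        te_class: str, strand: str = ".",
    ) -> "TELocus":
        return cls(
            te_id=f"{chrom}:{start}-{end}:{subfamily}",
            subfamily=subfamily,
            family=family,
            te_class=te_class,
            locus=GenomicInterval(chrom, start, end, strand),
        )


class TELabel(str, Enum):
    EXON = "EXON"
    START_CODON = "START_CODON"
    STOP_CODON = "STOP_CODON"
    INTRONIC = "INTRONIC"
    INTERGENIC = "INTERGENIC"
    DISCARDED = "DISCARDED"

    def __str__(self) -> str:  # noqa: D105 - plain value in TSVs
        return self.value


#: Labels retained for downstream gene-TE pairing.
RETAINED_LABELS = frozenset(
    {TELabel.EXON, TELabel.START_CODON, TELabel.STOP_CODON,
     TELabel.INTRONIC, TELabel.INTERGENIC}
)


@dataclass(frozen=True)
class TEClassification:
    te_id: str
    label: TELabel
    associated_gene_id: Optional[str]
    distance_bp: int


class AnnotationParseError(ValueError):
    pass


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GTF file.

    Recognized feature types: ``gene``, ``exon``, ``start_codon``,
    ``stop_codon``; anything else is silently ignored.  GTF coordinates
    (1-based, inclusive) are converted to 0-based half-open.  Genes that
    appear only through exon/codon lines get a body spanning them.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    order: list[str] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            cols = line.split("\t")
            if len(cols) < 9:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = cols[:9]
            if feature not in {"gene", "exon", "start_codon", "stop_codon"}:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"({start_s!r}, {end_s!r})"
                ) from exc
            if start1 < 1 or end1 < start1:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: invalid coordinate range "
                    f"{start1}-{end1}"
                )
            attr = dict(_GTF_ATTR_RE.findall(attrs))
            gene_id = attr.get("gene_id")
            if not gene_id:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: missing gene_id attribute"
                )
            iv = GenomicInterval(chrom, start1 - 1, end1, strand if strand in "+-" else ".")
            rec = genes.setdefault(
                gene_id,
                {"name": attr.get("gene_name", gene_id), "body": None,
                 "exons": [], "start_codon": [], "stop_codon": []},
            )
            if len(genes) > len(order):
                order.append(gene_id)
            if feature == "gene":
                rec["body"] = iv
            elif feature == "exon":
                rec["exons"].append(iv)
            else:
                rec[feature].append(iv)
    if n_lines == 0:
        logger.warning("gene annotation %s is empty", path)
        return []

    models: list[GeneModel] = []
    for gene_id in order:
        rec = genes[gene_id]
        parts = rec["exons"] + rec["start_codon"] + rec["stop_codon"]
        body = rec["body"]
        if body is None:
            if not parts:
                continue
            body = GenomicInterval(
                parts[0].chrom,
                min(p.start for p in parts),
                max(p.end for p in parts),
                parts[0].strand,
            )
        models.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=rec["name"],
                body=body,
                exons=sorted(rec["exons"], key=lambda iv: iv.start),
                start_codon=_span(rec["start_codon"]),
                stop_codon=_span(rec["stop_codon"]),
            )
        )
    return models


def _span(ivals: Sequence[GenomicInterval]) -> Optional[GenomicInterval]:
    if not ivals:
        return None
    return GenomicInterval(
        ivals[0].chrom,
        min(iv.start for iv in ivals),
        max(iv.end for iv in ivals),
        ivals[0].strand,
    )


def read_te_annotation(path: str | Path, strict: bool = False) -> list[TELocus]:
    """Read TE loci from BED6+ where the name field is ``subfamily:family:class``.

    Records whose class is not one of DNA/LINE/LTR/SINE are dropped with a
    warning, or rejected hard when ``strict`` is set.
    """
    path = Path(path)
    loci: list[TELocus] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected >=6 BED columns, got {len(cols)}"
                )
            chrom, start_s, end_s, name, _score, strand = cols[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            parts = name.split(":")
            if len(parts) != 3:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: name field must be "
                    f"'subfamily:family:class', got {name!r}"
                )
            subfamily, family, te_class = parts
            if te_class not in TE_CLASSES:
                msg = (
                    f"{path}: line {lineno}: TE class {te_class!r} not in "
                    f"{sorted(TE_CLASSES)}"
                )
                if strict:
                    raise AnnotationParseError(msg)
                logger.warning("%s; record dropped", msg)
                continue
            loci.append(
                TELocus.from_fields(
                    chrom, start, end, subfamily, family, te_class,
                    strand if strand in "+-" else ".",
                )
            )
    return loci


def write_te_bed(loci: Iterable[TELocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for te in loci:
            fh.write(
                f"{te.locus.chrom}\t{te.locus.start}\t{te.locus.end}\t"
                f"{te.subfamily}:{te.family}:{te.te_class}\t0\t{te.locus.strand}\n"
            )


def classify_te_locus(te: TELocus, genes: Sequence[GeneModel]) -> TEClassification:
    """Classify one TE locus against gene models (strand-agnostic).

    Discard rule: the locus is DISCARDED iff it is fully contained in the
    merged exon/start-codon/stop-codon union of a single overlapping gene.
    Otherwise, among gene-body overlaps, the label follows the priority
    START_CODON > STOP_CODON > EXON > INTRONIC evaluated on the associated
    gene (largest body overlap, ties to the lexicographically smaller
    gene_id).  A locus overlapping no gene body is INTERGENIC and is
    associated with the nearest gene body.
    """
    chrom_genes = [g for g in genes if g.body.chrom == te.locus.chrom]
    overlapping = [g for g in chrom_genes if g.body.overlaps(te.locus)]

    if not overlapping:
        if not chrom_genes:
            logger.warning(
                "TE %s: no genes on chromosome %s; intergenic with no "
                "associated gene", te.te_id, te.locus.chrom,
            )
            return TEClassification(te.te_id, TELabel.INTERGENIC, None, 0)
        gene_id, dist = associate_intergenic(te, chrom_genes)
        return TEClassification(te.te_id, TELabel.INTERGENIC, gene_id, dist)

    for g in overlapping:
        if _covered_by(te.locus, g.covered_union()):
            return TEClassification(te.te_id, TELabel.DISCARDED, None, 0)

    host = min(
        overlapping,
        key=lambda g: (-g.body.overlap_bp(te.locus), g.gene_id),
    )
    if host.start_codon is not None and te.locus.overlaps(host.start_codon):
        label = TELabel.START_CODON
    elif host.stop_codon is not None and te.locus.overlaps(host.stop_codon):
        label = TELabel.STOP_CODON
    elif any(te.locus.overlaps(e) for e in host.exons):
        label = TELabel.EXON
    else:
        label = TELabel.INTRONIC
    return TEClassification(te.te_id, label, host.gene_id, 0)


def _covered_by(iv: GenomicInterval, union: Sequence[GenomicInterval]) -> bool:
    return any(u.contains(iv) for u in union)


def associate_intergenic(
    te: TELocus, genes: Sequence[GeneModel]
) -> tuple[Optional[str], int]:
    """Nearest gene (body gap distance) for an intergenic TE.

    Equidistant genes break ties to the lexicographically smaller gene_id.
    """
    chrom_genes = [g for g in genes if g.body.chrom == te.locus.chrom]
    if not chrom_genes:
        logger.warning("TE %s: no gene on chromosome for association", te.te_id)
        return None, 0
    best = min(
        chrom_genes, key=lambda g: (te.locus.gap_to(g.body), g.gene_id)
    )
    return best.gene_id, te.locus.gap_to(best.body)


def classify_all(
    tes: Sequence[TELocus], genes: Sequence[GeneModel]
) -> list[TEClassification]:
    """Classify every TE locus; genes are bucketed per chromosome once."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.body.chrom, []).append(g)
    return [
        classify_te_locus(te, by_chrom.get(te.locus.chrom, []))
        for te in tes
    ]


def classification_frame(classifications: Sequence[TEClassification]):
    """Classifications as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "te_id": [c.te_id for c in classifications],
            "label": [c.label.value for c in classifications],
            "gene_id": [c.associated_gene_id or "" for c in classifications],
            "distance_bp": [c.distance_bp for c in classifications],
        }
    )
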