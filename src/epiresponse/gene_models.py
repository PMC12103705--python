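"""Gene annotation parsing and the 21-bin genic coordinate scheme.

Every gene is summarised by 21 labelled intervals used to profile histone-mark
signal around it:

* ``P1``..``P10`` — ten 200 bp bins tiling the 2 kb upstream of the TSS,
  ordered 5'->3' (P1 is furthest from the TSS);
* ``TSS`` — the single-nucleotide transcription start position;
* ``GB1``..``GB10`` — ten near-equal bins tiling the transcribed region,
  ordered 5'->3'.

All coordinates are internally 0-based half-open; converters sit at the I/O
boundary (GTF is 1-based inclusive, BED is already half-open).  Note the TSS
base is also the first base of GB1: the bins are features, not a partition.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

PROMOTER_LABELS = tuple(f"P{i}" for i in range(1, 11))
BODY_LABELS = tuple(f"GB{i}" for i in range(1, 11))
BIN_LABELS = PROMOTER_LABELS + ("TSS",) + BODY_LABELS
N_BINS = len(BIN_LABELS)


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent gene annotation input."""


class BinningError(ValueError):
    """Raised when a gene cannot receive a valid 21-bin scheme."""


@dataclass(frozen=True)
class GeneModel:
    """One gene's representative transcribed span.

    ``start``/``end`` are 0-based half-open genomic coordinates of the
    transcribed region.  The TSS and TES are derived from the strand:
    on ``+`` the TSS is ``start``; on ``-`` it is ``end - 1``.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )
        if not self.start < self.end:
            raise AnnotationError(
                f"gene {self.gene_id!r}: start {self.start} must be < end {self.end}"
            )
        if self.start < 0:
            raise AnnotationError(f"gene {self.gene_id!r}: negative start")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


class Bin(NamedTuple):
    label: str
    start: int
    end: int


@dataclass(frozen=True)
class BinSet:
    """The 21 labelled intervals of one gene, ordered 5'->3'."""

    gene_id: str
    chrom: str
    strand: str
    bins: tuple[Bin, ...]

    def __post_init__(self) -> None:
        if tuple(b.label for b in self.bins) != BIN_LABELS:
            raise BinningError(f"gene {self.gene_id!r}: bad bin labels/order")
        for b in self.bins:
            if not b.start < b.end:
                raise BinningError(f"gene {self.gene_id!r}: empty bin {b.label}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([b.end - b.start for b in self.bins], dtype=np.int64)

    def __getitem__(self, label: str) -> Bin:
        return self.bins[BIN_LABELS.index(label)]


# ---------------------------------------------------------------------------
# annotation readers
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(field))


def _iter_gtf(path: str, id_field: str) -> Iterator[tuple[str, str, str, int, int, str]]:
    """Yield (gene_id, chrom, strand, start0, end, feature) per GTF row."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("gene", "transcript", "mRNA"):
                continue
            try:
                start0 = int(start) - 1  # GTF is 1-based inclusive
                end0 = int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: bad coordinates") from exc
            attr_map = _parse_gtf_attributes(attrs)
            gene_id = attr_map.get(id_field)
            if gene_id is None:
                raise AnnotationError(
                    f"{path}:{lineno}: missing attribute {id_field!r}"
                )
            yield gene_id, chrom, strand, start0, end0, feature


def _read_gtf(path: str, id_field: str) -> list[tuple[str, str, str, int, int]]:
    transcript_rows: list[tuple[str, str, str, int, int]] = []
    gene_rows: list[tuple[str, str, str, int, int]] = []
    genes_with_tx: set[str] = set()
    for gene_id, chrom, strand, start, end, feature in _iter_gtf(path, id_field):
        rec = (gene_id, chrom, strand, start, end)
        if feature in ("transcript", "mRNA"):
            transcript_rows.append(rec)
            genes_with_tx.add(gene_id)
        else:
            gene_rows.append(rec)
    # gene rows only fill in for genes that have no transcript rows
    rows = transcript_rows + [r for r in gene_rows if r[0] not in genes_with_tx]
    return rows


def _read_bed12(path: str) -> list[tuple[str, str, str, int, int]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(f"{path}:{lineno}: BED needs >= 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                rows.append((name, chrom, strand, int(start), int(end)))
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: bad coordinates") from exc
    return rows


_TSV_COLUMNS = ("gene_id", "chrom", "strand", "start", "end")


def _read_gene_tsv(path: str) -> list[tuple[str, str, str, int, int]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise AnnotationError(f"{path}:{lineno}: gene TSV needs 5 columns")
            if lineno == 1 and fields[0] == "gene_id":
                continue  # header
            gene_id, chrom, strand, start, end = fields[:5]
            try:
                rows.append((gene_id, chrom, strand, int(start), int(end)))
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: bad coordinates") from exc
    return rows


def _sniff_format(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith((".gtf", ".gff", ".gtf.gz", ".gff3")):
        return "gtf"
    if lower.endswith(".bed"):
        return "bed12"
    return "tsv"


def read_gene_models(
    path: str,
    fmt: str | None = None,
    id_field: str = "gene_id",
    min_length: int = 200,
    tss_override: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Read gene annotations and collapse to one representative model per gene.

    Multi-transcript genes take the union span of their transcripts with the
    most-5' TSS (which, for a span anchored at the extremes, is the span
    boundary itself).  ``tss_override`` maps gene_id to a 0-based TSS position;
    an overridden TSS re-anchors the transcribed region at that base, keeping
    the downstream boundary.  Genes shorter than ``min_length`` after
    collapsing are dropped; the drop count is logged.

    Supported formats: ``gtf`` (1-based inclusive, attribute key
    ``id_field``), ``bed12`` (name column as gene id), ``tsv``
    (gene_id, chrom, strand, start, end; half-open).
    """
    fmt = fmt or _sniff_format(path)
    if fmt == "gtf":
        rows = _read_gtf(path, id_field)
    elif fmt in ("bed", "bed12"):
        rows = _read_bed12(path)
    elif fmt == "tsv":
        rows = _read_gene_tsv(path)
    else:
        raise AnnotationError(f"unknown annotation format {fmt!r}")

    spans: dict[str, list] = {}
    for gene_id, chrom, strand, start, end in rows:
        if strand not in ("+", "-"):
            raise AnnotationError(f"gene {gene_id!r}: unknown strand {strand!r}")
        if gene_id in spans:
            prev = spans[gene_id]
            if prev[0] != chrom:
                raise AnnotationError(
                    f"gene {gene_id!r}: conflicting chromosomes {prev[0]!r} vs {chrom!r}"
                )
            if prev[1] != strand:
                raise AnnotationError(f"gene {gene_id!r}: conflicting strands")
            prev[2] = min(prev[2], start)
            prev[3] = max(prev[3], end)
        else:
            spans[gene_id] = [chrom, strand, start, end]

    models: list[GeneModel] = []
    n_dropped = 0
    for gene_id, (chrom, strand, start, end) in spans.items():
        if tss_override and gene_id in tss_override:
            tss = int(tss_override[gene_id])
            if strand == "+":
                start = tss
            else:
                end = tss + 1
        if end - start < min_length:
            n_dropped += 1
            continue
        models.append(GeneModel(gene_id, chrom, strand, start, end))
    if n_dropped:
        logger.info(
            "read_gene_models: dropped %d/%d genes shorter than %d bp",
            n_dropped, len(spans), min_length,
        )
    models.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return models


# ---------------------------------------------------------------------------
# bin construction
# ---------------------------------------------------------------------------

def build_bins(
    gene: GeneModel,
    promoter_len: int = 2000,
    n_promoter: int = 10,
    n_body: int = 10,
    chrom_size: int | None = None,
) -> BinSet:
    """Construct the 21-bin scheme for one gene.

    Promoter bins tile the ``promoter_len`` window immediately upstream of
    the TSS in ``n_promoter`` equal pieces; the TSS bin is the single start
    base; gene-body bin edges sit at ``start + floor(k * L / n_body)`` so any
    two body-bin widths differ by at most 1 bp.  On the minus strand the
    whole layout is mirrored, and labels always run 5'->3' along the gene.

    Raises :class:`BinningError` for genes whose body is shorter than
    ``n_body`` bases or whose promoter window leaves the chromosome.
    """
    if promoter_len % n_promoter != 0:
        raise BinningError("promoter_len must be divisible by n_promoter")
    L = gene.end - gene.start
    if L < n_body:
        raise BinningError(
            f"gene {gene.gene_id!r}: body length {L} < {n_body} bins"
        )
    w = promoter_len // n_promoter
    edges = [gene.start + (k * L) // n_body for k in range(n_body + 1)]

    bins: list[Bin] = []
    if gene.strand == "+":
        p0 = gene.tss - promoter_len
        if p0 < 0:
            raise BinningError(
                f"gene {gene.gene_id!r}: promoter window extends before position 0"
            )
        for i in range(n_promoter):
            bins.append(Bin(f"P{i + 1}", p0 + i * w, p0 + (i + 1) * w))
        bins.append(Bin("TSS", gene.tss, gene.tss + 1))
        for i in range(n_body):
            bins.append(Bin(f"GB{i + 1}", edges[i], edges[i + 1]))
    else:
        p_end = gene.end + promoter_len
        if chrom_size is not None and p_end > chrom_size:
            raise BinningError(
                f"gene {gene.gene_id!r}: promoter window extends past chromosome end"
            )
        for i in range(n_promoter):  # P1 is 5'-most, i.e. genomically rightmost
            hi = p_end - i * w
            bins.append(Bin(f"P{i + 1}", hi - w, hi))
        bins.append(Bin("TSS", gene.tss, gene.tss + 1))
        for i in range(n_body):  # GB1 is 5'-most, i.e. genomically last edge pair
            bins.append(Bin(f"GB{i + 1}", edges[n_body - 1 - i], edges[n_body - i]))

    return BinSet(gene.gene_id, gene.chrom, gene.strand, tuple(bins))


def build_catalogue(
    genes: Iterable[GeneModel],
    promoter_len: int = 2000,
    n_promoter: int = 10,
    n_body: int = 10,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[BinSet]:
    """Build bins for every gene, excluding (with a warning) genes that fail."""
    catalogue: list[BinSet] = []
    n_excluded = 0
    for gene in genes:
        size = chrom_sizes.get(gene.chrom) if chrom_sizes else None
        try:
            catalogue.append(
                build_bins(gene, promoter_len, n_promoter, n_body, chrom_size=size)
            )
        except BinningError as exc:
            n_excluded += 1
            logger.warning("excluding gene: %s", exc)
    if n_excluded:
        logger.warning("build_catalogue: excluded %d genes", n_excluded)
    return catalogue


def bin_length_matrix(catalogue: Sequence[BinSet]) -> np.ndarray:
    """(n_genes, 21) array of bin widths in bp, rows aligned with the catalogue."""
    return np.stack([bs.lengths for bs in catalogue]) if catalogue else np.empty((0, N_BINS), dtype=np.int64)


def write_bins_bed(catalogue: Iterable[BinSet], path: str) -> None:
    """Write the bin catalogue as BED6: name ``<gene_id>|<bin_label>``, score 0."""
    with open(path, "w") as fh:
        for bs in catalogue:
            for b in bs.bins:
                fh.write(
                    f"{bs.chrom}\t{b.start}\t{b.end}\t{bs.gene_id}|{b.label}\t0\t{bs.strand}\n"
                )


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Read a two-column chromosome-sizes TSV (name, length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    return sizes
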