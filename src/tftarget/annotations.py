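"""lncRNA annotation handling: GTF parsing, TSS extraction, regulatory windows.

Coordinate conventions
----------------------
GTF coordinates are 1-based, inclusive on both ends (the format standard).
All internal interval work — regulatory regions, peak overlap — is done in
0-based, half-open coordinates, the convention of BED and of every interval
library worth using.  Conversions happen exactly once, here, and are tested
explicitly.

The regulatory region of a feature is the window ``[TSS - u, TSS + d]``
(1-based, strand-oriented: for a minus-strand feature upstream means larger
coordinates) around its transcription start site.  The window includes the
TSS base itself, so an unclamped region has length ``u + d + 1``.  The left
end is clamped at position 1; there is no right clamp because GTF carries no
chromosome lengths and an overhanging window is harmless for overlap.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationError",
    "GtfParseError",
    "AmbiguousNameError",
    "TranscriptRecord",
    "GeneRecord",
    "WindowSpec",
    "RegulatoryRegion",
    "WINDOW_PRESETS",
    "parse_gtf",
    "read_gtf",
    "write_gtf",
    "tss",
    "regulatory_region",
    "transcript_regions",
    "gene_regions",
    "build_regions",
    "resolve_ids",
    "strip_version",
]


class AnnotationError(ValueError):
    """Base class for annotation-layer errors."""


class GtfParseError(AnnotationError):
    """Malformed GTF input; message names the offending line number."""


class AmbiguousNameError(AnnotationError):
    """A feature name resolves to more than one ID."""


@dataclass(frozen=True)
class WindowSpec:
    """A −upstream/+downstream regulatory window around a TSS, in bp."""

    upstream_bp: int
    downstream_bp: int

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window extents must be non-negative")

    @property
    def length(self) -> int:
        """Unclamped window length (the TSS base is included)."""
        return self.upstream_bp + self.downstream_bp + 1


#: The five window presets, keyed by their conventional short names.
#: ``2k1k`` (−2 kb/+1 kb) is the default promoter-proximal choice.
WINDOW_PRESETS: Mapping[str, WindowSpec] = {
    "2k1k": WindowSpec(2_000, 1_000),
    "10k1k": WindowSpec(10_000, 1_000),
    "20k1k": WindowSpec(20_000, 1_000),
    "30k2k": WindowSpec(30_000, 2_000),
    "50k5k": WindowSpec(50_000, 5_000),
}

DEFAULT_WINDOW = WINDOW_PRESETS["2k1k"]


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated lncRNA transcript (1-based inclusive coordinates)."""

    transcript_id: str
    transcript_name: str
    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"transcript {self.transcript_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )


@dataclass(frozen=True)
class GeneRecord:
    """A gene and its member transcripts (all on one chrom and strand)."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    transcript_ids: tuple[str, ...]


@dataclass(frozen=True)
class RegulatoryRegion:
    """A TSS window in 0-based half-open coordinates, ready for overlap."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    window: WindowSpec

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"region {self.feature_id}: invalid interval [{self.start}, {self.end})"
            )


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')

# attribute keys consulted for the biotype, in preference order (GENCODE uses
# *_type, Ensembl GTFs use *_biotype)
_BIOTYPE_KEYS = ("transcript_type", "transcript_biotype", "gene_type", "gene_biotype")


class _TxAccumulator:
    __slots__ = ("gene_id", "gene_name", "transcript_name", "chrom", "strand",
                 "start", "end", "biotype", "first_line")

    def __init__(self, gene_id, chrom, strand, start, end, line_no):
        self.gene_id = gene_id
        self.gene_name = ""
        self.transcript_name = ""
        self.chrom = chrom
        self.strand = strand
        self.start = start
        self.end = end
        self.biotype = ""
        self.first_line = line_no


def parse_gtf(
    lines: Iterable[str],
    feature_filter: Optional[set[str]] = None,
) -> tuple[list[TranscriptRecord], list[GeneRecord]]:
    """Parse GTF lines into transcript and gene records.

    Every feature line carrying a ``transcript_id`` attribute (``transcript``,
    ``exon``, ...) contributes to its transcript: the transcript's span is the
    min start / max end over its features.  ``gene`` lines (no transcript_id)
    are validated but otherwise ignored; genes are reconstructed by grouping
    transcripts on ``gene_id``.

    Parameters
    ----------
    lines
        Iterable of GTF text lines.  Comment lines (``#``) are skipped.
    feature_filter
        Optional set of biotypes; transcripts whose biotype is not in the set
        are dropped (off by default — the supplied GTF is trusted to contain
        the intended lncRNA universe).

    Returns
    -------
    (transcripts, genes)
        In first-appearance order.

    Raises
    ------
    GtfParseError
        On a malformed line (wrong column count, non-integer or inverted
        coordinates) or on a transcript/gene whose features disagree on
        chromosome or strand; the message names the line number.
    """
    acc: dict[str, _TxAccumulator] = {}
    order: list[str] = []

    for line_no, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"line {line_no}: expected 9 tab-separated columns, got {len(fields)}"
            )
        chrom, _source, _feature, start_s, end_s, _score, strand, _frame, attrs = fields
        try:
            start = int(start_s)
            end = int(end_s)
        except ValueError:
            raise GtfParseError(
                f"line {line_no}: non-integer coordinates {start_s!r}/{end_s!r}"
            ) from None
        if start > end:
            raise GtfParseError(f"line {line_no}: start {start} > end {end}")
        if start < 1:
            raise GtfParseError(f"line {line_no}: GTF coordinates are 1-based, got {start}")

        attributes = dict(_ATTR_RE.findall(attrs))
        tid = attributes.get("transcript_id")
        if tid is None:
            continue  # gene line or other transcript-less feature
        if strand not in ("+", "-"):
            raise GtfParseError(
                f"line {line_no}: transcript feature needs strand '+' or '-', got {strand!r}"
            )
        gid = attributes.get("gene_id", "")

        rec = acc.get(tid)
        if rec is None:
            rec = _TxAccumulator(gid, chrom, strand, start, end, line_no)
            acc[tid] = rec
            order.append(tid)
        else:
            if rec.chrom != chrom or rec.strand != strand:
                raise GtfParseError(
                    f"line {line_no}: transcript {tid} switches chrom/strand "
                    f"({rec.chrom}{rec.strand} vs {chrom}{strand}; "
                    f"first seen at line {rec.first_line})"
                )
            if gid and rec.gene_id and gid != rec.gene_id:
                raise GtfParseError(
                    f"line {line_no}: transcript {tid} switches gene_id "
                    f"({rec.gene_id} vs {gid})"
                )
            rec.start = min(rec.start, start)
            rec.end = max(rec.end, end)
        if not rec.gene_name:
            rec.gene_name = attributes.get("gene_name", "")
        if not rec.transcript_name:
            rec.transcript_name = attributes.get("transcript_name", "")
        if not rec.biotype:
            for key in _BIOTYPE_KEYS:
                if key in attributes:
                    rec.biotype = attributes[key]
                    break

    transcripts: list[TranscriptRecord] = []
    for tid in order:
        rec = acc[tid]
        if feature_filter is not None and rec.biotype not in feature_filter:
            continue
        transcripts.append(
            TranscriptRecord(
                transcript_id=tid,
                transcript_name=rec.transcript_name,
                gene_id=rec.gene_id,
                gene_name=rec.gene_name,
                chrom=rec.chrom,
                start=rec.start,
                end=rec.end,
                strand=rec.strand,
                biotype=rec.biotype,
            )
        )

    genes: list[GeneRecord] = []
    by_gene: dict[str, list[TranscriptRecord]] = {}
    gene_order: list[str] = []
    for t in transcripts:
        if t.gene_id not in by_gene:
            by_gene[t.gene_id] = []
            gene_order.append(t.gene_id)
        by_gene[t.gene_id].append(t)
    for gid in gene_order:
        members = by_gene[gid]
        chroms = {t.chrom for t in members}
        strands = {t.strand for t in members}
        if len(chroms) > 1 or len(strands) > 1:
            raise GtfParseError(
                f"gene {gid}: member transcripts disagree on chrom/strand "
                f"({sorted(chroms)}, {sorted(strands)})"
            )
        genes.append(
            GeneRecord(
                gene_id=gid,
                gene_name=members[0].gene_name,
                chrom=members[0].chrom,
                strand=members[0].strand,
                transcript_ids=tuple(t.transcript_id for t in members),
            )
        )
    return transcripts, genes


def _open_text(path) -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gtf(path, feature_filter: Optional[set[str]] = None):
    """Parse a GTF file from disk (gzip accepted by ``.gz`` suffix)."""
    with _open_text(path) as fh:
        return parse_gtf(fh, feature_filter=feature_filter)


def write_gtf(transcripts: Sequence[TranscriptRecord], handle: TextIO) -> None:
    """Serialize transcripts as GTF (one transcript + one exon line each).

    Sufficient for round-tripping through :func:`parse_gtf`; single-exon
    models are written since exon structure plays no role here.
    """
    for t in transcripts:
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'gene_type "{t.biotype}"; gene_name "{t.gene_name}"; '
            f'transcript_type "{t.biotype}"; transcript_name "{t.transcript_name}";'
        )
        for feature in ("transcript", "exon"):
            handle.write(
                f"{t.chrom}\ttftarget\t{feature}\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# TSS and regulatory regions
# ---------------------------------------------------------------------------

def tss(record: TranscriptRecord) -> tuple[str, int, str]:
    """Transcription start site: the 5′-most transcribed base (1-based).

    For a plus-strand transcript this is ``start``; for minus strand, ``end``.
    """
    pos = record.start if record.strand == "+" else record.end
    return record.chrom, pos, record.strand


def regulatory_region(
    record: TranscriptRecord,
    window: WindowSpec = DEFAULT_WINDOW,
    feature_id: Optional[str] = None,
) -> RegulatoryRegion:
    """The strand-oriented −u/+d window around the transcript's TSS.

    In 1-based inclusive terms the region is ``[t − u, t + d]`` on plus
    strand and ``[t − d, t + u]`` on minus strand (upstream follows the
    direction of transcription).  The left end is clamped at position 1.
    The result is returned in 0-based half-open coordinates.
    """
    _, t, strand = tss(record)
    u, d = window.upstream_bp, window.downstream_bp
    if strand == "+":
        lo1, hi1 = t - u, t + d
    else:
        lo1, hi1 = t - d, t + u
    lo1 = max(lo1, 1)
    return RegulatoryRegion(
        feature_id=feature_id if feature_id is not None else record.transcript_id,
        chrom=record.chrom,
        start=lo1 - 1,
        end=hi1,
        strand=strand,
        window=window,
    )


def transcript_regions(
    transcripts: Iterable[TranscriptRecord],
    window: WindowSpec = DEFAULT_WINDOW,
) -> list[RegulatoryRegion]:
    """One region per transcript, keyed by transcript_id."""
    return [regulatory_region(t, window) for t in transcripts]


def gene_regions(
    gene: GeneRecord,
    transcripts: Mapping[str, TranscriptRecord],
    window: WindowSpec = DEFAULT_WINDOW,
) -> list[RegulatoryRegion]:
    """One region per member transcript, all keyed by the gene_id.

    Gene-level targeting is the union over member-transcript windows: a peak
    in any of them marks the gene targeted.  GENCODE genes commonly have
    several TSSs, and the union is the permissive reading of gene-level
    input; per-transcript runs are available via ``level="transcript"``.
    """
    regions = []
    for tid in gene.transcript_ids:
        try:
            rec = transcripts[tid]
        except KeyError:
            raise AnnotationError(
                f"gene {gene.gene_id}: member transcript {tid} not found"
            ) from None
        regions.append(regulatory_region(rec, window, feature_id=gene.gene_id))
    return regions


def build_regions(
    transcripts: Sequence[TranscriptRecord],
    genes: Sequence[GeneRecord],
    level: str = "gene",
    window: WindowSpec = DEFAULT_WINDOW,
) -> list[RegulatoryRegion]:
    """All regulatory regions at the requested level (``gene`` or ``transcript``)."""
    if level == "transcript":
        return transcript_regions(transcripts, window)
    if level == "gene":
        tindex = {t.transcript_id: t for t in transcripts}
        out: list[RegulatoryRegion] = []
        for g in genes:
            out.extend(gene_regions(g, tindex, window))
        return out
    raise ValueError(f"level must be 'gene' or 'transcript', got {level!r}")


# ---------------------------------------------------------------------------
# ID resolution
# ---------------------------------------------------------------------------

_VERSION_RE = re.compile(r"\.\d+$")


def strip_version(feature_id: str) -> str:
    """Drop a trailing Ensembl-style version suffix (``ENSG…​.7`` → ``ENSG…``)."""
    return _VERSION_RE.sub("", feature_id)


def resolve_ids(
    query_ids: Iterable[str],
    transcripts: Sequence[TranscriptRecord],
    genes: Sequence[GeneRecord],
    level: str = "gene",
    strip_versions: bool = True,
) -> tuple[list[str], list[str]]:
    """Map user-supplied IDs or names to canonical feature IDs.

    Resolution order per query: exact ID, version-stripped ID (when
    ``strip_versions``), then name.  A name matching several IDs raises
    :class:`AmbiguousNameError` listing the candidates.  Unrecognized
    entries are dropped with a warning and returned separately; duplicates
    (after resolution) are dropped with a logged count.

    Returns
    -------
    (resolved, unknown)
        ``resolved`` in first-appearance order, without duplicates.
    """
    if level == "gene":
        pairs = [(g.gene_id, g.gene_name) for g in genes]
    elif level == "transcript":
        pairs = [(t.transcript_id, t.transcript_name) for t in transcripts]
    else:
        raise ValueError(f"level must be 'gene' or 'transcript', got {level!r}")

    id_map: dict[str, str] = {}
    name_map: dict[str, set[str]] = {}
    for fid, name in pairs:
        id_map[fid] = fid
        if strip_versions:
            id_map.setdefault(strip_version(fid), fid)
        if name:
            name_map.setdefault(name, set()).add(fid)

    resolved: list[str] = []
    seen: set[str] = set()
    unknown: list[str] = []
    n_dupes = 0
    for raw in query_ids:
        q = raw.strip()
        if not q:
            continue
        fid = id_map.get(q)
        if fid is None and strip_versions:
            fid = id_map.get(strip_version(q))
        if fid is None:
            candidates = name_map.get(q)
            if candidates:
                if len(candidates) > 1:
                    raise AmbiguousNameError(
                        f"name {q!r} matches multiple IDs: {sorted(candidates)}"
                    )
                fid = next(iter(candidates))
        if fid is None:
            logger.warning("input ID %r not found in annotation; dropped", q)
            unknown.append(q)
            continue
        if fid in seen:
            n_dupes += 1
            continue
        seen.add(fid)
        resolved.append(fid)
    if n_dupes:
        logger.info("dropped %d duplicate input IDs after resolution", n_dupes)
    return resolved, unknown
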