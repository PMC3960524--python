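"""ChIP-Seq peak input: narrowPeak / broadPeak / BED parsing plus metadata.

Peaks are stored in their native 0-based half-open coordinates.  Peak strand
is carried through but deliberately ignored downstream: TF binding is
double-stranded and ENCODE uniform-processing peaks carry ``.``; only the
lncRNA's strand matters (it orients the TSS window).
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "PeakDataset",
    "PeakParseError",
    "ManifestError",
    "DIALECTS",
    "parse_peaks",
    "serialize_peaks",
    "load_dataset",
    "load_manifest",
    "normalize_chrom_names",
]

DIALECTS = ("narrowPeak", "broadPeak", "bed")

# required column counts per dialect; bed accepts 3..12 (extras ignored)
_NARROW_COLS = 10  # BED6+4
_BROAD_COLS = 9    # BED6+3


class PeakParseError(ValueError):
    """Malformed peak line; message names the line number."""


class ManifestError(ValueError):
    """Malformed or inconsistent dataset manifest."""


@dataclass(slots=True)
class Peak:
    """One enriched interval from a ChIP-Seq experiment (0-based half-open).

    Missing statistics use the ENCODE convention of ``-1``; ``summit_offset``
    is the narrowPeak point-source offset from ``start`` (``-1`` = not given).
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."
    signal_value: float = -1.0
    p_value_log: float = -1.0
    q_value_log: float = -1.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid peak interval [{self.start}, {self.end})")


@dataclass
class PeakDataset:
    """One ChIP-Seq experiment's peaks plus its identifying metadata."""

    dataset_id: str
    tf_name: str
    cell_line: str
    species: str
    peaks: list[Peak] = field(default_factory=list)


def _skip(line: str) -> bool:
    return (
        not line
        or line.startswith("#")
        or line.startswith("track")
        or line.startswith("browser")
    )


def parse_peaks(lines: Iterable[str], dialect: str = "narrowPeak") -> list[Peak]:
    """Parse peak lines in the declared dialect, order preserved.

    narrowPeak requires exactly 10 columns, broadPeak 9; plain ``bed``
    accepts 3 or more (columns 4–6 mapped when present, extras ignored).
    Track/browser/comment lines are skipped.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    peaks: list[Peak] = []
    for line_no, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if _skip(line):
            continue
        fields = line.split("\t")
        n = len(fields)
        if dialect == "narrowPeak" and n != _NARROW_COLS:
            raise PeakParseError(f"line {line_no}: narrowPeak needs 10 columns, got {n}")
        if dialect == "broadPeak" and n != _BROAD_COLS:
            raise PeakParseError(f"line {line_no}: broadPeak needs 9 columns, got {n}")
        if dialect == "bed" and n < 3:
            raise PeakParseError(f"line {line_no}: BED needs >= 3 columns, got {n}")
        try:
            start = int(fields[1])
            end = int(fields[2])
        except ValueError:
            raise PeakParseError(
                f"line {line_no}: non-integer coordinates {fields[1]!r}/{fields[2]!r}"
            ) from None
        if start < 0 or start >= end:
            raise PeakParseError(f"line {line_no}: invalid interval [{start}, {end})")
        try:
            peaks.append(
                Peak(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    name=fields[3] if n > 3 else "",
                    score=float(fields[4]) if n > 4 else 0.0,
                    strand=fields[5] if n > 5 else ".",
                    signal_value=float(fields[6]) if dialect != "bed" else -1.0,
                    p_value_log=float(fields[7]) if dialect != "bed" else -1.0,
                    q_value_log=float(fields[8]) if dialect != "bed" else -1.0,
                    summit_offset=int(fields[9]) if dialect == "narrowPeak" else -1,
                )
            )
        except ValueError as exc:
            raise PeakParseError(f"line {line_no}: {exc}") from None
    return peaks


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def serialize_peaks(peaks: Sequence[Peak], handle: TextIO, dialect: str = "narrowPeak") -> None:
    """Write peaks back out in the given dialect (value-exact round trip)."""
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    for p in peaks:
        cols = [p.chrom, str(p.start), str(p.end)]
        if dialect in ("narrowPeak", "broadPeak"):
            cols += [p.name, _fmt(p.score), p.strand,
                     _fmt(p.signal_value), _fmt(p.p_value_log), _fmt(p.q_value_log)]
            if dialect == "narrowPeak":
                cols.append(str(p.summit_offset))
        else:
            cols += [p.name, _fmt(p.score), p.strand]
        handle.write("\t".join(cols) + "\n")


def _open_text(path) -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_dataset(
    path,
    dataset_id: str,
    tf_name: str,
    cell_line: str,
    species: str,
    dialect: str = "narrowPeak",
) -> PeakDataset:
    """Load one peak file with its experiment metadata (gzip accepted)."""
    with _open_text(path) as fh:
        peaks = parse_peaks(fh, dialect=dialect)
    if not peaks:
        logger.warning("dataset %s (%s): no peaks parsed from %s", dataset_id, tf_name, path)
    else:
        logger.info("dataset %s (%s, %s): %d peaks", dataset_id, tf_name, cell_line, len(peaks))
    return PeakDataset(
        dataset_id=dataset_id,
        tf_name=tf_name,
        cell_line=cell_line,
        species=species,
        peaks=peaks,
    )


_MANIFEST_COLS = ("path", "dataset_id", "tf", "cell_line", "species", "dialect")


def load_manifest(path) -> list[PeakDataset]:
    """Load every dataset listed in a manifest TSV.

    The manifest has a header line with columns ``path  dataset_id  tf
    cell_line  species  dialect``; relative paths are resolved against the
    manifest's directory.  Duplicate dataset IDs are an error.
    """
    base = os.path.dirname(os.path.abspath(str(path)))
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ManifestError(f"manifest {path} is empty")
    header = lines[0].split("\t")
    if tuple(header) != _MANIFEST_COLS:
        raise ManifestError(
            f"manifest header must be {list(_MANIFEST_COLS)}, got {header}"
        )
    datasets: list[PeakDataset] = []
    seen: set[str] = set()
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(_MANIFEST_COLS):
            raise ManifestError(f"manifest row has {len(fields)} columns: {ln!r}")
        rel, ds_id, tf, cell, species, dialect = fields
        if ds_id in seen:
            raise ManifestError(f"duplicate dataset_id {ds_id!r} in manifest")
        seen.add(ds_id)
        peak_path = rel if os.path.isabs(rel) else os.path.join(base, rel)
        datasets.append(load_dataset(peak_path, ds_id, tf, cell, species, dialect))
    return datasets


def normalize_chrom_names(dataset: PeakDataset, mode: str) -> PeakDataset:
    """Return a copy with ``chr``-prefix added or stripped on every peak.

    Off by default everywhere: chromosome matching is exact string equality,
    and silent renaming hides data errors.  ``mode`` is ``add-chr`` or
    ``strip-chr``.
    """
    if mode == "add-chr":
        def fix(c: str) -> str:
            return c if c.startswith("chr") else "chr" + c
    elif mode == "strip-chr":
        def fix(c: str) -> str:
            return c[3:] if c.startswith("chr") else c
    else:
        raise ValueError(f"mode must be 'add-chr' or 'strip-chr', got {mode!r}")
    new_peaks = [
        Peak(fix(p.chrom), p.start, p.end, p.name, p.score, p.strand,
             p.signal_value, p.p_value_log, p.q_value_log, p.summit_offset)
        for p in dataset.peaks
    ]
    return PeakDataset(dataset.dataset_id, dataset.tf_name, dataset.cell_line,
                       dataset.species, new_peaks)
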