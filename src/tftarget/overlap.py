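"""Peak-to-region targeting: which lncRNA features have >= 1 overlapping peak.

A feature is "targeted" by a dataset when at least one peak overlaps at
least one of its regulatory regions by >= 1 bp.  Overlap is on 0-based
half-open intervals: ``max(starts) < min(ends)``; an abutting peak (peak
start == region end) does not count.

Two query paths share one index:

* ``RegionIndex.query`` — per-interval lookups backed by an interval tree
  (used by the browse/retrieve layer and for small ad-hoc questions);
* ``targets_of`` — the bulk path, a sorted-array counting join: for each
  region, the number of peaks overlapping it is ``#(peak_start < region_end)
  − #(peak_end <= region_start)``, both computed with a binary search over
  the dataset's sorted peak endpoints.  The subtraction is exact because any
  peak ending at or before the region start necessarily also starts before
  the region end.  A feature is targeted iff any of its regions has a
  positive count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, TextIO

import numpy as np
from intervaltree import IntervalTree

from .annotations import RegulatoryRegion
from .peaks import PeakDataset

logger = logging.getLogger(__name__)

__all__ = ["RegionIndex", "TargetMap", "build_index", "targets_of",
           "build_target_map", "write_target_map"]


class _ChromRegions:
    """Regions of one chromosome as parallel arrays sorted by start."""

    __slots__ = ("starts", "ends", "feature_ids", "regions", "_tree")

    def __init__(self, regions: list[RegulatoryRegion]):
        regions = sorted(regions, key=lambda r: (r.start, r.end, r.feature_id))
        self.regions = regions
        self.starts = np.array([r.start for r in regions], dtype=np.int64)
        self.ends = np.array([r.end for r in regions], dtype=np.int64)
        self.feature_ids = [r.feature_id for r in regions]
        self._tree: Optional[IntervalTree] = None

    @property
    def tree(self) -> IntervalTree:
        if self._tree is None:
            self._tree = IntervalTree.from_tuples(
                (r.start, r.end, r) for r in self.regions
            )
        return self._tree


class RegionIndex:
    """Searchable per-chromosome index over regulatory regions."""

    def __init__(self, regions: Iterable[RegulatoryRegion]):
        by_chrom: dict[str, list[RegulatoryRegion]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        self._by_chrom = {c: _ChromRegions(rs) for c, rs in by_chrom.items()}

    @property
    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    @property
    def feature_ids(self) -> frozenset:
        return frozenset(
            fid for cr in self._by_chrom.values() for fid in cr.feature_ids
        )

    def __len__(self) -> int:
        return sum(len(cr.regions) for cr in self._by_chrom.values())

    def query(self, chrom: str, start: int, end: int) -> list[RegulatoryRegion]:
        """All regions with >= 1 bp overlap with ``[start, end)``, sorted."""
        cr = self._by_chrom.get(chrom)
        if cr is None:
            return []
        hits = [iv.data for iv in cr.tree.overlap(start, end)]
        hits.sort(key=lambda r: (r.start, r.end, r.feature_id))
        return hits


def build_index(regions: Iterable[RegulatoryRegion]) -> RegionIndex:
    """Build a :class:`RegionIndex` (thin constructor wrapper)."""
    return RegionIndex(regions)


def targets_of(dataset: PeakDataset, index: RegionIndex) -> frozenset:
    """Feature IDs with at least one peak of the dataset in a regulatory region."""
    starts_by_chrom: dict[str, list[int]] = {}
    ends_by_chrom: dict[str, list[int]] = {}
    unknown: set[str] = set()
    for p in dataset.peaks:
        if p.chrom not in index._by_chrom:
            unknown.add(p.chrom)
            continue
        starts_by_chrom.setdefault(p.chrom, []).append(p.start)
        ends_by_chrom.setdefault(p.chrom, []).append(p.end)
    if unknown:
        logger.info(
            "dataset %s: %d peak chromosome(s) absent from annotation (e.g. %s); ignored",
            dataset.dataset_id, len(unknown), sorted(unknown)[0],
        )
    hit: set = set()
    for chrom, starts in starts_by_chrom.items():
        cr = index._by_chrom[chrom]
        ps = np.sort(np.array(starts, dtype=np.int64))
        pe = np.sort(np.array(ends_by_chrom[chrom], dtype=np.int64))
        counts = (
            np.searchsorted(ps, cr.ends, side="left")
            - np.searchsorted(pe, cr.starts, side="right")
        )
        for i in np.nonzero(counts > 0)[0]:
            hit.add(cr.feature_ids[i])
    return frozenset(hit)


@dataclass(frozen=True)
class TargetMap:
    """Per-dataset targeted-feature sets plus the universe they were computed against."""

    targets: Mapping[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        for ds_id, fids in self.targets.items():
            extra = fids - self.universe
            if extra:
                raise ValueError(
                    f"dataset {ds_id}: {len(extra)} targeted features outside the universe"
                )

    @property
    def universe_size(self) -> int:
        return len(self.universe)


def build_target_map(
    datasets: Sequence[PeakDataset],
    regions: Sequence[RegulatoryRegion],
    universe: Optional[Iterable] = None,
) -> TargetMap:
    """Compute per-dataset targeted sets over one annotation universe.

    ``universe`` defaults to the feature IDs carried by ``regions`` (i.e.,
    all annotated features at the chosen level).
    """
    index = build_index(regions)
    if universe is None:
        universe_set = index.feature_ids
    else:
        universe_set = frozenset(universe)
    targets = {ds.dataset_id: targets_of(ds, index) for ds in datasets}
    return TargetMap(targets=targets, universe=universe_set)


def write_target_map(target_map: TargetMap, handle: TextIO) -> None:
    """Audit export: one ``dataset_id<TAB>feature_id`` row per targeting call."""
    handle.write("dataset_id\tfeature_id\n")
    for ds_id in sorted(target_map.targets):
        for fid in sorted(target_map.targets[ds_id]):
            handle.write(f"{ds_id}\t{fid}\n")
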