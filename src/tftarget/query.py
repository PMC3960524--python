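"""Browse/retrieve TF–lncRNA relationships from a computed TargetMap.

Both directions — lncRNAs targeted by a TF, and TFs targeting a lncRNA —
are answered from the same TargetMap the enrichment step uses, so the two
panels can never disagree.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .overlap import TargetMap
from .peaks import PeakDataset

logger = logging.getLogger(__name__)

__all__ = ["UnknownFeatureError", "lncrnas_targeted_by", "tfs_targeting"]


class UnknownFeatureError(KeyError):
    """Queried feature ID is not in the annotation universe."""


def _meta_map(datasets) -> Mapping[str, PeakDataset]:
    if isinstance(datasets, Mapping):
        return datasets
    return {ds.dataset_id: ds for ds in datasets}


def lncrnas_targeted_by(
    tf_name: str,
    target_map: TargetMap,
    datasets: Union[Sequence[PeakDataset], Mapping[str, PeakDataset]],
    cell_line: Optional[str] = None,
    feature_names: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """All (dataset, lncRNA) pairs where the TF has >= 1 peak in the window.

    Returns a DataFrame with columns ``dataset_id, cell_line, feature_id,
    feature_name``, sorted by dataset_id then feature_id.  An unknown TF
    yields an empty table with a warning rather than an error.
    """
    meta = _meta_map(datasets)
    matching = [
        ds for ds in meta.values()
        if ds.tf_name == tf_name and (cell_line is None or ds.cell_line == cell_line)
    ]
    if not any(ds.tf_name == tf_name for ds in meta.values()):
        logger.warning("TF %r not present in any loaded dataset", tf_name)
    names = feature_names or {}
    rows = [
        (ds.dataset_id, ds.cell_line, fid, names.get(fid, ""))
        for ds in matching
        for fid in target_map.targets.get(ds.dataset_id, frozenset())
    ]
    df = pd.DataFrame(rows, columns=["dataset_id", "cell_line", "feature_id", "feature_name"])
    return df.sort_values(["dataset_id", "feature_id"], ignore_index=True)


def tfs_targeting(
    feature_id: str,
    target_map: TargetMap,
    datasets: Union[Sequence[PeakDataset], Mapping[str, PeakDataset]],
    cell_line: Optional[str] = None,
) -> pd.DataFrame:
    """All datasets whose TF has >= 1 peak in the feature's regulatory window.

    Returns a DataFrame with columns ``tf, cell_line, dataset_id``, sorted.
    A feature absent from the annotation universe raises
    :class:`UnknownFeatureError`.
    """
    if feature_id not in target_map.universe:
        raise UnknownFeatureError(feature_id)
    meta = _meta_map(datasets)
    rows = []
    for ds_id, fids in target_map.targets.items():
        if feature_id not in fids:
            continue
        ds = meta.get(ds_id)
        if ds is None:
            continue
        if cell_line is not None and ds.cell_line != cell_line:
            continue
        rows.append((ds.tf_name, ds.cell_line, ds.dataset_id))
    df = pd.DataFrame(rows, columns=["tf", "cell_line", "dataset_id"])
    return df.sort_values(["tf", "cell_line", "dataset_id"], ignore_index=True)
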