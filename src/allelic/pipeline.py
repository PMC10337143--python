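"""Convenience pipeline: aggregate -> filter -> test-ready matrix.

The canonical order is: sum to the requested level, drop uninformative
(equal-split) features, then apply the minimum-count filter.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .aggregate import aggregate, filter_min_count, filter_uninformative
from .grouping import GroupMap
from .matrix import AllelicMatrix

__all__ = ["prepare", "aggregate_array"]


def prepare(
    m: AllelicMatrix,
    group_map: Optional[GroupMap] = None,
    min_count: float = 10,
    min_n: int = 3,
) -> tuple[AllelicMatrix, pd.DataFrame]:
    """Aggregate (if a map is given) and apply both pre-test filters.

    Returns the test-ready matrix and the combined filter report.
    """
    if group_map is not None:
        m = aggregate(m, group_map)
    m, rep1 = filter_uninformative(m)
    m, rep2 = filter_min_count(m, min_count=min_count, min_n=min_n)
    return m, pd.concat([rep1, rep2], ignore_index=True)


def aggregate_array(
    values: np.ndarray, feature_ids: list, group_map: GroupMap
) -> tuple[np.ndarray, list]:
    """Sum a (F, ...) array to group level; returns (array, group ids).

    Used to carry simulation truth counts to the aggregation level of an
    estimated matrix.
    """
    mapped = [(i, group_map.tx2group[f]) for i, f in enumerate(feature_ids)
              if f in group_map.tx2group]
    if not mapped:
        raise ValueError("no features in group map")
    group_ids = sorted({g for _, g in mapped})
    gindex = {g: i for i, g in enumerate(group_ids)}
    out = np.zeros((len(group_ids),) + values.shape[1:], dtype=float)
    src = np.array([i for i, _ in mapped])
    dst = np.array([gindex[g] for _, g in mapped])
    np.add.at(out, dst, values[src])
    return out, group_ids
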