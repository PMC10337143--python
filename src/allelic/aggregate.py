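"""Group-level aggregation of allelic estimates and pre-test filters.

Aggregation sums both the point estimates and every bootstrap replicate
across the member isoforms of a group, per sample and per allele, so the
aggregated matrix carries the group-level inferential uncertainty.

Two filters are applied before testing, in this order:

1. ``filter_uninformative`` — features whose two allelic point estimates are
   exactly equal in every sample carry no allelic information: when no read
   distinguishes the alleles the quantifier splits the total equally, so the
   estimated allelic fold change is identically 1.
2. ``filter_min_count`` — features without a minimum count of 10 in three or
   more allele-sample columns are removed.

No library-size scaling is performed anywhere: the tests compare the two
alleles *within* each sample, where sequencing depth affects both alleles
equally, so scaling is unnecessary and should be avoided.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .grouping import GroupMap
from .matrix import AllelicMatrix

__all__ = ["aggregate", "filter_uninformative", "filter_min_count"]


def aggregate(m: AllelicMatrix, g: GroupMap) -> AllelicMatrix:
    """Sum counts, TPM, and every bootstrap replicate to group level.

    Features absent from the map are dropped with a warning; an empty
    intersection raises.
    """
    mapped = [f for f in m.feature_ids if f in g.tx2group]
    if not mapped:
        raise ValueError("no features of the matrix appear in the group map")
    if len(mapped) < m.n_features:
        warnings.warn(
            f"{m.n_features - len(mapped)} features not in group map; dropped"
        )
    group_ids = sorted({g.tx2group[f] for f in mapped})
    gindex = {gid: i for i, gid in enumerate(group_ids)}
    src = np.array([i for i, f in enumerate(m.feature_ids) if f in g.tx2group])
    dst = np.array([gindex[g.tx2group[m.feature_ids[i]]] for i in src])

    G = len(group_ids)
    counts = np.zeros((G, m.n_samples, 2))
    np.add.at(counts, dst, m.counts[src])
    boots = np.zeros((m.n_bootstraps, G, m.n_samples, 2))
    np.add.at(boots, (slice(None), dst), m.bootstraps[:, src])
    tpm = None
    if m.tpm is not None:
        tpm = np.zeros((G, m.n_samples, 2))
        np.add.at(tpm, dst, m.tpm[src])
    return AllelicMatrix(
        feature_ids=group_ids,
        sample_ids=m.sample_ids,
        counts=counts,
        bootstraps=boots,
        tpm=tpm,
        allele_labels=m.allele_labels,
        level=g.level,
    )


def filter_uninformative(
    m: AllelicMatrix, tol: float = 1e-8
) -> tuple[AllelicMatrix, pd.DataFrame]:
    """Drop features with allelic fold change identically 1.

    A feature is uninformative when its a1 and a2 point estimates are equal
    (within ``tol``, to survive text round-trips) in *every* sample.
    Returns the filtered matrix and a report of dropped ids.
    """
    equal = np.abs(m.counts[..., 1] - m.counts[..., 0]) <= tol  # (F, S)
    drop = equal.all(axis=1)
    report = pd.DataFrame(
        {
            "feature": [f for f, d in zip(m.feature_ids, drop) if d],
            "reason": "uninformative",
        }
    )
    return m.select_features(~drop), report


def filter_min_count(
    m: AllelicMatrix,
    min_count: float = 10,
    min_n: int = 3,
    per_sample_total: bool = False,
) -> tuple[AllelicMatrix, pd.DataFrame]:
    """Keep features with >= ``min_n`` columns reaching ``min_count``.

    By default a column is one allele-sample point estimate (2*S columns per
    feature); with ``per_sample_total=True`` the per-sample allele totals
    (S columns) are used instead.
    """
    if min_count <= 0 or min_n < 1:
        raise ValueError("min_count must be > 0 and min_n >= 1")
    if per_sample_total:
        cols = m.counts.sum(axis=2)  # (F, S)
    else:
        cols = m.counts.reshape(m.n_features, -1)  # (F, 2S)
    keep = (cols >= min_count).sum(axis=1) >= min_n
    report = pd.DataFrame(
        {
            "feature": [f for f, k in zip(m.feature_ids, keep) if not k],
            "reason": "min_count",
        }
    )
    return m.select_features(keep), report
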