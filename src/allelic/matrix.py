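"""Core data model for allele-level quantifications with inferential replicates.

The central container is :class:`AllelicMatrix`: estimated read counts for
every feature (transcript, TSS group, or gene) in every sample, resolved to
the two alleles of a phased diploid sample, together with ``B`` bootstrap
replicate count arrays that carry the quantifier's inferential uncertainty
(multi-mapping across alleles and isoforms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["AllelicMatrix", "SampleMetadata"]

#: levels of aggregation a matrix can be at
LEVELS = ("txp", "tss", "gene")


@dataclass
class SampleMetadata:
    """Per-sample metadata: id, optional continuous covariate, optional group.

    The covariate (e.g. day of a time course) is required by the dynamic
    allelic-imbalance test; the two-level group factor by the differential
    test.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample" not in self.table.columns:
            raise ValueError("metadata table requires a 'sample' column")
        if self.table["sample"].duplicated().any():
            raise ValueError("duplicated sample ids in metadata")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_samples(
        cls,
        sample_ids: Sequence[str],
        covariate: Optional[Sequence[float]] = None,
        group: Optional[Sequence[str]] = None,
    ) -> "SampleMetadata":
        tab = pd.DataFrame({"sample": list(sample_ids)})
        if covariate is not None:
            tab["covariate"] = np.asarray(covariate, dtype=float)
        if group is not None:
            tab["group"] = list(group)
        return cls(tab)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample"].tolist()

    @property
    def covariate(self) -> Optional[np.ndarray]:
        if "covariate" not in self.table.columns:
            return None
        return self.table["covariate"].to_numpy(dtype=float)

    @property
    def group(self) -> Optional[np.ndarray]:
        if "group" not in self.table.columns:
            return None
        return self.table["group"].to_numpy()


@dataclass
class AllelicMatrix:
    """Paired allelic counts plus bootstrap replicates.

    Parameters
    ----------
    feature_ids : list of str
        Transcript / TSS-group / gene identifiers (base ids, without allele
        suffixes).
    sample_ids : list of str
    allele_labels : (str, str)
        Ordered pair; ``a1`` (index 0) is the maternal/reference allele,
        ``a2`` (index 1) the paternal/alternate allele.  Reported effects are
        signed a2 vs a1.
    counts : ndarray, shape (F, S, 2)
        Point estimates of read counts.
    bootstraps : ndarray, shape (B, F, S, 2)
        Bootstrap replicate counts, B >= 1.
    tpm : ndarray, shape (F, S, 2), optional
    level : {"txp", "tss", "gene"}
    """

    feature_ids: list
    sample_ids: list
    counts: np.ndarray
    bootstraps: np.ndarray
    allele_labels: tuple = ("a1", "a2")
    tpm: Optional[np.ndarray] = None
    level: str = "txp"
    lengths: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        self.counts = np.asarray(self.counts, dtype=float)
        self.bootstraps = np.asarray(self.bootstraps, dtype=float)
        self.allele_labels = tuple(self.allele_labels)
        self.validate()

    # -- shape helpers -----------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_bootstraps(self) -> int:
        return self.bootstraps.shape[0]

    def validate(self) -> None:
        F, S = self.n_features, self.n_samples
        if self.counts.shape != (F, S, 2):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({F}, {S}, 2)"
            )
        if self.bootstraps.ndim != 4 or self.bootstraps.shape[1:] != (F, S, 2):
            raise ValueError(
                f"bootstraps shape {self.bootstraps.shape} incompatible with "
                f"counts shape {self.counts.shape}"
            )
        if self.bootstraps.shape[0] < 1:
            raise ValueError("at least one bootstrap replicate required (B >= 1)")
        if len(self.allele_labels) != 2:
            raise ValueError("exactly two allele labels required")
        if (self.counts < 0).any() or (self.bootstraps < 0).any():
            raise ValueError("negative counts")
        if np.isnan(self.bootstraps).any() or np.isnan(self.counts).any():
            raise ValueError("NaN in counts or bootstraps")
        if self.tpm is not None:
            self.tpm = np.asarray(self.tpm, dtype=float)
            if self.tpm.shape != (F, S, 2):
                raise ValueError("tpm shape mismatch")
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")

    # -- basic manipulations ----------------------------------------------
    def select_features(self, index: np.ndarray) -> "AllelicMatrix":
        """Subset to features given by boolean mask or integer index."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            feature_ids=[self.feature_ids[i] for i in index],
            counts=self.counts[index],
            bootstraps=self.bootstraps[:, index],
            tpm=None if self.tpm is None else self.tpm[index],
            lengths=None if self.lengths is None else self.lengths[index],
        )

    def swap_alleles(self) -> "AllelicMatrix":
        """Exchange the a1/a2 labels (used for the antisymmetry property)."""
        return replace(
            self,
            counts=self.counts[..., ::-1].copy(),
            bootstraps=self.bootstraps[..., ::-1].copy(),
            tpm=None if self.tpm is None else self.tpm[..., ::-1].copy(),
            allele_labels=(self.allele_labels[1], self.allele_labels[0]),
        )

    def feature_index(self) -> dict:
        return {f: i for i, f in enumerate(self.feature_ids)}
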