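"""Readers and writers for allele-level quantification artifacts.

Formats handled here are deliberately plain text:

* per-sample quantification tables in the ``quant.sf`` dialect
  (``Name  Length  EffectiveLength  TPM  NumReads``) where every base
  transcript id appears twice, once per allele suffix (default ``_M`` /
  ``_P`` for maternal / paternal);
* bootstrap replicate matrices, one TSV per replicate per sample, rows in
  quant-table order;
* a sample metadata TSV (``sample``, optional ``covariate``, optional
  ``group``).
"""

from __future__ import annotations

import os
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import AllelicMatrix, SampleMetadata

__all__ = [
    "read_quant_table",
    "write_quant_table",
    "read_bootstraps",
    "write_bootstraps",
    "read_metadata",
    "assemble",
    "load_dataset",
]

QUANT_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]
DEFAULT_SUFFIXES = ("_M", "_P")


class QuantFormatError(ValueError):
    """Raised when a quantification table violates the expected layout."""


def _strip_suffix(name: str, suffixes: Sequence[str]) -> Optional[tuple]:
    for k, suf in enumerate(suffixes):
        if name.endswith(suf):
            return name[: -len(suf)], k
    return None


def read_quant_table(
    path, allele_suffixes: Sequence[str] = DEFAULT_SUFFIXES
) -> pd.DataFrame:
    """Read one sample's allelic quantification table and pair the alleles.

    Returns a frame with one row per base transcript id and columns
    ``feature, length, tpm_a1, tpm_a2, count_a1, count_a2``, preserving the
    order of first appearance.  Counts and TPM are carried through
    unmodified.

    Raises
    ------
    QuantFormatError
        If the header is not the quant.sf dialect, a suffix is unknown, or
        any transcript is missing its partner allele row (the orphan base
        ids are named in the message).
    """
    tab = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(tab.columns) != QUANT_COLUMNS:
        raise QuantFormatError(
            f"{path}: expected columns {QUANT_COLUMNS}, got {list(tab.columns)}"
        )
    a1_suf, a2_suf = allele_suffixes
    parsed = [_strip_suffix(n, allele_suffixes) for n in tab["Name"]]
    bad = [n for n, p in zip(tab["Name"], parsed) if p is None]
    if bad:
        raise QuantFormatError(
            f"{path}: ids without allele suffix {allele_suffixes}: {bad[:5]}"
        )
    tab = tab.assign(
        feature=[p[0] for p in parsed], _allele=[p[1] for p in parsed]
    )
    wide = tab.pivot_table(
        index="feature",
        columns="_allele",
        values=["Length", "TPM", "NumReads"],
        aggfunc="first",
        sort=False,
    )
    counts_per_feature = tab.groupby("feature", sort=False).size()
    orphans = counts_per_feature.index[counts_per_feature != 2].tolist()
    if orphans or wide.isna().any().any():
        missing = sorted(
            set(orphans)
            | set(wide.index[wide.isna().any(axis=1)].tolist())
        )
        raise QuantFormatError(
            f"{path}: features missing a partner allele row: {missing}"
        )
    order = tab["feature"].drop_duplicates().tolist()
    wide = wide.loc[order]
    out = pd.DataFrame(
        {
            "feature": order,
            "length": wide[("Length", 0)].to_numpy(),
            "tpm_a1": wide[("TPM", 0)].to_numpy(),
            "tpm_a2": wide[("TPM", 1)].to_numpy(),
            "count_a1": wide[("NumReads", 0)].to_numpy(),
            "count_a2": wide[("NumReads", 1)].to_numpy(),
        }
    )
    return out


def write_quant_table(
    path,
    feature_ids: Sequence[str],
    lengths: np.ndarray,
    tpm: np.ndarray,
    counts: np.ndarray,
    allele_suffixes: Sequence[str] = DEFAULT_SUFFIXES,
    effective_lengths: Optional[np.ndarray] = None,
) -> None:
    """Write a quant.sf-dialect table; ``tpm``/``counts`` have shape (F, 2)."""
    lengths = np.asarray(lengths)
    if effective_lengths is None:
        effective_lengths = lengths
    rows = []
    for k, suf in enumerate(allele_suffixes):
        rows.append(
            pd.DataFrame(
                {
                    "Name": [f + suf for f in feature_ids],
                    "Length": lengths,
                    "EffectiveLength": effective_lengths,
                    "TPM": tpm[:, k],
                    "NumReads": counts[:, k],
                    "_order": np.arange(len(feature_ids)),
                    "_allele": k,
                }
            )
        )
    # interleave alleles per feature, matching upstream quantifier layout
    out = (
        pd.concat(rows)
        .sort_values(["_order", "_allele"], kind="stable")
        .drop(columns=["_order", "_allele"])
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_bootstraps(
    paths: Sequence, allele_suffixes: Sequence[str] = DEFAULT_SUFFIXES
) -> tuple:
    """Read one sample's bootstrap replicate matrices.

    Each file is a two-column TSV (``Name``, ``NumReads``) with rows in the
    same allelic-transcript order as the quant table.  Returns
    ``(array of shape (B, F, 2), feature_ids)`` after pairing alleles.

    Raises
    ------
    ValueError
        On B == 0, on row-count/ordering mismatch between replicates, or on
        unpaired allele rows.
    """
    if len(paths) == 0:
        raise ValueError("no bootstrap replicate files given (B = 0)")
    reps = []
    names = None
    for p in paths:
        tab = pd.read_csv(p, sep="\t", float_precision="round_trip")
        if list(tab.columns) != ["Name", "NumReads"]:
            raise QuantFormatError(f"{p}: expected columns Name, NumReads")
        if names is None:
            names = tab["Name"].tolist()
        elif tab["Name"].tolist() != names:
            raise ValueError(
                f"{p}: replicate rows disagree with first replicate "
                f"({len(tab)} rows vs {len(names)})"
            )
        reps.append(tab["NumReads"].to_numpy(dtype=float))
    mat = np.stack(reps)  # (B, 2F)
    if np.isnan(mat).any():
        raise ValueError("NaN in bootstrap replicates")
    parsed = [_strip_suffix(n, allele_suffixes) for n in names]
    if any(p is None for p in parsed):
        raise ValueError("bootstrap row ids without allele suffix")
    feats: list[str] = []
    index: dict = {}
    for base, _ in parsed:
        if base not in index:
            index[base] = len(feats)
            feats.append(base)
    out = np.full((mat.shape[0], len(feats), 2), np.nan)
    for col, (base, k) in enumerate(parsed):
        out[:, index[base], k] = mat[:, col]
    if np.isnan(out).any():
        missing = [f for i, f in enumerate(feats) if np.isnan(out[0, i]).any()]
        raise ValueError(f"bootstrap features missing an allele: {missing}")
    return out, feats


def write_bootstraps(
    dirpath,
    feature_ids: Sequence[str],
    bootstraps: np.ndarray,
    allele_suffixes: Sequence[str] = DEFAULT_SUFFIXES,
) -> list:
    """Write (B, F, 2) bootstraps as one TSV per replicate; returns paths."""
    os.makedirs(dirpath, exist_ok=True)
    names = []
    for f in feature_ids:
        for suf in allele_suffixes:
            names.append(f + suf)
    paths = []
    for b in range(bootstraps.shape[0]):
        flat = bootstraps[b].reshape(-1)  # (F*2,) feature-major, allele minor
        p = os.path.join(dirpath, f"bootstrap_{b:03d}.tsv")
        pd.DataFrame({"Name": names, "NumReads": flat}).to_csv(
            p, sep="\t", index=False, float_format="%.17g"
        )
        paths.append(p)
    return paths


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t"))


def assemble(
    tables: Mapping[str, pd.DataFrame],
    bootstraps: Mapping[str, np.ndarray],
    metadata: SampleMetadata,
    allele_labels: Sequence[str] = ("M", "P"),
) -> AllelicMatrix:
    """Combine per-sample paired tables and bootstrap arrays into a matrix.

    Sample order follows the metadata table.  All samples must share one
    feature set; a mismatch raises with the offending set difference.
    """
    sample_ids = metadata.sample_ids
    missing = [s for s in sample_ids if s not in tables]
    if missing:
        raise ValueError(f"metadata samples without quant tables: {missing}")
    ref = tables[sample_ids[0]]["feature"].tolist()
    ref_set = set(ref)
    for s in sample_ids[1:]:
        cur = set(tables[s]["feature"])
        if cur != ref_set:
            raise ValueError(
                f"feature sets differ between samples {sample_ids[0]} and {s}: "
                f"only-first={sorted(ref_set - cur)[:5]} "
                f"only-other={sorted(cur - ref_set)[:5]}"
            )
    F, S = len(ref), len(sample_ids)
    counts = np.empty((F, S, 2))
    tpm = np.empty((F, S, 2))
    lengths = None
    B = None
    boots = None
    for j, s in enumerate(sample_ids):
        tab = tables[s].set_index("feature").loc[ref]
        counts[:, j, 0] = tab["count_a1"].to_numpy()
        counts[:, j, 1] = tab["count_a2"].to_numpy()
        tpm[:, j, 0] = tab["tpm_a1"].to_numpy()
        tpm[:, j, 1] = tab["tpm_a2"].to_numpy()
        if lengths is None:
            lengths = tab["length"].to_numpy(dtype=float)
        barr = np.asarray(bootstraps[s], dtype=float)
        if B is None:
            B = barr.shape[0]
            boots = np.empty((B, F, S, 2))
        if barr.shape != (B, F, 2):
            raise ValueError(
                f"sample {s}: bootstrap array shape {barr.shape} != ({B}, {F}, 2)"
            )
        boots[:, :, j, :] = barr
    return AllelicMatrix(
        feature_ids=ref,
        sample_ids=sample_ids,
        counts=counts,
        bootstraps=boots,
        tpm=tpm,
        allele_labels=tuple(allele_labels),
        level="txp",
        lengths=lengths,
    )


def load_dataset(
    root, allele_suffixes: Sequence[str] = DEFAULT_SUFFIXES
) -> tuple:
    """Load a dataset directory written by the simulator (or equivalent).

    Layout: ``<root>/metadata.tsv`` and, per sample id,
    ``<root>/samples/<id>/quant.sf`` plus
    ``<root>/samples/<id>/bootstraps/bootstrap_*.tsv``.

    Returns ``(AllelicMatrix, SampleMetadata)``.
    """
    meta = read_metadata(os.path.join(root, "metadata.tsv"))
    tables = {}
    boots = {}
    for s in meta.sample_ids:
        sdir = os.path.join(root, "samples", str(s))
        tables[s] = read_quant_table(
            os.path.join(sdir, "quant.sf"), allele_suffixes
        )
        bdir = os.path.join(sdir, "bootstraps")
        paths = sorted(
            os.path.join(bdir, f)
            for f in os.listdir(bdir)
            if f.startswith("bootstrap_")
        )
        arr, feats = read_bootstraps(paths, allele_suffixes)
        if feats != tables[s]["feature"].tolist():
            raise ValueError(f"sample {s}: bootstrap feature order != quant order")
        boots[s] = arr
    labels = tuple(s.lstrip("_") for s in allele_suffixes)
    return assemble(tables, boots, meta, allele_labels=labels), meta
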