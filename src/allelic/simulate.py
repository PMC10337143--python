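"""Count-level simulator of an F1-cross allelic RNA-seq benchmark.

The generator emulates a diploid two-allele experiment at the count level:
genes with 1-6 isoforms laid out on a synthetic chromosome, a subset of
genes carrying allelic imbalance (AI), Negative Binomial across-sample
variation, and an allele-ambiguity layer standing in for the read-level
multi-mapping uncertainty that a quantifier's bootstrap replicates capture.

AI design
---------
* AI-eligible genes have 3-6 isoforms, at least two isoforms sharing a TSS,
  and at least two distinct TSS.
* **Concordant AI**: the paternal allele of every isoform of the gene is
  scaled by 1.25 (25% up) or 0.75 (25% down), chosen at random per gene.
* **Discordant AI**: one TSS group of the gene is chosen at random and its
  ``n`` isoforms get paternal fold ``1 + 1/(2n)``; the remaining isoforms
  are scaled down by the unique common factor restoring gene-level allelic
  balance (the gene total is exactly equal between alleles).
* The maternal abundance of every transcript is a constant across samples,
  drawn log-uniformly.

Counts
------
Expected counts are proportional to abundance x transcript length, scaled
to the library size per sample; observed counts are Negative Binomial with
dispersion parameter ``size`` (variance mu + mu^2/size), independently per
transcript-allele-sample.

Quantification emulation
------------------------
A fraction ``rho`` of each transcript pair's reads is allelically
ambiguous.  By default (``em_apportion=True``) the emulated estimator
behaves like an EM quantifier: the pooled ambiguous reads ``m`` are
apportioned between the alleles at the ratio of the unambiguous evidence
(``q = u1/(u1+u2)``), which is unbiased; only when *no* read distinguishes
the alleles (``u1+u2 = 0``, e.g. ``rho = 1``) does the estimator split the
total exactly in half — reproducing the equal-split artifact that the
uninformative filter removes.

Bootstrap replicates emulate a *well-calibrated* quantifier bootstrap: a
parametric bootstrap of the estimator's two error sources, jointly for the
two alleles of a pair (every read belongs to exactly one transcript).
Each replicate redraws the allele of origin of the pooled ambiguous reads
(``x ~ Binomial(m, q)``) and re-estimates the apportionment ratio from a
resample of the unambiguous reads (``q* = Binomial(u1+u2, q)/(u1+u2)``),
giving replicate count ``u1 + m q + (m q* - x)``.  Its variance equals the
estimator's actual error variance ``rho/(1-rho) p(1-p) t`` to first order,
so the normal-approximation intervals built from the replicates are close
to nominal coverage by construction.  Replicate totals per transcript and
per sample equal the observed totals.

``em_apportion=False`` switches to a blind 50/50 split (point estimate
``u + m/2``, replicates Binomial(m, 1/2)); this estimator is shrunk toward
allelic balance, so its intervals under-cover at high expression.  With
``resample_totals=True`` replicates additionally resample every
transcript's total by multinomial resampling of the sample's reads, which
widens intervals beyond the estimator's actual error.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import io as aio
from .grouping import GroupMap, TranscriptAnnotation, make_tx2gene, make_tx2tss
from .matrix import AllelicMatrix, SampleMetadata

__all__ = [
    "SimDesign",
    "build_gene_models",
    "assign_abundances",
    "expected_counts",
    "sample_counts",
    "emulate_bootstraps",
    "simulate_dataset",
    "write_dataset",
    "SimulatedDataset",
]


@dataclass
class SimDesign:
    """Simulation parameters.

    Defaults follow the benchmark design this generator emulates: 14,821
    genes of which 1000 carry AI (500 concordant / 500 discordant), 10
    samples, NB dispersion size=100, 25% concordant perturbation, 30
    bootstrap replicates.  The library size defaults to a desk-scale 2M
    reads (the original read-level benchmark used 50M read pairs); the
    ``desk()`` profile scales the gene count down for fast runs.
    """

    n_genes: int = 14821
    n_concordant: int = 500
    n_discordant: int = 500
    n_samples: int = 10
    library_size: float = 2_000_000.0
    nb_size: float = 100.0
    concordant_effect: float = 0.25
    ambiguity: float = 0.2
    n_bootstraps: int = 30
    resample_totals: bool = False
    em_apportion: bool = True
    # synthetic annotation knobs
    tss_spacing: int = 200
    length_range: tuple = (500, 5000)
    abundance_range: tuple = (1.0, 100.0)

    def __post_init__(self):
        if self.n_concordant + self.n_discordant > self.n_genes:
            raise ValueError("more AI genes than genes")
        if not (0 <= self.ambiguity < 1):
            raise ValueError("ambiguity must be in [0, 1)")
        if self.n_bootstraps < 1:
            raise ValueError("B >= 1 required")

    @classmethod
    def desk(cls, **overrides) -> "SimDesign":
        """Desk-scale profile: 2,000 genes, 250/250 AI, 2M library."""
        kw = dict(n_genes=2000, n_concordant=250, n_discordant=250)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def paper_scale(cls, **overrides) -> "SimDesign":
        """Full-scale profile: 14,821 genes, 500/500 AI, 50M library."""
        kw = dict(library_size=50_000_000.0)
        kw.update(overrides)
        return cls(**kw)

    @property
    def n_ai_genes(self) -> int:
        return self.n_concordant + self.n_discordant


def _random_partition(rng, k: int, n_groups: int) -> np.ndarray:
    """Surjective assignment of k items to n_groups groups."""
    assign = np.concatenate(
        [np.arange(n_groups), rng.integers(0, n_groups, size=k - n_groups)]
    )
    return rng.permutation(assign)


def build_gene_models(design: SimDesign, rng) -> pd.DataFrame:
    """Synthetic transcript models: one row per transcript.

    Columns: tx_id, gene_id, chrom, strand, tss, length, ai_class
    (balanced / concordant / discordant).  AI-designated genes always have
    3-6 isoforms, >= 2 isoforms sharing a TSS, and >= 2 distinct TSS;
    background genes have 1-6 isoforms with arbitrary TSS structure.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = design.n_genes
    ai_idx = rng.choice(n, size=design.n_ai_genes, replace=False)
    ai_class = np.array(["balanced"] * n, dtype=object)
    conc = rng.choice(design.n_ai_genes, size=design.n_concordant, replace=False)
    mask = np.zeros(design.n_ai_genes, dtype=bool)
    mask[conc] = True
    ai_class[ai_idx[mask]] = "concordant"
    ai_class[ai_idx[~mask]] = "discordant"

    lo_len, hi_len = design.length_range
    rows = []
    for g in range(n):
        gene = f"G{g:05d}"
        is_ai = ai_class[g] != "balanced"
        if is_ai:
            k = int(rng.integers(3, 7))  # 3..6 isoforms
            n_tss = int(rng.integers(2, k))  # 2..k-1 -> some group has >= 2
        else:
            k = int(rng.integers(1, 7))  # 1..6 isoforms
            n_tss = int(rng.integers(1, k + 1))
        assign = _random_partition(rng, k, n_tss)
        strand = "+" if rng.random() < 0.5 else "-"
        origin = 10_000 + g * 50_000
        tss_pos = origin + np.arange(n_tss) * design.tss_spacing
        lengths = np.exp(
            rng.uniform(np.log(lo_len), np.log(hi_len), size=k)
        ).astype(int)
        for i in range(k):
            rows.append(
                (
                    f"{gene}.t{i + 1}",
                    gene,
                    "sim1",
                    strand,
                    int(tss_pos[assign[i]]),
                    int(lengths[i]),
                    ai_class[g],
                )
            )
    return pd.DataFrame(
        rows,
        columns=["tx_id", "gene_id", "chrom", "strand", "tss", "length", "ai_class"],
    )


def models_to_annotation(models: pd.DataFrame) -> list:
    return [
        TranscriptAnnotation(r.tx_id, r.gene_id, r.chrom, r.strand, int(r.tss))
        for r in models.itertuples()
    ]


def write_gtf(models: pd.DataFrame, path) -> None:
    """Emit the synthetic annotation as a single-exon-per-transcript GTF."""
    with open(path, "w") as fh:
        for r in models.itertuples():
            if r.strand == "+":
                start, end = r.tss, r.tss + r.length - 1
            else:
                start, end = r.tss - r.length + 1, r.tss
            attrs = f'gene_id "{r.gene_id}"; transcript_id "{r.tx_id}";'
            for feat in ("transcript", "exon"):
                fh.write(
                    f"{r.chrom}\tsim\t{feat}\t{start}\t{end}\t.\t{r.strand}\t.\t{attrs}\n"
                )


def assign_abundances(
    models: pd.DataFrame, design: SimDesign, rng
) -> pd.DataFrame:
    """Per-transcript truth table with maternal/paternal abundances.

    Maternal abundance is constant per transcript (log-uniform).  Paternal
    abundance encodes the AI design; for discordant genes the paternal gene
    total equals the maternal gene total exactly.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    truth = models.copy()
    lo, hi = design.abundance_range
    truth["maternal"] = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=len(truth))
    )
    tss_map = make_tx2tss(models_to_annotation(models), window=0)
    truth["tss_group"] = [tss_map.group_of(t) for t in truth["tx_id"]]
    fold = np.ones(len(truth))
    direction = np.zeros(len(truth), dtype=int)
    e = design.concordant_effect

    for gene, sub in truth.groupby("gene_id", sort=False):
        cls = sub["ai_class"].iloc[0]
        idx = sub.index.to_numpy()
        mat = sub["maternal"].to_numpy()
        if cls == "concordant":
            up = rng.random() < 0.5
            fold[idx] = 1 + e if up else 1 - e
            direction[idx] = 1 if up else -1
        elif cls == "discordant":
            groups = sub["tss_group"].to_numpy()
            uniq = pd.unique(groups)
            order = rng.permutation(len(uniq))
            chosen = None
            for j in order:
                sel = groups == uniq[j]
                n_sel = int(sel.sum())
                delta = mat[sel].sum() / (2 * n_sel)
                others = mat[~sel].sum()
                if others > delta:
                    chosen = (sel, n_sel, delta, others)
                    break
            if chosen is None:
                raise ValueError(
                    f"gene {gene}: no feasible TSS choice for discordant AI"
                )
            sel, n_sel, delta, others = chosen
            fold[idx[sel]] = 1 + 1.0 / (2 * n_sel)
            fold[idx[~sel]] = 1 - delta / others
            direction[idx[sel]] = 1
            direction[idx[~sel]] = -1
    truth["fold"] = fold
    truth["paternal"] = truth["maternal"] * fold
    truth["direction"] = direction
    truth["status"] = truth["ai_class"]
    return truth


def expected_counts(truth: pd.DataFrame, design: SimDesign) -> np.ndarray:
    """Expected count matrix mu, shape (F, 2): abundance x length, scaled
    so that the per-sample total over all transcript-alleles equals the
    library size."""
    w = np.stack(
        [
            truth["maternal"].to_numpy() * truth["length"].to_numpy(),
            truth["paternal"].to_numpy() * truth["length"].to_numpy(),
        ],
        axis=1,
    )
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total abundance")
    return w * (design.library_size / total)


def sample_counts(
    mu: np.ndarray, nb_size: float, n_samples: int, rng
) -> np.ndarray:
    """Observed counts ~ NB(mean mu, size), iid per transcript-allele-sample."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = nb_size / (nb_size + mu)  # (F, 2); mu = 0 -> p = 1 -> count 0
    return rng.negative_binomial(
        nb_size, p[:, None, :], size=(mu.shape[0], n_samples, 2)
    ).astype(float)


def _amb_ratio(u1: np.ndarray, u2: np.ndarray, em: bool) -> np.ndarray:
    """Apportionment ratio for pooled ambiguous reads (allele 1 share)."""
    if not em:
        return np.full(np.broadcast(u1, u2).shape, 0.5)
    tot = u1 + u2
    return np.divide(
        u1, tot, out=np.full(np.broadcast(u1, u2).shape, 0.5), where=tot > 0
    )


def emulate_bootstraps(
    counts: np.ndarray,
    rho: float,
    B: int,
    rng,
    resample_totals: bool = False,
    em_apportion: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Emulated quantifier output: point estimates and bootstrap replicates.

    Returns ``(point (F, S, 2), bootstraps (B, F, S, 2))``.  See module
    docstring for the mechanism.  With ``rho = 0`` and
    ``resample_totals=False`` every replicate equals the observed counts;
    with ``rho = 1`` point estimates are exactly equal-split.
    """
    if not (0 <= rho <= 1):
        raise ValueError("rho must be in [0, 1]")
    if B < 1:
        raise ValueError("B >= 1 required")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a = np.asarray(counts)
    if (a < 0).any():
        raise ValueError("negative counts")
    a = np.round(a).astype(np.int64)
    F, S, _ = a.shape
    amb = rng.binomial(a, rho)  # (F, S, 2) ambiguous reads per allele
    u = a - amb  # unambiguous, keep allele of origin
    m = amb.sum(axis=2)  # (F, S) pooled ambiguous per transcript pair
    q = _amb_ratio(u[..., 0], u[..., 1], em_apportion)  # (F, S)
    point = np.stack([u[..., 0] + m * q, u[..., 1] + m * (1 - q)], axis=-1)

    boots = np.empty((B, F, S, 2))
    if resample_totals:
        for s in range(S):
            vec = np.concatenate([u[:, s, 0], u[:, s, 1], m[:, s]])
            T = vec.sum()
            if T == 0:
                boots[:, :, s, :] = 0.0
                continue
            prob = vec / T
            for b in range(B):
                draw = rng.multinomial(T, prob)
                u1s, u2s, ms = draw[:F], draw[F : 2 * F], draw[2 * F :]
                qs = _amb_ratio(u1s, u2s, em_apportion)
                x = rng.binomial(ms, qs)
                boots[b, :, s, 0] = u1s + x
                boots[b, :, s, 1] = u2s + (ms - x)
    else:
        t = a.sum(axis=2)  # (F, S) pair totals, preserved per replicate
        x = rng.binomial(m[None, :, :], q[None, :, :], size=(B, F, S))
        if em_apportion:
            U = u.sum(axis=2)
            ustar = rng.binomial(U[None, :, :], q[None, :, :], size=(B, F, S))
            qstar = np.divide(
                ustar,
                U[None, :, :],
                out=np.broadcast_to(q[None, :, :], (B, F, S)).copy(),
                where=U[None, :, :] > 0,
            )
        else:
            qstar = np.broadcast_to(q[None, :, :], (B, F, S))
        a1b = point[None, :, :, 0] + (m[None, :, :] * qstar - x)
        a1b = np.clip(a1b, 0.0, t[None, :, :])
        boots[..., 0] = a1b
        boots[..., 1] = t[None, :, :] - a1b
    return point, boots


@dataclass
class SimulatedDataset:
    """Everything a benchmark run needs, in memory."""

    design: SimDesign
    models: pd.DataFrame
    truth: pd.DataFrame
    mu: np.ndarray  # (F, 2) expected counts
    true_counts: np.ndarray  # (F, S, 2) NB realizations
    matrix: AllelicMatrix  # estimated (txp level, point + bootstraps)
    metadata: SampleMetadata
    tss_map: GroupMap = field(repr=False)
    gene_map: GroupMap = field(repr=False)


def _tpm(point: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    rate = point / lengths[:, None, None]
    denom = rate.sum(axis=(0, 2), keepdims=True)
    return np.divide(rate * 1e6, denom, out=np.zeros_like(rate), where=denom > 0)


def simulate_dataset(design: SimDesign, seed: int) -> SimulatedDataset:
    """Run the full generator from a single seed."""
    rng = np.random.default_rng(seed)
    models = build_gene_models(design, rng)
    truth = assign_abundances(models, design, rng)
    mu = expected_counts(truth, design)
    true_counts = sample_counts(mu, design.nb_size, design.n_samples, rng)
    point, boots = emulate_bootstraps(
        true_counts,
        design.ambiguity,
        design.n_bootstraps,
        rng,
        resample_totals=design.resample_totals,
        em_apportion=design.em_apportion,
    )
    sample_ids = [f"s{j + 1:02d}" for j in range(design.n_samples)]
    meta = SampleMetadata.from_samples(
        sample_ids, covariate=np.arange(1, design.n_samples + 1, dtype=float)
    )
    lengths = truth["length"].to_numpy(dtype=float)
    matrix = AllelicMatrix(
        feature_ids=truth["tx_id"].tolist(),
        sample_ids=sample_ids,
        counts=point,
        bootstraps=boots,
        tpm=_tpm(point, lengths),
        allele_labels=("M", "P"),
        level="txp",
        lengths=lengths,
    )
    annot = models_to_annotation(models)
    return SimulatedDataset(
        design=design,
        models=models,
        truth=truth,
        mu=mu,
        true_counts=true_counts,
        matrix=matrix,
        metadata=meta,
        tss_map=make_tx2tss(annot, window=0),
        gene_map=make_tx2gene(annot),
    )


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write quant tables, bootstrap files, GTF, truth and metadata TSVs."""
    os.makedirs(outdir, exist_ok=True)
    ds.metadata.table.to_csv(
        os.path.join(outdir, "metadata.tsv"), sep="\t", index=False
    )
    ds.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    tc = ds.true_counts
    long = pd.DataFrame(
        {
            "feature": np.repeat(ds.truth["tx_id"].to_numpy(), tc.shape[1] * 2),
            "sample": np.tile(np.repeat(ds.metadata.sample_ids, 2), tc.shape[0]),
            "allele": np.tile([0, 1], tc.shape[0] * tc.shape[1]),
            "count": tc.reshape(-1),
        }
    )
    long.to_csv(os.path.join(outdir, "true_counts.tsv"), sep="\t", index=False)
    write_gtf(ds.models, os.path.join(outdir, "annotation.gtf"))
    m = ds.matrix
    for j, s in enumerate(m.sample_ids):
        sdir = os.path.join(outdir, "samples", s)
        os.makedirs(sdir, exist_ok=True)
        aio.write_quant_table(
            os.path.join(sdir, "quant.sf"),
            m.feature_ids,
            m.lengths,
            m.tpm[:, j, :],
            m.counts[:, j, :],
        )
        aio.write_bootstraps(
            os.path.join(sdir, "bootstraps"), m.feature_ids, m.bootstraps[:, :, j, :]
        )
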