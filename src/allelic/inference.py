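"""Nonparametric allelic-imbalance tests averaged over bootstrap replicates.

Three tests are provided, all sharing the same recipe: compute a
nonparametric per-feature statistic on each bootstrap replicate count
matrix, average it over replicates (so inferential uncertainty from
multi-mapping reads is propagated into the statistic), and calibrate it
against a permutation null in which the same label permutation is applied
to all features per draw.

* **Global AI** — Wilcoxon signed-rank statistic on the paired allelic
  counts within samples; the null swaps the two allele labels within
  randomly chosen samples (a sign flip of the paired differences).
* **Dynamic AI** — Pearson or Spearman correlation between the per-sample
  pseudocounted allelic log2 fold change and a continuous covariate; the
  null permutes the covariate across samples.
* **Differential AI** — Mann-Whitney rank-sum statistic comparing the
  per-sample allelic log2 fold changes between two groups; the null
  permutes the group labels.

All three exploit a linear-algebra identity: ranks (and standardized LFCs)
are invariant under the respective label permutation, so the permuted
statistic is an inner product of a precomputed bootstrap-averaged matrix
with the permuted label vector.  This makes the permutation null exact with
respect to the bootstrap averaging at negligible cost.

Sign convention: positive statistic / log2FC means the second (paternal /
alternate) allele is higher.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import AllelicMatrix, SampleMetadata
from .qvalue import qvalue_from_null

__all__ = [
    "TestConfig",
    "AIResults",
    "AllelicImbalance",
    "signed_rank_stat",
    "global_ai_test",
    "dynamic_ai_test",
    "differential_ai_test",
]


@dataclass
class TestConfig:
    """Settings shared by the allelic-imbalance tests.

    n_perm : number of label permutations pooled across features.
    pseudocount : constant added to both allelic counts before log fold
        change, stabilizing ratios at low counts (default 5).
    correlation : "pearson" or "spearman" for the dynamic test.
    seed : seed for the permutation RNG; results are bit-reproducible.
    n_bootstraps : use only the first ``n_bootstraps`` replicates
        (default: all).
    """

    __test__ = False  # not a pytest collectable despite the name

    n_perm: int = 100
    pseudocount: float = 5.0
    correlation: str = "pearson"
    seed: int = 0
    n_bootstraps: Optional[int] = None

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError("correlation must be 'pearson' or 'spearman'")


class AIResults:
    """Per-feature test results with a statsmodels-flavoured summary.

    Attributes
    ----------
    table : DataFrame with columns feature_id, level, stat, log2fc,
        pvalue, qvalue.
    """

    def __init__(
        self, table: pd.DataFrame, test: str, level: str, config: TestConfig
    ):
        self.table = table.reset_index(drop=True)
        self.test = test
        self.level = level
        self.config = config

    @property
    def feature_ids(self):
        return self.table["feature_id"].tolist()

    @property
    def stat(self) -> np.ndarray:
        return self.table["stat"].to_numpy()

    @property
    def log2fc(self) -> np.ndarray:
        return self.table["log2fc"].to_numpy()

    @property
    def pvalues(self) -> np.ndarray:
        return self.table["pvalue"].to_numpy()

    @property
    def qvalues(self) -> np.ndarray:
        return self.table["qvalue"].to_numpy()

    def significant(self, alpha: float = 0.05) -> list:
        """Feature ids with q-value below the nominal FDR cutoff."""
        return self.table.loc[
            self.table["qvalue"] < alpha, "feature_id"
        ].tolist()

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self, alpha: float = 0.05) -> str:
        t = self.table
        lines = [
            f"Allelic imbalance test: {self.test} ({self.level} level)",
            f"features tested: {len(t)}   permutations: {self.config.n_perm}"
            f"   pseudocount: {self.config.pseudocount:g}",
            f"significant at q < {alpha:g}: {(t['qvalue'] < alpha).sum()}",
            "",
            t.reindex(t["qvalue"].sort_values(kind="stable").index)
            .head(10)
            .to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<AIResults {self.test}/{self.level}: {len(self.table)} features>"
        )


# ---------------------------------------------------------------------------
# statistic primitives


def signed_rank_stat(x1: np.ndarray, x2: np.ndarray) -> float:
    """Wilcoxon signed-rank statistic W = sum sign(d_i) * rank(|d_i|).

    d = x2 - x1; zero differences are excluded from ranking; ties get
    midranks.  All-zero d gives 0.  Equivalent, up to an affine map, to the
    classical W+ (sum of positive ranks) when no zeros occur.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be 1-D of equal length")
    if x1.size < 2:
        raise ValueError("need at least 2 paired samples")
    return float(_signed_rank_matrix(x1[None, :], x2[None, :]).sum())


def _signed_rank_matrix(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Per-element signed ranks, rows = features: R[f, s] = sign*rank or 0."""
    d = X2 - X1
    absd = np.abs(d)
    absd[d == 0] = np.nan  # zeros excluded from ranking
    with np.errstate(invalid="ignore"):
        ranks = rankdata(absd, method="average", axis=1, nan_policy="omit")
    return np.where(d == 0, 0.0, np.sign(d) * np.nan_to_num(ranks))


def _lfc(X1: np.ndarray, X2: np.ndarray, c: float) -> np.ndarray:
    return np.log2((X2 + c) / (X1 + c))


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Row z-scores (population sd); constant rows map to all-zero."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    out = np.zeros_like(X)
    np.divide(X - mu, sd, out=out, where=sd > 0)
    return out


def _boot_iter(m: AllelicMatrix, cfg: TestConfig):
    B = m.n_bootstraps if cfg.n_bootstraps is None else min(
        cfg.n_bootstraps, m.n_bootstraps
    )
    for b in range(B):
        yield m.bootstraps[b, :, :, 0], m.bootstraps[b, :, :, 1]


def _mean_log2fc(m: AllelicMatrix, cfg: TestConfig) -> np.ndarray:
    """Mean over samples and bootstrap replicates of pseudocounted log2FC."""
    acc = np.zeros(m.n_features)
    nb = 0
    for x1, x2 in _boot_iter(m, cfg):
        acc += _lfc(x1, x2, cfg.pseudocount).mean(axis=1)
        nb += 1
    return acc / nb


# ---------------------------------------------------------------------------
# model / results surface


class AllelicImbalance:
    """Allelic-imbalance testing model over an :class:`AllelicMatrix`.

    Built from the (aggregated, filtered) matrix and optional sample
    metadata; ``fit_global``, ``fit_dynamic`` and ``fit_differential``
    return :class:`AIResults`.
    """

    def __init__(
        self,
        matrix: AllelicMatrix,
        metadata: Optional[SampleMetadata] = None,
    ):
        if matrix.n_features == 0:
            raise ValueError("no features left to test (all filtered?)")
        if metadata is not None and metadata.sample_ids != matrix.sample_ids:
            raise ValueError("metadata sample ids do not match matrix")
        self.matrix = matrix
        self.metadata = metadata

    # -- global AI ---------------------------------------------------------
    def fit_global(self, config: Optional[TestConfig] = None) -> AIResults:
        """Consistent allelic imbalance across all samples.

        Observed statistic: signed-rank W on (a1, a2) bootstrap counts,
        averaged over replicates.  Null: allele labels swapped within
        randomly chosen samples (one shared sign-flip vector per draw).
        """
        cfg = config or TestConfig()
        m = self.matrix
        S = m.n_samples
        if S < 2:
            raise ValueError("global AI test needs >= 2 samples")
        rbar = np.zeros((m.n_features, S))
        nb = 0
        for x1, x2 in _boot_iter(m, cfg):
            rbar += _signed_rank_matrix(x1, x2)
            nb += 1
        rbar /= nb
        obs = rbar.sum(axis=1)
        rng = np.random.default_rng(cfg.seed)
        flips = rng.choice([-1.0, 1.0], size=(S, cfg.n_perm))
        null = rbar @ flips  # (F, n_perm)
        return self._finish(obs, null, "global", cfg)

    # -- dynamic AI --------------------------------------------------------
    def fit_dynamic(
        self,
        covariate: Optional[np.ndarray] = None,
        config: Optional[TestConfig] = None,
    ) -> AIResults:
        """Change of allelic imbalance along a continuous covariate.

        Observed statistic: correlation (Pearson or Spearman) between the
        per-sample pseudocounted allelic log2FC and the covariate, averaged
        over bootstrap replicates.  Null: covariate permuted across samples.
        """
        cfg = config or TestConfig()
        cov = self._covariate(covariate)
        if np.unique(cov).size < 3:
            raise ValueError("covariate needs >= 3 distinct values")
        m = self.matrix
        S = m.n_samples
        spearman = cfg.correlation == "spearman"
        c = cov if not spearman else rankdata(cov)
        zc = (c - c.mean()) / c.std()
        zbar = np.zeros((m.n_features, S))
        nb = 0
        for x1, x2 in _boot_iter(m, cfg):
            lfc = _lfc(x1, x2, cfg.pseudocount)
            if spearman:
                lfc = rankdata(lfc, axis=1)
            zbar += _standardize_rows(lfc)
            nb += 1
        zbar /= nb
        obs = zbar @ zc / S
        rng = np.random.default_rng(cfg.seed)
        perms = np.stack(
            [rng.permutation(zc) for _ in range(cfg.n_perm)], axis=1
        )
        null = zbar @ perms / S
        return self._finish(obs, null, "dynamic", cfg)

    # -- differential AI ---------------------------------------------------
    def fit_differential(
        self,
        group: Optional[np.ndarray] = None,
        config: Optional[TestConfig] = None,
    ) -> AIResults:
        """Difference in allelic imbalance between two groups of samples.

        Observed statistic: centered Mann-Whitney rank sum of the per-sample
        log2FCs in the group whose label sorts second (so exchanging the
        two labels negates the statistic), averaged over bootstrap
        replicates.  Null: group labels permuted across samples.
        """
        cfg = config or TestConfig()
        grp = self._group(group)
        levels = np.unique(grp)  # sorted: sign convention is stable
        if len(levels) != 2:
            raise ValueError("group must have exactly two levels")
        ind2 = (grp == levels[1]).astype(float)
        n2 = ind2.sum()
        if n2 < 2 or (len(grp) - n2) < 2:
            raise ValueError("both groups need >= 2 samples")
        m = self.matrix
        S = m.n_samples
        rbar = np.zeros((m.n_features, S))
        nb = 0
        for x1, x2 in _boot_iter(m, cfg):
            rbar += rankdata(_lfc(x1, x2, cfg.pseudocount), axis=1)
            nb += 1
        rbar /= nb
        center = n2 * (S + 1) / 2.0
        obs = rbar @ ind2 - center
        rng = np.random.default_rng(cfg.seed)
        perms = np.stack(
            [rng.permutation(ind2) for _ in range(cfg.n_perm)], axis=1
        )
        null = rbar @ perms - center
        return self._finish(obs, null, "differential", cfg)

    # -- shared tail -------------------------------------------------------
    def _finish(
        self, obs: np.ndarray, null: np.ndarray, test: str, cfg: TestConfig
    ) -> AIResults:
        p, q = qvalue_from_null(obs, null)
        table = pd.DataFrame(
            {
                "feature_id": self.matrix.feature_ids,
                "level": self.matrix.level,
                "stat": obs,
                "log2fc": _mean_log2fc(self.matrix, cfg),
                "pvalue": p,
                "qvalue": q,
            }
        )
        return AIResults(table, test, self.matrix.level, cfg)

    def _covariate(self, covariate) -> np.ndarray:
        if covariate is None:
            if self.metadata is None or self.metadata.covariate is None:
                raise ValueError("dynamic test requires a covariate")
            covariate = self.metadata.covariate
        cov = np.asarray(covariate, dtype=float)
        if cov.size != self.matrix.n_samples:
            raise ValueError("covariate length != number of samples")
        if np.unique(cov).size == 1:
            raise ValueError("covariate is constant")
        return cov

    def _group(self, group) -> np.ndarray:
        if group is None:
            if self.metadata is None or self.metadata.group is None:
                raise ValueError("differential test requires a group factor")
            group = self.metadata.group
        grp = np.asarray(group)
        if grp.size != self.matrix.n_samples:
            raise ValueError("group length != number of samples")
        return grp


# ---------------------------------------------------------------------------
# functional wrappers


def global_ai_test(
    m: AllelicMatrix, config: Optional[TestConfig] = None
) -> AIResults:
    return AllelicImbalance(m).fit_global(config)


def dynamic_ai_test(
    m: AllelicMatrix, covariate: np.ndarray, config: Optional[TestConfig] = None
) -> AIResults:
    return AllelicImbalance(m).fit_dynamic(covariate, config)


def differential_ai_test(
    m: AllelicMatrix, group: np.ndarray, config: Optional[TestConfig] = None
) -> AIResults:
    return AllelicImbalance(m).fit_differential(group, config)
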