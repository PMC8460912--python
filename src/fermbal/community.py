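"""Count-table rarefaction and significance-masked Spearman correlations
between taxa abundances and process variables.

Rarefaction subsamples each sample without replacement to a common depth
(default: the smallest sample total), making compositions comparable.
Spearman's rho is the Pearson correlation of mid-ranks (tie-corrected);
p-values come from a seeded permutation test (10,000 permutations) for
small n and from the t approximation otherwise. Cells failing the
significance threshold keep their rho but are masked. Raw p < alpha is the
default masking rule; Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ValidationError

#: below this many paired observations, use the permutation p-value.
PERMUTATION_N = 12


def rarefy(table: pd.DataFrame, depth: int | None = None,
           seed: int = 0) -> pd.DataFrame:
    """Subsample every sample (row) to exactly ``depth`` counts without
    replacement (multivariate hypergeometric draw); seed-reproducible.

    ``depth`` defaults to the smallest sample total. Samples with fewer
    counts than ``depth`` are all reported in the error.
    """
    counts = table.to_numpy()
    if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
        raise InputError("count table must hold nonnegative integers")
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise InputError("every sample must have a positive total")
    if depth is None:
        depth = int(totals.min())
    short = [str(s) for s, tot in zip(table.index, totals) if tot < depth]
    if short:
        raise InputError(
            f"depth {depth} exceeds sample totals for: {short}")
    rng = np.random.default_rng(seed)
    out = np.vstack([rng.multivariate_hypergeometric(row, depth)
                     for row in counts])
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    totals = table.sum(axis=1).to_numpy()[:, None]
    return table / totals


def filter_abundant(rel: pd.DataFrame, threshold: float = 0.01
                    ) -> pd.DataFrame:
    """Keep taxa whose mean relative abundance reaches ``threshold``."""
    keep = rel.mean(axis=0) >= threshold
    return rel.loc[:, keep]


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected Spearman rho: Pearson correlation of mid-ranks.

    Returns NaN for a constant vector (undefined, not an error)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _p_permutation(rx: np.ndarray, ry: np.ndarray, rho: float,
                   n_perm: int, rng: np.random.Generator) -> float:
    sx = (rx - rx.mean()) / rx.std()
    sy = (ry - ry.mean()) / ry.std()
    n = len(rx)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    stat = (sx[perms] * sy).mean(axis=1)
    return float((np.sum(np.abs(stat) >= abs(rho) - 1e-12) + 1)
                 / (n_perm + 1))


def _p_t_approx(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass(frozen=True)
class CorrelationMatrix:
    """Square symmetric rho/p matrices over taxa + covariates with a
    significance mask (True = significant at alpha)."""
    rho: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame
    alpha: float


def spearman_matrix(abundances: pd.DataFrame, covariates: pd.DataFrame,
                    alpha: float = 0.01, n_perm: int = 10_000,
                    seed: int = 0, bh: bool = False) -> CorrelationMatrix:
    """Spearman matrix over [taxa | covariates] columns, masked at alpha.

    Rows of the two frames are aligned on their index (samples). Requires
    at least 4 paired observations. ``bh=True`` applies Benjamini-Hochberg
    across the upper triangle before masking.
    """
    if not (0.0 < alpha < 1.0):
        raise InputError("alpha must be in (0, 1)")
    joined = abundances.join(covariates, how="inner", validate="1:1")
    if len(joined) < 4:
        raise InputError(f"{len(joined)} paired observations; need >= 4")
    cols = list(joined.columns)
    X = joined.to_numpy(float)
    n, k = X.shape
    rng = np.random.default_rng(seed)

    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r = spearman_rho(X[:, i], X[:, j])
            rho[i, j] = rho[j, i] = r
            if np.isnan(r):
                p = float("nan")
            elif n < PERMUTATION_N:
                p = _p_permutation(stats.rankdata(X[:, i]),
                                   stats.rankdata(X[:, j]), r, n_perm, rng)
            else:
                p = _p_t_approx(r, n)
            pval[i, j] = pval[j, i] = p

    if bh:
        iu = np.triu_indices(k, 1)
        raw = pval[iu]
        finite = np.isfinite(raw)
        adj = raw.copy()
        if finite.any():
            adj[finite] = stats.false_discovery_control(raw[finite])
        pval[iu] = adj
        pval.T[iu] = adj

    mask = np.isfinite(pval) & (pval < alpha)
    np.fill_diagonal(mask, False)
    idx = pd.Index(cols)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(pval, index=idx, columns=idx),
        mask=pd.DataFrame(mask, index=idx, columns=idx),
        alpha=alpha)


def period_mean_covariates(meta: pd.DataFrame, columns: list[str]
                           ) -> pd.DataFrame:
    """Default pairing of time-resolved rates with community samples: each
    sample carries its period's mean value of the chosen variables."""
    missing = [c for c in columns if c not in meta.columns]
    if missing:
        raise ValidationError(f"covariates absent from meta: {missing}")
    return meta[columns].astype(float)
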