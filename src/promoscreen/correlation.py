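"""Seed-gene correlation screen.

Every expressed gene is Spearman-correlated with a designated seed gene
(e.g. IL17C or TCF4) across samples; the correlated gene set is then cut
from the ranked results by an explicit, recorded selection policy.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class ConstantVectorError(ValueError):
    """Correlation is undefined for a constant expression vector."""


@dataclass
class SelectionPolicy:
    """Conjunctive thresholds defining the correlated gene set.

    sign: 'positive' keeps rho > 0, 'negative' keeps rho < 0, 'absolute'
    keeps either sign (thresholds then apply to |rho|).
    """

    rho_min: float | None = 0.5
    fdr_max: float | None = 0.05
    top_n: int | None = None
    sign: str = "positive"

    def describe(self) -> str:
        parts = [f"sign={self.sign}"]
        if self.rho_min is not None:
            parts.append(f"rho_min={self.rho_min}")
        if self.fdr_max is not None:
            parts.append(f"fdr_max={self.fdr_max}")
        if self.top_n is not None:
            parts.append(f"top_n={self.top_n}")
        return ",".join(parts)


@dataclass
class CorrelatedGeneSet:
    seed_gene_id: str
    member_gene_ids: list[str]
    selection_rule: str = ""


def _spearman_p_t(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value via the t approximation (the scipy default)."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(rho) >= 1.0, 0.0, p)


def _spearman_p_exact(x_ranks: np.ndarray, y_ranks: np.ndarray, rho: float) -> float:
    """Exact permutation p (all n! permutations); only sensible for n < 10."""
    n = len(x_ranks)
    xc = x_ranks - x_ranks.mean()
    yc = y_ranks - y_ranks.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    count = total = 0
    for perm in itertools.permutations(range(n)):
        r = float(xc[list(perm)] @ yc) / denom
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return count / total


def spearman_screen(
    expr, seed_gene_id: str, exact_p: bool = False
) -> pd.DataFrame:
    """Spearman rho of every gene against the seed gene.

    Returns a DataFrame indexed by gene id (seed excluded) with columns
    rho, p_value, fdr, n_samples.  Ties receive average ranks; p-values
    use the t approximation unless exact_p (permutation, small n only).
    """
    values = expr if isinstance(expr, pd.DataFrame) else expr.values
    if seed_gene_id not in values.index:
        raise KeyError(f"seed gene {seed_gene_id!r} not in expression matrix")
    n = values.shape[1]
    if n < 5:
        raise ValueError("need at least 5 samples for the correlation screen")
    seed = values.loc[seed_gene_id].to_numpy(dtype=float)
    if np.ptp(seed) == 0:
        raise ConstantVectorError("seed gene expression is constant")
    others = values.drop(index=seed_gene_id)
    mat = others.to_numpy(dtype=float)

    seed_r = stats.rankdata(seed)
    mat_r = stats.rankdata(mat, axis=1)
    sc = seed_r - seed_r.mean()
    mc = mat_r - mat_r.mean(axis=1, keepdims=True)
    denom = np.sqrt((mc**2).sum(axis=1) * (sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (mc @ sc) / denom
    constant = np.ptp(mat_r, axis=1) == 0
    rho = np.where(constant, np.nan, rho)

    if exact_p:
        if n >= 10:
            raise ValueError("exact permutation p only supported for n < 10")
        p = np.array(
            [
                np.nan if constant[i] else _spearman_p_exact(mat_r[i], seed_r, rho[i])
                for i in range(len(rho))
            ]
        )
    else:
        p = np.where(constant, np.nan, _spearman_p_t(rho, n))

    fdr = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {"rho": rho, "p_value": p, "fdr": fdr, "n_samples": n}, index=others.index
    )


def select_correlated_set(
    results: pd.DataFrame,
    seed_gene_id: str,
    policy: SelectionPolicy | None = None,
) -> CorrelatedGeneSet:
    """Cut the correlated gene set from screen results under a policy.

    Members are ordered by descending rho, ties broken lexicographically
    by gene id.  The applied rule is recorded for provenance.
    """
    if results.empty:
        raise ValueError("empty correlation results")
    policy = policy or SelectionPolicy()
    df = results.dropna(subset=["rho"]).copy()

    if policy.sign == "positive":
        keep = df["rho"] > 0
        metric = df["rho"]
    elif policy.sign == "negative":
        keep = df["rho"] < 0
        metric = -df["rho"]
    elif policy.sign == "absolute":
        keep = pd.Series(True, index=df.index)
        metric = df["rho"].abs()
    else:
        raise ValueError(f"unknown sign policy {policy.sign!r}")
    if policy.rho_min is not None:
        keep &= metric >= policy.rho_min
    if policy.fdr_max is not None:
        keep &= df["fdr"] <= policy.fdr_max
    df = df.loc[keep]
    tmp = df.assign(_m=metric[keep], _gid=df.index)
    tmp = tmp.sort_values(by=["_m", "_gid"], ascending=[False, True])
    if policy.top_n is not None:
        tmp = tmp.head(policy.top_n)
    members = list(tmp.index)
    if not members:
        warnings.warn("selection policy produced an empty gene set", stacklevel=2)
    return CorrelatedGeneSet(
        seed_gene_id=seed_gene_id,
        member_gene_ids=members,
        selection_rule=policy.describe(),
    )


def pairwise_gene_correlation(
    expr, gene_a: str, gene_b: str, method: str = "spearman"
) -> tuple[float, float, int]:
    """Correlation between two genes across samples: (r, two-sided p, n)."""
    values = expr if isinstance(expr, pd.DataFrame) else expr.values
    for g in (gene_a, gene_b):
        if g not in values.index:
            raise KeyError(f"gene {g!r} not in expression matrix")
    x = values.loc[gene_a].to_numpy(dtype=float)
    y = values.loc[gene_b].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("constant expression vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), n
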