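"""Semiparametric logistic enrichment test for motifs.

For each motif, membership in the correlated gene set is modelled as

    logit P(member = 1) = b0 + b1 * motif_predictor + s(gc) + s(log length)

with penalized cubic-spline smooths for the two promoter-composition
covariates (GC fraction and window length), absorbing the compositional
confounding a naive 2x2 test would inherit.  The motif effect b1 is
tested with a likelihood-ratio test of the full model against the model
with the motif term dropped; p-values are Benjamini-Hochberg adjusted
within one window-size family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .motifs import MotifLibrary, filter_min_sites

PREDICTORS = ("count", "log1p_count", "presence")


@dataclass
class EnrichmentResult:
    motif_id: str
    name: str
    window_bp: int
    effect: float  # log-odds per unit of motif predictor
    p_value: float
    fdr: float
    n_member: int
    n_background: int
    passed_min_sites: bool
    flag: str = ""  # 'separation', 'constant_predictor', or ''


def _motif_predictor(counts: np.ndarray, predictor: str) -> np.ndarray:
    if predictor == "count":
        return counts.astype(float)
    if predictor == "log1p_count":
        return np.log1p(counts.astype(float))
    if predictor == "presence":
        return (counts >= 1).astype(float)
    raise ValueError(f"unknown predictor {predictor!r}; choose from {PREDICTORS}")


def _smooth_design(covariates: np.ndarray, basis_dim: int):
    """BSplines smoother over the non-degenerate covariate columns.

    Columns with (near-)zero spread carry no information and would make
    the basis singular; they are dropped.  Returns None when no column
    survives (the fit then reduces to ordinary logistic regression).
    """
    keep = [
        j
        for j in range(covariates.shape[1])
        if np.ptp(covariates[:, j]) > 1e-12
    ]
    if not keep:
        return None
    x = covariates[:, keep]
    return BSplines(x, df=[basis_dim] * len(keep), degree=[3] * len(keep))


def _fit_logistic(y, X, smoother, alpha):
    if smoother is None:
        model = sm.GLM(y, X, family=sm.families.Binomial())
        return model.fit(maxiter=200)
    model = GLMGam(
        y, exog=X, smoother=smoother,
        alpha=[alpha] * smoother.k_variables,
        family=sm.families.Binomial(),
    )
    return model.fit(maxiter=200)


def _ridge_fallback(y, X_full, X_red) -> tuple[float, float, str]:
    """Ridge-stabilised logistic refit on the linear part, used when the
    full fit is (quasi-)separated; the smooths are dropped so the LR test
    stays well defined.  Flagged 'separation'."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_full = sm.GLM(y, X_full, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-3, L1_wt=0.0
        )
        res_red = sm.GLM(y, X_red, family=sm.families.Binomial()).fit(maxiter=200)
        effect = float(res_full.params[1])
        eps = 1e-12
        mu = np.clip(
            sm.families.Binomial().link.inverse(X_full @ res_full.params), eps, 1 - eps
        )
        llf_full = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
        lr = 2.0 * (llf_full - float(res_red.llf))
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return effect, p, "separation"


def fit_enrichment(
    member: np.ndarray,
    motif_counts: np.ndarray,
    covariates: np.ndarray | None = None,
    predictor: str = "log1p_count",
    basis_dim: int = 5,
    alpha: float = 1.0,
) -> tuple[float, float, str]:
    """Effect (log-odds) and LR p-value of the motif term.

    member: binary vector over genes; motif_counts: per-gene occurrence
    counts; covariates: columns gc and length (either may be constant,
    in which case its smooth is dropped).  Returns (effect, p, flag).
    """
    y = np.asarray(member, dtype=float)
    if y.min() == y.max():
        raise ValueError("both membership classes must be non-empty")
    if len(y) < 20:
        raise ValueError("need at least 20 genes to fit the enrichment model")
    x = _motif_predictor(np.asarray(motif_counts), predictor)
    if np.ptp(x) == 0:
        return 0.0, 1.0, "constant_predictor"
    cov = np.empty((len(y), 0)) if covariates is None else np.asarray(covariates, float)
    smoother = _smooth_design(cov, basis_dim)
    X_full = np.column_stack([np.ones_like(y), x])
    X_red = X_full[:, :1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res_full = _fit_logistic(y, X_full, smoother, alpha)
            res_red = _fit_logistic(y, X_red, smoother, alpha)
            effect = float(res_full.params[1])
            lr = 2.0 * (float(res_full.llf) - float(res_red.llf))
            if not (np.isfinite(effect) and np.isfinite(lr)) or abs(effect) > 25:
                raise np.linalg.LinAlgError("separation")
        except (np.linalg.LinAlgError, ValueError, PerfectSeparationError):
            return _ridge_fallback(y, X_full, X_red)
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return effect, p, ""


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_motif_screen(
    counts: pd.DataFrame,
    membership: pd.Series,
    covariates: pd.DataFrame,
    library: MotifLibrary,
    seed_gene_id: str,
    window_bp: int,
    min_sites: int = 5,
    predictor: str = "log1p_count",
    basis_dim: int = 5,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Enrichment screen over a motif library for one window size.

    counts: gene x motif occurrence grid (must contain the seed gene row
    used by the min-sites filter); membership: binary Series over the
    genes to model (the seed itself is excluded from the fit);
    covariates: DataFrame with columns 'gc' and 'length'.  Results are
    BH-adjusted within this window family and sorted by p ascending,
    ties broken by |effect| descending then motif id.
    """
    genes = membership.index
    if not genes.isin(counts.index).all():
        raise ValueError("count grid and membership gene universes differ")
    surviving = filter_min_sites(counts, seed_gene_id, min_sites)
    model_genes = genes[genes != seed_gene_id]
    y = membership.loc[model_genes].to_numpy()
    cov = covariates.loc[model_genes, ["gc", "length"]].to_numpy(dtype=float)
    cov[:, 1] = np.log(cov[:, 1])
    rows = []
    if not surviving:
        warnings.warn("no motif passed the min-sites filter", stacklevel=2)
    for m in library:
        if m.motif_id not in surviving:
            continue
        effect, p, flag = fit_enrichment(
            y,
            counts.loc[model_genes, m.motif_id].to_numpy(),
            cov,
            predictor=predictor,
            basis_dim=basis_dim,
            alpha=alpha,
        )
        rows.append(
            {
                "motif_id": m.motif_id,
                "name": m.name,
                "window_bp": window_bp,
                "effect": effect,
                "p_value": p,
                "n_member": int(y.sum()),
                "n_background": int((1 - y).sum()),
                "passed_min_sites": True,
                "flag": flag,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "motif_id", "name", "window_bp", "effect", "p_value",
            "n_member", "n_background", "passed_min_sites", "flag",
        ],
    )
    if df.empty:
        df["fdr"] = pd.Series(dtype=float)
        return df
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    df = df.iloc[
        np.lexsort(
            (df["motif_id"].to_numpy(), -df["effect"].abs().to_numpy(),
             df["p_value"].to_numpy())
        )
    ].reset_index(drop=True)
    return df[
        ["motif_id", "name", "window_bp", "effect", "p_value", "fdr",
         "n_member", "n_background", "passed_min_sites", "flag"]
    ]
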