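"""Motif-based target-gene ranking.

For one motif, each gene is scored by the geometric mean of two
within-universe empirical quantiles: of its motif occurrence count and
of its seed-gene correlation.  Quantiles are strictly-below fractions,
so a gene with zero motif sites (when zero is the minimum) scores zero —
a rank-product-style rule that is invariant under monotone transforms of
either input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _strict_quantile(values: np.ndarray) -> np.ndarray:
    """Fraction of genes strictly below each value."""
    order = np.argsort(values, kind="mergesort")
    n = len(values)
    quant = np.empty(n, dtype=float)
    sorted_vals = values[order]
    # first index of each tie-group = number strictly below
    below = np.searchsorted(sorted_vals, sorted_vals, side="left")
    quant[order] = below / n
    return quant


def predict_targets(
    counts: pd.DataFrame,
    correlations: pd.DataFrame,
    motif_id: str,
    top_n: int = 12,
) -> pd.DataFrame:
    """Top-ranked predicted target genes for one motif.

    counts: gene x motif occurrence grid; correlations: screen results
    with a 'rho' column indexed by gene id.  Gene universes are aligned
    on their intersection.  Ties break by motif count (desc) then gene
    id (asc).
    """
    if motif_id not in counts.columns:
        raise KeyError(f"motif {motif_id!r} not in count grid")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    genes = counts.index.intersection(correlations.index)
    c = counts.loc[genes, motif_id].to_numpy(dtype=float)
    rho = correlations.loc[genes, "rho"].to_numpy(dtype=float)
    ok = ~np.isnan(rho)
    genes, c, rho = genes[ok], c[ok], rho[ok]
    qm = _strict_quantile(c)
    qc = _strict_quantile(rho)
    score = np.sqrt(qm * qc)
    order = np.lexsort((genes.to_numpy(), -c, -score))
    df = pd.DataFrame(
        {
            "gene_id": genes.to_numpy()[order],
            "motif_component": qm[order],
            "correlation_component": qc[order],
            "combined_score": score[order],
        }
    )
    df["rank"] = np.arange(1, len(df) + 1)
    df.insert(0, "motif_id", motif_id)
    return df.head(top_n).reset_index(drop=True)
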