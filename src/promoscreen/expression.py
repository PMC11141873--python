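"""Count-level expression quantification and the detection filter.

Raw gene-by-sample read counts are normalised to CPM (counts per million)
and FPKM (fragments per kilobase per million mapped reads).  A gene counts
as *detected* in a sample when its CPM exceeds a threshold and the lower
bound of an exact Poisson confidence interval on its FPKM is positive; a
gene is kept when it is detected in at least a given fraction of samples.
Downstream correlation screening works on log2-CPM intensities (the offset
log-CPM formula of the voom transform).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ZeroLibrarySizeError(ValueError):
    """A sample has a zero column sum and cannot be CPM-normalised."""


class MissingGeneLengthError(KeyError):
    """One or more genes lack a length, so FPKM is undefined for them."""


@dataclass
class CountMatrix:
    """Raw gene x sample read counts with per-gene lengths.

    counts is a pandas DataFrame indexed by gene id with sample-id columns;
    gene_length_bp is a Series aligned to (a superset of) the gene index.
    """

    counts: pd.DataFrame
    gene_length_bp: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def require_lengths(self) -> pd.Series:
        missing = self.counts.index.difference(self.gene_length_bp.index)
        if len(missing):
            raise MissingGeneLengthError(
                f"genes without a length: {sorted(missing)[:10]}"
                + (" ..." if len(missing) > 10 else "")
            )
        lengths = self.gene_length_bp.reindex(self.counts.index)
        if (lengths <= 0).any():
            bad = list(lengths.index[lengths <= 0][:10])
            raise ValueError(f"non-positive gene lengths: {bad}")
        return lengths


@dataclass
class DetectionFilterConfig:
    """Thresholds of the detection filter (CPM cut-off, sample fraction,
    confidence level of the FPKM interval)."""

    cpm_threshold: float = 0.25
    min_sample_fraction: float = 0.05
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.cpm_threshold <= 0:
            raise ValueError("cpm_threshold must be > 0")
        if not 0 < self.min_sample_fraction <= 1:
            raise ValueError("min_sample_fraction must be in (0, 1]")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class ExpressionMatrix:
    """log2-scale expression values with the transform recorded."""

    values: pd.DataFrame
    transform_tag: str = "log2cpm+0.5"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def compute_cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million; every column sums to 1e6."""
    lib = cm.library_sizes
    zero = lib.index[lib == 0]
    if len(zero):
        raise ZeroLibrarySizeError(f"samples with zero library size: {list(zero)}")
    return cm.counts / lib * 1e6


def compute_fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of gene per million mapped reads."""
    lengths = cm.require_lengths()
    lib = cm.library_sizes
    zero = lib.index[lib == 0]
    if len(zero):
        raise ZeroLibrarySizeError(f"samples with zero library size: {list(zero)}")
    denom = np.outer(lengths.to_numpy() / 1e3, lib.to_numpy() / 1e6)
    return pd.DataFrame(
        cm.counts.to_numpy() / denom, index=cm.counts.index, columns=cm.counts.columns
    )


def poisson_lower_bound(count, level: float = 0.95):
    """Lower bound of the exact (Garwood) Poisson CI on a count.

    chi2.ppf(alpha/2, 2k)/2 for k >= 1 and exactly 0 for k = 0.
    Vectorised over `count`.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    k = np.asarray(count, dtype=float)
    alpha = 1.0 - level
    with np.errstate(invalid="ignore"):
        lower = stats.chi2.ppf(alpha / 2.0, 2.0 * k) / 2.0
    return np.where(k > 0, lower, 0.0)


def fpkm_lower_ci(
    count, length_bp, library_size, level: float = 0.95
):
    """Lower confidence bound on FPKM: the exact Poisson bound on the raw
    count rescaled to FPKM units.  Zero iff the count is zero."""
    lower = poisson_lower_bound(count, level)
    denom = (np.asarray(length_bp, dtype=float) / 1e3) * (
        np.asarray(library_size, dtype=float) / 1e6
    )
    return lower / denom


@dataclass
class DetectionReport:
    """Per-gene qualifying-sample counts and the keep decision."""

    table: pd.DataFrame  # columns: n_qualifying, kept
    min_qualifying: int
    config: DetectionFilterConfig = field(default_factory=DetectionFilterConfig)


def detection_filter(
    cm: CountMatrix, cfg: DetectionFilterConfig | None = None
) -> tuple[CountMatrix, DetectionReport]:
    """Keep genes detected (CPM > threshold and FPKM lower CI > 0) in at
    least ceil(min_sample_fraction * n_samples) samples."""
    import math
    import warnings

    cfg = cfg or DetectionFilterConfig()
    cpm = compute_cpm(cm)
    lengths = cm.require_lengths()
    lib = cm.library_sizes
    lower = fpkm_lower_ci(
        cm.counts.to_numpy(),
        lengths.to_numpy()[:, None],
        lib.to_numpy()[None, :],
        cfg.ci_level,
    )
    qualifies = (cpm.to_numpy() > cfg.cpm_threshold) & (lower > 0)
    n_qual = qualifies.sum(axis=1)
    min_q = math.ceil(cfg.min_sample_fraction * cm.counts.shape[1])
    kept = n_qual >= min_q
    report = DetectionReport(
        table=pd.DataFrame(
            {"n_qualifying": n_qual, "kept": kept}, index=cm.counts.index
        ),
        min_qualifying=min_q,
        config=cfg,
    )
    if not kept.any():
        warnings.warn("detection filter removed every gene", stacklevel=2)
    filtered = CountMatrix(
        counts=cm.counts.loc[kept], gene_length_bp=cm.gene_length_bp
    )
    return filtered, report


def log_cpm_transform(cm: CountMatrix) -> ExpressionMatrix:
    """log2((count + 0.5) / (library_size + 1) * 1e6) — the offset log-CPM
    of the voom transform, without precision weights."""
    lib = cm.library_sizes
    zero = lib.index[lib == 0]
    if len(zero):
        raise ZeroLibrarySizeError(f"samples with zero library size: {list(zero)}")
    vals = np.log2((cm.counts + 0.5) / (lib + 1.0) * 1e6)
    return ExpressionMatrix(values=vals)


def qpcr_relative_expression(ct_housekeeping: float, ct_gene: float) -> float:
    """Relative qPCR expression, 2^CT(housekeeping) / 2^CT(gene of interest)."""
    if not (np.isfinite(ct_housekeeping) and np.isfinite(ct_gene)):
        raise ValueError("CT values must be finite")
    return float(2.0 ** (ct_housekeeping - ct_gene))


# ---------------------------------------------------------------------------
# TSV interfaces

def read_counts_tsv(path) -> pd.DataFrame:
    """Counts TSV: first column gene id, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df


def read_lengths_tsv(path) -> pd.Series:
    """Two-column TSV (gene id, length bp)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.iloc[:, 0]


def load_count_matrix(counts_path, lengths_path) -> CountMatrix:
    return CountMatrix(
        counts=read_counts_tsv(counts_path),
        gene_length_bp=read_lengths_tsv(lengths_path),
    )
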