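"""Self-contained synthetic data with the structure the screen assumes.

The generator emulates a bulk RNA-Seq cohort in which a latent regulator
activity drives a seed gene and a set of target genes (negative-binomial
counts, log-normal library sizes), together with a synthetic genome
whose target-gene promoters carry planted instances of one IUPAC motif
at an elevated Poisson rate.  Everything is reproducible byte-for-byte
from a single integer seed, and per-gene truth labels plus planted-site
positions are retained so recovery can be measured at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .motifs import (
    IUPAC_SETS,
    MotifConsensus,
    MotifLibrary,
    reverse_complement_consensus,
)
from .promoters import GeneAnnotation, reverse_complement

_DEFAULT_PLANTED = MotifConsensus(
    motif_id="PLANTED", name="planted E-box", consensus_strings=("CAGGTG", "CACCTG")
)


@dataclass
class SimulationConfig:
    """Conditions of the synthetic study.

    beta is the log-scale effect of the latent regulator activity on
    target-gene means (negative values emulate repression); the seed
    gene itself follows the activity with unit effect.  Plant rates are
    expected planted-motif occurrences per promoter, by class.
    """

    n_genes: int = 1000
    n_samples: int = 99
    n_targets: int = 150
    beta: float = 1.5
    seed_gene_beta: float = 1.0
    nb_dispersion: float = 0.2
    baseline_log2_mean_range: tuple[float, float] = (3.0, 9.0)
    library_size_sigma: float = 0.2
    promoter_len_bp: int = 2000
    planted_motif: MotifConsensus = field(default_factory=lambda: _DEFAULT_PLANTED)
    plant_rate_target: float = 3.0
    plant_rate_background: float = 1.0
    gc_background: float = 0.45
    gc_confounding: float = 0.0
    n_decoys: int = 29
    genes_per_contig: int = 50
    contig_gap_bp: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_targets < self.n_genes:
            raise ValueError("need 0 < n_targets < n_genes")
        if self.plant_rate_background < 0 or (
            self.plant_rate_target < self.plant_rate_background
        ):
            raise ValueError("need plant_rate_target >= plant_rate_background >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    count_matrix: CountMatrix
    latent_activity: np.ndarray
    genome: dict[str, str]
    annotations: list[GeneAnnotation]
    library: MotifLibrary
    truth: pd.DataFrame  # gene_id index; is_seed, is_target, gc
    planted_sites: pd.DataFrame  # gene_id, start (promoter-oriented, 1-based), length, strand

    @property
    def seed_gene_id(self) -> str:
        return str(self.truth.index[self.truth["is_seed"]][0])


def _gene_ids(n_genes: int) -> list[str]:
    # gene 0 is the seed; targets and background drawn from the rest
    return ["SEED"] + [f"G{i:04d}" for i in range(1, n_genes)]


def simulate_expression(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CountMatrix, np.ndarray, pd.DataFrame]:
    """Negative-binomial counts driven by a latent per-sample activity.

    Returns (CountMatrix, latent activity vector, truth frame with
    is_seed / is_target flags).
    """
    rng = rng or np.random.default_rng(cfg.rng_seed)
    genes = _gene_ids(cfg.n_genes)
    samples = [f"S{j:03d}" for j in range(cfg.n_samples)]

    activity = rng.standard_normal(cfg.n_samples)
    target_idx = rng.choice(
        np.arange(1, cfg.n_genes), size=cfg.n_targets, replace=False
    )
    is_target = np.zeros(cfg.n_genes, dtype=bool)
    is_target[target_idx] = True
    is_seed = np.zeros(cfg.n_genes, dtype=bool)
    is_seed[0] = True

    lo, hi = cfg.baseline_log2_mean_range
    base_mean = 2.0 ** rng.uniform(lo, hi, cfg.n_genes)
    beta_g = np.where(is_target, cfg.beta, 0.0)
    beta_g[0] = cfg.seed_gene_beta
    lib_factor = rng.lognormal(0.0, cfg.library_size_sigma, cfg.n_samples)

    mu = base_mean[:, None] * np.exp(beta_g[:, None] * activity[None, :])
    mu = mu * lib_factor[None, :]
    size = 1.0 / cfg.nb_dispersion
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)

    lengths = rng.integers(200, 10000, cfg.n_genes)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples),
        gene_length_bp=pd.Series(lengths, index=genes, name="length_bp"),
    )
    truth = pd.DataFrame(
        {"is_seed": is_seed, "is_target": is_target},
        index=pd.Index(genes, name="gene_id"),
    )
    return cm, activity, truth


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _realize_instance(rng: np.random.Generator, motif: MotifConsensus) -> tuple[str, str]:
    """One concrete planted instance: (sequence to insert, strand)."""
    cons = motif.consensus_strings[rng.integers(len(motif.consensus_strings))]
    bases = "".join(
        IUPAC_SETS[c][rng.integers(len(IUPAC_SETS[c]))] for c in cons.upper()
    )
    if rng.random() < 0.5:
        return reverse_complement(bases), "-"
    return bases, "+"


def random_decoy_library(
    rng: np.random.Generator, n_decoys: int, planted: MotifConsensus
) -> MotifLibrary:
    """Planted motif plus random IUPAC decoys, length 5-8 with at most
    two degenerate positions (matching literature-consensus degeneracy)."""
    degenerate = "RYSWKM"
    motifs = [planted]
    seen = {s for s in planted.consensus_strings}
    i = 0
    while len(motifs) < n_decoys + 1:
        L = int(rng.integers(5, 9))
        s = list("ACGT"[rng.integers(4)] for _ in range(L))
        n_deg = int(rng.integers(0, 3))
        for pos in rng.choice(L, size=min(n_deg, L), replace=False):
            s[pos] = degenerate[rng.integers(len(degenerate))]
        cons = "".join(s)
        if cons in seen or reverse_complement_consensus(cons) in seen:
            continue
        seen.add(cons)
        motifs.append(
            MotifConsensus(motif_id=f"D{i:02d}", name=f"decoy {i}", consensus_strings=(cons,))
        )
        i += 1
    return MotifLibrary(motifs=motifs, provenance="synthetic decoy library")


class PromoterTooShortError(ValueError):
    """Promoter window cannot accommodate a planted motif instance."""


def generate_promoters(
    cfg: SimulationConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[GeneAnnotation], pd.DataFrame]:
    """Synthetic genome with planted motif instances.

    Per gene a promoter-oriented sequence of promoter_len_bp + 1 bases
    (an upstream_bp = promoter_len_bp, downstream_bp = 0 window) is
    drawn i.i.d. at the class GC, planted with Poisson(rate) motif
    instances at non-overlapping uniform positions, and written onto a
    contig on alternating strands with fixed spacing.  Returns (genome,
    annotations, planted-site truth).
    """
    W = cfg.promoter_len_bp
    seq_len = W + 1
    max_cons = max(len(s) for s in cfg.planted_motif.consensus_strings)
    if seq_len < max_cons:
        raise PromoterTooShortError(
            f"promoter of {seq_len} bp cannot hold a {max_cons} bp instance"
        )
    genes = list(truth.index)
    annotations: list[GeneAnnotation] = []
    site_rows = []
    genome: dict[str, str] = {}
    contig_parts: list[np.ndarray] = []
    contig_pos = 0  # 0-based offset within current contig
    contig_idx = 0

    for i, gid in enumerate(genes):
        row = truth.loc[gid]
        targetish = bool(row["is_target"] or row["is_seed"])
        gc = cfg.gc_background + (cfg.gc_confounding if targetish else 0.0)
        gc = min(max(gc, 0.05), 0.95)
        rate = cfg.plant_rate_target if targetish else cfg.plant_rate_background
        seq = _random_sequence(rng, seq_len, gc)

        n_sites = int(rng.poisson(rate))
        occupied: list[tuple[int, int]] = []
        for _ in range(n_sites):
            inst, strand = _realize_instance(rng, cfg.planted_motif)
            L = len(inst)
            for _attempt in range(100):
                start0 = int(rng.integers(0, seq_len - L + 1))
                if all(start0 + L <= a or start0 >= b for a, b in occupied):
                    occupied.append((start0, start0 + L))
                    seq[start0 : start0 + L] = np.frombuffer(
                        inst.encode(), dtype=np.uint8
                    )
                    site_rows.append(
                        {"gene_id": gid, "start": start0 + 1, "length": L, "strand": strand}
                    )
                    break

        promoter = seq.tobytes().decode()
        gene_strand = "+" if i % 2 == 0 else "-"
        gap = _random_sequence(rng, cfg.contig_gap_bp, cfg.gc_background)
        contig_parts.append(gap)
        contig_pos += cfg.contig_gap_bp
        win_start0 = contig_pos  # 0-based start of the window on the contig
        if gene_strand == "+":
            contig_parts.append(seq)
            tss = win_start0 + seq_len  # 1-based: window [tss-W, tss]
        else:
            contig_parts.append(
                np.frombuffer(reverse_complement(promoter).encode(), dtype=np.uint8)
            )
            tss = win_start0 + 1  # 1-based: window [tss, tss+W]
        contig_pos += seq_len
        annotations.append(
            GeneAnnotation(
                gene_id=gid, chrom=f"ctg{contig_idx:03d}", strand=gene_strand, tss=tss
            )
        )
        if (i + 1) % cfg.genes_per_contig == 0 or i == len(genes) - 1:
            genome[f"ctg{contig_idx:03d}"] = (
                np.concatenate(contig_parts).tobytes().decode()
            )
            contig_parts = []
            contig_pos = 0
            contig_idx += 1

    planted = pd.DataFrame(
        site_rows, columns=["gene_id", "start", "length", "strand"]
    )
    return genome, annotations, planted


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Full dataset — expression, genome, annotation, library, truth —
    from one seed."""
    rng = np.random.default_rng(cfg.rng_seed)
    cm, activity, truth = simulate_expression(cfg, rng)
    genome, annotations, planted = generate_promoters(cfg, truth, rng)
    library = random_decoy_library(rng, cfg.n_decoys, cfg.planted_motif)
    return SyntheticDataset(
        config=cfg,
        count_matrix=cm,
        latent_activity=activity,
        genome=genome,
        annotations=annotations,
        library=library,
        truth=truth,
        planted_sites=planted,
    )


def evaluate_recovery(
    selected_members: list[str],
    truth: pd.DataFrame,
    enrichment: pd.DataFrame | None = None,
    planted_motif_id: str = "PLANTED",
) -> dict:
    """Precision/recall of the selected set against truth targets, plus
    rank and FDR of the planted motif in the enrichment table."""
    unknown = set(selected_members) - set(truth.index)
    if unknown:
        raise ValueError(f"selected genes outside the truth universe: {sorted(unknown)[:5]}")
    true_targets = set(truth.index[truth["is_target"]])
    sel = set(selected_members)
    tp = len(sel & true_targets)
    report = {
        "n_selected": len(sel),
        "n_true_targets": len(true_targets),
        "true_positives": tp,
        "precision": tp / len(sel) if sel else float("nan"),
        "recall": tp / len(true_targets) if true_targets else float("nan"),
        "planted_motif_rank": None,
        "planted_motif_fdr": None,
    }
    if enrichment is not None and not enrichment.empty:
        hits = enrichment.index[enrichment["motif_id"] == planted_motif_id]
        if len(hits):
            pos = int(hits[0])
            report["planted_motif_rank"] = pos + 1
            report["planted_motif_fdr"] = float(enrichment.loc[pos, "fdr"])
    return report


# ---------------------------------------------------------------------------
# On-disk fixture emission (standard formats consumed by the pipeline)

def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_dataset(ds: SyntheticDataset, outdir, force: bool = False) -> dict[str, str]:
    """Emit counts/lengths TSV, genome FASTA, TSS BED6, motif TSV and
    truth tables.  Refuses to overwrite unless force."""
    import os

    from .motifs import write_motif_library

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "counts": os.path.join(outdir, "counts.tsv"),
        "lengths": os.path.join(outdir, "lengths.tsv"),
        "genome": os.path.join(outdir, "genome.fa"),
        "annotation": os.path.join(outdir, "annotation.bed"),
        "motifs": os.path.join(outdir, "motifs.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "planted_sites": os.path.join(outdir, "planted_sites.tsv"),
    }
    if not force:
        existing = [p for p in paths.values() if os.path.exists(p)]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite {existing[0]} (pass force=True)"
            )
    ds.count_matrix.counts.to_csv(paths["counts"], sep="\t")
    ds.count_matrix.gene_length_bp.rename("length_bp").to_csv(paths["lengths"], sep="\t")
    write_fasta(ds.genome, paths["genome"])
    with open(paths["annotation"], "w") as fh:
        for a in ds.annotations:
            fh.write(f"{a.chrom}\t{a.tss - 1}\t{a.tss}\t{a.gene_id}\t0\t{a.strand}\n")
    write_motif_library(ds.library, paths["motifs"])
    ds.truth.astype(int).to_csv(paths["truth"], sep="\t")
    ds.planted_sites.to_csv(paths["planted_sites"], sep="\t", index=False)
    return paths
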