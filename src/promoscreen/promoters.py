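"""Strand-aware TSS-anchored promoter windows and sequence extraction.

Coordinates are 1-based inclusive throughout.  A window of `upstream_bp`
upstream and `downstream_bp` downstream of a TSS spans upstream_bp +
downstream_bp + 1 bases and always contains the TSS; on the minus strand
the window is the reflection of the plus-strand convention.  Extracted
sequences are promoter-oriented: position 1 is the most-distal upstream
base regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_BASES = frozenset("ACGTN")


class UnknownChromosomeError(KeyError):
    """Annotation refers to a contig absent from the genome."""


class InvalidBaseError(ValueError):
    """Sequence contains a character outside A/C/G/T/N."""


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    strand: str
    tss: int  # 1-based

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 1:
            raise ValueError("tss must be >= 1")


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    upstream_bp: int
    downstream_bp: int
    clipped: bool = False


def upstream_window(
    ann: GeneAnnotation,
    upstream_bp: int,
    downstream_bp: int = 0,
    contig_length: int | None = None,
) -> PromoterWindow:
    """TSS-anchored window: [tss - up, tss + down] on '+', mirrored on '-'.

    Clipped (flagged, not an error) at position 1 and, when
    contig_length is given, at the contig end.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("window extents must be non-negative")
    if ann.strand == "+":
        start = ann.tss - upstream_bp
        end = ann.tss + downstream_bp
    else:
        start = ann.tss - downstream_bp
        end = ann.tss + upstream_bp
    clipped = False
    if start < 1:
        start = 1
        clipped = True
    if contig_length is not None and end > contig_length:
        end = contig_length
        clipped = True
    return PromoterWindow(
        gene_id=ann.gene_id,
        chrom=ann.chrom,
        start=start,
        end=end,
        strand=ann.strand,
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
        clipped=clipped,
    )


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def extract_sequence(genome, window: PromoterWindow) -> str:
    """Promoter-oriented window sequence from an indexed FASTA.

    `genome` is any mapping of contig name to sequence supporting
    slicing (a pyfaidx.Fasta or a plain dict of strings).  Minus-strand
    windows are reverse-complemented so position 1 is most-distal
    upstream.
    """
    if window.chrom not in genome:
        raise UnknownChromosomeError(
            f"contig {window.chrom!r} not present in genome"
        )
    record = genome[window.chrom]
    seq = str(record[window.start - 1 : window.end]).upper()
    bad = next((i for i, b in enumerate(seq) if b not in VALID_BASES), None)
    if bad is not None:
        raise InvalidBaseError(
            f"invalid base {seq[bad]!r} at {window.chrom}:{window.start + bad}"
        )
    if window.strand == "-":
        seq = reverse_complement(seq)
    return seq


def gc_content(seq: str) -> tuple[float, bool]:
    """GC fraction over unambiguous bases; flag True when >50% of the
    sequence is N."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    n_n = seq.count("N")
    if n_n == len(seq):
        raise InvalidBaseError("all-N sequence has undefined GC content")
    acgt = len(seq) - n_n
    gc = (seq.count("G") + seq.count("C")) / acgt
    return gc, n_n > len(seq) / 2


# ---------------------------------------------------------------------------
# Annotation input: BED6 (0-based half-open) or GFF3 (1-based inclusive)

def read_annotation_bed6(path) -> list[GeneAnnotation]:
    """BED6 gene records; the TSS is chromStart (0-based) for '+' genes
    and chromEnd - 1 for '-' genes, converted to 1-based."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    out = []
    for row in df.itertuples(index=False):
        tss = row.start + 1 if row.strand == "+" else row.end
        out.append(
            GeneAnnotation(
                gene_id=row.name, chrom=row.chrom, strand=row.strand, tss=int(tss)
            )
        )
    return out


def read_annotation_gff3(path, feature: str = "gene", id_attr: str = "ID") -> list[GeneAnnotation]:
    """GFF3 records of the given feature type; TSS is `start` for '+'
    and `end` for '-' (both 1-based inclusive per the standard)."""
    cols = [
        "seqid", "source", "type", "start", "end",
        "score", "strand", "phase", "attributes",
    ]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    df = df[df["type"] == feature]
    out = []
    for row in df.itertuples(index=False):
        attrs = dict(
            kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
        )
        gid = attrs.get(id_attr, f"{row.seqid}:{row.start}")
        tss = row.start if row.strand == "+" else row.end
        out.append(
            GeneAnnotation(
                gene_id=gid, chrom=str(row.seqid), strand=row.strand, tss=int(tss)
            )
        )
    return out


def windows_to_bed(windows: list[PromoterWindow]) -> pd.DataFrame:
    """Export windows as a BED6 frame (0-based half-open)."""
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start - 1 for w in windows],
            "end": [w.end for w in windows],
            "name": [w.gene_id for w in windows],
            "score": 0,
            "strand": [w.strand for w in windows],
        }
    )
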