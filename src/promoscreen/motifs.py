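"""IUPAC consensus motif library and double-strand promoter scanning.

A motif is one or more IUPAC consensus strings (e.g. the E-box pair
CAGGTG/CACCTG).  Scanning slides every window of each consensus length
over the promoter-oriented sequence and tests the forward window against
each consensus and the reverse complement of the window against each
consensus (i.e. a minus-strand site).  Occurrences are collapsed per
(start, length) window across orientations and consensus variants, so a
palindromic or reverse-complement-paired consensus is never counted
twice for the same physical element.  An N in the sequence never
satisfies a non-N consensus code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# IUPAC degeneracy sets; bit encoding A=1 C=2 G=4 T=8, sequence N = 16
IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 16}
IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_SEQ_CODE = np.zeros(256, dtype=np.uint8)
for _b, _v in _BASE_BIT.items():
    _SEQ_CODE[ord(_b)] = _v
    _SEQ_CODE[ord(_b.lower())] = _v


def _consensus_mask(consensus: str) -> np.ndarray:
    """Per-position bitmask of acceptable sequence codes."""
    mask = np.empty(len(consensus), dtype=np.uint8)
    for i, c in enumerate(consensus.upper()):
        if c not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {c!r} in consensus {consensus!r}")
        bits = sum(_BASE_BIT[b] for b in IUPAC_SETS[c])
        if c == "N":
            bits |= _BASE_BIT["N"]  # only N matches everything, incl. seq N
        mask[i] = bits
    return mask


def reverse_complement_consensus(consensus: str) -> str:
    return consensus.translate(IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifConsensus:
    motif_id: str
    name: str
    consensus_strings: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.consensus_strings:
            raise ValueError("motif needs at least one consensus string")
        for s in self.consensus_strings:
            if not s:
                raise ValueError("empty consensus string")
            _consensus_mask(s)  # validates the alphabet


@dataclass
class MotifLibrary:
    motifs: list[MotifConsensus]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [m.motif_id for m in self.motifs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate motif ids in library")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def get(self, motif_id: str) -> MotifConsensus:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m
        raise KeyError(f"motif {motif_id!r} not in library")


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_id: str
    start: int  # 1-based in promoter-oriented sequence
    length: int
    strand_of_match: str  # '+', '-' or '+/-'
    matched_substring: str


def iupac_match(consensus: str, window: str) -> bool:
    """True iff each window base lies in the degeneracy set of the
    corresponding consensus code.  Sequence N matches only consensus N."""
    if len(consensus) != len(window):
        raise ValueError(
            f"length mismatch: consensus {len(consensus)}, window {len(window)}"
        )
    mask = _consensus_mask(consensus)
    codes = _SEQ_CODE[np.frombuffer(window.upper().encode(), dtype=np.uint8)]
    if (codes == 0).any():
        bad = window[int(np.argmax(codes == 0))]
        raise ValueError(f"invalid base {bad!r} in window")
    return bool(((codes & mask) != 0).all())


def encode_sequence(seq: str) -> np.ndarray:
    codes = _SEQ_CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if (codes == 0).any():
        pos = int(np.argmax(codes == 0))
        raise ValueError(f"invalid base {seq[pos]!r} at position {pos + 1}")
    return codes


def _match_positions(codes: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Boolean vector over window starts (0-based) for one consensus mask."""
    L = len(mask)
    n = len(codes)
    if n < L:
        return np.zeros(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    return ((win & mask) != 0).all(axis=1)


def scan_sequence(
    seq: str, motif: MotifConsensus, gene_id: str = ""
) -> list[MotifHit]:
    """All collapsed occurrences of a motif in a promoter-oriented
    sequence, double-strand, sorted by start."""
    codes = encode_sequence(seq)
    # (length, start) -> set of orientations observed
    by_window: dict[tuple[int, int], set[str]] = {}
    for cons in motif.consensus_strings:
        L = len(cons)
        for strand, pattern in (("+", cons), ("-", reverse_complement_consensus(cons))):
            hits = _match_positions(codes, _consensus_mask(pattern))
            for start0 in np.nonzero(hits)[0]:
                by_window.setdefault((L, int(start0)), set()).add(strand)
    out = []
    for (L, start0), strands in sorted(by_window.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        strand = "+/-" if len(strands) == 2 else next(iter(strands))
        out.append(
            MotifHit(
                gene_id=gene_id,
                motif_id=motif.motif_id,
                start=start0 + 1,
                length=L,
                strand_of_match=strand,
                matched_substring=seq[start0 : start0 + L].upper(),
            )
        )
    return out


def count_motif_sites(
    promoters: dict[str, str], library: MotifLibrary
) -> pd.DataFrame:
    """Gene x motif grid of collapsed occurrence counts.

    Sequences are encoded once per gene; per motif the union of forward
    and reverse-complement matches over all consensus variants is counted
    per (start, length) window.
    """
    gene_ids = list(promoters)
    counts = np.zeros((len(gene_ids), len(library)), dtype=np.int64)
    # deduplicate masks per motif: forward and revcomp variants may coincide
    motif_masks: list[list[np.ndarray]] = []
    for m in library:
        seen: dict[tuple, np.ndarray] = {}
        for cons in m.consensus_strings:
            for pattern in (cons, reverse_complement_consensus(cons)):
                mask = _consensus_mask(pattern)
                seen.setdefault(tuple(mask), mask)
        motif_masks.append(list(seen.values()))

    for gi, gid in enumerate(gene_ids):
        codes = encode_sequence(promoters[gid])
        for mi, masks in enumerate(motif_masks):
            union_by_len: dict[int, np.ndarray] = {}
            for mask in masks:
                L = len(mask)
                pos = _match_positions(codes, mask)
                if L in union_by_len:
                    union_by_len[L] |= pos
                else:
                    union_by_len[L] = pos.copy()
            counts[gi, mi] = sum(int(v.sum()) for v in union_by_len.values())
    return pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"),
        columns=[m.motif_id for m in library],
    )


def motif_presence(counts: pd.DataFrame) -> pd.DataFrame:
    return (counts >= 1).astype(int)


def filter_min_sites(
    counts: pd.DataFrame, seed_gene_id: str, min_sites: int = 5
) -> list[str]:
    """Motifs with at least `min_sites` occurrences in the seed gene's
    designated window."""
    if seed_gene_id not in counts.index:
        raise KeyError(f"seed gene {seed_gene_id!r} not in count grid")
    row = counts.loc[seed_gene_id]
    return list(row.index[row >= min_sites])


# ---------------------------------------------------------------------------
# Library TSV: motif_id <tab> name <tab> comma-separated consensus strings

def read_motif_library(path, provenance: str = "") -> MotifLibrary:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["motif_id", "name", "consensus"], dtype=str,
    )
    motifs = [
        MotifConsensus(
            motif_id=row.motif_id,
            name=row.name,
            consensus_strings=tuple(row.consensus.split(",")),
        )
        for row in df.itertuples(index=False)
    ]
    return MotifLibrary(motifs=motifs, provenance=provenance or str(path))


def write_motif_library(library: MotifLibrary, path) -> None:
    with open(path, "w") as fh:
        for m in library:
            fh.write(f"{m.motif_id}\t{m.name}\t{','.join(m.consensus_strings)}\n")


def demo_library() -> MotifLibrary:
    """A small literature-consensus demonstration library.

    Includes the E-box pair bound by TCF4 and the PRRX1/TCF12/FOXO1/NFIB
    consensi, plus common core promoter and bZIP/Rel elements.  This is a
    demonstration vocabulary, not the full binding-site collection a
    production screen would use.
    """
    entries = [
        ("TCF4", "TCF4 E-box", ("CAGGTG", "CACCTG")),
        ("PRRX1", "PRRX1 homeobox", ("TAATT",)),
        ("TCF12", "TCF12", ("TGTTTRCW",)),
        ("FOXO1", "FOXO1 forkhead", ("WTGTTTAC",)),
        ("NFIB", "NFIB", ("STTYGC",)),
        ("NFKB", "NF-kB (Rel)", ("GGGRNNYYCC",)),
        ("AP1", "AP-1 (TRE)", ("TGASTCA",)),
        ("CEBP", "C/EBP", ("TTGCGCAA",)),
        ("CREB", "CREB (CRE)", ("TGACGTCA",)),
        ("TATA", "TATA box", ("TATAWAW",)),
        ("CAAT", "CCAAT box", ("CCAAT",)),
        ("GC", "Sp1 GC box", ("GGGCGG",)),
        ("IRF", "IRF (ISRE core)", ("AANTGAAA",)),
        ("STAT", "STAT (GAS)", ("TTCNNNGAA",)),
        ("ETS", "ETS core", ("GGAW",)),
        ("RUNX", "RUNX", ("TGTGGT",)),
        ("MEF2", "MEF2", ("CTAWWWWTAG",)),
        ("SRF", "SRF (CArG)", ("CCWWWWWWGG",)),
        ("GATA", "GATA", ("WGATAR",)),
        ("HSF", "Heat-shock element", ("NGAANNTTCN",)),
    ]
    return MotifLibrary(
        motifs=[MotifConsensus(m, n, c) for m, n, c in entries],
        provenance="promoscreen demo library",
    )
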