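"""JASPAR PFM parsing, log-odds PWM scanning and target-gene prioritization.

Position frequency matrices are turned into log2-odds position weight
matrices with a pseudocount distributed according to the background
(p = (count + pc * bg) / (colsum + pc)), the convention of the common
R motif-scanning tools.  Promoter windows (TSS +/- flank) are scanned on
both strands and hits reported when the relative score
(score - min) / (max - min) reaches a threshold.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """A position weight matrix with its provenance counts.

    Rows are ordered A, C, G, T; ``log_odds`` is log2(p / background).
    """

    motif_id: str
    name: str
    counts: np.ndarray
    background: np.ndarray
    pseudocount: float
    log_odds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must have 4 rows (A, C, G, T)")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every PFM column must have positive total count")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if (self.background <= 0).any():
            raise ValueError("background probabilities must all be positive")
        colsum = self.counts.sum(axis=0)
        probs = (self.counts + self.pseudocount * self.background[:, None]) / (
            colsum[None, :] + self.pseudocount
        )
        self.log_odds = np.log2(probs / self.background[:, None])

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))

    def score(self, kmer: str) -> float:
        """Log-odds score of one sequence of motif length (A/C/G/T only)."""
        if len(kmer) != self.length:
            raise ValueError(f"need a {self.length}-mer, got {len(kmer)} bases")
        return float(sum(self.log_odds[_BASE_INDEX[b], j] for j, b in enumerate(kmer.upper())))

    def relative(self, score: float) -> float:
        span = self.max_score - self.min_score
        return (score - self.min_score) / span if span > 0 else 1.0


@dataclass
class MotifHit:
    sequence_id: str
    offset: int  # 1-based start of the motif-length window on the given sequence
    strand: str  # "+" or "-"
    score: float
    relative_score: float


@dataclass
class PromoterWindow:
    gene: str
    sequence: str
    chromosome: str
    start_bp: int  # 1-based inclusive genomic interval of origin
    end_bp: int
    strand: str
    clipped: bool = False


def parse_jaspar_pfm(text: str) -> tuple[str, str, np.ndarray]:
    """Parse one JASPAR-format PFM record into (motif_id, name, 4xL counts).

    Accepts bracketed (``A [ 10  0 ]``) or bare rows; rows may appear in
    any order when base-labelled, and are returned in canonical A,C,G,T
    order.
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty PFM record")
    motif_id, name = "", ""
    if lines[0].startswith(">"):
        head = lines[0][1:].split(None, 1)
        motif_id = head[0] if head else ""
        name = head[1] if len(head) > 1 else motif_id
        lines = lines[1:]
    if len(lines) != 4:
        raise ValueError(f"expected 4 base rows, got {len(lines)}")
    rows: dict[str, list[float]] = {}
    for ln in lines:
        label = None
        body = ln
        first = ln.split(None, 1)[0]
        if first.isalpha():
            if first.upper() not in _BASE_INDEX:
                raise ValueError(f"unknown base label {first!r}")
            label = first.upper()
            body = ln[len(first):]
        body = body.replace("[", " ").replace("]", " ")
        values = [float(tok) for tok in body.split()]
        if any(v < 0 for v in values):
            raise ValueError("PFM counts must be non-negative")
        if label is None:
            label = BASES[len(rows)]  # bare rows assumed in A,C,G,T order
        if label in rows:
            raise ValueError(f"duplicate base row {label!r}")
        rows[label] = values
    missing = set(BASES) - set(rows)
    if missing:
        raise ValueError(f"unknown or missing base labels; need A,C,G,T, missing {sorted(missing)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"PFM rows have unequal lengths: {sorted(lengths)}")
    counts = np.array([rows[b] for b in BASES], dtype=float)
    return motif_id, name, counts


def read_jaspar_pfm(path: str | os.PathLike) -> tuple[str, str, np.ndarray]:
    with open(path) as fh:
        return parse_jaspar_pfm(fh.read())


def build_log_odds(
    counts: np.ndarray,
    background: np.ndarray | None = None,
    pseudocount: float = 0.8,
    motif_id: str = "",
    name: str = "",
) -> PWM:
    """Construct a :class:`PWM` from a count matrix (uniform background default)."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    return PWM(motif_id=motif_id, name=name, counts=counts, background=bg, pseudocount=pseudocount)


def scan_sequence(
    pwm: PWM, window: PromoterWindow | str, min_relative_score: float = 0.8
) -> list[MotifHit]:
    """Score every offset of the window on both strands.

    Offsets are 1-based on the given sequence; windows containing ``N``
    are skipped.  Hits at or above ``min_relative_score`` are returned
    sorted by offset (forward strand first on ties).
    """
    if isinstance(window, PromoterWindow):
        seq_id, seq = window.gene, window.sequence
    else:
        seq_id, seq = "sequence", window
    seq = seq.upper()
    L = pwm.length
    n = len(seq) - L + 1
    if n <= 0:
        return []
    codes = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    valid = codes >= 0

    # per-offset scores via strided indexing of the log-odds matrix
    offsets = np.arange(n)[:, None] + np.arange(L)[None, :]
    window_codes = codes[offsets]
    window_ok = valid[offsets].all(axis=1)
    lo = pwm.log_odds
    safe = np.where(window_codes < 0, 0, window_codes)
    fwd = lo[safe, np.arange(L)[None, :]].sum(axis=1)
    # minus strand: score of the reverse complement == scanning with the
    # reverse-complemented matrix at the same offset
    rc = lo[::-1, ::-1]  # complement rows (A<->T, C<->G) and reverse columns
    rev = rc[safe, np.arange(L)[None, :]].sum(axis=1)

    hits: list[MotifHit] = []
    for i in range(n):
        if not window_ok[i]:
            continue
        for strand, s in (("+", fwd[i]), ("-", rev[i])):
            r = pwm.relative(float(s))
            if r >= min_relative_score:
                hits.append(MotifHit(seq_id, i + 1, strand, float(s), r))
    return hits


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sequence_id": h.sequence_id,
                "offset": h.offset,
                "strand": h.strand,
                "score": h.score,
                "relative_score": h.relative_score,
            }
            for h in hits
        ],
        columns=["sequence_id", "offset", "strand", "score", "relative_score"],
    )


def extract_promoter_windows(
    tss_table: pd.DataFrame, genome: str | os.PathLike | Fasta, flank: int = 500
) -> list[PromoterWindow]:
    """Cut TSS +/- flank windows from a genome FASTA.

    ``tss_table`` needs columns gene, chromosome, position_bp (1-based),
    strand.  Minus-strand windows are reverse-complemented; windows
    running off a contig end are clipped and flagged.
    """
    fa = genome if isinstance(genome, Fasta) else Fasta(os.fspath(genome))
    windows = []
    for _, row in tss_table.iterrows():
        chrom = str(row["chromosome"])
        if chrom not in fa:
            raise ValueError(f"TSS contig {chrom!r} absent from FASTA (gene {row['gene']!r})")
        contig_len = len(fa[chrom])
        tss = int(row["position_bp"])
        start = tss - flank
        end = tss + flank
        clipped = start < 1 or end > contig_len
        start = max(start, 1)
        end = min(end, contig_len)
        seq = fa[chrom][start - 1 : end].seq.upper()
        strand = str(row["strand"])
        if strand == "-":
            seq = reverse_complement(seq)
        windows.append(
            PromoterWindow(
                gene=str(row["gene"]),
                sequence=seq,
                chromosome=chrom,
                start_bp=start,
                end_bp=end,
                strand=strand,
                clipped=bool(clipped),
            )
        )
    return windows


def prioritize_targets(
    hits_by_gene: dict[str, list[MotifHit]],
    expression: pd.DataFrame,
    min_expression: float = 0.0,
) -> pd.DataFrame:
    """Rank candidate target genes by best motif score, requiring expression.

    ``expression`` is a gene x sample abundance table (genes as index);
    genes absent from it count as unexpressed.  Genes whose mean abundance
    falls below ``min_expression`` are excluded; survivors are ranked by
    best relative score (descending), ties by hit count then name.
    """
    rows = []
    for gene, hits in hits_by_gene.items():
        if not hits:
            continue
        mean_expr = float(expression.loc[gene].mean()) if gene in expression.index else 0.0
        if mean_expr < min_expression:
            continue
        rows.append(
            {
                "gene": gene,
                "best_relative_score": max(h.relative_score for h in hits),
                "n_hits": len(hits),
                "mean_expression": mean_expr,
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "best_relative_score", "n_hits", "mean_expression"])
    return df.sort_values(
        by=["best_relative_score", "n_hits", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
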