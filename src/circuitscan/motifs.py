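"""PWM representation, log-odds scanning and motif enrichment in peak regions.

Motifs are position weight matrices in a HOCOMOCO-style plain-text format
(one ``>motif_id`` header, then one whitespace-separated row of four counts or
frequencies per position, columns ordered A C G T).  Counts are converted to
probabilities after adding a per-cell pseudocount (default 0.8).

Scanning scores every window of a sequence (both strands; the reverse strand
scores the reverse complement) with the log2 odds of the PWM against an
i.i.d. background model, and calls a hit when the score reaches a threshold
defined as a quantile (default 0.9999) of the *exact* score distribution of
the PWM under the background, computed by dynamic programming over positions
(scores discretized to 1e-3).  Enrichment of a motif in target regions versus
background regions is a per-region binomial hit-rate test: the background
per-region hit probability is estimated from the background collection
(floored at 1/(2*n_bg)) and the p-value is the upper binomial tail of the
observed number of hit-bearing target regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

SCORE_DECIMALS = 3  # log-odds discretization used by both the DP and scanning

_ENCODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _ENCODE[base] = i
    _ENCODE[base + 32] = i  # lowercase

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


class InvalidSequenceError(ValueError):
    pass


@dataclass
class PWM:
    """A position weight matrix with per-position base probabilities (A,C,G,T)."""

    motif_id: str
    tf_symbol: str
    probs: np.ndarray  # (length, 4), rows sum to 1
    pseudocount: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: probs must be (L, 4)")
        if len(self) < 4:
            raise ValueError(f"{self.motif_id}: motif length must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: position probabilities must sum to 1")
        if not (self.probs > 0).all():
            raise ValueError(f"{self.motif_id}: probabilities must be > 0")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))


@dataclass
class BackgroundModel:
    """i.i.d. base frequencies over A, C, G, T."""

    freqs: np.ndarray
    source: str = "uniform"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,):
            raise ValueError("background needs 4 base frequencies")
        if not np.isclose(self.freqs.sum(), 1.0, atol=1e-9) or not (self.freqs > 0).all():
            raise ValueError("background frequencies must be positive and sum to 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25), source="uniform")

    @classmethod
    def from_sequences(cls, sequences: list[str], source: str = "region-estimated") -> "BackgroundModel":
        counts = np.zeros(4)
        for seq in sequences:
            codes = encode(seq)
            counts += np.bincount(codes[codes < 4], minlength=4)
        if counts.sum() == 0:
            return cls.uniform()
        freqs = (counts + 1.0) / (counts.sum() + 4.0)
        return cls(freqs, source=source)


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    tf_symbol: str
    target_hits: int
    target_n: int
    bg_rate: float
    p: float
    rank: int | None = None


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0, C=1, G=2, T=3, anything else=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_pwms(
    path: str | Path,
    mapping_path: str | Path | None = None,
    pseudocount: float = 0.8,
) -> list[PWM]:
    """Load HOCOMOCO-style count/frequency matrices; map motif ids to TF symbols.

    The pseudocount is added per cell before row normalization.  Motifs with
    no entry in the mapping TSV (columns: motif_id, tf_symbol) keep an empty
    tf_symbol.
    """
    mapping: dict[str, str] = {}
    if mapping_path is not None:
        with open(mapping_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if fields[0].lower() == "motif_id":
                    continue
                if len(fields) >= 2:
                    mapping[fields[0]] = fields[1]
    pwms: list[PWM] = []
    motif_id: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        if motif_id is None:
            return
        if not rows or any(len(r) != 4 for r in rows):
            raise ValueError(f"{motif_id}: ragged or non-4-column matrix rows")
        mat = np.asarray(rows, dtype=float)
        mat = mat + pseudocount
        probs = mat / mat.sum(axis=1, keepdims=True)
        pwms.append(PWM(motif_id, mapping.get(motif_id, ""), probs, pseudocount))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                rows = []
            else:
                try:
                    rows.append([float(x) for x in line.split()])
                except ValueError as exc:
                    raise ValueError(f"{motif_id}: bad matrix row {line!r}") from exc
    flush()
    return pwms


def log_odds_matrix(pwm: PWM, bg: BackgroundModel) -> np.ndarray:
    """Per-position log2(p/bg), discretized to SCORE_DECIMALS for exact DP."""
    return np.round(np.log2(pwm.probs / bg.freqs[None, :]), SCORE_DECIMALS)


def log_odds_score(pwm: PWM, bg: BackgroundModel, seq: str) -> float:
    """Sum over positions of log2(p_pos(base)/bg(base)); seq length must match."""
    codes = encode(seq)
    if codes.shape[0] != len(pwm):
        raise InvalidSequenceError(
            f"sequence length {codes.shape[0]} != motif length {len(pwm)}"
        )
    if (codes >= 4).any():
        raise InvalidSequenceError("sequence contains non-ACGT characters")
    lo = log_odds_matrix(pwm, bg)
    return float(lo[np.arange(len(pwm)), codes].sum())


def score_distribution(pwm: PWM, bg: BackgroundModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the log-odds score under the background model.

    Dynamic programming over independent positions: convolve the four-point
    score distribution of each position; scores are carried at SCORE_DECIMALS
    precision so the support stays small.  Returns (sorted scores, probs);
    probs sum to 1.
    """
    lo = log_odds_matrix(pwm, bg)
    scale = 10**SCORE_DECIMALS
    ints = np.round(lo * scale).astype(np.int64)
    dist: dict[int, float] = {0: 1.0}
    for pos in range(len(pwm)):
        nxt: dict[int, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = s + ints[pos, b]
                nxt[key] = nxt.get(key, 0.0) + p * bg.freqs[b]
        dist = nxt
    keys = np.array(sorted(dist), dtype=np.int64)
    probs = np.array([dist[k] for k in keys])
    return keys / scale, probs


def score_threshold(
    pwm: PWM, bg: BackgroundModel, quantile: float = 0.9999
) -> float:
    """Smallest score s with P(score <= s) >= quantile under the background."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    scores, probs = score_distribution(pwm, bg)
    cum = np.cumsum(probs)
    idx = int(np.searchsorted(cum, quantile, side="left"))
    idx = min(idx, len(scores) - 1)
    return float(scores[idx])


def _window_scores(lo: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Scores of all windows of len(lo) over encoded sequence; NaN where N."""
    L = lo.shape[0]
    n_win = codes.shape[0] - L + 1
    if n_win <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (win < 4).all(axis=1)
    safe = np.where(win < 4, win, 0)
    scores = lo[np.arange(L)[None, :], safe].sum(axis=1)
    scores[~valid] = -np.inf
    return scores


def scan_sequence(
    pwm: PWM, bg: BackgroundModel, seq: str, threshold: float
) -> int:
    """Number of windows (both strands) scoring >= threshold; N windows skipped."""
    codes = encode(seq)
    if codes.shape[0] < len(pwm):
        return 0
    lo = log_odds_matrix(pwm, bg)
    # reverse strand: scoring the reverse complement of each window equals
    # scoring the forward window with the reversed, complement-permuted matrix
    lo_rc = lo[::-1, ::-1]
    eps = 10.0 ** (-SCORE_DECIMALS) / 2
    fwd = _window_scores(lo, codes)
    rev = _window_scores(lo_rc, codes)
    return int((fwd >= threshold - eps).sum() + (rev >= threshold - eps).sum())


def scan_regions(
    pwm: PWM,
    bg: BackgroundModel,
    sequences: list[str],
    threshold_quantile: float = 0.9999,
) -> np.ndarray:
    """Per-region hit counts at the exact background quantile threshold."""
    thr = score_threshold(pwm, bg, threshold_quantile)
    return np.array([scan_sequence(pwm, bg, s, thr) for s in sequences], dtype=int)


def motif_enrichment(
    pwm: PWM,
    bg: BackgroundModel,
    target_seqs: list[str],
    background_seqs: list[str],
    threshold_quantile: float = 0.9999,
) -> MotifEnrichmentResult:
    """Binomial upper-tail test of the per-region hit rate, target vs background."""
    if not target_seqs or not background_seqs:
        raise ValueError("motif_enrichment requires non-empty target and background")
    thr = score_threshold(pwm, bg, threshold_quantile)
    t_hits = sum(1 for s in target_seqs if scan_sequence(pwm, bg, s, thr) > 0)
    b_hits = sum(1 for s in background_seqs if scan_sequence(pwm, bg, s, thr) > 0)
    n_bg = len(background_seqs)
    bg_rate = max(b_hits / n_bg, 1.0 / (2 * n_bg))
    n = len(target_seqs)
    p = float(stats.binom.sf(t_hits - 1, n, bg_rate))  # P(X >= t_hits)
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return MotifEnrichmentResult(pwm.motif_id, pwm.tf_symbol, t_hits, n, bg_rate, p)


def rank_motifs(
    results: list[MotifEnrichmentResult], k: int = 20
) -> list[MotifEnrichmentResult]:
    """Top-k by ascending p; ties by descending hits then motif_id; ranks 1..k."""
    if not results:
        raise ValueError("rank_motifs requires >=1 result")
    ordered = sorted(results, key=lambda r: (r.p, -r.target_hits, r.motif_id))[:k]
    out = []
    for i, r in enumerate(ordered, start=1):
        out.append(
            MotifEnrichmentResult(
                r.motif_id, r.tf_symbol, r.target_hits, r.target_n, r.bg_rate, r.p, i
            )
        )
    return out


# ---------------------------------------------------------------------------
# Genome sequence access


def extract_sequences(fasta_path: str | Path, regions) -> list[str]:
    """Upper-case sequences for a RegionSet from an (indexed) FASTA file."""
    from pyfaidx import Fasta

    genome = Fasta(str(fasta_path), sequence_always_upper=True)
    out = []
    for iv in regions:
        out.append(str(genome[iv.chrom][iv.start : iv.end]))
    return out


def shuffle_regions(
    regions,
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
    avoid=None,
    max_tries: int = 100,
):
    """Relocate each region to a random position of matched length.

    Placements overlapping ``avoid`` (e.g. the original target set) are
    rejected and redrawn, giving the length-matched background set used for
    motif enrichment.
    """
    from circuitscan.intervals import GenomicInterval, RegionSet

    chroms = sorted(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    placed: list[GenomicInterval] = []
    for iv in regions:
        width = len(iv)
        for _ in range(max_tries):
            c = chroms[int(rng.choice(len(chroms), p=weights))]
            if chrom_sizes[c] <= width:
                continue
            start = int(rng.integers(0, chrom_sizes[c] - width))
            if avoid is not None and avoid.overlaps_interval(c, start, start + width):
                continue
            placed.append(GenomicInterval(c, start, start + width))
            break
        else:
            raise RuntimeError("could not place shuffled region; genome too crowded")
    return RegionSet(f"{regions.regulator}_shuffled", placed)
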