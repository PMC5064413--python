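"""Peak-to-gene assignment and hypergeometric pathway enrichment.

Peaks are assigned to genes by a window-then-nearest-TSS rule: a peak goes to
the gene whose regulatory window (10 kb upstream through gene end) contains
the peak midpoint, breaking ties by nearest TSS; peaks outside every window
fall back to the nearest TSS within 50 kb; anything further is unassigned.

Pathway enrichment of the assigned gene set against a GMT collection uses the
one-sided (upper-tail) hypergeometric test — equivalent to Fisher's exact
test for enrichment — with Benjamini–Hochberg adjustment across pathways and
significance tiers at raw p < 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from circuitscan.circuitry import regulatory_window
from circuitscan.intervals import GeneModel, GenomicInterval, RegionSet


@dataclass
class PeakGeneAssignment:
    peak: GenomicInterval
    gene_id: str
    rule: str  # "window" or "nearest"
    distance: int  # bp from peak midpoint to the gene's TSS


@dataclass
class PathwayEnrichment:
    pathway_id: str
    description: str
    N: int  # universe size
    K: int  # pathway genes in universe
    n: int  # target genes
    k: int  # overlap
    p: float  # hypergeometric upper tail
    q: float  # BH-adjusted
    stars: str  # "", "*", "**", "***" at raw p 0.05/0.01/0.001


def assign_peaks_to_genes(
    peaks: RegionSet,
    genes: list[GeneModel],
    upstream: int = 10000,
    max_distance: int = 50000,
) -> list[PeakGeneAssignment]:
    """Assign each peak to at most one gene (window, then nearest TSS <=50 kb)."""
    if not genes:
        raise ValueError("assign_peaks_to_genes requires >=1 gene")
    by_chrom: dict[str, list[tuple[GeneModel, int, int]]] = {}
    for g in genes:
        w = regulatory_window(g, upstream)
        by_chrom.setdefault(g.chrom, []).append((g, w.w_start, w.w_end))
    out: list[PeakGeneAssignment] = []
    for peak in peaks:
        mid = peak.midpoint()
        cands = by_chrom.get(peak.chrom, [])
        in_window = [
            (abs(mid - g.tss), g.gene_id, g)
            for g, ws, we in cands
            if ws <= mid < we
        ]
        if in_window:
            dist, _, g = min(in_window)
            out.append(PeakGeneAssignment(peak, g.gene_id, "window", dist))
            continue
        near = [(abs(mid - g.tss), g.gene_id, g) for g, _, _ in cands]
        if near:
            dist, _, g = min(near)
            if dist <= max_distance:
                out.append(PeakGeneAssignment(peak, g.gene_id, "nearest", dist))
    return out


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), computed in log space by scipy."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric parameters N={N} K={K} n={n} k={k}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_gmt(path) -> list[tuple[str, str, set[str]]]:
    """Read a GMT file: (set id, description, member genes) per line."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields")
            out.append((fields[0], fields[1], {g for g in fields[2:] if g}))
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pathway_enrichment(
    target_genes: set[str],
    pathways: list[tuple[str, str, set[str]]],
    universe: set[str],
) -> list[PathwayEnrichment]:
    """Hypergeometric enrichment of the target gene set in each pathway.

    Pathways are intersected with the universe; those left empty are skipped.
    q-values are BH-adjusted across the tested pathways.  Results are sorted
    by ascending p (ties by pathway id).
    """
    if not universe:
        raise ValueError("empty universe")
    if not target_genes <= universe:
        raise ValueError("target genes must be a subset of the universe")
    N = len(universe)
    n = len(target_genes)
    rows = []
    for pid, desc, members in pathways:
        members_u = members & universe
        K = len(members_u)
        if K == 0:
            continue
        k = len(target_genes & members_u)
        rows.append((pid, desc, K, k, hypergeom_upper(N, K, n, k)))
    if not rows:
        return []
    qs = bh_adjust([r[4] for r in rows])
    out = [
        PathwayEnrichment(pid, desc, N, K, n, k, p, float(q), _stars(p))
        for (pid, desc, K, k, p), q in zip(rows, qs)
    ]
    out.sort(key=lambda e: (e.p, e.pathway_id))
    return out
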