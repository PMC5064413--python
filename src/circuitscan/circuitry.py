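"""Candidate-TF selection and core regulatory circuitry graph construction.

Candidates for recruiting Mediator/Cohesin are transcription factors that
(1) rank in the top k (default 20) by their mean fraction of cofactor regions
(MED1, SMC1A, NIPBL) overlapped by the TF's peaks, and (2) have a binding
motif among the top-k motifs enriched in cofactor-occupied regions (symbol
match, case-insensitive, with an alias table for protein-vs-gene naming such
as ERa <-> ESR1).

The circuitry graph draws a directed edge A -> B when a peak of A falls in
B's regulatory window (10 kb upstream of the TSS through the end of the gene,
strand-aware).  A self-edge marks autoregulation; a node is additionally
flagged when the MED1∩SMC1A∩NIPBL co-occupied set touches its own window.
Leading candidates are the autoregulatory TFs whose own locus is co-occupied
by all three cofactors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from circuitscan.intervals import GeneModel, RegionSet, overlap_fraction

# protein-name <-> gene-symbol aliases used when matching motif TFs to peak TFs
DEFAULT_ALIASES: dict[str, str] = {
    "ERA": "ESR1",
    "ER-ALPHA": "ESR1",
    "HNF4ALPHA": "HNF4A",
    "AP1": "JUN",
}


@dataclass
class TFOverlapRanking:
    tf_symbol: str
    overlap_vs: dict[str, float]  # cofactor -> fraction of its regions overlapped
    summary: float  # mean of the cofactor fractions
    rank: int


@dataclass
class RegulatoryWindow:
    gene_id: str
    chrom: str
    w_start: int
    w_end: int
    derivation: str


@dataclass
class CircuitryGraph:
    graph: nx.DiGraph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def is_autoregulatory(self, tf: str) -> bool:
        return bool(self.graph.nodes[tf]["autoregulatory"])

    def cofactor_at_own_locus(self, tf: str) -> bool:
        return bool(self.graph.nodes[tf]["cofactor_at_own_locus"])


def rank_tf_overlap(
    cofactors: dict[str, RegionSet],
    tf_sets: dict[str, RegionSet],
    k: int = 20,
) -> list[TFOverlapRanking]:
    """Rank TFs by mean fraction of each cofactor's regions their peaks overlap.

    A TF with no peaks scores 0 on every cofactor.  Ties break by symbol.
    """
    if len(cofactors) != 3 or any(len(s) == 0 for s in cofactors.values()):
        raise ValueError("rank_tf_overlap requires 3 non-empty cofactor sets")
    if not tf_sets:
        raise ValueError("rank_tf_overlap requires >=1 TF set")
    rows: list[tuple[str, dict[str, float], float]] = []
    for tf, peaks in tf_sets.items():
        fracs = {}
        for cof, cof_set in cofactors.items():
            fracs[cof] = 0.0 if len(peaks) == 0 else overlap_fraction(cof_set, peaks)
        rows.append((tf, fracs, sum(fracs.values()) / len(fracs)))
    rows.sort(key=lambda r: (-r[2], r[0]))
    return [
        TFOverlapRanking(tf, fracs, summary, rank)
        for rank, (tf, fracs, summary) in enumerate(rows[:k], start=1)
    ]


def _canonical(symbol: str, aliases: dict[str, str]) -> str:
    s = symbol.strip().upper()
    return aliases.get(s, s)


def candidate_tfs(
    top_tfs: list[TFOverlapRanking],
    top_motifs,
    aliases: dict[str, str] | None = None,
) -> set[str]:
    """Cross-reference top co-occupying TFs with top enriched motifs.

    Returns the TF symbols (as named in the peak inputs) present in both
    lists; symbol matching is case-insensitive after alias canonicalization.
    A TF appearing only in the motif list (no ChIP peaks) cannot qualify.
    """
    aliases = DEFAULT_ALIASES if aliases is None else aliases
    motif_syms = {
        _canonical(m.tf_symbol, aliases) for m in top_motifs if m.tf_symbol
    }
    out = {
        t.tf_symbol
        for t in top_tfs
        if _canonical(t.tf_symbol, aliases) in motif_syms
    }
    if not out:
        import warnings

        warnings.warn("candidate_tfs: TF ranking and motif list are disjoint")
    return out


def regulatory_window(g: GeneModel, upstream: int = 10000) -> RegulatoryWindow:
    """Strand-aware window from -upstream of the TSS to the end of the gene."""
    if upstream < 0:
        raise ValueError("upstream must be >= 0")
    if g.strand == "+":
        w_start, w_end = max(0, g.start - upstream), g.end
        rule = f"+strand: [start-{upstream}, end)"
    else:
        w_start, w_end = g.start, g.end + upstream
        rule = f"-strand: [start, end+{upstream})"
    return RegulatoryWindow(g.gene_id, g.chrom, w_start, w_end, rule)


def build_circuitry(
    candidates: set[str] | list[str],
    tf_sets: dict[str, RegionSet],
    genes: dict[str, GeneModel],
    cofactor_coocc: RegionSet,
    upstream: int = 10000,
) -> CircuitryGraph:
    """Directed binding graph among candidate TFs over their gene windows.

    Edge A -> B iff >=1 peak of A overlaps B's regulatory window; the number
    of such peaks is kept as edge metadata.  Node flags: ``autoregulatory``
    (self-edge) and ``cofactor_at_own_locus`` (the MED1∩SMC1A∩NIPBL set
    touches the node's own window).
    """
    cands = sorted(candidates)
    for tf in cands:
        if tf not in genes:
            raise ValueError(f"candidate {tf!r} has no gene model")
        if tf not in tf_sets:
            raise ValueError(f"candidate {tf!r} has no peak set")
    g = nx.DiGraph()
    windows = {tf: regulatory_window(genes[tf], upstream) for tf in cands}
    for tf in cands:
        w = windows[tf]
        g.add_node(
            tf,
            autoregulatory=False,
            cofactor_at_own_locus=cofactor_coocc.overlaps_interval(
                w.chrom, w.w_start, w.w_end
            ),
        )
    for a in cands:
        peaks = tf_sets[a]
        for b in cands:
            w = windows[b]
            n_peaks = sum(
                1
                for iv in peaks
                if iv.chrom == w.chrom and iv.start < w.w_end and w.w_start < iv.end
            )
            if n_peaks:
                g.add_edge(a, b, n_peaks=n_peaks)
                if a == b:
                    g.nodes[a]["autoregulatory"] = True
    return CircuitryGraph(g)


def leading_candidates(g: CircuitryGraph) -> set[str]:
    """Autoregulatory TFs whose own locus is co-occupied by all three cofactors."""
    return {
        tf
        for tf in g.graph.nodes
        if g.is_autoregulatory(tf) and g.cofactor_at_own_locus(tf)
    }


def export_graph(g: CircuitryGraph, edges_path, graphml_path=None) -> None:
    """Write node/edge TSV and optionally GraphML."""
    with open(edges_path, "w") as fh:
        fh.write("source\ttarget\tn_peaks\tautoregulatory\n")
        for a, b in g.edges:
            fh.write(
                f"{a}\t{b}\t{g.graph.edges[a, b]['n_peaks']}\t{int(a == b)}\n"
            )
    if graphml_path is not None:
        nx.write_graphml(g.graph, graphml_path)
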