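"""Stage orchestration over a single YAML config; provenance-stamped outputs.

Stages run in the order cooccupancy -> motifs -> circuitry -> enrich; each can
also run alone on a prior stage's outputs.  Identical config + inputs yield
byte-identical outputs: every float is formatted explicitly, JSON keys are
sorted, and all randomness (background region shuffling) derives from the
configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

import circuitscan
from circuitscan import cooccupancy as co
from circuitscan import circuitry as ci
from circuitscan import enrichment as en
from circuitscan import motifs as mo
from circuitscan.intervals import RegionSet, intersect_all, read_bed, read_genes, write_bed

log = logging.getLogger("circuitscan")

REQUIRED_KEYS = ["genome", "genes", "peaks", "tf_peaks", "segmentation", "pwms", "motif_map", "pathways"]
DEFAULT_PARAMS = {
    "k": 20,
    "upstream": 10000,
    "threshold_quantile": 0.9999,
    "pseudocount": 0.8,
    "assignment_max_distance": 50000,
    "clustering_linkage": "average",
    "seed": 0,
}


class ConfigError(ValueError):
    pass


def load_config(config_path: str | Path) -> tuple[dict, Path]:
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg, config_path.parent


def validate_config(cfg: dict, base: Path) -> list[str]:
    """Schema-and-existence validation pass, run before any stage executes."""
    errors: list[str] = []
    for key in REQUIRED_KEYS:
        if key not in cfg:
            errors.append(f"missing config key: {key}")
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params") or {})
    if params["k"] < 1:
        errors.append("params.k must be >= 1")
    if params["upstream"] < 0:
        errors.append("params.upstream must be >= 0")
    if not 0 < params["threshold_quantile"] < 1:
        errors.append("params.threshold_quantile must be in (0, 1)")
    for key in ("genome", "genes", "segmentation", "pwms", "motif_map", "pathways"):
        if key in cfg and not (base / cfg[key]).exists():
            errors.append(f"{key}: missing file {cfg[key]}")
    for group in ("peaks", "tf_peaks"):
        for name, path in (cfg.get(group) or {}).items():
            if not (base / path).exists():
                errors.append(f"{group}.{name}: missing file {path}")
    for reg in ("MED1", "SMC1A", "NIPBL"):
        if reg not in (cfg.get("peaks") or {}):
            errors.append(f"peaks must include {reg}")
    return errors


def _params(cfg: dict) -> dict:
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params") or {})
    return params


def _outdir(cfg: dict, base: Path) -> Path:
    out = base / cfg.get("outdir", "results")
    out.mkdir(parents=True, exist_ok=True)
    return out


def _load_peaks(cfg: dict, base: Path) -> tuple[dict[str, RegionSet], RegionSet]:
    cof = {
        reg: read_bed(base / cfg["peaks"][reg], regulator=reg)
        for reg in ("MED1", "SMC1A", "NIPBL")
    }
    ctcf_path = cfg["peaks"].get("CTCF")
    ctcf = (
        read_bed(base / ctcf_path, regulator="CTCF")
        if ctcf_path
        else RegionSet("CTCF", [])
    )
    return cof, ctcf


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def run_cooccupancy(cfg: dict, base: Path) -> dict[str, str]:
    out = _outdir(cfg, base)
    cof, ctcf = _load_peaks(cfg, base)
    sets = [cof["MED1"], cof["SMC1A"], cof["NIPBL"]] + ([ctcf] if len(ctcf) else [])
    log.info("cooccupancy: %d regulator sets", len(sets))
    m = co.build_occupancy_matrix(sets)
    with open(out / "occupancy.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\t" + "\t".join(m.regulators) + "\n")
        for iv, row in zip(m.regions, m.M):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t" + "\t".join(map(str, row)) + "\n")
    pca = co.pca_regulators(m)
    pca_out = {
        "regulators": pca.regulators,
        "explained": [_fmt(x) for x in pca.explained],
        "variable_coords": {
            reg: [_fmt(x) for x in pca.variable_coords[i]]
            for i, reg in enumerate(pca.regulators)
        },
        "dim1_bimodal": {
            reg: co.count_density_modes(pca.dim1_density[reg]) >= 2
            for reg in pca.regulators
        },
    }
    (out / "pca.json").write_text(json.dumps(pca_out, indent=1, sort_keys=True) + "\n")
    with open(out / "correlations.tsv", "w") as fh:
        fh.write("a\tb\tR\tp\n")
        regs = m.regulators
        for i, a in enumerate(regs):
            for b in regs[i + 1 :]:
                r = co.regulator_correlation(m, a, b)
                fh.write(f"{a}\t{b}\t{_fmt(r.R)}\t{r.p:.6e}\n")
    if len(ctcf):
        with_ctcf, no_ctcf = co.partition_by_ctcf(cof["SMC1A"], ctcf)
        write_bed(with_ctcf, out / "SMC1A_with_CTCF.bed")
        write_bed(no_ctcf, out / "SMC1A_no_CTCF.bed")
    seg = co.read_segmentation(base / cfg["segmentation"])
    states = sorted({label for _, label in seg})
    with open(out / "state_ratios.tsv", "w") as fh:
        fh.write("regulator\t" + "\t".join(states) + "\t" + co.UNANNOTATED + "\n")
        profiled = dict(cof)
        if len(ctcf):
            profiled["CTCF"] = ctcf
            profiled["SMC1A_with_CTCF"] = with_ctcf
            profiled["SMC1A_no_CTCF"] = no_ctcf
        profiled["MED1_SMC1A_NIPBL"] = intersect_all(
            [cof["MED1"], cof["SMC1A"], cof["NIPBL"]]
        )
        for name, rs in profiled.items():
            prof = co.state_overlap_profile(rs, seg)
            vals = [prof.ratios.get(s, 0.0) for s in states] + [
                prof.ratios.get(co.UNANNOTATED, 0.0)
            ]
            fh.write(name + "\t" + "\t".join(_fmt(v) for v in vals) + "\n")
    coloc = co.colocalization_matrix(sets)
    with open(out / "colocalization.tsv", "w") as fh:
        fh.write(
            "# linkage=average distance=1-pearson order="
            + ",".join(coloc.regulators[i] for i in coloc.order)
            + "\n"
        )
        fh.write("regulator\t" + "\t".join(coloc.regulators) + "\n")
        for i, reg in enumerate(coloc.regulators):
            fh.write(reg + "\t" + "\t".join(_fmt(v) for v in coloc.F[i]) + "\n")
    return {"occupancy": "occupancy.tsv", "pca": "pca.json"}


def run_motifs(cfg: dict, base: Path) -> list[mo.MotifEnrichmentResult]:
    out = _outdir(cfg, base)
    params = _params(cfg)
    cof, _ = _load_peaks(cfg, base)
    targets = intersect_all([cof["MED1"], cof["SMC1A"], cof["NIPBL"]])
    if len(targets) == 0:
        raise RuntimeError("motifs: no co-occupied target regions")
    write_bed(targets, out / "cooccupied_regions.bed")
    from pyfaidx import Fasta

    genome = Fasta(str(base / cfg["genome"]), sequence_always_upper=True)
    chrom_sizes = {name: len(genome[name]) for name in genome.keys()}
    rng = np.random.default_rng(int(params["seed"]))
    bg_regions = mo.shuffle_regions(targets, chrom_sizes, rng, avoid=targets)
    target_seqs = [str(genome[iv.chrom][iv.start : iv.end]) for iv in targets]
    bg_seqs = [str(genome[iv.chrom][iv.start : iv.end]) for iv in bg_regions]
    bg_model = mo.BackgroundModel.from_sequences(
        bg_seqs, source="region-estimated"
    )
    pwms = mo.load_pwms(
        base / cfg["pwms"], base / cfg["motif_map"], pseudocount=params["pseudocount"]
    )
    log.info("motifs: %d PWMs, %d target regions", len(pwms), len(target_seqs))
    results = [
        mo.motif_enrichment(
            p, bg_model, target_seqs, bg_seqs, params["threshold_quantile"]
        )
        for p in pwms
    ]
    ranked = mo.rank_motifs(results, k=params["k"])
    with open(out / "motif_ranking.tsv", "w") as fh:
        fh.write("rank\tmotif_id\ttf_symbol\ttarget_hits\ttarget_n\tbg_rate\tp\n")
        for r in ranked:
            fh.write(
                f"{r.rank}\t{r.motif_id}\t{r.tf_symbol}\t{r.target_hits}\t"
                f"{r.target_n}\t{_fmt(r.bg_rate)}\t{r.p:.6e}\n"
            )
    return ranked


def _read_motif_ranking(out: Path) -> list[mo.MotifEnrichmentResult]:
    path = out / "motif_ranking.tsv"
    if not path.exists():
        raise RuntimeError("circuitry: motif_ranking.tsv not found; run motifs first")
    results = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            rank, mid, sym, hits, n, rate, p = line.rstrip("\n").split("\t")
            results.append(
                mo.MotifEnrichmentResult(
                    mid, sym, int(hits), int(n), float(rate), float(p), int(rank)
                )
            )
    return results


def run_circuitry(
    cfg: dict, base: Path, motif_ranking: list | None = None
) -> dict:
    out = _outdir(cfg, base)
    params = _params(cfg)
    cof, _ = _load_peaks(cfg, base)
    tf_sets = {
        sym: read_bed(base / path, regulator=sym)
        for sym, path in (cfg.get("tf_peaks") or {}).items()
    }
    if motif_ranking is None:
        motif_ranking = _read_motif_ranking(out)
    ranking = ci.rank_tf_overlap(cof, tf_sets, k=params["k"])
    with open(out / "tf_overlap_ranking.tsv", "w") as fh:
        fh.write("rank\ttf_symbol\tMED1\tSMC1A\tNIPBL\tsummary\n")
        for t in ranking:
            fh.write(
                f"{t.rank}\t{t.tf_symbol}\t"
                + "\t".join(_fmt(t.overlap_vs[c]) for c in ("MED1", "SMC1A", "NIPBL"))
                + f"\t{_fmt(t.summary)}\n"
            )
    candidates = ci.candidate_tfs(ranking, motif_ranking)
    genes = read_genes(base / cfg["genes"], format=cfg.get("genes_format", "gtf"))
    gene_by_symbol = {g.symbol: g for g in genes}
    coocc = intersect_all([cof["MED1"], cof["SMC1A"], cof["NIPBL"]])
    graph = ci.build_circuitry(
        candidates,
        tf_sets,
        gene_by_symbol,
        coocc,
        upstream=params["upstream"],
    )
    leading = ci.leading_candidates(graph)
    manual = sorted(cfg.get("manual_candidates") or [])
    report = {
        "candidates": sorted(candidates),
        "leading_candidates": sorted(leading),
        "manual_candidates": [
            {"tf_symbol": tf, "flag": "manual"} for tf in manual
        ],
        "autoregulatory": sorted(
            tf for tf in graph.nodes if graph.is_autoregulatory(tf)
        ),
        "edges": [list(e) for e in graph.edges],
    }
    (out / "circuitry.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    ci.export_graph(graph, out / "circuitry_edges.tsv", out / "circuitry.graphml")
    return report


def run_enrich(cfg: dict, base: Path) -> list[en.PathwayEnrichment]:
    out = _outdir(cfg, base)
    params = _params(cfg)
    cof, _ = _load_peaks(cfg, base)
    coocc = intersect_all([cof["MED1"], cof["SMC1A"], cof["NIPBL"]])
    genes = read_genes(base / cfg["genes"], format=cfg.get("genes_format", "gtf"))
    assignments = en.assign_peaks_to_genes(
        coocc,
        genes,
        upstream=params["upstream"],
        max_distance=params["assignment_max_distance"],
    )
    target = {a.gene_id for a in assignments}
    universe = {g.gene_id for g in genes}
    pathways = en.read_gmt(base / cfg["pathways"])
    results = en.pathway_enrichment(target, pathways, universe)
    with open(out / "pathway_enrichment.tsv", "w") as fh:
        fh.write("pathway_id\tN\tK\tn\tk\tp\tq\tstars\n")
        for r in results:
            fh.write(
                f"{r.pathway_id}\t{r.N}\t{r.K}\t{r.n}\t{r.k}\t"
                f"{r.p:.6e}\t{r.q:.6e}\t{r.stars}\n"
            )
    return results


def run_all(config_path: str | Path) -> dict:
    """Execute all stages in order and write a machine-readable run report."""
    cfg, base = load_config(config_path)
    errors = validate_config(cfg, base)
    if errors:
        raise ConfigError("; ".join(errors))
    out = _outdir(cfg, base)
    cfg_bytes = Path(config_path).read_bytes()
    run_cooccupancy(cfg, base)
    ranked = run_motifs(cfg, base)
    circuitry_report = run_circuitry(cfg, base, motif_ranking=ranked)
    enrich_results = run_enrich(cfg, base)
    report = {
        "version": circuitscan.__version__,
        "config_sha256": hashlib.sha256(cfg_bytes).hexdigest(),
        "params": _params(cfg),
        "stages": {
            "cooccupancy": ["occupancy.tsv", "pca.json", "correlations.tsv",
                             "state_ratios.tsv", "colocalization.tsv"],
            "motifs": ["motif_ranking.tsv", "cooccupied_regions.bed"],
            "circuitry": ["tf_overlap_ranking.tsv", "circuitry.json",
                           "circuitry_edges.tsv"],
            "enrich": ["pathway_enrichment.tsv"],
        },
        "candidates": circuitry_report["candidates"],
        "leading_candidates": circuitry_report["leading_candidates"],
        "manual_candidates": circuitry_report["manual_candidates"],
        "top_pathways": [r.pathway_id for r in enrich_results[:5]],
    }
    (out / "run_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    return report
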