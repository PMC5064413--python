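"""Synthetic input bundles with a planted core regulatory circuitry.

From a seed and a parameter set, this module writes a complete input bundle —
genome FASTA, gene GTF, peak BEDs for MED1/SMC1A/NIPBL/CTCF and every TF, a
ChromHMM-dense state segmentation, a HOCOMOCO-style PWM file with a
motif→TF mapping TSV, GMT pathways — plus a ground-truth JSON, so that every
pipeline stage can be exercised and scored with no external data.

The generator emulates the statistical structure of cofactor ChIP-Seq in a
cancer cell line:

* ``n_cofactor_sites`` regulatory sites; each carries all of MED1, SMC1A and
  NIPBL with probability ``coocc_prob`` (q), otherwise exactly one of them.
  Each cofactor additionally receives solo "noise" peaks at rate
  (2/3)·(1−q)·n_sites, which makes the fraction of one cofactor's peaks
  co-occupied by another equal q in expectation (and exactly removes the solo
  peaks in the q=1 limit).
* A disjoint population of CTCF sites, a subset of which also carries SMC1A,
  sized so that ``ctcf_smc1a_frac`` of all SMC1A peaks sit at CTCF sites —
  the CTCF-associated Cohesin subpopulation.
* ``n_crc_tfs`` circuitry TFs: each gets peaks at cofactor sites at rate
  ``motif_plant_rate_target``, a guaranteed peak in every circuitry gene's
  regulatory window (self-window only for the autoregulatory subset), and its
  PWM consensus written into the genome under every one of its peaks plus
  random background placements at ``motif_plant_rate_bg`` per ~500 bp.
  A forced co-occupied cofactor site sits at every circuitry gene's TSS.
* Decoy TFs with uniformly random peaks, and decoy PWMs mapped to TF symbols
  that have no peak set (as in a real motif-database cross-reference, where
  most motifs have no matching ChIP data in a given cell line).
* A state segmentation that tiles each chromosome exactly: active TSS
  (1_TssA) at promoters, active enhancer (9_EnhA1) at cofactor sites,
  transcription (5_Tx) over gene bodies and quiescent (18_Quies) elsewhere,
  including the CTCF-only sites.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from circuitscan.intervals import GeneModel, GenomicInterval, RegionSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)

STATE_QUIES = "18_Quies"
STATE_TX = "5_Tx"
STATE_TSS = "1_TssA"
STATE_ENH = "9_EnhA1"


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic bundle (defaults are the reference scenario)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 60
    n_crc_tfs: int = 3
    n_autoregulatory: int | None = None  # None -> all circuitry TFs
    n_decoy_tfs: int = 27
    n_decoy_motifs: int = 30
    coocc_prob: float = 0.8
    ctcf_smc1a_frac: float = 0.4
    motif_plant_rate_target: float = 0.6
    motif_plant_rate_bg: float = 0.05
    n_cofactor_sites: int = 200
    n_peaks_per_decoy: int = 100
    peak_width_median: float = 400.0
    peak_width_sigma: float = 0.25
    gc_content: float = 0.41
    motif_length: int = 9
    gene_length_min: int = 2000
    gene_length_max: int = 4000
    bg_plant_region_width: int = 500

    def __post_init__(self) -> None:
        for name in (
            "coocc_prob",
            "ctcf_smc1a_frac",
            "motif_plant_rate_target",
            "motif_plant_rate_bg",
            "gc_content",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chroms", "n_genes", "n_crc_tfs", "n_cofactor_sites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_genes < self.n_crc_tfs + self.n_decoy_tfs:
            raise ValueError("n_genes must cover all TF genes")
        genes_per_chrom = -(-self.n_genes // self.n_chroms)
        mean_gene = (self.gene_length_min + self.gene_length_max) / 2
        if self.chrom_length <= 10 * genes_per_chrom * mean_gene:
            raise ValueError(
                "chrom_length must exceed 10 x genes-per-chromosome x mean gene length"
            )
        n_auto = self.n_crc_tfs if self.n_autoregulatory is None else self.n_autoregulatory
        if not 0 <= n_auto <= self.n_crc_tfs:
            raise ValueError("n_autoregulatory must be in [0, n_crc_tfs]")


@dataclass
class SyntheticTruth:
    crc_tfs: list[str]
    autoregulatory: list[str]
    crc_motif_ids: dict[str, str]  # tf symbol -> motif id
    decoy_motif_ids: list[str]
    motif_placements: list[tuple[str, str, int, str]]  # (motif_id, chrom, pos, strand)
    site_classes: list[dict]  # per cofactor site: chrom, center, class
    planted_pathway: str
    config: dict
    files: dict[str, str]


@dataclass
class Bundle:
    """In-memory view of a generated (or on-disk) bundle."""

    outdir: Path
    cofactors: dict[str, RegionSet]
    ctcf: RegionSet
    tf_sets: dict[str, RegionSet]
    genes: list[GeneModel]
    genome_fasta: Path
    segmentation_bed: Path
    pwms_path: Path
    motif_map_path: Path
    gmt_path: Path
    chrom_sizes: dict[str, int]


def _sample_separated(
    rng: np.random.Generator,
    n: int,
    chrom_names: list[str],
    chrom_length: int,
    taken: dict[str, list[int]],
    min_dist: int = 2000,
    margin: int = 1000,
    max_tries: int = 10000,
) -> list[tuple[str, int]]:
    """Sample n positions keeping min_dist from already-taken centers."""
    out: list[tuple[str, int]] = []
    for _ in range(n):
        for _try in range(max_tries):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            pos = int(rng.integers(margin, chrom_length - margin))
            if all(abs(pos - t) >= min_dist for t in taken.get(chrom, [])):
                taken.setdefault(chrom, []).append(pos)
                out.append((chrom, pos))
                break
        else:
            raise RuntimeError(
                "could not place a separated site; increase chrom_length"
            )
    return out


def _peak(
    rng: np.random.Generator,
    chrom: str,
    center: int,
    cfg: SyntheticConfig,
    chrom_length: int,
    jitter: int = 20,
) -> GenomicInterval:
    width = int(round(cfg.peak_width_median * np.exp(rng.normal(0.0, cfg.peak_width_sigma))))
    width = max(width, cfg.motif_length + 20)
    c = center + int(rng.integers(-jitter, jitter + 1))
    start = max(0, c - width // 2)
    end = min(chrom_length, start + width)
    return GenomicInterval(chrom, start, end)


def generate_bundle(cfg: SyntheticConfig, outdir: str | Path) -> SyntheticTruth:
    """Write a complete synthetic bundle; deterministic given cfg.seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    L = cfg.chrom_length

    # -- genome ------------------------------------------------------------
    p_base = np.array(
        [
            (1 - cfg.gc_content) / 2,
            cfg.gc_content / 2,
            cfg.gc_content / 2,
            (1 - cfg.gc_content) / 2,
        ]
    )
    genome = {c: rng.choice(4, size=L, p=p_base).astype(np.uint8) for c in chrom_names}

    # -- genes ---------------------------------------------------------------
    genes_per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        genes_per_chrom[i] += 1
    margin = 15000
    gene_tuples: list[tuple[str, int, int, str]] = []  # chrom, start, end, strand
    for ci, chrom in enumerate(chrom_names):
        gpc = genes_per_chrom[ci]
        slot = (L - 2 * margin) / gpc
        for gi in range(gpc):
            length = int(rng.integers(cfg.gene_length_min, cfg.gene_length_max + 1))
            lo = int(margin + gi * slot)
            hi = int(margin + (gi + 1) * slot) - length - 1000
            start = int(rng.integers(lo, max(lo + 1, hi)))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_tuples.append((chrom, start, start + length, strand))

    def _window_of(idx: int, buffer: int = 2000) -> tuple[str, int, int]:
        chrom, start, end, strand = gene_tuples[idx]
        if strand == "+":
            return chrom, max(0, start - 10000) - buffer, end + buffer
        return chrom, start - buffer, end + 10000 + buffer

    def _crc_windows_disjoint(idxs: list[int]) -> bool:
        ws = [_window_of(i) for i in idxs]
        for i in range(len(ws)):
            for j in range(i + 1, len(ws)):
                a, b = ws[i], ws[j]
                if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                    return False
        return True

    # circuitry genes need pairwise-disjoint regulatory windows, otherwise a
    # connection peak at one circuitry gene can fall in another's own window
    for _try in range(100):
        perm = rng.permutation(cfg.n_genes)
        if _crc_windows_disjoint([int(i) for i in perm[: cfg.n_crc_tfs]]):
            break
    else:
        raise RuntimeError(
            "could not place circuitry genes with disjoint regulatory windows; "
            "increase chrom_length"
        )
    crc_idx = [int(i) for i in perm[: cfg.n_crc_tfs]]
    decoy_idx = [int(i) for i in perm[cfg.n_crc_tfs : cfg.n_crc_tfs + cfg.n_decoy_tfs]]
    symbols = [""] * cfg.n_genes
    for j, gi in enumerate(crc_idx):
        symbols[gi] = f"TF{j + 1}"
    for j, gi in enumerate(decoy_idx):
        symbols[gi] = f"DTF{j + 1:02d}"
    rest = 0
    for gi in range(cfg.n_genes):
        if not symbols[gi]:
            rest += 1
            symbols[gi] = f"GENE{rest:02d}"
    genes = [
        GeneModel(symbols[gi], symbols[gi], *gene_tuples[gi])
        for gi in range(cfg.n_genes)
    ]
    gene_by_symbol = {g.symbol: g for g in genes}
    crc_tfs = sorted(f"TF{j + 1}" for j in range(cfg.n_crc_tfs))
    decoy_tfs = sorted(f"DTF{j + 1:02d}" for j in range(cfg.n_decoy_tfs))
    n_auto = cfg.n_crc_tfs if cfg.n_autoregulatory is None else cfg.n_autoregulatory
    autoregulatory = crc_tfs[:n_auto]

    # -- PWMs (drawn before planting so consensus sequences exist) ----------
    Lm = cfg.motif_length
    crc_motifs: dict[str, np.ndarray] = {}  # symbol -> consensus codes
    crc_counts: dict[str, np.ndarray] = {}
    for tf in crc_tfs:
        cons = rng.integers(0, 4, size=Lm)
        counts = np.full((Lm, 4), 1.0)
        counts[np.arange(Lm), cons] = 97.0
        crc_motifs[tf] = cons.astype(np.uint8)
        crc_counts[tf] = counts
    planted_words = [crc_motifs[tf] for tf in crc_tfs]
    planted_words += [_COMP[w][::-1] for w in planted_words]

    def is_decoy_like(cons: np.ndarray) -> bool:
        # a decoy must be a genuinely unrelated motif, not a near-copy of a
        # planted consensus (either strand) at any small alignment offset
        for w in planted_words:
            for s in range(-3, 4):
                a = cons[max(0, s) : Lm + min(0, s)]
                b = w[max(0, -s) : Lm + min(0, -s)]
                if int((a != b).sum()) < 3:
                    return False
        return True

    decoy_counts: list[np.ndarray] = []
    for _ in range(cfg.n_decoy_motifs):
        cons = rng.integers(0, 4, size=Lm)
        while not is_decoy_like(cons):
            cons = rng.integers(0, 4, size=Lm)
        counts = np.full((Lm, 4), 5.0)
        counts[np.arange(Lm), cons] = 85.0
        decoy_counts.append(counts)

    # -- cofactor sites ------------------------------------------------------
    taken: dict[str, list[int]] = {}
    sites: list[tuple[str, int, str]] = []  # chrom, center, class
    for tf in crc_tfs:  # forced co-occupied site at every circuitry gene TSS
        g = gene_by_symbol[tf]
        taken.setdefault(g.chrom, []).append(g.tss)
        sites.append((g.chrom, g.tss, "all3"))
    n_free = cfg.n_cofactor_sites - len(sites)
    other_genes = [g for g in genes if g.symbol not in crc_tfs]
    n_prom = min(len(other_genes), n_free // 3)
    prom_pick = rng.choice(len(other_genes), size=n_prom, replace=False)
    prom_classes = []
    for idx in sorted(int(i) for i in prom_pick):
        g = other_genes[idx]
        taken.setdefault(g.chrom, []).append(g.tss)
        prom_classes.append((g.chrom, g.tss))
    enh = _sample_separated(rng, n_free - n_prom, chrom_names, L, taken)
    free_positions = prom_classes + enh
    for chrom, pos in free_positions:
        if rng.random() < cfg.coocc_prob:
            cls = "all3"
        else:
            cls = ["MED1", "SMC1A", "NIPBL"][int(rng.integers(3))]
        sites.append((chrom, pos, cls))

    cof_names = ["MED1", "SMC1A", "NIPBL"]
    cof_peaks: dict[str, list[GenomicInterval]] = {c: [] for c in cof_names}
    for chrom, pos, cls in sites:
        present = cof_names if cls == "all3" else [cls]
        for reg in present:
            cof_peaks[reg].append(_peak(rng, chrom, pos, cfg, L))

    # solo noise peaks: rate (2/3)(1-q) per cofactor, so that pairwise
    # co-occupancy among each factor's peaks equals q in expectation
    n_solo = int(round((2.0 / 3.0) * (1.0 - cfg.coocc_prob) * cfg.n_cofactor_sites))
    for reg in cof_names:
        for chrom, pos in _sample_separated(rng, n_solo, chrom_names, L, taken):
            cof_peaks[reg].append(_peak(rng, chrom, pos, cfg, L))

    # -- CTCF sites and the CTCF-associated SMC1A subpopulation -------------
    n_smc1a_free = len(cof_peaks["SMC1A"])
    f = cfg.ctcf_smc1a_frac
    n_ctcf_smc1a = int(round(n_smc1a_free * f / (1.0 - f))) if f < 1 else 0
    n_ctcf_only = int(round(0.2 * n_ctcf_smc1a))
    ctcf_sites = _sample_separated(
        rng, n_ctcf_smc1a + n_ctcf_only, chrom_names, L, taken
    )
    ctcf_peaks: list[GenomicInterval] = []
    for i, (chrom, pos) in enumerate(ctcf_sites):
        ctcf_peaks.append(_peak(rng, chrom, pos, cfg, L))
        if i < n_ctcf_smc1a:
            cof_peaks["SMC1A"].append(_peak(rng, chrom, pos, cfg, L))

    # -- TF peaks ------------------------------------------------------------
    tf_peaks: dict[str, list[GenomicInterval]] = {}
    placements: list[tuple[str, str, int, str]] = []
    windows = {}
    for tf in crc_tfs:
        g = gene_by_symbol[tf]
        ws = max(0, g.start - 10000) if g.strand == "+" else g.start
        we = g.end if g.strand == "+" else g.end + 10000
        windows[tf] = (g.chrom, ws, we)

    def in_own_window(tf: str, chrom: str, pos: int, buffer: int = 1500) -> bool:
        # buffer covers peak width + jitter so no peak can straddle the edge
        wc, ws, we = windows[tf]
        return chrom == wc and ws - buffer <= pos < we + buffer

    def plant(tf: str, peak: GenomicInterval) -> None:
        cons = crc_motifs[tf]
        center = (peak.start + peak.end) // 2
        off = int(rng.integers(-30, 31))
        pos = center - Lm // 2 + off
        pos = max(peak.start, min(pos, peak.end - Lm))
        pos = max(0, min(pos, L - Lm))
        strand = "+" if rng.random() < 0.5 else "-"
        word = cons if strand == "+" else _COMP[cons][::-1]
        genome[peak.chrom][pos : pos + Lm] = word
        placements.append((f"{tf}.M1", peak.chrom, pos, strand))

    for tf in crc_tfs:
        peaks: list[GenomicInterval] = []
        for chrom, pos, cls in sites:
            if tf not in autoregulatory and in_own_window(tf, chrom, pos):
                continue
            if rng.random() < cfg.motif_plant_rate_target:
                peaks.append(_peak(rng, chrom, pos, cfg, L))
        for other in crc_tfs:  # guaranteed circuitry connections
            if other == tf and tf not in autoregulatory:
                continue
            g = gene_by_symbol[other]
            peaks.append(_peak(rng, g.chrom, g.tss, cfg, L))
        for pk in peaks:
            plant(tf, pk)
        # background consensus placements (~motif_plant_rate_bg per ~500bp region)
        n_bg = int(
            round(
                cfg.motif_plant_rate_bg
                * (cfg.n_chroms * L)
                / cfg.bg_plant_region_width
            )
        )
        site_centers: dict[str, list[int]] = {}
        for chrom, pos, _cls in sites:
            site_centers.setdefault(chrom, []).append(pos)
        placed = 0
        while placed < n_bg:
            chrom = chrom_names[int(rng.integers(cfg.n_chroms))]
            pos = int(rng.integers(0, L - Lm))
            if any(abs(pos - c) < 1000 for c in site_centers.get(chrom, [])):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            cons = crc_motifs[tf]
            word = cons if strand == "+" else _COMP[cons][::-1]
            genome[chrom][pos : pos + Lm] = word
            placements.append((f"{tf}.M1", chrom, pos, strand))
            placed += 1
        tf_peaks[tf] = peaks

    for tf in decoy_tfs:
        peaks = []
        for _ in range(cfg.n_peaks_per_decoy):
            chrom = chrom_names[int(rng.integers(cfg.n_chroms))]
            pos = int(rng.integers(1000, L - 1000))
            peaks.append(_peak(rng, chrom, pos, cfg, L))
        tf_peaks[tf] = peaks

    # drop placements whose sequence was overwritten by a later overlapping
    # plant: truth records only instances actually present in the genome
    surviving = []
    for motif_id, chrom, pos, strand in placements:
        tf = motif_id.split(".")[0]
        cons = crc_motifs[tf]
        word = cons if strand == "+" else _COMP[cons][::-1]
        if np.array_equal(genome[chrom][pos : pos + Lm], word):
            surviving.append((motif_id, chrom, pos, strand))
    placements = surviving

    # -- segmentation (exact tiling per chromosome) --------------------------
    state_codes = {STATE_QUIES: 0, STATE_TX: 1, STATE_TSS: 2, STATE_ENH: 3}
    code_state = {v: k for k, v in state_codes.items()}
    seg_lines: list[str] = []
    for chrom in chrom_names:
        lab = np.zeros(L, dtype=np.uint8)
        for g in genes:
            if g.chrom == chrom:
                lab[g.start : g.end] = state_codes[STATE_TX]
        for g in genes:
            if g.chrom == chrom:
                lab[max(0, g.tss - 500) : min(L, g.tss + 500)] = state_codes[STATE_TSS]
        for schrom, pos, _cls in sites:
            if schrom == chrom:
                lab[max(0, pos - 500) : min(L, pos + 500)] = state_codes[STATE_ENH]
        breaks = np.flatnonzero(np.diff(lab)) + 1
        bounds = np.concatenate(([0], breaks, [L]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            seg_lines.append(f"{chrom}\t{s}\t{e}\t{code_state[int(lab[s])]}")

    # -- pathways -------------------------------------------------------------
    all3_centers: dict[str, list[int]] = {}
    for chrom, pos, cls in sites:
        if cls == "all3":
            all3_centers.setdefault(chrom, []).append(pos)
    target_genes = []
    for g in genes:
        ws = max(0, g.start - 10000) if g.strand == "+" else g.start
        we = g.end if g.strand == "+" else g.end + 10000
        if any(ws <= c < we for c in all3_centers.get(g.chrom, [])):
            target_genes.append(g.symbol)
    planted_pathway = "COFACTOR_TARGET_GENES"
    gmt_lines = [
        planted_pathway
        + "\tgenes with a co-occupied cofactor site in their regulatory window\t"
        + "\t".join(sorted(target_genes))
    ]
    n_decoy_pathways = 10
    for i in range(n_decoy_pathways):
        size = min(20, cfg.n_genes)
        pick = rng.choice(cfg.n_genes, size=size, replace=False)
        members = sorted(symbols[int(j)] for j in pick)
        gmt_lines.append(f"DECOY_PATHWAY_{i + 1:02d}\trandom gene set\t" + "\t".join(members))

    # -- write everything -----------------------------------------------------
    files: dict[str, str] = {}

    def reg_set(name: str, ivs: list[GenomicInterval]) -> RegionSet:
        return RegionSet(name, ivs)

    from circuitscan.intervals import write_bed

    fa_path = outdir / "genome.fa"
    with open(fa_path, "w") as fh:
        for chrom in chrom_names:
            fh.write(f">{chrom}\n")
            seq = _BASES[genome[chrom]].tobytes().decode("ascii")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    files["genome"] = fa_path.name

    sizes_path = outdir / "chrom.sizes"
    with open(sizes_path, "w") as fh:
        for chrom in chrom_names:
            fh.write(f"{chrom}\t{L}\n")
    files["chrom_sizes"] = sizes_path.name

    gtf_path = outdir / "genes.gtf"
    with open(gtf_path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
    files["genes"] = gtf_path.name

    for reg in cof_names:
        p = outdir / f"{reg}.bed"
        write_bed(reg_set(reg, cof_peaks[reg]), p)
        files[reg] = p.name
    p = outdir / "CTCF.bed"
    write_bed(reg_set("CTCF", ctcf_peaks), p)
    files["CTCF"] = p.name
    for tf in sorted(tf_peaks):
        p = outdir / f"TF_{tf}.bed"
        write_bed(reg_set(tf, tf_peaks[tf]), p)
        files[f"TF_{tf}"] = p.name

    seg_path = outdir / "segmentation.bed"
    seg_path.write_text("\n".join(seg_lines) + "\n")
    files["segmentation"] = seg_path.name

    pwm_path = outdir / "pwms.txt"
    map_path = outdir / "motif_map.tsv"
    with open(pwm_path, "w") as pf, open(map_path, "w") as mf:
        mf.write("motif_id\ttf_symbol\n")
        for tf in crc_tfs:
            pf.write(f">{tf}.M1\n")
            for row in crc_counts[tf]:
                pf.write("\t".join(f"{int(x)}" for x in row) + "\n")
            mf.write(f"{tf}.M1\t{tf}\n")
        for i, counts in enumerate(decoy_counts):
            sym = f"EXT{i + 1:02d}"
            pf.write(f">{sym}.M1\n")
            for row in counts:
                pf.write("\t".join(f"{int(x)}" for x in row) + "\n")
            mf.write(f"{sym}.M1\t{sym}\n")
    files["pwms"] = pwm_path.name
    files["motif_map"] = map_path.name

    gmt_path = outdir / "pathways.gmt"
    gmt_path.write_text("\n".join(gmt_lines) + "\n")
    files["pathways"] = gmt_path.name

    truth = SyntheticTruth(
        crc_tfs=crc_tfs,
        autoregulatory=autoregulatory,
        crc_motif_ids={tf: f"{tf}.M1" for tf in crc_tfs},
        decoy_motif_ids=[f"EXT{i + 1:02d}.M1" for i in range(cfg.n_decoy_motifs)],
        motif_placements=placements,
        site_classes=[
            {"chrom": c, "center": p_, "class": cls} for c, p_, cls in sites
        ],
        planted_pathway=planted_pathway,
        config=asdict(cfg),
        files=files,
    )
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(asdict(truth), indent=1, sort_keys=True) + "\n")

    _write_pipeline_config(cfg, outdir, files, sorted(tf_peaks))
    return truth


def _write_pipeline_config(
    cfg: SyntheticConfig, outdir: Path, files: dict[str, str], tf_symbols: list[str]
) -> None:
    """Emit a ready-to-run pipeline config with paths relative to the bundle."""
    import yaml

    config = {
        "genome": files["genome"],
        "genes": files["genes"],
        "genes_format": "gtf",
        "peaks": {reg: files[reg] for reg in ("MED1", "SMC1A", "NIPBL", "CTCF")},
        "tf_peaks": {tf: files[f"TF_{tf}"] for tf in tf_symbols},
        "segmentation": files["segmentation"],
        "pwms": files["pwms"],
        "motif_map": files["motif_map"],
        "pathways": files["pathways"],
        "params": {
            "k": 20,
            "upstream": 10000,
            "threshold_quantile": 0.9999,
            "pseudocount": 0.8,
            "assignment_max_distance": 50000,
            "clustering_linkage": "average",
            "seed": int(cfg.seed),
        },
        "manual_candidates": [],
        "outdir": "results",
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def load_bundle(outdir: str | Path) -> Bundle:
    """Load a generated bundle back into pipeline-ready objects."""
    from circuitscan.intervals import read_bed, read_genes

    outdir = Path(outdir)
    truth = json.loads((outdir / "truth.json").read_text())
    files = truth["files"]
    cofactors = {
        reg: read_bed(outdir / files[reg], regulator=reg)
        for reg in ("MED1", "SMC1A", "NIPBL")
    }
    ctcf = read_bed(outdir / files["CTCF"], regulator="CTCF")
    tf_sets = {}
    for key, fname in files.items():
        if key.startswith("TF_"):
            sym = key[3:]
            tf_sets[sym] = read_bed(outdir / fname, regulator=sym)
    genes = read_genes(outdir / files["genes"], format="gtf")
    chrom_sizes = {}
    for line in (outdir / files["chrom_sizes"]).read_text().splitlines():
        chrom, size = line.split("\t")
        chrom_sizes[chrom] = int(size)
    return Bundle(
        outdir=outdir,
        cofactors=cofactors,
        ctcf=ctcf,
        tf_sets=tf_sets,
        genes=genes,
        genome_fasta=outdir / files["genome"],
        segmentation_bed=outdir / files["segmentation"],
        pwms_path=outdir / files["pwms"],
        motif_map_path=outdir / files["motif_map"],
        gmt_path=outdir / files["pathways"],
        chrom_sizes=chrom_sizes,
    )
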