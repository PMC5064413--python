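"""Shared fixtures: small deterministic synthetic bundles and toy inputs."""

from __future__ import annotations

import numpy as np
import pytest

from circuitscan.intervals import GenomicInterval, RegionSet
from circuitscan.synth import SyntheticConfig, generate_bundle, load_bundle


def small_config(seed: int = 7, **overrides) -> SyntheticConfig:
    """A reduced bundle: one 400 kb chromosome, 12 genes, 5 decoy TFs."""
    kw = dict(
        seed=seed,
        n_chroms=1,
        chrom_length=400_000,
        n_genes=12,
        n_crc_tfs=3,
        n_decoy_tfs=5,
        n_decoy_motifs=8,
        n_cofactor_sites=60,
        n_peaks_per_decoy=30,
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    truth = generate_bundle(small_config(), outdir)
    return load_bundle(outdir), truth


def random_region_set(
    rng: np.random.Generator,
    n: int,
    name: str = "x",
    chroms: tuple[str, ...] = ("chr1", "chr2"),
    span: int = 1000,
    max_len: int = 60,
) -> RegionSet:
    """Random intervals on a small coordinate range (per-base oracles stay cheap)."""
    ivs = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span - 1))
        end = start + int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, min(end, span)))
    return RegionSet(name, ivs)


def coverage_mask(rs: RegionSet, chroms=("chr1", "chr2"), span: int = 1000):
    """Per-base boolean membership arrays — the brute-force coverage oracle."""
    masks = {c: np.zeros(span, dtype=bool) for c in chroms}
    for iv in rs:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks
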