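"""Regulator co-occupancy analyses over an atomic-union occupancy matrix.

The substrate is a binary membership matrix: rows are the merged union of all
input peak sets ("union regions"), columns are regulators, M[r, c] = 1 iff
union region r overlaps at least one peak of regulator c.  On top of it sit
the genome-wide structure analyses: a PCA variable-factor map with
per-regulator score densities on component 1, pairwise Pearson correlations,
the CTCF-based partition of Cohesin (SMC1A) peaks, chromatin-state overlap
profiles against a segmentation, and a clustered pairwise colocalization
matrix.

PCA columns are centered but not variance-scaled: all variables live on a
common 0/1 scale.  The sign of each principal component is fixed by forcing
the lexicographically smallest regulator to have a non-negative variable
coordinate, removing the SVD sign ambiguity.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from circuitscan.intervals import (
    GenomicInterval,
    RegionSet,
    UndefinedInputError,
    merge,
    overlap_fraction,
)

UNANNOTATED = "unannotated"


@dataclass
class OccupancyMatrix:
    regions: RegionSet  # merged union of all input sets
    regulators: list[str]
    M: np.ndarray  # (n_regions, n_regulators) uint8

    def column(self, regulator: str) -> np.ndarray:
        return self.M[:, self.regulators.index(regulator)]


@dataclass
class PCAResult:
    region_scores: np.ndarray  # (n_regions, n_components)
    variable_coords: np.ndarray  # (n_regulators, n_components), in [-1, 1]
    explained: np.ndarray  # variance fraction per component, sums to 1
    regulators: list[str]
    dim1_grid: np.ndarray  # common evaluation grid for the densities
    dim1_density: dict[str, np.ndarray]  # per-regulator, max normalized to 1


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    R: float
    p: float


@dataclass
class StateOverlapProfile:
    regulator: str
    ratios: dict[str, float]  # state label -> fraction of occupied bases


@dataclass
class ColocalizationMatrix:
    regulators: list[str]
    F: np.ndarray  # F[i, j] = overlap_fraction(set_i, set_j); not symmetric
    order: list[int]  # leaf order from hierarchical clustering
    linkage_method: str = "average"
    distance: str = "1 - pearson"


def build_occupancy_matrix(sets: list[RegionSet]) -> OccupancyMatrix:
    """Binary membership of merged union regions across regulators.

    Union regions are the merged union of all peaks of all sets (no splitting
    at set boundaries); every row therefore overlaps >=1 regulator.
    """
    if len(sets) < 2:
        raise ValueError("build_occupancy_matrix requires >=2 region sets")
    union = merge(
        RegionSet("union", [iv for s in sets for iv in s.intervals])
    )
    M = np.zeros((len(union), len(sets)), dtype=np.uint8)
    for c, s in enumerate(sets):
        for r, iv in enumerate(union):
            if s.overlaps_interval(iv.chrom, iv.start, iv.end):
                M[r, c] = 1
    return OccupancyMatrix(union, [s.regulator for s in sets], M)


def pca_regulators(
    m: OccupancyMatrix, scale: bool = False, grid_points: int = 512
) -> PCAResult:
    """PCA of the occupancy matrix with a variable-factor map.

    Variable coordinates are the Pearson correlations between each (binary)
    regulator column and the region scores on each component.  For each
    regulator, the density of its member regions' component-1 scores is
    estimated (Gaussian KDE on a common grid) and rescaled so the curve's
    maximum is exactly 1.
    """
    n, p = m.M.shape
    if p < 2 or n < 3:
        raise ValueError("pca_regulators requires >=2 regulators and >=3 regions")
    X = m.M.astype(float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    zero_var = sd == 0
    if scale:
        X[:, ~zero_var] = X[:, ~zero_var] / sd[~zero_var]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U * S  # (n, k)
    # sign convention: lexicographically smallest regulator non-negative
    ref = int(np.argmin(np.asarray(m.regulators, dtype=object)))
    for k in range(len(S)):
        if Vt[k, ref] < 0:
            Vt[k, :] *= -1
            scores[:, k] *= -1
    with np.errstate(invalid="ignore"):
        total_var = (S**2).sum()
        explained = (S**2) / total_var if total_var > 0 else np.zeros_like(S)
    coords = np.zeros((p, len(S)))
    score_sd = scores.std(axis=0, ddof=0)
    for c in range(p):
        if zero_var[c]:
            warnings.warn(
                f"regulator {m.regulators[c]!r} has zero variance; "
                "variable coordinates set to 0"
            )
            continue
        for k in range(len(S)):
            if score_sd[k] == 0:
                continue
            coords[c, k] = float(
                np.dot(X[:, c], scores[:, k]) / (n * sd[c] * score_sd[k])
            )
    coords = np.clip(coords, -1.0, 1.0)
    d1 = scores[:, 0]
    pad = 0.05 * (d1.max() - d1.min() + 1e-12)
    grid = np.linspace(d1.min() - pad, d1.max() + pad, grid_points)
    densities: dict[str, np.ndarray] = {}
    for c, reg in enumerate(m.regulators):
        member = d1[m.M[:, c] == 1]
        if member.size < 2 or np.ptp(member) == 0:
            dens = np.zeros_like(grid)
            if member.size:
                dens[np.argmin(np.abs(grid - member[0]))] = 1.0
        else:
            kde = stats.gaussian_kde(member)
            dens = kde(grid)
            peak = dens.max()
            if peak > 0:
                dens = dens / peak
            else:  # all mass off-grid (degenerate); mark nearest point
                dens = np.zeros_like(grid)
                dens[np.argmin(np.abs(grid - member.mean()))] = 1.0
        densities[reg] = dens
    return PCAResult(scores, coords, explained, list(m.regulators), grid, densities)


def count_density_modes(
    density: np.ndarray, valley_depth: float = 0.2, min_height: float = 0.3
) -> int:
    """Count well-separated, substantial modes of a density curve.

    Two local maxima count as separate modes when the valley between them lies
    at least ``valley_depth`` (fraction) below both peaks; a maximum must also
    reach ``min_height`` of the curve maximum to count as a mode at all.  Used
    to detect the split (bimodal) component-1 distribution of Cohesin regions.
    """
    d = np.asarray(density, dtype=float)
    floor = min_height * d.max() if d.size else 0.0
    peaks = [
        i
        for i in range(1, len(d) - 1)
        if d[i] > d[i - 1] and d[i] >= d[i + 1] and d[i] >= floor
    ]
    if not peaks:
        return 1 if d.size else 0
    modes = [peaks[0]]
    for pk in peaks[1:]:
        valley = d[modes[-1] : pk + 1].min()
        if valley <= (1 - valley_depth) * min(d[modes[-1]], d[pk]):
            modes.append(pk)
        elif d[pk] > d[modes[-1]]:
            modes[-1] = pk
    return len(modes)


def regulator_correlation(m: OccupancyMatrix, a: str, b: str) -> CorrelationResult:
    """Pearson R between two binary occupancy columns, p from the t transform."""
    if a not in m.regulators or b not in m.regulators:
        raise KeyError(f"regulators {a!r}/{b!r} not both present")
    x = m.column(a).astype(float)
    y = m.column(b).astype(float)
    if x.std() == 0 or y.std() == 0:
        raise UndefinedInputError(
            f"correlation undefined: zero variance in {a!r} or {b!r}"
        )
    res = stats.pearsonr(x, y)
    return CorrelationResult((a, b), float(res.statistic), float(res.pvalue))


def partition_by_ctcf(
    smc1a: RegionSet, ctcf: RegionSet
) -> tuple[RegionSet, RegionSet]:
    """Split Cohesin (SMC1A) peaks into CTCF-occupied and CTCF-free subsets."""
    if len(smc1a) == 0:
        raise UndefinedInputError("partition_by_ctcf requires non-empty SMC1A set")
    with_ctcf: list[GenomicInterval] = []
    no_ctcf: list[GenomicInterval] = []
    for iv in smc1a:
        if ctcf.overlaps_interval(iv.chrom, iv.start, iv.end):
            with_ctcf.append(iv)
        else:
            no_ctcf.append(iv)
    return (
        RegionSet(f"{smc1a.regulator}_with_CTCF", with_ctcf, _presorted=True),
        RegionSet(f"{smc1a.regulator}_no_CTCF", no_ctcf, _presorted=True),
    )


def state_overlap_profile(
    rs: RegionSet, segmentation: list[tuple[GenomicInterval, str]]
) -> StateOverlapProfile:
    """Fraction of a regulator's occupied bases falling into each chromatin state.

    ``segmentation`` is a labeled, non-overlapping interval list (ChromHMM
    dense BED: column 4 is the state label).  Bases outside any segment
    accumulate under the reserved label ``"unannotated"``.  Ratios sum to 1.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for iv, label in segmentation:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, label))
    for chrom, segs in by_chrom.items():
        segs.sort()
        for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping segmentation intervals on {chrom}")
    covered = rs if rs.merged else merge(rs)
    bases: dict[str, int] = {}
    total = 0
    for iv in covered:
        total += len(iv)
        segs = by_chrom.get(iv.chrom, [])
        starts = [s for s, _, _ in segs]
        annotated = 0
        i = bisect.bisect_right(starts, iv.start) - 1
        i = max(i, 0)
        while i < len(segs) and segs[i][0] < iv.end:
            s, e, label = segs[i]
            ov = min(e, iv.end) - max(s, iv.start)
            if ov > 0:
                bases[label] = bases.get(label, 0) + ov
                annotated += ov
            i += 1
        rest = len(iv) - annotated
        if rest:
            bases[UNANNOTATED] = bases.get(UNANNOTATED, 0) + rest
    if total == 0:
        return StateOverlapProfile(rs.regulator, {})
    ratios = {label: n / total for label, n in sorted(bases.items())}
    return StateOverlapProfile(rs.regulator, ratios)


def read_segmentation(path) -> list[tuple[GenomicInterval, str]]:
    """Read a ChromHMM dense BED segmentation (column 4 = state label)."""
    from circuitscan.intervals import read_bed

    rs = read_bed(path, regulator="segmentation")
    out = []
    for iv in rs:
        if iv.name is None:
            raise ValueError(f"segmentation interval missing state label: {iv}")
        out.append((iv, iv.name))
    return out


def colocalization_matrix(sets: list[RegionSet]) -> ColocalizationMatrix:
    """Pairwise colocalization frequencies with a clustered display order.

    F[i, j] = overlap_fraction(set_i, set_j) (fraction of i's regions touched
    by j; not symmetric).  Rows are ordered by average-linkage hierarchical
    clustering with distance 1 - Pearson correlation between rows of F.
    """
    if len(sets) < 2:
        raise ValueError("colocalization_matrix requires >=2 region sets")
    n = len(sets)
    F = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                F[i, j] = overlap_fraction(sets[i], sets[j])
    if n == 2:
        order = [0, 1]
    else:
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(F)
        C = np.nan_to_num(C, nan=0.0)
        D = 1.0 - C
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        D = np.clip(D, 0.0, None)
        Z = linkage(squareform(D, checks=False), method="average")
        order = [int(i) for i in leaves_list(Z)]
    return ColocalizationMatrix([s.regulator for s in sets], F, order)
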