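"""Genealogical, geographic and genetic interpretation of network clusters.

Four interpretive tools:

* birth-location grids — ancestral birth annotations within a generation
  window, snapped to a 0.5-degree grid, tallied separately for cluster
  members and non-members;
* per-grid-point odds ratios contrasting member vs non-member annotation
  odds, with a minimum-annotation rule for plotting;
* kernel PCA of region-level IBD with the normalized kernel
  K(i, j) = t(i, j) / sqrt(d(i) d(j)), which removes the effect of
  variation in total within-region IBD;
* Hudson-style F_ST between clusters using the ratio-of-averages
  estimator with finite-sample correction, plus the closed-form
  single-ancestor IBD probability with a Monte Carlo gene-dropping check.

Generation 0 is the genotyped individual throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .ibdseg import PairwiseIBD
from .simpop import GenotypeMatrix, Pedigree

__all__ = [
    "grid_birth_locations",
    "location_odds_ratio",
    "region_kernel_pca",
    "pairwise_fst",
    "FstEstimate",
    "ibd_kinship_probability",
    "kinship_gene_drop_mc",
]


# ---------------------------------------------------------------------------
# Birth-location grids and odds ratios
# ---------------------------------------------------------------------------

def _snap(x: np.ndarray, step: float) -> np.ndarray:
    return np.round(np.asarray(x) / step) * step


def grid_birth_locations(
    ped: Pedigree,
    members: Iterable[str],
    generation_window: tuple[int, int] = (0, 9),
    grid_step: float = 0.5,
    cohort: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Tally ancestral birth annotations on a lat/lon grid.

    An annotation is one (genotyped individual, ancestor) link: for each
    genotyped sample, every pedigree ancestor (including the sample
    itself at generation 0) whose generation distance lies within
    ``generation_window`` contributes its birth location once. Locations
    are snapped to the nearest multiple of ``grid_step`` degrees; each
    grid point records member and non-member annotation counts and the
    mean lat/lon of its assigned annotations.

    ``cohort`` defaults to all genotyped individuals; ``members`` must be
    a subset of it.
    """
    lo, hi = generation_window
    if hi < lo:
        raise ValueError("invalid generation window")
    if cohort is None:
        cohort = [ind.id for ind in ped.genotyped()]
    members = set(members)
    rows = []
    n_missing = 0
    for iid in cohort:
        is_member = iid in members
        for anc_id, depth in ped.ancestors(iid).items():
            if not lo <= depth <= hi:
                continue
            anc = ped[anc_id]
            if anc.birth_lat is None or np.isnan(anc.birth_lat) or np.isnan(anc.birth_lon):
                n_missing += 1
                continue
            rows.append((anc.birth_lat, anc.birth_lon, is_member))
    if not rows:
        df = pd.DataFrame(
            columns=["grid_lat", "grid_lon", "mean_lat", "mean_lon", "a", "c"]
        )
        df.attrs["n_missing"] = n_missing
        return df
    ann = pd.DataFrame(rows, columns=["lat", "lon", "member"])
    ann["grid_lat"] = _snap(ann["lat"].to_numpy(), grid_step)
    ann["grid_lon"] = _snap(ann["lon"].to_numpy(), grid_step)
    g = ann.groupby(["grid_lat", "grid_lon"], as_index=False).agg(
        mean_lat=("lat", "mean"),
        mean_lon=("lon", "mean"),
        a=("member", "sum"),
        c=("member", lambda s: int((~s).sum())),
    )
    g["a"] = g["a"].astype(int)
    g.attrs["n_missing"] = n_missing
    return g


def location_odds_ratio(grid: pd.DataFrame, min_annotations: int = 10) -> pd.DataFrame:
    """Per-grid-point odds ratio of member vs non-member annotations.

    OR = (a / (A - a)) / (c / (C - c)) where a, c are the point's member
    and non-member counts and A, C the grid-wide totals. A
    Haldane-Anscombe +0.5 correction is applied to all four cells when
    any is zero. Points with fewer than ``min_annotations`` member
    annotations keep their OR but are excluded from the plotted set
    (``plotted`` flag False).
    """
    out = grid.copy()
    A = float(out["a"].sum())
    C = float(out["c"].sum())
    a = out["a"].to_numpy(dtype=float)
    c = out["c"].to_numpy(dtype=float)
    b = A - a
    d = C - c
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a2, b2, c2, d2 = (np.where(zero, v + 0.5, v) for v in (a, b, c, d))
    flagged = (b2 <= 0) | (d2 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        orr = (a2 / b2) / (c2 / d2)
    out["odds_ratio"] = np.where(flagged, np.nan, orr)
    out["or_flagged"] = flagged
    out["plotted"] = (out["a"] >= min_annotations) & ~flagged
    return out


# ---------------------------------------------------------------------------
# Region-level kernel PCA
# ---------------------------------------------------------------------------

def region_kernel_pca(
    pairs: Iterable[PairwiseIBD],
    region_of: dict,
    min_total_cM: float = 12.0,
    n_components: int = 2,
    center: bool = True,
) -> pd.DataFrame:
    """Project regions onto principal components of cross-region IBD.

    Accumulates t(i, j), the total IBD between samples of regions i and j
    (t(i, i) = within-region IBD), counting only pairs sharing more than
    ``min_total_cM``. The kernel K(i, j) = t(i, j) / sqrt(d(i) d(j)) with
    d(i) = sum_j t(i, j) removes variation in overall regional IBD
    levels. K is (by default) double-centered and eigendecomposed; the
    returned scores are eigenvector * sqrt(eigenvalue) per component.
    Regions with d(i) = 0 are dropped with a warning attribute.
    """
    regions = sorted(set(region_of.values()))
    idx = {r: i for i, r in enumerate(regions)}
    n = len(regions)
    if n < 2:
        raise ValueError("need at least two regions")
    t = np.zeros((n, n))
    for p in pairs:
        if p.total_cM <= min_total_cM:
            continue
        ra = region_of.get(p.sample_a)
        rb = region_of.get(p.sample_b)
        if ra is None or rb is None:
            continue
        i, j = idx[ra], idx[rb]
        t[i, j] += p.total_cM
        if i != j:
            t[j, i] += p.total_cM
    d = t.sum(axis=1)
    keep = d > 0
    dropped = [r for r, k in zip(regions, keep) if not k]
    t = t[np.ix_(keep, keep)]
    d = d[keep]
    kept_regions = [r for r, k in zip(regions, keep) if k]
    K = t / np.sqrt(np.outer(d, d))
    if center:
        nk = len(kept_regions)
        J = np.eye(nk) - np.ones((nk, nk)) / nk
        K = J @ K @ J
    vals, vecs = np.linalg.eigh(K)
    order = np.argsort(vals)[::-1][:n_components]
    vals, vecs = vals[order], vecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    sign_idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[sign_idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    scores = vecs * signs * np.sqrt(np.clip(vals, 0.0, None))
    df = pd.DataFrame(
        scores, index=pd.Index(kept_regions, name="region"),
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    df.attrs["eigenvalues"] = vals
    df.attrs["dropped_regions"] = dropped
    return df


def geography_correlation(scores: pd.DataFrame, coordinate: dict) -> float:
    """|Spearman rho| between PC1 score and a 1-d region coordinate."""
    coords = [coordinate[r] for r in scores.index]
    rho = spearmanr(scores["PC1"].to_numpy(), coords).statistic
    return float(abs(rho))


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstEstimate:
    """Ratio-of-averages Hudson F_ST between two groups of samples."""

    fst: float
    n_snps_used: int
    numerators: np.ndarray
    denominators: np.ndarray
    defined: bool = True


def hudson_fst_from_counts(
    ac1: np.ndarray, n1: np.ndarray, ac2: np.ndarray, n2: np.ndarray
) -> FstEstimate:
    """Hudson F_ST from alternate-allele counts and allele totals per SNP.

    Per-SNP numerator (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and
    denominator p1(1-p2) + p2(1-p1); the estimate is the ratio of their
    sums (ratio of averages), which adjusts for sample-size differences.
    """
    p1 = ac1 / n1
    p2 = ac2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    total_den = float(den.sum())
    if total_den == 0:
        return FstEstimate(np.nan, len(num), num, den, defined=False)
    return FstEstimate(float(num.sum() / total_den), len(num), num, den)


def pairwise_fst(
    genotypes: GenotypeMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    call_rate_min: float = 0.95,
) -> FstEstimate:
    """Hudson ratio-of-averages F_ST between two clusters of samples.

    Missing genotypes (coded 255 in the haplotype matrix) are excluded;
    SNPs with call rate below ``call_rate_min`` in either group are
    dropped. Monomorphic-everywhere input yields an undefined estimate
    (flagged, F_ST = NaN).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two samples per cluster")
    idx = {s: i for i, s in enumerate(genotypes.samples)}
    ia = [idx[s] for s in group_a]
    ib = [idx[s] for s in group_b]
    acs, ns = [], []
    for rows in (ia, ib):
        hap_rows = np.array([[2 * i, 2 * i + 1] for i in rows]).ravel()
        H = np.concatenate(
            [genotypes.haplotypes[c][hap_rows] for c in genotypes.gmap.ids], axis=1
        )
        called = H != 255
        acs.append((H * called).sum(axis=0).astype(float))
        ns.append(called.sum(axis=0).astype(float))
    ac1, ac2 = acs
    n1, n2 = ns
    ok = (n1 >= call_rate_min * 2 * len(ia)) & (n2 >= call_rate_min * 2 * len(ib))
    ok &= (n1 > 1) & (n2 > 1)
    return hudson_fst_from_counts(ac1[ok], n1[ok], ac2[ok], n2[ok])


# ---------------------------------------------------------------------------
# Single-ancestor IBD probability
# ---------------------------------------------------------------------------

def ibd_kinship_probability(g_a: int, g_b: int) -> float:
    """P(a locus is IBD) for two descendants of one shared common ancestor.

    One ancestor, one connecting path, with the two descendants g_a and
    g_b meioses below it: the first meiosis on each side necessarily
    transmits one of the ancestor's two alleles; every further meiosis
    retains it with probability 1/2, and the two sides must pick the same
    allele (probability 1/2). Hence (1/2)^(g_a + g_b - 1). For
    g_a = g_b = 4 this is 1/128, just under 1%.
    """
    if g_a < 1 or g_b < 1:
        raise ValueError("each descendant must be at least one meiosis below the ancestor")
    return 0.5 ** (g_a + g_b - 1)


def kinship_gene_drop_mc(g_a: int, g_b: int, n_reps: int = 100_000, seed: int = 0) -> float:
    """Monte Carlo check of :func:`ibd_kinship_probability` by gene dropping.

    Drops a single locus down two independent lineages: each lineage
    first inherits one of the ancestor's two allele copies at random,
    then keeps it through each subsequent meiosis with probability 1/2
    (otherwise the lineage carries a non-ancestral allele). Returns the
    fraction of replicates where both descendants carry the same
    ancestral copy.
    """
    rng = np.random.default_rng(seed)

    def _descend(g: int) -> np.ndarray:
        # which ancestral copy (0/1) survives to the descendant; -1 = lost
        copy = rng.integers(0, 2, n_reps)
        survive = np.ones(n_reps, dtype=bool)
        for _ in range(g - 1):
            survive &= rng.random(n_reps) < 0.5
        return np.where(survive, copy, -1)

    a = _descend(g_a)
    b = _descend(g_b)
    return float(np.mean((a >= 0) & (a == b)))
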