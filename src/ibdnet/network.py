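"""Construction of the weighted IBD network.

Each pair's total shared IBD (cM) is mapped to an edge weight in [0, 1]
through a Beta cumulative distribution function. The weight is meant to
approximate the probability that a pair's IBD total reflects a recent
familial relationship — a common ancestor within a few generations
(at most ``max_meioses`` reproductive events apart). The curve can be
calibrated on gene-dropped simulations where each pair's true meiosis
count is known; the default shape parameters are alpha=2, beta=200.

Two thresholds structure the network: pairs sharing no more than
``include_threshold_cM`` (12 cM) get no edge at all, and edges above
``family_threshold_cM`` (72 cM) — close relatives — are removed before
clustering so that extended families do not masquerade as populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ibdseg import PairwiseIBD

__all__ = [
    "EdgeWeightModel",
    "weight",
    "calibrate_weight_curve",
    "CalibrationResult",
    "build_graph",
    "write_edge_list",
    "read_edge_list",
]

#: Total autosomal genetic length (cM) of the human sex-averaged map; the
#: default Beta-argument scale is one diploid genome, 2 x this value.
HUMAN_AUTOSOMAL_CM = 3560.0


@dataclass(frozen=True)
class EdgeWeightModel:
    """Beta-CDF weight function with inclusion/family thresholds.

    ``scale_cM`` normalizes a total-cM value into the Beta argument; the
    default is a diploid genome length, under which BetaCDF(12 cM) is a
    few percent — pairs at the inclusion threshold carry little weight.
    """

    alpha: float = 2.0
    beta: float = 200.0
    scale_cM: float = 2.0 * HUMAN_AUTOSOMAL_CM
    include_threshold_cM: float = 12.0
    family_threshold_cM: float = 72.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if self.scale_cM <= 0:
            raise ValueError("scale_cM must be positive")


def weight(total_cM, model: EdgeWeightModel | None = None):
    """Edge weight in [0, 1] for a pair's total IBD.

    Zero at or below the inclusion threshold; otherwise the Beta CDF of
    ``total_cM / scale_cM``. Vectorized over array input; non-decreasing.
    """
    if model is None:
        model = EdgeWeightModel()
    x = np.asarray(total_cM, dtype=float)
    if np.any(x < 0):
        raise ValueError("total_cM must be non-negative")
    w = stats.beta.cdf(np.clip(x / model.scale_cM, 0.0, 1.0), model.alpha, model.beta)
    w = np.where(x <= model.include_threshold_cM, 0.0, np.clip(w, 0.0, 1.0))
    return float(w) if np.isscalar(total_cM) or np.ndim(total_cM) == 0 else w


@dataclass
class CalibrationResult:
    alpha: float
    beta: float
    scale_cM: float
    curve: pd.DataFrame  # columns: bin_lo, bin_hi, bin_mid, n_pairs, total_cM, frac_recent
    sse: float

    def model(self, base: EdgeWeightModel | None = None) -> EdgeWeightModel:
        base = base or EdgeWeightModel()
        return EdgeWeightModel(
            alpha=self.alpha,
            beta=self.beta,
            scale_cM=self.scale_cM,
            include_threshold_cM=base.include_threshold_cM,
            family_threshold_cM=base.family_threshold_cM,
        )


def calibrate_weight_curve(
    totals_cM: Sequence[float],
    meioses: Sequence[float],
    bins: Sequence[float] | int = 30,
    max_meioses: int = 8,
    scale_cM: float | None = None,
    fit: bool = True,
) -> CalibrationResult:
    """Empirical recent-relationship curve and Beta-CDF fit.

    For pairs binned by total IBD, computes the proportion of total IBD
    length contributed by pairs separated by at most ``max_meioses``
    reproductive events, then (optionally) least-squares fits a Beta CDF
    (in ``total_cM / scale_cM``) to the binned curve, weighting bins by
    their IBD mass. Pairs with unknown meiosis count (None/NaN) are
    treated as distant. Empty bins are skipped.
    """
    totals = np.asarray(totals_cM, dtype=float)
    mei = np.array(
        [np.inf if m is None else float(m) for m in meioses], dtype=float
    )
    if totals.shape != mei.shape:
        raise ValueError("totals and meioses must have the same length")
    recent = mei <= max_meioses
    if isinstance(bins, int):
        edges = np.linspace(0.0, max(totals.max(), 1.0), bins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (totals >= lo) & (totals < hi)
        if not sel.any():
            continue
        mass = totals[sel].sum()
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "bin_mid": 0.5 * (lo + hi),
                "n_pairs": int(sel.sum()),
                "total_cM": float(mass),
                "frac_recent": float(totals[sel][recent[sel]].sum() / mass) if mass > 0 else 0.0,
            }
        )
    curve = pd.DataFrame(rows)
    if scale_cM is None:
        scale_cM = EdgeWeightModel().scale_cM
    alpha, beta_, sse = 2.0, 200.0, np.nan
    if fit and len(curve) >= 2 and curve["frac_recent"].nunique() > 1:
        x = curve["bin_mid"].to_numpy() / scale_cM
        y = curve["frac_recent"].to_numpy()
        wts = curve["total_cM"].to_numpy()
        wts = wts / wts.sum()

        def _loss(theta):
            a, b = np.exp(theta)
            return np.sum(wts * (stats.beta.cdf(x, a, b) - y) ** 2)

        res = optimize.minimize(_loss, np.log([2.0, 200.0]), method="Nelder-Mead")
        alpha, beta_ = np.exp(res.x)
        sse = float(res.fun)
    elif fit and len(curve):
        # degenerate curve (all 0 or all 1): keep defaults, record the SSE
        y = curve["frac_recent"].to_numpy()
        x = curve["bin_mid"].to_numpy() / scale_cM
        sse = float(np.mean((stats.beta.cdf(x, alpha, beta_) - y) ** 2))
    return CalibrationResult(
        alpha=float(alpha), beta=float(beta_), scale_cM=float(scale_cM), curve=curve, sse=sse
    )


def build_graph(
    pairs: Iterable[PairwiseIBD],
    model: EdgeWeightModel | None = None,
    exclude_family: bool = True,
    vertices: Iterable[str] | None = None,
) -> nx.Graph:
    """Build the weighted IBD network from pairwise totals.

    Edges exist for pairs with total IBD above the inclusion threshold;
    with ``exclude_family`` (the default used before clustering and
    spectral analysis), pairs above the family threshold are dropped as
    close relatives. Graph attributes record the connected components and
    flag the largest one as the analysis network.
    """
    if model is None:
        model = EdgeWeightModel()
    G = nx.Graph()
    if vertices is not None:
        G.add_nodes_from(vertices)
    for p in pairs:
        if p.total_cM <= model.include_threshold_cM:
            continue
        if exclude_family and p.total_cM > model.family_threshold_cM:
            continue
        G.add_edge(
            p.sample_a, p.sample_b, total_cM=p.total_cM, weight=weight(p.total_cM, model)
        )
    components = sorted(nx.connected_components(G), key=lambda c: (-len(c), min(c) if c else ""))
    G.graph["n_components"] = len(components)
    G.graph["largest_component"] = sorted(components[0]) if components else []
    G.graph["model"] = model
    return G


def largest_component_subgraph(G: nx.Graph) -> nx.Graph:
    return G.subgraph(G.graph["largest_component"]).copy()


EDGE_COLUMNS = ["sample_a", "sample_b", "total_cM", "weight"]


def write_edge_list(path: str, G: nx.Graph) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for a, b in sorted(tuple(sorted(e)) for e in G.edges):
            d = G.edges[a, b]
            fh.write(f"{a}\t{b}\t{d['total_cM']!r}\t{d['weight']!r}\n")


def read_edge_list(path: str, model: EdgeWeightModel | None = None) -> nx.Graph:
    G = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != EDGE_COLUMNS:
            raise ValueError(f"{path}:1: unexpected edge-list header")
        for lineno, line in enumerate(fh, 2):
            f = line.rstrip("\n").split("\t")
            if len(f) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            G.add_edge(f[0], f[1], total_cM=float(f[2]), weight=float(f[3]))
    components = sorted(nx.connected_components(G), key=lambda c: (-len(c), min(c) if c else ""))
    G.graph["n_components"] = len(components)
    G.graph["largest_component"] = sorted(components[0]) if components else []
    if model is not None:
        G.graph["model"] = model
    return G
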