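"""Independent reference implementations used only to check the package.

Everything here is deliberately written by the most direct route
available — grid scans, exhaustive enumeration, quadrature, per-locus
simulation — and shares no code path with the implementations under
test.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import integrate


# ---------------------------------------------------------------------------
# Brute-force maximal-exact-match scanner (detector oracle)
# ---------------------------------------------------------------------------

def _true_runs(eq: np.ndarray):
    """Maximal runs of True in a boolean vector as (start, end) half-open."""
    padded = np.concatenate(([False], eq, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def _contains_full_word(s: int, e: int, bits: int, n_words: int) -> bool:
    w = -(-s // bits)  # first word starting at or after s
    return w < n_words and (w + 1) * bits <= e


def brute_force_segments(gm, bits: int, min_m: float):
    """All maximal exactly-shared runs containing >=1 full word, per pair.

    Scans every one of the four haplotype pairings per sample pair
    position-by-position, keeps runs that contain at least one complete
    word of ``bits`` SNPs, union-merges runs per pair (overlapping or
    touching in SNP space) and filters to genetic length >= ``min_m``.
    Returns a sorted list of (sample_a, sample_b, chrom, start_snp,
    end_snp) tuples.
    """
    out = []
    n = gm.n_samples
    for chrom in gm.gmap.ids:
        H = gm.haplotypes[chrom]
        pos = gm.positions[chrom]
        n_words = H.shape[1] // bits
        if n_words == 0:
            continue
        for i, j in itertools.combinations(range(n), 2):
            runs = []
            for a in (2 * i, 2 * i + 1):
                for b in (2 * j, 2 * j + 1):
                    for s, e in _true_runs(H[a] == H[b]):
                        if _contains_full_word(s, e, bits, n_words):
                            runs.append((s, e))
            merged = []
            for s, e in sorted(runs):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            sa, sb = sorted((gm.samples[i], gm.samples[j]))
            for s, e in merged:
                if pos[e - 1] - pos[s] >= min_m:
                    out.append((sa, sb, chrom, s, e))
    return sorted(out)


# ---------------------------------------------------------------------------
# Grid-scan ground-truth IBD oracle
# ---------------------------------------------------------------------------

def grid_ibd_total(mosaic_a, mosaic_b, gmap, resolution: float = 0.01) -> float:
    """Total any-haplotype IBD between two mosaics by dense position scan."""
    total = 0.0
    for c, (_, length) in enumerate(gmap.chromosomes):
        x = np.arange(resolution / 2, length, resolution)
        labs_a = [lab[np.searchsorted(brk, x, side="right") - 1] for brk, lab in mosaic_a[c]]
        labs_b = [lab[np.searchsorted(brk, x, side="right") - 1] for brk, lab in mosaic_b[c]]
        shared = np.zeros(len(x), dtype=bool)
        for la in labs_a:
            for lb in labs_b:
                shared |= la == lb
        total += shared.sum() * resolution
    return float(total)


# ---------------------------------------------------------------------------
# Union-find connected components
# ---------------------------------------------------------------------------

def union_find_components(vertices, edges):
    parent = {v: v for v in vertices}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for v in vertices:
        comps.setdefault(find(v), set()).add(v)
    return sorted((frozenset(c) for c in comps.values()), key=lambda c: (-len(c), min(c)))


# ---------------------------------------------------------------------------
# Exhaustive modularity maximization (tiny graphs)
# ---------------------------------------------------------------------------

def _set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def modularity_matrix_form(G, partition: dict) -> float:
    """Q from the double-sum (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta."""
    import networkx as nx

    nodes = sorted(G.nodes)
    A = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    k = A.sum(axis=1)
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    labels = np.array([partition[v] for v in nodes], dtype=object)
    delta = labels[:, None] == labels[None, :]
    return float(((A - np.outer(k, k) / two_m) * delta).sum() / two_m)


def exhaustive_best_partition(G):
    """Globally optimal modularity partition by enumerating set partitions."""
    nodes = sorted(G.nodes)
    best_q, best_p = -np.inf, None
    for part in _set_partitions(nodes):
        p = {v: i for i, blk in enumerate(part) for v in blk}
        q = modularity_matrix_form(G, p)
        if q > best_q:
            best_q, best_p = q, p
    return best_q, best_p


# ---------------------------------------------------------------------------
# Quadrature incomplete beta (weight-function oracle)
# ---------------------------------------------------------------------------

def beta_cdf_quad(x: float, a: float, b: float) -> float:
    """Beta CDF via adaptive quadrature of the density."""
    from scipy.special import betaln

    if x <= 0:
        return 0.0
    if x >= 1:
        return 1.0
    norm = np.exp(-betaln(a, b))
    val, _ = integrate.quad(
        lambda t: norm * t ** (a - 1) * (1 - t) ** (b - 1), 0.0, x, epsabs=1e-14, limit=200
    )
    return float(val)


# ---------------------------------------------------------------------------
# Per-locus sib-sharing oracle
# ---------------------------------------------------------------------------

def sib_sharing_per_locus(n_reps: int, seed: int = 0) -> float:
    """Fraction of loci where full sibs share >=1 parental allele IBD.

    Direct per-locus simulation: each sib independently inherits one of
    two paternal and one of two maternal alleles; sharing occurs when the
    paternal or the maternal picks coincide. (Closed form: 3/4.)
    """
    rng = np.random.default_rng(seed)
    pat = rng.integers(0, 2, (2, n_reps))
    mat = rng.integers(0, 2, (2, n_reps))
    return float(np.mean((pat[0] == pat[1]) | (mat[0] == mat[1])))
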