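"""IBD segment detection between phased haplotypes.

Implements a word-hashing seed-and-extend detector in the style of
GERMLINE: each chromosome is sliced into consecutive non-overlapping
words of ``bits`` SNPs; haplotype words are matched exactly via a hash
table; matches seed segments that are extended SNP-by-SNP in both
directions while the haplotypes agree. Defaults reproduce the
parameterization ``bits=96, err_hom=0, err_het=0, min_m=5`` (no mismatch
tolerance, 5 cM minimum reported length).

Because seeds require a full matching word, shared runs containing no
complete word are undetectable by construction — the detector's
documented sensitivity floor.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IBDSegment",
    "PairwiseIBD",
    "DetectorParams",
    "detect_ibd",
    "aggregate_pairs",
    "read_match",
    "write_match",
    "detector_vs_truth",
    "merge_intervals",
]


@dataclass(frozen=True)
class IBDSegment:
    """A shared half-open cM interval between two samples.

    ``start_snp``/``end_snp`` are the first SNP index and one-past-last
    SNP index of the run (-1 when the segment is map-derived ground truth
    with no SNP support). ``sample_a < sample_b`` under string order.
    """

    sample_a: str
    sample_b: str
    chrom: str
    start_cM: float
    end_cM: float
    start_snp: int = -1
    end_snp: int = -1

    def __post_init__(self):
        if self.sample_a > self.sample_b:
            raise ValueError("sample_a must sort before sample_b")
        if self.end_cM <= self.start_cM:
            raise ValueError("segment must have positive genetic length")

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM

    @property
    def pair(self) -> tuple[str, str]:
        return (self.sample_a, self.sample_b)


@dataclass(frozen=True)
class PairwiseIBD:
    """Total IBD shared by one pair, summed over segments."""

    sample_a: str
    sample_b: str
    total_cM: float
    n_segments: int

    @property
    def pair(self) -> tuple[str, str]:
        return (self.sample_a, self.sample_b)


@dataclass(frozen=True)
class DetectorParams:
    bits: int = 96
    err_hom: int = 0
    err_het: int = 0
    min_m: float = 5.0

    def __post_init__(self):
        if self.bits < 1:
            raise ValueError("bits must be >= 1")
        if self.min_m <= 0:
            raise ValueError("min_m must be > 0")
        if self.err_hom != 0 or self.err_het != 0:
            raise NotImplementedError("mismatch tolerance is off by default and not implemented")


def merge_intervals(intervals: Iterable[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union-merge intervals; overlapping or touching intervals coalesce."""
    ivs = sorted(intervals)
    out: list[tuple[float, float]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _consecutive_runs(words: Sequence[int]) -> list[tuple[int, int]]:
    runs = []
    ws = sorted(words)
    start = prev = ws[0]
    for w in ws[1:]:
        if w == prev + 1:
            prev = w
        else:
            runs.append((start, prev))
            start = prev = w
    runs.append((start, prev))
    return runs


def _extend(ha: np.ndarray, hb: np.ndarray, s: int, e: int) -> tuple[int, int]:
    """Grow [s, e) while the two haplotypes agree exactly."""
    mism_left = np.nonzero(ha[:s] != hb[:s])[0]
    s2 = int(mism_left[-1]) + 1 if len(mism_left) else 0
    mism_right = np.nonzero(ha[e:] != hb[e:])[0]
    e2 = e + (int(mism_right[0]) if len(mism_right) else len(ha) - e)
    return s2, e2


def detect_ibd(genotypes, params: DetectorParams | None = None) -> list[IBDSegment]:
    """Detect IBD segments among all sample pairs of a phased genotype matrix.

    For every pair of haplotypes (from different samples) that share at
    least one full word exactly, the match is extended in both directions
    with zero mismatch tolerance; calls from the four haplotype pairings
    of a sample pair are union-merged into maximal SNP intervals, and
    merged intervals of genetic length >= ``min_m`` cM are reported,
    sorted by (pair, chrom, start).

    Word contents are compared through ``np.packbits`` keys, an exact
    encoding of the 0/1 alleles, so seeding never admits collisions.
    """
    if params is None:
        params = DetectorParams()
    if not genotypes.phased:
        raise ValueError("detector requires phased haplotypes")
    bits = params.bits
    segments: list[IBDSegment] = []
    samples = genotypes.samples
    for chrom in genotypes.gmap.ids:
        H = genotypes.haplotypes[chrom]
        pos = genotypes.positions[chrom]
        n_snps = H.shape[1]
        n_words = n_snps // bits
        if n_words == 0:
            logger.info(
                "chrom %s: %d SNPs shorter than one %d-SNP word; no calls", chrom, n_snps, bits
            )
            continue
        packed = {}
        hap_matches: dict[tuple[int, int], list[int]] = defaultdict(list)
        for w in range(n_words):
            word = np.packbits(H[:, w * bits : (w + 1) * bits], axis=1)
            buckets: dict[bytes, list[int]] = defaultdict(list)
            for h in range(word.shape[0]):
                buckets[word[h].tobytes()].append(h)
            for haps in buckets.values():
                if len(haps) < 2:
                    continue
                for i in range(len(haps)):
                    for j in range(i + 1, len(haps)):
                        a, b = haps[i], haps[j]
                        if a // 2 != b // 2:  # skip within-sample pairings
                            hap_matches[(a, b)].append(w)
        del packed
        pair_ivs: dict[tuple[int, int], list[tuple[int, int]]] = defaultdict(list)
        for (a, b), words in hap_matches.items():
            ha, hb = H[a], H[b]
            for w0, w1 in _consecutive_runs(words):
                s, e = _extend(ha, hb, w0 * bits, (w1 + 1) * bits)
                pair_ivs[tuple(sorted((a // 2, b // 2)))].append((s, e))
        for (ia, ib), ivs in pair_ivs.items():
            sa, sb = samples[ia], samples[ib]
            if sa > sb:
                sa, sb = sb, sa
            for s, e in merge_intervals(ivs):
                if pos[e - 1] - pos[s] >= params.min_m:
                    segments.append(
                        IBDSegment(
                            sample_a=sa, sample_b=sb, chrom=chrom,
                            start_cM=float(pos[s]), end_cM=float(pos[e - 1]),
                            start_snp=s, end_snp=e,
                        )
                    )
    segments.sort(key=lambda g: (g.sample_a, g.sample_b, g.chrom, g.start_cM))
    return segments


def aggregate_pairs(
    segments: Iterable[IBDSegment], min_total_cM: float = 5.0
) -> list[PairwiseIBD]:
    """Sum per-pair segment lengths; keep pairs with total > ``min_total_cM``."""
    totals: dict[tuple[str, str], list[float]] = defaultdict(list)
    for seg in segments:
        totals[seg.pair].append(seg.length_cM)
    out = [
        PairwiseIBD(sample_a=a, sample_b=b, total_cM=float(sum(ls)), n_segments=len(ls))
        for (a, b), ls in totals.items()
        if sum(ls) > min_total_cM
    ]
    out.sort(key=lambda p: p.pair)
    return out


MATCH_COLUMNS = [
    "sample_a", "sample_b", "chrom", "start_snp", "end_snp",
    "start_cM", "end_cM", "length_cM",
]


def write_match(path: str, segments: Iterable[IBDSegment]) -> None:
    """Write segments as a GERMLINE-style match TSV (deterministic order)."""
    segs = sorted(segments, key=lambda g: (g.sample_a, g.sample_b, g.chrom, g.start_cM))
    with open(path, "w") as fh:
        fh.write("\t".join(MATCH_COLUMNS) + "\n")
        for g in segs:
            fh.write(
                f"{g.sample_a}\t{g.sample_b}\t{g.chrom}\t{g.start_snp}\t{g.end_snp}\t"
                f"{g.start_cM!r}\t{g.end_cM!r}\t{g.length_cM!r}\n"
            )


def read_match(path: str) -> list[IBDSegment]:
    segments = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != MATCH_COLUMNS:
            raise ValueError(f"{path}:1: unexpected match header {header}")
        for lineno, line in enumerate(fh, 2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(MATCH_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(MATCH_COLUMNS)} columns")
            try:
                segments.append(
                    IBDSegment(
                        sample_a=f[0], sample_b=f[1], chrom=f[2],
                        start_cM=float(f[5]), end_cM=float(f[6]),
                        start_snp=int(f[3]), end_snp=int(f[4]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return segments


def _reciprocal_overlap(a: IBDSegment, b: IBDSegment) -> float:
    ov = min(a.end_cM, b.end_cM) - max(a.start_cM, b.start_cM)
    if ov <= 0:
        return 0.0
    return min(ov / a.length_cM, ov / b.length_cM)


def detector_vs_truth(
    detected: Sequence[IBDSegment],
    truth: Sequence[IBDSegment],
    min_cM: float = 0.0,
    bins: Sequence[float] = (0.0, 4.0, 6.0, 10.0, 20.0, np.inf),
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Precision/recall of detected segments by length bin.

    A detected and a truth segment match when they belong to the same pair
    and chromosome and have reciprocal overlap >= ``min_overlap``. Truth
    segments are binned by their own length for recall; detected segments
    by theirs for precision.
    """
    truth = [t for t in truth if t.length_cM >= min_cM]
    detected = [d for d in detected if d.length_cM >= min_cM]
    by_key: dict[tuple, list[IBDSegment]] = defaultdict(list)
    for d in detected:
        by_key[(d.pair, d.chrom)].append(d)
    truth_hit = []
    det_hit = {id(d): False for d in detected}
    for t in truth:
        hit = False
        for d in by_key.get((t.pair, t.chrom), []):
            if _reciprocal_overlap(d, t) >= min_overlap:
                hit = True
                det_hit[id(d)] = True
        truth_hit.append(hit)
    edges = np.asarray(bins, dtype=float)
    rows = []
    t_len = np.array([t.length_cM for t in truth])
    d_len = np.array([d.length_cM for d in detected])
    t_hit = np.array(truth_hit, dtype=bool)
    d_hit_arr = np.array([det_hit[id(d)] for d in detected], dtype=bool)
    for lo, hi in zip(edges[:-1], edges[1:]):
        t_in = (t_len >= lo) & (t_len < hi)
        d_in = (d_len >= lo) & (d_len < hi)
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "n_truth": int(t_in.sum()),
                "n_detected": int(d_in.sum()),
                "recall": float(t_hit[t_in].mean()) if t_in.any() else np.nan,
                "precision": float(d_hit_arr[d_in].mean()) if d_in.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)
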