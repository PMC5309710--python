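"""Synthetic multi-deme pedigrees with gene-dropped genomes.

Everything downstream of this module (segment detection, network
construction, clustering, spectral analysis, annotation) is exercised on
data produced here: a discrete-generation pedigree with demes, migration
and birth annotations; founder-labelled chromosome mosaics propagated by
recombination ("gene dropping"); ground-truth IBD segments derived from
those mosaics; and biallelic SNP genotypes painted onto the mosaics under
a Balding-Nichols allele-frequency model so that IBD segments are
identical by state.

Conventions
-----------
* Genetic positions are in centimorgans (cM); intervals are half-open
  ``[start, end)``; chromosome ids are strings ("1", "2", ...).
* Generation 0 is the most recent (genotyped) generation; founders sit at
  generation ``n_generations``.
* Crossovers follow a Haldane model: a Poisson process with rate one
  crossover per Morgan (100 cM), no interference, and a fair coin for the
  starting parental haplotype.
"""

from __future__ import annotations

import itertools
import os
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .ibdseg import IBDSegment, merge_intervals, read_match, write_match

__all__ = [
    "GeneticMap",
    "Individual",
    "Pedigree",
    "GenotypeMatrix",
    "default_map",
    "full_scale_map",
    "simulate_pedigree",
    "gene_drop",
    "mosaic_total_length",
    "true_ibd_segments",
    "paint_genotypes",
    "simulate_balding_nichols",
    "write_fixtures",
    "read_fixtures",
    "read_pedigree_table",
    "read_genotypes",
]


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """Chromosome lengths in cM."""

    chromosomes: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        for cid, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {cid} has non-positive length {length}")

    @property
    def total_cM(self) -> float:
        return float(sum(length for _, length in self.chromosomes))

    @property
    def ids(self) -> list[str]:
        return [cid for cid, _ in self.chromosomes]

    def length(self, chrom: str) -> float:
        for cid, ln in self.chromosomes:
            if cid == chrom:
                return ln
        raise KeyError(chrom)


def default_map(n_chrom: int = 10, length_cM: float = 150.0) -> GeneticMap:
    """Desk-scale map: 10 chromosomes x 150 cM (1,500 cM total)."""
    return GeneticMap(tuple((str(i + 1), length_cM) for i in range(n_chrom)))


def full_scale_map() -> GeneticMap:
    """Autosome-scale map: 22 chromosomes of ~160 cM."""
    return GeneticMap(tuple((str(i + 1), 160.0) for i in range(22)))


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    id: str
    father_id: str | None
    mother_id: str | None
    generation: int
    deme: str
    birth_year: int
    birth_lat: float
    birth_lon: float

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """Discrete-generation pedigree over a set of demes.

    ``demes`` maps deme name -> (lat, lon) centroid; ``migration_rate`` is
    the probability that a mate pair is cross-deme.
    """

    individuals: dict[str, Individual]
    demes: dict[str, tuple[float, float]]
    migration_rate: float = 0.0

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[iid]

    def by_generation(self, g: int) -> list[Individual]:
        return [ind for ind in self.individuals.values() if ind.generation == g]

    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals.values() if ind.is_founder]

    def genotyped(self) -> list[Individual]:
        """Generation-0 individuals (the 'samples')."""
        return self.by_generation(0)

    def mate_pairs(self) -> set[tuple[str, str]]:
        return {
            (ind.father_id, ind.mother_id)
            for ind in self.individuals.values()
            if not ind.is_founder
        }

    def cross_deme_fraction(self) -> float:
        """Fraction of mate pairs whose members live in different demes."""
        pairs = self.mate_pairs()
        if not pairs:
            return 0.0
        cross = sum(
            self.individuals[f].deme != self.individuals[m].deme for f, m in pairs
        )
        return cross / len(pairs)

    def ancestors(self, iid: str) -> dict[str, int]:
        """All ancestors of ``iid`` with minimal depth in meioses (self = 0)."""
        depths: dict[str, int] = {iid: 0}
        frontier = [iid]
        while frontier:
            nxt = []
            for cur in frontier:
                ind = self.individuals[cur]
                for pid in (ind.father_id, ind.mother_id):
                    if pid is None:
                        continue
                    d = depths[cur] + 1
                    if pid not in depths or d < depths[pid]:
                        depths[pid] = d
                        nxt.append(pid)
            frontier = nxt
        return depths

    def meioses_between(self, a: str, b: str) -> int | None:
        """Minimal number of meioses on a path through a common ancestor.

        Returns None for pairs with no common ancestor in the pedigree.
        """
        da, db = self.ancestors(a), self.ancestors(b)
        common = set(da) & set(db)
        if not common:
            return None
        return min(da[c] + db[c] for c in common)

    def validate(self) -> None:
        for ind in self.individuals.values():
            has_f, has_m = ind.father_id is not None, ind.mother_id is not None
            if has_f != has_m:
                raise ValueError(f"{ind.id}: exactly two parents or none required")
            if ind.deme not in self.demes:
                raise ValueError(f"{ind.id}: unknown deme {ind.deme}")
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    continue
                parent = self.individuals[pid]
                if parent.generation != ind.generation + 1:
                    raise ValueError(
                        f"{ind.id}: parent {pid} not in generation {ind.generation + 1}"
                    )


def simulate_pedigree(
    demes: dict[str, tuple[float, float]] | list[str],
    deme_sizes: dict[str, int] | int,
    n_generations: int,
    migration_rate: float = 0.0,
    seed: int = 0,
    reference_year: int = 2000,
    years_per_generation: int = 25,
    location_jitter: float = 0.1,
    topology: str = "island",
) -> Pedigree:
    """Simulate a discrete-generation multi-deme pedigree with random mating.

    Each generation of each deme holds ``deme_sizes[deme]`` individuals.
    Within a deme and generation, parents are paired monogamously at
    random; with probability ``migration_rate`` a pair is cross-deme, its
    second member drawn from another deme (uniformly under the default
    "island" topology, from an adjacent deme under "line", which yields a
    one-dimensional stepping-stone arrangement). Children are assigned to
    their deme's pairs uniformly at random.

    Birth year is ``reference_year - years_per_generation * generation``;
    birth location is the deme centroid plus Gaussian jitter of scale
    ``location_jitter`` degrees. Deterministic given ``seed``.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if isinstance(demes, list):
        demes = {name: (0.0, float(i)) for i, name in enumerate(demes)}
    deme_names = list(demes)
    if isinstance(deme_sizes, int):
        deme_sizes = {name: deme_sizes for name in deme_names}
    for name in deme_names:
        if deme_sizes[name] < 2:
            raise ValueError(f"deme {name} has size {deme_sizes[name]} < 2; no mate available")
    if topology not in ("island", "line"):
        raise ValueError(f"unknown topology {topology!r}")

    rng = np.random.default_rng(seed)
    individuals: dict[str, Individual] = {}

    def _make(iid, gen, deme, father=None, mother=None):
        lat, lon = demes[deme]
        individuals[iid] = Individual(
            id=iid,
            father_id=father,
            mother_id=mother,
            generation=gen,
            deme=deme,
            birth_year=reference_year - years_per_generation * gen,
            birth_lat=lat + rng.normal(0.0, location_jitter),
            birth_lon=lon + rng.normal(0.0, location_jitter),
        )

    # founders
    by_deme: dict[str, list[str]] = {}
    for deme in deme_names:
        ids = [f"g{n_generations}_{deme}_{i}" for i in range(deme_sizes[deme])]
        for iid in ids:
            _make(iid, n_generations, deme)
        by_deme[deme] = ids

    for gen in range(n_generations - 1, -1, -1):
        pairs_by_deme: dict[str, list[tuple[str, str]]] = {}
        for deme in deme_names:
            pool = list(by_deme[deme])
            rng.shuffle(pool)
            pairs = []
            for i in range(0, len(pool) - 1, 2):
                p1, p2 = pool[i], pool[i + 1]
                if len(deme_names) > 1 and rng.random() < migration_rate:
                    if topology == "island":
                        others = [d for d in deme_names if d != deme]
                        src = others[rng.integers(len(others))]
                    else:  # line: adjacent deme
                        k = deme_names.index(deme)
                        choices = [j for j in (k - 1, k + 1) if 0 <= j < len(deme_names)]
                        src = deme_names[choices[rng.integers(len(choices))]]
                    p2 = by_deme[src][rng.integers(len(by_deme[src]))]
                pairs.append((p1, p2))
            pairs_by_deme[deme] = pairs
        nxt: dict[str, list[str]] = {}
        for deme in deme_names:
            pairs = pairs_by_deme[deme]
            ids = []
            for i in range(deme_sizes[deme]):
                father, mother = pairs[rng.integers(len(pairs))]
                iid = f"g{gen}_{deme}_{i}"
                _make(iid, gen, deme, father, mother)
                ids.append(iid)
            nxt[deme] = ids
        by_deme = nxt

    ped = Pedigree(individuals=individuals, demes=dict(demes), migration_rate=migration_rate)
    ped.validate()
    return ped


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

# A haplotype mosaic for one chromosome: (breaks, labels), where breaks is a
# sorted float array of segment start positions (breaks[0] == 0) and labels
# the founder-haplotype label of each segment; segment i covers
# [breaks[i], breaks[i+1]) with the last running to the chromosome end.
Haplotype = tuple[np.ndarray, np.ndarray]
# Per individual: list over chromosomes of (paternal hap, maternal hap).
Mosaic = list[tuple[Haplotype, Haplotype]]


def _founder_hap(label: int) -> Haplotype:
    return np.array([0.0]), np.array([label], dtype=np.int64)


def _recombine(h0: Haplotype, h1: Haplotype, length: float, rng) -> Haplotype:
    """One meiosis: Haldane crossovers between the two parental haplotypes."""
    k = int(rng.poisson(length / 100.0))
    cur = int(rng.integers(2))
    haps = (h0, h1)
    if k == 0:
        b, l = haps[cur]
        return b.copy(), l.copy()
    bounds = np.empty(k + 2)
    bounds[0], bounds[-1] = 0.0, length
    bounds[1:-1] = np.sort(rng.uniform(0.0, length, k))
    out_b, out_l = [], []
    for i in range(k + 1):
        s, e = bounds[i], bounds[i + 1]
        if e > s:
            b, l = haps[cur]
            i0 = int(np.searchsorted(b, s, side="right")) - 1
            i1 = int(np.searchsorted(b, e, side="left"))
            seg_b = b[i0:i1].copy()
            seg_b[0] = s
            out_b.append(seg_b)
            out_l.append(l[i0:i1])
        cur ^= 1
    breaks = np.concatenate(out_b)
    labels = np.concatenate(out_l)
    keep = np.ones(len(labels), dtype=bool)
    keep[1:] = labels[1:] != labels[:-1]
    return breaks[keep], labels[keep]


def gene_drop(ped: Pedigree, gmap: GeneticMap, seed: int = 0) -> dict[str, Mosaic]:
    """Drop founder-labelled chromosomes down the pedigree.

    Founder haplotypes get globally unique integer labels (2k and 2k+1 for
    the k-th founder in pedigree insertion order); every transmission
    recombines the parent's two haplotypes under the Haldane model.
    Returns, per individual, a mosaic tiling each chromosome on both
    haplotypes.

    Randomness is consumed in pedigree insertion order (stable-sorted by
    decreasing generation), which does not depend on what the individuals
    are called: relabelling individuals and mapping the output back
    yields identical mosaics.
    """
    rng = np.random.default_rng(seed)
    mosaics: dict[str, Mosaic] = {}
    founder_ids = [ind.id for ind in ped.individuals.values() if ind.is_founder]
    for k, fid in enumerate(founder_ids):
        mosaics[fid] = [
            (_founder_hap(2 * k), _founder_hap(2 * k + 1)) for _ in gmap.chromosomes
        ]
    # children in order of decreasing generation so parents come first;
    # sort is stable, so insertion order breaks ties within a generation
    order = sorted(
        (ind for ind in ped.individuals.values() if not ind.is_founder),
        key=lambda ind: -ind.generation,
    )
    for ind in order:
        mos: Mosaic = []
        pat, mat = mosaics[ind.father_id], mosaics[ind.mother_id]
        for c, (_, length) in enumerate(gmap.chromosomes):
            from_father = _recombine(pat[c][0], pat[c][1], length, rng)
            from_mother = _recombine(mat[c][0], mat[c][1], length, rng)
            mos.append((from_father, from_mother))
        mosaics[ind.id] = mos
    return mosaics


def mosaic_total_length(mosaic: Mosaic, gmap: GeneticMap) -> float:
    """Total labelled length over both haplotypes (= 2 x map total if tiled)."""
    total = 0.0
    for (h0, h1), (_, length) in zip(mosaic, gmap.chromosomes):
        for breaks, _labels in (h0, h1):
            segs = np.diff(np.append(breaks, length))
            total += float(segs.sum())
    return total


# ---------------------------------------------------------------------------
# Ground-truth IBD
# ---------------------------------------------------------------------------

def _hap_segments(hap: Haplotype, length: float):
    breaks, labels = hap
    ends = np.append(breaks[1:], length)
    return zip(labels.tolist(), breaks.tolist(), ends.tolist())


def true_ibd_segments(
    mosaics: dict[str, Mosaic],
    gmap: GeneticMap,
    min_cM: float = 0.0,
    samples: list[str] | None = None,
) -> list[IBDSegment]:
    """Ground-truth IBD segments among ``samples`` from one gene_drop call.

    For each pair and chromosome, returns the maximal half-open intervals
    where any of the four haplotype combinations carries the same founder
    label, union-merged per pair and filtered to length >= ``min_cM``.

    Indexed by founder label so the cost scales with actual sharing rather
    than with the number of pairs.
    """
    if samples is None:
        samples = sorted(mosaics)
    sample_set = set(samples)
    out: list[IBDSegment] = []
    for c, (chrom, length) in enumerate(gmap.chromosomes):
        # founder label -> sample -> merged carrier intervals
        carriers: dict[int, dict[str, list[tuple[float, float]]]] = defaultdict(dict)
        for s in samples:
            per_label: dict[int, list[tuple[float, float]]] = defaultdict(list)
            for hap in mosaics[s][c]:
                for label, st, en in _hap_segments(hap, length):
                    per_label[label].append((st, en))
            for label, ivs in per_label.items():
                carriers[label][s] = merge_intervals(ivs)
        pair_ivs: dict[tuple[str, str], list[tuple[float, float]]] = defaultdict(list)
        for label, by_sample in carriers.items():
            if len(by_sample) < 2:
                continue
            items = sorted(by_sample.items())
            for (sa, iva), (sb, ivb) in itertools.combinations(items, 2):
                for s1, e1 in iva:
                    for s2, e2 in ivb:
                        s, e = max(s1, s2), min(e1, e2)
                        if e > s:
                            pair_ivs[(sa, sb)].append((s, e))
        for (sa, sb), ivs in sorted(pair_ivs.items()):
            for s, e in merge_intervals(ivs):
                if e - s >= min_cM and e > s:
                    out.append(
                        IBDSegment(
                            sample_a=sa, sample_b=sb, chrom=chrom,
                            start_cM=s, end_cM=e, start_snp=-1, end_snp=-1,
                        )
                    )
    out.sort(key=lambda seg: (seg.sample_a, seg.sample_b, seg.chrom, seg.start_cM))
    del sample_set
    return out


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Phased biallelic genotypes on a genetic map.

    ``haplotypes[chrom]`` is a (2n, n_snps) uint8 array; rows 2i and 2i+1
    are the two haplotypes of ``samples[i]``. ``positions[chrom]`` holds
    strictly increasing cM positions.
    """

    samples: list[str]
    gmap: GeneticMap
    positions: dict[str, np.ndarray]
    haplotypes: dict[str, np.ndarray]
    deme_of_sample: dict[str, str] = field(default_factory=dict)
    ancestral_freq: dict[str, np.ndarray] = field(default_factory=dict)
    deme_freq: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    phased: bool = True

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def hap(self, sample: str, which: int, chrom: str) -> np.ndarray:
        return self.haplotypes[chrom][2 * self.sample_index(sample) + which]

    def diploid(self, chrom: str) -> np.ndarray:
        """(n, n_snps) allele-count matrix (0/1/2)."""
        h = self.haplotypes[chrom]
        return h[0::2].astype(np.int16) + h[1::2].astype(np.int16)

    def allele_counts(self) -> np.ndarray:
        """(n, total_snps) allele counts concatenated over chromosomes."""
        return np.concatenate([self.diploid(c) for c in self.gmap.ids], axis=1)

    def validate(self) -> None:
        for chrom in self.gmap.ids:
            pos = self.positions[chrom]
            if len(pos) and not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on chrom {chrom}")
            if self.haplotypes[chrom].shape != (2 * self.n_samples, len(pos)):
                raise ValueError(f"haplotype shape mismatch on chrom {chrom}")

    def equals(self, other: "GenotypeMatrix") -> bool:
        if self.samples != other.samples or self.gmap != other.gmap:
            return False
        for chrom in self.gmap.ids:
            if not np.allclose(self.positions[chrom], other.positions[chrom]):
                return False
            if not np.array_equal(self.haplotypes[chrom], other.haplotypes[chrom]):
                return False
        return True


def _snp_positions(gmap: GeneticMap, n_snps: int, rng) -> dict[str, np.ndarray]:
    """Evenly spread jittered positions, strictly increasing per chromosome."""
    total = gmap.total_cM
    out = {}
    for chrom, length in gmap.chromosomes:
        n_c = max(1, int(round(n_snps * length / total)))
        h = length / n_c
        out[chrom] = (np.arange(n_c) + rng.uniform(0.0, 1.0, n_c)) * h
    return out


def _balding_nichols_freqs(p: np.ndarray, F: float, rng) -> np.ndarray:
    if F == 0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def paint_genotypes(
    mosaics: dict[str, Mosaic],
    ped: Pedigree,
    gmap: GeneticMap,
    n_snps: int,
    F: float = 0.0,
    seed: int = 0,
    samples: list[str] | None = None,
) -> GenotypeMatrix:
    """Paint SNP alleles onto gene-dropped mosaics.

    Ancestral frequencies are Uniform(0.05, 0.95); per-deme frequencies
    follow the Balding-Nichols model Beta(p(1-F)/F, (1-p)(1-F)/F) for
    differentiation F (F = 0 means no differentiation). Each founder
    haplotype draws its alleles from its deme's frequencies; descendants
    copy alleles through the mosaic, so IBD segments are identical by
    state.
    """
    if not 0.0 <= F < 1.0:
        raise ValueError("F must be in [0, 1)")
    rng = np.random.default_rng(seed)
    positions = _snp_positions(gmap, n_snps, rng)
    if samples is None:
        samples = sorted(ind.id for ind in ped.genotyped())

    chrom_ids = gmap.ids
    ancestral = {c: rng.uniform(0.05, 0.95, len(positions[c])) for c in chrom_ids}
    deme_freq = {}
    for deme in ped.demes:
        for c in chrom_ids:
            deme_freq[(deme, c)] = _balding_nichols_freqs(ancestral[c], F, rng)

    # founder haplotype label -> allele array per chromosome
    founder_ids = sorted(ind.id for ind in ped.founders())
    founder_alleles: dict[str, dict[int, np.ndarray]] = {c: {} for c in chrom_ids}
    for k, fid in enumerate(founder_ids):
        deme = ped[fid].deme
        for c in chrom_ids:
            q = deme_freq[(deme, c)]
            for label in (2 * k, 2 * k + 1):
                founder_alleles[c][label] = (
                    rng.random(len(q)) < q
                ).astype(np.uint8)

    haplotypes = {}
    for ci, c in enumerate(chrom_ids):
        pos = positions[c]
        H = np.empty((2 * len(samples), len(pos)), dtype=np.uint8)
        length = gmap.length(c)
        for si, s in enumerate(samples):
            for which in (0, 1):
                hap = mosaics[s][ci][which]
                row = H[2 * si + which]
                for label, st, en in _hap_segments(hap, length):
                    i0 = int(np.searchsorted(pos, st, side="left"))
                    i1 = int(np.searchsorted(pos, en, side="left"))
                    row[i0:i1] = founder_alleles[c][label][i0:i1]
        haplotypes[c] = H

    gm = GenotypeMatrix(
        samples=list(samples),
        gmap=gmap,
        positions=positions,
        haplotypes=haplotypes,
        deme_of_sample={s: ped[s].deme for s in samples},
        ancestral_freq=ancestral,
        deme_freq=deme_freq,
    )
    gm.validate()
    return gm


def simulate_balding_nichols(
    n_per_deme: int | dict[str, int],
    n_snps: int,
    F: float,
    seed: int = 0,
    demes: tuple[str, ...] = ("A", "B"),
    gmap: GeneticMap | None = None,
) -> GenotypeMatrix:
    """Unrelated diploid individuals drawn from Balding-Nichols deme frequencies.

    A pedigree-free shortcut for allele-frequency based statistics (e.g.
    F_ST calibration) where relatedness would only add noise.
    """
    if not 0.0 <= F < 1.0:
        raise ValueError("F must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if gmap is None:
        gmap = default_map()
    if isinstance(n_per_deme, int):
        n_per_deme = {d: n_per_deme for d in demes}
    positions = _snp_positions(gmap, n_snps, rng)
    ancestral = {c: rng.uniform(0.05, 0.95, len(positions[c])) for c in gmap.ids}
    deme_freq = {
        (d, c): _balding_nichols_freqs(ancestral[c], F, rng)
        for d in demes
        for c in gmap.ids
    }
    samples, deme_of = [], {}
    for d in demes:
        for i in range(n_per_deme[d]):
            s = f"{d}_{i}"
            samples.append(s)
            deme_of[s] = d
    haplotypes = {}
    for c in gmap.ids:
        rows = []
        for s in samples:
            q = deme_freq[(deme_of[s], c)]
            rows.append((rng.random((2, len(q))) < q).astype(np.uint8))
        haplotypes[c] = np.concatenate(rows, axis=0)
    gm = GenotypeMatrix(
        samples=samples,
        gmap=gmap,
        positions=positions,
        haplotypes=haplotypes,
        deme_of_sample=deme_of,
        ancestral_freq=ancestral,
        deme_freq=deme_freq,
    )
    gm.validate()
    return gm


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

PEDIGREE_COLUMNS = ["id", "father", "mother", "generation", "deme", "birth_year", "lat", "lon"]


def write_pedigree_table(path: str, ped: Pedigree) -> None:
    with open(path, "w") as fh:
        for deme, (lat, lon) in ped.demes.items():
            fh.write(f"#DEME\t{deme}\t{lat!r}\t{lon!r}\n")
        fh.write(f"#MIGRATION\t{ped.migration_rate!r}\n")
        fh.write("\t".join(PEDIGREE_COLUMNS) + "\n")
        for iid in sorted(ped.individuals):
            ind = ped.individuals[iid]
            fh.write(
                "\t".join(
                    [
                        ind.id,
                        ind.father_id or ".",
                        ind.mother_id or ".",
                        str(ind.generation),
                        ind.deme,
                        str(ind.birth_year),
                        repr(ind.birth_lat),
                        repr(ind.birth_lon),
                    ]
                )
                + "\n"
            )


def read_pedigree_table(path: str) -> Pedigree:
    demes: dict[str, tuple[float, float]] = {}
    migration = 0.0
    individuals: dict[str, Individual] = {}
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#DEME\t"):
                _, name, lat, lon = line.split("\t")
                demes[name] = (float(lat), float(lon))
                continue
            if line.startswith("#MIGRATION\t"):
                migration = float(line.split("\t")[1])
                continue
            if not header_seen:
                if line.split("\t") != PEDIGREE_COLUMNS:
                    raise ValueError(f"{path}:{lineno}: unexpected pedigree header")
                header_seen = True
                continue
            f = line.split("\t")
            if len(f) != len(PEDIGREE_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(PEDIGREE_COLUMNS)} columns")
            individuals[f[0]] = Individual(
                id=f[0],
                father_id=None if f[1] == "." else f[1],
                mother_id=None if f[2] == "." else f[2],
                generation=int(f[3]),
                deme=f[4],
                birth_year=int(f[5]),
                birth_lat=float(f[6]),
                birth_lon=float(f[7]),
            )
    return Pedigree(individuals=individuals, demes=demes, migration_rate=migration)


def _bp_positions(cm: np.ndarray) -> np.ndarray:
    """Map cM to strictly increasing integer bp for VCF POS (1 cM ~ 1 Mb)."""
    bp = np.round(cm * 1e6).astype(np.int64) + 1
    return np.maximum.accumulate(bp + np.arange(len(bp)))


def write_genotypes(prefix: str, gm: GenotypeMatrix) -> tuple[str, str]:
    """Write phased genotypes as a VCF-style file plus a cM map file.

    Returns (vcf_path, map_path). The map file has columns chrom, pos(bp),
    cM and preserves full float precision for the genetic positions.
    """
    vcf_path, map_path = prefix + ".vcf", prefix + ".map"
    with open(vcf_path, "w") as vcf, open(map_path, "w") as mp:
        vcf.write("##fileformat=VCFv4.2\n")
        vcf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in gm.gmap.chromosomes:
            vcf.write(f"##contig=<ID={chrom},length={int(length * 1e6) + 10**6}>\n")
        vcf.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        mp.write("chrom\tpos\tcM\n")
        for chrom in gm.gmap.ids:
            pos_cm = gm.positions[chrom]
            pos_bp = _bp_positions(pos_cm)
            H = gm.haplotypes[chrom]
            for j in range(len(pos_cm)):
                mp.write(f"{chrom}\t{pos_bp[j]}\t{float(pos_cm[j])!r}\n")
                gts = "\t".join(
                    f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(gm.n_samples)
                )
                vcf.write(
                    f"{chrom}\t{pos_bp[j]}\t{chrom}:{pos_bp[j]}\tA\tG\t.\t.\t.\tGT\t{gts}\n"
                )
    return vcf_path, map_path


def read_genotypes(vcf_path: str, map_path: str) -> GenotypeMatrix:
    """Read phased genotypes written by :func:`write_genotypes`."""
    from cyvcf2 import VCF

    cm_by_chrom: dict[str, list[float]] = defaultdict(list)
    with open(map_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["chrom", "pos", "cM"]:
            raise ValueError(f"{map_path}: unexpected map header")
        for line in fh:
            chrom, _pos, cm = line.rstrip("\n").split("\t")
            cm_by_chrom[chrom].append(float(cm))

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    haps: dict[str, list[np.ndarray]] = defaultdict(list)
    for var in vcf:
        gt = np.asarray(var.genotype.array())
        if len(gt) and not np.all(gt[:, 2] == 1):
            raise ValueError(f"unphased genotypes at {var.CHROM}:{var.POS}")
        haps[var.CHROM].append(gt[:, :2].astype(np.uint8).reshape(-1))
    vcf.close()

    chrom_order = list(cm_by_chrom)
    positions = {c: np.asarray(cm_by_chrom[c]) for c in chrom_order}
    haplotypes = {}
    for c in chrom_order:
        if len(haps[c]) != len(positions[c]):
            raise ValueError(f"map/VCF SNP count mismatch on chrom {c}")
        haplotypes[c] = (
            np.column_stack(haps[c]) if haps[c] else np.empty((2 * len(samples), 0), np.uint8)
        )
    # chromosome length: smallest multiple of 10 cM holding the last SNP
    chroms = []
    for c in chrom_order:
        last = positions[c][-1] if len(positions[c]) else 0.0
        chroms.append((c, float(np.ceil(last / 10.0) * 10.0) if last else 10.0))
    gm = GenotypeMatrix(
        samples=samples,
        gmap=GeneticMap(tuple(chroms)),
        positions=positions,
        haplotypes=haplotypes,
    )
    gm.validate()
    return gm


def write_fixtures(
    out_dir: str,
    ped: Pedigree,
    gm: GenotypeMatrix | None = None,
    truth: list[IBDSegment] | None = None,
    force: bool = False,
) -> dict[str, str]:
    """Write pedigree, genotype and ground-truth-segment fixtures.

    Refuses to overwrite an existing fixture set unless ``force``. Returns
    a dict of artifact name -> path. Output is deterministic: identical
    inputs produce byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {"pedigree": os.path.join(out_dir, "pedigree.tsv")}
    if gm is not None:
        paths["vcf"] = os.path.join(out_dir, "genotypes.vcf")
        paths["map"] = os.path.join(out_dir, "genotypes.map")
    if truth is not None:
        paths["truth"] = os.path.join(out_dir, "truth.match")
    if not force:
        for p in paths.values():
            if os.path.exists(p):
                raise FileExistsError(f"{p} exists; pass force=True to overwrite")
    write_pedigree_table(paths["pedigree"], ped)
    if gm is not None:
        write_genotypes(os.path.join(out_dir, "genotypes"), gm)
    if truth is not None:
        write_match(paths["truth"], truth)
    return paths


def read_fixtures(out_dir: str) -> tuple[Pedigree, GenotypeMatrix | None, list[IBDSegment] | None]:
    ped = read_pedigree_table(os.path.join(out_dir, "pedigree.tsv"))
    gm = None
    vcf_path = os.path.join(out_dir, "genotypes.vcf")
    if os.path.exists(vcf_path):
        gm = read_genotypes(vcf_path, os.path.join(out_dir, "genotypes.map"))
    truth = None
    truth_path = os.path.join(out_dir, "truth.match")
    if os.path.exists(truth_path):
        truth = read_match(truth_path)
    return ped, gm, truth
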