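import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ibdnet import simpop

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_map():
    """2 chromosomes x 100 cM."""
    return simpop.GeneticMap((("1", 100.0), ("2", 100.0)))


@pytest.fixture(scope="session")
def small_cohort(small_map):
    """One 12-member deme, 3 generations, with mosaics and samples."""
    ped = simpop.simulate_pedigree(["A"], 12, 3, migration_rate=0.0, seed=7)
    mosaics = simpop.gene_drop(ped, small_map, seed=8)
    samples = sorted(ind.id for ind in ped.genotyped())
    return ped, mosaics, samples


@pytest.fixture(scope="session")
def painted(small_cohort, small_map):
    """Phased genotypes painted onto the small cohort (dense SNPs)."""
    ped, mosaics, samples = small_cohort
    return simpop.paint_genotypes(
        mosaics, ped, small_map, n_snps=2000, F=0.0, seed=9, samples=samples
    )


def sib_pedigree(n_families: int) -> simpop.Pedigree:
    """Independent founder couples, each with exactly two children."""
    individuals = {}
    for f in range(n_families):
        for p, pid in enumerate((f"fam{f}_dad", f"fam{f}_mum")):
            individuals[pid] = simpop.Individual(
                id=pid, father_id=None, mother_id=None, generation=1,
                deme="A", birth_year=1975, birth_lat=0.0, birth_lon=0.0,
            )
        for c in range(2):
            cid = f"fam{f}_kid{c}"
            individuals[cid] = simpop.Individual(
                id=cid, father_id=f"fam{f}_dad", mother_id=f"fam{f}_mum",
                generation=0, deme="A", birth_year=2000, birth_lat=0.0, birth_lon=0.0,
            )
    return simpop.Pedigree(individuals=individuals, demes={"A": (0.0, 0.0)})


def planted_block_graph(
    n_background: int = 200,
    n_block: int = 60,
    p_in: float = 0.15,
    p_background: float = 0.10,
    p_cross: float = 0.002,
    w_cross: float = 0.05,
    seed: int = 0,
):
    """A near-disconnected planted block attached to a homogeneous core."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    G = nx.Graph()
    bg = [f"bg{i}" for i in range(n_background)]
    blk = [f"blk{i}" for i in range(n_block)]
    G.add_nodes_from(bg + blk)
    for i in range(n_background):
        for j in range(i + 1, n_background):
            if rng.random() < p_background:
                G.add_edge(bg[i], bg[j], weight=1.0, total_cM=30.0)
    for i in range(n_block):
        for j in range(i + 1, n_block):
            if rng.random() < p_in:
                G.add_edge(blk[i], blk[j], weight=1.0, total_cM=30.0)
    for u in blk:
        for v in bg:
            if rng.random() < p_cross:
                G.add_edge(u, v, weight=w_cross, total_cM=13.0)
    # keep it connected for the embedding
    G.add_edge(blk[0], bg[0], weight=w_cross, total_cM=13.0)
    comps = sorted(__import__("networkx").connected_components(G), key=len, reverse=True)
    return G.subgraph(comps[0]).copy(), set(blk) & set(comps[0])
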