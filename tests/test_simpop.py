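"""Pedigree simulation, gene dropping, ground-truth IBD and genotype painting."""

import itertools

import numpy as np
import pytest

from ibdnet import simpop
from ibdnet.simpop import (
    GeneticMap,
    gene_drop,
    mosaic_total_length,
    paint_genotypes,
    simulate_pedigree,
    true_ibd_segments,
)

from .conftest import sib_pedigree
from .oracles import grid_ibd_total, sib_sharing_per_locus


class TestSimulatePedigree:
    def test_single_deme_one_generation(self):
        ped = simulate_pedigree(["A"], 4, 1, migration_rate=0.0, seed=1)
        assert len(ped) == 8
        assert len(ped.founders()) == 4
        assert len(ped.genotyped()) == 4
        assert {i.deme for i in ped.individuals.values()} == {"A"}
        for child in ped.genotyped():
            assert ped[child.father_id].generation == 1
            assert ped[child.mother_id].generation == 1

    def test_zero_migration_closure(self):
        ped = simulate_pedigree([f"D{i}" for i in range(5)], 6, 3, migration_rate=0.0, seed=3)
        for ind in ped.genotyped():
            deme = ind.deme
            assert all(ped[a].deme == deme for a in ped.ancestors(ind.id))

    def test_cross_deme_mating_rate(self):
        ped = simulate_pedigree(["A", "B"], 100, 5, migration_rate=0.1, seed=7)
        n_pairs = len(ped.mate_pairs())
        frac = ped.cross_deme_fraction()
        se = np.sqrt(0.1 * 0.9 / n_pairs)
        assert abs(frac - 0.1) < 3 * se

    def test_line_topology_migrates_to_neighbours_only(self):
        names = [f"D{i}" for i in range(5)]
        ped = simulate_pedigree(names, 20, 4, migration_rate=0.5, seed=5, topology="line")
        idx = {d: i for i, d in enumerate(names)}
        for f, m in ped.mate_pairs():
            assert abs(idx[ped[f].deme] - idx[ped[m].deme]) <= 1

    def test_rejects_tiny_deme(self):
        with pytest.raises(ValueError, match="no mate"):
            simulate_pedigree(["A"], 1, 1)

    def test_birth_annotations(self):
        ped = simulate_pedigree({"A": (40.0, -111.0)}, 4, 2, seed=2, location_jitter=0.05)
        for ind in ped.individuals.values():
            assert ind.birth_year == 2000 - 25 * ind.generation
            assert abs(ind.birth_lat - 40.0) < 1.0
            assert abs(ind.birth_lon + 111.0) < 1.0

    def test_deterministic_given_seed(self):
        p1 = simulate_pedigree(["A", "B"], 10, 3, migration_rate=0.2, seed=42)
        p2 = simulate_pedigree(["A", "B"], 10, 3, migration_rate=0.2, seed=42)
        assert p1.individuals == p2.individuals


class TestGeneDrop:
    def test_mosaics_tile_chromosomes(self, small_cohort, small_map):
        _, mosaics, _ = small_cohort
        for mos in mosaics.values():
            assert abs(mosaic_total_length(mos, small_map) - 2 * small_map.total_cM) < 1e-9
            for (h0, h1), (_, length) in zip(mos, small_map.chromosomes):
                for breaks, labels in (h0, h1):
                    assert breaks[0] == 0.0
                    assert np.all(np.diff(breaks) > 0)
                    assert breaks[-1] < length
                    assert len(breaks) == len(labels)

    def test_parent_child_full_transmission(self, small_map):
        ped = sib_pedigree(1)
        mosaics = gene_drop(ped, small_map, seed=1)
        segs = true_ibd_segments(
            mosaics, small_map, min_cM=0.0, samples=["fam0_dad", "fam0_kid0"]
        )
        total = sum(s.length_cM for s in segs)
        assert total == pytest.approx(small_map.total_cM, abs=1e-9)

    def test_founder_pair_shares_nothing(self, small_map):
        ped = sib_pedigree(2)
        mosaics = gene_drop(ped, small_map, seed=1)
        segs = true_ibd_segments(
            mosaics, small_map, min_cM=0.0, samples=["fam0_dad", "fam1_dad"]
        )
        assert segs == []

    def test_sib_sharing_matches_per_locus_oracle(self):
        # fraction of the genome where full sibs share >=1 allele IBD
        gmap = GeneticMap((("1", 3500.0),))  # genome-length chromosome
        n_fam = 200
        ped = sib_pedigree(n_fam)
        mosaics = gene_drop(ped, gmap, seed=11)
        fracs = []
        for f in range(n_fam):
            segs = true_ibd_segments(
                mosaics, gmap, min_cM=0.0, samples=[f"fam{f}_kid0", f"fam{f}_kid1"]
            )
            fracs.append(sum(s.length_cM for s in segs) / gmap.total_cM)
        fracs = np.array(fracs)
        oracle = sib_sharing_per_locus(200_000, seed=5)
        assert oracle == pytest.approx(0.75, abs=0.01)
        se = fracs.std(ddof=1) / np.sqrt(n_fam)
        assert abs(fracs.mean() - oracle) < 3 * se + 0.01

    def test_relabelling_equivariance(self, small_map):
        """Permuting ids (preserving insertion order) permutes outputs only."""
        ped = simulate_pedigree(["A"], 6, 2, seed=3)
        rename = {iid: f"x{k}" for k, iid in enumerate(ped.individuals)}
        individuals = {
            rename[i.id]: simpop.Individual(
                id=rename[i.id],
                father_id=None if i.father_id is None else rename[i.father_id],
                mother_id=None if i.mother_id is None else rename[i.mother_id],
                generation=i.generation, deme=i.deme, birth_year=i.birth_year,
                birth_lat=i.birth_lat, birth_lon=i.birth_lon,
            )
            for i in ped.individuals.values()
        }
        ped2 = simpop.Pedigree(individuals=individuals, demes=ped.demes)
        m1 = gene_drop(ped, small_map, seed=9)
        m2 = gene_drop(ped2, small_map, seed=9)
        for iid in ped.individuals:
            for (a0, a1), (b0, b1) in zip(m1[iid], m2[rename[iid]]):
                for ha, hb in ((a0, b0), (a1, b1)):
                    assert np.array_equal(ha[0], hb[0])
                    assert np.array_equal(ha[1], hb[1])


class TestTrueIBD:
    def test_identical_mosaics_tile_genome(self, small_cohort, small_map):
        _, mosaics, samples = small_cohort
        twin = dict(mosaics)
        twin["twin"] = mosaics[samples[0]]
        segs = true_ibd_segments(twin, small_map, min_cM=0.0, samples=[samples[0], "twin"])
        by_chrom = {c: 0.0 for c in small_map.ids}
        for s in segs:
            by_chrom[s.chrom] += s.length_cM
        for c, length in small_map.chromosomes:
            assert by_chrom[c] == pytest.approx(length, abs=1e-9)

    def test_totals_match_grid_scan_oracle(self, small_cohort, small_map):
        _, mosaics, samples = small_cohort
        segs = true_ibd_segments(mosaics, small_map, min_cM=0.0, samples=samples)
        totals = {}
        nseg = {}
        for s in segs:
            totals[s.pair] = totals.get(s.pair, 0.0) + s.length_cM
            nseg[s.pair] = nseg.get(s.pair, 0) + 1
        for a, b in itertools.combinations(samples[:8], 2):
            oracle = grid_ibd_total(mosaics[a], mosaics[b], small_map, resolution=0.01)
            got = totals.get((a, b), 0.0)
            tol = 0.02 * (nseg.get((a, b), 0) + 2)
            assert got == pytest.approx(oracle, abs=tol)

    def test_min_cm_filter_monotone(self, small_cohort, small_map):
        _, mosaics, samples = small_cohort
        all_segs = true_ibd_segments(mosaics, small_map, min_cM=0.0, samples=samples)
        filtered = true_ibd_segments(mosaics, small_map, min_cM=10.0, samples=samples)
        keys = {(s.pair, s.chrom, s.start_cM) for s in all_segs}
        assert all((s.pair, s.chrom, s.start_cM) in keys for s in filtered)
        assert all(s.length_cM >= 10.0 for s in filtered)


class TestPaintGenotypes:
    def test_no_differentiation_equal_freqs(self, small_map):
        gm = simpop.simulate_balding_nichols(50, 1000, F=0.0, seed=4, gmap=small_map)
        for c in small_map.ids:
            for d in ("A", "B"):
                assert np.array_equal(gm.deme_freq[(d, c)], gm.ancestral_freq[c])

    def test_copy_through_identity(self, small_cohort, small_map, painted):
        """Shared founder labels imply identical alleles over the interval."""
        _, mosaics, samples = small_cohort
        gm = painted
        segs = true_ibd_segments(mosaics, small_map, min_cM=5.0, samples=samples)
        for seg in segs[:20]:
            pos = gm.positions[seg.chrom]
            i0, i1 = np.searchsorted(pos, [seg.start_cM, seg.end_cM], side="left")
            i1 = max(i1 - 1, i0)  # interior SNPs only; boundaries may round out
            a, b = seg.sample_a, seg.sample_b
            match_any = np.zeros(i1 - i0, dtype=bool)
            for ha in (0, 1):
                for hb in (0, 1):
                    match_any |= (
                        gm.hap(a, ha, seg.chrom)[i0:i1] == gm.hap(b, hb, seg.chrom)[i0:i1]
                    )
            assert match_any.all()

    def test_positions_strictly_increasing(self, painted):
        for c in painted.gmap.ids:
            assert np.all(np.diff(painted.positions[c]) > 0)

    def test_rejects_bad_F(self, small_cohort, small_map):
        ped, mosaics, samples = small_cohort
        with pytest.raises(ValueError):
            paint_genotypes(mosaics, ped, small_map, 100, F=1.0, samples=samples)


class TestFixtureIO:
    def test_roundtrip(self, tmp_path, small_cohort, small_map, painted):
        ped, mosaics, samples = small_cohort
        truth = true_ibd_segments(mosaics, small_map, min_cM=5.0, samples=samples)
        simpop.write_fixtures(str(tmp_path), ped, painted, truth)
        ped2, gm2, truth2 = simpop.read_fixtures(str(tmp_path))
        assert ped2.individuals == ped.individuals
        assert ped2.demes == ped.demes
        assert gm2.samples == painted.samples
        for c in small_map.ids:
            assert np.array_equal(gm2.haplotypes[c], painted.haplotypes[c])
            np.testing.assert_allclose(gm2.positions[c], painted.positions[c])
        assert truth2 == truth

    def test_refuses_overwrite(self, tmp_path, small_cohort):
        ped, _, _ = small_cohort
        simpop.write_fixtures(str(tmp_path), ped)
        with pytest.raises(FileExistsError):
            simpop.write_fixtures(str(tmp_path), ped)
        simpop.write_fixtures(str(tmp_path), ped, force=True)

    def test_empty_pedigree_header_only(self, tmp_path):
        ped = simpop.Pedigree(individuals={}, demes={})
        simpop.write_fixtures(str(tmp_path), ped)
        lines = (tmp_path / "pedigree.tsv").read_text().splitlines()
        assert lines == ["#MIGRATION\t0.0", "\t".join(simpop.PEDIGREE_COLUMNS)]

    def test_byte_identical_across_runs(self, tmp_path, small_map):
        def _run(sub):
            ped = simulate_pedigree(["A", "B"], 10, 2, migration_rate=0.1, seed=21)
            mosaics = gene_drop(ped, small_map, seed=22)
            samples = sorted(i.id for i in ped.genotyped())
            gm = paint_genotypes(mosaics, ped, small_map, 500, F=0.05, seed=23, samples=samples)
            truth = true_ibd_segments(mosaics, small_map, min_cM=5.0, samples=samples)
            out = tmp_path / sub
            simpop.write_fixtures(str(out), ped, gm, truth)
            return {p.name: p.read_bytes() for p in out.iterdir()}

        assert _run("a") == _run("b")
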