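import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pbscan import gl as glmod
from pbscan.gl import (
    GenotypeLikelihoodTable,
    SiteRecord,
    compute_gl,
    compute_gl_table,
    estimate_maf_em,
    estimate_maf_table,
    filter_maf,
    read_beagle,
    read_vcf_gl,
    table_from_genotypes,
    write_beagle,
    write_vcf_gl,
    _maf_em_array,
)
from pbscan.simdata import SimulationConfig, simulate_dataset, simulate_reads

from _oracles import gl_triple_oracle


class TestComputeGL:
    def test_no_reads_is_uninformative(self):
        assert np.array_equal(compute_gl([], [], "A", "C"), np.ones(3))

    def test_single_major_read_frozen_values(self):
        # L(g) = (1 - g/2)(1 - eps) + (g/2)(eps/3), eps = 0.01
        gl = compute_gl(["A"], [20], "A", "C")
        assert np.allclose(gl, [1.0, 0.501684, 0.003367], atol=1e-6)

    def test_het_maximizes_major_plus_minor(self):
        gl = compute_gl(["A", "C"], [20, 20], "A", "C")
        assert gl.argmax() == 1

    def test_low_quality_and_foreign_bases_discarded(self):
        gl = compute_gl(["A", "G", "A"], [10, 40, 40], "A", "C")
        # only the last read survives (q>=20 and base in {A, C})
        expected = compute_gl(["A"], [40], "A", "C")
        assert np.allclose(gl, expected)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        st.lists(
            st.tuples(st.sampled_from("ACGT"), st.integers(20, 40)),
            min_size=0, max_size=6,
        )
    )
    def test_matches_chromosome_enumeration_oracle(self, reads):
        bases = [b for b, _ in reads]
        quals = [q for _, q in reads]
        fast = compute_gl(bases, quals, "A", "C")
        slow = gl_triple_oracle(bases, quals, "A", "C")
        assert np.allclose(fast, slow, atol=1e-12)

    def test_table_path_equals_per_read_path(self, small_dataset):
        _, _, pileup, table = small_dataset
        s = 3
        for i in range(5):
            mask = (pileup.site_idx == s) & (pileup.indiv == i)
            from pbscan.simdata import BASES

            trip = compute_gl(
                list(BASES[pileup.base[mask]]),
                pileup.qual[mask],
                pileup.sites["major"][s],
                pileup.sites["minor"][s],
            )
            assert np.allclose(table.gl[s, i], trip, atol=1e-12)


class TestMafEM:
    def test_all_homozygous_major_gives_zero(self):
        gl = np.tile([1.0, 0.0, 0.0], (10, 1))
        assert estimate_maf_em(gl).freq == pytest.approx(0.0, abs=1e-5)

    def test_certain_genotypes_give_count_over_2N(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 1])
        table = table_from_genotypes(g[:, None])  # individuals x 1 site
        maf = estimate_maf_table(table)
        assert maf[0] == pytest.approx(g.sum() / (2 * len(g)), abs=1e-6)

    def test_uninformative_site_reports_missing(self):
        gl = np.ones((5, 3))
        est = estimate_maf_em(gl)
        assert np.isnan(est.freq)

    def test_matches_grid_scan_oracle_on_low_coverage_data(self, rng):
        # true f = 0.3, N = 33, ~2x coverage
        g = rng.binomial(2, 0.3, size=(33, 1))
        pu = simulate_reads(g, 2.0, 0.01, rng)
        table = compute_gl_table(pu)
        est = estimate_maf_em(table.gl[0])
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-3)
        prior = np.stack([(1 - grid) ** 2, 2 * grid * (1 - grid), grid**2], axis=1)
        ll = np.log(np.einsum("ig,fg->if", table.gl[0], prior)).sum(axis=0)
        f_grid = grid[np.argmax(ll)]
        assert abs(est.freq - f_grid) <= 1e-3 + 1e-9

    def test_high_depth_estimate_equals_sample_frequency(self, rng):
        g = rng.binomial(2, 0.25, size=(20, 50))
        pu = simulate_reads(g, 30.0, 0.0, rng)
        # error-free depth-30 reads: quality is capped finite so GLs are one-hot
        table = compute_gl_table(pu)
        maf = estimate_maf_table(table, tol=1e-10, max_iter=500)
        truth = g.sum(axis=0) / (2 * g.shape[0])
        covered = (pu.depths() > 0).all(axis=1)
        assert np.allclose(maf[covered], truth[covered], atol=1e-6)

    def test_loglik_monotone_every_iteration(self, rng):
        gl = rng.random((20, 15, 3))
        gl /= gl.max(axis=2, keepdims=True)
        _, _, _, hist = _maf_em_array(gl, tol=0.0, max_iter=40, record_loglik=True)
        assert np.all(np.diff(hist, axis=0) >= -1e-10)


class TestFilterMaf:
    def _table_with_mafs(self, freqs, n=200, seed=0):
        rng = np.random.default_rng(seed)
        g = np.stack([rng.binomial(2, f, size=n) for f in freqs], axis=1)
        return table_from_genotypes(g)

    def test_threshold_is_strict(self):
        # exact MAF 0.05: 1 het among 10 individuals
        g = np.zeros((10, 1), dtype=int)
        g[0, 0] = 1
        table = table_from_genotypes(g)
        out = filter_maf(table, 0.05)
        assert out.n_sites == 0  # MAF exactly 0.05 removed

    def test_counts_kept_sites(self):
        g = np.zeros((10, 3), dtype=int)
        g[0, 1] = 1  # site 1: maf 0.05
        g[:4, 2] = 1  # site 2: maf 0.2
        table = table_from_genotypes(g)
        out = filter_maf(table, 0.05)
        assert out.n_sites == 1
        assert out.sites["pos"].iloc[0] == 3

    def test_zero_threshold_drops_only_monomorphic(self):
        g = np.zeros((10, 2), dtype=int)
        g[0, 1] = 1
        table = table_from_genotypes(g)
        out = filter_maf(table, 0.0)
        assert out.n_sites == 1


class TestIO:
    def test_beagle_round_trip(self, small_dataset, tmp_path):
        _, _, _, table = small_dataset
        path = tmp_path / "gl.beagle"
        write_beagle(table, path)
        back = read_beagle(path)
        assert np.allclose(back.gl, table.gl, rtol=1e-6, atol=1e-8)
        assert (back.sites["pos"].to_numpy() == table.sites["pos"].to_numpy()).all()
        assert (back.sites["chrom"].astype(str).to_numpy()
                == table.sites["chrom"].astype(str).to_numpy()).all()

    def test_marker_parsing(self, tmp_path):
        path = tmp_path / "one.beagle"
        path.write_text(
            "marker\tallele1\tallele2\tInd0\tInd0\tInd0\n"
            "1_155545\t0\t1\t1.0\t0.5\t0.01\n"
        )
        table = read_beagle(path)
        assert str(table.sites["chrom"][0]) == "1"
        assert table.sites["pos"][0] == 155545
        assert table.sites["major"][0] == "A" and table.sites["minor"][0] == "C"

    def test_malformed_column_count_rejected(self, tmp_path):
        path = tmp_path / "bad.beagle"
        path.write_text("marker\tallele1\tallele2\tInd0\tInd0\n1_5\t0\t1\t1.0\t0.5\n")
        with pytest.raises(ValueError, match="column"):
            read_beagle(path)

    def test_missing_triples_survive_round_trip(self, tmp_path):
        g = np.array([[0, -1], [1, 1]])  # ind 0 missing at site 2... shape ind x site
        table = table_from_genotypes(np.array([[0, -1], [1, 1]]))
        path = tmp_path / "m.beagle"
        write_beagle(table, path)
        back = read_beagle(path)
        assert np.array_equal(back.gl[1, 0], np.ones(3))

    def test_vcf_round_trip(self, small_dataset, tmp_path):
        _, _, _, table = small_dataset
        sub = table.subset_sites(np.arange(table.n_sites) < 50)
        path = tmp_path / "gl.vcf"
        write_vcf_gl(sub, path)
        back = read_vcf_gl(path)
        assert np.allclose(back.gl, sub.gl, rtol=1e-5, atol=1e-6)

    def test_multiallelic_record_rejected(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GL,Number=G,Type=Float,Description="GL">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tInd0\n"
            "1\t100\t.\tA\tC,G\t.\tPASS\t.\tGL\t0,-1,-2,-3,-4,-5\n"
        )
        with pytest.raises(ValueError, match="biallelic"):
            read_vcf_gl(path)

    def test_log10_encoding(self, tmp_path):
        gl = np.array([[[1.0, 0.5, 0.003367]]])
        table = GenotypeLikelihoodTable(
            sites=pd.DataFrame({"chrom": ["1"], "pos": [10], "major": ["A"], "minor": ["C"]}),
            gl=gl,
        )
        path = tmp_path / "enc.vcf"
        write_vcf_gl(table, path)
        line = [l for l in path.read_text().splitlines() if l.startswith("1\t")][0]
        vals = [float(x) for x in line.split("\t")[-1].split(",")]
        assert np.allclose(vals, [0.0, -0.30103, -2.47276], atol=1e-5)


def test_site_record_validation():
    with pytest.raises(ValueError):
        SiteRecord("1", 5, "A", "A")
    with pytest.raises(ValueError):
        SiteRecord("1", 0, "A", "C")
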