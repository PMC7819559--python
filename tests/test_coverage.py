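"""Coverage IO, destranding, filtering and uniting."""

import io

import numpy as np
import pandas as pd
import pytest

from urbmeth.coverage import (CoverageFormatError, filter_coverage, merge_strands,
                              read_coverage, relaxed_background, unite)


def _cov_file(text: str) -> io.StringIO:
    return io.StringIO(text)


class TestReadCoverage:
    def test_converts_one_based_and_sums_counts(self):
        df = read_coverage(_cov_file("chr1\t101\t101\t50.0\t5\t5\n"))
        assert df.iloc[0].pos == 100
        assert df.iloc[0].meth == 5
        assert df.iloc[0].total == 10

    def test_empty_file_gives_empty_frame(self):
        assert read_coverage(_cov_file("")).empty

    def test_zero_coverage_rows_dropped(self):
        df = read_coverage(_cov_file("chr1\t10\t10\t0.0\t0\t0\nchr1\t20\t20\t100.0\t3\t0\n"))
        assert list(df.pos) == [19]

    def test_malformed_line_names_line_number(self):
        with pytest.raises(CoverageFormatError, match="line 2"):
            read_coverage(_cov_file("chr1\t10\t10\t0.0\t1\t1\nchr1\txx\t20\t0.0\t1\t1\n"))

    def test_negative_counts_rejected(self):
        with pytest.raises(CoverageFormatError, match="negative"):
            read_coverage(_cov_file("chr1\t10\t10\t0.0\t5\t-1\n"))

    def test_inconsistent_percentage_warns_but_trusts_counts(self):
        with pytest.warns(UserWarning, match="counts trusted"):
            df = read_coverage(_cov_file("chr1\t10\t10\t90.0\t5\t5\n"))
        assert df.iloc[0].meth == 5 and df.iloc[0].total == 10


class TestMergeStrands:
    GENOME = {"chr1": "AACGTTACGT"}  # CpG units at 2 and 7

    def test_plus_and_minus_records_summed_into_one_unit(self):
        sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [2, 3],
                              "meth": [5, 3], "total": [10, 10]})
        out = merge_strands(sites, self.GENOME)
        assert len(out) == 1
        assert out.iloc[0].pos == 2
        assert out.iloc[0].meth == 8 and out.iloc[0].total == 20

    def test_single_strand_passes_through_at_unit_position(self):
        plus = merge_strands(pd.DataFrame({"chrom": ["chr1"], "pos": [7],
                                           "meth": [2], "total": [4]}), self.GENOME)
        minus = merge_strands(pd.DataFrame({"chrom": ["chr1"], "pos": [8],
                                            "meth": [2], "total": [4]}), self.GENOME)
        assert plus.iloc[0].pos == 7 and minus.iloc[0].pos == 7

    def test_merged_fraction_is_pooled_not_mean_of_fractions(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m1, m2 = rng.integers(0, 10, 2)
            t1, t2 = m1 + rng.integers(1, 10), m2 + rng.integers(1, 10)
            sites = pd.DataFrame({"chrom": "chr1", "pos": [2, 3],
                                  "meth": [m1, m2], "total": [t1, t2]})
            out = merge_strands(sites, self.GENOME)
            assert out.iloc[0].meth / out.iloc[0].total == pytest.approx((m1 + m2) / (t1 + t2))

    def test_total_reads_conserved(self):
        rng = np.random.default_rng(5)
        sites = pd.DataFrame({"chrom": "chr1", "pos": [2, 3, 7, 8],
                              "meth": rng.integers(0, 5, 4), "total": rng.integers(5, 9, 4)})
        out = merge_strands(sites, self.GENOME)
        assert out.total.sum() == sites.total.sum()

    def test_non_cpg_record_passes_with_warning(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [0], "meth": [1], "total": [2]})
        with pytest.warns(UserWarning, match="outside CpG context"):
            out = merge_strands(sites, self.GENOME)
        assert out.iloc[0].pos == 0

    def test_position_beyond_chromosome_end_raises(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [99], "meth": [1], "total": [2]})
        with pytest.raises(ValueError, match="beyond chromosome end"):
            merge_strands(sites, self.GENOME)


class TestFilterCoverage:
    def _sites(self, totals):
        return pd.DataFrame({"chrom": "chr1", "pos": np.arange(len(totals)),
                             "meth": 0, "total": totals})

    def test_below_ten_removed_ten_retained(self):
        out = filter_coverage(self._sites([9, 10, 11]), max_quantile=1.0)
        assert list(out.total) == [10, 11]

    def test_extreme_outlier_removed_by_quantile_cap(self):
        totals = np.full(10_000, 30)
        totals[1234] = 100_000
        out = filter_coverage(self._sites(totals))
        assert len(out) == 9_999
        expected_cap = np.quantile(totals, 0.999)
        assert (out.total <= expected_cap).all()

    def test_empty_input_empty_output(self):
        assert filter_coverage(self._sites([])).empty


def _toy_samples(n=4):
    ids = [f"u{i}" for i in range(n // 2)] + [f"f{i}" for i in range(n // 2)]
    return pd.DataFrame({"sample_id": ids,
                         "habitat": ["urban"] * (n // 2) + ["forest"] * (n // 2),
                         "tissue": "liver"})


def _toy_sample_sites(n_samples=4, n_sites=100, drop_for=None, drop_n=0, seed=0):
    rng = np.random.default_rng(seed)
    out = {}
    samples = _toy_samples(n_samples)
    for sid in samples.sample_id:
        df = pd.DataFrame({"chrom": "chr1", "pos": np.arange(n_sites) * 50,
                           "meth": rng.integers(0, 10, n_sites),
                           "total": rng.integers(10, 30, n_sites)})
        if sid == drop_for:
            df = df.iloc[drop_n:]
        out[sid] = df.reset_index(drop=True)
    return out, samples


class TestUnite:
    def test_intersection_across_samples(self):
        sites, samples = _toy_sample_sites(drop_for="u0", drop_n=10)
        m = unite(sites, samples, min_coverage=1, max_quantile=1.0)
        assert m.n_sites == 90

    def test_single_shared_site(self):
        sites, samples = _toy_sample_sites(n_sites=1)
        m = unite(sites, samples, min_coverage=1, max_quantile=1.0)
        assert m.n_sites == 1

    def test_sample_order_permutation_invariant(self):
        sites, samples = _toy_sample_sites()
        m1 = unite(sites, samples, min_coverage=1, max_quantile=1.0)
        perm = samples.iloc[[2, 0, 3, 1]].reset_index(drop=True)
        m2 = unite(sites, perm, min_coverage=1, max_quantile=1.0)
        assert m1.sites.equals(m2.sites)
        order = [list(perm.sample_id).index(s) for s in samples.sample_id]
        np.testing.assert_array_equal(m1.meth, m2.meth[:, order])

    def test_filter_then_unite_idempotent(self):
        sites, samples = _toy_sample_sites()
        m1 = unite(sites, samples)
        again = {sid: pd.DataFrame({"chrom": m1.sites.chrom, "pos": m1.sites.pos,
                                    "meth": m1.meth[:, j], "total": m1.total[:, j]})
                 for j, sid in enumerate(samples.sample_id)}
        m2 = unite(again, samples, prefiltered=True)
        assert m1.sites.equals(m2.sites)
        np.testing.assert_array_equal(m1.total, m2.total)

    def test_empty_intersection_advises_relaxing(self):
        sites, samples = _toy_sample_sites()
        sites["u0"] = sites["u0"].assign(pos=sites["u0"].pos + 7)  # disjoint
        with pytest.raises(ValueError, match="relax"):
            unite(sites, samples, min_coverage=1, max_quantile=1.0)

    def test_needs_two_samples_per_habitat(self):
        sites, samples = _toy_sample_sites()
        with pytest.raises(ValueError, match="two samples"):
            unite(sites, samples[samples.sample_id != "f1"])

    def test_matrix_mean_coverage_matches_simulator(self, dataset, matrix):
        mean = matrix.total.mean()
        cfg = dataset.config
        se = (cfg.coverage_mean + cfg.coverage_mean ** 2 / cfg.coverage_dispersion) ** 0.5 \
            / (matrix.n_sites * len(matrix.samples)) ** 0.5
        # filters truncate both tails; allow a generous band around the truth
        assert abs(mean - cfg.coverage_mean) < max(2 * se, 0.05 * cfg.coverage_mean)


class TestRelaxedBackground:
    def test_three_reads_in_one_sample_included(self):
        samples = {"a": pd.DataFrame({"chrom": ["chr1"], "pos": [5], "meth": [0], "total": [3]}),
                   "b": pd.DataFrame({"chrom": ["chr1"], "pos": [9], "meth": [0], "total": [2]})}
        out = relaxed_background(samples)
        assert list(out.pos) == [5]

    def test_max_two_reads_everywhere_excluded(self):
        samples = {"a": pd.DataFrame({"chrom": ["chr1"], "pos": [5], "meth": [0], "total": [2]}),
                   "b": pd.DataFrame({"chrom": ["chr1"], "pos": [5], "meth": [1], "total": [2]})}
        assert relaxed_background(samples).empty

    def test_relaxed_set_superset_of_united(self, merged_counts, matrix, background_sites):
        united = set(zip(matrix.sites.chrom, matrix.sites.pos))
        relaxed = set(zip(background_sites.chrom, background_sites.pos))
        assert united <= relaxed


def test_matrix_tsv_round_trip(tmp_path, matrix):
    path = tmp_path / "m.tsv"
    matrix.to_tsv(path)
    from urbmeth.coverage import MethylationMatrix
    back = MethylationMatrix.from_tsv(path, matrix.samples)
    assert back.sites.equals(matrix.sites)
    np.testing.assert_array_equal(back.meth, matrix.meth)
    np.testing.assert_array_equal(back.total, matrix.total)
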