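"""Genotype source validation, chunk planning/iteration, VCF conversion."""

import numpy as np
import pytest

import eigenratio as er
from eigenratio.genotype_io import C_OVERHEAD

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


class TestOpenSources:
    def test_column_counts_add_across_files(self, npy_pair):
        (pa, _), (pb, _) = npy_pair
        src = er.open_sources([pa, pb])
        assert (src.n, src.p) == (4, 25)
        assert src.col_counts == (10, 15)

    def test_p_additivity_against_single_file(self, npy_pair):
        (pa, _), (pb, b) = npy_pair
        assert er.open_sources([pa, pb]).p - er.open_sources([pa]).p == b.shape[1]

    def test_row_mismatch_names_both_files(self, tmp_path, rng):
        pa, pb = tmp_path / "a.npy", tmp_path / "b.npy"
        np.save(pa, np.zeros((4, 10)) )
        np.save(pb, np.ones((5, 10)))
        with pytest.raises(er.DimensionError, match=r"a\.npy.*4.*b\.npy.*5"):
            er.open_sources([pa, pb])

    def test_out_of_domain_entry_reports_coordinates(self, tmp_path):
        arr = np.zeros((3, 4))
        arr[1, 2] = 3.0
        path = tmp_path / "bad.npy"
        np.save(path, arr)
        with pytest.raises(er.DomainError, match=r"row 1, column 2"):
            er.open_sources([path])

    def test_negative_integer_in_npy_is_domain_error(self, tmp_path):
        arr = np.zeros((3, 4), dtype=np.int32)
        arr[0, 1] = -9
        path = tmp_path / "neg.npy"
        np.save(path, arr)
        with pytest.raises(er.DomainError):
            er.open_sources([path])

    def test_missing_file(self, tmp_path):
        with pytest.raises(er.GenotypeIOError, match="not found"):
            er.open_sources([tmp_path / "nope.npy"])


class TestMissingDialects:
    def test_text_and_npy_dialects_normalize_to_nan(self, tmp_path):
        # text dialects: negative integer and NA/"." tokens; NPY dialect: NaN
        (tmp_path / "t.tsv").write_text("0\t-9\t2\n1\tNA\t.\n")
        arr = np.array([[0.0, np.nan, 2.0], [1.0, 0.0, 1.0]])
        np.save(tmp_path / "t.npy", arr)
        src = er.open_sources([tmp_path / "t.tsv", tmp_path / "t.npy"])
        plan = er.ChunkPlan(chunk_width=6, memory_budget_bytes=1 << 20)
        (_, block), = list(er.iter_column_chunks(src, plan))
        expect = np.array([[0, np.nan, 2, 0, np.nan, 2],
                           [1, np.nan, np.nan, 1, 0, 1]], dtype=float)
        np.testing.assert_array_equal(block, expect)

    def test_csv_dialect(self, tmp_path):
        (tmp_path / "t.csv").write_text("0,1,2\n2,NA,0\n")
        src = er.open_sources([tmp_path / "t.csv"])
        assert (src.n, src.p) == (2, 3)


class TestPlanChunks:
    def test_width_from_budget(self, tmp_path, rng):
        # budget sized so exactly 10,000 columns fit beside the accumulator
        src = er.GenotypeSource(paths=("x",), n=1000, p=25_000,
                                col_counts=(25_000,), _arrays=())
        budget = 8 * 1000**2 + 8 * 1000 * C_OVERHEAD * 10_000
        plan = er.plan_chunks(src, budget)
        assert plan.chunk_width == 10_000
        ranges = list(plan.ranges(src.p))
        assert ranges == [(0, 10_000), (10_000, 20_000), (20_000, 25_000)]

    def test_budget_too_small(self):
        src = er.GenotypeSource(paths=("x",), n=100, p=10, col_counts=(10,), _arrays=())
        with pytest.raises(er.ResourceError, match="at least"):
            er.plan_chunks(src, 8 * 100**2 + 8 * 100 * C_OVERHEAD - 1)

    def test_wide_budget_gives_single_chunk(self, npy_pair):
        (pa, _), (pb, _) = npy_pair
        src = er.open_sources([pa, pb])
        plan = er.plan_chunks(src, 1 << 30)
        assert plan.chunk_width >= src.p
        assert list(plan.ranges(src.p)) == [(0, src.p)]


class TestIterColumnChunks:
    def test_tiling(self):
        plan = er.ChunkPlan(chunk_width=10, memory_budget_bytes=1)
        assert list(plan.ranges(25)) == [(0, 10), (10, 20), (20, 25)]

    @pytest.mark.parametrize("width", [1, 2, 24, 25, 32])
    def test_roundtrip_equals_single_shot_read(self, npy_pair, width):
        """Concatenated chunks reconstruct the whole matrix bit-exactly."""
        (pa, a), (pb, b) = npy_pair
        full = np.concatenate([a, b], axis=1)  # oracle: one-piece read
        src = er.open_sources([pa, pb])
        plan = er.ChunkPlan(chunk_width=width, memory_budget_bytes=1 << 20)
        blocks = [blk for _, blk in er.iter_column_chunks(src, plan)]
        np.testing.assert_array_equal(np.concatenate(blocks, axis=1), full)


def _write_vcf(path, records, samples=("S1", "S2", "S3")):
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n"
    )
    lines = []
    for pos, ref, alt, gts in records:
        lines.append(f"1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    path.write_text(header + "\n".join(lines) + "\n")


class TestVcfToMatrix:
    def test_orientation_ties_and_missing(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        _write_vcf(vcf, [
            (100, "A", "G", ["0/0", "0/1", "1/1"]),   # ALT freq 0.5: tie -> ALT counted
            (200, "C", "T", ["1/1", "1/1", "0/1"]),   # ALT freq 5/6: minor is REF
            (300, "G", "A", ["./.", "0/1", "0/0"]),   # missing cell propagates
            (400, "T", "C,G", ["0/1", "0/2", "1/2"]),  # multi-allelic: skipped
        ])
        out = tmp_path / "x.npy"
        summary = er.vcf_to_matrix(vcf, out)
        mat = np.load(out)
        np.testing.assert_array_equal(mat[:, 0], [0, 1, 2])
        np.testing.assert_array_equal(mat[:, 1], [0, 0, 1])
        assert np.isnan(mat[0, 2]) and mat[1, 2] == 1 and mat[2, 2] == 0
        assert summary["n_skipped_multiallelic"] == 1
        assert summary["p"] == 3
        manifest = (tmp_path / "x.npy.manifest.tsv").read_text()
        assert manifest.count("\t1\n") == 1  # exactly one skipped row

    def test_minor_allele_frequency_at_most_half(self, tmp_path, rng):
        """Converted columns always have minor-allele frequency <= 0.5."""
        records = []
        for pos in range(100, 130):
            gts = ["/".join(map(str, sorted(rng.integers(0, 2, 2)))) for _ in range(3)]
            records.append((pos, "A", "G", gts))
        vcf = tmp_path / "r.vcf"
        _write_vcf(vcf, records)
        out = tmp_path / "r.npy"
        er.vcf_to_matrix(vcf, out)
        mat = np.load(out)
        freqs = np.nanmean(mat, axis=0) / 2.0
        assert (freqs <= 0.5 + 1e-12).all()

    def test_no_biallelic_variants(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        _write_vcf(vcf, [(100, "T", "C,G", ["0/1", "0/2", "1/2"])])
        with pytest.raises(er.EmptyOutputError):
            er.vcf_to_matrix(vcf, tmp_path / "m.npy")
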