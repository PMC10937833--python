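import numpy as np
import pandas as pd
import pytest

from sigplier import (
    DataError,
    ExpressionMatrix,
    Signature,
    SignatureAtlas,
    build_prior_matrix,
    filter_genes,
    log_transform,
    read_expression,
    read_gmt,
    write_expression,
    write_gmt,
)
from sigplier.data_model import LOG2_TPM_HALF, NON_ASSOCIATED, TPM


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadExpression:
    def test_parses_genes_by_samples_table(self, tmp_path):
        p = _write(tmp_path, "x.tsv", "gene\ts1\ts2\ng1\t1\t2\ng2\t3\t4\ng3\t5\t6\n")
        em = read_expression(p)
        assert (em.n_genes, em.n_samples) == (3, 2)
        assert list(em.genes) == ["g1", "g2", "g3"]
        assert em.values[1, 1] == 4.0

    def test_duplicate_gene_rows_are_an_error(self, tmp_path):
        p = _write(tmp_path, "x.tsv", "gene\ts1\ng1\t1\ng1\t2\n")
        with pytest.raises(DataError, match="duplicate"):
            read_expression(p)

    def test_empty_file_is_an_error(self, tmp_path):
        with pytest.raises(DataError):
            read_expression(_write(tmp_path, "x.tsv", ""))

    def test_non_numeric_cells_are_an_error(self, tmp_path):
        p = _write(tmp_path, "x.tsv", "gene\ts1\ng1\tabc\n")
        with pytest.raises(DataError, match="non-numeric"):
            read_expression(p)

    def test_roundtrip_is_value_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        em = ExpressionMatrix(
            [f"g{i}" for i in range(5)], ["a", "b", "c"], rng.normal(size=(5, 3)) ** 2
        )
        write_expression(em, tmp_path / "y.tsv")
        back = read_expression(tmp_path / "y.tsv")
        np.testing.assert_array_equal(back.values, em.values)
        assert list(back.samples) == list(em.samples)


class TestLogTransform:
    @pytest.mark.parametrize("tpm,expected", [(0.0, -1.0), (0.5, 0.0), (1.5, 1.0)])
    def test_log2_of_tpm_plus_half(self, tpm, expected):
        em = ExpressionMatrix(["g1"], ["s1"], [[tpm]], TPM)
        out = log_transform(em)
        assert out.scale == LOG2_TPM_HALF
        assert out.values[0, 0] == pytest.approx(expected)

    def test_negative_values_are_an_error(self):
        em = ExpressionMatrix(["g1"], ["s1"], [[-1.0]], TPM)
        with pytest.raises(DataError, match="negative"):
            log_transform(em)

    def test_already_logged_matrix_is_an_error(self):
        em = ExpressionMatrix(["g1"], ["s1"], [[1.0]], LOG2_TPM_HALF)
        with pytest.raises(DataError, match="TPM"):
            log_transform(em)


@pytest.fixture
def toy_atlas():
    return SignatureAtlas([
        Signature("sigA", ("g1", "g2"), {"cell_type": "PT"}),
        Signature("sigB", ("g2", "g3"), {}),
    ])


class TestFilterGenes:
    def test_drops_null_variance_and_unsignatured_genes(self, toy_atlas):
        em = ExpressionMatrix(
            ["g1", "g2", "g3", "g4"], ["s1", "s2"],
            [[1, 2], [5, 5], [3, 4], [7, 8]], TPM,
        )
        # g2 constant, g4 in no signature
        out = filter_genes(em, toy_atlas)
        assert list(out.genes) == ["g1", "g3"]

    def test_zero_fraction_rule_is_strict(self, toy_atlas):
        rng = np.random.default_rng(1)
        n = 100
        v96 = np.zeros(n); v96[:4] = rng.uniform(1, 2, 4)      # 96% zeros: removed
        v95 = np.zeros(n); v95[:5] = rng.uniform(1, 2, 5)      # exactly 95%: kept
        em = ExpressionMatrix(
            ["g1", "g2"], [f"s{i}" for i in range(n)], np.vstack([v96, v95]), TPM
        )
        out = filter_genes(em, toy_atlas)
        assert list(out.genes) == ["g2"]

    def test_idempotent(self, toy_atlas):
        rng = np.random.default_rng(2)
        em = ExpressionMatrix(
            ["g1", "g2", "g3"], ["s1", "s2", "s3"], rng.uniform(0, 5, (3, 3)), TPM
        )
        once = filter_genes(em, toy_atlas)
        twice = filter_genes(once, toy_atlas)
        assert list(once.genes) == list(twice.genes)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_removing_every_gene_is_an_error(self, toy_atlas):
        em = ExpressionMatrix(["g9"], ["s1", "s2"], [[1.0, 2.0]], TPM)
        with pytest.raises(DataError, match="every gene"):
            filter_genes(em, toy_atlas)


class TestReadGmt:
    def test_two_line_gmt(self, tmp_path):
        p = _write(tmp_path, "a.gmt", "sigA\tna\tg1\tg2\nsigB\tna\tg3\n")
        atlas = read_gmt(p)
        assert len(atlas) == 2
        assert atlas["sigA"].genes == ("g1", "g2")
        assert atlas["sigB"].cell_type == NON_ASSOCIATED

    def test_signature_without_genes_is_an_error(self, tmp_path):
        p = _write(tmp_path, "a.gmt", "sigA\tdesc\n")
        with pytest.raises(DataError, match="no genes"):
            read_gmt(p)

    def test_duplicate_names_are_an_error(self, tmp_path):
        p = _write(tmp_path, "a.gmt", "sigA\tna\tg1\nsigA\tna\tg2\n")
        with pytest.raises(DataError, match="duplicate"):
            read_gmt(p)

    def test_metadata_join_and_unknown_row_warning(self, tmp_path):
        p = _write(tmp_path, "a.gmt", "sigA\tna\tg1\tg2\n")
        m = _write(
            tmp_path, "m.tsv",
            "name\tauthor\tspecies\tclinical_condition\tcell_type\n"
            "sigA\tdoe\thuman\tCKD\tPT\nsigZ\tdoe\thuman\tCKD\tST\n",
        )
        with pytest.warns(UserWarning, match="no signature"):
            atlas = read_gmt(p, m)
        assert atlas["sigA"].cell_type == "PT"
        assert atlas["sigA"].metadata["author"] == "doe"

    def test_write_read_roundtrip(self, tmp_path, toy_atlas):
        write_gmt(toy_atlas, tmp_path / "out.gmt", tmp_path / "out_meta.tsv")
        back = read_gmt(tmp_path / "out.gmt", tmp_path / "out_meta.tsv")
        assert back.names == toy_atlas.names
        for sig in toy_atlas:
            assert back[sig.name].genes == sig.genes
            assert back[sig.name].cell_type == sig.cell_type


class TestBuildPriorMatrix:
    def test_membership_column(self, toy_atlas):
        C = build_prior_matrix(toy_atlas, ["g1", "g2", "g3"])
        np.testing.assert_array_equal(C.to_frame()["sigA"].to_numpy(), [1, 1, 0])
        np.testing.assert_array_equal(C.to_frame()["sigB"].to_numpy(), [0, 1, 1])

    def test_disjoint_signature_column_dropped_with_warning(self):
        atlas = SignatureAtlas([Signature("a", ("g1",)), Signature("b", ("g9",))])
        with pytest.warns(UserWarning, match="dropped"):
            C = build_prior_matrix(atlas, ["g1", "g2"])
        assert list(C.signature_names) == ["a"]

    def test_shared_gene_marks_both_columns(self):
        atlas = SignatureAtlas([Signature("a", ("g1", "g2")), Signature("b", ("g1",))])
        C = build_prior_matrix(atlas, ["g1", "g2"])
        assert C.values[0, 0] == 1 and C.values[0, 1] == 1

    def test_column_sums_equal_intersection_sizes(self, sim_small):
        _, atlas, _, _ = sim_small
        universe = sorted(atlas.gene_union())[:300]
        C = build_prior_matrix(atlas, universe)
        for j, name in enumerate(C.signature_names):
            expected = len(set(atlas[name].genes) & set(universe))
            assert C.values[:, j].sum() == expected

    def test_no_overlap_at_all_is_an_error(self, toy_atlas):
        with pytest.raises(DataError):
            build_prior_matrix(toy_atlas, ["zz1", "zz2"])
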