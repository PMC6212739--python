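import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antebayes.data_model import (
    GenotypeCodingError,
    MapFormatError,
    PhenotypeData,
    allele_frequencies,
    chromosome_boundaries,
    read_genotypes,
    read_phenotypes,
    split_reference_candidate,
    write_genotypes,
)
from conftest import make_geno


def write_inputs(tmp_path, matrix_text, map_text):
    gf = tmp_path / "geno.txt"
    mf = tmp_path / "markers.map"
    gf.write_text(matrix_text)
    mf.write_text(map_text)
    return gf, mf


class TestReaders:
    def test_matrix_dialect_parses_shape(self, tmp_path):
        gf, mf = write_inputs(tmp_path, "0 1\n2 1\n1 0\n", "s1 1 100\ns2 1 200\n")
        g = read_genotypes(gf, "matrix", mf)
        assert g.markers.shape == (3, 2)
        assert list(g.marker_ids) == ["s1", "s2"]

    def test_bad_coding_names_cell(self, tmp_path):
        gf, mf = write_inputs(tmp_path, "0 1\n3 1\n", "s1 1 100\ns2 1 200\n")
        with pytest.raises(GenotypeCodingError, match="row 1, column 0"):
            read_genotypes(gf, "matrix", mf)

    def test_unsorted_map_is_resorted_with_warning(self, tmp_path, caplog):
        gf, mf = write_inputs(tmp_path, "0 1\n2 1\n1 0\n", "s2 1 200\ns1 1 100\n")
        with caplog.at_level(logging.WARNING):
            g = read_genotypes(gf, "matrix", mf)
        assert "re-sorting" in caplog.text
        # hand-sorted toy input: column order swaps
        assert list(g.marker_ids) == ["s1", "s2"]
        np.testing.assert_array_equal(g.markers, [[1, 0], [1, 2], [0, 1]])

    def test_duplicate_position_rejected(self, tmp_path):
        gf, mf = write_inputs(tmp_path, "0 1\n", "s1 1 100\ns2 1 100\n")
        with pytest.raises(MapFormatError, match="duplicate position"):
            read_genotypes(gf, "matrix", mf)

    def test_plink_raw_imputes_na(self, tmp_path):
        raw = (
            "FID IID PAT MAT SEX PHENOTYPE s1_A s2_A\n"
            "f1 a1 0 0 1 -9 0 2\n"
            "f2 a2 0 0 1 -9 NA 2\n"
            "f3 a3 0 0 1 -9 2 1\n"
        )
        gf = tmp_path / "g.raw"
        gf.write_text(raw)
        mf = tmp_path / "m.map"
        mf.write_text("s1 1 10\ns2 1 20\n")
        g = read_genotypes(gf, "plink_raw", mf)
        # column mean of observed s1 values (0, 2) is 1
        assert g.markers[1, 0] == 1
        assert list(g.animal_ids) == ["a1", "a2", "a3"]

    @pytest.mark.parametrize("dialect", ["matrix", "plink_raw"])
    def test_round_trip_is_bit_exact(self, tmp_path, dialect):
        rng = np.random.default_rng(3)
        g = make_geno(rng.integers(0, 3, (5, 7)), chrom=[1, 1, 1, 2, 2, 2, 2])
        gp, mp = tmp_path / "g.txt", tmp_path / "g.map"
        write_genotypes(g, gp, dialect, mp)
        g2 = read_genotypes(gp, dialect, mp)
        np.testing.assert_array_equal(g.markers, g2.markers)
        assert list(g.marker_ids) == list(g2.marker_ids)
        assert list(g.position) == list(g2.position)


class TestDerived:
    @pytest.mark.parametrize(
        "column,expected",
        [([0, 1, 2], 0.5), ([0, 0, 0], 0.0), ([2, 2, 1, 1], 0.75)],
    )
    def test_allele_frequencies(self, column, expected):
        g = make_geno(np.array(column).reshape(-1, 1))
        assert allele_frequencies(g)[0] == pytest.approx(expected)

    @pytest.mark.parametrize(
        "chrom,expected",
        [([1, 1, 1, 2, 2], [0, 3]), ([1, 1, 1], [0]), ([1, 2, 3], [0, 1, 2])],
    )
    def test_chromosome_boundaries(self, chrom, expected):
        g = make_geno(np.zeros((2, len(chrom)), dtype=int), chrom=chrom)
        assert chromosome_boundaries(g).tolist() == expected

    def test_sorting_preserves_marker_multiset(self, tmp_path):
        gf = tmp_path / "g.txt"
        mf = tmp_path / "m.map"
        gf.write_text("0 1 2\n1 1 1\n")
        mf.write_text("b 2 5\na 1 9\nc 1 2\n")
        g = read_genotypes(gf, "matrix", mf)
        assert sorted(g.marker_ids) == ["a", "b", "c"]
        assert list(g.marker_ids) == ["c", "a", "b"]


class TestSplit:
    @pytest.mark.parametrize("n,frac,expected_ref", [(10, 0.5, 5), (11, 0.5, 6)])
    def test_partition_sizes(self, n, frac, expected_ref):
        g = make_geno(np.tile([0, 1, 2], (n, 1)))
        p = PhenotypeData(y=np.arange(n, dtype=float))
        sp = split_reference_candidate(g, p, frac, seed=1)
        assert sp.reference_geno.n_animals == expected_ref
        assert sp.candidate_geno.n_animals == n - expected_ref

    def test_partition_disjoint_exhaustive_deterministic(self):
        g = make_geno(np.tile([0, 1, 2], (9, 1)))
        p = PhenotypeData(y=np.arange(9, dtype=float))
        a = split_reference_candidate(g, p, 0.4, seed=5)
        b = split_reference_candidate(g, p, 0.4, seed=5)
        assert list(a.reference_geno.animal_ids) == list(b.reference_geno.animal_ids)
        union = set(a.reference_geno.animal_ids) | set(a.candidate_geno.animal_ids)
        assert union == set(g.animal_ids)
        assert not set(a.reference_geno.animal_ids) & set(a.candidate_geno.animal_ids)

    def test_many_seeds_cover_all_animals(self):
        g = make_geno(np.tile([0, 1, 2], (8, 1)))
        p = PhenotypeData(y=np.arange(8, dtype=float))
        covered = set()
        for seed in range(12):
            covered |= set(
                split_reference_candidate(g, p, 0.5, seed).reference_geno.animal_ids
            )
        assert covered == set(g.animal_ids)

    def test_too_few_animals(self):
        g = make_geno(np.array([[0, 1, 2]]))
        p = PhenotypeData(y=np.array([1.0]))
        with pytest.raises(ValueError, match="at least 2"):
            split_reference_candidate(g, p, 0.5, seed=0)


class TestPhenotypeData:
    def test_intercept_added_once(self):
        p = PhenotypeData(y=[1.0, 2.0, 3.0], fixed_design=np.eye(3)[:, :1])
        assert p.fixed_design.shape == (3, 2)
        assert np.all(p.fixed_design[:, 0] == 1)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(4), np.arange(4.0), 2 * np.arange(4.0)])
        with pytest.raises(ValueError, match="rank"):
            PhenotypeData(y=np.zeros(4), fixed_design=X)

    def test_read_phenotypes_aligns_to_animals(self, tmp_path):
        f = tmp_path / "p.txt"
        f.write_text("a2 1.5\na1 0.5\n")
        p = read_phenotypes(f, animal_ids=["a1", "a2"])
        np.testing.assert_allclose(p.y, [0.5, 1.5])


@settings(derandomize=True, max_examples=25)
@given(st.integers(2, 30), st.integers(1, 4), st.integers(0, 1000))
def test_sorting_permutation_is_bijection(m, n_chrom, seed):
    """Loading any shuffled map yields a column permutation (id multiset kept)."""
    rng = np.random.default_rng(seed)
    chrom = np.sort(rng.integers(1, n_chrom + 1, m))
    pos = np.concatenate(
        [np.cumsum(rng.integers(1, 50, np.sum(chrom == c))) for c in np.unique(chrom)]
    )
    perm = rng.permutation(m)
    ids = [f"s{j}" for j in range(m)]
    map_text = "".join(f"{ids[j]} {chrom[j]} {pos[j]}\n" for j in perm)
    mat_text = "".join(" ".join("1" for _ in range(m)) + "\n" for _ in range(2))
    import tempfile, pathlib
    with tempfile.TemporaryDirectory() as td:
        gf = pathlib.Path(td) / "g.txt"
        mf = pathlib.Path(td) / "m.map"
        gf.write_text(mat_text)
        mf.write_text(map_text)
        g = read_genotypes(gf, "matrix", mf)
    assert sorted(g.marker_ids) == sorted(ids)
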