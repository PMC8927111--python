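"""Pedigree structure, pair classification and relationship matrix."""

import numpy as np
import pandas as pd
import pytest

from kinstats import (
    Individual,
    Pedigree,
    PedigreeError,
    classify_pairs,
    families,
    read_pedigree,
    relationship_matrix,
)
from kinstats.pedigree import write_fam

from helpers import gene_drop_relatedness, random_pedigree


class TestReading:
    def test_fam_trio(self, tmp_path):
        p = tmp_path / "trio.fam"
        p.write_text("FAM1 dad 0 0 1 -9\nFAM1 mom 0 0 2 -9\nFAM1 kid dad mom 1 -9\n")
        ped = read_pedigree(p, "plink_fam")
        assert len(ped) == 3
        assert sorted(ped.founders) == ["dad", "mom"]
        assert ped["kid"].father == "dad" and ped["kid"].mother == "mom"

    def test_missing_parent_code_zero(self, tmp_path):
        p = tmp_path / "p.fam"
        p.write_text("F a 0 0 1 -9\nF b 0 a 0 -9\n")
        with pytest.raises(PedigreeError):
            read_pedigree(p, "plink_fam")  # 'a' is male but used as mother
        p.write_text("F a 0 0 2 -9\nF b 0 a 0 -9\n")
        ped = read_pedigree(p, "plink_fam")
        assert ped["b"].father is None  # "0" means unknown father
        assert ped["b"].mother == "a"

    def test_cycle_error(self):
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree([Individual("a", "b", None), Individual("b", "a", None)])

    def test_own_parent_error(self):
        with pytest.raises(PedigreeError):
            Individual("a", "a", None)

    def test_duplicate_id_error(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            Pedigree([Individual("a"), Individual("a")])

    def test_ghost_parents_materialized(self):
        with pytest.warns(UserWarning, match="founder"):
            ped = Pedigree([Individual("c", "f", "m")])
        assert len(ped) == 3 and set(ped.founders) == {"f", "m"}

    def test_csv_dialect_with_partner_links(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("person,pa,ma,sx,sp\nA,,,m,B\nB,,,f,\n")
        ped = read_pedigree(
            p, "csv", id_col="person", father_col="pa", mother_col="ma",
            sex_col="sx", partner_col="sp",
        )
        pairs = classify_pairs(ped)
        assert list(pairs["relation"]) == ["spouse"]

    def test_linkage_roundtrip(self, tmp_path, trio):
        path = tmp_path / "out.fam"
        write_fam(trio, path)
        back = read_pedigree(path, "linkage_ped")
        assert sorted(back.ids) == sorted(trio.ids)
        assert back["kid"].father == "dad"


class TestFamilies:
    def test_two_disjoint_trios(self, tmp_path):
        p = tmp_path / "two.fam"
        p.write_text(
            "F1 a 0 0 1 -9\nF1 b 0 0 2 -9\nF1 c a b 0 -9\n"
            "F2 d 0 0 1 -9\nF2 e 0 0 2 -9\nF2 f d e 0 -9\n"
        )
        fam = families(read_pedigree(p))
        assert sorted(len(v) for v in fam.values()) == [3, 3]

    def test_singleton(self):
        fam = families(Pedigree([Individual("solo")]))
        assert list(fam.values()) == [["solo"]]

    def test_three_generation_single_family(self):
        ped = Pedigree(
            [
                Individual("g1", sex="male"), Individual("g2", sex="female"),
                Individual("g3", sex="male"), Individual("g4", sex="female"),
                Individual("p1", "g1", "g2", "male"),
                Individual("p2", "g3", "g4", "female"),
                Individual("c", "p1", "p2"),
            ]
        )
        fam = families(ped)
        assert len(fam) == 1 and len(next(iter(fam.values()))) == 7
        assert ped.generation["c"] == 2


class TestClassifyPairs:
    def test_trio(self, trio):
        pairs = classify_pairs(trio)
        counts = pairs["relation"].value_counts().to_dict()
        assert counts == {"parent-offspring": 2, "spouse": 1}

    def test_full_siblings(self):
        ped = Pedigree(
            [Individual("f"), Individual("m"),
             Individual("a", "f", "m"), Individual("b", "f", "m")]
        )
        pairs = classify_pairs(ped)
        assert ((pairs["relation"] == "full-sibling").sum()) == 1

    def test_half_siblings_not_first_degree(self):
        ped = Pedigree(
            [Individual("m", sex="female"), Individual("f1"), Individual("f2"),
             Individual("a", "f1", "m"), Individual("b", "f2", "m")]
        )
        pairs = classify_pairs(ped).set_index(["id_a", "id_b"])
        assert ("a", "b") not in pairs.index  # half sibs are "other"

    def test_consanguineous_spouse_flagged(self):
        ped = Pedigree(
            [Individual("f"), Individual("m", sex="female"),
             Individual("s1", "f", "m", "male"), Individual("s2", "f", "m", "female"),
             Individual("x", "s1", "s2")]
        )
        pairs = classify_pairs(ped)
        row = pairs[(pairs.id_a == "s1") & (pairs.id_b == "s2")].iloc[0]
        assert row["relation"] == "full-sibling" and row["consanguineous"]

    def test_canonical_ordering_unique(self, textbook_pedigree):
        pairs = classify_pairs(textbook_pedigree)
        assert (pairs["id_a"] < pairs["id_b"]).all()
        assert not pairs.duplicated(["id_a", "id_b"]).any()


class TestRelationshipMatrix:
    def test_textbook_identities(self, textbook_pedigree):
        rm = relationship_matrix(textbook_pedigree)
        assert rm.coeff("f1", "m1") == 0.0
        assert rm.coeff("f1", "s1") == 0.5  # parent-offspring
        assert rm.coeff("s1", "s2") == 0.5  # full siblings
        assert rm.coeff("s1", "h1") == 0.25  # half siblings
        assert rm.coeff("f1", "gc") == 0.25  # grandparent-grandchild
        assert rm.coeff("inb", "inb") == 1.25  # offspring of full-sib mating

    def test_founders_identity(self):
        ped = Pedigree([Individual(f"x{i}") for i in range(5)])
        assert np.allclose(relationship_matrix(ped).dense(), np.eye(5))

    def test_subset_keeps_ancestral_relatedness(self, textbook_pedigree):
        rm = relationship_matrix(textbook_pedigree, subset=["s1", "s2", "gc"])
        assert rm.ids == ["s1", "s2", "gc"]
        assert rm.coeff("s1", "s2") == 0.5  # parents not in subset

    def test_subset_unknown_id_errors(self, trio):
        with pytest.raises(KeyError):
            relationship_matrix(trio, subset=["kid", "nobody"])

    def test_sparse_dense_agree(self, textbook_pedigree):
        d = relationship_matrix(textbook_pedigree, sparse=False).dense()
        s = relationship_matrix(textbook_pedigree, sparse=True).dense()
        assert np.allclose(d, s, atol=1e-10)

    def test_psd_and_permutation_invariance(self, rng):
        for _ in range(5):
            ped = random_pedigree(rng, n_target=int(rng.integers(8, 25)))
            rm = relationship_matrix(ped)
            assert np.linalg.eigvalsh(rm.dense()).min() >= -1e-8
            perm = list(rng.permutation(rm.ids))
            rm2 = relationship_matrix(ped, subset=perm)
            idx = [perm.index(i) for i in rm.ids]
            assert np.allclose(rm2.dense()[np.ix_(idx, idx)], rm.dense(), atol=1e-12)

    def test_gene_dropping_oracle_small(self, rng):
        """Tabular A matches Monte-Carlo IBD sharing on one random pedigree."""
        ped = random_pedigree(rng, n_target=15)
        ids, a_hat, a_se = gene_drop_relatedness(ped, 60_000, rng)
        A = relationship_matrix(ped, subset=ids).dense()
        dev = np.abs(A - a_hat)
        # 5 se bound per pair (individual 3-sigma checks would fail by
        # multiplicity over ~100 pairs); deterministic pairs exact
        assert np.all(dev[a_se == 0] <= 1e-12)
        assert np.all(dev[a_se > 0] <= 5 * a_se[a_se > 0])
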