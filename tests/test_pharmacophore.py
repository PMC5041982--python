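import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hit2lead.chem_io import Compound
from hit2lead.pharmacophore import (
    DEFAULT_BIN_EDGES,
    MissingConformerError,
    PharmFeature,
    PharmFingerprint,
    PharmacophoreRanker,
    embed_compound,
    perceive_features,
    pharm_fingerprint,
    pharm_similarity,
    rank_and_select,
)


def rigid_move(compound, angles=(30, 45, 60), shift=(1.0, -2.0, 3.0)):
    R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
    conf = [
        (el, *(R @ np.array([x, y, z]) + np.array(shift))) for el, x, y, z in compound.conformer
    ]
    return Compound(compound.id, compound.smiles, conformer=conf)


def test_packaged_rules_file_matches_defaults():
    from importlib import resources

    from hit2lead.pharmacophore import DEFAULT_FEATURE_RULES, load_feature_rules

    with resources.as_file(resources.files("hit2lead.data") / "feature_rules.yaml") as p:
        assert load_feature_rules(p) == DEFAULT_FEATURE_RULES


class TestPerceiveFeatures:
    def test_benzene_single_ring_feature_at_centroid(self, benzene_planar):
        feats = perceive_features(benzene_planar)
        assert [f.ftype for f in feats] == ["R"]
        centroid = np.mean([[x, y, z] for _e, x, y, z in benzene_planar.conformer], axis=0)
        assert feats[0].centroid == pytest.approx(tuple(centroid), abs=1e-9)

    def test_methanol_donor_and_acceptor_on_oxygen(self):
        meoh = embed_compound(Compound("m", "CO"))
        types = sorted(f.ftype for f in perceive_features(meoh))
        assert types == ["A", "D"]

    def test_methane_has_no_features(self):
        ch4 = embed_compound(Compound("x", "C"))
        assert perceive_features(ch4) == []

    def test_carboxylate_negative_ionizable_group_centroid(self):
        acid = embed_compound(Compound("a", "CC(=O)O"))
        nfeats = [f for f in perceive_features(acid) if f.ftype == "N"]
        assert len(nfeats) == 1

    def test_missing_conformer(self):
        with pytest.raises(MissingConformerError):
            perceive_features(Compound("c", "CCO"))


class TestPharmFingerprint:
    def test_pair_at_three_angstrom_falls_in_second_bin(self):
        feats = [PharmFeature("D", (0.0, 0.0, 0.0)), PharmFeature("A", (3.0, 0.0, 0.0))]
        fp = pharm_fingerprint(feats)
        assert fp.counts == {("A", "D", 1): 1}  # 2 <= 3.0 < 4

    def test_rigid_motion_invariance(self, benzene_planar):
        meoh = embed_compound(Compound("m", "CCO"))
        fp1 = pharm_fingerprint(perceive_features(meoh))
        fp2 = pharm_fingerprint(perceive_features(rigid_move(meoh)))
        assert fp1.counts == fp2.counts

    def test_three_features_give_three_pair_counts(self):
        feats = [
            PharmFeature("D", (0.0, 0.0, 0.0)),
            PharmFeature("A", (3.0, 0.0, 0.0)),
            PharmFeature("H", (0.0, 5.0, 0.0)),
        ]
        fp = pharm_fingerprint(feats)
        assert fp.total() == 3

    def test_overflow_bin_for_long_distances(self):
        feats = [PharmFeature("D", (0.0, 0.0, 0.0)), PharmFeature("A", (99.0, 0.0, 0.0))]
        fp = pharm_fingerprint(feats)
        assert fp.counts == {("A", "D", len(DEFAULT_BIN_EDGES) - 1): 1}

    def test_bad_bin_edges_rejected(self):
        with pytest.raises(ValueError):
            pharm_fingerprint([], bin_edges=(1.0, 2.0))
        with pytest.raises(ValueError):
            pharm_fingerprint([], bin_edges=(0.0, 2.0, 2.0))


class TestPharmSimilarity:
    def test_identity_scores_100(self):
        fp = PharmFingerprint({("A", "D", 1): 2}, DEFAULT_BIN_EDGES)
        assert pharm_similarity(fp, fp) == 100.0

    def test_min_over_max_count_vector(self):
        a = PharmFingerprint({("A", "D", 1): 2}, DEFAULT_BIN_EDGES)
        b = PharmFingerprint({("A", "D", 1): 1, ("D", "H", 0): 1}, DEFAULT_BIN_EDGES)
        assert pharm_similarity(a, b) == pytest.approx(100.0 / 3.0)  # min-sum 1, max-sum 3

    def test_disjoint_keys_score_zero(self):
        a = PharmFingerprint({("A", "D", 1): 1}, DEFAULT_BIN_EDGES)
        b = PharmFingerprint({("D", "H", 2): 1}, DEFAULT_BIN_EDGES)
        assert pharm_similarity(a, b) == 0.0

    def test_both_empty_scores_100_one_empty_zero(self):
        e = PharmFingerprint({}, DEFAULT_BIN_EDGES)
        f = PharmFingerprint({("A", "D", 1): 1}, DEFAULT_BIN_EDGES)
        assert pharm_similarity(e, e) == 100.0
        assert pharm_similarity(e, f) == 0.0

    def test_symmetry_and_bounds(self):
        a = PharmFingerprint({("A", "D", 1): 3, ("A", "A", 2): 1}, DEFAULT_BIN_EDGES)
        b = PharmFingerprint({("A", "D", 1): 1, ("H", "R", 0): 2}, DEFAULT_BIN_EDGES)
        assert pharm_similarity(a, b) == pharm_similarity(b, a)
        assert 0.0 <= pharm_similarity(a, b) <= 100.0

    def test_bin_edge_mismatch_rejected(self):
        a = PharmFingerprint({}, DEFAULT_BIN_EDGES)
        b = PharmFingerprint({}, (0.0, 1.0, 2.0))
        with pytest.raises(ValueError):
            pharm_similarity(a, b)


class TestRankAndSelect:
    def test_reference_ranks_first_with_score_100(self):
        ref = embed_compound(Compound("ref", "c1ccccc1CCO"))
        lib = [ref, embed_compound(Compound("alkane", "CCCC"))]
        ranked, selected = rank_and_select(lib, ref, threshold=70)
        assert ranked.iloc[0]["compound_id"] == "ref"
        assert ranked.iloc[0]["score"] == 100.0
        assert "ref" in selected

    def test_threshold_100_excludes_even_identity(self):
        ref = embed_compound(Compound("ref", "c1ccccc1CCO"))
        _ranked, selected = rank_and_select([ref], ref, threshold=100)
        assert selected == []  # strict '>' leaves exact matches out

    def test_selection_monotone_in_threshold(self):
        ref = embed_compound(Compound("ref", "c1ccccc1CCO"))
        lib = [ref] + [
            embed_compound(Compound(f"d{i}", smi))
            for i, smi in enumerate(["CCO", "c1ccccc1C", "CCCCN"])
        ]
        sizes = [len(rank_and_select(lib, ref, threshold=t)[1]) for t in (0, 30, 70, 100)]
        assert sizes == sorted(sizes, reverse=True)

    def test_embedding_disabled_requires_conformer(self):
        ref = Compound("ref", "c1ccccc1CCO")
        ranker = PharmacophoreRanker(embed=False)
        with pytest.raises(MissingConformerError):
            ranker.fit(ref)

    def test_pooled_reference_uses_count_maxima(self):
        a = embed_compound(Compound("a", "c1ccccc1CCO"))
        b = embed_compound(Compound("b", "CCO"))
        ranker = PharmacophoreRanker().fit([a, b])
        fa = pharm_fingerprint(perceive_features(a))
        fb = pharm_fingerprint(perceive_features(b))
        for k in set(fa.counts) | set(fb.counts):
            assert ranker.reference_fp_.counts[k] == max(
                fa.counts.get(k, 0), fb.counts.get(k, 0)
            )
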