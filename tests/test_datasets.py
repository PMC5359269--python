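"""Labeled-set builders, neighbour counting, and the synthetic library."""

import numpy as np
import pytest

import hardmorph as hm
from hardmorph.datasets import LabeledSet, neighbor_counts

from conftest import degenerate_table


class TestFixtureLibrary:
    def test_deterministic(self):
        a = [hm.canonical_smiles(m) for m in hm.fixture_library(50, seed=4)]
        b = [hm.canonical_smiles(m) for m in hm.fixture_library(50, seed=4)]
        assert a == b

    def test_all_eleven_bins_populated_at_1100(self):
        mols = hm.fixture_library(1100, seed=5)
        counts = np.zeros(11, dtype=int)
        for m in mols:
            counts[hm.mw_bin(hm.mol_weight(m))] += 1
        assert (counts >= 10).all(), counts.tolist()

    def test_all_outputs_parse_and_sanitize(self, ref_library):
        for m in ref_library:
            hm.parse_smiles(hm.canonical_smiles(m))

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            hm.fixture_library(0)


class TestBuildMorphSets:
    def test_grid_variant_balanced_and_easy_are_hit_starts(self, table, starts):
        rng = np.random.default_rng(1)
        lset, records = hm.build_morph_sets(starts, table, rng=rng)
        assert len(lset.easy) == len(lset.hard) > 0
        hit_starts = {r["start"] for r in records if r["status"] == "HIT" and r["n_steps"] >= 1}
        assert set(lset.easy) <= hit_starts
        assert not set(lset.easy) & set(lset.hard)

    def test_random_easy_sample_reproducible(self, table, starts, ref_library):
        out1, _ = hm.build_morph_sets(
            starts[:20], table, rng=np.random.default_rng(8), easy_pool=ref_library
        )
        out2, _ = hm.build_morph_sets(
            starts[:20], table, rng=np.random.default_rng(8), easy_pool=ref_library
        )
        assert out1.easy == out2.easy and out1.hard == out2.hard

    def test_unreachable_thresholds_give_empty_set_with_warning(self, starts, caplog):
        t = degenerate_table(float("inf"))
        with caplog.at_level("WARNING"):
            lset, _ = hm.build_morph_sets(
                starts[:5], t, rng=np.random.default_rng(0), max_steps=3
            )
        assert len(lset) == 0
        assert any("no morphing path" in r.message for r in caplog.records)

    def test_round_trip_hard_set_rescored(self, table, starts):
        lset, _ = hm.build_morph_sets(starts, table, rng=np.random.default_rng(2))
        cond = hm.StopCondition()
        for s in lset.hard:
            m = hm.parse_smiles(s)
            assert hm.exceeds(hm.complexity_vector(m), hm.mol_weight(m), table, cond)


class TestBuildSAScoreSets:
    def test_threshold_partition(self, rng):
        scored = [
            {"smiles": "CCO", "sascore": 3.0},
            {"smiles": "CCN", "sascore": 5.0},
            {"smiles": "CCC", "sascore": 7.0},
        ]
        lset = hm.build_sascore_sets(scored, rng=rng)
        assert lset.hard == ["CCC"]
        assert lset.easy == ["CCO"]

    @pytest.mark.parametrize("boundary", [4.0, 6.0])
    def test_boundary_scores_excluded(self, boundary, rng):
        scored = [
            {"smiles": "CCO", "sascore": 3.0},
            {"smiles": "CCCC", "sascore": boundary},
            {"smiles": "CCC", "sascore": 7.0},
        ]
        lset = hm.build_sascore_sets(scored, n_easy=1, rng=rng)
        assert "CCCC" not in lset.easy + lset.hard

    def test_pool_too_small_rejected(self, rng):
        scored = [{"smiles": "CCO", "sascore": 3.0}, {"smiles": "CCC", "sascore": 7.0}]
        with pytest.raises(ValueError, match="easy"):
            hm.build_sascore_sets(scored, n_easy=5, rng=rng)


class TestNeighborCount:
    def test_identical_molecules_have_n_minus_one_neighbors(self):
        fps = [hm.morgan_fp(hm.parse_smiles("CCO")) for _ in range(7)]
        assert all(hm.neighbor_count(i, fps) == 6 for i in range(7))

    def test_disjoint_structures_have_zero(self):
        fps = [hm.morgan_fp(hm.parse_smiles(s)) for s in ("CCCCCC", "c1ccncc1", "OS(=O)(=O)O")]
        assert [hm.neighbor_count(i, fps) for i in range(3)] == [0, 0, 0]

    def test_index_out_of_range(self):
        fps = [hm.morgan_fp(hm.parse_smiles("C"))]
        with pytest.raises(IndexError):
            hm.neighbor_count(5, fps)

    def test_bulk_counts_equal_brute_force(self, ref_library):
        mols = ref_library[:200]
        fps = [hm.morgan_fp(m) for m in mols]
        counts = neighbor_counts(fps, t=0.6)
        for i in range(len(fps)):
            brute = sum(
                1 for j in range(len(fps)) if j != i and hm.tanimoto(fps[i], fps[j]) >= 0.6
            )
            assert counts[i] == brute


def _cluster_library():
    """Engineered density clusters: one tight 25-member family (close analogs),
    plus isolated singletons."""
    family = [f"CCCCCCCCC{'C' * i}O" for i in range(25)]  # homologous alcohols
    singletons = ["c1ccc2nc3ccccc3nc2c1", "OS(=O)(=O)O", "BrC(Br)(Br)Br", "C1CC2CCC1C2"]
    return [hm.parse_smiles(s) for s in family + singletons]


class TestBuildDRSets:
    def test_empty_library(self, rng):
        lset, unlabeled = hm.build_dr_sets([], rng=rng)
        assert len(lset) == 0 and unlabeled == []

    def test_identical_molecules_all_easy(self, rng):
        mols = [hm.parse_smiles("CCO")] * 25
        lset, _ = hm.build_dr_sets(mols, rng=rng)
        # 24 neighbours each -> easy; duplicates collapse to one record
        assert lset.easy == ["CCO"] and lset.hard == []

    def test_membership_equals_brute_force(self, rng):
        mols = _cluster_library()
        fps = [hm.morgan_fp(m) for m in mols]
        lset, unlabeled = hm.build_dr_sets(mols, rng=rng)
        smiles = [hm.canonical_smiles(m) for m in mols]
        for i, s in enumerate(smiles):
            n = sum(1 for j in range(len(fps)) if j != i and hm.tanimoto(fps[i], fps[j]) >= 0.6)
            if n <= 1:
                assert s in lset.hard
            elif n < 20:
                assert s in unlabeled

    def test_labels_permutation_invariant(self):
        mols = _cluster_library()
        l1, u1 = hm.build_dr_sets(mols, rng=np.random.default_rng(0))
        perm = np.random.default_rng(1).permutation(len(mols))
        l2, u2 = hm.build_dr_sets([mols[i] for i in perm], rng=np.random.default_rng(0))
        assert set(l1.hard) == set(l2.hard)
        assert set(u1) == set(u2)


class TestLabeledSet:
    def test_dedup_within_class(self):
        lset = LabeledSet.from_smiles(easy=["CCO", "CCO", "CC"], hard=["CCC"])
        assert lset.easy == ["CCO", "CC"]

    def test_write_and_reload(self, tmp_path):
        lset = LabeledSet.from_smiles(easy=["CCO"], hard=["CCC"], role="test")
        p = tmp_path / "set.smi"
        lset.write(p)
        back = hm.load_test_set(p)
        assert back.easy == ["CCO"] and back.hard == ["CCC"]
        assert (tmp_path / "set.smi.json").exists()


class TestLoadTestSet:
    def _write(self, path, lines):
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_expected_composition(self, tmp_path):
        """A 120-easy / 40-hard labeled file loads with that composition."""
        lines = [f"{'C' * (i + 1)}N e{i} easy" for i in range(120)]
        lines += [f"O{'C' * (i + 1)}O m{i} hard" for i in range(40)]
        p = self._write(tmp_path / "t.smi", lines)
        lset = hm.load_test_set(p)
        assert len(lset.easy) == 120 and len(lset.hard) == 40
        assert lset.role == "test"

    def test_unknown_label_reported_with_line(self, tmp_path):
        p = self._write(tmp_path / "t.smi", ["CCO a easy", "CCC b medium"])
        with pytest.raises(ValueError, match="line 2"):
            hm.load_test_set(p)

    def test_empty_file_rejected(self, tmp_path):
        p = self._write(tmp_path / "t.smi", ["# only a comment"])
        with pytest.raises(ValueError, match="empty"):
            hm.load_test_set(p)
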