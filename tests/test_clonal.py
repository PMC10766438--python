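"""Clonal family construction, identity threshold, convergence annotation."""

import itertools
import random

import pytest
from sklearn.metrics import adjusted_rand_score

from igconverge.clonal_families import (
    annotate_convergence,
    build_clonal_families,
    cdr3_identity,
    clone_key,
    consensus_cdr3,
    strip_allele,
)
from igconverge.errors import ContractError
from igconverge.qc_filter import pair_cells
from igconverge.synthetic_data import SimulationConfig, simulate_repertoire

from conftest import make_cell

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_components(cdr3s, threshold):
    """Exhaustive connected components of the >=threshold identity graph."""
    n = len(cdr3s)
    comp = list(range(n))
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(n), 2):
            if cdr3_identity(cdr3s[i], cdr3s[j]) >= threshold and comp[i] != comp[j]:
                tgt, src = min(comp[i], comp[j]), max(comp[i], comp[j])
                comp = [tgt if c == src else c for c in comp]
                changed = True
    return comp


class TestIdentity:
    def test_identical(self):
        assert cdr3_identity("ARDW", "ARDW") == 1.0

    def test_three_of_four(self):
        assert cdr3_identity("ARDW", "ARDY") == 0.75

    def test_unequal_lengths_contract_error(self):
        with pytest.raises(ContractError):
            cdr3_identity("ARD", "ARDW")

    def test_matches_naive_character_loop(self):
        rnd = random.Random(7)
        for _ in range(300):
            n = rnd.randint(1, 25)
            a = "".join(rnd.choice(AA) for _ in range(n))
            b = "".join(rnd.choice(AA) for _ in range(n))
            hamming = sum(1 for x, y in zip(a, b) if x != y)
            assert cdr3_identity(a, b) == pytest.approx(1 - hamming / n)


class TestBuild:
    def test_identical_cdr3s_merge(self):
        cells = [make_cell("c1", cdr3_aa="ARDYW"), make_cell("c2", cdr3_aa="ARDYW")]
        fams = build_clonal_families(cells)
        assert len(fams) == 1 and fams[0].size == 2

    def test_identity_070_merges_069_does_not(self):
        # length 10: 7 matches = 0.70 merges; length 100: 69 matches stays split
        a10, b10 = "ARDYWARDYW", "ARDYWAR" + "YWA"
        assert cdr3_identity(a10, b10) == 0.70
        fams = build_clonal_families([make_cell("c1", cdr3_aa=a10), make_cell("c2", cdr3_aa=b10)])
        assert len(fams) == 1

        a100 = "".join(random.Random(3).choice(AA) for _ in range(100))
        b100 = list(a100)
        for i in range(31):  # 69 matches -> identity 0.69
            b100[i] = "A" if a100[i] != "A" else "C"
        b100 = "".join(b100)
        assert cdr3_identity(a100, b100) == 0.69
        fams = build_clonal_families([make_cell("c1", cdr3_aa=a100), make_cell("c2", cdr3_aa=b100)])
        assert len(fams) == 2

    def test_different_keys_never_merge(self):
        cells = [
            make_cell("c1", cdr3_aa="ARDYW"),
            make_cell("c2", cdr3_aa="ARDYW", v_call="IGHV2-2*01"),
        ]
        assert len(build_clonal_families(cells)) == 2

    @pytest.mark.parametrize("group_size", [2, 4, 6, 8])
    def test_single_linkage_matches_exhaustive_components(self, group_size):
        rnd = random.Random(group_size)
        for trial in range(30):
            length = rnd.randint(6, 12)
            base = "".join(rnd.choice(AA) for _ in range(length))
            cdr3s = []
            for _ in range(group_size):
                s = list(base)
                for _ in range(rnd.randint(0, length // 2)):
                    s[rnd.randrange(length)] = rnd.choice(AA)
                cdr3s.append("".join(s))
            cells = [make_cell(f"c{i}", cdr3_aa=c) for i, c in enumerate(cdr3s)]
            fams = build_clonal_families(cells, threshold=0.70)
            inferred = {}
            for f in fams:
                for m in f.members:
                    inferred[m.cell_id] = f.cf_id
            expected = brute_force_components(cdr3s, 0.70)
            got = [inferred[f"c{i}"] for i in range(group_size)]
            assert adjusted_rand_score(expected, got) == 1.0 or len(set(expected)) == 1 == len(set(got))

    def test_partition_covers_all_cells(self, small_sim):
        _, (records, profiles, _) = small_sim
        cells, _ = pair_cells(records, profiles)
        fams = build_clonal_families(cells)
        member_ids = sorted(m.cell_id for f in fams for m in f.members)
        assert member_ids == sorted(c.cell_id for c in cells)

    def test_permutation_invariance(self, small_sim):
        _, (records, profiles, _) = small_sim
        cells, _ = pair_cells(records, profiles)
        fams_fwd = build_clonal_families(cells)
        fams_rev = build_clonal_families(cells[::-1])
        key = lambda fams: {f.cf_id: sorted(m.cell_id for m in f.members) for f in fams}
        assert key(fams_fwd) == key(fams_rev)

    def test_threshold_monotonicity_refines_only(self, small_sim):
        _, (records, profiles, _) = small_sim
        cells, _ = pair_cells(records, profiles)
        coarse = build_clonal_families(cells, threshold=0.70)
        fine = build_clonal_families(cells, threshold=0.90)
        coarse_of = {m.cell_id: f.cf_id for f in coarse for m in f.members}
        fine_groups = [{m.cell_id for m in f.members} for f in fine]
        for group in fine_groups:
            assert len({coarse_of[c] for c in group}) == 1

    def test_simulated_recovery_ari(self, small_sim):
        _, (records, profiles, truth) = small_sim
        cells, _ = pair_cells(records, profiles)
        fams = build_clonal_families(cells)
        inferred = {m.cell_id: f.cf_id for f in fams for m in f.members}
        planted = truth.family_labels()
        ids = sorted(inferred)
        ari = adjusted_rand_score([planted[i] for i in ids], [inferred[i] for i in ids])
        assert ari >= 0.95


class TestConvergence:
    def test_two_subject_family_is_convergent(self):
        cells = [make_cell("a1", subject_id="A"), make_cell("q1", subject_id="Q")]
        fams = annotate_convergence(build_clonal_families(cells))
        assert fams[0].is_convergent and fams[0].n_subjects == 2

    def test_single_subject_multi_sample_persistence(self):
        cells = [
            make_cell(f"a{i}", subject_id="A") for i in range(5)
        ]
        for i, c in enumerate(cells):
            c.sample_id = "A-1" if i < 3 else "A-3"
            c.heavy.sample_id = c.sample_id
        fams = annotate_convergence(build_clonal_families(cells))
        assert not fams[0].is_convergent
        assert fams[0].persistence == {"A": ["A-1", "A-3"]}

    def test_planted_public_families_flagged(self, small_sim):
        config, (records, profiles, truth) = small_sim
        cells, _ = pair_cells(records, profiles)
        fams = annotate_convergence(build_clonal_families(cells))
        assert sum(f.is_convergent for f in fams) == config.n_public_families


class TestConsensus:
    def test_majority(self):
        fam = build_clonal_families(
            [make_cell(f"c{i}", cdr3_aa=c) for i, c in enumerate(["ARDYW", "ARDYW", "AKDYW"])]
        )[0]
        assert consensus_cdr3(fam) == "ARDYW"

    def test_single_member(self):
        fam = build_clonal_families([make_cell("c1", cdr3_aa="ARDYW")])[0]
        assert consensus_cdr3(fam) == "ARDYW"

    def test_tie_breaks_alphabetically(self):
        fam = build_clonal_families(
            [make_cell("c1", cdr3_aa="ADYYW"), make_cell("c2", cdr3_aa="AEYYW")]
        )[0]
        assert consensus_cdr3(fam)[1] == "D"


def test_strip_allele_and_key():
    assert strip_allele("IGHV1-69*02") == "IGHV1-69"
    assert strip_allele("IGHV3-30,IGHV3-30-3") == "IGHV3-30"
    cell = make_cell("c1", cdr3_aa="ARDYW")
    key = clone_key(cell)
    assert (key.vh_v_gene, key.vh_j_gene, key.cdr3_length) == ("IGHV1-1", "IGHJ4", 5)
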