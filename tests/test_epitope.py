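"""Peptide tiling, motif scanning, array-signal projection and alignment."""

import itertools
import random

import numpy as np
import pytest
from Bio import Align

from igconverge.airr_io import ProteinRecord
from igconverge.epitope_motif import (
    align_global,
    map_array_signal,
    scan_motif,
    tile_protein,
)
from igconverge.errors import ContractError
from igconverge.synthetic_data import make_loop_protein, simulate_peptide_array

AA = "ACDEFGHIKLMNPQRSTVWY"
LOOP_PEPTIDE = "DPYSPSQDPYSPSQDPDRRDPYSPSPY"


def naive_scan(seq: str, motif: str) -> list[int]:
    return [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]


class TestTiling:
    def test_exact_length_single_tile(self):
        tiles = tile_protein(ProteinRecord("p", "A" * 15), k=15)
        assert len(tiles) == 1 and tiles[0].start == 0

    def test_length_20_gives_6_tiles(self):
        tiles = tile_protein(ProteinRecord("p", "ACDEFGHIKLMNPQRSTVWY"), k=15, offset=1)
        assert len(tiles) == 6

    def test_too_short_protein_errors(self):
        with pytest.raises(ContractError, match="protein_too_short"):
            tile_protein(ProteinRecord("p", "ACD"), k=15)

    def test_tiles_are_parent_slices_and_coverage_counts(self, rng):
        for _ in range(10):
            length = int(rng.integers(20, 80))
            k = int(rng.integers(5, 16))
            offset = int(rng.integers(1, 4))
            seq = "".join(rng.choice(list(AA), size=length))
            tiles = tile_protein(ProteinRecord("p", seq), k=k, offset=offset)
            assert len(tiles) == (length - k) // offset + 1
            for t in tiles:
                assert t.sequence == seq[t.start : t.end]
            coverage = np.zeros(length, dtype=int)
            for t in tiles:
                coverage[t.start : t.end] += 1
            for i in range(length):
                n_windows = sum(1 for t in tiles if t.start <= i < t.end)
                assert coverage[i] == n_windows


class TestMotifScan:
    def test_loop_peptide_hits_at_0_7_19(self):
        hits = scan_motif(ProteinRecord("pep", LOOP_PEPTIDE), "DPYSPS")
        assert [h.start for h in hits] == [0, 7, 19]

    def test_self_scan_single_hit(self):
        hits = scan_motif(ProteinRecord("p", "MKVL"), "MKVL")
        assert len(hits) == 1 and hits[0].start == 0

    def test_overlap_rule(self):
        assert [h.start for h in scan_motif(ProteinRecord("p", "AAAA"), "AA")] == [0, 1, 2]
        assert [h.start for h in scan_motif(ProteinRecord("p", "AAAA"), "AA", allow_overlap=False)] == [0, 2]

    def test_matches_naive_scanner(self):
        rnd = random.Random(12)
        for _ in range(1000):
            seq = "".join(rnd.choice("DPYS") for _ in range(rnd.randint(4, 40)))
            motif = "".join(rnd.choice("DPYS") for _ in range(rnd.randint(1, 5)))
            got = [h.start for h in scan_motif(ProteinRecord("p", seq), motif)]
            assert got == naive_scan(seq, motif)

    def test_hit_invariant(self):
        protein = ProteinRecord("pep", LOOP_PEPTIDE)
        for h in scan_motif(protein, "DPYSPS"):
            assert protein.sequence[h.start : h.end] == h.motif


class TestArraySignal:
    def test_all_zero_no_intervals(self):
        tiles = tile_protein(ProteinRecord("p", "A" * 30), k=15)
        profile = map_array_signal(tiles, [0.0] * len(tiles))
        assert profile.values.tolist() == [0.0] * 30
        assert profile.intervals == []

    def test_single_positive_tile_spans_itself(self):
        tiles = tile_protein(ProteinRecord("p", "A" * 30), k=15)
        signals = [0.0] * len(tiles)
        signals[4] = 2.0
        profile = map_array_signal(tiles, signals)
        assert profile.intervals == [(4, 19)]

    def test_per_residue_max_matches_brute_force(self, rng):
        seq = "A" * 40
        tiles = tile_protein(ProteinRecord("p", seq), k=9, offset=2)
        signals = rng.random(len(tiles)).tolist()
        profile = map_array_signal(tiles, signals)
        for i in range(len(profile.values)):
            covering = [s for t, s in zip(tiles, signals) if t.start <= i < t.end]
            assert profile.values[i] == pytest.approx(max(covering) if covering else 0.0)

    def test_length_mismatch_errors(self):
        tiles = tile_protein(ProteinRecord("p", "A" * 20), k=15)
        with pytest.raises(ContractError):
            map_array_signal(tiles, [1.0])


def enumerate_alignments(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Exhaustive global alignment score by recursion (tiny inputs only)."""
    if not a:
        return gap * len(b)
    if not b:
        return gap * len(a)
    return max(
        enumerate_alignments(a[1:], b[1:]) + (match if a[0] == b[0] else mismatch),
        enumerate_alignments(a[1:], b) + gap,
        enumerate_alignments(a, b[1:]) + gap,
    )


class TestGlobalAlignment:
    def test_identical_sequences(self):
        res = align_global(ProteinRecord("a", "MKVLA"), ProteinRecord("b", "MKVLA"))
        assert res.score == 5.0
        assert res.percent_identity == 1.0
        assert res.unmatched_region_b == []

    def test_single_gap_column(self):
        res = align_global(ProteinRecord("a", "ACD"), ProteinRecord("b", "AD"))
        assert res.score == 0.0  # 2 matches - 1 gap
        assert res.aligned_a == "ACD" and res.aligned_b == "A-D"
        assert res.unmatched_region_b == [(1, 2)]

    def test_matches_exhaustive_enumeration(self):
        rnd = random.Random(8)
        for _ in range(60):
            a = "".join(rnd.choice("ACD") for _ in range(rnd.randint(1, 4)))
            b = "".join(rnd.choice("ACD") for _ in range(rnd.randint(1, 4)))
            assert align_global(ProteinRecord("a", a), ProteinRecord("b", b)).score == enumerate_alignments(a, b)

    def test_score_matches_biopython(self):
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        rnd = random.Random(15)
        for _ in range(25):
            a = "".join(rnd.choice(AA) for _ in range(rnd.randint(3, 25)))
            b = "".join(rnd.choice(AA) for _ in range(rnd.randint(3, 25)))
            assert align_global(ProteinRecord("a", a), ProteinRecord("b", b)).score == aligner.score(a, b)

    def test_score_symmetry(self):
        rnd = random.Random(2)
        for _ in range(20):
            a = "".join(rnd.choice(AA) for _ in range(rnd.randint(1, 12)))
            b = "".join(rnd.choice(AA) for _ in range(rnd.randint(1, 12)))
            fwd = align_global(ProteinRecord("a", a), ProteinRecord("b", b)).score
            rev = align_global(ProteinRecord("b", b), ProteinRecord("a", a)).score
            assert fwd == rev

    def test_degapped_alignment_recovers_inputs(self):
        res = align_global(ProteinRecord("a", "MKVWDPYSPS"), ProteinRecord("b", "MKWDYSPS"))
        assert res.aligned_a.replace("-", "") == "MKVWDPYSPS"
        assert res.aligned_b.replace("-", "") == "MKWDYSPS"

    def test_insertion_recovered_as_unmatched_region(self):
        base = "MKVLAEQWRTYHGFDSA"
        inserted = base[:8] + "DPYSPS" + base[8:]
        res = align_global(ProteinRecord("a", inserted), ProteinRecord("b", base))
        assert (8, 14) in res.unmatched_region_b

    def test_loop_unique_to_antigen_recovered(self):
        with_loop, without = make_loop_protein(seed=5)
        res = align_global(with_loop, without)
        spans = [iv for iv in res.unmatched_region_b if iv[1] - iv[0] >= 20]
        assert len(spans) == 1
        start, end = spans[0]
        loop = with_loop.sequence[start:end]
        assert "DPYSPS" in loop


class TestSimulatedArray:
    def test_noise_free_intervals_cover_motif_tiles(self):
        with_loop, _ = make_loop_protein(seed=3)
        tiles, signals, truth = simulate_peptide_array(with_loop, noise_sd=0.0)
        profile = map_array_signal(tiles, signals.tolist())
        assert profile.intervals == truth

    def test_no_motif_no_intervals(self):
        protein = ProteinRecord("p", "MKVLAEQWRTYHGFDSA" * 3)
        tiles, signals, truth = simulate_peptide_array(protein, noise_sd=0.0)
        assert truth == []
        assert map_array_signal(tiles, signals.tolist()).intervals == []

    def test_every_motif_copy_overlapped_by_a_called_interval(self):
        with_loop, _ = make_loop_protein(seed=8)
        tiles, signals, _ = simulate_peptide_array(with_loop, noise_sd=0.5, seed=4)
        profile = map_array_signal(tiles, signals.tolist())
        hits = scan_motif(with_loop, "DPYSPS")
        assert len(hits) == 3
        for h in hits:
            assert any(s < h.end and h.start < e for s, e in profile.intervals)
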