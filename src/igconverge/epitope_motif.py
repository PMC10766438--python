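"""Linear epitope mapping: peptide tiling, motif scanning, alignment.

Supports localizing linear epitopes such as the tandem DPYSPS repeat in the
flexible loop of the peanut 2S-albumin Ara h 2: overlapping k-mer tiling
(default 15-mers offset by 1), exact repeat-motif scanning with overlaps,
projection of per-tile array signals onto residues (max over covering
tiles), and global pairwise alignment against homologs (e.g., Ara h 6) to
expose regions unique to one protein. All coordinates are 0-based,
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError
from .airr_io import ProteinRecord


@dataclass
class PeptideTile:
    parent_id: str
    start: int
    length: int
    sequence: str

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class MotifHit:
    parent_id: str
    motif: str
    start: int

    @property
    def end(self) -> int:
        return self.start + len(self.motif)


def tile_protein(protein: ProteinRecord, k: int = 15, offset: int = 1) -> list[PeptideTile]:
    """Overlapping k-mer tiles at starts 0, offset, 2*offset, ...

    Tile count is floor((L-k)/offset) + 1.
    """
    seq = protein.sequence
    if k <= 0 or offset <= 0:
        raise ContractError("k and offset must be positive")
    if k > len(seq):
        raise ContractError(f"protein_too_short: {protein.id} has length {len(seq)} < k={k}")
    return [
        PeptideTile(protein.id, start, k, seq[start : start + k])
        for start in range(0, len(seq) - k + 1, offset)
    ]


def scan_motif(
    protein: ProteinRecord, motif: str, allow_overlap: bool = True
) -> list[MotifHit]:
    """All exact occurrences of ``motif``; overlapping hits included by default."""
    if not motif:
        raise ContractError("motif must be non-empty")
    motif = motif.upper()
    seq = protein.sequence
    hits: list[MotifHit] = []
    start = 0
    while True:
        idx = seq.find(motif, start)
        if idx < 0:
            break
        hits.append(MotifHit(protein.id, motif, idx))
        start = idx + 1 if allow_overlap else idx + len(motif)
    return hits


@dataclass
class ResidueProfile:
    """Per-residue array signal (max over covering tiles) with call intervals."""

    parent_id: str
    values: np.ndarray
    intervals: list[tuple[int, int]]  # 0-based half-open, above threshold
    threshold: float


def map_array_signal(
    tiles: list[PeptideTile],
    signals: list[float],
    threshold_fraction: float = 0.5,
) -> ResidueProfile:
    """Project per-tile signals onto residues.

    Each residue receives the maximum signal over all tiles covering it;
    contiguous runs at or above ``threshold_fraction`` of the profile
    maximum are reported as candidate epitope intervals (none when the
    profile is non-positive).
    """
    if len(tiles) != len(signals):
        raise ContractError(f"{len(tiles)} tiles but {len(signals)} signals")
    if not tiles:
        raise ContractError("map_array_signal requires at least one tile")
    length = max(t.end for t in tiles)
    values = np.zeros(length)
    for tile, s in zip(tiles, signals):
        seg = values[tile.start : tile.end]
        np.maximum(seg, s, out=seg)
    peak = float(values.max())
    intervals: list[tuple[int, int]] = []
    threshold = threshold_fraction * peak
    if peak > 0:
        above = values >= threshold
        start = None
        for i, flag in enumerate(above):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                intervals.append((start, i))
                start = None
        if start is not None:
            intervals.append((start, length))
    return ResidueProfile(tiles[0].parent_id, values, intervals, threshold)


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    unmatched_region_b: list[tuple[int, int]] = field(default_factory=list)


def align_global(
    a: ProteinRecord,
    b: ProteinRecord,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> AlignmentResult:
    """Needleman-Wunsch global alignment with linear gaps.

    Traceback ties resolve diagonal > up (gap in b) > left (gap in a),
    making the alignment deterministic. ``unmatched_region_b`` lists
    intervals of ``a`` (in a's coordinates, half-open) aligned entirely to
    gaps in ``b`` — candidate regions unique to ``a`` such as a
    homolog-absent loop.
    """
    sa, sb = a.sequence, b.sequence
    n, m = len(sa), len(sb)
    score = np.empty((n + 1, m + 1))
    score[0, :] = np.arange(m + 1) * gap
    score[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        prev, cur = score[i - 1], score[i]
        ca = sa[i - 1]
        for j in range(1, m + 1):
            sub = match if ca == sb[j - 1] else mismatch
            cur[j] = max(prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
    # traceback, diag > up > left on ties
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = match if sa[i - 1] == sb[j - 1] else mismatch
            if score[i, j] == score[i - 1, j - 1] + sub:
                out_a.append(sa[i - 1])
                out_b.append(sb[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(sb[j - 1])
        j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(x == y for x, y in zip(aligned_a, aligned_b) if x != "-" or y != "-")
    ncols = sum(1 for x, y in zip(aligned_a, aligned_b) if not (x == "-" and y == "-"))
    # intervals of a aligned entirely to gaps in b, in a-coordinates
    unmatched: list[tuple[int, int]] = []
    pos_a = 0
    run_start = None
    for x, y in zip(aligned_a, aligned_b):
        if x != "-" and y == "-":
            if run_start is None:
                run_start = pos_a
        else:
            if run_start is not None:
                unmatched.append((run_start, pos_a))
                run_start = None
        if x != "-":
            pos_a += 1
    if run_start is not None:
        unmatched.append((run_start, pos_a))
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score[n, m]),
        percent_identity=matches / ncols if ncols else 0.0,
        unmatched_region_b=unmatched,
    )


def hits_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"parent_id": h.parent_id, "motif": h.motif, "start": h.start, "end": h.end}
            for h in hits
        ],
        columns=["parent_id", "motif", "start", "end"],
    )
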