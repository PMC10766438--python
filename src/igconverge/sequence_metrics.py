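"""Pairwise edit distances, somatic hypermutation, and logo matrices.

Edit distances are unit-cost Levenshtein distances over variable-region
amino-acid sequences (computed by edlib). SHM is the position-wise
nucleotide mismatch fraction of the observed V segment against its germline
(IMGT-style percent mutation), with N positions excluded from both numerator
and denominator. Logo position-frequency matrices include an explicit gap
symbol and support a center-gap policy for aligning CDR3s of unequal length,
reflecting that junction conservation is strongest at both ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .errors import ContractError
from .airr_io import RearrangementRecord
from .qc_filter import PairedCell

GAP = "-"


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (substitution/insertion/deletion)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise edit distances plus a clustermap leaf order."""

    labels: list[str]
    values: np.ndarray
    chain: str
    order: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(cells: list[PairedCell], chain: str = "VH") -> DistanceMatrix:
    """Full pairwise edit-distance matrix over one chain's aa sequences.

    The returned ``order`` comes from average-linkage hierarchical
    clustering with labels pre-sorted for deterministic tie-breaking.
    """
    if chain not in ("VH", "VL"):
        raise ContractError(f"chain must be VH or VL, got {chain!r}")
    if len(cells) < 2:
        raise ContractError("distance_matrix needs at least 2 cells")
    ordered = sorted(cells, key=lambda c: c.cell_id)
    seqs = []
    for cell in ordered:
        rec = cell.heavy if chain == "VH" else cell.light
        aa = rec.aa_sequence()
        if not aa:
            raise ContractError(f"cell {cell.cell_id}: no {chain} sequence")
        seqs.append(aa)
    n = len(seqs)
    values = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d = edit_distance(seqs[i], seqs[j])
            values[i, j] = values[j, i] = d
    if np.all(values == 0):
        order = list(range(n))
    else:
        z = sch.linkage(ssd.squareform(values.astype(float), checks=False), method="average")
        order = sch.leaves_list(z).tolist()
    return DistanceMatrix(labels=[c.cell_id for c in ordered], values=values, chain=chain, order=order)


@dataclass
class SHMEstimate:
    cell_id: str
    chain: str
    n_mismatches_nt: int
    v_length_compared_nt: int
    shm_fraction: float


class NoGermlineError(ContractError):
    """Raised when a record carries no aligned germline V sequence."""


def shm_estimate(rec: RearrangementRecord) -> SHMEstimate:
    """Nucleotide mismatch fraction of the observed V segment vs germline.

    Positions where either string is N are excluded from numerator and
    denominator; comparison is case-insensitive.
    """
    if not rec.v_germline_nt:
        raise NoGermlineError(f"no_germline: cell {rec.cell_id} ({rec.locus})")
    germ = rec.v_germline_nt.upper()
    obs = rec.sequence_nt.upper()[: len(germ)]
    mism = compared = 0
    for o, g in zip(obs, germ):
        if o == "N" or g == "N":
            continue
        compared += 1
        mism += o != g
    frac = mism / compared if compared else 0.0
    return SHMEstimate(
        cell_id=rec.cell_id,
        chain="VH" if rec.locus == "IGH" else "VL",
        n_mismatches_nt=mism,
        v_length_compared_nt=compared,
        shm_fraction=frac,
    )


def shm_table(cells: list[PairedCell]) -> pd.DataFrame:
    """Per-cell, per-chain SHM; missing germlines yield NaN, never zero."""
    rows = []
    for cell in cells:
        for rec in (cell.heavy, cell.light):
            try:
                est = shm_estimate(rec)
                rows.append(
                    {
                        "cell_id": est.cell_id,
                        "chain": est.chain,
                        "n_mismatches_nt": est.n_mismatches_nt,
                        "v_length_compared_nt": est.v_length_compared_nt,
                        "shm_fraction": est.shm_fraction,
                    }
                )
            except NoGermlineError:
                rows.append(
                    {
                        "cell_id": rec.cell_id,
                        "chain": "VH" if rec.locus == "IGH" else "VL",
                        "n_mismatches_nt": np.nan,
                        "v_length_compared_nt": np.nan,
                        "shm_fraction": np.nan,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue frequencies (gap included) for logo rendering."""

    positions: list[int]
    frequencies: list[dict[str, float]]
    n_sequences: int
    gap_fraction: list[float]

    def to_frame(self) -> pd.DataFrame:
        alphabet = sorted({r for f in self.frequencies for r in f})
        return pd.DataFrame(
            [[f.get(r, 0.0) for r in alphabet] for f in self.frequencies],
            index=self.positions,
            columns=alphabet,
        )


def _pad(seq: str, width: int, align: str) -> str:
    gaps = GAP * (width - len(seq))
    if align == "left":
        return seq + gaps
    if align == "right":
        return gaps + seq
    if align == "center_gap":
        keep_left = math.ceil(len(seq) / 2)
        return seq[:keep_left] + gaps + seq[keep_left:]
    raise ContractError(f"unknown alignment policy {align!r}")


def logo_pfm(cdr3s: list[str], align: str = "center_gap") -> PositionFrequencyMatrix:
    """Position-frequency matrix over CDR3s of possibly unequal length.

    ``center_gap`` keeps ceil(L/2) residues left-anchored and floor(L/2)
    right-anchored, inserting gaps centrally up to the maximum length.
    """
    if not cdr3s:
        raise ContractError("logo_pfm requires at least one sequence")
    width = max(len(s) for s in cdr3s)
    padded = [_pad(s.upper(), width, align) for s in cdr3s]
    n = len(padded)
    frequencies = []
    gap_fraction = []
    for col in zip(*padded):
        freq: dict[str, float] = {}
        for r in col:
            freq[r] = freq.get(r, 0.0) + 1.0 / n
        frequencies.append(freq)
        gap_fraction.append(freq.get(GAP, 0.0))
    return PositionFrequencyMatrix(
        positions=list(range(width)),
        frequencies=frequencies,
        n_sequences=n,
        gap_fraction=gap_fraction,
    )
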