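"""Cell- and sequence-level retention criteria.

A cell is retained when it has exactly one passing heavy (IGH) and exactly
one passing light (IGK/IGL) chain and at least ``min_genes`` expressed genes.
A chain passes when its V segment exceeds ``min_v_length`` nucleotides, its
variable-region translation is stop-free up to the end of the junction, its
nucleotide sequence is unambiguous (A/C/G/T only), its CDR3 is in frame and
consistent with the reported amino acids, its constant-region call maps to
exactly one isotype, and the assembler called it productive.

Every verdict enumerates *all* failed criteria, and the per-reason tallies in
the :class:`QCReport` account for every rejected cell.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .airr_io import ExpressionProfile, RearrangementRecord, translate_nt

ISOTYPES = ("IgE", "IgG", "IgA", "IgM", "IgD", "other")

_HEAVY_ISOTYPE = {
    "IGHE": "IgE",
    "IGHG": "IgG",
    "IGHG1": "IgG",
    "IGHG2": "IgG",
    "IGHG3": "IgG",
    "IGHG4": "IgG",
    "IGHA": "IgA",
    "IGHA1": "IgA",
    "IGHA2": "IgA",
    "IGHM": "IgM",
    "IGHD": "IgD",
}


@dataclass
class QCConfig:
    """Thresholds for retention; defaults follow the standard criteria
    (>250 nt V segments, >=500 expressed genes)."""

    min_v_length: int = 250
    min_genes: int = 500


@dataclass
class PairedCell:
    """A QC-passing cell: exactly one heavy and one light productive chain."""

    cell_id: str
    subject_id: str
    sample_id: str
    heavy: RearrangementRecord
    light: RearrangementRecord
    isotype: str
    expression: ExpressionProfile | None = None


@dataclass
class QCReport:
    """Per-cell outcomes plus per-reason tallies over rejected cells."""

    outcomes: dict[str, str] = field(default_factory=dict)  # cell_id -> retained/rejected
    reasons: dict[str, list[str]] = field(default_factory=dict)
    tallies: Counter = field(default_factory=Counter)

    @property
    def n_retained(self) -> int:
        return sum(1 for v in self.outcomes.values() if v == "retained")

    @property
    def n_rejected(self) -> int:
        return sum(1 for v in self.outcomes.values() if v == "rejected")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": c,
                "outcome": o,
                "reasons": ",".join(self.reasons.get(c, [])),
            }
            for c, o in sorted(self.outcomes.items())
        ]
        return pd.DataFrame(rows, columns=["cell_id", "outcome", "reasons"])

    def summary(self) -> dict:
        return {
            "n_cells": len(self.outcomes),
            "n_retained": self.n_retained,
            "n_rejected": self.n_rejected,
            "reject_tallies": dict(sorted(self.tallies.items())),
        }


def resolve_isotype(c_call: str) -> str | None:
    """Map a constant-region call to a single isotype, or None if ambiguous.

    Multi-calls are comma-split and allele suffixes stripped; the call is
    unambiguous when exactly one distinct constant-region gene remains. Light
    chain constants (IGKC/IGLC) resolve to "other" at the cell level.
    """
    genes = {part.strip().split("*")[0] for part in c_call.split(",") if part.strip()}
    if len(genes) != 1:
        return None
    (gene,) = genes
    if gene.startswith(("IGKC", "IGLC")):
        return "other"
    return _HEAVY_ISOTYPE.get(gene, "other" if gene.startswith("IGH") else None)


def _stop_free_to_junction(rec: RearrangementRecord) -> bool:
    """True when the translation carries no stop codon before the junction end."""
    seq = rec.sequence_nt.upper()
    limit = len(seq)
    if rec.cdr3_nt:
        idx = seq.find(rec.cdr3_nt.upper())
        if idx >= 0:
            limit = idx + len(rec.cdr3_nt)
    aa = translate_nt(seq[rec.frame_offset : limit + (limit - rec.frame_offset) % 3])
    return "*" not in aa


def check_sequence(rec: RearrangementRecord, config: QCConfig | None = None) -> tuple[bool, list[str]]:
    """Return (passes, reason codes); reasons enumerate all failed criteria."""
    config = config or QCConfig()
    reasons: list[str] = []
    if rec.v_sequence_length_nt <= config.min_v_length:
        reasons.append("short_v")
    seq = rec.sequence_nt.upper()
    if set(seq) - set("ACGT"):
        reasons.append("ambiguous_nt")
    if not _stop_free_to_junction(rec):
        # ambiguous codons translate to X, not *, so an N alone never
        # triggers this reason; a real stop still does even alongside an N
        reasons.append("stop_codon")
    if rec.cdr3_nt:
        if len(rec.cdr3_nt) % 3 != 0 or (
            rec.cdr3_aa and translate_nt(rec.cdr3_nt) != rec.cdr3_aa
        ):
            reasons.append("frame")
    if resolve_isotype(rec.c_call) is None:
        reasons.append("ambiguous_c_call")
    if not rec.productive:
        reasons.append("nonproductive")
    return (not reasons, reasons)


def pair_cells(
    records: Sequence[RearrangementRecord],
    profiles: Sequence[ExpressionProfile] | None,
    config: QCConfig | None = None,
) -> tuple[list[PairedCell], QCReport]:
    """Pair heavy/light chains per cell and apply all retention criteria.

    ``profiles=None`` skips the expression criterion entirely (for re-pairing
    already-filtered tables); a cell *missing* from a provided profile list is
    rejected with reason ``no_expression``.
    """
    config = config or QCConfig()
    by_cell: dict[str, list[RearrangementRecord]] = defaultdict(list)
    for rec in records:
        by_cell[rec.cell_id].append(rec)
    prof_by_cell = {p.cell_id: p for p in profiles} if profiles is not None else None

    cells: list[PairedCell] = []
    report = QCReport()
    for cell_id in sorted(by_cell):
        recs = by_cell[cell_id]
        heavy = [r for r in recs if r.locus == "IGH"]
        light = [r for r in recs if r.locus in ("IGK", "IGL")]
        h_pass = [r for r in heavy if check_sequence(r, config)[0]]
        l_pass = [r for r in light if check_sequence(r, config)[0]]
        reasons: list[str] = []
        if len(h_pass) > 1 or len(l_pass) > 1:
            reasons.append("multiplet")
        if not h_pass:
            chain_reasons = sorted({c for r in heavy for c in check_sequence(r, config)[1]})
            reasons.extend(chain_reasons if chain_reasons else ["no_heavy"])
        if not l_pass:
            chain_reasons = sorted({c for r in light for c in check_sequence(r, config)[1]})
            reasons.extend(c for c in (chain_reasons if chain_reasons else ["no_light"]) if c not in reasons)
        profile = None
        if prof_by_cell is not None:
            profile = prof_by_cell.get(cell_id)
            if profile is None:
                reasons.append("no_expression")
            elif profile.n_genes_expressed < config.min_genes:
                reasons.append("min_genes")
        if reasons:
            report.outcomes[cell_id] = "rejected"
            report.reasons[cell_id] = reasons
            report.tallies.update(reasons)
        else:
            report.outcomes[cell_id] = "retained"
            h, l = h_pass[0], l_pass[0]
            cells.append(
                PairedCell(
                    cell_id=cell_id,
                    subject_id=h.subject_id,
                    sample_id=h.sample_id,
                    heavy=h,
                    light=l,
                    isotype=resolve_isotype(h.c_call) or "other",
                    expression=profile,
                )
            )
    return cells, report
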