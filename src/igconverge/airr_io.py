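"""Readers and writers for the formats the pipeline touches.

Three on-disk formats are supported, all plain text:

* AIRR-style rearrangement tables (TSV, one row per chain per cell), in two
  dialects: ``airr`` (standard AIRR Rearrangement column names, with
  ``subject_id``/``sample_id`` as custom extension columns) and ``minimal``
  (the nine columns the pipeline strictly needs).
* Gene-by-cell integer count matrices, as dense TSV (genes in rows, cells in
  columns) or MatrixMarket coordinate ``.mtx`` with ``<stem>.genes.tsv`` /
  ``<stem>.cells.tsv`` label sidecars.
* Protein FASTA (wrapped at 60 columns on write).

All positional coordinates written by this package are 0-based, half-open.
Readers never silently drop malformed rows: rejects are returned alongside
accepted records with a reason string each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ContractError

log = logging.getLogger(__name__)

LOCI = ("IGH", "IGK", "IGL")

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = _CODON_TABLE.forward_table
_STOPS = set(_CODON_TABLE.stop_codons)


def translate_nt(seq: str, frame: int = 0) -> str:
    """Translate DNA from ``frame``; stop codons -> ``*``, ambiguous -> ``X``.

    Trailing partial codons are ignored.
    """
    s = seq.upper()
    out = []
    for i in range(frame, len(s) - 2, 3):
        codon = s[i : i + 3]
        if codon in _FORWARD:
            out.append(_FORWARD[codon])
        elif codon in _STOPS:
            out.append("*")
        else:
            out.append("X")
    return "".join(out)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class RearrangementRecord:
    """One chain observation for one cell.

    ``sequence_nt`` is the assembled variable-region nucleotide sequence
    (V + junction + J); ``v_germline_nt`` is the germline V segment aligned
    position-wise to the start of the observed V portion.
    """

    cell_id: str
    subject_id: str
    locus: str
    v_call: str
    j_call: str
    sequence_nt: str
    sample_id: str = ""
    sequence_aa: str = ""
    junction_aa: str = ""
    cdr3_aa: str = ""
    cdr3_nt: str = ""
    v_sequence_length_nt: int = 0
    v_germline_nt: str = ""
    productive: bool = True
    c_call: str = ""
    frame_offset: int = 0

    def __post_init__(self):
        if not self.sequence_nt:
            raise ContractError("sequence_nt must be non-empty")
        if self.locus not in LOCI:
            raise ContractError(f"locus must be one of {LOCI}, got {self.locus!r}")
        if self.cdr3_aa and self.cdr3_nt and len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
            raise ContractError(
                f"cdr3_nt length {len(self.cdr3_nt)} != 3 x cdr3_aa length "
                f"{len(self.cdr3_aa)} for cell {self.cell_id}"
            )

    def aa_sequence(self) -> str:
        """The variable-region protein sequence, translating if absent."""
        if self.sequence_aa:
            return self.sequence_aa
        return translate_nt(self.sequence_nt, self.frame_offset)


@dataclass
class ExpressionProfile:
    """Per-cell gene expression counts."""

    cell_id: str
    counts: dict[str, int]
    n_genes_expressed: int = field(init=False)
    total_counts: int = field(init=False)

    def __post_init__(self):
        self.n_genes_expressed = sum(1 for v in self.counts.values() if v > 0)
        self.total_counts = int(sum(self.counts.values()))


@dataclass
class ProteinRecord:
    """A named protein sequence (uppercase; X permitted but flagged)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ContractError(f"empty protein sequence for {self.id!r}")
        self.sequence = self.sequence.upper()
        if "X" in self.sequence:
            log.warning("protein %s contains ambiguous residue X", self.id)


@dataclass
class Reject:
    """A row that could not be validated, with the 0-based data-row index."""

    row: int
    reason: str


# ---------------------------------------------------------------------------
# Rearrangement TSV
# ---------------------------------------------------------------------------

# our field name -> AIRR Rearrangement column name
_AIRR_COLS = {
    "cell_id": "cell_id",
    "subject_id": "subject_id",
    "sample_id": "sample_id",
    "locus": "locus",
    "v_call": "v_call",
    "j_call": "j_call",
    "sequence_nt": "sequence",
    "sequence_aa": "sequence_aa",
    "junction_aa": "junction_aa",
    "cdr3_aa": "cdr3_aa",
    "cdr3_nt": "cdr3",
    "v_sequence_length_nt": "v_sequence_length",
    "v_germline_nt": "v_germline_alignment",
    "productive": "productive",
    "c_call": "c_call",
    "frame_offset": "frame_offset",
}

_MINIMAL_COLS = (
    "cell_id",
    "subject_id",
    "locus",
    "v_call",
    "j_call",
    "sequence_nt",
    "cdr3_aa",
    "v_sequence_length_nt",
    "productive",
)

# fields that must be non-empty in every data row
_REQUIRED_FIELDS = ("cell_id", "subject_id", "locus", "v_call", "j_call", "sequence_nt")

_TRUTHY = {"t", "true", "1", "yes", "y"}
_FALSY = {"f", "false", "0", "no", "n", ""}


def _parse_bool(value: str, row: int) -> bool:
    v = str(value).strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise FormatError(f"row {row}: unparseable boolean {value!r}")


def read_rearrangements(
    path: str | Path, dialect: str = "airr"
) -> tuple[list[RearrangementRecord], list[Reject]]:
    """Read a rearrangement TSV into records plus a reject list.

    Rows with missing required fields are returned as :class:`Reject`
    entries, never silently dropped; accepted + rejected partition the data
    rows exactly.
    """
    path = Path(path)
    if dialect not in ("airr", "minimal"):
        raise ContractError(f"unknown dialect {dialect!r}")
    colmap = _AIRR_COLS if dialect == "airr" else {f: f for f in _MINIMAL_COLS}
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    required_cols = (
        [colmap[f] for f in _REQUIRED_FIELDS + ("v_sequence_length_nt", "productive")]
        if dialect == "minimal"
        else [colmap[f] for f in _REQUIRED_FIELDS]
    )
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[RearrangementRecord] = []
    rejects: list[Reject] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        kwargs: dict = {}
        bad = None
        for fname, col in colmap.items():
            kwargs[fname] = rowd.get(col, "")
        for fname in _REQUIRED_FIELDS:
            if not str(kwargs.get(fname, "")).strip():
                bad = f"missing {fname}"
                break
        if bad is None and kwargs["locus"] not in LOCI:
            bad = f"invalid locus {kwargs['locus']!r}"
        if bad is not None:
            rejects.append(Reject(i, bad))
            continue
        try:
            kwargs["productive"] = _parse_bool(kwargs.get("productive", "T"), i)
            kwargs["v_sequence_length_nt"] = int(kwargs.get("v_sequence_length_nt") or 0)
            kwargs["frame_offset"] = int(kwargs.get("frame_offset") or 0)
            records.append(RearrangementRecord(**kwargs))
        except (FormatError, ContractError, ValueError) as exc:
            rejects.append(Reject(i, str(exc)))
    return records, rejects


def write_rearrangements(
    records: Iterable[RearrangementRecord], path: str | Path, dialect: str = "airr"
) -> None:
    """Write records as a rearrangement TSV (inverse of read_rearrangements)."""
    path = Path(path)
    if dialect not in ("airr", "minimal"):
        raise ContractError(f"unknown dialect {dialect!r}")
    rows = []
    for rec in records:
        d = asdict(rec)
        d["productive"] = "T" if d["productive"] else "F"
        if dialect == "airr":
            rows.append({col: d[fname] for fname, col in _AIRR_COLS.items()})
        else:
            rows.append({f: d[f] for f in _MINIMAL_COLS})
    cols = list(_AIRR_COLS.values()) if dialect == "airr" else list(_MINIMAL_COLS)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


def _validate_counts(values: np.ndarray, genes: Sequence[str], cells: Sequence[str]) -> np.ndarray:
    bad = np.argwhere(~np.isfinite(values) | (values < 0) | (values != np.floor(values)))
    if bad.size:
        r, c = bad[0]
        raise FormatError(
            f"count matrix entry at gene {genes[r]!r}, cell {cells[c]!r} "
            f"is not a non-negative integer: {values[r, c]!r}"
        )
    return values.astype(np.int64)


def read_expression_matrix(path: str | Path) -> list[ExpressionProfile]:
    """Read a gene-by-cell count matrix (dense TSV or .mtx + label sidecars).

    Returns one :class:`ExpressionProfile` per cell column;
    ``n_genes_expressed`` counts strictly positive entries.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        genes = Path(path.with_suffix(".genes.tsv")).read_text().split()
        cells = Path(path.with_suffix(".cells.tsv")).read_text().split()
        mat = scipy.io.mmread(path)
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if values.shape != (len(genes), len(cells)):
            raise FormatError(
                f"{path}: matrix shape {values.shape} does not match labels "
                f"({len(genes)} genes x {len(cells)} cells)"
            )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    counts = _validate_counts(values, genes, cells)
    return [
        ExpressionProfile(cell_id=cell, counts=dict(zip(genes, counts[:, j].tolist())))
        for j, cell in enumerate(cells)
    ]


def write_expression_matrix(
    profiles: Sequence[ExpressionProfile], path: str | Path
) -> None:
    """Write profiles as gene-by-cell counts (dense TSV, or MTX if ``.mtx``)."""
    path = Path(path)
    genes = sorted({g for p in profiles for g in p.counts})
    cells = [p.cell_id for p in profiles]
    mat = np.zeros((len(genes), len(cells)), dtype=np.int64)
    gidx = {g: i for i, g in enumerate(genes)}
    for j, p in enumerate(profiles):
        for g, v in p.counts.items():
            mat[gidx[g], j] = v
    if path.suffix == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(mat))
        path.with_suffix(".genes.tsv").write_text("\n".join(genes) + "\n")
        path.with_suffix(".cells.tsv").write_text("\n".join(cells) + "\n")
    else:
        pd.DataFrame(mat, index=genes, columns=cells).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA; duplicate ids are an error, empty file a warning."""
    path = Path(path)
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
    ]
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise FormatError(f"{path}: duplicate FASTA ids: {', '.join(dups)}")
    if not records:
        log.warning("FASTA file %s is empty", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein FASTA, 60-column wrapped (inverse of read_fasta)."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def canonical_gene(symbol: str) -> str:
    """Case-insensitive gene symbol with any version suffix (``.1``) stripped."""
    s = symbol.strip().upper()
    head, dot, tail = s.rpartition(".")
    if dot and tail.isdigit():
        return head
    return s
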