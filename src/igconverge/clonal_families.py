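"""Clonal family inference and cross-subject convergence annotation.

Cells are first grouped by heavy-chain V gene, J gene and CDR3 length
(allele suffixes stripped), then clustered within each group at a CDR3
identity threshold (default 0.70, "70% or higher" merges). Single linkage —
connected components of the >=-threshold identity graph — is the default
clonotyping realization; complete linkage is available for sensitivity
analysis. A family whose members span two or more subjects is convergent
(public).

Light chains play no role in assignment; within-family light-chain V-gene
concordance is reported as a diagnostic only.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .errors import ContractError
from .qc_filter import PairedCell

_EPS = 1e-9


def strip_allele(call: str) -> str:
    """First gene of a (possibly multi-)call, with any ``*allele`` removed."""
    return call.split(",")[0].strip().split("*")[0]


@dataclass(frozen=True)
class CloneKey:
    """Grouping key: heavy V gene, heavy J gene, CDR3 amino-acid length."""

    vh_v_gene: str
    vh_j_gene: str
    cdr3_length: int

    def __post_init__(self):
        if self.cdr3_length <= 0:
            raise ContractError("cdr3_length must be positive")


@dataclass
class ClonalFamily:
    cf_id: str
    key: CloneKey
    members: list[PairedCell]
    subjects: set[str] = field(default_factory=set)
    n_subjects: int = 0
    isotype_composition: Counter = field(default_factory=Counter)
    is_convergent: bool = False
    consensus_cdr3_aa: str = ""
    persistence: dict[str, list[str]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)

    def light_v_concordance(self) -> float:
        """Fraction of members carrying the modal light-chain V gene."""
        genes = Counter(strip_allele(m.light.v_call) for m in self.members)
        return max(genes.values()) / len(self.members)


def cell_cdr3(cell: PairedCell, on: str = "aa") -> str:
    """The heavy-chain CDR3 used for clustering.

    Falls back to the junction minus its two anchor residues when only
    ``junction_aa`` is present (AIRR convention).
    """
    rec = cell.heavy
    if on == "nt":
        if not rec.cdr3_nt:
            raise ContractError(f"cell {cell.cell_id}: no cdr3_nt")
        return rec.cdr3_nt.upper()
    if rec.cdr3_aa:
        return rec.cdr3_aa.upper()
    if rec.junction_aa and len(rec.junction_aa) > 2:
        return rec.junction_aa[1:-1].upper()
    raise ContractError(f"cell {cell.cell_id}: no CDR3 amino-acid sequence")


def clone_key(cell: PairedCell) -> CloneKey:
    rec = cell.heavy
    length = len(rec.cdr3_aa) if rec.cdr3_aa else len(cell_cdr3(cell))
    return CloneKey(strip_allele(rec.v_call), strip_allele(rec.j_call), length)


def cdr3_identity(a: str, b: str) -> float:
    """Position-wise (Hamming) fractional identity of two equal-length CDR3s."""
    if len(a) != len(b):
        raise ContractError(f"cdr3_identity requires equal lengths ({len(a)} vs {len(b)})")
    if not a:
        raise ContractError("cdr3_identity requires non-empty sequences")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _single_linkage_components(cdr3s: list[str], threshold: float) -> list[int]:
    """Connected components of the >=threshold identity graph (union-find)."""
    n = len(cdr3s)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if cdr3_identity(cdr3s[i], cdr3s[j]) >= threshold - _EPS:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    return [find(i) for i in range(n)]


def _complete_linkage_components(cdr3s: list[str], threshold: float) -> list[int]:
    n = len(cdr3s)
    if n == 1:
        return [0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - cdr3_identity(cdr3s[i], cdr3s[j])
            dist[i, j] = dist[j, i] = d
    z = sch.linkage(ssd.squareform(dist, checks=False), method="complete")
    labels = sch.fcluster(z, t=1.0 - threshold + _EPS, criterion="distance")
    return labels.tolist()


def build_clonal_families(
    cells: list[PairedCell],
    threshold: float = 0.70,
    linkage: str = "single",
    on: str = "aa",
) -> list[ClonalFamily]:
    """Partition cells into clonal families.

    Deterministic and input-order independent: cells are sorted by
    (subject_id, cell_id) before grouping, and family ids are assigned in
    sorted order of (key, first member).
    """
    if linkage not in ("single", "complete"):
        raise ContractError(f"unknown linkage {linkage!r}")
    ordered = sorted(cells, key=lambda c: (c.subject_id, c.cell_id))
    groups: dict[CloneKey, list[PairedCell]] = defaultdict(list)
    for cell in ordered:
        groups[clone_key(cell)].append(cell)

    cluster_fn = (
        _single_linkage_components if linkage == "single" else _complete_linkage_components
    )
    families: list[ClonalFamily] = []
    for key in sorted(groups, key=lambda k: (k.vh_v_gene, k.vh_j_gene, k.cdr3_length)):
        members = groups[key]
        cdr3s = [cell_cdr3(c, on=on) for c in members]
        labels = cluster_fn(cdr3s, threshold)
        by_label: dict[int, list[PairedCell]] = defaultdict(list)
        for cell, lab in zip(members, labels):
            by_label[lab].append(cell)
        # stable order: by first (already sorted) member of each component
        for lab in sorted(by_label, key=lambda l: (by_label[l][0].subject_id, by_label[l][0].cell_id)):
            fam_members = by_label[lab]
            fam = ClonalFamily(cf_id="", key=key, members=fam_members)
            fam.subjects = {m.subject_id for m in fam_members}
            fam.n_subjects = len(fam.subjects)
            fam.isotype_composition = Counter(m.isotype for m in fam_members)
            fam.consensus_cdr3_aa = consensus_cdr3(fam)
            families.append(fam)
    for i, fam in enumerate(families):
        fam.cf_id = f"CF{i + 1:04d}"
    return families


def annotate_convergence(families: list[ClonalFamily]) -> list[ClonalFamily]:
    """Flag public families (members from >=2 subjects) and fill the
    per-subject sample persistence table supporting longitudinal claims."""
    for fam in families:
        fam.subjects = {m.subject_id for m in fam.members}
        fam.n_subjects = len(fam.subjects)
        fam.is_convergent = fam.n_subjects >= 2
        persistence: dict[str, set[str]] = defaultdict(set)
        for m in fam.members:
            persistence[m.subject_id].add(m.sample_id)
        fam.persistence = {s: sorted(v) for s, v in sorted(persistence.items())}
    return families


def consensus_cdr3(fam: ClonalFamily) -> str:
    """Position-wise modal residue of the members' CDR3s; ties alphabetical."""
    if not fam.members:
        raise ContractError("consensus of an empty family")
    cdr3s = [cell_cdr3(c) for c in fam.members]
    out = []
    for col in zip(*cdr3s):
        counts = Counter(col)
        best = min(counts, key=lambda r: (-counts[r], r))
        out.append(best)
    return "".join(out)


def membership_frame(families: list[ClonalFamily]) -> pd.DataFrame:
    rows = []
    for fam in families:
        for m in fam.members:
            rows.append(
                {
                    "cell_id": m.cell_id,
                    "cf_id": fam.cf_id,
                    "subject_id": m.subject_id,
                    "sample_id": m.sample_id,
                    "vh_v_gene": fam.key.vh_v_gene,
                    "vh_j_gene": fam.key.vh_j_gene,
                    "cdr3_length": fam.key.cdr3_length,
                    "isotype": m.isotype,
                    "is_convergent": fam.is_convergent,
                }
            )
    return pd.DataFrame(rows)


def summary_frame(families: list[ClonalFamily]) -> pd.DataFrame:
    rows = [
        {
            "cf_id": fam.cf_id,
            "size": fam.size,
            "n_subjects": fam.n_subjects,
            "is_convergent": fam.is_convergent,
            "vh_v_gene": fam.key.vh_v_gene,
            "vh_j_gene": fam.key.vh_j_gene,
            "cdr3_length": fam.key.cdr3_length,
            "consensus_cdr3_aa": fam.consensus_cdr3_aa,
            "light_v_concordance": fam.light_v_concordance(),
            "isotypes": ";".join(f"{k}:{v}" for k, v in sorted(fam.isotype_composition.items())),
        }
        for fam in families
    ]
    return pd.DataFrame(rows)
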