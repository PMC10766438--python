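"""Ground-truth repertoire and expression simulator.

Emulates the statistical structure of a multi-subject single-cell antibody
discovery experiment: paired heavy/light chains assembled from a bundled toy
germline set, clonal families seeded by founder recombinations with
substitution-only CDR3 diversification and per-site V-region somatic
hypermutation, planted public (multi-subject) families, per-cell QC defects
with labels, and negative-binomial expression counts in which plasmablasts
are PRDM1-high/MS4A1-low and memory cells the reverse (plus a small
state-signature gene module so the partition is visible to unsupervised
methods, as it is for real antibody-secreting cells).

Everything derives from a single seeded NumPy generator, so runs are
byte-reproducible. The toy germline segments are bundled constants — no
download, and no attempt to match real human allele frequencies or SHM
hotspot targeting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .errors import ContractError
from .airr_io import ExpressionProfile, ProteinRecord, RearrangementRecord
from .epitope_motif import PeptideTile, scan_motif, tile_protein

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = _TABLE.forward_table
_STOPS = set(_TABLE.stop_codons)
_AA = "ACDEFGHIKLMNPQRSTVWY"
_NONSTOP = sorted(_FORWARD)
_CODONS_FOR = {aa: sorted(c for c, a in _FORWARD.items() if a == aa) for aa in _AA}
_BASES = "ACGT"

ISOTYPE_C_CALL = {"IgE": "IGHE", "IgG": "IGHG1", "IgA": "IGHA1", "IgM": "IGHM", "IgD": "IGHD"}

DEFECT_CLASSES = (
    "stop_codon",
    "ambiguous_nt",
    "short_v",
    "min_genes",
    "multiplet",
    "ambiguous_c_call",
)
# defects that make the resident heavy chain fail sequence QC
_HEAVY_FATAL = {"stop_codon", "ambiguous_nt", "short_v", "ambiguous_c_call"}


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_NONSTOP, size=n))


def _back_translate(rng: np.random.Generator, aa: str) -> list[str]:
    return [_CODONS_FOR[a][rng.integers(len(_CODONS_FOR[a]))] for a in aa]


def _make_germline() -> dict[str, dict[str, str]]:
    """Bundled toy germline set: >=10 V and >=4 J stop-free segments per locus."""
    rng = np.random.default_rng(20240601)
    germ: dict[str, dict[str, str]] = {}
    for locus in ("IGH", "IGK", "IGL"):
        segs: dict[str, str] = {}
        for i in range(1, 13):  # 12 V genes, 258-300 nt (>250 nt QC floor)
            n_codons = int(rng.integers(86, 101))
            segs[f"{locus}V{1 + i % 4}-{i}*01"] = _random_codons(rng, n_codons)
        for i in range(1, 6):  # 5 J genes
            segs[f"{locus}J{i}*01"] = _random_codons(rng, int(rng.integers(15, 21)))
        germ[locus] = segs
    return germ


GERMLINE = _make_germline()


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment."""

    n_subjects: int = 8
    cells_per_subject: int = 150
    n_public_families: int = 3
    n_private_families: int = 40
    shm_rate_per_site: float = 0.02
    cdr3_intra_family_mutation_rate: float = 0.05
    defect_rates: dict[str, float] = field(default_factory=dict)
    isotype_mix: dict[str, float] = field(
        default_factory=lambda: {"IgE": 0.9, "IgG": 0.1}
    )
    plasmablast_fraction: float = 0.6
    marker_fold_change: float = 8.0
    nb_dispersion: float = 0.25  # NB dispersion alpha; size r = 1/alpha
    n_genes: int = 1000
    n_signature_genes: int = 40
    samples_per_subject: int = 2
    seed: int = 0

    def validate(self) -> None:
        errs = []
        if self.n_subjects < 1 or self.cells_per_subject < 1:
            errs.append("n_subjects and cells_per_subject must be >= 1")
        if self.n_public_families < 0 or self.n_private_families < 0:
            errs.append("family counts must be >= 0")
        if self.n_public_families > 0 and self.n_subjects < 2:
            errs.append("public families need >= 2 subjects")
        total = self.n_subjects * self.cells_per_subject
        if self.n_public_families * 2 + self.n_private_families > total:
            errs.append("more planted family members than cells")
        for name, rate in self.defect_rates.items():
            if name not in DEFECT_CLASSES:
                errs.append(f"unknown defect class {name!r}")
            if not 0 <= rate <= 1:
                errs.append(f"defect rate for {name} outside [0,1]")
        for label, mix in (("isotype_mix", self.isotype_mix),):
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                errs.append(f"{label} must sum to 1")
        if not 0 <= self.plasmablast_fraction <= 1:
            errs.append("plasmablast_fraction outside [0,1]")
        if not 0 <= self.shm_rate_per_site <= 1:
            errs.append("shm_rate_per_site outside [0,1]")
        if not 0 <= self.cdr3_intra_family_mutation_rate <= 1:
            errs.append("cdr3_intra_family_mutation_rate outside [0,1]")
        if self.n_genes < self.n_signature_genes + 2:
            errs.append("n_genes too small for markers plus signature")
        if errs:
            raise ContractError("invalid SimulationConfig: " + "; ".join(errs))


@dataclass
class GroundTruth:
    """Planted per-cell and per-family labels, consistent with emitted files."""

    cells: dict[str, dict]
    families: dict[str, dict]

    def family_labels(self) -> dict[str, str]:
        return {c: d["family"] for c, d in self.cells.items()}

    def public_family_ids(self) -> set[str]:
        return {f for f, d in self.families.items() if d["public"]}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"cells": self.cells, "families": self.families}, indent=1, sort_keys=True)
        )


@dataclass
class _Founder:
    fam_id: str
    locus_l: str
    vh: str
    jh: str
    vl: str
    jl: str
    cdr3h_aa: str
    cdr3h_codons: list[str]
    cdr3l_aa: str
    cdr3l_codons: list[str]


def _mutate_v(rng: np.random.Generator, v_nt: str, rate: float) -> str:
    """Per-site substitutions avoiding stop-codon creation (frame 0)."""
    seq = list(v_nt)
    n_mut = rng.binomial(len(seq), rate)
    if n_mut == 0:
        return v_nt
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    for pos in positions:
        codon_start = 3 * (pos // 3)
        alternatives = [b for b in _BASES if b != seq[pos]]
        rng.shuffle(alternatives)
        for base in alternatives:
            codon = seq[codon_start : codon_start + 3]
            codon[pos - codon_start] = base
            if "".join(codon) not in _STOPS:
                seq[pos] = base
                break
    return "".join(seq)


def _mutate_cdr3(
    rng: np.random.Generator, aa: str, codons: list[str], rate: float
) -> tuple[str, list[str]]:
    # capped so expected intra-family pairwise identity stays >= ~0.8
    rate = min(rate, 0.10)
    out_aa = list(aa)
    out_codons = list(codons)
    for i in range(len(out_aa)):
        if rng.random() < rate:
            new = _AA[rng.integers(len(_AA))]
            while new == out_aa[i]:
                new = _AA[rng.integers(len(_AA))]
            out_aa[i] = new
            out_codons[i] = _CODONS_FOR[new][rng.integers(len(_CODONS_FOR[new]))]
    return "".join(out_aa), out_codons


def _make_founder(rng: np.random.Generator, fam_id: str, used: list[tuple]) -> _Founder:
    """Draw a founder recombination whose key+CDR3 cannot collide with
    an existing family at the clustering threshold."""
    for _ in range(200):
        vh = str(rng.choice(sorted(g for g in GERMLINE["IGH"] if g.startswith("IGHV"))))
        jh = str(rng.choice(sorted(g for g in GERMLINE["IGH"] if g.startswith("IGHJ"))))
        cdr3h_len = int(rng.integers(10, 19))
        cdr3h = "".join(rng.choice(list(_AA), size=cdr3h_len))
        key = (vh.split("*")[0], jh.split("*")[0], cdr3h_len)
        collision = any(
            k == key and sum(x == y for x, y in zip(c, cdr3h)) / cdr3h_len >= 0.5
            for k, c in used
        )
        if not collision:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise ContractError("could not draw a non-colliding founder CDR3")
    used.append((key, cdr3h))
    locus_l = "IGK" if rng.random() < 0.6 else "IGL"
    vl = str(rng.choice(sorted(g for g in GERMLINE[locus_l] if g.startswith(f"{locus_l}V"))))
    jl = str(rng.choice(sorted(g for g in GERMLINE[locus_l] if g.startswith(f"{locus_l}J"))))
    cdr3l = "".join(rng.choice(list(_AA), size=int(rng.integers(9, 12))))
    return _Founder(
        fam_id=fam_id,
        locus_l=locus_l,
        vh=vh,
        jh=jh,
        vl=vl,
        jl=jl,
        cdr3h_aa=cdr3h,
        cdr3h_codons=_back_translate(rng, cdr3h),
        cdr3l_aa=cdr3l,
        cdr3l_codons=_back_translate(rng, cdr3l),
    )


def _make_chain(
    rng: np.random.Generator,
    cell_id: str,
    subject: str,
    sample: str,
    locus: str,
    v_call: str,
    j_call: str,
    cdr3_aa: str,
    cdr3_codons: list[str],
    c_call: str,
    config: SimulationConfig,
) -> RearrangementRecord:
    v_germ = GERMLINE[locus][v_call]
    j_nt = GERMLINE[locus][j_call]
    cdr3_aa, cdr3_codons = _mutate_cdr3(
        rng, cdr3_aa, cdr3_codons, config.cdr3_intra_family_mutation_rate
    )
    v_obs = _mutate_v(rng, v_germ, config.shm_rate_per_site)
    cdr3_nt = "".join(cdr3_codons)
    return RearrangementRecord(
        cell_id=cell_id,
        subject_id=subject,
        sample_id=sample,
        locus=locus,
        v_call=v_call,
        j_call=j_call,
        sequence_nt=v_obs + cdr3_nt + j_nt,
        junction_aa="C" + cdr3_aa + "W",
        cdr3_aa=cdr3_aa,
        cdr3_nt=cdr3_nt,
        v_sequence_length_nt=len(v_obs),
        v_germline_nt=v_germ,
        productive=True,
        c_call=c_call,
        frame_offset=0,
    )


def _apply_heavy_defects(
    rng: np.random.Generator, rec: RearrangementRecord, defects: list[str]
) -> RearrangementRecord:
    v = list(rec.sequence_nt[: rec.v_sequence_length_nt])
    germ = rec.v_germline_nt
    tail = rec.sequence_nt[rec.v_sequence_length_nt :]
    if "short_v" in defects:
        v = v[:246]  # 82 codons, fails the >250 nt criterion, keeps frame
        germ = germ[:246]
    n_codons = len(v) // 3
    if "stop_codon" in defects:
        # second half of V, clear of any planted N (placed in the first half)
        codon_idx = int(rng.integers(n_codons // 2, n_codons - 1))
        stop = str(rng.choice(sorted(_STOPS)))
        v[3 * codon_idx : 3 * codon_idx + 3] = list(stop)
    if "ambiguous_nt" in defects:
        pos = int(rng.integers(0, (n_codons // 2) * 3))
        v[pos] = "N"
    rec.sequence_nt = "".join(v) + tail
    rec.v_sequence_length_nt = len(v)
    rec.v_germline_nt = germ
    if "ambiguous_c_call" in defects:
        rec.c_call = "IGHE,IGHG1"
    return rec


def _allocate_members(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[list[tuple[str, str]], dict[str, list[str]]]:
    """Return per-family subject assignments honouring per-subject budgets.

    Public families always span >= 2 subjects; private families belong to a
    single subject; every cell budget is spent.
    """
    subjects = [f"S{i:02d}" for i in range(1, config.n_subjects + 1)]
    budget = {s: config.cells_per_subject for s in subjects}
    fam_ids = [f"PUB{i:02d}" for i in range(1, config.n_public_families + 1)] + [
        f"PRV{i:03d}" for i in range(1, config.n_private_families + 1)
    ]
    owners: dict[str, str] = {}
    for i, fid in enumerate(f for f in fam_ids if f.startswith("PRV")):
        owners[fid] = subjects[i % len(subjects)]
    reserved = {s: sum(1 for o in owners.values() if o == s) for s in subjects}
    if any(budget[s] < reserved[s] for s in subjects):
        raise ContractError("infeasible config: private families exceed subject budgets")

    members: dict[str, list[str]] = {fid: [] for fid in fam_ids}
    total = sum(budget.values())
    base = max(3, min(17, (total - config.n_private_families) // max(1, config.n_public_families) + 1))
    for fid in (f for f in fam_ids if f.startswith("PUB")):
        size = int(rng.integers(2, base)) if base > 2 else 2
        for k in range(size):
            free = [s for s in subjects if budget[s] - reserved[s] > 0]
            if not free:
                break
            if k == 1 and len({*members[fid]}) == 1:
                alt = [s for s in free if s != members[fid][0]]
                free = alt or free
            weights = np.array([budget[s] - reserved[s] for s in free], dtype=float)
            s = str(rng.choice(free, p=weights / weights.sum()))
            members[fid].append(s)
            budget[s] -= 1
        if len(set(members[fid])) < 2:
            raise ContractError("infeasible config: cannot span 2 subjects for a public family")
    for s in subjects:
        owned = [f for f, o in owners.items() if o == s]
        leftover = budget[s] - reserved[s]
        if owned:
            extra = rng.multinomial(leftover, np.ones(len(owned)) / len(owned))
            for fid, e in zip(owned, extra):
                members[fid].extend([s] * (1 + int(e)))
            budget[s] = 0
        elif leftover + reserved[s] > 0:
            pubs = [f for f in fam_ids if f.startswith("PUB")]
            if not pubs:
                raise ContractError("infeasible config: leftover cells but no families to hold them")
            for _ in range(budget[s]):
                members[str(rng.choice(pubs))].append(s)
            budget[s] = 0
    assignments = [(fid, s) for fid in fam_ids for s in members[fid]]
    return assignments, members


def _expression_counts(
    rng: np.random.Generator,
    genes: list[str],
    base_mu: np.ndarray,
    state_mu: dict[str, np.ndarray],
    state: str,
    low_gene_count: bool,
    r: float,
) -> np.ndarray:
    mu = state_mu[state]
    counts = rng.negative_binomial(r, r / (r + mu))
    if low_gene_count:
        keep = np.zeros(len(genes), dtype=bool)
        keep[rng.choice(len(genes), size=min(300, len(genes)), replace=False)] = True
        counts = np.where(keep, counts, 0)
    return counts


def simulate_repertoire(
    config: SimulationConfig,
) -> tuple[list[RearrangementRecord], list[ExpressionProfile], GroundTruth]:
    """Generate rearrangements, expression and ground truth from one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    assignments, fam_members = _allocate_members(rng, config)
    fam_ids = sorted(fam_members, key=lambda f: (not f.startswith("PUB"), f))

    used: list[tuple] = []
    founders = {fid: _make_founder(rng, fid, used) for fid in fam_ids}

    genes = (
        ["PRDM1", "MS4A1"]
        + [f"PBSG{i:03d}" for i in range(config.n_signature_genes // 2)]
        + [f"MEMG{i:03d}" for i in range(config.n_signature_genes - config.n_signature_genes // 2)]
        + [f"GENE{i:04d}" for i in range(config.n_genes - 2 - config.n_signature_genes)]
    )
    base_mu = np.clip(rng.gamma(2.0, 2.0, size=len(genes)), 0.5, None)
    lo, hi = 5.0, 5.0 * config.marker_fold_change
    sig_hi, sig_lo = 8.0, 2.0
    mu_pb = base_mu.copy()
    mu_mem = base_mu.copy()
    for i, g in enumerate(genes):
        if g == "PRDM1":
            mu_pb[i], mu_mem[i] = hi, lo
        elif g == "MS4A1":
            mu_pb[i], mu_mem[i] = lo, hi
        elif g.startswith("PBSG"):
            mu_pb[i], mu_mem[i] = sig_hi, sig_lo
        elif g.startswith("MEMG"):
            mu_pb[i], mu_mem[i] = sig_lo, sig_hi
    state_mu = {"plasmablast": mu_pb, "naive_memory": mu_mem}
    r = 1.0 / config.nb_dispersion

    iso_names = sorted(config.isotype_mix)
    iso_probs = np.array([config.isotype_mix[k] for k in iso_names])
    samples = {
        s: [f"{s}_d{j + 1}" for j in range(config.samples_per_subject)]
        for s in {subj for _, subj in assignments}
    }

    records: list[RearrangementRecord] = []
    profiles: list[ExpressionProfile] = []
    truth_cells: dict[str, dict] = {}
    counters: dict[str, int] = {}
    for fid in fam_ids:
        founder = founders[fid]
        for subject in fam_members[fid]:
            counters[subject] = counters.get(subject, 0) + 1
            cell_id = f"{subject}_c{counters[subject]:04d}"
            sample = str(rng.choice(samples[subject]))
            isotype = str(rng.choice(iso_names, p=iso_probs))
            state = "plasmablast" if rng.random() < config.plasmablast_fraction else "naive_memory"
            defects = [d for d in DEFECT_CLASSES if rng.random() < config.defect_rates.get(d, 0.0)]
            if "multiplet" in defects and (_HEAVY_FATAL & set(defects)):
                defects.remove("multiplet")

            heavy = _make_chain(
                rng, cell_id, subject, sample, "IGH", founder.vh, founder.jh,
                founder.cdr3h_aa, founder.cdr3h_codons, ISOTYPE_C_CALL[isotype], config,
            )
            heavy = _apply_heavy_defects(rng, heavy, defects)
            light = _make_chain(
                rng, cell_id, subject, sample, founder.locus_l, founder.vl, founder.jl,
                founder.cdr3l_aa, founder.cdr3l_codons, f"{founder.locus_l}C", config,
            )
            records.append(heavy)
            records.append(light)
            if "multiplet" in defects:
                extra = _make_chain(
                    rng, cell_id, subject, sample, "IGH", founder.vh, founder.jh,
                    founder.cdr3h_aa, founder.cdr3h_codons, ISOTYPE_C_CALL[isotype], config,
                )
                records.append(extra)
            counts = _expression_counts(
                rng, genes, base_mu, state_mu, state, "min_genes" in defects, r
            )
            profiles.append(ExpressionProfile(cell_id=cell_id, counts=dict(zip(genes, counts.tolist()))))
            truth_cells[cell_id] = {
                "family": fid,
                "subject": subject,
                "sample": sample,
                "state": state,
                "isotype": isotype,
                "defects": sorted(defects),
            }

    truth_families = {
        fid: {
            "public": fid.startswith("PUB"),
            "founder_cdr3": founders[fid].cdr3h_aa,
            "vh_v_gene": founders[fid].vh.split("*")[0],
            "vh_j_gene": founders[fid].jh.split("*")[0],
            "subjects": sorted(set(fam_members[fid])),
            "size": len(fam_members[fid]),
        }
        for fid in fam_ids
    }
    return records, profiles, GroundTruth(cells=truth_cells, families=truth_families)


# ---------------------------------------------------------------------------
# Peptide-array simulation
# ---------------------------------------------------------------------------


def make_loop_protein(
    seed: int = 0,
    length: int = 160,
    loop: str = "DPYSPSQDPYSPSQDPDRRDPYSPSPY",
    loop_at: int = 70,
) -> tuple[ProteinRecord, ProteinRecord]:
    """A synthetic antigen carrying a tandem-repeat loop, plus a homolog
    identical except for the loop (for unique-region alignment checks)."""
    rng = np.random.default_rng(seed)
    backbone = "".join(rng.choice(list(_AA.replace("D", "").replace("P", "")), size=length))
    with_loop = backbone[:loop_at] + loop + backbone[loop_at:]
    homolog = list(backbone)
    for _ in range(max(3, length // 30)):  # sprinkle substitutions on the homolog
        i = int(rng.integers(length))
        homolog[i] = _AA[int(rng.integers(len(_AA)))]
    return (
        ProteinRecord(id="antigen_with_loop", sequence=with_loop),
        ProteinRecord(id="homolog_without_loop", sequence="".join(homolog)),
    )


def simulate_peptide_array(
    protein: ProteinRecord,
    motif: str = "DPYSPS",
    k: int = 15,
    offset: int = 1,
    high: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[PeptideTile], np.ndarray, list[tuple[int, int]]]:
    """Per-tile binding signals: tiles containing >=1 full motif copy get a
    high mean, others baseline zero, Gaussian noise added (clipped at 0).

    Returns (tiles, signals, truth intervals), where truth intervals are the
    residue spans (0-based half-open) covered by motif-containing tiles.
    """
    rng = np.random.default_rng(seed)
    tiles = tile_protein(protein, k=k, offset=offset)
    hits = scan_motif(protein, motif)
    contains = np.array(
        [any(h.start >= t.start and h.end <= t.end for h in hits) for t in tiles]
    )
    signals = np.where(contains, high, 0.0)
    if noise_sd > 0:
        signals = np.clip(signals + rng.normal(0.0, noise_sd, size=len(tiles)), 0.0, None)
    covered = np.zeros(len(protein.sequence), dtype=bool)
    for t, has in zip(tiles, contains):
        if has:
            covered[t.start : t.end] = True
    intervals: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(covered):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, len(covered)))
    return tiles, signals, intervals
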