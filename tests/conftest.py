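import numpy as np
import pytest

from igconverge.airr_io import ExpressionProfile, RearrangementRecord
from igconverge.qc_filter import PairedCell
from igconverge.synthetic_data import SimulationConfig, simulate_repertoire

# stop-free heavy-chain scaffold used by hand-built records: 86 codons (258 nt)
_V_NT = ("GCT" * 40 + "GAA" * 26 + "TGT" * 20)
_J_NT = "TGGGGCCAAGGA"


def make_record(
    cell_id="cellA",
    subject_id="S01",
    locus="IGH",
    cdr3_aa="ARDYW",
    v_call="IGHV1-1*01",
    j_call="IGHJ4*01",
    c_call="IGHE",
    v_nt=_V_NT,
    **kwargs,
):
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1].forward_table
    codon = {aa: min(c for c, a in table.items() if a == aa) for aa in set(table.values())}
    cdr3_nt = "".join(codon[a] for a in cdr3_aa)
    defaults = dict(
        cell_id=cell_id,
        subject_id=subject_id,
        sample_id=f"{subject_id}_d1",
        locus=locus,
        v_call=v_call,
        j_call=j_call,
        sequence_nt=v_nt + cdr3_nt + _J_NT,
        junction_aa="C" + cdr3_aa + "W",
        cdr3_aa=cdr3_aa,
        cdr3_nt=cdr3_nt,
        v_sequence_length_nt=len(v_nt),
        v_germline_nt=v_nt,
        productive=True,
        c_call=c_call,
        frame_offset=0,
    )
    defaults.update(kwargs)
    return RearrangementRecord(**defaults)


def make_light(cell_id="cellA", subject_id="S01", **kwargs):
    kwargs.setdefault("locus", "IGK")
    kwargs.setdefault("v_call", "IGKV1-1*01")
    kwargs.setdefault("j_call", "IGKJ1*01")
    kwargs.setdefault("c_call", "IGKC")
    kwargs.setdefault("cdr3_aa", "QQSYS")
    return make_record(cell_id=cell_id, subject_id=subject_id, **kwargs)


def make_profile(cell_id="cellA", n_expressed=600, prdm1=40, ms4a1=5):
    counts = {f"GENE{i:04d}": 3 for i in range(n_expressed - 2)}
    counts.update({f"OFF{i:04d}": 0 for i in range(50)})
    counts["PRDM1"] = prdm1
    counts["MS4A1"] = ms4a1
    return ExpressionProfile(cell_id=cell_id, counts=counts)


def make_cell(cell_id="cellA", subject_id="S01", cdr3_aa="ARDYW", isotype="IgE", **heavy_kwargs):
    heavy = make_record(cell_id=cell_id, subject_id=subject_id, cdr3_aa=cdr3_aa, **heavy_kwargs)
    light = make_light(cell_id=cell_id, subject_id=subject_id)
    return PairedCell(
        cell_id=cell_id,
        subject_id=subject_id,
        sample_id=heavy.sample_id,
        heavy=heavy,
        light=light,
        isotype=isotype,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small clean repertoire with ground truth, shared across tests."""
    config = SimulationConfig(
        n_subjects=3,
        cells_per_subject=40,
        n_public_families=2,
        n_private_families=9,
        seed=11,
    )
    return config, simulate_repertoire(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
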