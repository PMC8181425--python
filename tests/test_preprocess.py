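"""Count preprocessing and disease-gene filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dime.errors import DimeError
from dime.io import DiseaseGeneNetwork, ImmunomeMatrix
from dime.preprocess import (
    CountMatrix,
    aggregate_median_by_celltype,
    counts_to_immunome,
    cpm_log_transform,
    filter_low_count_genes,
    remove_hla_genes,
    restrict_to_immunome,
)


def _cm(counts, celltypes=None):
    counts = np.asarray(counts)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    if celltypes is None:
        celltypes = {s: "ct0" for s in samples}
    else:
        celltypes = dict(zip(samples, celltypes))
    return CountMatrix(genes, samples, counts, celltypes)


# -------------------------------------------------------------- low-count filter


def test_filter_removes_gene_below_threshold_everywhere():
    # count 19 in all 20 samples: fraction below 20 is 1.0 >= 0.95 -> removed
    counts = np.vstack([np.full(20, 19), np.full(20, 100)])
    out = filter_low_count_genes(_cm(counts))
    assert out.gene_ids == ["g1"]


def test_filter_keeps_gene_with_enough_covered_samples():
    # 25 reads in 2 of 20 samples: low fraction 0.90 < 0.95 -> kept
    row = np.zeros(20); row[:2] = 25
    counts = np.vstack([row, np.full(20, 100)])
    out = filter_low_count_genes(_cm(counts))
    assert out.gene_ids == ["g0", "g1"]


def test_filter_min_count_zero_is_identity():
    counts = np.arange(40).reshape(2, 20)
    out = filter_low_count_genes(_cm(counts), min_count=0)
    assert out.gene_ids == ["g0", "g1"]


def test_filter_all_removed_errors():
    with pytest.raises(DimeError, match="threshold|filter"):
        filter_low_count_genes(_cm(np.zeros((2, 5))))


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000), lo=st.integers(1, 30))
def test_filter_monotone_in_min_count(seed, lo):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 60, size=(8, 10))
    counts[0] = 100  # keep at least one gene
    cm = _cm(counts)
    kept_lo = set(filter_low_count_genes(cm, min_count=lo).gene_ids)
    kept_hi = set(filter_low_count_genes(cm, min_count=lo + 10).gene_ids)
    assert kept_hi <= kept_lo


# ------------------------------------------------------------------ CPM + median


def test_cpm_closed_forms():
    counts = np.array([[0, 10], [5, 90]])
    cm = _cm(counts)
    expr = cpm_log_transform(cm)
    assert expr[0, 0] == 0.0  # log2(0 + 1)
    assert expr[0, 1] == pytest.approx(np.log2(1e5 + 1))
    assert expr[1, 1] == pytest.approx(np.log2(9e5 + 1))
    # single nonzero gene in a sample: CPM = 1e6
    assert expr[1, 0] == pytest.approx(np.log2(1e6 + 1))


def test_cpm_zero_library_names_sample():
    counts = np.array([[1, 0], [1, 0]])
    with pytest.raises(DimeError, match="s1"):
        cpm_log_transform(_cm(counts))


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_cpm_mass_conservation(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(1, 500, size=(6, 4))
    expr = cpm_log_transform(_cm(counts))
    back = np.power(2.0, expr) - 1.0
    assert np.allclose(back.sum(axis=0), 1e6, rtol=1e-9)


def test_median_conventions():
    expr = np.array([[1.0, 2.0, 9.0, 1.0, 3.0]])
    genes, samples = ["g0"], [f"s{i}" for i in range(5)]
    labels = {"s0": "A", "s1": "A", "s2": "A", "s3": "B", "s4": "B"}
    imm = aggregate_median_by_celltype(
        np.vstack([expr, expr]), ["g0", "g1"], samples, labels
    )
    assert imm.cell_ids == ["A", "B"]  # first-appearance order
    assert imm.values[0, 0] == 2.0  # odd n
    assert imm.values[0, 1] == 2.0  # even n midpoint of (1, 3)


def test_single_sample_per_celltype_is_relabeling():
    rng = np.random.default_rng(3)
    expr = rng.uniform(0, 5, size=(3, 2))
    labels = {"s0": "X", "s1": "Y"}
    imm = aggregate_median_by_celltype(expr, ["g0", "g1", "g2"], ["s0", "s1"], labels)
    assert np.allclose(imm.values, expr)


def test_counts_to_immunome_pipeline_runs():
    rng = np.random.default_rng(0)
    counts = rng.integers(25, 500, size=(10, 6))
    cm = _cm(counts, celltypes=["A"] * 3 + ["B"] * 3)
    imm = counts_to_immunome(cm)
    assert imm.cell_ids == ["A", "B"]
    assert (imm.values >= 0).all()


# ------------------------------------------------------------ gene-set filtering


def _net(genes, did="D1"):
    net = DiseaseGeneNetwork()
    for g in genes:
        net.add(did, did, g)
    return net


def test_hla_prefix_removal():
    net = remove_hla_genes(_net({"HLA-B", "TNF", "hla-DRB1", "HHLA2"}))
    assert net.diseases["D1"].genes == {"TNF", "HHLA2"}


def test_hla_removal_empty_set():
    net = DiseaseGeneNetwork()
    net.diseases = {}
    assert remove_hla_genes(net).diseases == {}


def test_hla_explicit_exclusion_list():
    net = remove_hla_genes(_net({"TNF", "MICA"}), exclusion_list={"MICA"})
    assert net.diseases["D1"].genes == {"TNF"}


def test_restrict_to_immunome(small_immunome):
    net = _net({"g1", "g2", "gX"})
    out = restrict_to_immunome(net, small_immunome)
    assert out.diseases["D1"].genes == {"g1", "g2"}


def test_restrict_drops_disease_outside_immunome(small_immunome, caplog):
    net = _net({"zz1", "zz2"}, did="D9")
    net.add("D1", "D1", "g1")
    net.add("D1", "D1", "g3")
    with caplog.at_level("WARNING"):
        out = restrict_to_immunome(net, small_immunome)
    assert "D9" not in out.diseases
    assert "D1" in out.diseases
    assert any("D9" in r.message for r in caplog.records)


def test_restrict_all_dropped_errors(small_immunome):
    with pytest.raises(DimeError):
        restrict_to_immunome(_net({"nope"}), small_immunome)
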