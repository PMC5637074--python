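"""Quantification: size selection, assignment, tails, CPM, families, lengths."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mirwaves import catalog as cat
from mirwaves import quantify as qt
from mirwaves import simulate as sim


# ---------------------------------------------------------------------------
# size selection

def test_size_select_bounds_are_inclusive():
    reads = [("r1", "A" * 15), ("r2", "A" * 16), ("r3", "A" * 29), ("r4", "A" * 30)]
    kept = qt.size_select(reads)
    assert [r[0] for r in kept] == ["r2", "r3"]


def test_size_select_empty():
    assert qt.size_select([]) == []


@given(st.lists(st.integers(1, 50), max_size=100))
def test_size_select_matches_comprehension_oracle(lengths):
    reads = [(f"r{i}", "G" * n) for i, n in enumerate(lengths)]
    kept = qt.size_select(reads, 16, 29)
    assert kept == [r for r in reads if 16 <= len(r[1]) <= 29]


# ---------------------------------------------------------------------------
# tail classification

def test_tail_classes_basic():
    assert qt.classify_tail("", "GG") == "unmodified"
    assert qt.classify_tail("AA", "AAG") == "templated_extension"
    assert qt.classify_tail("AA", "GU") == "adenylation"
    assert qt.classify_tail("TT", "GG") == "uridylation"
    assert qt.classify_tail("AU", "GG") == "other"


def test_tail_classification_matches_rule_oracle_exhaustively():
    alphabet = "ACGU"
    tails = [""] + ["".join(t) for n in (1, 2) for t in itertools.product(alphabet, repeat=n)]
    downstreams = ["".join(d) for d in itertools.product(alphabet, repeat=2)]

    def oracle(tail, down):
        if not tail:
            return "unmodified"
        if down[: len(tail)] == tail:
            return "templated_extension"
        if all(c == "A" for c in tail):
            return "adenylation"
        if all(c == "U" for c in tail):
            return "uridylation"
        return "other"

    for tail in tails:
        for down in downstreams:
            got = qt.classify_tail(tail, down)
            assert got == oracle(tail, down)
            assert got in qt.TAIL_CLASSES  # total function


# ---------------------------------------------------------------------------
# assignment

def _mini_catalog():
    """Two-gene toy: known genome string with two embedded matures."""
    genome, catalog = sim.make_toy_annotation(2, 0, seed=42)
    return genome, catalog


def test_exact_mature_read_is_assigned():
    genome, catalog = _mini_catalog()
    g = catalog.genes[0]
    mat = genome[g.scaffold][g.mature.start:g.mature.end]
    asn = qt.assign_reads([("r1", mat)], catalog, genome)["library"]
    assert asn.n_assigned == 1
    assert asn.counts[g.mature.arm_id] == 1.0
    assert asn.tail_class_weight["unmodified"] == 1.0


def test_nontemplated_tail_is_recorded():
    genome, catalog = _mini_catalog()
    g = catalog.genes[0]
    mat = genome[g.scaffold][g.mature.start:g.mature.end]
    # the +1 genomic base is forced to C, so an AA suffix is nontemplated
    asn = qt.assign_reads([("r1", mat + "AA")], catalog, genome)["library"]
    assert asn.n_assigned == 1
    assert asn.tail_class_weight["adenylation"] == 1.0


def test_templated_extension_not_called_modified():
    genome, catalog = _mini_catalog()
    g = catalog.genes[0]
    mat = genome[g.scaffold][g.mature.start:g.mature.end]
    down = genome[g.scaffold][g.mature.end:g.mature.end + 2]
    asn = qt.assign_reads([("r1", mat + down)], catalog, genome)["library"]
    # the suffix matches the genome, so it extends the templated prefix
    assert asn.tail_class_weight["unmodified"] == 1.0
    prof = qt.tailmod_profile(asn if isinstance(asn, dict) else {"library": asn})
    assert prof.loc["library", "frequency"] == 0.0


def test_unrelated_read_is_unassigned():
    genome, catalog = _mini_catalog()
    asn = qt.assign_reads([("r1", "ACGT" * 6)], catalog, genome)["library"]
    assert asn.n_assigned == 0 and asn.n_unassigned == 1


def test_multi_matching_read_splits_fractionally(default_annotation):
    genome, catalog, _ = default_annotation
    units = catalog.expression_units()
    # craft a genome with two identical mature loci under distinct unit ids
    g = catalog.genes[0]
    mat = genome[g.scaffold][g.mature.start:g.mature.end]
    twin_genome = {"s1": ("T" * 50 + mat + "C" + "T" * 60 + mat + "C" + "T" * 50)}
    arm = len(mat)
    def mk(gid, start):
        return cat.MirnaGene(
            gid, "s1", "+", start - 20, start + 2 * arm + 20,
            cat.Arm(f"{gid}-mat", mat, start, start + arm),
            cat.Arm(f"{gid}-star", "G" * arm, start + arm + 10, start + 2 * arm + 10),
            "novel",
        )
    twin_cat = cat.MirnaCatalog(genes=[mk("tw1", 50), mk("tw2", 50 + arm + 1 + 60)])
    # identical sequences collapse into ONE expression unit -> weight 1
    asn = qt.assign_reads([("r1", mat)], twin_cat, twin_genome)["library"]
    assert sum(asn.counts.values()) == pytest.approx(1.0)

    # distinct matures sharing a long prefix split the read between units
    mat2 = mat[:-1] + ("G" if mat[-1] != "G" else "A")
    twin_genome2 = {"s1": "T" * 50 + mat + "C" + "T" * 60 + mat2 + "C" + "T" * 50}
    twin_cat2 = cat.MirnaCatalog(genes=[mk("tw1", 50), mk("tw2", 50 + arm + 1 + 60)])
    twin_cat2.genes[1] = cat.MirnaGene(
        "tw2", "s1", "+", twin_cat2.genes[1].start, twin_cat2.genes[1].end,
        cat.Arm("tw2-mat", mat2, twin_cat2.genes[1].mature.start, twin_cat2.genes[1].mature.end),
        twin_cat2.genes[1].star, "novel",
    )
    shared_prefix = mat[:-1]
    asn2 = qt.assign_reads([("r1", shared_prefix)], twin_cat2, twin_genome2)["library"]
    weights = list(asn2.counts.values())
    assert len(weights) == 2
    assert sum(weights) == pytest.approx(1.0)
    assert weights[0] == pytest.approx(0.5)


def test_assignment_recall_against_truth(default_annotation, small_read_sim):
    genome, catalog, _ = default_annotation
    _, reads, truth = small_read_sim
    units = truth.unit_ids
    total = hit = 0
    for lib in ("ED0_rep1", "N3_rep2"):
        asn = qt.assign_reads({lib: reads[lib]}, catalog, genome, keep_read_units=True)[lib]
        rt = truth.reads[lib]
        for matched, ui in zip(asn.read_units, rt.unit_idx):
            if ui < 0:
                continue
            total += 1
            hit += units[ui] in matched
    assert total > 5000
    assert hit / total >= 0.99


def test_genome_mismatch_names_offending_feature():
    genome, catalog = _mini_catalog()
    g = catalog.genes[0]
    seq = genome[g.scaffold]
    bad = {g.scaffold: seq[: g.mature.start] + "N" * 5 + seq[g.mature.start + 5:]}
    with pytest.raises(ValueError, match=g.mature.arm_id):
        qt.assign_reads([("r1", "A" * 22)], catalog, bad)


# ---------------------------------------------------------------------------
# tail-modification profile

def test_tailmod_profile_zero_when_unmodified():
    la = qt.LibraryAssignment("L", counts={"u": 10}, n_assigned=10)
    la.tail_class_weight["unmodified"] = 10.0
    prof = qt.tailmod_profile({"L": la})
    assert prof.loc["L", "frequency"] == 0.0


def test_tailmod_recovery_on_generated_reads(default_annotation, small_read_sim, small_assignments):
    _, _, truth = small_read_sim
    prof = qt.tailmod_profile(small_assignments)
    stage = prof.index.str.rsplit("_rep", n=1).str[0]
    freq = prof["frequency"].groupby(stage).mean()
    # early-embryo burst tops every other stage (rates 0.20 vs 0.09)
    assert min(freq["ED0"], freq["ED1"]) > freq.drop(["ED0", "ED1"]).max()


def test_templated_extension_flag_moves_reads():
    la = qt.LibraryAssignment("L", counts={"u": 10}, n_assigned=10.0)
    la.tail_class_weight.update({"unmodified": 6.0, "templated_extension": 2.0,
                                 "adenylation": 2.0})
    off = qt.tailmod_profile({"L": la})
    on = qt.tailmod_profile({"L": la}, count_templated_extensions=True)
    assert off.loc["L", "frequency"] == pytest.approx(0.2)
    assert on.loc["L", "frequency"] == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# CPM + families

def test_cpm_single_gene_column():
    counts = pd.DataFrame({"L1": [7, 0]}, index=["a", "b"])
    cpm = qt.cpm_normalize(counts)
    assert cpm.loc["a", "L1"] == pytest.approx(1e6)


def test_cpm_scale_invariance_and_column_sums():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.integers(0, 500, (20, 4)) + 1,
                          index=[f"g{i}" for i in range(20)],
                          columns=list("ABCD"))
    cpm = qt.cpm_normalize(counts)
    assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-9)
    doubled = counts.copy()
    doubled["B"] *= 2
    assert np.allclose(qt.cpm_normalize(doubled)["B"], cpm["B"], rtol=1e-12)
    # direct formula oracle
    expected = counts * 1e6 / counts.sum(axis=0)
    assert np.allclose(cpm, expected, rtol=1e-9)


def test_cpm_zero_library_names_culprit():
    counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
    with pytest.raises(ValueError, match="empty"):
        qt.cpm_normalize(counts)


def test_family_expression_sums_members():
    cpm = pd.DataFrame({"L1": [10.0, 20.0, 30.0], "L2": [1.0, 2.0, 3.0]},
                       index=["a", "b", "c"])
    fams = [cat.MirnaFamily("f1", "SEEDAAA", ("a", "b")),
            cat.MirnaFamily("f2", "SEEDCCC", ("c",))]
    fx = qt.family_expression(cpm, fams)
    assert fx.loc["f1", "L1"] == 30.0 and fx.loc["f2", "L2"] == 3.0
    # singleton family equals the member row
    assert (fx.loc["f2"] == cpm.loc["c"]).all()


def test_family_holding_all_genes_sums_to_one_million():
    counts = pd.DataFrame({"L1": [5, 5, 10]}, index=["a", "b", "c"])
    cpm = qt.cpm_normalize(counts)
    fx = qt.family_expression(cpm, [cat.MirnaFamily("all", "NNNNNNN", ("a", "b", "c"))])
    assert fx.loc["all", "L1"] == pytest.approx(1e6)


def test_family_with_missing_member_errors():
    cpm = pd.DataFrame({"L1": [1.0]}, index=["a"])
    with pytest.raises(KeyError):
        qt.family_expression(cpm, [cat.MirnaFamily("f", "NNNNNNN", ("a", "ghost"))])


def test_random_partition_matches_group_sum_oracle():
    rng = np.random.default_rng(4)
    genes = [f"g{i}" for i in range(30)]
    cpm = pd.DataFrame(rng.uniform(0, 100, (30, 3)), index=genes, columns=list("XYZ"))
    labels = rng.integers(0, 5, 30)
    fams = [cat.MirnaFamily(f"f{k}", "NNNNNNN",
                            tuple(g for g, l in zip(genes, labels) if l == k))
            for k in range(5) if (labels == k).any()]
    fx = qt.family_expression(cpm, fams)
    for fam in fams:
        assert np.allclose(fx.loc[fam.family_id], cpm.loc[list(fam.member_ids)].sum(axis=0))


# ---------------------------------------------------------------------------
# length distribution

def test_length_peaks_at_22_and_28(small_read_sim):
    _, reads, _ = small_read_sim
    dist = qt.length_distribution(reads)
    for lib in ("NFE_rep1", "ED0_rep1"):
        assert 22 in dist.peaks[lib]
        assert 28 in dist.peaks[lib]


def test_single_length_single_peak():
    dist = qt.length_distribution([("r", "A" * 20), ("s", "C" * 20)])
    assert dist.peaks["library"] == [20]


def test_histogram_totals_match_counting_oracle():
    rng = np.random.default_rng(9)
    lengths = rng.integers(14, 32, 300)
    reads = [(f"r{i}", "A" * n) for i, n in enumerate(lengths)]
    dist = qt.length_distribution(reads)
    in_range = ((lengths >= 16) & (lengths <= 29)).sum()
    assert dist.histograms["library"].sum() == in_range
    for n in range(16, 30):
        assert dist.histograms.loc[n, "library"] == (lengths == n).sum()
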