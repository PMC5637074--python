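"""Coexpression: Spearman matrix, threshold network, modules, metagenes, CV."""

import numpy as np
import pandas as pd
import pytest

from conftest import spearman_bruteforce
from mirwaves import coexpression as cx
from mirwaves import quantify as qt
from mirwaves import simulate as sim
from mirwaves.stages import STAGES


# ---------------------------------------------------------------------------
# stage means

def test_stage_means_average_replicates():
    cpm = pd.DataFrame({f"{s}_rep{r}": [10.0 if r == 1 else 30.0] for s in STAGES for r in (1, 2)},
                       index=["g"])
    prof = cx.stage_means(cpm)
    assert (prof.loc["g"] == 20.0).all()


def test_stage_means_match_groupby_oracle(default_counts):
    counts, _ = default_counts
    cpm = qt.cpm_normalize(counts)
    prof = cx.stage_means(cpm)
    for stage in ("NFE", "ED2", "Adult"):
        expected = cpm[[f"{stage}_rep1", f"{stage}_rep2"]].mean(axis=1)
        assert np.allclose(prof[stage], expected)


def test_missing_stage_errors():
    cpm = pd.DataFrame({"ED0_rep1": [1.0]})
    with pytest.raises(ValueError, match="stages without libraries"):
        cx.stage_means(cpm)


# ---------------------------------------------------------------------------
# Spearman

def _profiles(rows):
    return pd.DataFrame(rows, columns=list(STAGES))


def test_monotone_profiles_correlate_perfectly():
    prof = _profiles([np.arange(1, 12), 2 * np.arange(1, 12)])
    rho = cx.spearman_matrix(prof)
    assert rho.iloc[0, 1] == pytest.approx(1.0)
    rev = _profiles([np.arange(1, 12), np.arange(11, 0, -1)])
    assert cx.spearman_matrix(rev).iloc[0, 1] == pytest.approx(-1.0)


def test_spearman_with_ties_matches_bruteforce_oracle():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 5, (6, 11)).astype(float)  # heavy ties
    rho = cx.spearman_matrix(_profiles(x))
    for i in range(6):
        for j in range(i + 1, 6):
            assert rho.iloc[i, j] == pytest.approx(spearman_bruteforce(x[i], x[j]), abs=1e-12)
    assert np.allclose(rho, rho.T)
    assert np.allclose(np.diag(rho), 1.0)


def test_spearman_invariant_under_monotone_transform():
    rng = np.random.default_rng(1)
    x = rng.uniform(1, 100, (4, 11))
    r1 = cx.spearman_matrix(_profiles(x))
    r2 = cx.spearman_matrix(_profiles(np.log(x) ** 3))
    assert np.allclose(r1, r2, atol=1e-12)


def test_constant_profile_becomes_zero_with_warning():
    prof = _profiles([np.arange(11.0), np.full(11, 5.0)])
    with pytest.warns(UserWarning, match="constant"):
        rho = cx.spearman_matrix(prof)
    assert rho.iloc[0, 1] == 0.0 and rho.iloc[1, 0] == 0.0
    assert rho.iloc[1, 1] == 1.0


# ---------------------------------------------------------------------------
# network + modules

def test_threshold_is_strict():
    rho = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=["a", "b"], columns=["a", "b"])
    net = cx.build_network(rho, 0.9)
    assert net.number_of_edges() == 0
    rho.iloc[0, 1] = rho.iloc[1, 0] = 0.900001
    assert cx.build_network(rho, 0.9).number_of_edges() == 1


def test_anticorrelation_never_connects():
    rho = pd.DataFrame([[1.0, -0.99], [-0.99, 1.0]], index=["a", "b"], columns=["a", "b"])
    assert cx.build_network(rho, 0.9).number_of_edges() == 0


def test_network_edges_match_comprehension_oracle():
    rng = np.random.default_rng(2)
    n = 15
    m = rng.uniform(-1, 1, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    names = [f"g{i}" for i in range(n)]
    rho = pd.DataFrame(m, index=names, columns=names)
    net = cx.build_network(rho, 0.3)
    expected = {frozenset((names[i], names[j])) for i in range(n)
                for j in range(i + 1, n) if m[i, j] > 0.3}
    assert {frozenset(e) for e in net.edges()} == expected


def test_two_cliques_two_modules():
    names = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
    m = np.eye(10)
    m[:5, :5] = 0.95
    m[5:, 5:] = 0.95
    np.fill_diagonal(m, 1.0)
    rho = pd.DataFrame(m, index=names, columns=names)
    mods = cx.find_modules(cx.build_network(rho, 0.9))
    assert [len(x.members) for x in mods] == [5, 5]
    assert mods[0].module_id == "CoMod-1"


def test_isolated_nodes_form_no_modules():
    rho = pd.DataFrame(np.eye(6))
    assert cx.find_modules(cx.build_network(rho, 0.9)) == []


def test_module_recovery_on_default_fixture(default_counts):
    counts, truth = default_counts
    prof = cx.stage_means(qt.cpm_normalize(counts))
    rho = cx.spearman_matrix(prof)
    net = cx.build_network(rho)
    mods = cx.find_modules(net)
    found = {g: m.module_id for m in mods for g in m.members}
    assert len(mods) == 4
    assert sim.recovery_ari(found, truth.module_label_of) >= 0.9


def test_split_on_constructed_block_matrix():
    # A1/A2 blocks: 0.91 across (inside the 0.9-0.925 band), 0.95 within
    names = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
    m = np.full((12, 12), 0.91)
    m[:6, :6] = 0.95
    m[6:, 6:] = 0.95
    np.fill_diagonal(m, 1.0)
    rho = pd.DataFrame(m, index=names, columns=names)
    net = cx.build_network(rho, 0.9)
    mods = cx.find_modules(net)
    assert len(mods) == 1 and len(mods[0].members) == 12
    subs = cx.split_largest(net, rho, 0.925)
    assert [sorted(s.members) for s in subs] == [sorted(names[:6]), sorted(names[6:])]
    assert all(s.parent == mods[0].module_id for s in subs)


def test_homogeneous_module_stays_whole():
    rho = pd.DataFrame(np.full((4, 4), 0.99) + 0.01 * np.eye(4))
    net = cx.build_network(rho, 0.9)
    subs = cx.split_largest(net, rho, 0.925)
    assert len(subs) == 1 and len(subs[0].members) == 4


def test_split_without_modules_errors():
    rho = pd.DataFrame(np.eye(4))
    with pytest.raises(ValueError):
        cx.split_largest(cx.build_network(rho, 0.9), rho)


def test_planted_submodule_split_recovered(default_counts):
    counts, truth = default_counts
    prof = cx.stage_means(qt.cpm_normalize(counts))
    rho = cx.spearman_matrix(prof)
    net = cx.build_network(rho)
    subs = cx.split_largest(net, rho)
    assert len(subs) == 2
    largest = cx.find_modules(net)[0]
    wave_truth = {g: truth.wave_of[g] for g in largest.members}
    found = {g: s.module_id for s in subs for g in s.members}
    assert sim.recovery_ari(found, wave_truth) >= 0.9


# ---------------------------------------------------------------------------
# metagene

def test_rank_one_module_recovers_direction_in_raw_mode():
    v = np.array([1.0, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1])
    prof = _profiles([2 * v, 5 * v, 0.5 * v])
    mg = cx.metagene(prof, standardize=False)
    assert np.linalg.norm(mg) == pytest.approx(1.0)
    assert np.allclose(mg, v / np.linalg.norm(v), atol=1e-12)


def test_metagene_matches_full_decomposition_oracle():
    rng = np.random.default_rng(3)
    x = rng.uniform(1, 50, (8, 11))
    prof = _profiles(x)
    mg = cx.metagene(prof)
    z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
    w, v = np.linalg.eigh(z.T @ z)  # independent eigendecomposition route
    top = v[:, np.argmax(w)]
    assert abs(np.dot(mg, top / np.linalg.norm(top))) >= 0.9999


def test_metagene_invariant_to_member_order():
    rng = np.random.default_rng(4)
    x = rng.uniform(1, 50, (7, 11))
    prof = _profiles(x)
    mg1 = cx.metagene(prof)
    mg2 = cx.metagene(prof.iloc[::-1])
    assert np.allclose(mg1, mg2, atol=1e-9)


def test_wave_b_metagene_peaks_at_ed2(default_counts):
    counts, truth = default_counts
    prof = cx.stage_means(qt.cpm_normalize(counts))
    b_genes = [g for g, w in truth.wave_of.items() if w == "B"]
    mg = cx.metagene(prof.loc[b_genes])
    assert STAGES[int(np.argmax(mg))] == "ED2"


def test_degenerate_module_errors():
    prof = _profiles([np.full(11, 3.0), np.full(11, 8.0)])
    with pytest.raises(ValueError):
        cx.metagene(prof)
    with pytest.raises(ValueError):
        cx.metagene(_profiles([np.arange(11.0)]))  # single member


# ---------------------------------------------------------------------------
# CV + Welch

def test_cv_of_constant_profile_is_zero():
    assert cx.expression_cv(_profiles([np.full(11, 7.0)])).iloc[0] == 0.0


def test_cv_single_spike_is_sqrt_eleven():
    prof = _profiles([[0.0] * 10 + [42.0]])
    assert cx.expression_cv(prof).iloc[0] == pytest.approx(np.sqrt(11))


def test_cv_matches_formula_oracle():
    rng = np.random.default_rng(5)
    x = rng.uniform(0.1, 100, (20, 11))
    cv = cx.expression_cv(_profiles(x))
    expected = x.std(axis=1, ddof=1) / x.mean(axis=1)
    assert np.allclose(cv, expected, rtol=1e-12)


def test_zero_mean_genes_excluded_with_warning():
    prof = _profiles([np.zeros(11), np.arange(11.0)])
    with pytest.warns(UserWarning, match="zero-mean"):
        cv = cx.expression_cv(prof)
    assert len(cv) == 1


def test_welch_identical_groups_null():
    t, df, p = cx.welch_test([1.0, 2, 3, 4], [1.0, 2, 3, 4])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_welch_matches_hand_formula():
    a = [27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1, 21.9, 22.6, 23.1, 19.6]
    b = [27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0, 24.8, 20.2, 21.9, 22.1]
    t, df, p = cx.welch_test(a, b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t_hand = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
    df_hand = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy import stats
    p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
    assert t == pytest.approx(t_hand, abs=1e-10)
    assert df == pytest.approx(df_hand, abs=1e-10)
    assert p == pytest.approx(p_hand, abs=1e-10)


def test_welch_needs_two_per_group():
    with pytest.raises(ValueError):
        cx.welch_test([1.0], [1.0, 2.0])


def test_novel_genes_vary_more_than_conserved(default_counts):
    """Newly discovered (mostly embryonic-wave) genes have higher expression
    CV across the 11 stages than conserved genes."""
    counts, truth = default_counts
    prof = cx.stage_means(qt.cpm_normalize(counts))
    cv = cx.expression_cv(prof)
    novel = cv[[g for g in cv.index if truth.provenance_of[g] != "conserved"]]
    conserved = cv[[g for g in cv.index if truth.provenance_of[g] == "conserved"]]
    assert novel.mean() > conserved.mean()
    _, _, p = cx.welch_test(novel, conserved)
    assert p < 0.01
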