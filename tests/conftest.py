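import numpy as np
import pytest
from hypothesis import settings

from mirwaves import quantify as qt
from mirwaves import simulate as sim

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

FIXTURE_SEED = sim.DEFAULT_SEED  # 20171011


@pytest.fixture(scope="session")
def default_counts():
    """The default 157-gene, 22-library count matrix with its ground truth."""
    return sim.simulate_counts(sim.SimConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def default_annotation():
    """Toy genome + 166-gene catalog + decoy loci used by quantification tests."""
    return sim.default_catalog(FIXTURE_SEED)


@pytest.fixture(scope="session")
def small_read_sim(default_annotation):
    """A light read simulation (5k reads/library) for assignment tests."""
    genome, catalog, decoys = default_annotation
    cfg = sim.SimConfig(seed=FIXTURE_SEED, read_lib_size_mean=5_000.0)
    reads, truth = sim.simulate_reads(cfg, catalog, genome, decoy_positions=decoys)
    return cfg, reads, truth


@pytest.fixture(scope="session")
def small_assignments(default_annotation, small_read_sim):
    genome, catalog, _ = default_annotation
    _, reads, _ = small_read_sim
    selected = {lib: qt.size_select(r) for lib, r in reads.items()}
    return qt.assign_reads(selected, catalog, genome)


@pytest.fixture(scope="session")
def default_species_panel():
    """Four-species NFE family-abundance fixture."""
    return sim.make_species_panel(FIXTURE_SEED)


def spearman_bruteforce(x, y):
    """Independent average-rank Spearman: rank by hand, then Pearson formula."""
    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den
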