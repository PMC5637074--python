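"""Synthetic small-RNA data with the statistical structure the analysis assumes.

The generator emulates the study design: 11 developmental stages x 2
replicate libraries, four co-expression waves (early-embryo A1, mid-embryo
A2, an acute ED2 spike B, and post-embryonic C) plus maternally loaded genes
peaking in the non-fertilized egg, a 22-nt miRNA / 28-nt piRNA-like read
length mixture, and stage-dependent nontemplated 3'-tailing (elevated in
ED0-ED1, mostly adenylation, then uridylation). Every stochastic choice is
recorded in a :class:`SimTruth` so downstream recovery can be scored.

Wave templates are peak-normalized 11-vectors designed by rank arithmetic:
the A1/A2 templates have Spearman rho = 1 - 6*20/1320 = 0.9091, inside the
(0.9, 0.925] band, so A1 and A2 genes merge into one module at the 0.9
network cut-off but separate at the 0.925 submodule cut-off; every other
template pair sits well below 0.9. Consecutive rank values are spaced by a
factor of 1.7 so replicate noise almost never flips the stage ranks that the
band arithmetic depends on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import Arm, MirnaCatalog, MirnaGene, CandidateEvidence
from .stages import STAGES, N_STAGES, REPLICATES, library_name

DEFAULT_SEED = 20171011

WAVE_NAMES = ("maternal", "A1", "A2", "B", "C")

#: designed stage ranks per template (1 = lowest intensity, 11 = peak).
#: The A1/A2 rank pair has sum(d^2) = 20, i.e. Spearman 1 - 20/220 = 0.9091,
#: inside the (0.9, 0.925] band; every other pair is far from both cut-offs.
_TEMPLATE_RANKS: dict[str, tuple[int, ...]] = {
    #           NFE ED0 ED1 ED2 ED6 ED13 N1 N3 N5 N6 Adult
    "maternal": (11, 10,  9,  7,  6,  5,  4,  3,  2,  1,  8),
    "A1":       ( 8, 11, 10,  9,  7,  6,  5,  4,  3,  2,  1),
    "A2":       ( 5,  9, 10, 11,  8,  7,  6,  4,  3,  2,  1),
    "B":        ( 1,  6,  9, 11, 10,  8,  7,  5,  4,  3,  2),
    "C":        ( 1,  2,  3,  4,  5,  6,  7,  8,  9, 10, 11),
}

#: geometric spacing between consecutive rank values; large enough that
#: replicate noise almost never reorders a template's stage ranks
_RANK_SPACING = 1.7

#: stage-intensity templates, peak-normalized, in STAGES order
_TEMPLATE_VALUES: dict[str, tuple[float, ...]] = {
    name: tuple(_RANK_SPACING ** (r - 11) for r in ranks)
    for name, ranks in _TEMPLATE_RANKS.items()
}

#: wave -> module-level label (A1 and A2 belong to the same 0.9-threshold module)
MODULE_OF_WAVE = {"maternal": "maternal", "A1": "A", "A2": "A", "B": "B", "C": "C"}


@dataclass(frozen=True)
class WaveTemplate:
    """A named, peak-normalized 11-stage intensity profile."""

    name: str
    profile: tuple[float, ...]

    def __post_init__(self):
        if len(self.profile) != N_STAGES:
            raise ValueError(f"template {self.name}: profile length != {N_STAGES}")
        if min(self.profile) < 0:
            raise ValueError(f"template {self.name}: negative intensity")
        if abs(max(self.profile) - 1.0) > 1e-9:
            raise ValueError(f"template {self.name}: profile is not peak-normalized")


def default_templates() -> list[WaveTemplate]:
    return [WaveTemplate(name, _TEMPLATE_VALUES[name]) for name in WAVE_NAMES]


def _default_tailmod_rates() -> dict[str, float]:
    # early-embryo tailing burst: ED0-ED1 within the observed 15-26% band,
    # all other stages within the 7-11% band
    return {s: (0.20 if s in ("ED0", "ED1") else 0.09) for s in STAGES}


def _default_pirna_fractions() -> dict[str, float]:
    # piRNA-like 28-mers are proportionally highest where the relative miRNA
    # share dips (ED0-ED1); values are free parameters of the toy model
    base = {s: 0.25 for s in STAGES}
    base.update({"NFE": 0.35, "ED0": 0.50, "ED1": 0.50, "ED2": 0.35})
    return base


@dataclass
class SimConfig:
    """Generator parameters; defaults encode the study conditions."""

    n_genes_per_wave: dict[str, int] = field(
        default_factory=lambda: {"maternal": 12, "A1": 20, "A2": 20, "B": 20, "C": 20}
    )
    n_background_genes: int = 65
    dispersion: float = 0.02
    lib_size_mean: float = 1_000_000.0
    read_lib_size_mean: float = 100_000.0
    tailmod_rate_by_stage: dict[str, float] = field(default_factory=_default_tailmod_rates)
    tail_composition: dict[str, float] = field(
        default_factory=lambda: {"A": 0.50, "U": 0.25, "other": 0.25}
    )
    pirna_fraction_by_stage: dict[str, float] = field(default_factory=_default_pirna_fractions)
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        for w, n in self.n_genes_per_wave.items():
            if w not in WAVE_NAMES:
                raise ValueError(f"unknown wave {w!r}")
            if n < 0:
                raise ValueError(f"negative gene count for wave {w}")
        if self.n_background_genes < 0:
            raise ValueError("negative background gene count")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.lib_size_mean <= 0 or self.read_lib_size_mean <= 0:
            raise ValueError("library size means must be positive")
        for name, m in (
            ("tailmod_rate_by_stage", self.tailmod_rate_by_stage),
            ("pirna_fraction_by_stage", self.pirna_fraction_by_stage),
        ):
            for s, fr in m.items():
                if s not in STAGES:
                    raise ValueError(f"{name}: unknown stage {s!r}")
                if not 0.0 <= fr <= 1.0:
                    raise ValueError(f"{name}[{s}] = {fr} outside [0, 1]")
        if set(self.tail_composition) != {"A", "U", "other"}:
            raise ValueError("tail_composition must have keys A, U, other")
        if abs(sum(self.tail_composition.values()) - 1.0) > 1e-9:
            raise ValueError("tail_composition must sum to 1")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


@dataclass
class ReadTruth:
    """Per-read ground truth for one library (parallel arrays)."""

    unit_idx: np.ndarray          # index into unit_ids; -1 for piRNA-like decoys
    templated_len: np.ndarray
    tails: list[str]


@dataclass
class SimTruth:
    """Ground-truth record: everything a recovery test needs."""

    wave_of: dict[str, str]
    provenance_of: dict[str, str]
    mean_profiles: pd.DataFrame | None = None      # genes x stages, true stage means
    size_factors: dict[str, float] | None = None
    tailmod_rate_by_stage: dict[str, float] | None = None
    tail_composition: dict[str, float] | None = None
    unit_ids: list[str] | None = None
    reads: dict[str, ReadTruth] = field(default_factory=dict)

    @property
    def module_label_of(self) -> dict[str, str]:
        return {g: MODULE_OF_WAVE.get(w, w) for g, w in self.wave_of.items()}


# ---------------------------------------------------------------------------
# provenance bookkeeping for simulated genes

def _assign_provenances(wave: str, n: int) -> list[str]:
    """Deterministic provenance mix per wave.

    Maternal loading mixes conserved housekeeping miRNAs with a few
    previously described species-restricted ones; the early-embryo waves are
    dominated by newly discovered miRNAs; the post-embryonic wave and the
    background are conserved. Proportions reproduce the catalog's
    88 conserved / 11 previous / 58 novel split at the default sizes.
    """
    if wave == "maternal":
        n_prev = round(0.25 * n)
        return ["conserved"] * (n - n_prev) + ["previous"] * n_prev
    if wave == "A2":
        n_prev = round(0.40 * n)
        return ["previous"] * n_prev + ["novel"] * (n - n_prev)
    if wave in ("A1", "B"):
        return ["novel"] * n
    if wave == "C":
        return ["conserved"] * n
    # background
    n_nov = round(0.09 * n)
    return ["conserved"] * (n - n_nov) + ["novel"] * n_nov


# ---------------------------------------------------------------------------
# count simulation

def simulate_counts(
    config: SimConfig,
    templates: Sequence[WaveTemplate] | None = None,
    gene_ids: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate the 22-library count matrix.

    Per-gene stage means are ``scale_g * template_w(stage)`` (background genes
    get an independent lognormal wiggle profile), columns are rescaled so each
    stage totals ``lib_size_mean``, and replicate counts are drawn
    NB(mean * size_factor, dispersion); dispersion 0 degenerates to Poisson.
    Identical configs give byte-identical output.
    """
    config.validate()
    templates = list(templates) if templates is not None else default_templates()
    if not templates:
        raise ValueError("no wave templates supplied")
    tmpl_by_name = {t.name: t for t in templates}
    for w, n in config.n_genes_per_wave.items():
        if n > 0 and w not in tmpl_by_name:
            raise ValueError(f"no template for wave {w!r}")

    rng = np.random.default_rng(config.seed)
    genes: list[str] = []
    waves: list[str] = []
    provs: list[str] = []
    profiles: list[np.ndarray] = []

    for w in WAVE_NAMES:
        n = config.n_genes_per_wave.get(w, 0)
        if n == 0:
            continue
        prof = np.asarray(tmpl_by_name[w].profile)
        ids = (gene_ids or {}).get(w) or [f"sim-{w}-{i + 1:03d}" for i in range(n)]
        if len(ids) != n:
            raise ValueError(f"gene_ids[{w}] has {len(ids)} ids, expected {n}")
        genes += list(ids)
        waves += [w] * n
        provs += _assign_provenances(w, n)
        profiles += [prof] * n

    n_bg = config.n_background_genes
    bg_ids = (gene_ids or {}).get("background") or [f"sim-bg-{i + 1:03d}" for i in range(n_bg)]
    if len(bg_ids) != n_bg:
        raise ValueError(f"gene_ids[background] has {len(bg_ids)} ids, expected {n_bg}")
    genes += list(bg_ids)
    waves += ["background"] * n_bg
    provs += _assign_provenances("background", n_bg)
    n_wave = len(profiles)
    for _ in range(n_bg):
        profiles.append(rng.lognormal(0.0, 0.35, N_STAGES))

    n_genes = len(genes)
    if n_genes == 0:
        raise ValueError("configuration yields zero genes")

    scales = rng.lognormal(mean=0.0, sigma=0.6, size=n_genes)
    mean_mat = np.asarray(profiles) * scales[:, None]
    # Keep stage totals constant by construction: the flat background pool
    # absorbs the stage-dependent wave mass (the highly expressed conserved
    # miRNAs act as a compositional buffer), so that CPM stage profiles of
    # wave genes follow their templates exactly rather than being warped by
    # a per-stage normalizer.
    if n_wave and n_bg:
        t_wave = mean_mat[:n_wave].sum(axis=0)
        total = t_wave.max() / 0.30  # wave mass peaks at 30% of the library
        fill = (total - t_wave) / mean_mat[n_wave:].sum(axis=0)
        mean_mat[n_wave:] *= fill[None, :]
        mean_mat *= config.lib_size_mean / total
    else:
        mean_mat *= config.lib_size_mean / mean_mat.sum(axis=0, keepdims=True)

    libs = [library_name(s, r) for s in STAGES for r in REPLICATES]
    size_factors = {lib: float(rng.lognormal(0.0, 0.05)) for lib in libs}

    counts = np.empty((n_genes, len(libs)), dtype=np.int64)
    alpha = config.dispersion
    for j, lib in enumerate(libs):
        stage_idx = STAGES.index(lib.rsplit("_rep", 1)[0])
        mu = mean_mat[:, stage_idx] * size_factors[lib]
        if alpha == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / alpha
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=libs)
    truth = SimTruth(
        wave_of=dict(zip(genes, waves)),
        provenance_of=dict(zip(genes, provs)),
        mean_profiles=pd.DataFrame(mean_mat, index=counts_df.index, columns=list(STAGES)),
        size_factors=size_factors,
        tailmod_rate_by_stage=dict(config.tailmod_rate_by_stage),
        tail_composition=dict(config.tail_composition),
    )
    return counts_df, truth


# ---------------------------------------------------------------------------
# toy genome + annotation

_DNA = np.frombuffer(b"ACGT", dtype="S1")
_COMP = str.maketrans("ACGT", "TGCA")

_FLANK = 12
_LOOP = 15


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_DNA, size=n).tobytes().decode()


def _make_precursor(rng: np.random.Generator, arm_len: int, mature_arm: str,
                    arm5_seq: str | None = None):
    """One hairpin: 5' flank + 5p arm + loop + 3p arm (revcomp of 5p) + 3' flank.

    The mature occupies one arm exactly; the star is the other arm shifted so
    the duplex carries a 2-nt 3' overhang on both strands. The base
    immediately downstream of the mature 3' end is forced to 'C' so that
    synthetic A/U tails are unambiguously nontemplated.
    """
    f, l, m = _FLANK, _LOOP, arm_len
    n = 2 * f + 2 * m + l
    s5 = arm5_seq if arm5_seq is not None else _random_dna(rng, m)
    loop = list(_random_dna(rng, l))
    flank5 = _random_dna(rng, f)
    flank3 = list(_random_dna(rng, f))
    if mature_arm == "5p":
        loop[0] = "C"                       # +1 base after the 5p mature
        mature_rel = (f, f + m)
        star_rel = (n - f - m + 2, n - f + 2)
    elif mature_arm == "3p":
        flank3[0] = "C"                     # +1 base after the 3p mature
        mature_rel = (f + m + l, f + 2 * m + l)
        star_rel = (f + 2, f + m + 2)
    else:
        raise ValueError(f"mature_arm must be '5p' or '3p', got {mature_arm!r}")
    seq = flank5 + s5 + "".join(loop) + _revcomp(s5) + "".join(flank3)
    return seq, mature_rel, star_rel, s5


@dataclass
class _GeneSpec:
    gene_id: str
    provenance: str = "novel"
    arm_len: int | None = None
    mature_arm: str | None = None
    copy_of: str | None = None        # reuse another spec's 5p arm (identical mature)
    mutate_first: bool = False        # change mature position 1 (same seed, new mature)
    mutate_variant: int = 0           # which alternative base the mutation picks


def _build_annotation(
    groups: list[list[_GeneSpec]],
    within_gap_bp: int,
    between_gap_bp: int,
    seed: int,
    scaffold: str = "scaffold_1",
) -> tuple[dict[str, str], MirnaCatalog, list[int]]:
    """Lay out precursor groups on one scaffold.

    ``groups`` of length >= 2 become genomic clusters (consecutive starts
    ``within_gap_bp`` apart); singleton groups and distinct groups are
    separated by ``between_gap_bp``. Returns (genome, catalog, decoy
    positions) where decoy positions are gap midpoints well away from any
    precursor, used for piRNA-like reads.
    """
    rng = np.random.default_rng(seed)

    # resolve arm sequences up front so copy_of may reference any spec
    resolved: dict[str, tuple[str, int, str]] = {}
    pending = [s for g in groups for s in g]
    while pending:
        progress = False
        for spec in list(pending):
            if spec.copy_of is None:
                m = spec.arm_len or int(rng.choice([21, 22, 23], p=[0.2, 0.6, 0.2]))
                arm = spec.mature_arm or ("5p" if rng.random() < 0.5 else "3p")
                resolved[spec.gene_id] = (_random_dna(rng, m), m, arm)
            elif spec.copy_of in resolved:
                s5, m, arm = resolved[spec.copy_of]
                if spec.mutate_first:
                    # change mature position 1 only: s5[0] for a 5p mature,
                    # s5[-1] (whose complement opens the 3p mature) otherwise;
                    # the variant index keeps sibling mutants distinct
                    pos = 0 if arm == "5p" else m - 1
                    alts = [b for b in "ACGT" if b != s5[pos]]
                    alt = alts[spec.mutate_variant % 3]
                    s5 = s5[:pos] + alt + s5[pos + 1:]
                resolved[spec.gene_id] = (s5, m, arm)
            else:
                continue
            pending.remove(spec)
            progress = True
        if not progress:
            raise ValueError("unresolvable copy_of reference among gene specs")

    parts: list[str] = []
    cursor = 0
    genes: list[MirnaGene] = []
    decoys: list[int] = []

    def emit_gap(length: int):
        nonlocal cursor
        if length <= 0:
            return
        parts.append(_random_dna(rng, length))
        if length > 600:
            decoys.append(cursor + length // 2)
        cursor += length

    first = True
    for group in groups:
        prev_start = None
        for k, spec in enumerate(group):
            s5, m, arm = resolved[spec.gene_id]
            seq, mat_rel, star_rel, _ = _make_precursor(rng, m, arm, s5)

            if first:
                emit_gap(800)
                first = False
            elif k == 0:
                emit_gap(between_gap_bp)
            else:
                gap = within_gap_bp - (cursor - prev_start)
                emit_gap(max(gap, 120))
            prev_start = cursor
            start = cursor
            parts.append(seq)
            cursor += len(seq)
            mature = Arm(f"{spec.gene_id}-mat", seq[mat_rel[0]:mat_rel[1]],
                         start + mat_rel[0], start + mat_rel[1])
            star_seq = seq[star_rel[0]:star_rel[1]]
            star = Arm(f"{spec.gene_id}-star", star_seq, start + star_rel[0], start + star_rel[1])
            genes.append(
                MirnaGene(spec.gene_id, scaffold, "+", start, start + len(seq),
                          mature, star, spec.provenance)
            )
    emit_gap(800)
    genome = {scaffold: "".join(parts)}
    return genome, MirnaCatalog(genes=genes), decoys


def make_toy_annotation(
    n_precursors: int,
    n_clusters: int,
    gap_kb: float = 8.0,
    seed: int = DEFAULT_SEED,
) -> tuple[dict[str, str], MirnaCatalog]:
    """A toy genome with embedded hairpin precursors.

    With ``n_clusters >= 1``, precursors are distributed as evenly as possible
    among the clusters with consecutive starts ``gap_kb`` apart; with 0, all
    precursors are isolated singletons. Coordinates round-trip through the
    GFF3 writer.
    """
    if n_precursors < 0 or n_clusters < 0:
        raise ValueError("counts must be non-negative")
    if n_precursors < n_clusters:
        raise ValueError("need at least one precursor per cluster")
    specs = [_GeneSpec(f"mir-toy-{i + 1:03d}") for i in range(n_precursors)]
    if n_clusters == 0:
        groups = [[s] for s in specs]
    else:
        groups = [list(a) for a in np.array_split(np.array(specs, dtype=object), n_clusters)]
        groups = [g for g in groups if g]
    genome, catalog, _ = _build_annotation(
        groups, within_gap_bp=int(gap_kb * 1000),
        between_gap_bp=max(2 * int(gap_kb * 1000), 25_000), seed=seed,
    )
    return genome, catalog


def default_catalog(seed: int = DEFAULT_SEED) -> tuple[dict[str, str], MirnaCatalog, list[int]]:
    """The default 157-mature catalog fixture.

    166 gene models: 88 conserved, 11 previously described, 63 newly
    discovered plus a 4-gene MIR-309-like cluster. Among the 63 new genes,
    three triplets and three pairs share identical matures (63 genes -> 54
    distinct matures) and six further mature pairs share a seed (54 matures ->
    48 families). 43 of the new genes sit in nine clusters of 2-10 genes.
    """
    rng = np.random.default_rng(seed)

    novel_specs: list[_GeneSpec] = []
    idx = 0

    def new_novel(**kw) -> _GeneSpec:
        nonlocal idx
        idx += 1
        return _GeneSpec(f"Mir-bgn{idx:02d}", provenance="novel", **kw)

    # duplicate-mature groups: 3 triplets + 3 pairs (9 excess genes)
    for size in (3, 3, 3, 2, 2, 2):
        head = new_novel()
        novel_specs.append(head)
        for _ in range(size - 1):
            novel_specs.append(new_novel(copy_of=head.gene_id))
    # 6 seed-sharing pairs among otherwise distinct matures
    for _ in range(6):
        head = new_novel()
        novel_specs.append(head)
        novel_specs.append(new_novel(copy_of=head.gene_id, mutate_first=True))
    while len(novel_specs) < 63:
        novel_specs.append(new_novel())

    mir309 = [_GeneSpec(f"Mir-309-{c}", provenance="novel") for c in "abcd"]
    # the four paralogs share the seed but have distinct matures
    for v, g in enumerate(mir309[1:]):
        g.copy_of = mir309[0].gene_id
        g.mutate_first = True
        g.mutate_variant = v

    conserved = [_GeneSpec(f"Mir-c{i + 1:02d}", provenance="conserved") for i in range(88)]
    previous = [_GeneSpec(f"Mir-bg{i + 1:02d}", provenance="previous") for i in range(11)]

    # nine clusters of new genes (sizes 2-10, 43 genes) + the MIR-309 cluster
    sizes = [10, 7, 5, 5, 4, 4, 3, 3, 2]
    order = list(rng.permutation(len(novel_specs)))
    groups: list[list[_GeneSpec]] = [mir309]
    taken = 0
    for s in sizes:
        groups.append([novel_specs[order[taken + j]] for j in range(s)])
        taken += s
    singles = [novel_specs[order[i]] for i in range(taken, len(novel_specs))]
    for spec in singles + conserved + previous:
        groups.append([spec])

    within = int(rng.integers(4_000, 8_000))
    genome, catalog, decoys = _build_annotation(
        groups, within_gap_bp=within, between_gap_bp=15_000, seed=seed + 1,
    )
    return genome, catalog, decoys


def assign_units_to_waves(catalog: MirnaCatalog) -> dict[str, list[str]]:
    """Deterministically map the catalog's expression units onto waves.

    Mirrors the provenance mix of :func:`_assign_provenances` at the default
    catalog sizes: maternal loading is conserved + previously described,
    A1/B are novel (the MIR-309-like paralogs spike at ED2, i.e. wave B),
    A2 mixes previous and novel, C is conserved, and the remainder is
    background. Works proportionally for other catalog compositions.
    """
    units = catalog.expression_units()
    by_prov: dict[str, list[str]] = {"conserved": [], "previous": [], "novel": []}
    mir309: list[str] = []
    for uid, genes in sorted(units.items()):
        prov = genes[0].provenance
        if any(g.gene_id.startswith("Mir-309") for g in genes):
            mir309.append(uid)
        else:
            by_prov[prov].append(uid)
    nc, npv, nn = len(by_prov["conserved"]), len(by_prov["previous"]), len(by_prov["novel"])

    def take(pool: list[str], n: int) -> list[str]:
        out, pool[:] = pool[:n], pool[n:]
        return out

    waves: dict[str, list[str]] = {}
    waves["A1"] = take(by_prov["novel"], min(20, nn))
    waves["B"] = mir309 + take(by_prov["novel"], max(0, 20 - len(mir309)))
    waves["A2"] = take(by_prov["previous"], min(8, npv)) + take(by_prov["novel"], 12)
    waves["maternal"] = take(by_prov["conserved"], min(9, nc)) + take(by_prov["previous"], 3)
    waves["C"] = take(by_prov["conserved"], 20)
    waves["background"] = by_prov["conserved"] + by_prov["previous"] + by_prov["novel"]
    return waves


# ---------------------------------------------------------------------------
# read simulation

_TAIL_LEN_P = (0.5, 0.3, 0.2)


def simulate_reads(
    config: SimConfig,
    catalog: MirnaCatalog,
    genome: dict[str, str],
    decoy_positions: Sequence[int] | None = None,
    truth: SimTruth | None = None,
    stage_weights: pd.DataFrame | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], SimTruth]:
    """Simulate per-library reads (DNA, FASTQ-ready) from the catalog's matures.

    miRNA reads are the mature sequence (occasionally 3'-trimmed by 1 nt);
    a stage-dependent fraction carries a 1-3 nt nontemplated 3' tail whose
    first base mismatches the genomic +1 base by construction. piRNA-like
    decoys are 27-29-nt genomic fragments drawn from loci far from any
    precursor. ``stage_weights`` (units x stages) makes the per-library
    sampling of matures follow a stage-dependent abundance profile; without
    it, a fixed lognormal abundance is drawn once. Returns
    ({library: [(read_id, sequence), ...]}, truth).
    """
    config.validate()
    units = catalog.expression_units()
    if not units:
        raise ValueError("catalog has no miRNA genes")
    unit_ids = list(units)
    mature_dna: list[str] = []
    starts: list[int] = []
    scaffolds: list[str] = []
    for uid, genes in units.items():
        g = genes[0]
        seq = genome.get(g.scaffold)
        if seq is None:
            raise ValueError(f"scaffold {g.scaffold!r} of {g.gene_id} absent from genome")
        dna = seq[g.mature.start:g.mature.end]
        if dna.replace("T", "U") != g.mature.sequence:
            raise ValueError(f"mature {g.mature.arm_id} does not match the genome")
        mature_dna.append(dna)
        starts.append(g.mature.start)
        scaffolds.append(g.scaffold)

    if decoy_positions is None or len(decoy_positions) == 0:
        scaff = scaffolds[0]
        glen = len(genome[scaff])
        occupied = sorted((g.start, g.end) for g in catalog.genes if g.scaffold == scaff)
        rng0 = np.random.default_rng(config.seed + 7)
        decoy_positions = []
        for _ in range(200):
            p = int(rng0.integers(0, max(glen - 40, 1)))
            if all(not (s - 40 < p < e + 40) for s, e in occupied):
                decoy_positions.append(p)
        if not decoy_positions:
            decoy_positions = [0]
    decoy_positions = list(decoy_positions)
    decoy_scaffold = scaffolds[0]

    ss = np.random.SeedSequence(config.seed)
    lib_seeds = ss.spawn(N_STAGES * len(REPLICATES) + 1)
    if stage_weights is not None:
        missing = [u for u in unit_ids if u not in stage_weights.index]
        if missing:
            raise ValueError(f"stage_weights missing units: {missing[:5]}...")
        wmat = stage_weights.loc[unit_ids, list(STAGES)].to_numpy(dtype=float)
        weights_by_stage = {
            s: wmat[:, i] / wmat[:, i].sum() for i, s in enumerate(STAGES)
        }
    else:
        weight_rng = np.random.default_rng(lib_seeds[-1])
        flat = weight_rng.lognormal(0.0, 0.8, len(unit_ids))
        flat /= flat.sum()
        weights_by_stage = {s: flat for s in STAGES}

    tail_intern: dict[str, str] = {"": ""}
    reads_by_lib: dict[str, list[tuple[str, str]]] = {}
    out_truth = truth or SimTruth(wave_of={}, provenance_of={})
    out_truth.unit_ids = unit_ids
    out_truth.tailmod_rate_by_stage = dict(config.tailmod_rate_by_stage)
    out_truth.tail_composition = dict(config.tail_composition)

    comp_names = ("A", "U", "other")
    comp_p = np.array([config.tail_composition[c] for c in comp_names])

    li = 0
    for stage in STAGES:
        for rep in REPLICATES:
            lib = library_name(stage, rep)
            rng = np.random.default_rng(lib_seeds[li])
            li += 1
            n = int(rng.poisson(config.read_lib_size_mean))
            n_pi = int(rng.binomial(n, config.pirna_fraction_by_stage.get(stage, 0.0)))
            n_mi = n - n_pi

            uidx = rng.choice(len(unit_ids), size=n_mi, p=weights_by_stage[stage])
            tailed = rng.random(n_mi) < config.tailmod_rate_by_stage.get(stage, 0.0)
            trim = np.where(~tailed & (rng.random(n_mi) < 0.2), 1, 0)
            tail_class = rng.choice(3, size=n_mi, p=comp_p)
            tail_len = rng.choice([1, 2, 3], size=n_mi, p=_TAIL_LEN_P)

            seqs: list[str] = []
            tails: list[str] = []
            tlens = np.empty(n_mi, dtype=np.int32)
            other_extra = rng.integers(0, 4, size=n_mi * 2)  # pool for 'other' tail bases
            oe = 0
            bases = "ACGT"
            for i in range(n_mi):
                mat = mature_dna[uidx[i]]
                if tailed[i]:
                    L = int(tail_len[i])
                    c = comp_names[tail_class[i]]
                    if c == "A":
                        tail = "A" * L
                    elif c == "U":
                        tail = "T" * L
                    else:
                        # first base 'G' mismatches the forced 'C' downstream base
                        # and guarantees an 'other' classification
                        extra = "".join(bases[other_extra[oe + k]] for k in range(L - 1))
                        oe += L - 1
                        tail = "G" + extra
                    tail = tail_intern.setdefault(tail, tail)
                    seqs.append(mat + tail)
                    tails.append(tail)
                    tlens[i] = len(mat)
                else:
                    t = int(trim[i])
                    seqs.append(mat[: len(mat) - t] if t else mat)
                    tails.append("")
                    tlens[i] = len(mat) - t

            # piRNA-like decoys
            if n_pi:
                dpos = rng.choice(len(decoy_positions), size=n_pi)
                dlen = rng.choice([27, 28, 29], size=n_pi, p=[0.2, 0.6, 0.2])
                gseq = genome[decoy_scaffold]
                for i in range(n_pi):
                    p = decoy_positions[dpos[i]]
                    seqs.append(gseq[p:p + int(dlen[i])])
                    tails.append("")

            records = [(f"{lib}_r{i + 1}", s) for i, s in enumerate(seqs)]
            reads_by_lib[lib] = records
            out_truth.reads[lib] = ReadTruth(
                unit_idx=np.concatenate([uidx, np.full(n_pi, -1, dtype=uidx.dtype)]),
                templated_len=np.concatenate(
                    [tlens, np.array([len(r[1]) for r in records[n_mi:]], dtype=np.int32)]
                ),
                tails=tails,
            )
    return reads_by_lib, out_truth


# ---------------------------------------------------------------------------
# candidate-evidence funnel fixture

def make_candidate_funnel(
    seed: int = DEFAULT_SEED, n_candidates: int = 264, n_pass: int = 67
) -> list[CandidateEvidence]:
    """Candidate hairpin evidence emulating a prediction funnel.

    Exactly ``n_pass`` candidates satisfy every default biogenesis criterion;
    the rest fail at least one (missing star support, thin mature coverage,
    ragged 5' ends, or non-canonical duplex overhangs).
    """
    if not 0 <= n_pass <= n_candidates:
        raise ValueError("need 0 <= n_pass <= n_candidates")
    rng = np.random.default_rng(seed)
    cands: list[CandidateEvidence] = []
    for i in range(n_candidates):
        cid = f"cand-{i + 1:03d}"
        good = i < n_pass
        if good:
            mreads = int(rng.integers(30, 800))
            modal = int(math.ceil(0.93 * mreads))
            five = {100: modal, 99: mreads - modal} if mreads > modal else {100: mreads}
            oh = tuple(int(rng.integers(1, 4)) for _ in range(2))  # within 2 +/- 1
            sreads = int(rng.integers(2, 60))
        else:
            failure = rng.choice(["no_star", "few_reads", "ragged_5p", "bad_overhang"])
            mreads = int(rng.integers(12, 300))
            modal = int(math.ceil(0.93 * mreads))
            five = {100: modal, 99: mreads - modal} if mreads > modal else {100: mreads}
            oh = (2, 2)
            sreads = int(rng.integers(1, 40))
            if failure == "no_star":
                sreads = 0
            elif failure == "few_reads":
                mreads = int(rng.integers(0, 10))
                modal = max(mreads - 1, 0) or mreads
                five = {100: mreads} if mreads else {}
            elif failure == "ragged_5p":
                a = int(math.ceil(mreads * 0.5))
                five = {100: a, 98: mreads - a}
            else:
                oh = (int(rng.choice([0, 4, 5])), 2)
        cands.append(CandidateEvidence(cid, mreads, sreads, five, oh))
    perm = rng.permutation(n_candidates)
    return [cands[i] for i in perm]


# ---------------------------------------------------------------------------
# cross-species family-abundance fixture

def make_species_panel(seed: int = DEFAULT_SEED) -> tuple[pd.DataFrame, dict[str, str]]:
    """Family-level CPM sums for four NFE libraries (synthetic stand-in panel).

    Two short-germ-band-like libraries (bge, tca) are enriched in MIR-276 and
    MIR-279; two long-germ-band-like libraries (dme, dvi) in MIR-92, with dvi
    more extreme so MIR-92 dominates the second principal axis. A handful of
    species-private families exercises the shared-family intersection.
    """
    rng = np.random.default_rng(seed)
    libs = ["bge_NFE", "tca_NFE", "dme_NFE", "dvi_NFE"]
    species = {lib: lib.split("_")[0] for lib in libs}
    shared = [
        "MIR-276", "MIR-279", "MIR-92", "LET-7", "BANTAM", "MIR-1", "MIR-8",
        "MIR-9", "MIR-10", "MIR-34", "MIR-71", "MIR-100", "MIR-124", "MIR-125",
        "MIR-137", "MIR-184", "MIR-252", "MIR-263", "MIR-275", "MIR-305",
    ]
    base = rng.lognormal(mean=np.log(2000), sigma=0.3, size=(len(shared), len(libs)))
    tab = pd.DataFrame(base, index=pd.Index(shared, name="family"), columns=libs)
    tab.loc["MIR-276", ["bge_NFE", "tca_NFE"]] *= 12.0
    tab.loc["MIR-279", ["bge_NFE", "tca_NFE"]] *= 9.0
    tab.loc["MIR-92", ["dme_NFE", "dvi_NFE"]] *= [5.0, 8.0]
    # species-private families (zero elsewhere) drop out of the shared table
    tab.loc["MIR-BG5"] = [60_000.0, 0.0, 0.0, 0.0]
    tab.loc["MIR-TC1"] = [0.0, 4000.0, 0.0, 0.0]
    tab.loc["MIR-DM1"] = [0.0, 0.0, 3000.0, 0.0]
    return tab, species


# ---------------------------------------------------------------------------
# recovery scoring + serialization helpers

def recovery_ari(found_labels: dict[str, str], true_labels: dict[str, str]) -> float:
    """Adjusted Rand index between two labelings over the union of genes.

    Genes missing from ``found_labels`` are treated as one 'unassigned'
    group, so both lost wave genes and background intrusions count against
    the score.
    """
    from sklearn.metrics import adjusted_rand_score

    genes = sorted(true_labels)
    a = [found_labels.get(g, "unassigned") for g in genes]
    b = [true_labels[g] for g in genes]
    return float(adjusted_rand_score(a, b))


def write_fastq(records: Sequence[tuple[str, str]], path) -> None:
    """Plain FASTQ, phred+33 constant quality."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
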