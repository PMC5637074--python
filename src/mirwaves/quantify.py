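"""Read-level miRNA quantification and 3'-end modification profiling.

Reads are assigned to annotated matures by exact templated-prefix matching:
a read belongs to a mature when its longest genome-templated prefix starts
within +/-2 nt of the annotated mature 5' end and the untemplated residue at
the 3' end is at most 5 nt. The residue is the candidate tail; a tail that
equals the genomic continuation is a templated extension, not a
modification, while all-A and all-U tails are adenylation and uridylation.
Reads matching k > 1 distinct matures contribute 1/k to each.

There is no mismatch-tolerant alignment here: the toy genomes this package
quantifies against make exact matching sufficient, and tolerance beyond the
5' offset and 3' tail is explicitly out of scope.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import MirnaCatalog, MirnaFamily

TAIL_CLASSES = ("unmodified", "templated_extension", "adenylation", "uridylation", "other")

_INDEX_K = 12


def _seq_of(read) -> str:
    return read if isinstance(read, str) else read[1]


def size_select(reads: Sequence, min_len: int = 16, max_len: int = 29) -> list:
    """Retain reads with min_len <= length <= max_len (inclusive bounds)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [r for r in reads if min_len <= len(_seq_of(r)) <= max_len]


def classify_tail(candidate_tail: str, genomic_downstream: str) -> str:
    """Classify a 3' residue against the genomic continuation.

    Total on every (tail, downstream) pair: empty -> unmodified; equal to the
    same-length genomic continuation -> templated_extension; otherwise all-A
    -> adenylation, all-U/T -> uridylation, anything else -> other.
    """
    if not candidate_tail:
        return "unmodified"
    tail = candidate_tail.upper().replace("T", "U")
    down = genomic_downstream.upper().replace("T", "U")
    if len(down) >= len(tail) and down[: len(tail)] == tail:
        return "templated_extension"
    if set(tail) == {"A"}:
        return "adenylation"
    if set(tail) == {"U"}:
        return "uridylation"
    return "other"


@dataclass
class LibraryAssignment:
    """Assignment outcome for one library."""

    library_id: str
    counts: dict[str, float] = field(default_factory=dict)
    tail_class_weight: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in TAIL_CLASSES}
    )
    n_assigned: float = 0.0
    n_unassigned: int = 0
    read_units: list[tuple[str, ...]] | None = None  # per read, matched unit ids


def _build_index(catalog: MirnaCatalog, genome: Mapping[str, str], tolerance: int):
    """k-mer index over the +/-tolerance window around every mature 5' end."""
    units = catalog.expression_units()
    unit_ids = list(units)
    index: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for ui, (uid, genes) in enumerate(units.items()):
        for g in genes:
            gseq = genome.get(g.scaffold)
            if gseq is None:
                raise ValueError(f"scaffold {g.scaffold!r} of {g.gene_id} absent from genome")
            if gseq[g.mature.start:g.mature.end].replace("T", "U") != g.mature.sequence:
                raise ValueError(
                    f"annotation/genome mismatch at mature {g.mature.arm_id}"
                )
            for off in range(-tolerance, tolerance + 1):
                s = g.mature.start + off
                if s < 0 or s + _INDEX_K > len(gseq):
                    continue
                index[gseq[s:s + _INDEX_K]].append((s, ui, g.scaffold))
    return unit_ids, dict(index)


def assign_reads(
    reads,
    catalog: MirnaCatalog,
    genome: Mapping[str, str],
    five_prime_tolerance: int = 2,
    max_tail: int = 5,
    min_templated: int = 16,
    keep_read_units: bool = False,
) -> dict[str, LibraryAssignment]:
    """Assign reads to catalog matures.

    ``reads`` is either ``{library_id: [(read_id, seq), ...]}`` or a flat list
    (treated as one library named ``"library"``). Distinct read sequences are
    resolved once and the resolution reused, so runtime scales with the number
    of unique sequences, not reads.
    """
    if not isinstance(reads, dict):
        reads = {"library": list(reads)}
    unit_ids, index = _build_index(catalog, genome, five_prime_tolerance)

    # cache: sequence -> (matched unit ids, per-match tail class)
    cache: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}

    def resolve(seq: str):
        hit = cache.get(seq)
        if hit is not None:
            return hit
        best: dict[int, tuple[int, str]] = {}  # unit -> (templated len, tail class)
        for s, ui, scaff in index.get(seq[:_INDEX_K], ()):
            gseq = genome[scaff]
            limit = min(len(seq), len(gseq) - s)
            t = 0
            while t < limit and seq[t] == gseq[s + t]:
                t += 1
            tail = seq[t:]
            if t < min_templated or len(tail) > max_tail:
                continue
            if ui not in best or t > best[ui][0]:
                down = gseq[s + t:s + t + len(tail)]
                best[ui] = (t, classify_tail(tail, down))
        hit = (tuple(unit_ids[ui] for ui in best), tuple(tc for _, tc in best.values()))
        cache[seq] = hit
        return hit

    out: dict[str, LibraryAssignment] = {}
    for lib, records in reads.items():
        la = LibraryAssignment(library_id=lib)
        # U and T are equivalent on input; the genome is DNA
        counter = Counter(_seq_of(r).upper().replace("U", "T") for r in records)
        seq_res = {seq: resolve(seq) for seq in counter}
        for seq, n in counter.items():
            hit_units, hit_classes = seq_res[seq]
            k = len(hit_units)
            if k == 0:
                la.n_unassigned += n
                continue
            w = n / k
            for uid, tc in zip(hit_units, hit_classes):
                la.counts[uid] = la.counts.get(uid, 0.0) + w
                la.tail_class_weight[tc] += w
            la.n_assigned += n
        if keep_read_units:
            la.read_units = [
                seq_res[_seq_of(r).upper().replace("U", "T")][0] for r in records
            ]
        out[lib] = la
    return out


def assignments_to_counts(
    assignments: Mapping[str, LibraryAssignment], catalog: MirnaCatalog | None = None
) -> pd.DataFrame:
    """Units x libraries count matrix (fractional where reads multi-match)."""
    if catalog is not None:
        units = list(catalog.expression_units())
    else:
        units = sorted({u for la in assignments.values() for u in la.counts})
    libs = list(assignments)
    mat = np.zeros((len(units), len(libs)))
    upos = {u: i for i, u in enumerate(units)}
    for j, lib in enumerate(libs):
        for u, c in assignments[lib].counts.items():
            mat[upos[u], j] = c
    return pd.DataFrame(mat, index=pd.Index(units, name="gene_id"), columns=libs)


def tailmod_profile(
    assignments: Mapping[str, LibraryAssignment],
    count_templated_extensions: bool = False,
) -> pd.DataFrame:
    """Per-library 3'-modification frequency and tail composition.

    Templated extensions count as unmodified unless
    ``count_templated_extensions`` is set (they then enter the modified pool
    and its 'other' composition bucket).
    """
    rows = []
    for lib, la in assignments.items():
        w = la.tail_class_weight
        mod = w["adenylation"] + w["uridylation"] + w["other"]
        other = w["other"]
        if count_templated_extensions:
            mod += w["templated_extension"]
            other += w["templated_extension"]
        freq = mod / la.n_assigned if la.n_assigned else 0.0
        rows.append(
            {
                "library": lib,
                "n_assigned": la.n_assigned,
                "n_modified": mod,
                "frequency": freq,
                "frac_A": w["adenylation"] / mod if mod else 0.0,
                "frac_U": w["uridylation"] / mod if mod else 0.0,
                "frac_other": other / mod if mod else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("library")


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: each column scaled to a 1e6 total."""
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total library: {', '.join(map(str, zero.index))}")
    return counts * 1e6 / totals


def family_expression(cpm: pd.DataFrame, families: Iterable[MirnaFamily]) -> pd.DataFrame:
    """Family x library matrix: the sum of member CPM rows per family."""
    rows = {}
    for fam in families:
        missing = [m for m in fam.member_ids if m not in cpm.index]
        if missing:
            raise KeyError(f"family {fam.family_id}: members absent from matrix: {missing}")
        rows[fam.family_id] = cpm.loc[list(fam.member_ids)].sum(axis=0)
    return pd.DataFrame(rows).T.rename_axis("family")


@dataclass
class LengthDistribution:
    """Per-library read-length histogram with detected local maxima."""

    histograms: pd.DataFrame   # lengths x libraries
    peaks: dict[str, list[int]]


def length_distribution(reads, min_len: int = 16, max_len: int = 29) -> LengthDistribution:
    """Histogram of read lengths within [min_len, max_len] plus peak calls.

    A peak is a strict local maximum of the histogram (boundary bins compare
    against their single neighbour).
    """
    if not isinstance(reads, dict):
        reads = {"library": list(reads)}
    lengths = list(range(min_len, max_len + 1))
    hists = {}
    peaks = {}
    for lib, records in reads.items():
        c = Counter(len(_seq_of(r)) for r in records)
        h = np.array([c.get(n, 0) for n in lengths])
        hists[lib] = h
        p = []
        for i, v in enumerate(h):
            left = h[i - 1] if i > 0 else -1
            right = h[i + 1] if i < len(h) - 1 else -1
            if v > left and v > right and v > 0:
                p.append(lengths[i])
        peaks[lib] = p
    df = pd.DataFrame(hists, index=pd.Index(lengths, name="length"))
    return LengthDistribution(histograms=df, peaks=peaks)


# ---------------------------------------------------------------------------
# I/O helpers

def read_fastq(path) -> list[tuple[str, str]]:
    """Read a FASTQ (optionally gzipped) into (read_id, sequence) pairs."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        return [(entry.name, entry.sequence) for entry in fh]


def write_tail_profile_tsv(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, sep="\t")


def write_length_histogram_tsv(dist: LengthDistribution, path) -> None:
    dist.histograms.to_csv(path, sep="\t")
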