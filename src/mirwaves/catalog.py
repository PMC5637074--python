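"""miRNA catalog: biogenesis filtering, seed families, genomic clusters.

A catalog holds miRNA gene models (precursor + mature + star arm), their
provenance (conserved across insects, previously described in the species, or
newly discovered), seed-based families and genomic clusters. Candidate
hairpins coming from an upstream predictor are filtered with configurable
miRNA-biogenesis criteria (read support on both arms, 5' homogeneity of the
mature arm, and the ~2-nt 3' overhang left by Drosha/Dicer processing).

Internal coordinates are 0-based half-open; GFF3 I/O (miRBase dialect with
``miRNA_primary_transcript`` and ``miRNA`` features) converts to 1-based
closed at the boundary.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

PROVENANCES = ("conserved", "previous", "novel")

_RNA = set("ACGU")


def _to_rna(seq: str) -> str:
    """Uppercase and map T to U; reject non-nucleotide characters."""
    s = seq.upper().replace("T", "U")
    if not set(s) <= _RNA | {"N"}:
        raise ValueError(f"sequence contains non-nucleotide characters: {seq!r}")
    return s


@dataclass(frozen=True)
class Arm:
    """A mature or star arm: RNA sequence plus genomic interval (0-based, half-open)."""

    arm_id: str
    sequence: str
    start: int
    end: int

    def __post_init__(self):
        object.__setattr__(self, "sequence", _to_rna(self.sequence))
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid arm interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class MirnaGene:
    """One miRNA gene: precursor hairpin with a mature and a star arm."""

    gene_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    mature: Arm
    star: Arm
    provenance: str

    def __post_init__(self):
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        for arm in (self.mature, self.star):
            if not (self.start <= arm.start and arm.end <= self.end):
                raise ValueError(
                    f"{arm.arm_id}: arm [{arm.start},{arm.end}) not nested in "
                    f"precursor [{self.start},{self.end}) of {self.gene_id}"
                )


@dataclass(frozen=True)
class MirnaFamily:
    """Matures sharing an identical seed (positions 2-8 of the mature)."""

    family_id: str
    seed: str
    member_ids: tuple[str, ...]


@dataclass(frozen=True)
class GenomicCluster:
    """>=2 genes chained along a scaffold with inter-start gaps below a linkage threshold."""

    cluster_id: str
    scaffold: str
    member_ids: tuple[str, ...]
    span_bp: int


@dataclass
class CandidateEvidence:
    """Read-level evidence for one candidate hairpin.

    ``five_prime_positions`` maps distinct mature-arm 5' positions to read
    counts; its values sum to ``mature_reads``.
    """

    candidate_id: str
    mature_reads: int
    star_reads: int
    five_prime_positions: dict[int, int]
    overhangs: tuple[int, int]

    def validate(self) -> None:
        if self.mature_reads < 0 or self.star_reads < 0:
            raise ValueError(f"{self.candidate_id}: negative read counts")
        if self.five_prime_positions and sum(self.five_prime_positions.values()) != self.mature_reads:
            raise ValueError(
                f"{self.candidate_id}: 5' position counts do not sum to mature_reads"
            )


@dataclass
class MirnaCatalog:
    """The full catalog: genes, plus derived families and clusters."""

    genes: list[MirnaGene] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def distinct_matures(self) -> dict[str, list[MirnaGene]]:
        """Distinct mature sequences -> the genes carrying them.

        Paralogous genes may encode identical matures; expression analyses
        treat each distinct mature as one unit.
        """
        out: dict[str, list[MirnaGene]] = defaultdict(list)
        for g in self.genes:
            out[g.mature.sequence].append(g)
        return dict(out)

    def expression_units(self) -> dict[str, list[MirnaGene]]:
        """Unit id -> genes; one unit per distinct mature sequence.

        The unit id is the lexicographically smallest mature arm id among the
        genes sharing the sequence, which makes naming deterministic.
        """
        units: dict[str, list[MirnaGene]] = {}
        for _, genes in sorted(self.distinct_matures().items()):
            uid = min(g.mature.arm_id for g in genes)
            units[uid] = sorted(genes, key=lambda g: g.gene_id)
        return dict(sorted(units.items()))


# ---------------------------------------------------------------------------
# seed families

def seed_of(mature_sequence: str) -> str:
    """Seed heptamer: positions 2-8 (1-based) of the mature sequence."""
    seq = _to_rna(mature_sequence)
    if len(seq) < 8:
        raise ValueError(f"mature sequence shorter than 8 nt: {mature_sequence!r}")
    return seq[1:8]


def group_families(matures: Iterable[tuple[str, str]]) -> list[MirnaFamily]:
    """Partition (mature_id, sequence) pairs into families by exact seed identity.

    Family ids are ``fam-<smallest member id>``, so naming is deterministic
    under input permutation.
    """
    by_seed: dict[str, list[str]] = defaultdict(list)
    for mid, seq in matures:
        by_seed[seed_of(seq)].append(mid)
    fams = []
    for seed, members in by_seed.items():
        members = sorted(members)
        fams.append(MirnaFamily(f"fam-{members[0]}", seed, tuple(members)))
    fams.sort(key=lambda f: f.family_id)
    return fams


# ---------------------------------------------------------------------------
# genomic clusters

def find_clusters(genes: Sequence[MirnaGene], linkage_gap_bp: int = 10_000) -> list[GenomicCluster]:
    """Single-linkage chaining of genes along each scaffold.

    A gene joins the running chain when its precursor start is within
    ``linkage_gap_bp`` of the previous member's start; chains with >=2 members
    become clusters. Strand is deliberately ignored.
    """
    by_scaffold: dict[str, list[MirnaGene]] = defaultdict(list)
    for g in genes:
        by_scaffold[g.scaffold].append(g)
    clusters: list[GenomicCluster] = []
    for scaffold in sorted(by_scaffold):
        members = sorted(by_scaffold[scaffold], key=lambda g: (g.start, g.gene_id))
        chain: list[MirnaGene] = []
        for g in members + [None]:  # sentinel flushes the last chain
            if chain and (g is None or g.start - chain[-1].start > linkage_gap_bp):
                if len(chain) >= 2:
                    span = max(x.end for x in chain) - min(x.start for x in chain)
                    clusters.append(
                        GenomicCluster(
                            cluster_id=f"cluster-{len(clusters) + 1}",
                            scaffold=scaffold,
                            member_ids=tuple(x.gene_id for x in chain),
                            span_bp=span,
                        )
                    )
                chain = []
            if g is not None:
                chain.append(g)
    return clusters


# ---------------------------------------------------------------------------
# duplex geometry

def duplex_overhang(mature: Arm, star: Arm, precursor_start: int, precursor_end: int) -> tuple[int, int]:
    """3' overhang lengths at the two ends of the mature/star duplex.

    Assumes the symmetric hairpin fold in which precursor position ``i`` pairs
    with ``N - 1 - i`` (N = precursor length), the convention under which the
    toy annotations are built. Returns (overhang at the loop-side end, overhang
    at the base-side end); a canonical Drosha/Dicer product gives (2, 2).
    """
    n = precursor_end - precursor_start
    if n <= 0:
        raise ValueError("empty precursor interval")
    arms = sorted([mature, star], key=lambda a: a.start)
    five, three = arms
    if five.end > three.start:
        raise ValueError(f"arms {mature.arm_id}/{star.arm_id} overlap on the precursor")
    # precursor-relative coordinates
    f_start, f_end = five.start - precursor_start, five.end - precursor_start
    t_start, t_end = three.start - precursor_start, three.end - precursor_start
    loop_side = (f_end - 1) + t_start - (n - 1)
    base_side = (t_end - 1) + f_start - (n - 1)
    return loop_side, base_side


# ---------------------------------------------------------------------------
# biogenesis filter

@dataclass(frozen=True)
class FilterThresholds:
    """Configurable miRNA-biogenesis criteria.

    The criteria themselves (read floors, overhang tolerance) follow the
    conventional Drosha/Dicer signature; they are configuration, not a claim
    about any particular published filter.
    """

    min_mature_reads: int = 10
    require_star_reads: bool = True
    required_overhang: int = 2
    overhang_tolerance: int = 1
    min_five_prime_homogeneity: float = 0.9


def biogenesis_filter(
    candidates: Sequence[CandidateEvidence],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[CandidateEvidence], list[tuple[CandidateEvidence, list[str]]]]:
    """Partition candidates into (accepted, rejected-with-reasons).

    A candidate is accepted iff every enabled criterion passes; all failing
    criteria are enumerated for the rejection report.
    """
    th = thresholds or FilterThresholds()
    accepted: list[CandidateEvidence] = []
    rejected: list[tuple[CandidateEvidence, list[str]]] = []
    for cand in candidates:
        cand.validate()
        reasons = []
        if cand.mature_reads < th.min_mature_reads:
            reasons.append(f"mature read support {cand.mature_reads} < {th.min_mature_reads}")
        if th.require_star_reads and cand.star_reads == 0:
            reasons.append("no star support")
        lo = th.required_overhang - th.overhang_tolerance
        hi = th.required_overhang + th.overhang_tolerance
        for side, oh in zip(("loop-side", "base-side"), cand.overhangs):
            if not (lo <= oh <= hi):
                reasons.append(f"{side} 3' overhang {oh} outside [{lo}, {hi}]")
        if cand.mature_reads > 0:
            if not cand.five_prime_positions:
                raise ValueError(f"{cand.candidate_id}: mature reads without 5' positions")
            modal = max(cand.five_prime_positions.values())
            homog = modal / cand.mature_reads
            if homog < th.min_five_prime_homogeneity:
                reasons.append(
                    f"5' homogeneity {homog:.3f} < {th.min_five_prime_homogeneity}"
                )
        if reasons:
            rejected.append((cand, reasons))
        else:
            accepted.append(cand)
    return accepted, rejected


# ---------------------------------------------------------------------------
# summary

def catalog_summary(catalog: MirnaCatalog, linkage_gap_bp: int = 10_000) -> dict:
    """Bookkeeping totals: genes and distinct matures by provenance, families, clusters."""
    genes_by_prov = {p: sum(1 for g in catalog.genes if g.provenance == p) for p in PROVENANCES}
    units = catalog.expression_units()
    matures_by_prov = {p: 0 for p in PROVENANCES}
    for uid, genes in units.items():
        # a distinct mature inherits the "most established" provenance of its genes
        provs = {g.provenance for g in genes}
        for p in PROVENANCES:  # conserved < previous < novel precedence
            if p in provs:
                matures_by_prov[p] += 1
                break
    fams = group_families(
        [(uid, genes[0].mature.sequence) for uid, genes in units.items()]
    )
    clusters = find_clusters(catalog.genes, linkage_gap_bp)
    return {
        "n_genes": len(catalog.genes),
        "n_genes_by_provenance": genes_by_prov,
        "n_distinct_matures": len(units),
        "n_matures_by_provenance": matures_by_prov,
        "n_families": len(fams),
        "n_clusters": len(clusters),
        "cluster_sizes": sorted((len(c.member_ids) for c in clusters), reverse=True),
        "cluster_spans_bp": sorted((c.span_bp for c in clusters), reverse=True),
    }


# ---------------------------------------------------------------------------
# I/O

def write_gff3(catalog: MirnaCatalog, path) -> None:
    """miRBase-dialect GFF3: precursors as miRNA_primary_transcript, arms as miRNA.

    Converts internal 0-based half-open coordinates to GFF3 1-based closed.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in catalog.genes:
            fh.write(
                f"{g.scaffold}\t.\tmiRNA_primary_transcript\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};provenance={g.provenance}\n"
            )
            for arm, role in ((g.mature, "mature"), (g.star, "star")):
                fh.write(
                    f"{g.scaffold}\t.\tmiRNA\t{arm.start + 1}\t{arm.end}\t.\t{g.strand}\t.\t"
                    f"ID={arm.arm_id};Derives_from={g.gene_id};arm_role={role}\n"
                )


def read_gff3(path, genome: dict[str, str]) -> MirnaCatalog:
    """Parse a miRBase-dialect GFF3 back into a catalog.

    Arm sequences are re-extracted from ``genome`` (scaffold -> DNA string) so
    that coordinates and sequences cannot drift apart.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    # miRBase links arms to precursors via Derives_from, not Parent
    arms_by_parent: dict[str, dict[str, Arm]] = defaultdict(dict)
    for child in db.features_of_type("miRNA"):
        parent = child.attributes.get("Derives_from", [None])[0]
        if parent is None:
            raise ValueError(f"miRNA feature {child.id} lacks Derives_from")
        role = child.attributes.get("arm_role", ["mature"])[0]
        start, end = child.start - 1, child.end
        seq = genome[child.seqid][start:end]
        arms_by_parent[parent][role] = Arm(child.id, seq, start, end)

    genes: list[MirnaGene] = []
    for prec in db.features_of_type("miRNA_primary_transcript"):
        if prec.seqid not in genome:
            raise ValueError(f"scaffold {prec.seqid!r} of {prec.id} absent from genome")
        arms = arms_by_parent.get(prec.id, {})
        if set(arms) != {"mature", "star"}:
            raise ValueError(f"{prec.id}: expected exactly one mature and one star arm")
        genes.append(
            MirnaGene(
                gene_id=prec.id,
                scaffold=prec.seqid,
                strand=prec.strand,
                start=prec.start - 1,
                end=prec.end,
                mature=arms["mature"],
                star=arms["star"],
                provenance=prec.attributes.get("provenance", ["novel"])[0],
            )
        )
    return MirnaCatalog(genes=genes)


def write_catalog_json(catalog: MirnaCatalog, path) -> None:
    with open(path, "w") as fh:
        json.dump({"genes": [asdict(g) for g in catalog.genes]}, fh, indent=1)


def read_catalog_json(path) -> MirnaCatalog:
    with open(path) as fh:
        doc = json.load(fh)
    genes = []
    for g in doc["genes"]:
        g["mature"] = Arm(**g["mature"])
        g["star"] = Arm(**g["star"])
        genes.append(MirnaGene(**g))
    return MirnaCatalog(genes=genes)


def write_filter_report(rejected, accepted, path) -> None:
    """TSV report: candidate_id, decision, semicolon-joined reasons."""
    with open(path, "w") as fh:
        fh.write("candidate_id\tdecision\treasons\n")
        for cand in accepted:
            fh.write(f"{cand.candidate_id}\taccepted\t\n")
        for cand, reasons in rejected:
            fh.write(f"{cand.candidate_id}\trejected\t{'; '.join(reasons)}\n")
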