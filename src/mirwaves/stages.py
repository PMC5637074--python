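"""The 11-stage developmental design shared by every module.

The study samples the German cockroach ontogeny at eleven points: the
non-fertilized egg (NFE, maternal loading), five embryonic days (ED0, ED1,
ED2, ED6, ED13), four nymphal instars (N1, N3, N5, N6) and the adult female,
each with two replicate small-RNA libraries.
"""

from __future__ import annotations

STAGES: tuple[str, ...] = (
    "NFE", "ED0", "ED1", "ED2", "ED6", "ED13",
    "N1", "N3", "N5", "N6", "Adult",
)

N_STAGES = len(STAGES)

#: embryonic stage -> hours after oviposition (18-day embryogenesis at 29 C)
HOURS_AFTER_OVIPOSITION: dict[str, float] = {
    "ED0": 8.0,
    "ED1": 24.0,
    "ED2": 48.0,
    "ED6": 144.0,
    "ED13": 312.0,
}

#: total embryogenesis duration in hours (18 days)
TOTAL_EMBRYO_HOURS = 18 * 24.0

REPLICATES = (1, 2)


def library_name(stage: str, replicate: int) -> str:
    """Canonical library id, e.g. ``ED2_rep1``."""
    return f"{stage}_rep{replicate}"


def default_libraries() -> list[str]:
    """The 22 library ids in stage order, replicate-minor."""
    return [library_name(s, r) for s in STAGES for r in REPLICATES]


def parse_library_name(library_id: str) -> tuple[str, int]:
    """Split ``STAGE_repN`` into (stage, replicate); raises on malformed ids."""
    try:
        stage, rep = library_id.rsplit("_rep", 1)
        replicate = int(rep)
    except ValueError as exc:
        raise ValueError(f"malformed library id {library_id!r}: expected STAGE_repN") from exc
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r} in library id {library_id!r}")
    return stage, replicate


def stage_of_library(library_id: str) -> str:
    return parse_library_name(library_id)[0]
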