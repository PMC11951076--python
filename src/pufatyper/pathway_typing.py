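"""Four-lineage typing of strains from a presence/absence matrix.

The decision rule mirrors the published lineage definitions:

* Type I   — complete ELO/DES pathway, no PUFA synthase;
* Type II  — complete ELO/DES pathway plus PUFA synthase;
* Type III — PUFA synthase, no canonical Δ9 desaturase (Δ9DES-A), but the
  long-chain C18/C20 elongases retained;
* Type IV  — PUFA synthase, no Δ9DES-A, C18/C20 elongases lost.

A "complete" ELO/DES pathway requires the main-route enzymes Δ9A, Δ4, Δ5, ω3,
either the Δ6- or the Δ8-route desaturase, and the C16/C18/C20/Δ9 elongases.
The ω6/Δ9B, U-family and C16L genes are deliberately outside the completeness
predicate (they are not main-route enzymes); ``strict=True`` adds ω6/Δ9B as a
sensitivity check.  Cytosolic acetyl-CoA supply is inferred from the accessory
genes: ATP-citrate lyase (citrate route) if present, else carnitine
acetyltransferase (acetyl-carnitine shuttle), else undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_model import (
    CladeGroup,
    GenePanel,
    InputError,
    Presence,
    PresenceAbsenceMatrix,
)

LINEAGES = ("I", "II", "III", "IV")
UNCLASSIFIED = "unclassified"

#: Main-route genes required for a complete ELO/DES pathway (Δ6/Δ8 handled as
#: alternative routes).
CORE_ELO_DES = ("DES_D9A", "DES_D4", "DES_D5", "DES_w3",
                "ELO_C16", "ELO_C18", "ELO_C20", "ELO_D9")
ALT_ROUTE = ("DES_D6", "DES_D8")

ROUTE_CITRATE = "citrate_ACLY"
ROUTE_CARNITINE = "carnitine_cCrAT"
ROUTE_UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class PathwayFlags:
    pufas_complete: bool
    elodes_complete: bool
    has_d9a: bool
    has_acly: bool
    has_ccrat: bool
    has_crtz: bool
    has_crto: bool
    has_long_elos: bool
    uncertain: frozenset[str] = frozenset()  # unknown cells that fed a flag


@dataclass(frozen=True)
class TypeCall:
    strain_id: str
    lineage: str
    flags: PathwayFlags
    acetylcoa_route: str
    rationale: tuple[str, ...]
    caveat: str = ""


def _lookup(row, gene: str, uncertain: set[str]) -> bool:
    if gene not in row:
        raise InputError(f"matrix row lacks panel gene {gene!r}")
    value = row[gene]
    if value is Presence.UNKNOWN:
        uncertain.add(gene)
        return False
    return value is Presence.PRESENT


def pathway_flags(row, panel: GenePanel, strict: bool = False) -> PathwayFlags:
    """Derive the typing flags from one matrix row (gene → Presence mapping).

    Unknown cells count as absent and are collected in ``flags.uncertain``.
    """
    for gene in panel.names:
        if gene not in row:
            raise InputError(f"matrix row lacks panel gene {gene!r}")
    uncertain: set[str] = set()
    pufas = all(_lookup(row, g, uncertain) for g in ("PfaA", "PfaB", "PfaC"))
    core = list(CORE_ELO_DES)
    if strict:
        core.append("DES_w6D9B")
    core_ok = all(_lookup(row, g, uncertain) for g in core)
    route_ok = any(_lookup(row, g, uncertain) for g in ALT_ROUTE)
    return PathwayFlags(
        pufas_complete=pufas,
        elodes_complete=core_ok and route_ok,
        has_d9a=_lookup(row, "DES_D9A", uncertain),
        has_acly=_lookup(row, "ACLY", uncertain),
        has_ccrat=_lookup(row, "cCrAT", uncertain),
        has_crtz=_lookup(row, "CrtZ", uncertain),
        has_crto=_lookup(row, "CrtO", uncertain),
        has_long_elos=_lookup(row, "ELO_C18", uncertain) and _lookup(row, "ELO_C20", uncertain),
        uncertain=frozenset(uncertain),
    )


def call_type(flags: PathwayFlags) -> tuple[str, tuple[str, ...]]:
    """Lineage call with the ordered list of evaluated rule clauses.

    Clauses are evaluated I→IV, first match wins.
    """
    rationale: list[str] = []
    predicates = (
        ("I", "elodes_complete and not pufas_complete",
         flags.elodes_complete and not flags.pufas_complete),
        ("II", "elodes_complete and pufas_complete",
         flags.elodes_complete and flags.pufas_complete),
        ("III", "pufas_complete and not has_d9a and has_long_elos",
         flags.pufas_complete and not flags.has_d9a and flags.has_long_elos),
        ("IV", "pufas_complete and not has_d9a and not has_long_elos",
         flags.pufas_complete and not flags.has_d9a and not flags.has_long_elos),
    )
    for lineage, clause, value in predicates:
        rationale.append(f"Type {lineage}: {clause} -> {value}")
        if value:
            if flags.uncertain:
                rationale.append(f"uncertain (unknown cells treated absent): "
                                 f"{', '.join(sorted(flags.uncertain))}")
            return lineage, tuple(rationale)
    rationale.append("no lineage predicate fired -> unclassified")
    if flags.uncertain:
        rationale.append(f"uncertain (unknown cells treated absent): "
                         f"{', '.join(sorted(flags.uncertain))}")
    return UNCLASSIFIED, tuple(rationale)


def acetylcoa_route(flags: PathwayFlags) -> str:
    """Cytosolic acetyl-CoA supply: citrate/ACLY route, else the
    acetyl-carnitine shuttle, else undetermined."""
    if flags.has_acly:
        return ROUTE_CITRATE
    if flags.has_ccrat:
        return ROUTE_CARNITINE
    return ROUTE_UNDETERMINED


@dataclass(frozen=True)
class TypingReport:
    calls: tuple[TypeCall, ...]            # thraustochytrid strains
    relative_calls: tuple[TypeCall, ...]   # close relatives, heuristic typing
    pufas_complete_count: int
    elodes_complete_count: int
    lineage_counts: dict[str, int] = field(compare=False)

    @property
    def distinct_lineages(self) -> int:
        return len([k for k, v in self.lineage_counts.items()
                    if v > 0 and k != UNCLASSIFIED])

    def call(self, strain_id: str) -> TypeCall:
        for c in self.calls + self.relative_calls:
            if c.strain_id == strain_id:
                return c
        raise KeyError(strain_id)


def type_strain(strain_id: str, row, panel: GenePanel, strict: bool = False,
                caveat: str = "") -> TypeCall:
    flags = pathway_flags(row, panel, strict=strict)
    lineage, rationale = call_type(flags)
    return TypeCall(strain_id, lineage, flags, acetylcoa_route(flags), rationale, caveat)


def summarize(matrix: PresenceAbsenceMatrix, panel: GenePanel,
              strict: bool = False) -> TypingReport:
    """Per-strain type calls plus aggregate counts.

    Relatives are typed with a heuristic caveat and reported separately; the
    aggregate counts cover thraustochytrid strains only.
    """
    calls: list[TypeCall] = []
    relative_calls: list[TypeCall] = []
    lineage_counts: dict[str, int] = {k: 0 for k in LINEAGES + (UNCLASSIFIED,)}
    pufas_n = 0
    elodes_n = 0
    for strain in matrix.strains:
        row = matrix.row(strain.strain_id)
        if strain.clade_group is CladeGroup.RELATIVE:
            relative_calls.append(type_strain(
                strain.strain_id, row, panel, strict,
                caveat="non-thraustochytrid; typing heuristic only"))
            continue
        call = type_strain(strain.strain_id, row, panel, strict)
        calls.append(call)
        lineage_counts[call.lineage] += 1
        pufas_n += call.flags.pufas_complete
        elodes_n += call.flags.elodes_complete
    return TypingReport(tuple(calls), tuple(relative_calls),
                        pufas_n, elodes_n, lineage_counts)


def typing_table_rows(report: TypingReport) -> list[dict[str, str]]:
    """Flat rows (strain, lineage, flags, route, rationale) for TSV export."""
    rows = []
    for call in report.calls + report.relative_calls:
        f = call.flags
        rows.append({
            "strain_id": call.strain_id,
            "lineage": call.lineage,
            "pufas_complete": str(int(f.pufas_complete)),
            "elodes_complete": str(int(f.elodes_complete)),
            "has_d9a": str(int(f.has_d9a)),
            "has_long_elos": str(int(f.has_long_elos)),
            "acetylcoa_route": call.acetylcoa_route,
            "uncertain_cells": ",".join(sorted(f.uncertain)) or "-",
            "caveat": call.caveat or "-",
            "rationale": " | ".join(call.rationale),
        })
    return rows
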