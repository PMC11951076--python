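"""Homology-based family assignment and presence/absence matrix construction.

Candidate proteins are assigned to a panel family by best local-alignment hit
against a library of per-family archetype sequences (the exact-alignment
analogue of a BLASTP search), fused with histidine-box motif evidence.  Scores
are normalised by the archetype self-score so that 1.0 means "identical to the
archetype"; the default acceptance threshold of 0.3 is a package decision, not
a published cutoff, chosen loosely enough to tolerate ~30-40% divergence while
rejecting shuffled decoys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .core_model import (
    Category,
    ConfigError,
    GenePanel,
    InputError,
    Presence,
    PresenceAbsenceMatrix,
    ProteinRecord,
    StrainRecord,
)
from .motif_scan import (
    ELONGASE_CANDIDATE,
    UNCLASSIFIED,
    SignatureMatch,
    SignatureRegistry,
    classify_desaturase,
    classify_elongase,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_NORM_SCORE = 0.3
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_MATRIX = "BLOSUM62"


# ---------------------------------------------------------------------------
# Local alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentResult:
    score: float
    identity_fraction: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]


def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # a gap of length L costs gap_open + gap_extend * L
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(query: str, subject: str,
                matrix_name: str = DEFAULT_MATRIX,
                gap_open: int = DEFAULT_GAP_OPEN,
                gap_extend: int = DEFAULT_GAP_EXTEND) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment under affine gaps.

    A gap of length L costs ``gap_open + gap_extend * L``.  Deterministic: the
    first optimal traceback reported by the aligner is used.
    """
    if not query or not subject:
        raise InputError("local_align: empty sequence")
    aligner = _aligner(matrix_name, gap_open, gap_extend)
    alignments = aligner.align(query, subject)
    try:
        best = alignments[0]
    except IndexError:  # no positive-scoring alignment
        return AlignmentResult(0.0, 0.0, (0, 0), (0, 0))
    counts = best.counts()
    aligned_cols = counts.identities + counts.mismatches
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    qa, sa = best.aligned[0], best.aligned[1]
    query_span = (int(qa[0][0]), int(qa[-1][1])) if len(qa) else (0, 0)
    subject_span = (int(sa[0][0]), int(sa[-1][1])) if len(sa) else (0, 0)
    return AlignmentResult(float(best.score), identity, query_span, subject_span)


def self_score(sequence: str, matrix_name: str = DEFAULT_MATRIX) -> float:
    """Alignment score of a sequence against itself (no gaps needed)."""
    matrix = substitution_matrices.load(matrix_name)
    return float(sum(matrix[aa, aa] for aa in sequence))


# ---------------------------------------------------------------------------
# Reference library
# ---------------------------------------------------------------------------

class ReferenceLibrary:
    """Per-family archetype protein records used as best-hit subjects."""

    def __init__(self, entries: Mapping[str, Sequence[ProteinRecord]],
                 matrix_name: str = DEFAULT_MATRIX):
        self.entries: dict[str, tuple[ProteinRecord, ...]] = {
            fam: tuple(records) for fam, records in entries.items()
        }
        if not self.entries or not any(self.entries.values()):
            raise ConfigError("reference library is empty")
        self.matrix_name = matrix_name
        self._self_scores: dict[str, float] = {}
        for fam, records in self.entries.items():
            if not records:
                raise ConfigError(f"reference library family {fam} has no archetype")
            for rec in records:
                self._self_scores[rec.protein_id] = self_score(rec.sequence, matrix_name)

    def validate_against_panel(self, panel: GenePanel) -> None:
        missing = [g.name for g in panel.genes if g.name not in self.entries]
        if missing:
            raise ConfigError(f"reference library lacks archetypes for: {missing}")

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(sorted(self.entries))

    def archetype_self_score(self, protein_id: str) -> float:
        return self._self_scores[protein_id]


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyAssignment:
    protein_id: str
    family: str  # panel gene label or "unclassified"
    evidence: frozenset[str]  # subset of {"motif", "best_hit"}
    normalized_score: float | None = None
    motif_match: SignatureMatch | None = None

    def __post_init__(self):
        if self.family != UNCLASSIFIED and not self.evidence:
            raise InputError(f"{self.protein_id}: classified without evidence")


def best_hit_assign(query: ProteinRecord, library: ReferenceLibrary,
                    min_norm_score: float = DEFAULT_MIN_NORM_SCORE) -> FamilyAssignment:
    """Family of the archetype maximising the self-score-normalised local score.

    Ties broken by higher identity fraction, then alphabetical family label.
    Below-threshold best hits yield ``unclassified``.
    """
    best: tuple[float, float, str] | None = None  # (norm, identity, family)
    for family in library.families:
        for archetype in library.entries[family]:
            res = local_align(query.sequence, archetype.sequence, library.matrix_name)
            denom = library.archetype_self_score(archetype.protein_id)
            norm = res.score / denom if denom > 0 else 0.0
            cand = (norm, res.identity_fraction, family)
            if best is None:
                best = cand
            elif (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
            elif (cand[0], cand[1]) == (best[0], best[1]) and cand[2] < best[2]:
                best = cand
    assert best is not None
    norm, _, family = best
    if norm < min_norm_score:
        return FamilyAssignment(query.protein_id, UNCLASSIFIED, frozenset(),
                                normalized_score=None)
    return FamilyAssignment(query.protein_id, family, frozenset({"best_hit"}),
                            normalized_score=min(norm, 1.0))


def _motif_call(sequence: str, registry: SignatureRegistry) -> tuple[str, SignatureMatch | None]:
    """Combined motif verdict: specific desaturase family, ELO_C20 candidate,
    generic elongase candidate, or unclassified."""
    family, match = classify_desaturase(sequence, registry)
    if family != UNCLASSIFIED:
        return family, match
    return classify_elongase(sequence, registry)


def _motif_agrees(motif_family: str, assigned_family: str, category: Category) -> bool:
    if category is Category.DESATURASE:
        return motif_family == assigned_family
    if category is Category.ELONGASE:
        if assigned_family == "ELO_C20":
            return motif_family == "ELO_C20"
        return motif_family == ELONGASE_CANDIDATE
    return False


def assign_proteome(proteins: Iterable[ProteinRecord], panel: GenePanel,
                    library: ReferenceLibrary, registry: SignatureRegistry,
                    min_norm_score: float = DEFAULT_MIN_NORM_SCORE) -> list[FamilyAssignment]:
    """Assign every protein, fusing motif and best-hit evidence.

    Desaturases/elongases: agreement of both lines of evidence is recorded;
    on conflict the best hit wins with a logged warning (motif signatures
    within a subfamily are lossy placeholders).  A desaturase motif call with
    no acceptable best hit is kept as motif-only evidence.  PUFA-S subunits
    and accessory genes are assigned on best hit alone.
    """
    library.validate_against_panel(panel)
    assignments: list[FamilyAssignment] = []
    for protein in proteins:
        bh = best_hit_assign(protein, library, min_norm_score)
        motif_family, motif_match = _motif_call(protein.sequence, registry)
        if bh.family != UNCLASSIFIED:
            category = panel[bh.family].category
            if category in (Category.DESATURASE, Category.ELONGASE):
                if _motif_agrees(motif_family, bh.family, category):
                    assignments.append(FamilyAssignment(
                        protein.protein_id, bh.family,
                        frozenset({"motif", "best_hit"}),
                        bh.normalized_score, motif_match))
                    continue
                if motif_family != UNCLASSIFIED:
                    logger.warning(
                        "%s: motif evidence (%s) conflicts with best hit (%s); keeping best hit",
                        protein.protein_id, motif_family, bh.family)
            assignments.append(FamilyAssignment(
                protein.protein_id, bh.family, frozenset({"best_hit"}),
                bh.normalized_score, None))
        elif motif_family not in (UNCLASSIFIED, ELONGASE_CANDIDATE, "ELO_C20"):
            # specific desaturase family by motif alone
            assignments.append(FamilyAssignment(
                protein.protein_id, motif_family, frozenset({"motif"}),
                None, motif_match))
        else:
            # elongase-box candidates without homology support stay unclassified
            assignments.append(FamilyAssignment(
                protein.protein_id, UNCLASSIFIED, frozenset(), None, motif_match))
    return assignments


def presence_matrix(per_strain_assignments: Mapping[str, Sequence[FamilyAssignment]],
                    panel: GenePanel,
                    strains: Sequence[StrainRecord]) -> PresenceAbsenceMatrix:
    """Presence/absence matrix: a cell is present iff the strain has at least
    one assignment to that family; all other cells are absent."""
    known = {s.strain_id for s in strains}
    unknown = set(per_strain_assignments) - known
    if unknown:
        raise InputError(f"assignments reference unknown strain(s): {sorted(unknown)}")
    cells: dict[tuple[str, str], Presence] = {
        (s.strain_id, g): Presence.ABSENT for s in strains for g in panel.names
    }
    for strain_id, assignments in per_strain_assignments.items():
        for a in assignments:
            if a.family != UNCLASSIFIED:
                cells[(strain_id, a.family)] = Presence.PRESENT
    return PresenceAbsenceMatrix(strains, panel.names, cells)
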