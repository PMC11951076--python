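"""Histidine-box motif scanning and subfamily classification.

Membrane desaturases carry three short His-rich catalytic boxes whose shapes
differ between the First, Front-End and Omega subfamilies; PUFA elongases carry
a single box, canonically HXXHH, with the C20 group bearing the atypical QXXHH
variant.  Patterns use literal residues, the wildcard ``X`` and bracketed
alternatives (``H[ED]CGH``).  Only the subfamily-level box shapes are published;
the default registry therefore instantiates one wildcard position per family
with a distinguishing residue so that synthetic members are separable by motif
alone, while real within-subfamily resolution is deferred to homology evidence
(see ``family_assign``).
"""

from __future__ import annotations

import configparser
import itertools
from dataclasses import dataclass, field

from .core_model import AMINO_ACIDS, Category, ConfigError, GenePanel, InputError

#: Enumeration cap per box when combining box hits into signature candidates.
MAX_MATCHES_PER_BOX = 50

#: Default min/max residue separation between consecutive desaturase boxes.
DEFAULT_SPACING: tuple[int, int] = (15, 300)

#: Default N-terminal search window (residues) for domain core motifs.
DEFAULT_NTERM_WINDOW = 150

#: Core motifs used as N-terminal domain heuristics.  The cytochrome-b5 heme
#: pocket tetrapeptide HPGG is the standard diagnostic core; no default motifs
#: are configured for the DUF3474/DUF1129 domains (their detection is skipped,
#: i.e. treated as satisfied, unless the user supplies a pattern).
NTERM_CORE_MOTIFS: dict[str, str | None] = {
    "none": None,
    "cytb5": "HPGG",
    "DUF3474": None,
    "DUF1129": None,
}

#: Marker returned by classify_elongase for a histidine-box hit that cannot be
#: resolved to a specific group without homology evidence.
ELONGASE_CANDIDATE = "ELO_candidate"

UNCLASSIFIED = "unclassified"


class PatternError(ConfigError):
    """Unparseable box pattern."""


# ---------------------------------------------------------------------------
# Box patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxPattern:
    """A degenerate 5-6 residue box; ``positions[i]`` is the allowed residue set
    at offset ``i`` (``None`` = wildcard)."""

    name: str
    pattern: str
    positions: tuple[frozenset | None, ...] = field(compare=False)

    def __post_init__(self):
        if not (5 <= len(self.positions) <= 6):
            raise PatternError(f"{self.pattern!r}: box length must be 5-6 residues")
        n_hq = sum(1 for p in self.positions if p is not None and p <= {"H", "Q"} and len(p) == 1)
        if n_hq < 2:
            raise PatternError(f"{self.pattern!r}: needs at least two literal H/Q positions")

    @classmethod
    def parse(cls, pattern: str, name: str = "box") -> "BoxPattern":
        positions: list[frozenset | None] = []
        i = 0
        while i < len(pattern):
            ch = pattern[i]
            if ch == "X":
                positions.append(None)
                i += 1
            elif ch == "[":
                j = pattern.find("]", i)
                if j < 0:
                    raise PatternError(f"{pattern!r}: unclosed bracket")
                alts = pattern[i + 1:j]
                if not alts or any(a not in AMINO_ACIDS for a in alts):
                    raise PatternError(f"{pattern!r}: bad alternative set {alts!r}")
                positions.append(frozenset(alts))
                i = j + 1
            elif ch in AMINO_ACIDS:
                positions.append(frozenset(ch))
                i += 1
            else:
                raise PatternError(f"{pattern!r}: illegal character {ch!r}")
        return cls(name=name, pattern=pattern, positions=tuple(positions))

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def literal_count(self) -> int:
        """Number of constrained (non-wildcard) positions."""
        return sum(1 for p in self.positions if p is not None)

    def matches_at(self, sequence: str, start: int) -> bool:
        if start < 0 or start + len(self) > len(sequence):
            return False
        for offset, allowed in enumerate(self.positions):
            if allowed is not None and sequence[start + offset] not in allowed:
                return False
        return True


@dataclass(frozen=True)
class BoxMatch:
    pattern_name: str
    start: int
    matched_text: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched_text)


def scan_boxes(sequence: str, pattern: BoxPattern | str) -> list[BoxMatch]:
    """All occurrences of ``pattern`` in ``sequence``, left to right, overlaps allowed."""
    if isinstance(pattern, str):
        pattern = BoxPattern.parse(pattern)
    hits = []
    for start in range(len(sequence) - len(pattern) + 1):
        if pattern.matches_at(sequence, start):
            hits.append(BoxMatch(pattern.name, start, sequence[start:start + len(pattern)]))
    return hits


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifSignature:
    signature_id: str
    family: str
    boxes: tuple[BoxPattern, ...]
    spacing: tuple[tuple[int, int], ...]   # per-gap (min, max) residue separation
    nterm_domain: str = "none"
    nterm_window: int = DEFAULT_NTERM_WINDOW

    def __post_init__(self):
        if len(self.boxes) not in (1, 3):
            raise ConfigError(f"{self.signature_id}: signatures have 1 (elongase) or 3 (desaturase) boxes")
        if len(self.spacing) != len(self.boxes) - 1:
            raise ConfigError(f"{self.signature_id}: need {len(self.boxes) - 1} spacing bounds")
        for lo, hi in self.spacing:
            if lo > hi:
                raise ConfigError(f"{self.signature_id}: spacing min {lo} > max {hi}")
        if self.nterm_domain not in NTERM_CORE_MOTIFS:
            raise ConfigError(f"{self.signature_id}: unknown N-terminal domain tag {self.nterm_domain!r}")

    @property
    def literal_count(self) -> int:
        return sum(b.literal_count for b in self.boxes)


@dataclass(frozen=True)
class SignatureMatch:
    signature_id: str
    box_matches: tuple[BoxMatch, ...]
    spacing_ok: bool
    nterm_ok: bool
    score: int  # matched constrained positions across all boxes

    @property
    def span(self) -> tuple[int, int]:
        return self.box_matches[0].start, self.box_matches[-1].end


def detect_nterm_domain(sequence: str, domain_tag: str,
                        window: int = DEFAULT_NTERM_WINDOW,
                        core_motifs: dict[str, str | None] | None = None) -> bool:
    """True iff the tag's core motif starts within the first ``window`` residues.

    Tag ``none`` (or a tag with no configured core motif) is always satisfied.
    """
    motifs = NTERM_CORE_MOTIFS if core_motifs is None else core_motifs
    if domain_tag not in motifs:
        raise ConfigError(f"unknown N-terminal domain tag {domain_tag!r}")
    motif = motifs[domain_tag]
    if motif is None:
        return True
    return sequence.find(motif, 0, window + len(motif) - 1) >= 0


def match_signature(sequence: str, signature: MotifSignature,
                    max_matches_per_box: int = MAX_MATCHES_PER_BOX) -> SignatureMatch | None:
    """Best combination of box hits: maximize matched constrained positions, then
    minimize total span; boxes must occur in order without overlapping.  Returns
    ``None`` when any box has no hit."""
    per_box: list[list[BoxMatch]] = []
    for box in signature.boxes:
        hits = scan_boxes(sequence, box)
        if not hits:
            return None
        if len(hits) > max_matches_per_box:
            raise InputError(
                f"{signature.signature_id}: box {box.name} has {len(hits)} hits "
                f"(cap {max_matches_per_box}); sequence too repetitive")
        per_box.append(hits)

    score = sum(b.literal_count for b in signature.boxes)  # same for every full combination
    best: tuple[int, tuple[BoxMatch, ...]] | None = None
    for combo in itertools.product(*per_box):
        ok = all(combo[i + 1].start >= combo[i].end for i in range(len(combo) - 1))
        if not ok:
            continue
        span = combo[-1].end - combo[0].start
        if best is None or span < best[0]:
            best = (span, combo)
    if best is None:
        return None
    combo = best[1]
    spacing_ok = all(
        lo <= combo[i + 1].start - combo[i].end <= hi
        for i, (lo, hi) in enumerate(signature.spacing)
    )
    nterm_ok = detect_nterm_domain(sequence, signature.nterm_domain, signature.nterm_window)
    return SignatureMatch(signature.signature_id, combo, spacing_ok, nterm_ok, score)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

# Subfamily box shapes: First = HRLWSH / HRXHH / HNXHH; Front-End = HDXGH /
# HXXHH (observed variant of the canonical HXXXHH) / QXEHH; Omega = H[ED]CGH /
# HXXHH / HVXHH.  One wildcard per family is instantiated with a family tag
# residue (synthetic default, see module docstring).  The Delta4 group keeps
# the canonical 6-residue second box with relaxed flanking boxes; U1-U3 are
# Front-End-shaped placeholders; U3 carries a long N-terminal extension ahead
# of its cytb5 domain, hence the enlarged search window.
DEFAULT_REGISTRY_CONFIG = """\
[DES_D9A]
family = DES_D9A
boxes = HRLWSH, HRXHH, HNXHH
nterm = none

[DES_D4]
family = DES_D4
boxes = HPXHH, HXXXHH, HGXXH
nterm = cytb5

[DES_D5]
family = DES_D5
boxes = HDAGH, HAXHH, QAEHH
nterm = cytb5

[DES_D6]
family = DES_D6
boxes = HDEGH, HEXHH, QEEHH
nterm = cytb5

[DES_D8]
family = DES_D8
boxes = HDGGH, HGXHH, QGEHH
nterm = cytb5

[DES_w6D9B]
family = DES_w6D9B
boxes = HECGH, HTXHH, HVTHH
nterm = DUF3474

[DES_w3]
family = DES_w3
boxes = HDCGH, HWXHH, HVWHH
nterm = none

[DES_U1]
family = DES_U1
boxes = HDMGH, HMXHH, QMEHH
nterm = cytb5

[DES_U2]
family = DES_U2
boxes = HDNGH, HNXHH, QNEHH
nterm = cytb5

[DES_U3]
family = DES_U3
boxes = HDSGH, HSXHH, QSEHH
nterm = cytb5
nterm_window = 700

[ELO_C16]
family = ELO_C16
boxes = HXXHH

[ELO_C16L]
family = ELO_C16L
boxes = HXXHH

[ELO_C18]
family = ELO_C18
boxes = HXXHH

[ELO_C20]
family = ELO_C20
boxes = QXXHH

[ELO_D9]
family = ELO_D9
boxes = HXXHH

[ELO_U1]
family = ELO_U1
boxes = HXXHH

[ELO_U2]
family = ELO_U2
boxes = HXXHH
"""


@dataclass(frozen=True)
class SignatureRegistry:
    signatures: tuple[MotifSignature, ...]

    def __post_init__(self):
        ids = [s.signature_id for s in self.signatures]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate signature ids in registry")

    def __getitem__(self, signature_id: str) -> MotifSignature:
        for sig in self.signatures:
            if sig.signature_id == signature_id:
                return sig
        raise KeyError(signature_id)

    def __contains__(self, signature_id: str) -> bool:
        return any(s.signature_id == signature_id for s in self.signatures)

    def for_panel(self, panel: GenePanel, category: Category) -> tuple[MotifSignature, ...]:
        wanted = {g.signature_id for g in panel.by_category(category)}
        sigs = tuple(s for s in self.signatures if s.signature_id in wanted)
        missing = wanted - {s.signature_id for s in sigs}
        if missing:
            raise ConfigError(f"registry lacks signature(s): {sorted(missing)}")
        return sigs

    @property
    def desaturase_signatures(self) -> tuple[MotifSignature, ...]:
        return tuple(s for s in self.signatures if len(s.boxes) == 3)

    @property
    def elongase_signatures(self) -> tuple[MotifSignature, ...]:
        return tuple(s for s in self.signatures if len(s.boxes) == 1)


def load_registry(config_text: str | None = None) -> SignatureRegistry:
    """Parse a signature registry (INI: one section per signature).

    Keys: ``family``, ``boxes`` (comma-separated patterns), optional ``spacing``
    (comma-separated ``min-max`` per gap), ``nterm``, ``nterm_window``.
    """
    text = DEFAULT_REGISTRY_CONFIG if config_text is None else config_text
    parser = configparser.ConfigParser()
    try:
        parser.read_string(text)
    except configparser.Error as exc:
        raise ConfigError(f"bad registry config: {exc}") from exc
    signatures = []
    for section in parser.sections():
        raw = parser[section]
        if "family" not in raw or "boxes" not in raw:
            raise ConfigError(f"signature {section}: needs 'family' and 'boxes'")
        box_tokens = [t.strip() for t in raw["boxes"].split(",")]
        boxes = tuple(
            BoxPattern.parse(tok, name=f"box{i + 1}" if len(box_tokens) > 1 else "elo_box")
            for i, tok in enumerate(box_tokens)
        )
        if "spacing" in raw:
            spacing = []
            for tok in raw["spacing"].split(","):
                lo, _, hi = tok.strip().partition("-")
                spacing.append((int(lo), int(hi)))
            spacing = tuple(spacing)
        else:
            spacing = tuple(DEFAULT_SPACING for _ in range(len(boxes) - 1))
        signatures.append(MotifSignature(
            signature_id=section,
            family=raw["family"].strip(),
            boxes=boxes,
            spacing=spacing,
            nterm_domain=raw.get("nterm", "none").strip(),
            nterm_window=int(raw.get("nterm_window", str(DEFAULT_NTERM_WINDOW))),
        ))
    return SignatureRegistry(tuple(signatures))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_desaturase(sequence: str,
                        registry: SignatureRegistry) -> tuple[str, SignatureMatch | None]:
    """Family of the highest-scoring spacing-consistent signature match.

    Ties broken by more constrained positions in the signature, then by
    alphabetical family label.  Returns ``("unclassified", None)`` when no
    signature fully matches with legal spacing.
    """
    sigs = registry.desaturase_signatures
    if not sigs:
        raise ConfigError("registry holds no desaturase signatures")
    best: tuple[tuple[int, int, str], str, SignatureMatch] | None = None
    for sig in sorted(sigs, key=lambda s: s.family):
        match = match_signature(sequence, sig)
        if match is None or not match.spacing_ok:
            continue
        key = (-match.score, -sig.literal_count, sig.family)
        if best is None or key < best[0]:
            best = (key, sig.family, match)
    if best is None:
        return UNCLASSIFIED, None
    return best[1], best[2]


def classify_elongase(sequence: str,
                      registry: SignatureRegistry) -> tuple[str, SignatureMatch | None]:
    """Single-box elongase call.

    A QXXHH hit marks a C20-elongase candidate (``ELO_C20``); an HXXHH hit
    marks a generic elongase candidate (:data:`ELONGASE_CANDIDATE`) whose group
    is resolvable only with homology evidence; no hit → ``unclassified``.
    """
    sigs = registry.elongase_signatures
    if not sigs:
        raise ConfigError("registry holds no elongase signatures")
    c20 = [s for s in sigs if s.family == "ELO_C20"]
    if c20:
        match = match_signature(sequence, c20[0])
        if match is not None:
            return "ELO_C20", match
    for sig in sorted((s for s in sigs if s.family != "ELO_C20"), key=lambda s: s.family):
        match = match_signature(sequence, sig)
        if match is not None:
            return ELONGASE_CANDIDATE, match
    return UNCLASSIFIED, None
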