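"""Domain types, the diagnostic gene panel, and the packaged strain × gene fixture.

Thraustochytrids build long-chain ω3 PUFAs (DHA, EPA) through two routes: the
iterative elongase/desaturase (ELO/DES) pathway and the polyketide-synthase-like
PUFA synthase (PUFA-S) complex with three subunits PfaA/PfaB/PfaC.  The panel
below registers the diagnostic genes for both routes plus four accessory genes
(acetyl-CoA supply and xanthophyll biosynthesis).  The packaged fixture encodes
the published presence/absence pattern of those genes across 19 thraustochytrid
strains and three labyrinthulomycete relatives; every filled cell is backed by
an explicit statement in the source study's text, cells not covered by a
statement are left ``unknown``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PufatyperError(Exception):
    """Base class for all package errors."""


class ConfigError(PufatyperError):
    """Invalid panel/signature/run configuration."""


class InputError(PufatyperError):
    """Invalid user input (sequences, matrices, annotations)."""


class ParseError(InputError):
    """Malformed structured-text input."""


# ---------------------------------------------------------------------------
# Enumerations and simple records
# ---------------------------------------------------------------------------

class Presence(enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"

    @property
    def token(self) -> str:
        return {Presence.PRESENT: "1", Presence.ABSENT: "0", Presence.UNKNOWN: "?"}[self]

    @classmethod
    def from_token(cls, token: str) -> "Presence":
        try:
            return {"1": cls.PRESENT, "0": cls.ABSENT, "?": cls.UNKNOWN}[token]
        except KeyError:
            raise ParseError(f"illegal presence token {token!r} (expected 1, 0 or ?)") from None


class Category(enum.Enum):
    PUFA_SYNTHASE = "pufa_synthase"
    DESATURASE = "desaturase"
    ELONGASE = "elongase"
    ACCESSORY = "accessory"


class CladeGroup(enum.Enum):
    THRAUSTOCHYTRID = "thraustochytrid"
    RELATIVE = "relative"


class EvidenceSource(enum.Enum):
    GENOME = "genome"
    TRANSCRIPTOME = "transcriptome"


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class PanelGene:
    name: str
    category: Category
    signature_id: str | None = None


@dataclass(frozen=True)
class StrainRecord:
    strain_id: str
    genus: str
    clade_group: CladeGroup
    evidence_source: EvidenceSource
    ploidy_note: str = ""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence attached to a strain; alphabet is the 20 standard residues plus X."""

    protein_id: str
    strain_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"protein {self.protein_id}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise InputError(
                f"protein {self.protein_id}: illegal residues {sorted(bad)}"
            )


# ---------------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------------

#: Canonical panel: 3 PUFA-S subunits, 10 desaturase families, 7 elongase groups
#: (6 major + the C16-like minor group) and 4 accessory genes.
PANEL_GENE_NAMES: tuple[str, ...] = (
    "PfaA", "PfaB", "PfaC",
    "DES_D4", "DES_D5", "DES_D6", "DES_D8", "DES_D9A",
    "DES_w6D9B", "DES_w3", "DES_U1", "DES_U2", "DES_U3",
    "ELO_C16", "ELO_C16L", "ELO_C18", "ELO_C20", "ELO_D9", "ELO_U1", "ELO_U2",
    "ACLY", "cCrAT", "CrtZ", "CrtO",
)

DEFAULT_PANEL_CONFIG = """\
# gene<TAB>category<TAB>signature_id (or '-' for none)
PfaA\tpufa_synthase\t-
PfaB\tpufa_synthase\t-
PfaC\tpufa_synthase\t-
DES_D4\tdesaturase\tDES_D4
DES_D5\tdesaturase\tDES_D5
DES_D6\tdesaturase\tDES_D6
DES_D8\tdesaturase\tDES_D8
DES_D9A\tdesaturase\tDES_D9A
DES_w6D9B\tdesaturase\tDES_w6D9B
DES_w3\tdesaturase\tDES_w3
DES_U1\tdesaturase\tDES_U1
DES_U2\tdesaturase\tDES_U2
DES_U3\tdesaturase\tDES_U3
ELO_C16\telongase\tELO_C16
ELO_C16L\telongase\tELO_C16L
ELO_C18\telongase\tELO_C18
ELO_C20\telongase\tELO_C20
ELO_D9\telongase\tELO_D9
ELO_U1\telongase\tELO_U1
ELO_U2\telongase\tELO_U2
ACLY\taccessory\t-
cCrAT\taccessory\t-
CrtZ\taccessory\t-
CrtO\taccessory\t-
"""


@dataclass(frozen=True)
class GenePanel:
    genes: tuple[PanelGene, ...]

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"duplicate panel gene name(s): {dupes}")
        for gene in self.genes:
            if gene.category in (Category.DESATURASE, Category.ELONGASE) and not gene.signature_id:
                raise ConfigError(f"{gene.name}: {gene.category.value} panel gene lacks a signature link")
        missing = set(PANEL_GENE_NAMES) - set(names)
        if missing:
            raise ConfigError(f"panel is missing canonical gene(s): {sorted(missing)}")
        unknown = set(names) - set(PANEL_GENE_NAMES)
        if unknown:
            raise ConfigError(f"panel declares unknown gene(s): {sorted(unknown)}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    def __getitem__(self, name: str) -> PanelGene:
        for gene in self.genes:
            if gene.name == name:
                return gene
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(g.name == name for g in self.genes)

    def by_category(self, category: Category) -> tuple[PanelGene, ...]:
        return tuple(g for g in self.genes if g.category == category)

    @property
    def desaturases(self) -> tuple[PanelGene, ...]:
        return self.by_category(Category.DESATURASE)

    @property
    def elongases(self) -> tuple[PanelGene, ...]:
        return self.by_category(Category.ELONGASE)


def load_panel(panel_config: str | None = None) -> GenePanel:
    """Parse a panel configuration (tab-separated ``gene  category  signature``).

    ``panel_config=None`` loads the default 24-gene panel.
    """
    text = DEFAULT_PANEL_CONFIG if panel_config is None else panel_config
    genes: list[PanelGene] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ConfigError(f"panel config line {lineno}: expected 3 tab-separated fields")
        name, cat_token, sig = parts
        try:
            category = Category(cat_token)
        except ValueError:
            raise ConfigError(f"panel config line {lineno}: unknown category {cat_token!r}") from None
        genes.append(PanelGene(name, category, None if sig == "-" else sig))
    return GenePanel(tuple(genes))


# ---------------------------------------------------------------------------
# Presence/absence matrix
# ---------------------------------------------------------------------------

class PresenceAbsenceMatrix:
    """Rectangular strain × panel-gene matrix with present/absent/unknown cells.

    Equality and the TSV round trip are defined over strain ids, gene names and
    cell values; strain metadata (genus, evidence source, notes) travels with
    the ``strains`` records but is not part of the TSV dialect.
    """

    def __init__(self, strains: Iterable[StrainRecord], genes: Iterable[str],
                 cells: Mapping[tuple[str, str], Presence] | pd.DataFrame):
        self.strains: tuple[StrainRecord, ...] = tuple(strains)
        self.genes: tuple[str, ...] = tuple(genes)
        strain_ids = [s.strain_id for s in self.strains]
        if len(set(strain_ids)) != len(strain_ids):
            raise InputError("duplicate strain ids in matrix")
        if len(set(self.genes)) != len(self.genes):
            raise InputError("duplicate gene names in matrix")
        if isinstance(cells, pd.DataFrame):
            df = cells.copy()
            if list(df.index) != strain_ids or list(df.columns) != list(self.genes):
                raise InputError("cell frame labels do not match strain/gene lists")
        else:
            df = pd.DataFrame(index=strain_ids, columns=list(self.genes), dtype=object)
            for (sid, gene), value in cells.items():
                if sid not in df.index or gene not in df.columns:
                    raise InputError(f"cell ({sid!r}, {gene!r}) outside matrix frame")
                df.loc[sid, gene] = value
        for sid in strain_ids:
            for gene in self.genes:
                v = df.loc[sid, gene]
                if not isinstance(v, Presence):
                    raise InputError(f"cell ({sid!r}, {gene!r}) has no Presence value")
        self._df = df

    # -- accessors ---------------------------------------------------------
    @property
    def strain_ids(self) -> tuple[str, ...]:
        return tuple(s.strain_id for s in self.strains)

    def strain(self, strain_id: str) -> StrainRecord:
        for s in self.strains:
            if s.strain_id == strain_id:
                return s
        raise KeyError(strain_id)

    def cell(self, strain_id: str, gene: str) -> Presence:
        return self._df.loc[strain_id, gene]

    def row(self, strain_id: str) -> dict[str, Presence]:
        if strain_id not in self._df.index:
            raise KeyError(strain_id)
        return dict(self._df.loc[strain_id])

    def thraustochytrids(self) -> tuple[StrainRecord, ...]:
        return tuple(s for s in self.strains if s.clade_group == CladeGroup.THRAUSTOCHYTRID)

    def relatives(self) -> tuple[StrainRecord, ...]:
        return tuple(s for s in self.strains if s.clade_group == CladeGroup.RELATIVE)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceAbsenceMatrix):
            return NotImplemented
        return (self.strain_ids == other.strain_ids and self.genes == other.genes
                and self._df.equals(other._df))

    def __repr__(self) -> str:
        return f"PresenceAbsenceMatrix({len(self.strains)} strains x {len(self.genes)} genes)"


def write_matrix_tsv(matrix: PresenceAbsenceMatrix, path) -> None:
    """Serialize to TSV: header of gene names, first column ``strain_id``, cells 1/0/?."""
    with open(path, "w") as fh:
        fh.write("strain_id\t" + "\t".join(matrix.genes) + "\n")
        for sid in matrix.strain_ids:
            row = matrix.row(sid)
            fh.write(sid + "\t" + "\t".join(row[g].token for g in matrix.genes) + "\n")


def read_matrix_tsv(path, strains: Iterable[StrainRecord] | None = None) -> PresenceAbsenceMatrix:
    """Read the TSV dialect written by :func:`write_matrix_tsv`.

    If ``strains`` is given, its metadata is attached to the matching rows
    (ids must agree); otherwise bare thraustochytrid/genome records are built.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError("empty matrix file (missing header)")
    header = lines[0].split("\t")
    if header[0] != "strain_id":
        raise ParseError("matrix header must start with 'strain_id'")
    genes = header[1:]
    cells: dict[tuple[str, str], Presence] = {}
    ids: list[str] = []
    for lineno, line in enumerate(lines[1:], 2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(f"line {lineno}: ragged row ({len(parts)} fields, expected {len(header)})")
        sid = parts[0]
        ids.append(sid)
        for gene, token in zip(genes, parts[1:]):
            cells[(sid, gene)] = Presence.from_token(token)
    if strains is None:
        records = [StrainRecord(sid, "unknown", CladeGroup.THRAUSTOCHYTRID, EvidenceSource.GENOME)
                   for sid in ids]
    else:
        by_id = {s.strain_id: s for s in strains}
        missing = [sid for sid in ids if sid not in by_id]
        if missing:
            raise InputError(f"no strain metadata for {missing}")
        records = [by_id[sid] for sid in ids]
    return PresenceAbsenceMatrix(records, genes, cells)


# ---------------------------------------------------------------------------
# Packaged fixture: 19 thraustochytrids + 3 relatives x 24 panel genes
# ---------------------------------------------------------------------------

_T = CladeGroup.THRAUSTOCHYTRID
_R = CladeGroup.RELATIVE
_G = EvidenceSource.GENOME
_X = EvidenceSource.TRANSCRIPTOME

#: (strain_id, genus, lineage key, clade group, evidence source, note)
FIXTURE_STRAIN_TABLE: tuple[tuple[str, str, str, CladeGroup, EvidenceSource, str], ...] = (
    # Type I: exclusively the ELO/DES pathway
    ("B. sp. S-28", "Botryochytrium", "I", _T, _X, "RNA-seq evidence only"),
    ("P. sp. I65-24A", "Parietichytrium", "I", _T, _G, ""),
    ("S. aggregatum ATCC 28209", "Schizochytrium", "I", _T, _G, ""),
    ("T. striatum ATCC 24473", "Thraustochytrium", "I", _T, _G, ""),
    # Type II: both PUFA-S and a complete ELO/DES pathway
    ("T. aureum ATCC 34304", "Thraustochytrium", "II", _T, _G, ""),
    ("T. aureum ssp. strugatskii", "Thraustochytrium", "II", _T, _X, "RNA-seq evidence only"),
    # Type III: PUFA-S plus an incomplete ELO/DES pathway lacking the canonical Delta9 desaturase
    ("A. sp. T66", "Aurantiochytrium", "III", _T, _G, ""),
    ("A. sp. KH105", "Aurantiochytrium", "III", _T, _G, "diploid"),
    ("H. fermentalgiana FCC1311", "Hondaea", "III", _T, _G, ""),
    ("T. sp. ATCC 26185", "Thraustochytrium", "III", _T, _G, ""),
    ("T. sp. TN22", "Thraustochytrium", "III", _T, _G, ""),
    ("S. sp. CCTCC M209059", "Schizochytrium", "III", _T, _G,
     "ACLY homolog is a 422-residue truncation lacking the N-terminal ATP/citrate/CoA binding "
     "domains; recorded absent for typing"),
    ("S. sp. ATCC 20888", "Schizochytrium", "III", _T, _X, "RNA-seq evidence only"),
    # Type IV: PUFA-S only, most ELO/DES enzymes missing
    ("A. acetophilum HS399", "Aurantiochytrium", "IV", _T, _G, ""),
    ("A. limacinum ATCC MYA-1381", "Aurantiochytrium", "IV", _T, _G, ""),
    ("A. limacinum SR21", "Aurantiochytrium", "IV", _T, _G, ""),
    ("A. sp. R2", "Aurantiochytrium", "IV", _T, _X, "RNA-seq evidence only"),
    ("S. sp. TIO01", "Schizochytrium", "IV", _T, _G, ""),
    ("S. sp. x62-1", "Schizochytrium", "IV", _T, _X, "RNA-seq evidence only"),
    # Close labyrinthulomycete relatives (typed with a heuristic caveat only)
    ("O. sp. RT2316-13", "Oblongichytrium", "relative", _R, _X,
     "not among the listed genome assemblies; lacks PUFA-S, carries the ELO/DES pathway"),
    ("A. kerguelense PBS07", "Aplanochytrium", "relative", _R, _G,
     "PUFA-S plus an incomplete ELO/DES pathway"),
    ("L. sp. SR_Ha_C", "Labyrinthula", "relative", _R, _G,
     "PUFA-S only; no elongase genes detected"),
)

#: Published lineage of each thraustochytrid fixture strain (transcribed strain lists).
FIXTURE_LINEAGES: dict[str, str] = {
    sid: lineage for sid, _, lineage, group, _, _ in FIXTURE_STRAIN_TABLE
    if group is CladeGroup.THRAUSTOCHYTRID
}

# Per-lineage cell templates.  Tokens: 1 present, 0 absent, ? unknown.  Only
# cells fixed by an explicit text statement are 1/0; everything else stays '?'.
_TEMPLATE_COLUMNS = PANEL_GENE_NAMES

_TYPE_TEMPLATES: dict[str, str] = {
    #        PfaA PfaB PfaC D4 D5 D6 D8 D9A w6D9B w3 U1 U2 U3 C16 C16L C18 C20 ED9 EU1 EU2 ACLY cCrAT CrtZ CrtO
    "I":        "0 0 0 1 1 1 1 1 ? 1 0 1 1 1 1 1 1 1 1 1 1 1 0 1",
    "II":       "1 1 1 1 1 1 1 1 ? 1 0 1 1 1 1 1 1 1 1 1 1 1 0 0",
    "III":      "1 1 1 1 1 1 1 0 1 1 0 0 1 1 0 1 1 1 1 1 0 1 1 1",
    "IV":       "1 1 1 0 0 0 1 0 0 1 0 0 1 ? 0 0 0 1 1 1 0 0 1 1",
    # Relatives: pathway-level statements only
    "O":        "0 0 0 ? ? ? ? ? ? ? ? ? ? ? ? ? ? ? 1 1 ? 1 0 ?",
    "A_kerg":   "1 1 1 ? ? ? ? ? ? ? ? ? ? ? ? ? ? ? ? ? ? 1 0 ?",
    "L":        "1 1 1 ? ? ? ? ? ? ? ? ? ? 0 0 0 0 0 0 0 ? 1 0 ?",
}

# Strain-specific overrides of the lineage template, each backed by a statement.
_OVERRIDES: dict[tuple[str, str], str] = {
    # the U1 desaturase occurs solely in two Type I strains
    ("P. sp. I65-24A", "DES_U1"): "1",
    ("S. aggregatum ATCC 28209", "DES_U1"): "1",
    # CrtO was found in most strains except T. striatum (Type I); the Type II
    # template already encodes its absence from all T. aureum strains
    ("T. striatum ATCC 24473", "CrtO"): "0",
}

_RELATIVE_TEMPLATE_KEYS = {
    "O. sp. RT2316-13": "O",
    "A. kerguelense PBS07": "A_kerg",
    "L. sp. SR_Ha_C": "L",
}


def build_fixture_matrix() -> PresenceAbsenceMatrix:
    """The packaged 22-strain × 24-gene matrix transcribed from the source study."""
    strains = [StrainRecord(sid, genus, group, ev, note)
               for sid, genus, _, group, ev, note in FIXTURE_STRAIN_TABLE]
    cells: dict[tuple[str, str], Presence] = {}
    for sid, _, lineage, group, _, _ in FIXTURE_STRAIN_TABLE:
        key = lineage if group is CladeGroup.THRAUSTOCHYTRID else _RELATIVE_TEMPLATE_KEYS[sid]
        tokens = _TYPE_TEMPLATES[key].split()
        assert len(tokens) == len(_TEMPLATE_COLUMNS)
        for gene, token in zip(_TEMPLATE_COLUMNS, tokens):
            token = _OVERRIDES.get((sid, gene), token)
            cells[(sid, gene)] = Presence.from_token(token)
    return PresenceAbsenceMatrix(strains, PANEL_GENE_NAMES, cells)


# ---------------------------------------------------------------------------
# Machine-checked fixture consistency statements
# ---------------------------------------------------------------------------

def _present(m: PresenceAbsenceMatrix, sid: str, gene: str) -> bool:
    return m.cell(sid, gene) is Presence.PRESENT


def _thraus_ids(m: PresenceAbsenceMatrix) -> list[str]:
    return [s.strain_id for s in m.thraustochytrids()]


def _lineage_ids(lineage: str) -> list[str]:
    return [sid for sid, lin in FIXTURE_LINEAGES.items() if lin == lineage]


def _stmt_19_strains(m):
    ids = _thraus_ids(m)
    genera = {m.strain(sid).genus for sid in ids}
    return len(ids) == 19 and len(genera) == 6


def _stmt_pufa_s_rows(m):
    with_pufas = {sid for sid in _thraus_ids(m)
                  if all(_present(m, sid, g) for g in ("PfaA", "PfaB", "PfaC"))}
    expected = set(_lineage_ids("II") + _lineage_ids("III") + _lineage_ids("IV"))
    return with_pufas == expected and len(with_pufas) == 15


def _stmt_d9a_u2_exclusive(m):
    type12 = set(_lineage_ids("I") + _lineage_ids("II"))
    for gene in ("DES_D9A", "DES_U2"):
        carriers = {sid for sid in _thraus_ids(m) if _present(m, sid, gene)}
        if carriers != type12:
            return False
    return True


def _stmt_u1_two_strains(m):
    carriers = {sid for sid in _thraus_ids(m) if _present(m, sid, "DES_U1")}
    return carriers == {"P. sp. I65-24A", "S. aggregatum ATCC 28209"}


def _stmt_type4_desaturases(m):
    des = [g for g in PANEL_GENE_NAMES if g.startswith("DES_")]
    for sid in _lineage_ids("IV"):
        present = {g for g in des if _present(m, sid, g)}
        if present != {"DES_D8", "DES_w3", "DES_U3"}:
            return False
    return True


def _stmt_type4_no_long_elos(m):
    return all(m.cell(sid, g) is Presence.ABSENT
               for sid in _lineage_ids("IV") for g in ("ELO_C18", "ELO_C20"))


def _stmt_c16l_exclusive(m):
    carriers = {sid for sid in _thraus_ids(m) if _present(m, sid, "ELO_C16L")}
    return carriers == set(_lineage_ids("I") + _lineage_ids("II"))


def _stmt_acly_type12(m):
    carriers = {sid for sid in _thraus_ids(m) if _present(m, sid, "ACLY")}
    return carriers == set(_lineage_ids("I") + _lineage_ids("II"))


def _stmt_crtz_type34(m):
    carriers = {sid for sid in _thraus_ids(m) if _present(m, sid, "CrtZ")}
    ok_thraus = carriers == set(_lineage_ids("III") + _lineage_ids("IV"))
    ok_rel = all(m.cell(s.strain_id, "CrtZ") is Presence.ABSENT for s in m.relatives())
    return ok_thraus and ok_rel


def _stmt_crto_exceptions(m):
    non_carriers = {sid for sid in _thraus_ids(m) if not _present(m, sid, "CrtO")}
    return non_carriers == {"T. striatum ATCC 24473", "T. aureum ATCC 34304",
                            "T. aureum ssp. strugatskii"}


def _stmt_ccrat(m):
    carriers = {sid for sid in _thraus_ids(m) if _present(m, sid, "cCrAT")}
    ok_thraus = carriers == set(_lineage_ids("I") + _lineage_ids("II") + _lineage_ids("III"))
    ok_rel = all(_present(m, s.strain_id, "cCrAT") for s in m.relatives())
    return ok_thraus and ok_rel


def _stmt_elo_u1_u2(m):
    carriers_ok = all(_present(m, sid, g)
                      for sid in _thraus_ids(m) for g in ("ELO_U1", "ELO_U2"))
    o_ok = _present(m, "O. sp. RT2316-13", "ELO_U1") and _present(m, "O. sp. RT2316-13", "ELO_U2")
    return carriers_ok and o_ok


def _stmt_labyrinthula_no_elongases(m):
    elos = [g for g in PANEL_GENE_NAMES if g.startswith("ELO_")]
    return all(m.cell("L. sp. SR_Ha_C", g) is Presence.ABSENT for g in elos)


def _stmt_complete_elodes_count(m):
    # six thraustochytrid strains carry a complete ELO/DES pathway (core set)
    core = ("DES_D9A", "DES_D4", "DES_D5", "DES_w3",
            "ELO_C16", "ELO_C18", "ELO_C20", "ELO_D9")
    n = 0
    for sid in _thraus_ids(m):
        route = _present(m, sid, "DES_D6") or _present(m, sid, "DES_D8")
        if route and all(_present(m, sid, g) for g in core):
            n += 1
    return n == 6


#: Each published statement encoded as a predicate over the fixture matrix.
FIXTURE_STATEMENTS: tuple[tuple[str, object], ...] = (
    ("19 thraustochytrid strains across six genera", _stmt_19_strains),
    ("15 thraustochytrid strains carry all three PUFA-S subunits (Types II-IV)", _stmt_pufa_s_rows),
    ("Delta9A and U2 desaturases occur in exactly the Type I/II strains", _stmt_d9a_u2_exclusive),
    ("U1 desaturase occurs solely in P. sp. I65-24A and S. aggregatum", _stmt_u1_two_strains),
    ("Type IV strains carry only the Delta8, omega3 and U3 desaturases", _stmt_type4_desaturases),
    ("Type IV strains lack the C18 and C20 elongases", _stmt_type4_no_long_elos),
    ("the C16-like elongase occurs exactly in the Type I/II strains", _stmt_c16l_exclusive),
    ("ACLY homologues occur in exactly the Type I/II strains", _stmt_acly_type12),
    ("CrtZ occurs in exactly the Type III/IV strains and in no relative", _stmt_crtz_type34),
    ("CrtO is missing only from T. striatum and the T. aureum strains", _stmt_crto_exceptions),
    ("cCrAT occurs in Types I-III and every relative, not in Type IV", _stmt_ccrat),
    ("elongases U1/U2 occur in every thraustochytrid and in O. sp. RT2316-13", _stmt_elo_u1_u2),
    ("no elongase gene was detected in L. sp. SR_Ha_C", _stmt_labyrinthula_no_elongases),
    ("six thraustochytrid strains carry a complete ELO/DES pathway", _stmt_complete_elodes_count),
)


def validate_fixture(matrix: PresenceAbsenceMatrix) -> list[str]:
    """Return descriptions of violated fixture statements (empty list = consistent)."""
    return [desc for desc, pred in FIXTURE_STATEMENTS if not pred(matrix)]


# ---------------------------------------------------------------------------
# FASTA I/O for protein collections
# ---------------------------------------------------------------------------

def read_proteins_fasta(path, strain_id: str) -> list[ProteinRecord]:
    """Read a proteome FASTA into ProteinRecords attached to one strain."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, strain_id, str(rec.seq).upper(),
                                     rec.description))
    if not records:
        raise InputError(f"{path}: no FASTA records")
    return records


def write_proteins_fasta(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.protein_id}{desc}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


def attach_known_strain_metadata(matrix: PresenceAbsenceMatrix) -> PresenceAbsenceMatrix:
    """Re-attach packaged strain metadata (genus, clade group, evidence) to
    rows whose ids match fixture strains; other rows keep their records.

    Matrices read from a bare TSV carry no metadata; without this, relative
    strains would be counted among the thraustochytrid aggregates.
    """
    known = {sid: StrainRecord(sid, genus, group, ev, note)
             for sid, genus, _, group, ev, note in FIXTURE_STRAIN_TABLE}
    records = [known.get(s.strain_id, s) for s in matrix.strains]
    cells = {(sid, gene): matrix.cell(sid, gene)
             for sid in matrix.strain_ids for gene in matrix.genes}
    return PresenceAbsenceMatrix(records, matrix.genes, cells)
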