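"""Seeded generators for synthetic proteomes, annotated contigs and tree-evolved
sequences.

The generators emulate the statistical structure the pipeline assumes: family
members are random-background proteins with the family's histidine boxes (and
N-terminal domain core motif, if any) planted at spacing-legal offsets; strains
are gene-set profiles of the four published lineages plus shuffled decoys;
contigs are linear gene orders with controlled flank conservation; clade
structure comes from mutation accumulation along a known tree.  Background
residues are uniform over the 20 amino acids — the simplest null under which
spurious box hits are analytically quantifiable.  All randomness flows from a
single seed through labelled substreams, so every stage is independently
reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .core_model import (
    AMINO_ACIDS,
    ConfigError,
    GenePanel,
    InputError,
    Presence,
    ProteinRecord,
    build_fixture_matrix,
    load_panel,
)
from .motif_scan import BoxPattern, SignatureRegistry, load_registry
from .family_assign import ReferenceLibrary
from .synteny import GeneFeature

#: Seed of the packaged synthetic archetype library (independent of run seeds).
DEFAULT_LIBRARY_SEED = 1009

_AA = np.array(list(AMINO_ACIDS))


def derive_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-stage substream keyed by a label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())]))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    mutation_rate: float = 0.0
    box_preservation_prob: float = 0.9
    decoys_per_strain: int = 5
    contig_gene_count: int = 9
    desaturase_length_range: tuple[int, int] = (360, 440)
    elongase_length_range: tuple[int, int] = (260, 320)
    pufa_s_length_range: tuple[int, int] = (480, 560)
    accessory_length_range: tuple[int, int] = (380, 460)
    flank_protein_length: int = 200
    box_gap_range: tuple[int, int] = (20, 60)
    u3_extension: int = 500

    def __post_init__(self):
        for name in ("mutation_rate", "box_preservation_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {value}")
        if self.decoys_per_strain < 0 or self.contig_gene_count < 1:
            raise ConfigError("decoys_per_strain/contig_gene_count out of range")


# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------

def _random_residues(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[rng.integers(0, len(_AA), size=length)])


def _instantiate_box(pattern: BoxPattern, rng: np.random.Generator) -> str:
    residues = []
    for allowed in pattern.positions:
        if allowed is None:
            residues.append(str(_AA[rng.integers(0, len(_AA))]))
        else:
            choices = sorted(allowed)
            residues.append(choices[int(rng.integers(0, len(choices)))])
    return "".join(residues)


def mutate(sequence: str, rate: float, config: SimConfig | None = None,
           rng: np.random.Generator | None = None,
           protected_ranges=()) -> str:
    """Per-site point substitution with probability ``rate``.

    A substitution always changes the residue (drawn uniformly from the 19
    others), so the expected changed fraction equals ``rate`` outside
    protected ranges.  Sites inside ``protected_ranges`` (half-open intervals,
    e.g. planted boxes) are spared with probability ``box_preservation_prob``.
    """
    if not 0.0 <= rate <= 1.0:
        raise InputError(f"mutation rate must lie in [0, 1], got {rate}")
    config = config or SimConfig()
    if rng is None:
        rng = derive_rng(config.seed, "mutate")
    protected = np.zeros(len(sequence), dtype=bool)
    for start, end in protected_ranges:
        protected[start:end] = True
    out = list(sequence)
    hit = rng.random(len(sequence)) < rate
    spare = rng.random(len(sequence)) < config.box_preservation_prob
    for i in np.nonzero(hit)[0]:
        if protected[i] and spare[i]:
            continue
        current = out[i]
        alternatives = [aa for aa in AMINO_ACIDS if aa != current]
        out[i] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Family members
# ---------------------------------------------------------------------------

def _length_range(config: SimConfig, family: str, panel: GenePanel) -> tuple[int, int]:
    category = panel[family].category.value
    return {
        "desaturase": config.desaturase_length_range,
        "elongase": config.elongase_length_range,
        "pufa_synthase": config.pufa_s_length_range,
        "accessory": config.accessory_length_range,
    }[category]


def synth_family_protein_detailed(
        family: str, registry: SignatureRegistry, config: SimConfig,
        rng: np.random.Generator, panel: GenePanel | None = None,
        protein_id: str | None = None, strain_id: str = "synthetic",
) -> tuple[ProteinRecord, tuple[tuple[int, int], ...]]:
    """Family member plus the half-open ranges of its planted motifs."""
    panel = panel or load_panel()
    if family not in panel:
        raise ConfigError(f"unknown panel family {family!r}")
    protein_id = protein_id or f"{strain_id}|{family}"
    sig_id = panel[family].signature_id
    lo, hi = _length_range(config, family, panel)

    if sig_id is None:  # PUFA-S subunits and accessory genes: homology only
        seq = _random_residues(rng, int(rng.integers(lo, hi + 1)))
        return ProteinRecord(protein_id, strain_id, seq, f"synthetic {family}"), ()

    signature = registry[sig_id]
    parts: list[str] = []
    ranges: list[tuple[int, int]] = []
    pos = 0

    def emit(segment: str, planted: bool = False):
        nonlocal pos
        if planted:
            ranges.append((pos, pos + len(segment)))
        parts.append(segment)
        pos += len(segment)

    glo, ghi = config.box_gap_range
    if signature.nterm_domain == "cytb5":
        prefix = int(rng.integers(20, 61))
        if family == "DES_U3":  # long N-terminal extension ahead of the domain
            prefix += config.u3_extension
        emit(_random_residues(rng, prefix))
        emit("HPGG", planted=True)
    else:
        emit(_random_residues(rng, int(rng.integers(20, 61))))

    for box in signature.boxes:
        emit(_random_residues(rng, int(rng.integers(glo, ghi + 1))))
        emit(_instantiate_box(box, rng), planted=True)
    tail_target = max(0, int(rng.integers(lo, hi + 1)) - pos)
    emit(_random_residues(rng, max(tail_target, 40)))
    seq = "".join(parts)
    return ProteinRecord(protein_id, strain_id, seq, f"synthetic {family}"), tuple(ranges)


def synth_family_protein(family: str, registry: SignatureRegistry,
                         config: SimConfig | None = None,
                         rng: np.random.Generator | None = None,
                         panel: GenePanel | None = None,
                         protein_id: str | None = None,
                         strain_id: str = "synthetic") -> ProteinRecord:
    """Random-background protein with the family's motifs planted (seeded)."""
    config = config or SimConfig()
    if rng is None:
        rng = derive_rng(config.seed, f"family:{family}")
    record, _ = synth_family_protein_detailed(
        family, registry, config, rng, panel, protein_id, strain_id)
    return record


# ---------------------------------------------------------------------------
# Archetype library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticArchetypes:
    """Packaged synthetic reference library with the planted motif ranges."""
    library: ReferenceLibrary
    records: dict[str, ProteinRecord] = field(compare=False)
    planted_ranges: dict[str, tuple[tuple[int, int], ...]] = field(compare=False)


def default_reference_library(panel: GenePanel | None = None,
                              registry: SignatureRegistry | None = None,
                              seed: int = DEFAULT_LIBRARY_SEED) -> SyntheticArchetypes:
    """One seeded archetype per panel family.

    The C16-like elongase archetype is derived from the C16 archetype
    (30% substitution outside the fully protected box) so the pair shows the
    published high mutual identity with an identical histidine box, making the
    C16/C16L split a genuine best-hit discrimination problem.
    """
    panel = panel or load_panel()
    registry = registry or load_registry()
    config = SimConfig(seed=seed)
    records: dict[str, ProteinRecord] = {}
    ranges: dict[str, tuple[tuple[int, int], ...]] = {}
    for gene in panel.genes:
        family = gene.name
        if family == "ELO_C16L":
            continue
        rng = derive_rng(seed, f"archetype:{family}")
        rec, planted = synth_family_protein_detailed(
            family, registry, config, rng, panel,
            protein_id=f"{family}|ref", strain_id="reference")
        records[family] = rec
        ranges[family] = planted
    rng = derive_rng(seed, "archetype:ELO_C16L")
    c16 = records["ELO_C16"]
    c16l_seq = mutate(c16.sequence, 0.30,
                      replace(config, box_preservation_prob=1.0), rng,
                      protected_ranges=ranges["ELO_C16"])
    records["ELO_C16L"] = ProteinRecord("ELO_C16L|ref", "reference", c16l_seq,
                                        "synthetic ELO_C16L (derived from ELO_C16)")
    ranges["ELO_C16L"] = ranges["ELO_C16"]
    library = ReferenceLibrary({fam: (rec,) for fam, rec in records.items()})
    return SyntheticArchetypes(library, records, ranges)


# ---------------------------------------------------------------------------
# Lineage profiles and whole strains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TypeProfile:
    lineage: str
    genes: frozenset[str]

    def __post_init__(self):
        if self.lineage in ("I", "II") and "DES_D9A" not in self.genes:
            raise ConfigError(f"Type {self.lineage} profile must contain DES_D9A")
        if self.lineage in ("III", "IV") and "DES_D9A" in self.genes:
            raise ConfigError(f"Type {self.lineage} profile must lack DES_D9A")
        if self.lineage == "IV" and self.genes & {"ELO_C18", "ELO_C20"}:
            raise ConfigError("Type IV profile must lack the C18/C20 elongases")


def _profile_from_fixture(strain_id: str, lineage: str) -> TypeProfile:
    matrix = build_fixture_matrix()
    row = matrix.row(strain_id)
    genes = frozenset(g for g, v in row.items() if v is Presence.PRESENT)
    return TypeProfile(lineage, genes)


#: Canonical per-lineage gene sets, read off representative fixture strains.
TYPE_PROFILES: dict[str, TypeProfile] = {
    "I": _profile_from_fixture("P. sp. I65-24A", "I"),
    "II": _profile_from_fixture("T. aureum ATCC 34304", "II"),
    "III": _profile_from_fixture("H. fermentalgiana FCC1311", "III"),
    "IV": _profile_from_fixture("A. limacinum SR21", "IV"),
}


@dataclass(frozen=True)
class StrainSim:
    strain_id: str
    proteome: tuple[ProteinRecord, ...]
    truth: dict[str, str] = field(compare=False)  # protein_id -> family


def synth_strain(profile: TypeProfile, config: SimConfig,
                 archetypes: SyntheticArchetypes | None = None,
                 panel: GenePanel | None = None,
                 registry: SignatureRegistry | None = None,
                 strain_id: str | None = None,
                 rng: np.random.Generator | None = None) -> StrainSim:
    """One protein per present panel gene (mutated copy of the family
    archetype, planted boxes protected) plus shuffled decoys."""
    panel = panel or load_panel()
    registry = registry or load_registry()
    archetypes = archetypes or default_reference_library(panel, registry)
    strain_id = strain_id or f"sim_type_{profile.lineage}"
    if rng is None:
        rng = derive_rng(config.seed, f"strain:{strain_id}")
    proteome: list[ProteinRecord] = []
    truth: dict[str, str] = {}
    for family in [g for g in panel.names if g in profile.genes]:
        archetype = archetypes.records[family]
        seq = mutate(archetype.sequence, config.mutation_rate, config, rng,
                     protected_ranges=archetypes.planted_ranges[family])
        pid = f"{strain_id}|{family}"
        proteome.append(ProteinRecord(pid, strain_id, seq, f"synthetic {family} member"))
        truth[pid] = family
    members = list(proteome)
    for i in range(config.decoys_per_strain):
        template = members[int(rng.integers(0, len(members)))]
        shuffled = "".join(np.array(list(template.sequence))[
            rng.permutation(len(template.sequence))])
        pid = f"{strain_id}|decoy{i + 1}"
        proteome.append(ProteinRecord(pid, strain_id, shuffled,
                                      "shuffled decoy (composition-preserving)"))
    return StrainSim(strain_id, tuple(proteome), truth)


# ---------------------------------------------------------------------------
# Annotated contigs for synteny tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeighborhoodSpec:
    """Which flank slots (u1..u4 upstream, d1..d4 downstream, nearest first)
    are conserved across the non-reference strains."""
    n_strains: int = 2
    target_family: str = "DES_D9A"
    conserved: tuple[str, ...] = ("u1", "d1", "d2")
    window: int = 4
    strand_flips: tuple[str, ...] = ()

    def __post_init__(self):
        legal = {f"u{i}" for i in range(1, self.window + 1)} | \
                {f"d{i}" for i in range(1, self.window + 1)}
        bad = set(self.conserved) - legal
        if bad:
            raise ConfigError(f"unknown flank slot(s): {sorted(bad)}")
        if self.n_strains < 2:
            raise ConfigError("need at least 2 strains for synteny")


def synth_neighborhoods(spec: NeighborhoodSpec, config: SimConfig,
                        registry: SignatureRegistry | None = None,
                        panel: GenePanel | None = None,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[dict[str, list[GeneFeature]],
                                   dict[str, dict[str, ProteinRecord]]]:
    """Linear contigs with the target locus and controlled flank conservation.

    Returns (annotations_by_strain, proteomes).  Slot proteins in conserved
    positions are mutated copies of the reference strain's protein; all other
    flanks are fresh random proteins.
    """
    panel = panel or load_panel()
    registry = registry or load_registry()
    if rng is None:
        rng = derive_rng(config.seed, "neighborhoods")
    w = spec.window
    slots = [f"u{i}" for i in range(w, 0, -1)] + ["target"] + \
            [f"d{i}" for i in range(1, w + 1)]

    ref_proteins: dict[str, ProteinRecord] = {}
    annotations: dict[str, list[GeneFeature]] = {}
    proteomes: dict[str, dict[str, ProteinRecord]] = {}
    for s in range(spec.n_strains):
        strain = f"sim{s}"
        features: list[GeneFeature] = []
        proteome: dict[str, ProteinRecord] = {}
        for i, slot in enumerate(slots):
            pid = f"{strain}_g{i}"
            if slot == "target":
                rec = synth_family_protein(spec.target_family, registry, config,
                                           rng, panel, protein_id=pid, strain_id=strain)
                family = spec.target_family
            else:
                family = None
                if s == 0:
                    rec = ProteinRecord(pid, strain,
                                        _random_residues(rng, config.flank_protein_length))
                    ref_proteins[slot] = rec
                elif slot in spec.conserved:
                    seq = mutate(ref_proteins[slot].sequence, config.mutation_rate,
                                 config, rng)
                    rec = ProteinRecord(pid, strain, seq)
                else:
                    rec = ProteinRecord(pid, strain,
                                        _random_residues(rng, config.flank_protein_length))
            strand = "+"
            if s > 0 and slot in spec.strand_flips:
                strand = "-"
            start = i * 2000
            features.append(GeneFeature(pid, f"{strain}_contig1", start,
                                        start + 3 * len(rec.sequence), strand,
                                        product=pid, family=family))
            proteome[pid] = rec
        annotations[strain] = features
        proteomes[strain] = proteome
    return annotations, proteomes


def synth_pfa_contigs(adjacent_flags, config: SimConfig,
                      rng: np.random.Generator | None = None,
                      ) -> dict[str, list[GeneFeature]]:
    """Contigs carrying PfaA and PfaB, adjacent or separated by an inserted
    gene, for adjacency testing (one strain per flag)."""
    if rng is None:
        rng = derive_rng(config.seed, "pfa_contigs")
    annotations: dict[str, list[GeneFeature]] = {}
    for s, adjacent in enumerate(adjacent_flags):
        strain = f"pfa_sim{s}"
        order = ["filler0", "PfaA"]
        if not adjacent:
            order.append("spacer")
        order += ["PfaB", "filler1"]
        features = []
        for i, name in enumerate(order):
            start = i * 2000
            family = name if name in ("PfaA", "PfaB") else None
            features.append(GeneFeature(f"{strain}_g{i}", f"{strain}_contig1",
                                        start, start + 900, "+",
                                        product=None, family=family))
        annotations[strain] = features
    return annotations


# ---------------------------------------------------------------------------
# Sequence evolution along a tree
# ---------------------------------------------------------------------------

def evolve_along_tree(tree, root_sequence: str, rate_per_branch: float,
                      config: SimConfig | None = None,
                      rng: np.random.Generator | None = None) -> dict[str, str]:
    """Evolve ``root_sequence`` down a tree (newick string or dendropy Tree).

    Per branch, each site substitutes independently with probability
    ``min(1, rate_per_branch * branch_length)``; seeded and deterministic.
    Returns tip-label -> sequence.
    """
    if rate_per_branch < 0:
        raise InputError("rate_per_branch must be >= 0")
    config = config or SimConfig()
    if rng is None:
        rng = derive_rng(config.seed, "evolve")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    sequences: dict[str, str] = {}
    node_seq = {tree.seed_node: root_sequence}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            current = root_sequence
        else:
            length = node.edge.length or 0.0
            rate = min(1.0, rate_per_branch * length)
            current = mutate(node_seq[node.parent_node], rate, config, rng)
        node_seq[node] = current
        if node.is_leaf():
            label = node.taxon.label if node.taxon else str(id(node))
            sequences[label] = current
    return sequences


# ---------------------------------------------------------------------------
# End-to-end study helper
# ---------------------------------------------------------------------------

def simulate_and_type(seed: int, mutation_rate: float = 0.05,
                      archetypes: SyntheticArchetypes | None = None,
                      panel: GenePanel | None = None,
                      registry: SignatureRegistry | None = None,
                      decoys_per_strain: int = 5) -> dict[str, str]:
    """Generate one strain per lineage profile, run scan→assign→matrix→type,
    and return true lineage -> called lineage."""
    from .core_model import CladeGroup, EvidenceSource, StrainRecord
    from .family_assign import assign_proteome, presence_matrix
    from .pathway_typing import summarize

    panel = panel or load_panel()
    registry = registry or load_registry()
    archetypes = archetypes or default_reference_library(panel, registry)
    config = SimConfig(seed=seed, mutation_rate=mutation_rate,
                       decoys_per_strain=decoys_per_strain)
    strains = []
    per_strain = {}
    truth_lineage = {}
    for lineage, profile in TYPE_PROFILES.items():
        sim = synth_strain(profile, config, archetypes, panel, registry)
        strains.append(StrainRecord(sim.strain_id, "simulated",
                                    CladeGroup.THRAUSTOCHYTRID, EvidenceSource.GENOME))
        per_strain[sim.strain_id] = assign_proteome(
            sim.proteome, panel, archetypes.library, registry)
        truth_lineage[sim.strain_id] = lineage
    matrix = presence_matrix(per_strain, panel, strains)
    report = summarize(matrix, panel)
    return {truth_lineage[c.strain_id]: c.lineage for c in report.calls}
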