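"""End-to-end orchestration: scan → assign → matrix → type → synteny → phylo → report.

Every output file begins with a header comment carrying the tool version, a
hash of the serialized run configuration and the seed, so a run is fully
reproducible from its output directory alone.  All randomness flows from the
single top-level seed through stage-labelled substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .core_model import (
    CladeGroup,
    attach_known_strain_metadata,
    EvidenceSource,
    InputError,
    PresenceAbsenceMatrix,
    StrainRecord,
    load_panel,
    read_matrix_tsv,
    read_proteins_fasta,
)
from .family_assign import (
    DEFAULT_MIN_NORM_SCORE,
    ReferenceLibrary,
    assign_proteome,
    presence_matrix,
)
from .motif_scan import load_registry
from .pathway_typing import summarize, typing_table_rows
from .phylo import bootstrap_support, progressive_align
from .synteny import read_gff_lite, synteny_conservation
from .synthetic_data import default_reference_library, derive_rng

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    proteomes: dict[str, str] = dataclasses.field(default_factory=dict)  # strain -> FASTA path
    annotations: dict[str, str] = dataclasses.field(default_factory=dict)  # strain -> GFF path
    matrix_path: str | None = None          # typing-only mode
    reference_fasta: str | None = None      # archetypes; default synthetic library
    min_norm_score: float = DEFAULT_MIN_NORM_SCORE
    bootstrap_reps: int = 100
    synteny_target: str | None = None
    phylo_family: str | None = None
    strict: bool = False
    seed: int = 0
    out_dir: str = "pufatyper_out"
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0.0 <= self.min_norm_score <= 1.0:
            raise InputError("min_norm_score must lie in [0, 1]")
        if self.bootstrap_reps < 1:
            raise InputError("bootstrap_reps must be >= 1")


def _config_hash(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    # only analysis parameters; where results land and how much is logged
    # must not change the recorded run identity
    payload.pop("out_dir", None)
    payload.pop("log_level", None)
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return (f"# pufatyper {__version__} | config_hash={_config_hash(config)} "
            f"| seed={config.seed}\n")


def _write_tsv(path: Path, config: RunConfig, columns: list[str],
               rows: list[dict[str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(row[c] for c in columns) + "\n")


def _load_reference(config: RunConfig) -> ReferenceLibrary:
    if config.reference_fasta is None:
        return default_reference_library().library
    from .core_model import read_proteins_fasta as read_fasta

    records = read_fasta(config.reference_fasta, "reference")
    entries: dict[str, list] = {}
    for rec in records:
        # archetype family = text before the first '|' separator, else full id
        family = rec.protein_id.split("|")[0]
        entries.setdefault(family, []).append(rec)
    return ReferenceLibrary({fam: tuple(v) for fam, v in entries.items()})


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages feasible under the configuration; returns a summary dict.

    Stage failures after a successful parse skip the downstream stages that
    need them and are recorded in the summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = load_panel()
    registry = load_registry()
    summary: dict = {"version": __version__, "seed": config.seed,
                     "config_hash": _config_hash(config), "stages": {}}

    with open(out / "run_config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)

    matrix: PresenceAbsenceMatrix | None = None
    if config.matrix_path:
        matrix = attach_known_strain_metadata(read_matrix_tsv(config.matrix_path))
        summary["stages"]["matrix"] = f"loaded from {config.matrix_path}"
    elif config.proteomes:
        library = _load_reference(config)
        strains = [StrainRecord(sid, "unknown", CladeGroup.THRAUSTOCHYTRID,
                                EvidenceSource.GENOME)
                   for sid in sorted(config.proteomes)]
        per_strain = {}
        assign_rows = []
        for strain in strains:
            proteins = read_proteins_fasta(config.proteomes[strain.strain_id],
                                           strain.strain_id)
            assignments = assign_proteome(proteins, panel, library, registry,
                                          config.min_norm_score)
            per_strain[strain.strain_id] = assignments
            for a in assignments:
                assign_rows.append({
                    "strain_id": strain.strain_id,
                    "protein_id": a.protein_id,
                    "family": a.family,
                    "evidence": ",".join(sorted(a.evidence)) or "-",
                    "normalized_score": (f"{a.normalized_score:.4f}"
                                         if a.normalized_score is not None else "-"),
                })
        _write_tsv(out / "assignments.tsv", config,
                   ["strain_id", "protein_id", "family", "evidence", "normalized_score"],
                   assign_rows)
        matrix = presence_matrix(per_strain, panel, strains)
        summary["stages"]["assign"] = f"{len(assign_rows)} proteins"

    if matrix is not None:
        matrix_path = out / "matrix.tsv"
        with open(matrix_path, "w") as fh:
            fh.write(_header(config))
        with open(matrix_path, "a") as fh:
            fh.write("strain_id\t" + "\t".join(matrix.genes) + "\n")
            for sid in matrix.strain_ids:
                row = matrix.row(sid)
                fh.write(sid + "\t" + "\t".join(row[g].token for g in matrix.genes) + "\n")
        report = summarize(matrix, panel, strict=config.strict)
        rows = typing_table_rows(report)
        _write_tsv(out / "typing.tsv", config, list(rows[0].keys()), rows)
        summary["stages"]["typing"] = {
            "lineage_counts": report.lineage_counts,
            "distinct_lineages": report.distinct_lineages,
            "pufas_complete": report.pufas_complete_count,
            "elodes_complete": report.elodes_complete_count,
        }
    else:
        summary["stages"]["typing"] = "skipped (no matrix or proteomes)"

    if config.synteny_target and config.annotations:
        annotations = {sid: read_gff_lite(path)
                       for sid, path in sorted(config.annotations.items())}
        proteomes = {}
        for sid in annotations:
            if sid not in config.proteomes:
                raise InputError(f"synteny: no proteome FASTA for strain {sid!r}")
            proteomes[sid] = {r.protein_id: r
                              for r in read_proteins_fasta(config.proteomes[sid], sid)}
        results, adjacency, skipped = synteny_conservation(
            config.synteny_target, annotations, proteomes,
            min_norm_score=config.min_norm_score)
        rows = [{
            "reference": r.reference_strain, "other": r.other_strain,
            "conserved_upstream": str(r.conserved_upstream),
            "conserved_downstream": str(r.conserved_downstream),
            "pairs": ";".join(f"{p.ref_gene}~{p.other_gene}({p.side},{p.normalized_score:.2f})"
                              for p in r.pairs) or "-",
        } for r in results]
        _write_tsv(out / "synteny.tsv", config,
                   ["reference", "other", "conserved_upstream", "conserved_downstream", "pairs"],
                   rows)
        summary["stages"]["synteny"] = {
            "pairs": len(results), "skipped_strains": skipped,
            "pfa_adjacency": {k: v for k, v in adjacency.items() if v is not None},
        }

    if config.phylo_family and config.proteomes:
        members = []
        for sid in sorted(config.proteomes):
            for rec in read_proteins_fasta(config.proteomes[sid], sid):
                if rec.protein_id.endswith(config.phylo_family):
                    members.append(rec)
        if len(members) >= 2:
            msa = progressive_align(members)
            rng = derive_rng(config.seed, "bootstrap")
            tree = bootstrap_support(msa, n_reps=config.bootstrap_reps, rng=rng)
            with open(out / f"{config.phylo_family}.nwk", "w") as fh:
                fh.write(_header(config))
                fh.write(tree.newick(include_support=True) + "\n")
            summary["stages"]["phylo"] = {
                "family": config.phylo_family, "n_tips": len(members),
                "bootstrap_reps": config.bootstrap_reps,
            }
        else:
            summary["stages"]["phylo"] = f"skipped (<2 members of {config.phylo_family})"

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "summary.txt", "w") as fh:
        fh.write(_header(config))
        fh.write(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
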