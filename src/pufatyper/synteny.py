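"""Gene-neighborhood (microsynteny) conservation around a target locus.

For each strain the four genes up- and downstream of a target gene are
extracted from a GFF-lite annotation; flank genes are paired across strains by
reciprocal-best local alignment and a conserved-flank count is reported per
side.  Conservation is membership-based: a flank gene counts as conserved when
its reciprocal-best partner lies anywhere within the corresponding window of
the other strain; order and strand agreement are reported as flags, not
enforced.  Matching is restricted to corresponding windows (upstream with
upstream, downstream with downstream) so that conserved counts are symmetric
under swapping reference and other strain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_model import InputError, ParseError, ProteinRecord
from .family_assign import DEFAULT_MIN_NORM_SCORE, local_align, self_score

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 4


@dataclass(frozen=True)
class GeneFeature:
    """A gene on a contig; 0-based half-open coordinates."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str | None = None   # protein_id in the matching proteome
    family: str | None = None    # panel family, when annotated upstream

    def __post_init__(self):
        if self.start >= self.end:
            raise InputError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise InputError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class Neighborhood:
    strain_id: str
    target: GeneFeature
    upstream: tuple[GeneFeature, ...]    # nearest first
    downstream: tuple[GeneFeature, ...]  # nearest first


@dataclass(frozen=True)
class SyntenyPair:
    ref_gene: str
    other_gene: str
    side: str  # "upstream" | "downstream"
    normalized_score: float
    same_strand: bool


@dataclass(frozen=True)
class SyntenyResult:
    reference_strain: str
    other_strain: str
    conserved_upstream: int
    conserved_downstream: int
    pairs: tuple[SyntenyPair, ...]


# ---------------------------------------------------------------------------
# GFF-lite I/O
# ---------------------------------------------------------------------------
# Tab-separated, 9 columns: contig, source, type(=gene), start, end, score,
# strand, frame, attributes.  Coordinates on disk are 1-based inclusive (GFF
# convention) and converted to 0-based half-open on read.  Attributes are
# ;-separated key=value pairs with at least gene_id.

def read_gff_lite(path) -> list[GeneFeature]:
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"line {lineno}: expected 9 tab-separated columns")
            contig, _source, ftype, start, end, _score, strand, _frame, attrs = parts
            if ftype != "gene":
                continue
            fields = {}
            for item in attrs.split(";"):
                item = item.strip()
                if item:
                    key, _, value = item.partition("=")
                    fields[key] = value
            if "gene_id" not in fields:
                raise ParseError(f"line {lineno}: attributes lack gene_id")
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric coordinates") from None
            features.append(GeneFeature(
                gene_id=fields["gene_id"], contig_id=contig,
                start=start_i, end=end_i, strand=strand,
                product=fields.get("protein_id"), family=fields.get("family")))
    return features


def write_gff_lite(features: Iterable[GeneFeature], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            attrs = [f"gene_id={f.gene_id}"]
            if f.product:
                attrs.append(f"protein_id={f.product}")
            if f.family:
                attrs.append(f"family={f.family}")
            fh.write("\t".join([
                f.contig_id, "pufatyper", "gene", str(f.start + 1), str(f.end),
                ".", f.strand, ".", ";".join(attrs)]) + "\n")


# ---------------------------------------------------------------------------
# Neighborhood extraction
# ---------------------------------------------------------------------------

def extract_neighborhood(features: Sequence[GeneFeature], target_gene_id: str,
                         window: int = DEFAULT_WINDOW,
                         strain_id: str = "") -> Neighborhood:
    """Up to ``window`` genes on each side of the target, on its contig, in
    contig coordinate order (upstream = smaller coordinates, nearest first)."""
    target = next((f for f in features if f.gene_id == target_gene_id), None)
    if target is None:
        raise InputError(f"target gene {target_gene_id!r} not found")
    contig = sorted((f for f in features if f.contig_id == target.contig_id),
                    key=lambda f: (f.start, f.end))
    seen = [f.gene_id for f in contig]
    if len(set(seen)) != len(seen):
        raise InputError(f"duplicate gene ids on contig {target.contig_id}")
    idx = next(i for i, f in enumerate(contig) if f.gene_id == target_gene_id)
    upstream = tuple(reversed(contig[max(0, idx - window):idx]))
    downstream = tuple(contig[idx + 1:idx + 1 + window])
    return Neighborhood(strain_id, target, upstream, downstream)


# ---------------------------------------------------------------------------
# Homolog mapping
# ---------------------------------------------------------------------------

def _flank_protein(feature: GeneFeature,
                   proteome: Mapping[str, ProteinRecord]) -> str | None:
    if feature.product is None or feature.product not in proteome:
        logger.warning("no protein for flank gene %s; gene unmappable", feature.gene_id)
        return None
    return proteome[feature.product].sequence


def _reciprocal_best_pairs(genes_a: Sequence[GeneFeature], genes_b: Sequence[GeneFeature],
                           prot_a: Mapping[str, ProteinRecord],
                           prot_b: Mapping[str, ProteinRecord],
                           min_norm_score: float,
                           side: str) -> list[SyntenyPair]:
    seqs_a = {f.gene_id: _flank_protein(f, prot_a) for f in genes_a}
    seqs_b = {f.gene_id: _flank_protein(f, prot_b) for f in genes_b}
    strands_a = {f.gene_id: f.strand for f in genes_a}
    strands_b = {f.gene_id: f.strand for f in genes_b}
    norm: dict[tuple[str, str], float] = {}
    for ga, sa in seqs_a.items():
        for gb, sb in seqs_b.items():
            if sa is None or sb is None:
                continue
            score = local_align(sa, sb).score
            denom = max(self_score(sa), self_score(sb))
            norm[(ga, gb)] = score / denom if denom > 0 else 0.0

    def best_partner(g, candidates, getter):
        scored = [(getter(g, c), c) for c in candidates if getter(g, c) is not None]
        scored = [(s, c) for s, c in scored if s >= min_norm_score]
        if not scored:
            return None
        scored.sort(key=lambda t: (-t[0], t[1]))
        return scored[0][1]

    pairs: list[SyntenyPair] = []
    for ga in seqs_a:
        gb = best_partner(ga, list(seqs_b), lambda a, b: norm.get((a, b)))
        if gb is None:
            continue
        back = best_partner(gb, list(seqs_a), lambda b, a: norm.get((a, b)))
        if back == ga:
            pairs.append(SyntenyPair(ga, gb, side, norm[(ga, gb)],
                                     strands_a[ga] == strands_b[gb]))
    return pairs


def map_homologs(nbr_a: Neighborhood, nbr_b: Neighborhood,
                 proteomes: Mapping[str, Mapping[str, ProteinRecord]],
                 min_norm_score: float = DEFAULT_MIN_NORM_SCORE) -> SyntenyResult:
    """Reciprocal-best pairing of flank genes between two neighborhoods.

    Each flank gene pairs at most once; scores are normalised by the larger of
    the two self-scores (symmetric in the pair).
    """
    prot_a = proteomes[nbr_a.strain_id]
    prot_b = proteomes[nbr_b.strain_id]
    up = _reciprocal_best_pairs(nbr_a.upstream, nbr_b.upstream, prot_a, prot_b,
                                min_norm_score, "upstream")
    down = _reciprocal_best_pairs(nbr_a.downstream, nbr_b.downstream, prot_a, prot_b,
                                  min_norm_score, "downstream")
    return SyntenyResult(nbr_a.strain_id, nbr_b.strain_id,
                         len(up), len(down), tuple(up + down))


# ---------------------------------------------------------------------------
# Cross-strain conservation
# ---------------------------------------------------------------------------

def _find_family_gene(features: Sequence[GeneFeature], family: str) -> GeneFeature | None:
    hits = [f for f in features if f.family == family]
    return hits[0] if hits else None


def pfa_locus_adjacent(features: Sequence[GeneFeature]) -> bool | None:
    """True iff PfaA and PfaB are consecutive gene features on the same contig
    (any strand combination); None when either gene is missing."""
    a = _find_family_gene(features, "PfaA")
    b = _find_family_gene(features, "PfaB")
    if a is None or b is None:
        return None
    if a.contig_id != b.contig_id:
        return False
    contig = sorted((f for f in features if f.contig_id == a.contig_id),
                    key=lambda f: (f.start, f.end))
    ia = contig.index(a)
    ib = contig.index(b)
    return abs(ia - ib) == 1


def synteny_conservation(target_family: str,
                         annotations_by_strain: Mapping[str, Sequence[GeneFeature]],
                         proteomes: Mapping[str, Mapping[str, ProteinRecord]],
                         reference_strain: str | None = None,
                         window: int = DEFAULT_WINDOW,
                         min_norm_score: float = DEFAULT_MIN_NORM_SCORE,
                         ) -> tuple[list[SyntenyResult], dict[str, bool | None], list[str]]:
    """Pairwise flank conservation of the target-family locus against a
    reference strain, plus the PfaA-PfaB adjacency flag per strain.

    Returns (results, adjacency_by_strain, skipped_strains); strains lacking
    the target family are skipped with a log note.
    """
    strains = list(annotations_by_strain)
    if reference_strain is None:
        reference_strain = strains[0]
    if reference_strain not in annotations_by_strain:
        raise InputError(f"unknown reference strain {reference_strain!r}")

    neighborhoods: dict[str, Neighborhood] = {}
    skipped: list[str] = []
    for strain in strains:
        features = annotations_by_strain[strain]
        target = _find_family_gene(features, target_family)
        if target is None:
            logger.info("strain %s lacks target family %s; skipped", strain, target_family)
            skipped.append(strain)
            continue
        neighborhoods[strain] = extract_neighborhood(
            features, target.gene_id, window, strain_id=strain)

    if reference_strain not in neighborhoods:
        raise InputError(
            f"reference strain {reference_strain!r} lacks target family {target_family!r}")

    results = [
        map_homologs(neighborhoods[reference_strain], neighborhoods[strain],
                     proteomes, min_norm_score)
        for strain in strains
        if strain != reference_strain and strain in neighborhoods
    ]
    adjacency = {strain: pfa_locus_adjacent(annotations_by_strain[strain])
                 for strain in strains}
    return results, adjacency, skipped
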