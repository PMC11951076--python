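"""Local alignment, best-hit assignment and matrix construction."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

import pufatyper as pt
from pufatyper.core_model import CladeGroup, EvidenceSource, Presence, StrainRecord
from pufatyper.family_assign import self_score
from pufatyper.motif_scan import UNCLASSIFIED
from pufatyper.synthetic_data import SimConfig, TYPE_PROFILES, derive_rng, mutate, synth_strain

B62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Independent quadratic DP oracle for the local affine-gap score
    (gap of length L costs gap_open + gap_extend * L)."""
    n, m = len(a), len(b)
    neg = -1e9
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), neg)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i, j] = max(M[i - 1, j] - gap_open - gap_extend, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open - gap_extend, Y[i, j - 1] - gap_extend)
            sub = B62[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, M[i - 1, j - 1] + sub, X[i, j], Y[i, j])
            best = max(best, M[i, j])
    return best


def _random_seq(rng, length):
    return "".join(np.array(list(pt.AMINO_ACIDS))[rng.integers(0, 20, size=length)])


class TestLocalAlign:
    def test_identity(self):
        seq = _random_seq(np.random.default_rng(1), 100)
        res = pt.local_align(seq, seq)
        assert res.identity_fraction == 1.0
        assert res.score == self_score(seq)
        assert res.query_span == (0, 100)

    def test_textbook_pair_matches_dp_oracle(self):
        assert pt.local_align("HEAGAWGHEE", "PAWHEAE").score == \
               gotoh_local_score("HEAGAWGHEE", "PAWHEAE")

    @pytest.mark.parametrize("seed", range(8))
    def test_random_pairs_match_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_seq(rng, 50)
        b = a[::-1] if seed % 2 else _random_seq(rng, 40)
        assert pt.local_align(a, b).score == gotoh_local_score(a, b)

    def test_score_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a, b = _random_seq(rng, 60), _random_seq(rng, 60)
            assert pt.local_align(a, b).score == pt.local_align(b, a).score

    def test_empty_sequence_rejected(self):
        with pytest.raises(pt.InputError):
            pt.local_align("", "MKV")


class TestBestHit:
    def test_archetype_hits_itself(self, archetypes):
        rec = archetypes.records["DES_D5"]
        result = pt.best_hit_assign(rec, archetypes.library)
        assert result.family == "DES_D5"
        assert result.normalized_score == 1.0

    def test_normalized_score_in_unit_interval(self, archetypes):
        rng = derive_rng(3, "besthit")
        query = pt.ProteinRecord("q", "s", _random_seq(rng, 300))
        for family in ("DES_D4", "ELO_C16", "PfaA"):
            rec = archetypes.records[family]
            res = pt.local_align(query.sequence, rec.sequence)
            norm = res.score / self_score(rec.sequence)
            assert 0.0 <= norm < 1.0

    def test_mutated_archetypes_recovered(self, archetypes):
        """Members at 10% point mutation map back to their own family."""
        config = SimConfig(seed=0)
        recovered = total = 0
        for family in ("DES_D5", "ELO_C18", "ACLY"):
            rng = derive_rng(17, f"recover:{family}")
            archetype = archetypes.records[family]
            for _ in range(20):
                seq = mutate(archetype.sequence, 0.10, config, rng)
                query = pt.ProteinRecord("q", "s", seq)
                total += 1
                recovered += pt.best_hit_assign(query, archetypes.library).family == family
        assert recovered / total >= 0.95

    def test_random_sequence_unclassified(self, archetypes):
        rng = derive_rng(9, "negative")
        query = pt.ProteinRecord("q", "s", _random_seq(rng, 400))
        assert pt.best_hit_assign(query, archetypes.library).family == UNCLASSIFIED

    def test_empty_library_is_config_error(self):
        with pytest.raises(pt.ConfigError):
            pt.ReferenceLibrary({})


class TestAssignProteome:
    def test_type_II_proteome_fully_assigned(self, panel, registry, archetypes):
        """A zero-mutation Type II strain covers every profile family."""
        sim = synth_strain(TYPE_PROFILES["II"], SimConfig(seed=2, decoys_per_strain=0),
                          archetypes, panel, registry)
        assignments = pt.assign_proteome(sim.proteome, panel, archetypes.library, registry)
        assigned = {a.protein_id: a.family for a in assignments}
        assert assigned == sim.truth

    def test_c16_and_c16l_resolved_distinctly(self, panel, registry, archetypes):
        """Despite >50% mutual identity and an identical box, the two C16-group
        elongases separate by best hit."""
        config = SimConfig(seed=4)
        rng = derive_rng(4, "c16")
        for family in ("ELO_C16", "ELO_C16L"):
            seq = mutate(archetypes.records[family].sequence, 0.05, config, rng,
                         protected_ranges=archetypes.planted_ranges[family])
            rec = pt.ProteinRecord(f"q_{family}", "s", seq)
            [a] = pt.assign_proteome([rec], panel, archetypes.library, registry)
            assert a.family == family
            assert "best_hit" in a.evidence

    def test_shuffled_decoys_all_rejected(self, panel, registry, archetypes):
        """Composition-preserving shuffles carry neither motif nor homology."""
        rng = derive_rng(21, "decoys")
        decoys = []
        sources = [archetypes.records[f] for f in ("DES_D5", "ELO_C16", "PfaA", "ACLY")]
        for i in range(60):
            src = sources[i % len(sources)].sequence
            shuffled = "".join(np.array(list(src))[rng.permutation(len(src))])
            decoys.append(pt.ProteinRecord(f"decoy{i}", "s", shuffled))
        assignments = pt.assign_proteome(decoys, panel, archetypes.library, registry)
        assigned = [a for a in assignments if a.family != UNCLASSIFIED]
        assert assigned == []


class TestPresenceMatrix:
    STRAINS = [StrainRecord("s1", "g", CladeGroup.THRAUSTOCHYTRID, EvidenceSource.GENOME)]

    def test_empty_assignments_all_absent(self, panel):
        matrix = pt.presence_matrix({"s1": []}, panel, self.STRAINS)
        assert all(matrix.cell("s1", g) is Presence.ABSENT for g in panel.names)

    def test_duplicate_assignments_idempotent(self, panel):
        a = pt.FamilyAssignment("p1", "PfaA", frozenset({"best_hit"}), 0.9)
        b = pt.FamilyAssignment("p2", "PfaA", frozenset({"best_hit"}), 0.8)
        matrix = pt.presence_matrix({"s1": [a, b]}, panel, self.STRAINS)
        assert matrix.cell("s1", "PfaA") is Presence.PRESENT

    def test_unknown_strain_rejected(self, panel):
        a = pt.FamilyAssignment("p1", "PfaA", frozenset({"best_hit"}), 0.9)
        with pytest.raises(pt.InputError):
            pt.presence_matrix({"ghost": [a]}, panel, self.STRAINS)

    def test_generator_round_trip_reproduces_profile(self, panel, registry, archetypes):
        """assign→matrix on a zero-mutation Type IV strain equals the profile."""
        profile = TYPE_PROFILES["IV"]
        sim = synth_strain(profile, SimConfig(seed=6, decoys_per_strain=2),
                          archetypes, panel, registry)
        strains = [StrainRecord(sim.strain_id, "sim", CladeGroup.THRAUSTOCHYTRID,
                                EvidenceSource.GENOME)]
        assignments = pt.assign_proteome(sim.proteome, panel, archetypes.library, registry)
        matrix = pt.presence_matrix({sim.strain_id: assignments}, panel, strains)
        present = {g for g in panel.names
                   if matrix.cell(sim.strain_id, g) is Presence.PRESENT}
        assert present == set(profile.genes)
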