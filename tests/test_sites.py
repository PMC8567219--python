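"""Localization filter, site aggregation, phosphoislands and counter groups."""

import random

import numpy as np
import pytest

from phosphoflow import (
    AssemblyError,
    assemble_sites,
    attach_ucg,
    build_phosphoislands,
    filter_localization,
    isoform_probability,
)

from conftest import make_record


def _corrected(rec, value):
    rec.log2_corrected = value
    return rec


class TestIsoformProbability:
    def test_single_site(self):
        rec = make_record(phospho=(4,), probs={4: 0.95}, sequence="AAASK")
        assert isoform_probability(rec) == pytest.approx(0.95)

    def test_product_of_two(self):
        rec = make_record(
            sequence="AASTK", phospho=(3, 4), probs={3: 0.9, 4: 0.8}
        )
        assert isoform_probability(rec) == pytest.approx(0.72)

    def test_certainty(self):
        rec = make_record(sequence="AASTK", phospho=(3, 4), probs={3: 1.0, 4: 1.0})
        assert isoform_probability(rec) == 1.0

    def test_takes_highest_candidates(self):
        # 1 phosphate, candidates 0.9 / 0.1: the best isoform carries 0.9
        rec = make_record(
            sequence="AASTK", phospho=(3,), probs={3: 0.9, 4: 0.1}
        )
        assert isoform_probability(rec) == pytest.approx(0.9)


class TestFilterLocalization:
    @pytest.mark.parametrize(
        "probs, retained",
        [
            ({3: 0.9, 4: 0.8}, True),     # 0.72 >= 0.70
            ({3: 0.9, 4: 0.75}, False),   # 0.675 < 0.70
            ({3: 1.0, 4: 0.7}, True),     # exactly 0.70 retained
        ],
    )
    def test_threshold_boundary(self, probs, retained):
        rec = make_record(sequence="AASTK", phospho=(3, 4), probs=probs)
        assert (len(filter_localization([rec])) == 1) is retained

    def test_unphosphorylated_records_pass(self):
        rec = make_record()
        assert filter_localization([rec]) == [rec]


class TestAssembleSites:
    def test_two_level_mean(self):
        records = [
            _corrected(make_record(phospho=(4,), sequence="AAASK", replicate="A"), 1.0),
            _corrected(make_record(phospho=(4,), sequence="AAASK", replicate="A"), 3.0),
            _corrected(make_record(phospho=(4,), sequence="AAASK", replicate="B"), 2.0),
        ]
        (site,) = assemble_sites(records)
        assert site.per_replicate_log2 == {"A": 2.0, "B": 2.0}
        assert site.final_log2 == pytest.approx(2.0)
        assert site.n_evidence == 3

    def test_missed_cleavage_variants_merge(self):
        records = [
            _corrected(make_record(phospho=(4,), sequence="AAASK", start=1), 1.0),
            _corrected(
                make_record(phospho=(4,), sequence="AAASKR", start=1), 1.0
            ),
        ]
        (site,) = assemble_sites(records)
        assert site.n_evidence == 2
        assert site.positions == (4,)

    def test_oxidation_variant_merges_without_changing_ratio(self):
        records = [
            _corrected(make_record(phospho=(4,), sequence="AAASK"), 0.7),
            _corrected(make_record(phospho=(4,), sequence="AAASK", mods=("oxidation",)), 0.7),
        ]
        (site,) = assemble_sites(records)
        assert site.final_log2 == pytest.approx(0.7)

    def test_single_entry(self):
        (site,) = assemble_sites(
            [_corrected(make_record(phospho=(4,), sequence="AAASK"), 0.0)]
        )
        assert site.final_log2 == 0.0

    def test_permutation_invariance(self):
        records = [
            _corrected(
                make_record(phospho=(4,), sequence="AAASK", replicate=rep), v
            )
            for rep, v in [("A", 0.3), ("B", -1.2), ("A", 0.9), ("C", 2.0)]
        ]
        (forward,) = assemble_sites(records)
        (backward,) = assemble_sites(records[::-1])
        assert forward.final_log2 == pytest.approx(backward.final_log2)
        assert forward.per_replicate_log2 == backward.per_replicate_log2

    def test_residue_validated_against_fasta(self):
        rec = _corrected(make_record(phospho=(4,), sequence="AAASK"), 0.0)
        assert assemble_sites([rec], {"P1": "AAASKXXXXX"})[0].residues == "S"
        with pytest.raises(AssemblyError):
            assemble_sites([rec], {"P1": "AAATKXXXXX"})  # FASTA says T, evidence S


def _phospho_pep(protein, start, length, phospho, value=0.0, replicate="r1"):
    offset_positions = tuple(sorted(phospho))
    seq = []
    for i in range(length):
        pos = start + i
        seq.append("S" if pos in offset_positions else "A")
    return _corrected(
        make_record(
            protein=protein, start=start, sequence="".join(seq),
            phospho=offset_positions, replicate=replicate,
        ),
        value,
    )


class TestPhosphoislands:
    def test_shared_position_joins_transitively(self):
        records = [
            _phospho_pep("P1", 10, 8, (12,)),
            _phospho_pep("P1", 10, 8, (12, 15)),
            _phospho_pep("P1", 18, 6, (20,)),
        ]
        islands = build_phosphoislands(records, attach_ucgs=False)
        assert [isl.positions for isl in islands] == [(12, 15), (20,)]
        assert islands[0].span == (12, 15)

    def test_single_peptide_single_island(self):
        islands = build_phosphoislands(
            [_phospho_pep("P1", 5, 6, (7,))], attach_ucgs=False
        )
        assert len(islands) == 1

    def test_sequence_overlap_without_shared_phospho_is_not_an_edge(self):
        records = [
            _phospho_pep("P1", 8, 10, (10,)),
            _phospho_pep("P1", 8, 10, (15,)),
        ]
        islands = build_phosphoislands(records, attach_ucgs=False)
        assert len(islands) == 2

    def test_matches_brute_force_transitive_closure(self):
        rng = random.Random(42)
        for _ in range(30):
            records = []
            for _ in range(rng.randint(1, 30)):
                start = rng.randint(1, 40)
                length = rng.randint(4, 12)
                k = rng.randint(1, min(2, length))
                phospho = rng.sample(range(start, start + length), k)
                records.append(_phospho_pep("P1", start, length, tuple(phospho)))
            islands = build_phosphoislands(records, attach_ucgs=False)
            got = sorted(isl.positions for isl in islands)
            assert got == _oracle_islands(records)

    def test_every_peptide_in_exactly_one_island(self):
        records = [
            _phospho_pep("P1", s, 8, (s + 2,)) for s in (1, 3, 5, 20, 30)
        ]
        islands = build_phosphoislands(records, attach_ucgs=False)
        covered = [p for isl in islands for p in isl.positions]
        assert sorted(covered) == sorted(
            {p for r in records for p in r.phospho_positions}
        )


def _oracle_islands(records):
    """Brute-force transitive closure: repeatedly merge position sets that
    intersect."""
    groups = [set(r.phospho_positions) for r in records]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i] and groups[i] & groups[j]:
                    groups[i] |= groups[j]
                    groups[j] = set()
                    changed = True
    return sorted(tuple(sorted(g)) for g in groups if g)


class TestUCG:
    def test_covering_unphosphorylated_peptide(self):
        phospho = [_phospho_pep("P1", 10, 6, (12,))]
        unphos = _corrected(make_record(protein="P1", start=10, sequence="A" * 9), 0.5)
        (island,) = build_phosphoislands(phospho + [unphos])
        assert island.ucg_log2 == pytest.approx(0.5)
        assert island.ucg_n == 1

    def test_no_covering_peptide_undefined(self):
        phospho = [_phospho_pep("P1", 10, 6, (12,))]
        unphos = _corrected(make_record(protein="P1", start=30, sequence="AAAAA"), 0.5)
        (island,) = build_phosphoislands(phospho + [unphos])
        assert island.ucg_log2 is None
        assert island.ucg_n == 0

    def test_within_replicate_mean(self):
        phospho = [_phospho_pep("P1", 10, 6, (12,))]
        unphos = [
            _corrected(make_record(protein="P1", start=10, sequence="AAAAA"), 0.0),
            _corrected(make_record(protein="P1", start=11, sequence="AAAAA"), 1.0),
        ]
        island = attach_ucg(
            build_phosphoislands(phospho, attach_ucgs=False)[0], phospho + unphos
        )
        assert island.ucg_log2 == pytest.approx(0.5)


class TestNullClosure:
    def test_noise_free_null_world_gives_all_zero_sites(self):
        from phosphoflow import (
            SimulationConfig, apply_normalization, fit_groups, generate_proteome,
            plan_site_effects, read_evidence, simulate_evidence,
            write_evidence_table,
        )
        import io

        proteome = generate_proteome(6, (120, 200), seed=9)
        table, _ = plan_site_effects(proteome, n_static=6, seed=9)
        null_table = {k: 0.0 for k in table}
        cfg = SimulationConfig(
            n_evidence=240, noise_sd=0.0, site_effect_table=null_table, seed=9,
        )
        evidence, _ = simulate_evidence(cfg, proteome)
        buf = io.StringIO()
        write_evidence_table(evidence, buf)
        buf.seek(0)
        records, _ = read_evidence(buf)
        apply_normalization(records, fit_groups(records))
        retained = filter_localization(records)
        for site in assemble_sites(retained, proteome):
            assert abs(site.final_log2) < 1e-12
        for island in build_phosphoislands(retained, proteome):
            if island.ucg_log2 is not None:
                assert abs(island.ucg_log2) < 1e-12
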