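"""Core mapping: per-chain matching, cutoff, catalog aggregation, AlphaFold route."""

import pytest
from hypothesis import given, strategies as st

from epistruct.catalog import DiscontinuousSite, EpitopeRecord
from epistruct.mapper import (
    AlphaFoldModel,
    map_catalog,
    map_catalog_alphafold,
    map_epitope_to_chain,
    passes_cutoff,
    resolve_epitope_positions,
    run_full_mapping,
)
from epistruct.sifts import ResidueAlignment, StructureResidue, alignment_from_identity
from epistruct.structures import StructureMeta

from oracles import brute_force_matched


def linear(seq, eid="E1", acc="P1", start=None):
    return EpitopeRecord(epitope_id=eid, classification="linear", sequence=seq,
                         parent_accession=acc, start_position=start)


def subset_alignment(sequence, observed_positions, accession="P1", sid="1AAA", offset=0):
    """Identity-lettered alignment covering only the given positions."""
    entries = {
        ("A", i): StructureResidue("A", i + offset, "", sequence[i - 1], True)
        for i in observed_positions
    }
    return ResidueAlignment(structure_id=sid, accession=accession, entries=entries)


class TestMapEpitopeToChain:
    def test_full_identity_coverage(self):
        rec = linear("ACDEFGHI")
        aln = alignment_from_identity("P1", "ACDEFGHI")
        m = map_epitope_to_chain(rec, list(range(1, 9)), list("ACDEFGHI"), aln, "A")
        assert m.mapped_fraction == 1.0 and not m.unmatched

    def test_not_observed_gap_reduces_fraction(self):
        seq = "ACDEFGHIKL"
        aln = alignment_from_identity("P1", seq)
        for pos in (3, 7):  # carve a 2-residue unmodeled gap
            aln.entries[("A", pos)] = StructureResidue("A", None, "", seq[pos - 1], False)
        m = map_epitope_to_chain(linear(seq), list(range(1, 11)), list(seq), aln, "A")
        assert m.mapped_fraction == pytest.approx(0.8)
        assert sorted(r for _, r in m.unmatched) == ["not_observed", "not_observed"]

    def test_identity_mismatches_counted(self):
        seq = "ACDEFGHIKL"
        # structure agrees at position 1 only
        aln = alignment_from_identity("P1", seq[0] + "Y" * 9)
        m = map_epitope_to_chain(linear(seq), list(range(1, 11)), list(seq), aln, "A")
        assert m.mapped_fraction == pytest.approx(0.1)
        assert all(r == "identity_mismatch" for _, r in m.unmatched)

    def test_positions_outside_alignment_are_no_mapping(self):
        aln = alignment_from_identity("P1", "ACD")
        m = map_epitope_to_chain(linear("ACDEF"), list(range(1, 6)), list("ACDEF"), aln, "A")
        assert {r for _, r in m.unmatched} == {"no_mapping"}
        assert m.mapped_fraction == pytest.approx(0.6)

    def test_length_invariant(self):
        aln = alignment_from_identity("P1", "ACD")
        m = map_epitope_to_chain(linear("ACDEF"), list(range(1, 6)), list("ACDEF"), aln, "A")
        assert len(m.matched) + len(m.unmatched) == 5 == m.epitope_length

    @given(st.sets(st.integers(1, 20), max_size=20))
    def test_removing_alignment_entries_never_raises_fraction(self, removed):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        full = alignment_from_identity("P1", seq)
        reduced = ResidueAlignment(
            structure_id="1AAA", accession="P1",
            entries={k: v for k, v in full.entries.items() if k[1] not in removed},
        )
        rec = linear(seq)
        args = (rec, list(range(1, 21)), list(seq))
        assert (
            map_epitope_to_chain(*args, reduced, "A").mapped_fraction
            <= map_epitope_to_chain(*args, full, "A").mapped_fraction
        )


class TestCutoff:
    @pytest.mark.parametrize("fraction_pct,expected", [(19, False), (20, True), (21, True), (100, True)])
    def test_boundary(self, fraction_pct, expected):
        seq = "A" * 100
        aln = subset_alignment(seq, range(1, fraction_pct + 1))
        m = map_epitope_to_chain(linear(seq), list(range(1, 101)), list(seq), aln, "A")
        assert m.mapped_fraction == pytest.approx(fraction_pct / 100)
        assert passes_cutoff(m) is expected


def make_meta(sid="1AAA", acc="P1", res=2.0, length=100):
    return StructureMeta(structure_id=sid, accession=acc, resolution=res,
                         covered_length=length, source="experimental")


class TestMapCatalog:
    def test_single_epitope_fully_covered(self):
        parent = "M" + "ACDEFGHI" + "W" * 10
        rec = linear("ACDEFGHI", start=2)
        aln = alignment_from_identity("P1", parent, structure_id="1AAA")
        aln.structure_id = "1AAA"
        res = map_catalog([rec], {"P1": [make_meta()]}, {"1AAA": aln}, {"P1": parent})
        assert [s.n_epitopes_mapped for s in res.summaries] == [1]
        assert res.unmapped == [] and res.fallback_accessions == []

    def test_epitope_in_unmodeled_loop_reported_not_observed(self):
        parent = "ACDEFGHIKLMNPQRSTVWY"
        aln = alignment_from_identity("P1", parent, structure_id="1AAA")
        aln.structure_id = "1AAA"
        for pos in range(5, 13):
            aln.entries[("A", pos)] = StructureResidue("A", None, "", parent[pos - 1], False)
        ok = linear(parent[:4], eid="OK", start=1)
        in_loop = linear(parent[4:12], eid="LOOP", start=5)
        res = map_catalog([ok, in_loop], {"P1": [make_meta()]}, {"1AAA": aln}, {"P1": parent})
        assert res.summaries[0].n_epitopes_mapped == 1
        assert [(u.epitope_id, u.reason) for u in res.unmapped] == [("LOOP", "not_observed")]

    def test_all_epitopes_below_cutoff_sends_accession_to_fallback(self):
        parent = "ACDEFGHIKLMNPQRSTVWY"
        aln = subset_alignment(parent, [1], sid="1AAA")  # 1/20 = 5% < 20%
        rec = linear(parent, eid="E1", start=1)
        res = map_catalog([rec], {"P1": [make_meta()]}, {"1AAA": aln}, {"P1": parent})
        assert res.fallback_accessions == ["P1"]
        assert res.summaries[0].n_epitopes_mapped == 0

    def test_no_experimental_structure_sends_accession_to_fallback(self):
        rec = linear("ACDEF", acc="P9", start=1)
        res = map_catalog([rec], {}, {}, {"P9": "ACDEF"})
        assert res.fallback_accessions == ["P9"]
        assert res.unmapped[0].reason == "no_structure"

    def test_multichain_counts_epitope_once_but_rows_per_chain(self):
        parent = "ACDEFGHIKL"
        entries = {}
        for chain in ("A", "B"):
            for i, aa in enumerate(parent, 1):
                entries[(chain, i)] = StructureResidue(chain, i, "", aa, True)
        aln = ResidueAlignment(structure_id="1AAA", accession="P1", entries=entries)
        rec = linear(parent, start=1)
        res = map_catalog([rec], {"P1": [make_meta()]}, {"1AAA": aln}, {"P1": parent})
        assert len(res.chain_mappings) == 2
        assert res.summaries[0].n_epitopes_mapped == 1

    def test_discontinuous_epitope_uses_site_letters(self):
        parent = "ACDEFGHIKL"
        aln = alignment_from_identity("P1", parent, structure_id="1AAA")
        aln.structure_id = "1AAA"
        rec = EpitopeRecord(
            epitope_id="D1", classification="discontinuous", parent_accession="P1",
            sites=(DiscontinuousSite(residue="C", position=2),
                   DiscontinuousSite(residue="F", position=5),
                   DiscontinuousSite(residue="L", position=10)),
        )
        res = map_catalog([rec], {"P1": [make_meta()]}, {"1AAA": aln}, {"P1": parent})
        assert res.summaries[0].n_epitopes_mapped == 1
        (m,) = res.chain_mappings
        assert [mr.uniprot_position for mr in m.matched] == [2, 5, 10]

    def test_brute_force_oracle_equivalence(self, pipeline_inputs):
        records, index, alignments, parents, _ = pipeline_inputs
        res = map_catalog(records, index, alignments, parents)
        by_key = {(m.epitope_id, m.chain_id): {mr.uniprot_position for mr in m.matched}
                  for m in res.chain_mappings}
        aln = next(iter(alignments.values()))
        for rec in records:
            positions, letters = resolve_epitope_positions(rec, parents[rec.parent_accession])
            expected = brute_force_matched(positions, letters, aln)
            for chain, matched in expected.items():
                if (rec.epitope_id, chain) in by_key:
                    assert by_key[(rec.epitope_id, chain)] == matched
                else:  # excluded by cutoff
                    assert len(matched) / len(positions) < 0.20


class TestAlphaFoldRoute:
    def test_identity_mapping_attaches_plddt(self):
        parent = "ACDEFGHIKLMNPQRSTVWY" * 5
        plddt = tuple(float(50 + i % 40) for i in range(len(parent)))
        model = AlphaFoldModel(accession="P1", sequence=parent, plddt=plddt)
        rec = linear(parent[4:12], start=5)
        res = map_catalog_alphafold([rec], {"P1": model}, {"P1": parent})
        (m,) = res.chain_mappings
        assert m.mapped_fraction == 1.0
        assert [mr.plddt for mr in m.matched] == list(plddt[4:12])
        assert res.summaries[0].source == "predicted"

    def test_model_shorter_than_epitope_tail_is_no_mapping(self):
        parent = "ACDEFGHIKL"
        model = AlphaFoldModel(accession="P1", sequence=parent, plddt=tuple([80.0] * 10))
        rec = linear(parent + "WW", start=1)  # overhangs the model by 2
        res = map_catalog_alphafold([rec], {"P1": model}, {"P1": parent + "WW"})
        # model != parent now, so the record is skipped entirely
        assert res.unmapped[0].reason == "no_structure"

    def test_truncated_model_positions_reported_no_mapping(self):
        parent = "ACDEFGHIKL"
        model = AlphaFoldModel(accession="P1", sequence=parent, plddt=tuple([80.0] * 10))
        rec = EpitopeRecord(
            epitope_id="D1", classification="discontinuous", parent_accession="P1",
            sites=(DiscontinuousSite(residue="A", position=1),
                   DiscontinuousSite(residue="W", position=55)),
        )
        res = map_catalog_alphafold([rec], {"P1": model}, {"P1": parent})
        (m,) = res.chain_mappings
        assert m.unmatched == [(55, "no_mapping")]

    def test_mismatching_model_sequence_skipped_with_warning(self, caplog):
        import logging

        model = AlphaFoldModel(accession="P1", sequence="AAAA", plddt=(80.0,) * 4)
        rec = linear("ACDE", start=1)
        with caplog.at_level(logging.WARNING):
            res = map_catalog_alphafold([rec], {"P1": model}, {"P1": "ACDE"})
        assert res.chain_mappings == []
        assert any("skipped" in m for m in caplog.messages)


class TestPipelineConservation:
    def test_ledger_adds_up_on_fixture(self, pipeline_inputs):
        records, index, alignments, parents, models = pipeline_inputs
        result = run_full_mapping(records, index, alignments, parents, models)
        ledger = result.ledger()
        assert ledger["total"] == len(records)
        assert ledger["mapped"] + ledger["unmapped"] == ledger["total"]
        assert ledger["mapped"] == ledger["mapped_experimental"] + ledger["mapped_predicted"]
        assert len(result.unmapped) == ledger["unmapped"]

    def test_fallback_antigen_recovered_by_predicted_model(self):
        parent = "ACDEFGHIKLMNPQRSTVWY"
        aln = subset_alignment(parent, [1], sid="1AAA")  # everything below cutoff
        rec = linear(parent, start=1)
        model = AlphaFoldModel(accession="P1", sequence=parent, plddt=tuple([75.0] * 20))
        result = run_full_mapping([rec], {"P1": [make_meta()]}, {"1AAA": aln},
                                  {"P1": parent}, {"P1": model})
        ledger = result.ledger()
        assert ledger == {"total": 1, "mapped": 1, "unmapped": 0,
                          "mapped_experimental": 0, "mapped_predicted": 1}
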