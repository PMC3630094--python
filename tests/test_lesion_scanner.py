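"""Lesion detection: hand fixtures, frameshift parity, simulator completeness."""

import pytest
from hypothesis import given, settings, strategies as st

import opsinphylo as op
from opsinphylo.data_io import Segment


def make_aln_model(rows, segments=None, ref="REF"):
    aln = op.CodonAlignment(list(rows), dict(rows))
    segments = segments or [("exon", 1, len(rows[ref]))]
    model = op.GeneModel("g", [Segment(k, a, b) for k, a, b in segments],
                         1, {i: i for i in range(1, 400)}, ref)
    return aln, model


REF_CDS = "ATGAAACCCGGGTTTCTGAGCATCGAGTAA"  # 10 codons incl. terminal stop


class TestScanIndels:
    def test_gap_free_alignment_is_clean(self):
        aln, model = make_aln_model({"REF": REF_CDS, "X": REF_CDS})
        assert op.scan_indels(aln, model) == []

    def test_in_frame_deletion_not_reported(self):
        x = REF_CDS[:6] + "---" + REF_CDS[9:]
        aln, model = make_aln_model({"REF": REF_CDS, "X": x})
        assert op.scan_indels(aln, model) == []

    @pytest.mark.parametrize("size,expected", [(1, 1), (2, 1), (3, 0), (4, 1), (6, 0)])
    def test_frameshift_parity(self, size, expected):
        x = REF_CDS[:6] + "-" * size + REF_CDS[6 + size:]
        aln, model = make_aln_model({"REF": REF_CDS, "X": x})
        recs = op.scan_indels(aln, model)
        assert len(recs) == expected
        if expected:
            assert recs[0].lesion_type == "frameshift_deletion"
            assert (recs[0].start, recs[0].end) == (7, 6 + size)

    def test_insertion_polarity_against_reference(self):
        # reference gapped, focal taxon carries sequence: an insertion
        ref = REF_CDS[:9] + "--" + REF_CDS[9:]
        x = REF_CDS[:9] + "CA" + REF_CDS[9:]
        aln, model = make_aln_model({"REF": ref, "X": x})
        recs = op.scan_indels(aln, model)
        assert [r.lesion_type for r in recs] == ["frameshift_insertion"]
        assert (recs[0].start, recs[0].end) == (10, 11)

    def test_shared_coordinates_merge_taxa(self):
        x = REF_CDS[:6] + "----" + REF_CDS[10:]
        aln, model = make_aln_model({"REF": REF_CDS, "A": x, "B": x})
        recs = op.scan_indels(aln, model)
        assert len(recs) == 1
        assert sorted(recs[0].taxa) == ["A", "B"]

    def test_adjacent_runs_not_merged(self):
        # two 2-bp runs separated by one base: jointly in-frame (4 bp) but
        # each run is evaluated alone
        x = REF_CDS[:6] + "--" + REF_CDS[8] + "--" + REF_CDS[11:]
        aln, model = make_aln_model({"REF": REF_CDS, "X": x})
        recs = op.scan_indels(aln, model)
        assert len(recs) == 2

    @given(st.integers(min_value=1, max_value=12))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_parity_property(self, size):
        """A single gap run is reported iff its length is not a multiple of 3."""
        x = REF_CDS[:3] + "-" * size + REF_CDS[3 + size:]
        aln, model = make_aln_model({"REF": REF_CDS, "X": x})
        recs = op.scan_indels(aln, model)
        assert bool(recs) == (size % 3 != 0)


class TestScanPrematureStops:
    def test_reference_identical_sequence_clean(self):
        aln, model = make_aln_model({"REF": REF_CDS, "X": REF_CDS})
        assert op.scan_premature_stops(aln, model) == []

    def test_stop_in_shifted_frame_after_deletion(self):
        # a 4-bp deletion (columns 4-7) shifts the frame; the taxon's
        # gap-stripped sequence ATG CCG GGT TTC TGA ... hits TGA at stripped
        # bases 13-15, which sit at alignment columns 17-19 (hand-computed);
        # the reference frame at those columns reads ...T TTC TGA... harmlessly
        x = REF_CDS[:3] + "----" + REF_CDS[7:]
        aln, model = make_aln_model({"REF": REF_CDS, "X": x})
        recs = op.scan_premature_stops(aln, model)
        assert len(recs) == 1
        assert (recs[0].start, recs[0].end) == (17, 19)
        assert recs[0].detail == "premature TGA"

    def test_nonsense_codon_at_exact_columns(self):
        x = REF_CDS[:12] + "TGA" + REF_CDS[15:]
        aln, model = make_aln_model({"REF": REF_CDS, "X": x})
        recs = op.scan_premature_stops(aln, model)
        assert len(recs) == 1
        assert (recs[0].start, recs[0].end) == (13, 15)
        assert recs[0].detail == "premature TGA"

    def test_terminal_stop_not_premature(self):
        # a taxon sharing only the reference's own terminal stop is clean
        aln, model = make_aln_model({"REF": REF_CDS, "X": REF_CDS})
        assert op.scan_premature_stops(aln, model) == []


class TestScanSpliceSites:
    INTRON = "GT" + "A" * 8 + "AG"

    def layout(self, donor="GT", acceptor="AG"):
        intron = donor + "A" * 8 + acceptor
        row = REF_CDS[:9] + self.INTRON + REF_CDS[9:]
        x = REF_CDS[:9] + intron + REF_CDS[9:]
        segs = [("exon", 1, 9), ("intron", 10, 21), ("exon", 22, len(row))]
        return make_aln_model({"REF": row, "X": x}, segs)

    def test_canonical_sites_clean(self):
        aln, model = self.layout()
        assert op.scan_splice_sites(aln, model) == []

    def test_donor_disruption(self):
        aln, model = self.layout(donor="GC")
        recs = op.scan_splice_sites(aln, model)
        assert [r.lesion_type for r in recs] == ["splice_donor"]
        assert recs[0].detail == "GT to GC"
        assert (recs[0].start, recs[0].end) == (10, 11)

    def test_acceptor_disruption(self):
        aln, model = self.layout(acceptor="AA")
        recs = op.scan_splice_sites(aln, model)
        assert [r.lesion_type for r in recs] == ["splice_acceptor"]
        assert recs[0].detail == "AG to AA"

    def test_shared_disruption_merges_taxa(self):
        intron = "GA" + "A" * 8 + "AG"
        row = REF_CDS[:9] + self.INTRON + REF_CDS[9:]
        x = REF_CDS[:9] + intron + REF_CDS[9:]
        segs = [("exon", 1, 9), ("intron", 10, 21), ("exon", 22, len(row))]
        aln, model = make_aln_model({"REF": row, "P": x, "K": x}, segs)
        recs = op.scan_splice_sites(aln, model)
        assert len(recs) == 1
        assert sorted(recs[0].taxa) == ["K", "P"]
        assert recs[0].detail == "GT to GA"

    def test_deleted_intron_unassessable(self):
        row = REF_CDS[:9] + self.INTRON + REF_CDS[9:]
        x = REF_CDS[:9] + "-" * 12 + REF_CDS[9:]
        segs = [("exon", 1, 9), ("intron", 10, 21), ("exon", 22, len(row))]
        aln, model = make_aln_model({"REF": row, "X": x}, segs)
        assert op.scan_splice_sites(aln, model) == []


class TestScanKeyResidues:
    RULE = op.KeyResidueRule("g", 3, frozenset("E"), frozenset("G"),
                             "counterion site")

    def test_inactivating_state_reported(self):
        x = REF_CDS[:6] + "GGG" + REF_CDS[9:]
        aln, model = make_aln_model({"REF": REF_CDS, "X": x})
        recs = op.scan_key_residues(aln, model, [self.RULE])
        assert len(recs) == 1
        assert recs[0].detail == "E3G"
        assert (recs[0].start, recs[0].end) == (7, 9)

    def test_intact_state_not_listed(self):
        x = REF_CDS[:6] + "GAG" + REF_CDS[9:]  # E, the intact state
        aln, model = make_aln_model({"REF": REF_CDS, "X": x})
        assert op.scan_key_residues(aln, model, [self.RULE]) == []

    def test_empty_inactivating_set_is_noop(self):
        rule = op.KeyResidueRule("g", 3, frozenset("E"), frozenset())
        aln, model = make_aln_model({"REF": REF_CDS, "X": REF_CDS})
        assert op.scan_key_residues(aln, model, [rule]) == []

    def test_disjoint_states_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            op.KeyResidueRule("g", 3, frozenset("E"), frozenset("E"))


class TestSimulatorCompleteness:
    """Every injected lesion recovered at exact coordinates; no spurious
    records in lesion-free genes (random histories)."""

    TREE = ("(O:0.1,((A:0.05,B:0.05)7:0.03,(C:0.05,D:0.05)8:0.03)9:0.03)10;")

    def random_spec(self, rng, seed):
        tree = op.SpeciesTree.from_newick(self.TREE)
        # lesions stay inside the ingroup so the outgroup O remains an intact
        # reference defining indel polarity and frame
        ingroup = set(tree.subtree_leaf_ids(9)) | {9, 7, 8}
        branches = [b for b in tree.branches() if b[1] in ingroup and b != (10, 9)]
        branch = branches[rng.integers(len(branches))]
        kind = ["frameshift_deletion", "frameshift_insertion", "nonsense",
                "splice_donor", "splice_acceptor", "key_missense"][rng.integers(6)]
        if kind.startswith("frameshift"):
            size = int(rng.choice([1, 2, 4, 5]))
            lesion = op.LesionEvent(branch, 0.5, kind, size=size,
                                    cds_codon=int(rng.integers(2, 38)))
        elif kind == "nonsense":
            lesion = op.LesionEvent(branch, 0.5, kind,
                                    cds_codon=int(rng.integers(2, 59)))
        elif kind == "key_missense":
            lesion = op.LesionEvent(branch, 0.5, kind, cds_codon=5, to="GGA")
        else:
            lesion = op.LesionEvent(branch, 0.5, kind, intron=1,
                                    to="GC" if kind == "splice_donor" else "AA")
        return op.SimSpec(tree=tree, codons=60, kappa=2.0, omega=0.2,
                          introns=[(40, 30)], lesions=[lesion],
                          tuning_root={5: "GAA"}, reference_taxon="O",
                          allow_stop_drift=False, seed=seed), lesion, tree

    def test_injected_lesions_recovered_exactly(self):
        import numpy as np
        rng = np.random.default_rng(2024)
        rules = [op.KeyResidueRule("gene", 5, frozenset("E"), frozenset("G"))]
        for rep in range(100):
            spec, lesion, tree = self.random_spec(rng, seed=50_000 + rep)
            aln, model, truth = op.simulate(spec)
            recs = op.scan_all(aln, model, rules)
            ev = truth.events[0]
            lt = {"nonsense": "premature_stop",
                  "key_missense": "key_residue_missense"}.get(
                      ev.lesion_type, ev.lesion_type)
            matches = [r for r in recs if r.lesion_type == lt
                       and (r.start, r.end) == (ev.start, ev.end)
                       and set(ev.carriers) <= set(r.taxa)]
            assert matches, (rep, ev, recs)

    def test_no_spurious_records_in_lesion_free_genes(self):
        tree = op.SpeciesTree.from_newick(self.TREE)
        for rep in range(20):
            spec = op.SimSpec(tree=tree, codons=60, kappa=2.0, omega=0.3,
                              introns=[(40, 30)], reference_taxon="O",
                              seed=60_000 + rep)
            aln, model, truth = op.simulate(spec)
            assert op.scan_all(aln, model) == []
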