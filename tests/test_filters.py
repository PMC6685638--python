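"""Remapping-based reference-bias mitigation filters."""

import numpy as np
import pytest

from refbias import (
    Mapper,
    ReferenceGenome,
    SNPPanel,
    SNPRecord,
    bias_summary,
    build_modified_reference,
    classify_heterozygous,
    combined_filter,
    filter_short,
    flip_ref_to_alt,
    modified_read_filter,
    modified_reference_filter,
    pileup,
    remove_duplicates,
)
from refbias.simulate import SimulationConfig, simulate_dataset
from conftest import make_alignment


@pytest.fixture(scope="module")
def toy():
    """Repeat-free 5 kb genome with two panel SNPs 5 bp apart."""
    rng = np.random.default_rng(17)
    seq = list(rng.choice(list("ACGT"), size=5000))
    seq[100], seq[105] = "A", "G"
    reference = ReferenceGenome({"chr1": "".join(seq)})
    panel = SNPPanel(
        [SNPRecord("chr1", 101, "A", "T"), SNPRecord("chr1", 106, "G", "C")]
    )
    return reference, panel


class TestFlip:
    def test_single_snp_flipped(self, toy):
        reference, panel = toy
        read = make_alignment(reference["chr1"][90:130], start=90)
        flip = flip_ref_to_alt(read, panel)
        assert flip.changed
        assert flip.sequence[10] == "T" and flip.sequence[15] == "C"
        assert flip.flipped_positions == (100, 105)
        # all other bases untouched
        assert [
            i for i in range(40) if flip.sequence[i] != read.sequence[i]
        ] == [10, 15]

    def test_alt_carrying_read_unchanged(self, toy):
        reference, panel = toy
        seq = list(reference["chr1"][90:130])
        seq[10], seq[15] = "T", "C"  # alt at both SNPs
        read = make_alignment("".join(seq), start=90)
        flip = flip_ref_to_alt(read, panel)
        assert not flip.changed
        assert flip.sequence == read.sequence

    def test_no_overlap_is_error(self, toy):
        _reference, panel = toy
        read = make_alignment("ACGT" * 10, start=2000)
        with pytest.raises(ValueError, match="no panel SNP"):
            flip_ref_to_alt(read, panel)


class TestModifiedReference:
    def test_third_allele_outside_ref_alt(self, toy):
        reference, panel = toy
        modified = build_modified_reference(reference, panel, seed=1)
        for r in panel:
            third = modified.genome[r.chrom][r.pos0]
            assert third not in (r.ref_allele, r.alt_allele)

    def test_same_seed_is_bitwise_identical(self, toy):
        reference, panel = toy
        m1 = build_modified_reference(reference, panel, seed=5)
        m2 = build_modified_reference(reference, panel, seed=5)
        assert m1.genome == m2.genome
        assert m1.substitutions.equals(m2.substitutions)

    def test_non_snp_positions_untouched(self, toy):
        reference, panel = toy
        modified = build_modified_reference(reference, panel, seed=1)
        orig = reference["chr1"]
        mod = modified.genome["chr1"]
        assert [i for i in range(len(orig)) if orig[i] != mod[i]] == [100, 105]

    def test_panel_reference_mismatch_errors(self, toy):
        reference, _panel = toy
        bad_panel = SNPPanel([SNPRecord("chr1", 101, "C", "T")])  # genome has A
        with pytest.raises(ValueError, match="disagree"):
            build_modified_reference(reference, bad_panel, seed=1)

    def test_filter_rejects_foreign_substitution_table(self, toy):
        reference, panel = toy
        modified = build_modified_reference(reference, panel, seed=1)
        other_panel = SNPPanel([SNPRecord("chr1", 101, "A", "T")])
        with pytest.raises(ValueError, match="not built from this panel"):
            modified_reference_filter([], other_panel, modified)


def _reads_at_snp(reference, panel, haplotype, starts, length=40):
    """Coordinate-sorted alignments of haplotype extracts covering SNP 1."""
    mapper = Mapper(reference)
    alns = []
    for i, s in enumerate(sorted(starts)):
        aln = mapper.map_read(haplotype[s : s + length], read_id=f"t{i}")
        assert aln is not None
        alns.append(aln)
    alns.sort(key=lambda a: (a.chrom, a.start, a.read_id))
    return alns


class TestModifiedReadFilter:
    def test_clean_reads_pass(self, toy):
        reference, panel = toy
        alns = _reads_at_snp(reference, panel, reference["chr1"], [80, 90, 95])
        passed, report = modified_read_filter(alns, panel, reference)
        assert len(passed) == 3
        assert report.n_flipped_or_remapped == 3
        assert report.n_passed == 3 and report.n_removed == 0

    def test_read_at_edit_budget_fails_after_flip(self, toy):
        reference, panel = toy
        # ref-carrying 40-mer with maxdiff(40)=3 non-SNP mismatches: still
        # maps, but the flip adds a 4th mismatch and exceeds the budget
        seq = list(reference["chr1"][90:130])
        for off in (2, 25, 35):
            seq[off] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[off]]
        mapper = Mapper(reference)
        aln = mapper.map_read("".join(seq), read_id="budget")
        assert aln is not None and aln.start == 90
        passed, report = modified_read_filter([aln], panel, reference)
        assert passed == []
        assert report.n_failed_position == 1

    def test_non_overlapping_reads_untouched(self, toy):
        reference, panel = toy
        far = make_alignment(reference["chr1"][3000:3040], start=3000)
        passed, report = modified_read_filter([far], panel, reference)
        assert passed == [far]
        assert report.n_flipped_or_remapped == 0


class TestModifiedReferenceFilter:
    def test_both_alleles_pass_symmetrically(self, toy):
        reference, panel = toy
        modified = build_modified_reference(reference, panel, seed=2)
        h_ref = reference["chr1"]
        h_alt = h_ref[:100] + "T" + h_ref[101:105] + "C" + h_ref[106:]
        starts = [75, 85, 95]
        ref_alns = _reads_at_snp(reference, panel, h_ref, starts)
        alt_alns = _reads_at_snp(reference, panel, h_alt, starts)
        p_ref, rep_ref = modified_reference_filter(ref_alns, panel, modified)
        p_alt, rep_alt = modified_reference_filter(alt_alns, panel, modified)
        assert len(p_ref) == len(ref_alns)
        assert len(p_alt) == len(alt_alns)
        assert rep_ref.n_passed == rep_alt.n_passed

    def test_budget_read_fails_with_third_allele(self, toy):
        reference, panel = toy
        seq = list(reference["chr1"][90:130])
        for off in (2, 25, 35):
            seq[off] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[off]]
        mapper = Mapper(reference)
        aln = mapper.map_read("".join(seq), read_id="budget")
        modified = build_modified_reference(reference, panel, seed=2)
        passed, report = modified_reference_filter([aln], panel, modified)
        assert passed == []
        assert report.n_failed_position == 1


class TestCombinedAndInvariants:
    def test_combination_is_intersection(self, biased_run):
        reference, _genotypes, panel, alignments = biased_run
        subset = alignments[:600]
        modified = build_modified_reference(reference, panel, seed=7)
        p1, _ = modified_read_filter(subset, panel, reference)
        p2, _ = modified_reference_filter(subset, panel, modified)
        pc, _ = combined_filter(subset, panel, reference, modified)
        key = lambda a: (a.read_id, a.chrom, a.start, a.strand)
        assert {key(a) for a in pc} == {key(a) for a in p1} & {key(a) for a in p2}

    def test_filters_idempotent(self, biased_run):
        reference, _genotypes, panel, alignments = biased_run
        subset = alignments[:400]
        modified = build_modified_reference(reference, panel, seed=7)
        once, _ = modified_reference_filter(subset, panel, modified)
        twice, _ = modified_reference_filter(once, panel, modified)
        assert twice == once
        once_r, _ = modified_read_filter(subset, panel, reference)
        twice_r, _ = modified_read_filter(once_r, panel, reference)
        assert twice_r == once_r

    def test_non_overlapping_never_removed(self, biased_run):
        reference, _genotypes, panel, alignments = biased_run
        subset = alignments[:600]
        modified = build_modified_reference(reference, panel, seed=7)
        outside = [
            a for a in subset if not panel.overlapping(a.chrom, a.start, a.ref_end)
        ]
        for passed, _rep in (
            modified_read_filter(subset, panel, reference),
            modified_reference_filter(subset, panel, modified),
            combined_filter(subset, panel, reference, modified),
        ):
            ids = {a.read_id for a in passed}
            assert all(a.read_id in ids for a in outside)


class TestResidualBias:
    def test_filters_cannot_repair_pre_mapping_losses(self):
        """Alternative reads lost before mapping (reference-matching
        contamination) stay lost: no filter pushes the mean alt fraction
        above 0.5 + 2 SE."""
        cfg = SimulationConfig(
            genome_length=25_000,
            snp_density=6.0,
            het_fraction=1.0,
            coverage=40.0,
            length_mode=45,
            contamination=(0.2, 1.0),
            seed=23,
        )
        reference, _genotypes, panel, reads = simulate_dataset(cfg)
        mapper = Mapper(reference)
        alns = remove_duplicates(filter_short(mapper.map_reads(reads), 35))
        modified = build_modified_reference(reference, panel, seed=3)

        def mean_alt(alignments):
            sites = pileup(alignments, panel, 30, 30)
            het = [s for s in sites if classify_heterozygous(s)]
            return bias_summary(het)

        base = mean_alt(alns)
        assert base.mean_alt_fraction < 0.5  # contamination biases downward
        for passed, _ in (
            modified_read_filter(alns, panel, reference),
            modified_reference_filter(alns, panel, modified),
            combined_filter(alns, panel, reference, modified),
        ):
            s = mean_alt(passed)
            assert s.mean_alt_fraction <= 0.5 + 2 * s.se
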