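"""Upload pipeline: FASTA input, gene calling, translation, re-orientation."""

import pytest

from manna import ingest
from manna.errors import (
    AdapterUnavailableError,
    AlphabetError,
    FormatError,
    TranslationError,
    UniquenessError,
    ValidationError,
)
from manna.fixtures import make_synthetic_phage, make_terminase_db
from manna.ingest import FeatureDraft, UploadOptions


class TestReadSingleFasta:
    def test_lowercase_sequence_uppercased(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">p\nacgt\n")
        assert ingest.read_single_fasta(p) == ("p", "ACGT")

    def test_multi_record_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(FormatError):
            ingest.read_single_fasta(p)

    def test_non_nucleotide_characters_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGX\n")
        with pytest.raises(AlphabetError):
            ingest.read_single_fasta(p)

    def test_empty_sequence_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\n\n")
        with pytest.raises(ValidationError):
            ingest.read_single_fasta(p)


class TestBuiltinGeneCaller:
    def test_planted_genes_recovered_exactly(self):
        _, truth = make_synthetic_phage(seed=5, n_genes=8, with_terminase="large")
        called = {
            (d.start, d.stop, d.strand)
            for d in ingest.call_genes_builtin(truth.sequence)
        }
        planted = {(g.start, g.stop, g.strand) for g in truth.genes}
        assert called == planted

    def test_minus_strand_gene_recovered_with_planted_protein(self):
        _, truth = make_synthetic_phage(seed=6, n_genes=8, with_terminase="none")
        minus = [g for g in truth.genes if g.strand == "-"]
        assert minus, "fixture should plant at least one minus-strand gene"
        drafts = {
            (d.start, d.stop, d.strand): d
            for d in ingest.call_genes_builtin(truth.sequence)
        }
        for gene in minus:
            draft = drafts[(gene.start, gene.stop, gene.strand)]
            assert (
                ingest.translate_cds(truth.sequence, draft.start, draft.stop, draft.strand)
                == gene.protein
            )

    def test_all_n_sequence_yields_nothing(self):
        assert ingest.call_genes_builtin("N" * 500) == []

    def test_nested_same_frame_orfs_resolve_to_longest(self):
        # two in-frame ATGs, one stop: the earlier start wins
        seq = "ATG" + "ATG" + "AAA" * 40 + "TAA"
        (orf,) = ingest.call_genes_builtin(seq, min_aa_len=10)
        assert (orf.start, orf.stop) == (0, len(seq))


class TestTranslateCds:
    def test_simple_plus_strand(self):
        assert ingest.translate_cds("ATGAAATAA", 0, 9, "+") == "MK"

    def test_minus_strand_reverse_complement(self):
        # revcomp("TTACATCAT") == "ATGATGTAA" -> "MM"
        assert ingest.translate_cds("TTACATCAT", 0, 9, "-") == "MM"

    def test_internal_stop_is_an_error(self):
        with pytest.raises(TranslationError):
            ingest.translate_cds("ATGTAAAAATAA", 0, 12, "+")

    def test_alternative_start_codon_translates_to_methionine(self):
        assert ingest.translate_cds("GTGAAATAA", 0, 9, "+") == "MK"

    def test_wrapping_cds(self):
        genome = "AAATAAXXXATG".replace("X", "C")  # ATG at 9 wraps to AAA TAA
        assert ingest.translate_cds(genome, 9, 6, "+", wraps_origin=True) == "MK"


class TestTerminalRepeats:
    def test_basic_arithmetic(self):
        a, b = ingest.add_terminal_repeats(1000, 50)
        assert (a.start, a.stop) == (0, 50)
        assert (b.start, b.stop) == (950, 1000)
        assert a.kind == b.kind == "repeat_region"

    def test_half_genome_rejected(self):
        with pytest.raises(ValidationError):
            ingest.add_terminal_repeats(100, 50)

    def test_minimal_repeat(self):
        a, b = ingest.add_terminal_repeats(1000, 1)
        assert (a.start, a.stop, b.start, b.stop) == (0, 1, 999, 1000)


class TestUserFeatures:
    def test_gff3_coordinates_converted(self):
        (draft,) = ingest.load_user_features("g\t.\tCDS\t1\t99\t.\t+\t.\tID=x")
        assert (draft.start, draft.stop, draft.strand) == (0, 99, "+")

    def test_out_of_range_rejected_with_line(self):
        with pytest.raises(FormatError, match="line 1"):
            ingest.load_user_features("g\t.\tCDS\t1\t99\t.\t+\t.", genome_length=50)

    def test_unsupported_kind_skipped(self):
        drafts = ingest.load_user_features(
            "g\t.\tgene\t1\t99\t.\t+\t.\ng\t.\tCDS\t1\t99\t.\t+\t."
        )
        assert [d.kind for d in drafts] == ["CDS"]

    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(FormatError, match="multiple of 3"):
            ingest.load_user_features("g\t.\tCDS\t1\t100\t.\t+\t.")

    def test_five_column_table_accepted(self):
        (draft,) = ingest.load_user_features("g\ttRNA\t10\t85\t-")
        assert (draft.kind, draft.start, draft.stop, draft.strand) == ("tRNA", 9, 85, "-")


class TestExternalCallers:
    def test_glimmer_predict_parsed(self, tmp_path):
        out = tmp_path / "run.predict"
        out.write_text(
            ">genome\norf00001      101      403  +1     9.12\n"
            "orf00002      900      550  -2     4.50\n"
        )
        drafts = ingest.run_external_caller(
            "ACGT", "glimmer", {"glimmer": {"recorded_output": str(out)}}
        )
        assert (drafts[0].start, drafts[0].stop, drafts[0].strand) == (100, 403, "+")
        assert (drafts[1].start, drafts[1].stop, drafts[1].strand) == (549, 900, "-")
        assert all(d.source == "external_caller" for d in drafts)

    def test_trnascan_output_parsed(self, tmp_path):
        out = tmp_path / "trna.txt"
        out.write_text(
            "Sequence\t\ttRNA\t...\nName    \ttRNA #\tBegin\tEnd\tType\n"
            "--------\t------\t-----\t---\t----\n"
            "genome\t1\t120\t192\tLeu\tCAA\t0\t0\t55.0\n"
            "genome\t2\t400\t330\tSer\tGCT\t0\t0\t60.1\n"
        )
        drafts = ingest.run_external_caller(
            "ACGT", "trnascan", {"trnascan": {"recorded_output": str(out)}}
        )
        assert [d.kind for d in drafts] == ["tRNA", "tRNA"]
        assert (drafts[0].start, drafts[0].stop, drafts[0].strand) == (119, 192, "+")
        assert (drafts[1].start, drafts[1].stop, drafts[1].strand) == (329, 400, "-")

    def test_unconfigured_adapter_unavailable(self):
        with pytest.raises(AdapterUnavailableError):
            ingest.run_external_caller("ACGT", "glimmer", {})


def _call_and_translate(sequence):
    drafts = ingest.call_genes_builtin(sequence)
    proteins = [
        ingest.translate_cds(sequence, d.start, d.stop, d.strand) for d in drafts
    ]
    return drafts, proteins


class TestDetectTerminase:
    def test_planted_large_subunit_found(self):
        _, truth = make_synthetic_phage(seed=9, n_genes=6, with_terminase="large")
        db = make_terminase_db(truth, seed=10)
        call = ingest.detect_terminase(*_call_and_translate(truth.sequence), db)
        gene = truth.gene_with_role("terminase_large")
        assert call is not None
        assert call.subunit == "large"
        assert (call.feature.start, call.feature.stop) == (gene.start, gene.stop)
        assert call.best_evalue <= 1e-10
        assert call.query_coverage >= 0.5

    def test_upstream_subunit_selected_when_both_present(self):
        _, truth = make_synthetic_phage(seed=9, n_genes=6, with_terminase="both")
        db = make_terminase_db(truth, seed=10)
        call = ingest.detect_terminase(*_call_and_translate(truth.sequence), db)
        small = truth.gene_with_role("terminase_small")
        large = truth.gene_with_role("terminase_large")
        assert small.start < large.start  # operon-like fixture layout
        assert call.subunit == "small"
        assert call.feature.start == small.start

    def test_decoy_only_database_yields_none(self):
        _, truth = make_synthetic_phage(seed=9, n_genes=4, with_terminase="none")
        db = make_terminase_db(truth, seed=10, n_decoys=6)
        assert ingest.detect_terminase(*_call_and_translate(truth.sequence), db) is None


class TestReorient:
    def test_rotation_modular_arithmetic(self):
        terminase = FeatureDraft("CDS", 300, 600, "+")
        other = FeatureDraft("CDS", 500, 800, "+")
        seq = "ACGT" * 250  # N = 1000
        new_seq, feats = ingest.reorient_genome(seq, [terminase, other], terminase)
        assert new_seq == seq[300:] + seq[:300]
        remapped = {(f.start, f.stop) for f in feats}
        assert (0, 300) in remapped and (200, 500) in remapped

    def test_minus_strand_terminase_ends_at_origin_forward(self):
        _, truth = make_synthetic_phage(
            seed=11, n_genes=6, with_terminase="large", permute=True, rc=True
        )
        drafts, proteins = _call_and_translate(truth.sequence)
        db = make_terminase_db(truth, seed=12)
        call = ingest.detect_terminase(drafts, proteins, db)
        assert call.feature.strand == "-"
        new_seq, feats = ingest.reorient_genome(truth.sequence, drafts, call)
        assert new_seq == truth.canonical_sequence
        anchor = min((f for f in feats if f.kind == "CDS"), key=lambda f: f.start)
        assert (anchor.start, anchor.strand) == (0, "+")

    def test_conservation_of_length_counts_and_translations(self):
        _, truth = make_synthetic_phage(seed=13, n_genes=8, with_terminase="large", permute=True)
        drafts, proteins = _call_and_translate(truth.sequence)
        call = ingest.detect_terminase(
            drafts, proteins, make_terminase_db(truth, seed=14)
        )
        new_seq, feats = ingest.reorient_genome(truth.sequence, drafts, call)
        assert len(new_seq) == len(truth.sequence)
        assert len(feats) == len(drafts)
        n = len(new_seq)
        assert sorted(f.length(n) for f in feats) == sorted(
            d.length(n) for d in drafts
        )
        new_proteins = [
            ingest.translate_cds(
                new_seq, f.start, f.stop, f.strand, wraps_origin=f.wraps_origin
            )
            for f in feats
        ]
        assert sorted(new_proteins) == sorted(proteins)

    def test_reorient_is_idempotent(self):
        _, truth = make_synthetic_phage(seed=15, n_genes=6, with_terminase="large")
        drafts, _ = _call_and_translate(truth.sequence)
        anchor = min(drafts, key=lambda d: d.start)
        seq1, feats1 = ingest.reorient_genome(truth.sequence, drafts, anchor)
        anchor1 = min(feats1, key=lambda d: d.start)
        seq2, feats2 = ingest.reorient_genome(seq1, feats1, anchor1)
        assert seq2 == seq1 and feats2 == feats1

    def test_feature_split_by_rotation_wraps_origin(self):
        terminase = FeatureDraft("CDS", 300, 600, "+")
        straddler = FeatureDraft("CDS", 250, 379, "+")  # spans the future origin
        seq = "ACGT" * 250  # N = 1000
        _, feats = ingest.reorient_genome(seq, [terminase, straddler], terminase)
        (wrapped,) = [f for f in feats if f.wraps_origin]
        assert (wrapped.start, wrapped.stop) == (950, 79)
        assert wrapped.length(1000) == 129

    def test_foreign_feature_rejected(self):
        with pytest.raises(ValidationError):
            ingest.reorient_genome(
                "ACGT" * 10, [FeatureDraft("CDS", 0, 9, "+")], FeatureDraft("CDS", 3, 12, "+")
            )


class TestUpload:
    def test_upload_creates_unannotated_cds_annotations(self, store, phage):
        path, truth = phage
        genome = ingest.upload_genome(store, path, "Toy phage", UploadOptions(mode="phage"))
        cds = [f for f in genome.features if f.kind == "CDS"]
        assert len(cds) == len(truth.genes)
        flags = {store.get_annotation(f.accession).flag for f in cds}
        assert flags == {"UNANNOTATED"}

    def test_second_upload_creates_no_new_annotations(self, store, phage):
        path, _ = phage
        ingest.upload_genome(store, path, "first", UploadOptions(mode="phage"))
        n = store.counts()["annotation"]
        ingest.upload_genome(store, path, "second", UploadOptions(mode="phage"))
        assert store.counts()["annotation"] == n
        # same accessions seen from both genomes
        a = {f.accession for f in store.get_genome("first").features}
        b = {f.accession for f in store.get_genome("second").features}
        assert a == b

    def test_assignment_applied_to_new_annotations(self, store, phage):
        path, _ = phage
        genome = ingest.upload_genome(
            store, path, "Toy", UploadOptions(mode="phage", assign_to="bob")
        )
        for f in genome.features:
            assert store.get_annotation(f.accession).assigned_to == "bob"

    def test_duplicate_name_rejected(self, store, phage):
        path, _ = phage
        ingest.upload_genome(store, path, "Toy", UploadOptions(mode="phage"))
        with pytest.raises(UniquenessError):
            ingest.upload_genome(store, path, "Toy", UploadOptions(mode="phage"))

    def test_failed_upload_leaves_store_unchanged(self, store, tmp_path, phage):
        path, _ = phage
        before = store.counts()
        features = tmp_path / "bad.gff3"
        # internal stop codon: translation fails after feature loading
        genome_fa = tmp_path / "g.fa"
        genome_fa.write_text(">g\nATGTAATAA\n")
        features.write_text("g\t.\tCDS\t1\t9\t.\t+\t.")
        with pytest.raises(TranslationError):
            ingest.upload_genome(
                store, genome_fa, "bad",
                UploadOptions(mode="custom", features_path=str(features)),
            )
        assert store.counts() == before
        assert not store.has_genome("bad")

    def test_reorienting_upload_restores_canonical_sequence(self, store, tmp_path):
        fasta, truth = make_synthetic_phage(
            seed=21, n_genes=8, with_terminase="large", permute=True
        )
        p = tmp_path / "perm.fa"
        p.write_text(fasta)
        genome = ingest.upload_genome(
            store, p, "perm",
            UploadOptions(
                mode="phage", reorient_terminase=True,
                terminase_db=make_terminase_db(truth, seed=22),
            ),
        )
        assert genome.sequence == truth.canonical_sequence

    def test_dtr_features_added(self, store, tmp_path, phage):
        path, truth = phage
        genome = ingest.upload_genome(
            store, path, "dtr", UploadOptions(mode="phage", dtr_length=25)
        )
        repeats = [f for f in genome.features if f.kind == "repeat_region"]
        n = len(genome.sequence)
        assert {(f.start, f.stop) for f in repeats} == {(0, 25), (n - 25, n)}

    def test_dtr_in_bacterial_mode_rejected(self, store, phage):
        path, _ = phage
        with pytest.raises(ValidationError):
            ingest.upload_genome(
                store, path, "b", UploadOptions(mode="bacterial", dtr_length=10)
            )
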