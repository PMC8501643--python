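"""Parsers, the builtin search vs a brute-force alignment oracle, internal DB."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from manna import homology, ingest
from manna.errors import (
    AdapterUnavailableError,
    ConfigurationError,
    FormatError,
    ValidationError,
)
from manna.fixtures import make_synthetic_phage, _hhr_text
from manna.homology import (
    BuiltinBackend,
    Hit,
    RecordedBackend,
    builtin_protein_search,
    parse_blast_tabular,
    parse_hhr,
    rebuild_internal_db,
    run_genome_searches,
    run_search,
    smith_waterman,
    write_blast_tabular,
)
from manna.ingest import UploadOptions, upload_genome

AA = "ACDEFGHIKLMNPQRSTVWY"

# --- independent brute-force affine Smith-Waterman oracle -------------------
# Written against the scoring definition (BLOSUM62, first gap column costs the
# open penalty, later columns the extend penalty), not against the
# implementation.

import biotite.sequence.align as _ba
import biotite.sequence as _bs

_MAT = _ba.SubstitutionMatrix.std_protein_matrix()
_IDX = {str(sym): i for i, sym in enumerate(_MAT.get_alphabet1())}
_SCORES = _MAT.score_matrix()


def _blosum(a: str, b: str) -> int:
    return int(_SCORES[_IDX[a], _IDX[b]])


def sw_oracle(query: str, subject: str, open_pen: int = 11, ext_pen: int = 1) -> int:
    """Exhaustive O(nm) affine-gap local alignment DP; returns the best score."""
    n, m = len(query), len(subject)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - open_pen, E[i - 1][j] - ext_pen)
            F[i][j] = max(H[i][j - 1] - open_pen, F[i][j - 1] - ext_pen)
            H[i][j] = max(
                0, H[i - 1][j - 1] + _blosum(query[i - 1], subject[j - 1]),
                E[i][j], F[i][j],
            )
            best = max(best, H[i][j])
    return best


def _random_protein(rng, lo=5, hi=40):
    return "".join(rng.choice(AA) for _ in range(rng.randint(lo, hi)))


class TestBuiltinAligner:
    def test_textbook_pair_matches_oracle(self):
        raw = smith_waterman("HEAGAWGHEE", "PAWHEAE")[0]
        assert raw == sw_oracle("HEAGAWGHEE", "PAWHEAE")

    def test_scores_match_oracle_on_random_pairs(self):
        rng = random.Random(1234)
        for _ in range(60):
            q, s = _random_protein(rng), _random_protein(rng)
            res = smith_waterman(q, s)
            got = res[0] if res else 0
            assert got == sw_oracle(q, s), (q, s)

    def test_self_hit_is_rank_one_and_full_length(self):
        rng = random.Random(7)
        target = _random_protein(rng, 30, 40)
        db = [("SELF", "the query itself", target)] + [
            (f"R{i}", "random", _random_protein(rng, 30, 40)) for i in range(5)
        ]
        hits = builtin_protein_search(target, db)
        assert hits[0].subject_id == "SELF"
        assert (hits[0].q_start, hits[0].q_end) == (1, len(target))
        assert (hits[0].s_start, hits[0].s_end) == (1, len(target))

    def test_unrelated_random_proteins_give_no_hits_at_strict_cutoff(self):
        rng = random.Random(99)
        db = [(f"R{i}", "random", _random_protein(rng, 100, 150)) for i in range(8)]
        query = _random_protein(rng, 100, 150)
        assert builtin_protein_search(query, db, max_evalue=1e-6) == []

    def test_empty_query_rejected(self):
        with pytest.raises(ValidationError):
            builtin_protein_search("", [("a", "", "MKL")])
        with pytest.raises(ConfigurationError):
            builtin_protein_search("MKL", [])

    def test_evalue_monotone_decreasing_in_bit_score(self):
        evalues = [homology.expect_value(bits, 200, 10000) for bits in range(10, 100, 5)]
        assert all(a > b for a, b in zip(evalues, evalues[1:]))


BLAST_ROW = (
    "q1\tSP_P1\t97.5\t200\t5\t0\t1\t200\t1\t200\t3e-42\t180.2\t200\tterminase large subunit"
)


class TestBlastTabular:
    def test_single_row_parsed(self):
        (hit,) = parse_blast_tabular(BLAST_ROW)
        assert hit.evalue == 3e-42
        assert hit.subject_length == 200
        assert hit.subject_description == "terminase large subunit"

    def test_comment_lines_skipped_in_outfmt7(self):
        text = "# BLASTP 2.12.0\n# Fields: ...\n" + BLAST_ROW + "\n"
        assert len(parse_blast_tabular(text, has_comments=True)) == 1
        with pytest.raises(FormatError):
            parse_blast_tabular(text, has_comments=False)

    def test_reversed_query_coordinates_rejected(self):
        bad = BLAST_ROW.replace("\t1\t200\t1\t200\t", "\t200\t1\t1\t200\t")
        with pytest.raises(FormatError, match="qstart"):
            parse_blast_tabular(bad)

    def test_wrong_column_count_names_dialect(self):
        with pytest.raises(FormatError, match="slen stitle"):
            parse_blast_tabular("a\tb\tc\n")

    def test_hits_sorted_by_evalue(self):
        rows = "\n".join(
            BLAST_ROW.replace("3e-42", e) for e in ("1e-5", "1e-50", "1e-20")
        )
        hits = parse_blast_tabular(rows)
        assert [h.evalue for h in hits] == [1e-50, 1e-20, 1e-5]

    def test_round_trip_through_writer(self):
        hits = parse_blast_tabular(BLAST_ROW)
        again = parse_blast_tabular(write_blast_tabular(hits, query_id="q1"))
        assert again == hits


class TestHhr:
    def _text(self):
        return _hhr_text(
            "q1", 150,
            [
                ("1ABC_A", "portal protein", 99.1, 1.2e-30, 160, (1, 145, 5, 150)),
                ("2DEF_B", "unrelated coil", 45.0, 0.5, 80, (10, 60, 1, 55)),
            ],
        )

    def test_two_hits_ordered_by_probability(self):
        hits = parse_hhr(self._text())
        assert [h.score for h in hits] == [99.1, 45.0]
        assert hits[0].evalue == pytest.approx(1.2e-30)
        assert hits[0].subject_description == "portal protein"
        assert (hits[0].q_start, hits[0].q_end) == (1, 145)
        assert (hits[0].s_start, hits[0].s_end) == (5, 150)
        assert hits[0].subject_length == 160

    def test_empty_hit_list(self):
        text = self._text().split(" No Hit")[0] + " No Hit  Prob E-value P-value  Score    SS Cols Query HMM  Template HMM\n\n"
        assert parse_hhr(text) == []

    def test_truncated_table_reports_line(self):
        lines = self._text().splitlines()
        lines[9] = lines[9][:40]  # mangle the first summary row
        with pytest.raises(FormatError, match="line"):
            parse_hhr("\n".join(lines))

    def test_missing_header_is_format_error(self):
        with pytest.raises(FormatError, match="summary header"):
            parse_hhr("Query q1\njust noise\n")


def _upload_fixture(store, tmp_path, seed=31, name="g", n_genes=6):
    fasta, truth = make_synthetic_phage(seed=seed, n_genes=n_genes, with_terminase="none")
    p = tmp_path / f"{name}.fa"
    p.write_text(fasta)
    return upload_genome(store, p, name, UploadOptions(mode="phage")), truth


class TestRunSearch:
    def test_unsupported_combination_rejected(self, store, tmp_path):
        genome, _ = _upload_fixture(store, tmp_path)
        acc = genome.features[0].accession
        with pytest.raises(ValidationError, match="unsupported"):
            run_search(store, acc, "blastp", "cdd", BuiltinBackend(store=store))

    def test_rerun_supersedes_stored_result(self, store, tmp_path):
        genome, _ = _upload_fixture(store, tmp_path)
        acc = next(f.accession for f in genome.features if f.kind == "CDS")
        backend = BuiltinBackend(store=store)
        run_search(store, acc, "blastp", "internal", backend)
        run_search(store, acc, "blastp", "internal", backend)
        assert len(store.search_results_for(acc)) == 1

    def test_stale_internal_db_rebuilt_before_search(self, store, tmp_path):
        genome, _ = _upload_fixture(store, tmp_path)
        accs = [f.accession for f in genome.features if f.kind == "CDS"]
        target, other = accs[0], accs[1]
        store.update_annotation(other, {"label": "portal protein"}, user="u")
        assert store.internal_db_stale
        backend = BuiltinBackend(store=store)
        result = run_search(store, target, "blastp", "internal", backend)
        assert not store.internal_db_stale
        descriptions = " ".join(h.subject_description for h in result.hits)
        assert "portal protein" in descriptions

    def test_internal_search_never_returns_the_query_itself(self, store, tmp_path):
        genome, _ = _upload_fixture(store, tmp_path)
        acc = next(f.accession for f in genome.features if f.kind == "CDS")
        result = run_search(store, acc, "blastp", "internal", BuiltinBackend(store=store))
        assert acc not in {h.subject_id for h in result.hits}


class TestGenomeSearches:
    def test_cardinality(self, store, tmp_path):
        genome, truth = _upload_fixture(store, tmp_path)
        n_cds = len({f.accession for f in genome.features if f.kind == "CDS"})
        files = {
            ("blastp", "swissprot"): {"*": ""},
            ("blastp", "nr"): {"*": ""},
        }
        summary = run_genome_searches(
            store, "g", [("blastp", "swissprot"), ("blastp", "nr")],
            RecordedBackend(files),
        )
        assert len(summary.results) == 2 * n_cds
        assert summary.failures == []

    def test_missing_adapter_collected_not_fatal(self, store, tmp_path):
        genome, _ = _upload_fixture(store, tmp_path)
        n_cds = len({f.accession for f in genome.features if f.kind == "CDS"})
        summary = run_genome_searches(
            store, "g", [("blastp", "internal"), ("hhsearch", "pdb")],
            BuiltinBackend(store=store),
        )
        assert len(summary.results) == n_cds
        assert len(summary.failures) == n_cds

    def test_genome_without_cds_yields_nothing(self, store):
        store.add_genome("bare", "TTAA" * 50)
        summary = run_genome_searches(
            store, "bare", [("blastp", "internal")], BuiltinBackend(store=store)
        )
        assert summary.results == [] and summary.failures == []


class TestInternalDb:
    def test_one_entry_per_distinct_protein_across_genomes(self, store, tmp_path):
        _upload_fixture(store, tmp_path, seed=31, name="g1")
        _upload_fixture(store, tmp_path, seed=31, name="g2")  # identical genome
        db = rebuild_internal_db(store)
        assert len(db.entries) == len(store.distinct_proteins())

    def test_label_edit_reflected_after_rebuild(self, store, tmp_path):
        genome, _ = _upload_fixture(store, tmp_path)
        acc = genome.features[0].accession
        store.update_annotation(acc, {"label": "holin", "flag": "GREEN"}, user="u")
        db = rebuild_internal_db(store)
        entry = db.entries[store.get_annotation(acc).sequence]
        assert entry == (acc, "holin", "GREEN")
        assert not db.stale

    def test_flag_encoded_in_fasta_headers(self, store, tmp_path):
        genome, _ = _upload_fixture(store, tmp_path)
        acc = genome.features[0].accession
        store.update_annotation(acc, {"flag": "RED", "label": "toxin"}, user="u")
        fasta = rebuild_internal_db(store).to_fasta()
        assert f">{acc}|RED|toxin" in fasta
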