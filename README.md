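# manna

**manna** is a headless, scriptable workbench for the *manual functional
annotation* of phage and bacterial genomes — the stage after gene calling
where a curator decides what each predicted protein actually is. Automated
annotators are convenient but manual curation, weighing evidence from
several homology tools and databases side by side, still produces the most
accurate product names. manna gives that workflow structure: it ingests
unannotated genomes, models features and sequence-deduplicated annotations
with flags and full edit history, collects homology evidence per
(tool, database), recommends labels through an encoded decision guide, and
exports annotated genomes in standard formats. It is aimed at phage
biologists and microbial genomics groups who want a reproducible,
pipeline-friendly curation store rather than a web application.

## The model

Three entities, persisted in a single-file relational store:

* **genome** — one uploaded nucleotide sequence;
* **feature** — a located CDS / tRNA / repeat region on one genome;
* **annotation** — the curated record (auto-assigned accession `MAS_0000001`,
  …, label, flag, public/private notes, user assignment), keyed by sequence.

Two features whose sequences are identical share one annotation, so a
protein conserved across twenty phage uploads is curated exactly once.
Every edit is an append-only event; replaying an annotation's history
reconstructs its current state.

Around that core:

* **Upload** — automated gene calling (builtin maximal-ORF caller with start
  codons ATG/GTG/TTG and table-11 translation, or Glimmer / tRNAscan-SE
  adapters), user-supplied coordinates (GFF3/TSV), direct-terminal-repeat
  features, and terminase-based re-orientation: candidate terminases are
  CDSs whose best hit against a terminase database has E ≤ 10⁻¹⁰ and query
  coverage ≥ 0.5; the genome is rotated (reverse-complemented first if
  needed) so the terminase — or the upstream subunit, when both packaging
  subunits are present — starts at coordinate 0.
* **Evidence** — parsers for NCBI BLAST tabular (`outfmt 6 std slen stitle`)
  and HH-suite `.hhr` reports; a builtin Smith–Waterman search (BLOSUM62,
  affine gaps 11/1) with Karlin–Altschul statistics
  S′ = (λS − ln K)/ln 2, E = mn·2^(−S′) (λ = 0.267, K = 0.041); and an
  auto-refreshing *internal database* of every curated protein, headers
  encoded `accession|flag|label` for naming consistency and self-review.
* **Decision guide** — twelve ordered procedures mapping an evidence summary
  (significance, consistency within and across databases, length similarity,
  coverage classes) to a suggested label and flag, from "hypothetical
  protein" with no evidence through "`<DOMAIN>` domain-containing protein",
  "putative "-prefixed moderate evidence, internal-database label reuse, and
  review flags for inconsistent or partial-coverage evidence. Suggestions
  are applied only on explicit accept, through the normal history-recording
  edit path.
* **Export** — GenBank, GFF3, FASTA, CDS translations and an annotation
  table (TSV/XLSX), singly or as a reproducible tarball bundle; private
  notes never leave the annotation table.

See `docs/methods.md` for every threshold, convention and design choice.

## Worked example

Everything below is offline and self-contained: the fixtures module
generates a circularly permuted synthetic phage genome with known ground
truth, a matching terminase database, and mock homology-result files (in
real use the blastp/rpsblast/hhsearch adapters fill that role).

```python
from pathlib import Path
from manna import fixtures, ingest, evidence, homology, decision, io_export, open_store

fasta, truth = fixtures.make_synthetic_phage(
    seed=11, n_genes=8, with_terminase="both", permute=True
)
Path("phage.fasta").write_text(fasta)
Path("terminase.faa").write_text(fixtures.make_terminase_db(truth, seed=12))

store = open_store("demo.sqlite")
genome = ingest.upload_genome(
    store, "phage.fasta", "Pseudomonas phage Demo11",
    ingest.UploadOptions(
        mode="phage", reorient_terminase=True, terminase_db="terminase.faa",
    ),
)
print(f"{genome.name}: {len(genome)} bp, {len(genome.features)} CDS features")
print("re-oriented to canonical form:", genome.sequence == truth.canonical_sequence)

# map each planted gene to the accession its protein deduplicated into
by_protein = {a.sequence: a.accession for a in store.distinct_proteins()}
query_ids = [by_protein[g.protein] for g in truth.genes]
files = fixtures.make_mock_results(
    truth, [("blastp", "swissprot"), ("blastp", "nr")], query_ids=query_ids
)
report = homology.run_genome_searches(
    store, genome.name, [("blastp", "swissprot"), ("blastp", "nr")],
    homology.RecordedBackend(files),
)
print(f"{len(report.results)} searches completed, {len(report.failures)} failed")

for feat in [f for f in genome.features if f.kind == "CDS"][:3]:
    rec = decision.recommend(evidence.summarize_evidence(store, feat.accession))
    decision.apply_recommendation(store, rec, user="demo")
    print(f"{feat.accession} {rec.procedure:>3}: {rec.final_label!r}")

io_export.export_bundle(store, genome.name, "demo_bundle.tar.gz")
```

Output:

```
Pseudomonas phage Demo11: 2490 bp, 8 CDS features
re-oriented to canonical form: True
16 searches completed, 0 failed
MAS_0000001  P7: 'terminase small subunit'
MAS_0000002  P7: 'terminase large subunit'
MAS_0000003  P1: 'hypothetical protein'
```

The uploaded genome was rotated back to its canonical form anchored at the
small terminase subunit (the upstream of the two packaging genes). The first
two proteins had significant, consistent, full-length Swiss-Prot and nr
evidence, so procedure P7 adopts the Swiss-Prot label verbatim; the third
had no results, so P1 labels it "hypothetical protein". Accepting each
suggestion wrote it through the history-recording edit path, and the bundle
contains the genome FASTA, CDS translations, GFF3, annotation table and
GenBank file.

The same workflow is available from a shell via the `manna` console script
(`manna upload-phage`, `search`, `suggest`, `set`, `list`, `export`,
`import-annotations`, `map`; see `manna --help`).

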