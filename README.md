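# peptaxon

Database-independent taxonomic attribution of degraded proteomes from de novo
peptide lists, with a reference-based marker/substitution track and a seeded
synthetic data generator for end-to-end validation.

Degraded biomineral samples (e.g. ancient mollusc shell) yield sparse, noisy
de novo peptide lists that rarely match sequence databases directly. This
package implements two complementary comparison routes:

* **peptide-list similarity** — samples are compared by the canonical peptides
  they share (overlap coefficient by default, Jaccard optional), under
  I/L equivalence and deamidation-tolerant residue mapping (N→D, Q→E); the
  all-pairwise similarity matrix is converted to distances and embedded with
  classical (Torgerson) MDS, and per-query attributions rank reference
  samples by similarity;
* **reference-based matching** — peptides are placed on reference protein
  sequences allowing at most one internal mismatch, yielding per-residue
  coverage, tiered protein calls (stringent: ≥ 2 unique peptides; relaxed:
  ≥ 1, asterisk-flagged), candidate amino-acid substitution calls
  (`-` uncovered, `?` ambiguous, residue letter otherwise), and chord-diagram
  adjacency weights for shared proteins.

A spectrum-level comparison (greedy-paired cosine over fragment peaks,
precursor-gated) provides an independent cross-check, and the
`peptaxon.synthetic` module generates ground-truthed reference panels —
taxa sharing repeated low-complexity blocks verbatim but diverging in unique
segments — and degraded samples (trypsin/elastase digestion, biased peptide
loss, deamidation, near-isobaric sequencing errors, ALC scores).

## CLI

```bash
# generate a 4-taxon synthetic panel with 2 samples per taxon
peptaxon simulate --seed 7 --samples-per-taxon 2 --out panel/

# full pipeline: prep -> match -> similarity -> MDS -> adjacency -> attribution
peptaxon attribute panel/taxon01_s1.tsv \
    --references panel/references.fasta --digest-references \
    --out run1/
peptaxon report run1/report.json

# individual stages
peptaxon prep panel/taxon01_s1.tsv --out prep.tsv
peptaxon match panel/taxon01_s1.tsv --references panel/references.fasta --out match/
peptaxon similarity panel/*_s1.tsv --out sim.tsv
peptaxon mds sim.tsv --out mds.tsv --plot mds.png
peptaxon spectra panel/taxon01_s1.tsv --out spectra.mgf
```

Exit codes: 0 success, 2 input error, 3 insufficient-data outcome.

File formats: peptide tables are TSV with header
`sample_id  peptide  alc  mods  charge  enzyme` (mods as `pos:kind;...`);
references are FASTA with `entry_id|taxon|clade[|marker]` headers; spectra
are MGF; matrices are labelled TSV.

## Layout

| module | contents |
| --- | --- |
| `peptaxon.formats_io` | TSV/FASTA/MGF/matrix readers & writers, domain records |
| `peptaxon.peptide_prep` | ALC filter, contaminant removal, canonicalization, collapse |
| `peptaxon.reference_matching` | substitution-tolerant placement, coverage, protein & substitution calls |
| `peptaxon.proteome_similarity` | pairwise similarity, distance, classical MDS, attribution, adjacency |
| `peptaxon.spectral_similarity` | peak-paired cosine, sample-level spectral similarity |
| `peptaxon.synthetic` | reference-panel generator, in-silico digestion, degradation model, spectra |
| `peptaxon.cli` | `peptaxon` command-line interface and pipeline orchestration |
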