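# diagnostax

Character-based DNA-barcode diagnosis and morphological identification
tooling for NE Atlantic trichobranchid annelids (*Terebellides*).

The package implements an integrative species-diagnosis pipeline:

* **`msa_io`** — aligned FASTA and species-map (TSV) I/O with a single
  internal alphabet (uppercase, `U`→`T`, IUPAC codes retained) and 1-based
  inclusive column coordinates throughout.
* **`diagnostics`** — extraction of per-species diagnostic nucleotide
  combinations from a labeled COI alignment (within-species invariant
  columns, strictly diagnostic columns, maximal-run region assembly),
  verification of a diagnosis against an alignment, greedy minimisation,
  and a tolerant-but-flagging parser/formatter for the printed
  `start–end: MOTIF` diagnosis dialect.
* **`identify_molecular`** — placement of raw (unaligned) queries into
  reference coordinates via global Needleman–Wunsch alignment against the
  majority-rule consensus (match +1 / mismatch −1 / gap −2, deterministic
  tie-breaking), identification against diagnosis profiles, uncorrected
  p-distance matrices and single-linkage threshold clustering.
  Queries are assumed forward-strand barcodes — **no reverse-complement
  search is performed**.
* **`morphology`** — uncini (thoracic types 1/3/4, abdominal 1A/2),
  branchiae (types 1–4) and Methyl-Green staining (patterns 1/2/9)
  typologies with configurable numeric thresholds; a taxon×character
  matrix identifier; and an 18-couplet dichotomous key engine (bundled
  YAML resources encode the matrix and the key).
* **`synthetic_data`** — simulators for alignments with *planted, known*
  diagnostic structure (emitting a machine-readable truth set) and for
  specimen morphology drawn from the published per-species ranges.
* **`registry`** — parser for museum specimen listings
  (`ZMBN`/`GNM`/`NTNU-VM` codes, bare numbers inheriting the preceding
  prefix), holotype measurement extraction, and specimen-weighted
  depth-cutoff summaries.

Printed data fixtures (diagnosis blocks, material-examined listings,
holotype description) ship under `src/diagnostax/resources/printed/`.

## Command line

A single `diagnostax` entry point exposes the pipeline:

```sh
# extract diagnoses from a labeled alignment
diagnostax diagnose --alignment aln.fasta --species map.tsv --out profiles.yaml

# parse a printed diagnosis block and report structural flags
diagnostax validate-block --block block.txt

# reduce verified profiles to minimal covering region subsets
diagnostax minimize --profiles profiles.yaml --alignment aln.fasta --species map.tsv

# identify unaligned queries (forward strand only!)
diagnostax identify --query q.fasta --profiles profiles.yaml --reference aln.fasta

# run the dichotomous key on observed character states
diagnostax key --answers answers.yaml

# synthetic data
diagnostax simulate alignment --config sim.yaml --out-prefix out/run1
diagnostax simulate specimens --n 20 --seed 1

# specimen listings
diagnostax registry parse --text material.txt
diagnostax registry summarize --text material.txt --cutoff 200
```

## Conventions and caveats

* Alignment columns are 1-based and inclusive everywhere (`78–99` covers
  22 columns).
* A background IUPAC code compatible with the focal state disqualifies a
  column from being diagnostic (conservative); a background gap neither
  matches nor disqualifies.
* Parsed printed diagnosis blocks treat the whole span as
  candidate-diagnostic: the print-only underline marking of the strictly
  diagnostic nucleotides is not machine-readable. The parser flags
  internal inconsistencies (span/motif length mismatches, missing end
  coordinates) without repairing them.
* The synthetic alignment generator guarantees exact planted-truth
  recovery for configs with ≥3 species, zero intraspecific noise and the
  default zero interspecific divergence; with only two species, every
  diagnostic column is symmetric between them.
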