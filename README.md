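# gintools

Detection, delimitation and recombination modelling of a class of mobile
genomic islands defined by a three-integrase (*gin*) operon. The package
implements:

- **genome_io** — GenBank / FASTA+GFF3 reading and writing with a single
  internal coordinate convention (0-based half-open), CDS translation and
  AT-fraction scoring.
- **gin_survey** — a permissive protein-homology survey: explicit local
  alignment (BLOSUM62, affine gaps 11/1) with Karlin–Altschul expectation
  values, detection of three consecutive same-strand CDSs matching the
  GinA/B/C references at E ≤ 0.1 (GinD appended when present, never
  required), pairwise identity matrices, and the R-H-R-H-Y
  tyrosine-recombinase catalytic-motif check.
- **island_delimiter** — island boundary calling around a detected operon:
  imperfect direct-repeat (attL/attR) search of 10–17 nt with up to 3
  mismatches, chance-expectation filtering, tripartite annotation
  (operon / cargo / AT-rich 3′ end), insertion-site classification,
  empty-site location against a reference genome, and sequence-logo
  position profiles.
- **recombination_model** — site-specific integration and excision by 6-nt
  staggered cuts: arm exchange around the overhang, heteroduplex
  resolution toward the element or host template (whole-overhang or
  per-position), excision-product sampling, att identity scoring, and the
  minimal circular element assembler.
- **synthetic_data** — deterministic generators for host genomes with an
  attB-bearing target gene and planted islands whose flanking repeats are
  produced by the integration model, with full ground truth.
- **pipeline_cli** — a `gintools` command with `survey`, `delimit`,
  `recomb`, `synth` and `version` subcommands.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, one test per acceptance
criterion (assembly arithmetic, 50% parental excision spectrum,
brute-force oracle equivalence, synthetic parameter recovery over 100
seeds, the integrate/excise inverse property, and identity monotonicity
of host-resolved variants).

## CLI

```bash
# generate a synthetic genome with a planted island + truth annotation
gintools synth --seed 23 --out-dir demo

# survey + delimit it
gintools delimit --genome demo/genome.fasta --gff3 demo/genome.gff3 --out-dir demo/out

# survey GenBank genomes against your own reference proteins
gintools survey --genomes strain1.gb --refs gin_refs.fasta --out-dir out

# integrate an attI/attB pair and sample 10,000 excision products
gintools recomb --atti GGATCGATCCG --attb GGTTGGAACCG -n 10000 --seed 1
```

Outputs are GFF3 (island with `gin_operon`, `cargo`, `three_prime_end`
and two `direct_repeat` children), TSV summaries and FASTA.

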