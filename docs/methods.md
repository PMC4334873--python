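# Methods

## Scope and model

`genoscore` scores the *completeness* of a prokaryotic genome assembly from
its sequence and from feature predictions made over it. The underlying
assumption is that a completely sequenced genome is one contiguous piece
per replicon, and that near-universal features of prokaryotic genomes —
full-length rRNA genes, tRNAs for all 20 standard amino acids, a panel of
essential protein domains — will be recovered by standard predictors
whenever the sequence containing them is present and intact. Missing
features are therefore read as evidence of missing or broken sequence, not
of genuine biological absence. This assumption fails for a small set of
reduced genomes (endosymbionts genuinely lack tRNAs; some archaea carry
many pseudo-tRNA calls), which is why the score is a screening statistic,
not a verdict on any single genome.

The scorers consume feature predictions, never raw predictions' quality:
adapters parse tRNAscan-SE tabular output, RNAmmer GFF2, Prodigal GFF3 and
HMMER3 `--domtblout` tables into canonical records, and a native
plain-text feature table allows scoring with no external tools. Running
the predictors themselves is out of scope.

## Components and their constants

All constants live in `ScoringConfig` and are overridable; defaults:

| parameter | default | meaning |
|---|---|---|
| `contig_penalty_bp` | 10,000 | denominator bases per contig after the first (drafts) |
| `gap_penalty_bp` | 10,000 | denominator bases per counted N-run |
| `gap_min_run` | 10 | minimum N-run length (in bases) counted as a gap |
| `min/max_retained_size` | 138,500 / 18,000,000 | size-filter bounds, in bp (bounds retained) |
| rRNA ideal windows | 5S 100–120, 16S 1450–1700, 23S 2900–3500 | full-length evidence, bases |
| rRNA tiers | 0.1 base; +0.3 / +0.2 / +0.1 per molecule | ideal / > half-minimum / any prediction |
| `trna_decrement`, floor | 0.1, 0.1 | per missing standard amino acid |
| `essential_decrement`, floor | 0.01, 0.1 | per missing panel domain |

The contig/gap penalty approximates the sequence a break costs: each break
loses on the order of one gene (~1 kb), scaled up tenfold so that an
assembly capturing "only" 90% of genes does not still look high-quality.
Penalties are absolute, so they dilute with genome size — the score is
effectively driven by contigs-per-megabase.

Reading of the rules at edges, fixed here once:

* The N-run threshold is *run length ≥ 10* (`gap_min_run`, configurable):
  the reading embedded in the score definition itself.
* N bases outside counted runs are neither good nor bad; they inflate only
  the assembly's total size.
* Sequences are uppercased on ingest, so soft-masked bases count as good —
  masking is annotation, not sequence quality.
* N runs never span contig boundaries; each contig is scanned alone.
* The *complete*-status exemption removes only the contig penalty; bad-base
  and gap penalties always apply.
* rRNA: the best prediction per molecule type sets its tier (multi-copy
  operons are the norm; one full-length copy demonstrates completeness).
  A prediction longer than the ideal maximum keeps the 0.2 tier but is
  logged, since over-long calls usually flag predictor artifacts or
  N-contaminated rDNA.
* The half-length rRNA tier requires length strictly greater than half the
  window minimum.
* tRNA coverage is decided by the predictor's amino-acid call (never by
  translating the anticodon); pseudo-flagged calls and non-standard types
  (SeC, undetermined) never demonstrate coverage of the 20.
* Essential-domain presence is per distinct version-stripped accession
  (`PF00312.14` ≡ `PF00312`); copies do not add. No E-value threshold is
  applied by default — whatever the producer of the hit table considered a
  hit counts — with an optional independent `max_evalue` cutoff.
* A genome with zero good bases scores 0 on sequence quality, with a
  warning.

### The essential-domain panel

The bundled panel (`data/essential_domains_synthetic.txt`) is a synthetic
stand-in: 102 Pfam-A accessions of broadly conserved prokaryotic families
(ribosomal proteins, translation factors, synthetase classes, RNA
polymerase subunits, core replication/secretion machinery), assembled for
this package rather than taken from any published reference panel. Every
scoring rule depends only on the panel's size and on membership agreement
between panel and hit table, so the published worked values (0.90 at 10
missing of 102, the 0.1 floor) are exact with any 102-entry panel. Users
scoring real genomes should supply the marker list their HMMER scan
actually used, via `essential_domains_file` in the YAML config.

## Cohort standardization

Across a cohort of size ≥ 2 each component is standardized to zero mean
and unit variance — population σ, since the cohort being scored is the
whole universe of interest, not a sample — the four z-scores are averaged,
and the average is min-max rescaled to [0, 1] (the only transform
consistent with "minimum 0, maximum 1" without extra assumptions). A
component with σ = 0 carries no ranking information and contributes z = 0
everywhere. For a single genome, or a cohort whose averaged z-scores are
all identical, the raw combined mean is reported instead.

A property worth knowing: standardization is nearly rank-preserving
(Spearman ρ vs the raw mean ≈ 0.99 in the test cohorts) when degradation is
*correlated* across components — the structure of real repositories, where
finished genomes score well on everything and read-archive assemblies score
poorly on everything. If the four components are degraded independently
with very different spreads, z-averaging reweights them by 1/σ and can
reorder substantially (ρ ≈ 0.8 in simulations). Standardized totals are a
within-cohort ranking; for absolute screening use the raw mean.

## Deduplication and size filtering

An assembly's fingerprint is the MD5 hex digest of the comma-joined,
lexicographically sorted per-contig MD5 digests of the uppercase sequences.
Ids and descriptions are excluded (names drift between repositories) and
sorting makes the fingerprint invariant to contig order. Only byte-identical
assemblies collapse; near-duplicates (different gap treatment, trimmed
contigs) intentionally do not match. Whether upstream pipelines hashed raw
bytes, uppercase or line-wrapped text is generally unknowable, so
cross-repository reproduction of third-party fingerprints is not promised.

Assemblies with total size strictly below 138,500 bp are classified as
stray plasmids, strictly above 18,000,000 bp as eukaryotic; both bounds are
retained. The classification is monotone in size with exactly two
thresholds.

## Anticodon analytics

The anticodon alphabet has 62 members: the reverse complements of the 61
sense codons plus TCA, the selenocysteine anticodon read from the UGA stop.
The default rare set is structural — the 15 anticodons beginning with A
(codons ending in U) other than arginine's ACG — and overridable. Counts
include optional tRNAs (SeC) and exclude pseudo predictions; unknown
anticodons tally under `unknown`, outside the 62. Display of group
percentages matches the score-report convention: whole numbers with exact
halves rounded down for values ≥ 1% (87.5 → 87), one decimal below 1%
(0.1378 → 0.1); exact values are always retained in the data.

## Synthetic generator

The generator emulates exactly the degradation modes the score measures:
fragmentation, N-gap runs, bad bases, missing rRNA/tRNA/domain features. It
does not emulate read errors, repeats, homology or real gene content, so
passing tests demonstrate that the *scoring rules* behave as specified on
genomes with known defect counts — not that the upstream predictors behave
well on real sequence.

Count-valued degradations are placed constructively (exact contig counts,
exact gap runs of fixed length at evenly spaced interior positions, exact
bad-base counts at evenly spaced positions) so unit tests assert exact
scores; only base composition is stochastic. Defaults describe a typical
clean bacterial genome: 4 Mb, 50% GC, one contig, ~1 gene/kb with lengths
~N(950, 150) nt. Tests and examples pass smaller sizes (50 kb–1 Mb)
explicitly; the acceptance script scores a 1 Mb genome. A single integer
seed drives everything; per-genome streams derive from (seed, index), so a
cohort member's content is independent of cohort size and order.
`simulate_cohort` supports group profiles (parameter overrides per group,
assigned round-robin — used to build quality-tier mixtures and per-genus
contrasts) and per-genome jitter ranges for fields a group does not pin.

## Numerical notes

Scores are computed unrounded in double precision; report writers round to
two decimals for display only. The min-max rescale treats `max − min`
below 1e-12 as degenerate. Component floors make each feature score's
attainable values a small lattice (tRNA: {0.1, 0.2, …, 1.0}), which the
tests assert exactly.

## Limitations

Completeness only: contamination, chimerism, misassembly and taxonomic
misidentification are invisible to all four components. The sequence score
saturates for very large, very clean genomes and is insensitive to base
accuracy. Genuinely reduced genomes score poorly without being incomplete.
The bundled domain panel is a stand-in (above). Tool-output parsers target
the classic formats of tRNAscan-SE 1.x tabular, RNAmmer 1.2 GFF2, Prodigal
2.x GFF3 and HMMER3 domtblout; other versions' dialects may need the native
feature-table route.
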