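# Methods

## Scope and data model

The pipeline consumes a merged-assembly annotation (GTF) containing the
reference transcripts plus unannotated assemblies, a reference
annotation with biotypes, genome sequence (FASTA), a per-transcript
count matrix over named samples grouped by cell type, an optional
per-base conservation track, and an optional gene→term map. Internal
coordinates are 0-based half-open everywhere; GTF I/O converts to and
from 1-based inclusive at the file boundary, which keeps all overlap and
distance arithmetic free of off-by-one cases. Chromosome naming is taken
verbatim from the inputs (no dialect normalization), so reference and
assembly must agree on it.

Biotype mapping is configurable; the default maps `protein_coding` to
coding, biotypes containing `lncRNA`/`lincRNA`/`antisense` to annotated
lncRNA, and anything without a recognized biotype (e.g. `MSTRG.*`
assembler ids) to unannotated.

## Novelty cascade

Stages run in a fixed order — length/expression, known-exon overlap,
single-exon distance, coding potential — and each candidate stops at its
first failure, producing a per-transcript decision record with the
failed criteria. Defaults and their rationale:

| parameter | default | meaning |
|---|---|---|
| `min_length` | 200 nt | pass requires length strictly > 200 |
| `min_fpkm` | 0.5 | strictly exceeded in ≥ 1 sample |
| `min_single_exon_distance` | 2000 bp | locus-span gap strictly > 2 kb |
| `coding_score_max` | 0 | score strictly < 0 |
| `stranded_overlap` | off | antisense exon overlap disqualifies |
| `min_exons` | off | optional exon-count floor |

All boundaries are strict: a transcript of exactly 200 nt, an FPKM of
exactly 0.5, a gap of exactly 2000 bp, or a score of exactly 0 fails.
The overlap test is exon-level only (a known exon inside a candidate's
intron does not disqualify), and strand-blind by default as the
conservative reading of "no overlap with known exons"; a `--stranded-overlap`
flag restricts it to same-strand exons. Distance is measured between
locus spans (first exon start to last exon end), not exon to exon,
reading "located > 2 kb away" as a locus-level clearance; both choices
are configurable. The 2 kb rule is applied against known (reference)
single-exon transcripts only. An exon-count filter exists but has no
default threshold, since a defensible universal cutoff does not exist
for merged assemblies; single-exon candidates are instead handled by the
clearance rule.

FPKM is computed from raw counts with per-sample library sizes equal to
the column sums; externally computed FPKM can be supplied and is then
used verbatim.

## Coding-potential scorer

Four features per transcript:

- **ORF length / coverage** — longest ATG→stop ORF over the three
  forward frames, stop codon included, no ORF without a stop; reverse
  frames are not scanned because transcript orientation is already
  resolved by strand. Length enters the model as log1p(ORF nt).
- **Fickett TESTCODE** — the published position and content lookup
  tables and weights (Fickett 1982) embedded as constants; the position
  parameter is max/(min+1) of each base's counts over the three codon
  positions.
- **Hexamer bias** — per-hexamer log((f_cod+ε)/(f_non+ε)) with in-frame
  (step-3) counting and ε = ψ/4096, ψ = 1 by default. The pseudocount is
  applied on the frequency scale so the table is invariant to corpus
  duplication and antisymmetric under corpus swap. The transcript
  feature is the mean log-odds over in-frame hexamer positions of the
  longest ORF, 0 when there is no ORF; hexamers containing N are
  skipped.

The combiner is an unpenalized logistic regression (IRLS via
statsmodels); when the likelihood has no finite maximizer (perfect
separation — the usual case on cleanly simulated corpora), the fit
falls back to a deterministic ridge-penalized logistic fit (α = 1).
The reported score is the logistic log-odds, so the noncoding call is
exactly score < 0, with score = 0 counted as not noncoding. The scorer
is a single pluggable component; verdicts from external tools exposing
the same signed-score contract can be consensus-combined by AND of
their noncoding calls (`consensus_noncoding`). No attempt is made to
reproduce any external tool's numeric scores.

In the pipeline the scorer is trained per run on the reference coding
genes (positives) vs annotated lncRNAs (negatives) of the supplied
annotation, then applied to the unannotated candidates.

## Differential expression

- **Normalization**: median-of-ratios size factors over features with
  all-positive counts (geometric-mean pseudo-reference); a
  `pseudo_reference` fallback handles matrices with no such feature.
  These match DESeq2's estimator exactly (cross-checked against
  pydeseq2 in the test suite). Note the pseudo-reference couples the
  factors: scaling one sample's column by *c* scales its factor ratio to
  every other sample by exactly *c*, not the factor itself.
- **Dispersion**: per-feature method of moments,
  α̂ = max(0, (pooled within-group variance − mean)/mean²), shrunk
  toward a common dispersion fitted by profile likelihood with a
  Cox–Reid adjustment: α_i = (d₀·α_common + d·α̂_i)/(d₀ + d), prior df
  d₀ = 20, d = residual df. The raw moment estimator is essentially
  uninformative at 2–3 replicates per group (and left the null
  false-positive rate near 0.18 at nominal 0.05); the moderated default
  brings it to ≈ 0.05. Raw estimates remain available via
  `estimate_dispersion`.
- **Test**: log₂FC = log₂(mean_a+c₀) − log₂(mean_b+c₀) on normalized
  counts with offset c₀ = 0.5 (configurable); the SE comes from the NB
  variance μ/s + αμ² of each normalized count via the delta method,
  with μ floored by c₀ so zero-count groups keep a finite SE; p-values
  are two-sided normal. Features with zero counts in both groups get
  log₂FC 0, p 1; features with zero counts everywhere are dropped
  before testing and excluded from the BH family.
- **Calling**: BH step-up across tested features; significant ⇔
  padj < 0.05 and |log₂FC| > 1, both strict. Fold changes are oriented
  group_a over group_b; the built-in contrasts are White vs Brown,
  Beige vs White, Beige vs Brown.

The c₀ offset means log₂FC is scale-invariant under renormalization only
up to a residual < 0.01 log₂ at low counts; this is a deliberate
stability/exactness trade-off.

## Integration

Cross-contrast intersection is membership-only (direction-agnostic):
a feature significant in all contrasts counts as common even if signs
disagree; exclusive Venn regions partition the union. Cis assignment
takes the nearest coding gene by locus-gap within 100 kb (the standard
cis window), ties broken toward the lexicographically smaller gene id;
upstream/downstream are expressed in the target gene's orientation and
sense/antisense by strand equality. Enrichment is the exact
hypergeometric upper tail P(X ≥ k) per term with BH across tested
terms; terms with zero hits are skipped, and the universe defaults to
all features with at least one read.

## Synthetic benchmark

The generator emulates the structure of a three-cell-type (white,
brown, beige) × two-replicate adipocyte RNA-seq study built on a merged
assembly. Defaults: 300 multi-exon coding genes, 160 multi-exon plus 40
single-exon annotated lncRNAs, 50 true novel lncRNAs, and 10 decoys per
violation class, placed without collisions on a 2 × 2.2 Mb toy genome
with > 2.5 kb inter-locus gaps (so clearances hold by construction).
Coding mRNAs carry codon-biased ORFs (one preferred codon per amino
acid, weight 8:1) flanked by UTRs, giving the scorer a learnable
hexamer and position signal; noncoding sequences are random-composition
draws rejection-sampled to longest-ORF coverage ≤ 0.5. Each decoy class
violates exactly one criterion: spliced length ≤ 200 nt; zero planted
expression; one exon overlapping an annotated lncRNA exon by 60 bp;
placement 0.2–1.5 kb from a single-exon locus; or a codon-biased ORF
spanning the transcript. Two demonstration cis pairs are planted with
controlled geometry (novel lncRNA 1 kb downstream-antisense of a coding
gene; 4 kb upstream-sense) and beige-high expression.

Counts are gamma–Poisson (NB) with dispersion α = 0.1, planted size
factors (log-normal, σ = 0.15, geometric mean 1), and log-normal
baselines ordered coding > novel lncRNA > annotated lncRNA (ln-means
5.0 / 4.1 / 3.2), matching the qualitative expression ordering the
characterization stage should recover. A fraction (20%) of expressed
features get a ±3 log₂ effect in one cell type; 30% of those get an
opposing effect in a second type, which makes them differential in all
three pairwise contrasts (the "common DEG" population). Conservation is
a windowed (100 bp) beta-distributed track with coding exons ~Beta(8,2),
lncRNA exons ~Beta(3,7), introns ~Beta(2,8). A separate bare NB
simulator (`simulate_nb_counts`, 2,000 features) backs the DE
calibration studies.

What the generator does **not** emulate: read-level errors, positional
coverage bias, isoform ambiguity and shared exons between transcripts
of one gene, correlated expression structure, GC/mappability effects,
and real mouse-genome composition. Passing the planted-truth benchmarks
therefore demonstrates the correctness of the decision logic and the
calibration of the statistics under the stated model — not performance
on real libraries, where assembly artifacts and quantification noise
dominate.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeded from
  the run seed (distinct fixed streams per generator stage), so a seed
  fixes every output byte-for-byte; the report embeds seed and config
  hash.
- Benchmark sizes (≈ 660 annotated loci on a 4.4 Mb toy genome; 2,000
  features for calibration) keep a full end-to-end run in seconds on a
  single CPU while leaving every class large enough for stable rank
  tests.
- Degenerate inputs: empty unannotated set → empty output with an empty
  audit trail; a class with < 3 transcripts is summarized but excluded
  from rank-sum testing; conservation means ignore uncovered bases and
  single-exon transcripts contribute no intron value; a missing track
  chromosome is an error naming it.
- Known limitations: the Wald test's normal approximation is
  anticonservative below ~5 counts per group mean (the c₀ floor
  mitigates but does not remove this); the cis heuristic assigns at
  most one target per lncRNA and ignores enhancer-like distal action;
  GTF parsing consumes exon features only, so transcripts without exon
  lines are invisible.
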