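# Methods

`mitophylo` re-implements, as a tested pipeline, the standard analysis chain
used to characterize a newly sequenced mammalian mitochondrial genome and to
place it among congeners by distance-based phylogenetics. This note records
the models, conventions and numerical choices behind each stage, what the
synthetic-data generators do and do not emulate, and the known limitations.

## Data model and coordinate conventions

A `MitoGenome` is a (usually circular) nucleotide sequence plus an ordered
list of `GeneFeature`s in the 1-based inclusive coordinate convention of
GenBank and of published genome-organization tables; conversions to 0-based
slices are internal and never exposed. A feature with `end < start` is legal
only on a circular genome and denotes the splice `[start..L] + [1..end]`
(control regions commonly span the origin). Overlapping features are legal
and preserved — the bundled annotation keeps the published ATP8/ATP6 overlap
— and class roll-ups are plain sums of declared sizes without overlap
de-duplication, matching how such tables are totalled in the literature.
Gene names are normalized to one canonical vocabulary (ND1–ND6, ND4L,
COX1–3, ATP6/8, Cytb, 12S/16S rRNA, `tRNA-Xaa` with Leu1/Leu2 and Ser1/Ser2
disambiguated by anticodon or suffix) because GenBank records and printed
tables spell them differently.

The bundled table ships *sequence-free*: it carries the published per-gene
base-composition percentages instead of nucleotides, so every roll-up and
skew it supports is computed from the printed numbers, not from a private
copy of the record. Note the gene inventory arithmetic: the canonical
"37 genes" are 13 protein-coding genes + 22 tRNAs + 2 rRNAs; the control
region (D-loop) is a 38th annotated feature but not a gene, and the package
counts it that way.

## Composition and skews

Base composition excludes IUPAC ambiguity codes and gaps from every
denominator and treats U as T on input. Strand asymmetry is summarized by

    AT skew = (A − T) / (A + T),   GC skew = (G − C) / (G + C),

which are scale-invariant (counts and percentages give identical values) and
undefined — reported as missing, never as 0 — when the denominator is zero.
Raw values are kept at full precision; rendering rounds percentages to 2
decimals and skews to 3, the printed precision of the source tables.

## Codon usage and RSCU

All codon logic runs under the vertebrate mitochondrial genetic code (NCBI
translation table 2: AGA/AGG are stops, AUA codes Met, UGA codes Trp), taken
from Biopython's codon tables and pinned in full by a test. L-strand genes
are reverse-complemented at extraction, so codon routines always see the
coding sense. Mitochondrial CDSs often end in a truncated stop completed by
polyadenylation of the mRNA; a CDS of length ≡ 2 (mod 3) renders its stop
token as e.g. `TA-` and one of length ≡ 1 (mod 3) as `T--`.

Usage counting follows CodonW conventions: only complete codons are read,
trailing partial codons are dropped (and tallied), and a terminal complete
stop codon is excluded from usage. RSCU for codon *c* in a synonymous
family of size *k* is `n_c / ((1/k) Σ_family n_j)`; family RSCU values sum
to *k* whenever the family is used, and an unused family reports 0 for all
members by convention. Families are defined per amino acid (Leu and Ser are
single 6-fold families); codons are reported in the RNA alphabet.

## Distances

Three estimators over gapped alignments, all under pairwise deletion (per
pair, only columns where both sequences carry an unambiguous A/C/G/T):

* **p-distance** — differing sites / valid sites.
* **TN93 (closed form)** — the Tamura–Nei (1993) correction computed per
  pair from the purine-transition, pyrimidine-transition and transversion
  proportions with base frequencies pooled over the two sequences. When a
  logarithm argument is non-positive (saturation) the distance is reported
  missing with a warning rather than truncated. In the equal-frequency,
  equal-rate limit the formula collapses to Jukes–Cantor,
  −(3/4)·ln(1 − 4p/3), which a test enforces to 1e−6.
* **Maximum composite likelihood (MCL)** — the "ML distances" of
  MEGA-style tables. The TN93 substitution model is parameterized by base
  frequencies π (pooled over the whole alignment), two
  transition/transversion rate ratios κ1 (A↔G) and κ2 (C↔T) with the
  transversion rate fixed at 1, and the rate matrix scaled to one expected
  substitution per site per unit branch length. The two ratios are shared
  across all pairs and estimated by maximizing the sum of pairwise
  log-likelihoods (Nelder–Mead on the log-ratios, `xatol` 1e−6); inside each
  evaluation every pair's distance is profiled out by a bounded 1-D search
  (`xatol` 1e−10, distances capped at 20 substitutions/site). Transition
  probabilities use the model's closed-form spectral decomposition,
  cross-checked against a numerical matrix exponential in tests. For two
  taxa the composite likelihood is the single-pair likelihood, so the MCL
  distance reduces to the pairwise TN93 ML distance. Identical pairs are
  assigned distance 0 without optimization. Non-convergence raises an error
  naming the tolerances.

Distances are computed on nucleotide supermatrices; concatenation appends
gene blocks in input order, gap-fills taxa missing a gene (logged, and
neutral under pairwise deletion), and records each gene's 1-based column
range in a partition map. The default supermatrix exclusion is ND6, the one
light-strand protein-coding gene, conventionally dropped from concatenated
nucleotide analyses for its deviant composition.

## Neighbor joining and bootstrap

NJ is the Saitou–Nei agglomeration with the Q-criterion, written for strict
determinism: ties on Q break toward the lowest (row, column) index pair, and
negative limb lengths are clamped to 0. On additive matrices NJ is exact;
tests verify that trees rebuilt from path-length matrices of random trees
(up to 8 taxa) reproduce both topology and all pairwise path sums, and that
the implementation agrees with an independent NJ implementation
(scikit-bio). Trees wrap dendropy for Newick round-tripping; bipartitions
are stored normalized (the side not containing the lexicographically
smallest leaf).

Bootstrap support resamples whole alignment columns with replacement
(ignoring partitions), rebuilds the distance matrix and NJ tree per
replicate, and labels each internal edge of the full-data tree with the
percentage of replicates containing its bipartition. A fixed seed gives
byte-identical output.

## Synthetic data

The generators provide every input with known ground truth:

* **Trees** — uniform over the (2n−5)!! unrooted labelled topologies by
  sequential random-edge insertion (a χ² test over all 105 six-taxon
  topologies at 10,000 draws guards the uniformity), with iid uniform branch
  lengths, default 0.02–0.2 substitutions/site — the within-genus divergence
  scale of the distance stage.
* **Alignments** — root sequence drawn from the stationary frequencies,
  per-edge substitution by the closed-form TN93 transition matrices. The
  defaults (π = 0.34/0.22/0.13/0.31 in ACGT order, κ1 = κ2 = 8) mirror the
  AT-rich, G-poor, strongly transition-biased composition of mammalian
  mitogenomes. Sites are iid: no rate heterogeneity (Γ), no indels —
  pairwise-deletion code paths are exercised instead by post-hoc random gap
  masking.
* **Genomes** — a circular genome with the mammalian layout (13 PCGs, 22
  tRNAs, 2 rRNAs, one control region), ND6 and eight tRNAs on the L strand,
  and PCGs whose declared start/stop tokens — including truncated stops at a
  configurable fraction (default 0.3, roughly the observed share) — are
  consistent with the embedded sequence.

One root seed feeds named child streams (tree / sequences / genome / gaps),
so adding a stage never perturbs earlier draws.

Because the simulator generates exactly the model family the estimators
assume, passing recovery tests demonstrates correctness of the estimation
machinery, not robustness to real-data violations (alignment error, rate
heterogeneity, compositional non-stationarity between lineages).

## Morphometrics

Specimen measurements (body mass in g; lengths in mm) are compared index by
index against published reference ranges with inclusive bounds. References
reported from a single individual are degenerate intervals; these are
compared with a relative tolerance (default 5%) rather than exact equality,
since such point values are quoted informally. The verdict table reports
within/below/above/no-reference per index plus the fraction of referenced
indices within range.

## Problem sizes and reproducibility

The test and analysis defaults are sized for a laptop-class run: recovery
tests use a fixed 6-taxon tree with 20 kb alignments over 10 seeds
(composite-likelihood path-length RMSE < 0.01), NJ exactness is checked on
100 random additive trees up to 8 taxa, RSCU conservation on 1,000 random
usage tables, and bootstrap demonstrations use tens to hundreds of
replicates (the CLI default is 1,000, the conventional choice). All
randomness flows from explicit seeds; re-running any driver or test with
the same seed reproduces its outputs byte for byte.

## Known limitations

* Reproducing published inter-species distance tables from deposited
  accessions requires the records and an aligner, and carries
  alignment-choice uncertainty (the source analyses do not name their
  alignment or trimming protocol); the real-data check therefore allows
  ±0.005 and only runs when the records have been fetched locally
  (`scripts/fetch_accessions.py`).
* The bundled annotation reproduces its source table verbatim, including
  small internal inconsistencies of that table's prose context (e.g. a
  tRNA length quoted differently in text and table); only table-derived
  values are asserted.
* Tree inference is deliberately limited to NJ on the package's own
  distance matrices; likelihood/Bayesian tree search, model selection and
  species-tree methods are out of scope, as are indel-aware simulation and
  de novo annotation.
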