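# Methods

## Pipeline model

`varfold` treats a species' data as three layers joined on (transcript,
residue): annotation-derived transcript models give the map from genomic
position to codon and residue; population genotypes give per-variant minor
allele frequencies; predicted structures give per-residue features. All
coordinates are 1-based inclusive (the GFF3/VCF convention); CDS offsets
run 5'→3' in coding orientation, so minus-strand arithmetic reduces to
`offset' = L − offset + 1`.

### Transcript models and primary transcripts

Models are chains of non-overlapping CDS intervals on one chromosome and
strand. Annotations encode "canonical/primary transcript" inconsistently
across GFF3 dialects, so the package uses a deterministic proxy: per gene,
the transcript with the longest total CDS, ties broken by smallest
transcript id. The CDS phase column is ignored (intervals are assumed
frame-consistent); a warning is emitted when a model's CDS length is not a
multiple of 3. Ambiguous bases (N) translate to 'X' rather than erroring.

### Consequence classification

SNVs inside the CDS are typed by substituting the strand-complemented
alternate base into the affected codon: synonymous, missense, stop-gained
(premature stop), stop-lost (terminal stop removed), start-lost (any
change to the ATG of codon 1). Indels are typed by net length change only
(frameshift iff not a multiple of 3); the shifted tail is deliberately not
re-translated, since the grade — the unit of all downstream statistics —
is already determined. The splice "site" is the canonical 2-bp GT/AG
intron core: the donor is the intron end adjacent to the coding-upstream
exon. Deliberate simplifications, each flagged in code: a variant spanning
an exon–intron junction is graded HIGH as a frameshift with a warning
flag; UTRs are not modelled, so positions outside a gene's CDS footprint
are intergenic; multi-codon MNVs are out of scope. MODIFIER calls
(intronic/intergenic/non-coding) are produced but excluded from all
statistics by default.

The engine is verified two ways: an exhaustive oracle test classifies
every possible SNV of fixture genes and compares against an independent
brute-force classifier that rebuilds the mutant chromosome and
re-translates the full coding sequence; and a strand-symmetry test
re-classifies each variant on the mirror-image construction (gene and
variant reverse-complemented onto the flipped chromosome).

### Allele frequencies

Computed from FORMAT/GT calls only, never from INFO tags, so datasets with
different INFO conventions behave identically. Missing alleles ('.') leave
the denominator; haploid calls contribute one allele; phased and unphased
separators are equivalent; multi-allelic sites are split with each ALT
counted against all called alleles. The rare-variant filter boundary is
inclusive (`MAF ≥ threshold` retained), so a 5% filter excludes strictly
`MAF < 0.05`. Indel left-alignment is delegated to upstream normalization
tools.

### Residue features

* **pLDDT**: mean B-factor over a residue's atoms. Predictor outputs come
  in a 0–1 and a 0–100 dialect; a file whose maximum B-factor is ≤ 1 is
  rescaled by 100.
* **SASA**: Shrake–Rupley with a deterministic Fibonacci-spiral point set
  (no RNG), default 960 points, probe 1.4 Å, heavy atoms only, van der
  Waals radii C 1.70 / N 1.55 / O 1.52 / S 1.80 Å (unknown elements get
  1.70 Å with a warning). Instead of a hard in/out occlusion count, each
  surface point contributes a weight ramping linearly over one
  point-spacing of signed distance to the nearest occluding sphere. This
  antialiasing leaves the closed forms exact (an isolated carbon scores
  exactly 4π(1.70+1.4)² Ų; a fully buried atom scores 0) and preserves
  monotonicity under added neighbours, while reducing rotational jitter by
  roughly an order of magnitude (measured: < 0.1% per-residue change under
  rigid-body transforms at 960 points, vs ~0.6% with the hard indicator;
  960-point results sit within 0.4% of 10 000-point results on fixture
  structures).
* **rASA**: SASA divided by the residue's theoretical maximum (Tien et
  al. 2013 "theoretical" column, shipped as a data table), clamped to
  [0, 1]. Note the numeric SASA definition here differs from DSSP-style
  accessibility; rASA values are comparable within a run, and the clamp
  makes the disorder interpretation (0 buried → 1 exposed) explicit.
* **Proportional position**: `(i−1)/(L−1)` over standard residues, so the
  termini hit exactly 0 and 1; a length-1 chain scores 0.5.

### Substitution subclasses

The functional-group partition (nowhere standardized) is declared in one
table: aliphatic/nonpolar {G,A,V,L,I,P,M}, aromatic {F,W,Y}, polar
uncharged {S,T,C,N,Q}, positive {K,R,H}, negative {D,E}; a substitution is
*conservative* iff both residues share a group. BLOSUM62 comes from
biopython's published matrix (provenance-tested against hand-checked
entries). Codon usage is counted from the species' own coding sequences;
RSCU = count × family size / family total (stop codons form their own
family), and a codon is *common* iff RSCU ≥ 1 — used at least as often as
the uniform within-family expectation. Both the partition and the cutoff
are arguments, never silently changed.

### Statistics

* **Binned summaries**: equal-width MAF bins partitioning [0, 0.5]
  (default 10; edges are printed in the output), mean and SE = sd/√n of
  rASA per (group, bin); single-record bins report SE 0 with a flag; empty
  bins are omitted. Binned means replace presentation-layer GAM smoothing;
  the smoothing is presentation, not inference.
* **Pairwise rank tests**: two-sided Mann–Whitney per pair of grades;
  exact null distribution when both groups have ≤ 8 untied observations,
  else the normal approximation with tie and continuity corrections; Holm
  step-down adjustment across pairs by default (the convention of the
  standard pairwise test in R). The test suite checks the implementation
  against an exhaustive-permutation oracle for all group sizes ≤ 6.
* **Correlation**: Pearson or Spearman over residue features; zero
  variance returns null with a warning.
* Mixed-effects modelling (e.g. MAF ~ rASA with a transcript random
  intercept) is intentionally out of scope; the joined TSV is the exported
  surface for fitting such models externally.

## The synthetic-data generator

The simulator emulates exactly what the pipeline consumes, with truth
recorded at generation time.

* **Genome/annotation**: by default 8 genes of 20–45 codons on one
  chromosome, introns (canonical GT/AG, 20–40 bp) with probability 0.4,
  half the genes on the minus strand, ≥ 20 bp intergenic spacers —
  desk-scale stand-ins for a proteome chosen to exercise every coordinate
  path (splicing, both strands, multi-exon phase) rather than to mimic
  genome statistics.
* **Variants**: constructed bottom-up from the intended consequence type
  (degenerate-position change for synonymous, 1-bp deletion for
  frameshift, intron-core SNV for splice, …), so the intended type is true
  by construction. Default plan: 30 synonymous, 30 missense, 8
  stop-gained, 8 frameshift, 4 start-lost, 4 stop-lost, 6+6 in-frame
  indels, 3+3 splice, 6 intronic, 6 intergenic among 20 diploid samples —
  small enough for fast tests, large enough for the grade-level
  statistics. Allele frequencies are planted through GT fields (base
  frequency uniform on [0.08, 0.45], alt kept minor).
* **Selection caricature** (`selection_effect` s > 0): damaging variants
  choose exposed target residues with odds multiplied by exp(s·c), with
  c = 1.0 (HIGH), 0.4 (MODERATE), −0.5 (LOW); and the planted allele
  frequency of HIGH/MODERATE variants is shifted linearly on the logit
  scale by s·(rASA proxy − 0.5), the proxy being 0.8 for exposed and 0.15
  for buried residues. This is a monotone caricature of purifying
  selection — sufficient for ordering/recovery tests, not a coalescent
  model. With s = 0 the placement and frequencies are exposure-independent
  (verified: |r| < 0.1 over ≥ 1000 variants).
* **Structures**: geometric caricatures, not folds. Four compact heavy
  pseudo-atoms (N, CA, C, O) per residue on a 10 Å-spaced chain; buried
  residues are wrapped in a 12-atom icosahedral shell (radius 4.3 Å,
  emitted as trailing 'SHL' placeholder residues that parse to 'X' and are
  excluded downstream), driving their computed rASA below 0.25 while
  exposed residues stay above 0.5; B-factors carry the planted pLDDT
  (higher for buried residues, dipping toward the termini). Because
  downstream code consumes only coordinates and B-factors, physical
  plausibility is unnecessary — which is also why passing tests certify
  the pipeline's bookkeeping and statistics, not predictor accuracy on
  real proteins.

Everything derives from one integer seed; reruns are byte-identical.

## Numerical and testing choices

* Problem sizes: module tests use the default bundle; selection-recovery
  checks use 10 genes with a doubled variant plan so each grade has tens
  of observations; the exposure-decoupling check uses 32 genes /
  ~1000 variants.
* Type-I control: 200 permutation replicates from an uncoupled fixture;
  the family-wise rejection rate is compared to 5% with a two-standard-
  error binomial tolerance (a rate estimated from 200 draws has sd ≈ 1.5
  points; an exact ≤ 5% assertion would fail by sampling noise alone at a
  nominal-level test).
* Ties/degenerate inputs: identical multisets give p = 1; empty groups,
  zero-variance correlations, unknown residues/elements and out-of-range
  indices raise or warn explicitly rather than propagating silently.
* The rASA burial threshold pair (0.25 / 0.5) is part of the generator's
  contract, asserted in tests, not a biological claim.

## Known limitations

* SASA is Shrake–Rupley, not DSSP's algorithm; absolute values differ
  from DSSP-derived accessibility by a method-dependent factor.
* Indel consequences ignore downstream tail effects; MNVs and variants in
  UTRs are not modelled; snpEff's wider 3–8 bp "splice_region" (LOW) is
  not emitted — only the 2-bp HIGH core.
* The simulator's genotypes are independent across samples (no LD,
  population structure or coalescent history).
* Structures are single-chain; mmCIF input is not supported.
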