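# Methods

`repdrift` analyzes longitudinal heavy-chain antibody repertoires: how much of
a donor's circulating repertoire persists between two sampling timepoints, how
similar repertoire composition remains, which clonotypes are shared between
donors, and whether high-level genetic features alone can identify a sample's
donor and timepoint. All statistics operate on annotated rearrangement tables
(AIRR-style TSV); a synthetic V(D)J generator with registered ground truth
makes every stage testable by parameter recovery.

## Units of analysis

* **Clonotype** — same V gene, same J gene, identical CDRH3 amino-acid
  sequence. Gene calls are normalized to gene level (allele suffix after `*`
  stripped) because clonotype identity is defined on genes, not alleles. The
  CDRH3 is the IMGT junction minus its conserved first (Cys104) and last
  (Trp118/Phe) residues; all CDRH3-length statistics use this convention. A
  switch allows keying on the full junction for sensitivity analysis.
* **Sequence** — exact nucleotide identity of the junction. This refines
  clonotype identity, so sequence-level persistence can never exceed
  clonotype-level persistence; the property is asserted on every simulated
  dataset.
* **Species** (similarity analyses) — the (V gene, J gene, CDRH3 length)
  combination. Individual sequences almost never recur between unrelated
  samples, so similarity needs a coarser, recurrent unit, analogous to species
  in ecological overlap statistics.

## Morisita–Horn similarity

For species count vectors x, y with totals X, Y:

    CH = 2 Σᵢ xᵢyᵢ / [ (Σᵢ xᵢ²/X² + Σᵢ yᵢ²/Y²) · X · Y ]

summed over the union of species present in either sample (absent species
contribute xᵢyᵢ = 0). CH is 0 for disjoint species sets, 1 for identical
frequency distributions, and is abundance-weighted: dominant clones dominate
the index. The implementation evaluates the algebraically identical form
2·Σxᵢyᵢ·XY / (Σxᵢ²·Y² + Σyᵢ²·X²), which is exact for integer counts, so
CH(x, x) = 1.0 and CH(disjoint) = 0.0 hold exactly in floating point; tests
verify agreement with an exact rational-arithmetic oracle to 1e-12.

Bootstrap rarefaction resamples each side **with replacement** at a grid of
depths (default 20 draws, 2.5/97.5-percentile CIs). Because resampling is
with replacement, depths above the census size are permitted; they are
flagged (`exceeds_census`) rather than rejected. Replicate clustering applies
single linkage to the **rows of the pairwise CH matrix under the Euclidean
metric** (default); `metric="one_minus_ch"` instead treats 1 − CH as a
precomputed distance. Both behaviors are exposed because either is a
defensible reading of "similarity as the distance measure" with a Euclidean
metric; rows are pre-sorted lexicographically so leaf order is deterministic.

## Turnover and persistence

Between timepoints, with species counted at clonotype or sequence level:

    turnover%    = 100 · (appearing + disappearing) / total observed
    persistence% = 100 − turnover% = 100 · shared / total

where appearing/disappearing are species seen only at the later/earlier
timepoint and total is the union. The two identities
(persistence + turnover = 100, persistence = 100·shared/total) are enforced
by construction and tested on random set pairs.

Observed sharing is depth-dependent: at finite sampling depth most rare
species are missed on at least one side, so the shared fraction rises with
depth. `sharing_vs_depth` quantifies this (bootstrap per depth); it is a
diagnostic of sampling limitation, not a depth-corrected estimate of true
persistence — depth-corrected statistical modeling is explicitly out of
scope.

Shared vs unshared clonotypes are compared on four per-clonotype measures:
CDRH3 length, IgG⁺ frequency, mean V-gene nucleotide mutation count, and
occurrence in more than one biological replicate (biological replicates are
disjoint cell samples, so repeat occurrence implies a clonally expanded
lineage). Group differences use two-sided Mann–Whitney rank tests with
Benjamini–Hochberg correction across the four measures; the test family is a
documented package choice, not a claim about the original analyses. Sequence
logos are position × amino-acid frequency matrices at a fixed CDRH3 length
(default 13), columns summing to 1; they are emitted as matrices (TSV), not
rendered graphics.

**Public clonotypes** are those present in every subject; **persistent
public** clonotypes are additionally present at both timepoints. Because the
exact set algebra over subjects is a modeling choice, both modes are
implemented: persistent in *all* subjects (default) or in *at least one*.

## Classification

A repertoire sample is reduced to the concatenation of three frequency
blocks — V-gene usage, J-gene usage, CDRH3-length distribution (5–35 AA) —
each summing to 1, with out-of-vocabulary genes pooled into an `OTHER`
bucket. The marginal representation is the default (a joint V×J×length table
is available behind a flag). A one-versus-rest support-vector machine with a
linear kernel and C = 1.0 (features already normalized, no scaling) is
evaluated leave-one-replicate-out: each biological replicate is held out in
rotation, one feature vector per (class, replicate) is subsampled at each
training/test size, and per-class ROC AUC is computed from decision scores
pooled over rotations, averaged over independent subsampling repeats. The
evaluation is leakage-free by construction (train and test vectors come from
disjoint replicates) and the record-id audit is reported with every run.
Kernel and regularization are defaults of this package; only the classifier
family is fixed by the problem statement.

## Synthetic repertoire generator

The generator emulates the study design: subjects × timepoints × biological
replicates × sequences per replicate, defaulting to 2 × 2 × 6. Model:

* Each clonal **lineage** draws V/D/J genes and CDRH3 length from
  configurable usage distributions (defaults: common human IGHV/IGHD/IGHJ
  genes with plausible usage, IGHJ4-dominant; CDRH3 lengths bell-shaped
  around 15–16 AA over the IMGT range 5–35) and junction residues from an
  amino-acid bias enriched for Gly/Tyr/Ser/Asp/Arg. The nucleotide junction
  is a random codon realization of the amino-acid junction — a deliberate
  simplification standing in for templated V/D/J segments plus N/P
  additions; it preserves exactly the properties downstream analyses read
  (translation consistency, anchor residues, no stops, configured length).
* **Compartments:** a lineage is naive with probability `naive_fraction`
  (default 0.7); naive cells are IgM with zero V mutations. Memory cells
  draw isotype per cell (`memory_isotype_probs`, default IgM/IgG 0.5/0.5 —
  overall IgM fraction ≈ 0.85, within the 0.76–0.94 range typical of
  circulating repertoires) and Poisson V-mutation counts (mean `shm_rate`,
  default 6). Memory cells also acquire synonymous junction substitutions
  (rate 0.02 per codon), which makes nucleotide identity a strict refinement
  of clonotype identity without disturbing clonotype keys.
* **Clonal structure:** lineage sizes follow a discrete power law (Zipf
  exponent `lineage_size_exponent`, default 2.5, capped at 10⁴), so expanded
  lineages are over-represented among sampled cells. Each timepoint's cell
  pool is the exact multiset of lineage cells, shuffled and partitioned into
  disjoint biological replicates — multi-replicate occurrence therefore
  implies expansion, never resampling of one cell.
* **Persistence:** a lineage present at one timepoint carries to the next
  with probability `persistent_fraction` (default 0.02, the low-persistence
  regime of interest); carried lineages keep their identity and redraw their
  size. When `persistent_fraction = 1` the pool is static: no fresh
  recruitment, leftover capacity redistributes over carried lineages, so
  downstream persistence is exactly 100% by construction.
* **Public pool:** `public_pool_size` clonotype identities (default 100) are
  shared verbatim (V, D, J, CDRH3 amino acids) by all subjects and receive a
  `public_pool_weight` fraction of each pool's cells (default 0.01);
  nucleotide junctions are realized independently per subject, modeling
  amino-acid convergence rather than nucleotide identity.
* **Configurable effects:** optional `LineageBias` overrides give persistent
  or public lineages different compartment balance, SHM, IgG probability,
  CDRH3-length shift, or size multiplier; optional Dirichlet concentrations
  perturb usage distributions per subject and per timepoint. All default to
  neutral — effects exist only when a study question needs them.

A single seeded generator drives every draw in documented order, so one seed
reproduces the record set and ground truth byte-for-byte. The ground truth
registers every lineage (clonotype key, compartment, public flag, timepoint
membership) and maps every emitted sequence to exactly one lineage.

### What the generator does not emulate

Sequencing error and PCR bias (inputs model post-QC, UMI-deduplicated data),
germline-segment micro-structure of junctions, light chains, receptor
editing, selection, affinity-maturation dynamics, and any quantitative model
of naive B-cell half-life — `persistent_fraction` abstracts persistence
phenomenologically. Passing tests therefore demonstrate correctness of the
statistics and recoverability of configured effects, not biological fidelity
of any particular parameter value.

## Null constructions used in tests

Two nulls deserve explanation because naive versions are not actually null:

* **Classifier null.** Two subjects simulated with identical generative
  parameters still differ through their realized lineage censuses — that is
  genuine individuality signal, not noise (it is exactly why replicates
  cluster by donor). The no-signal control therefore splits 12 exchangeable
  replicates of a *single* simulated condition into two pseudo-classes whose
  labels carry no information; mean leave-one-replicate-out AUC then hovers
  at 0.5.
* **Intra- vs inter-timepoint similarity null.** Dominant clones are shared
  among replicates of one timepoint but not across timepoints, so even with
  identical usage distributions the abundance-weighted index separates intra
  from inter pairs. The exchangeable null suppresses clone dominance
  (size exponent 5, sizes ≈ 1), making timepoints interchangeable draws from
  one species distribution; intra and inter IQRs then overlap.

## Numerical and scale choices

Worked-example and oracle tests run in milliseconds. Simulation-backed tests
use 2 × 2 × 6 × 400 records (shared fixture), parameter recovery pools 20
seeds × 3 persistence settings at 1 subject × 6 × 250, the classifier null
uses 12 replicates × 15 000 sequences with test size 10⁴ over 20 repeats, and
the characterization analysis uses ~10⁴ clonotype observations. These sizes
give the rank tests and binomial checks comfortable power on a single CPU in
minutes while remaining far below the original study's ~6×10⁸ reads; the
pipeline itself is size-agnostic. Depth-curve monotonicity is asserted within
two bootstrap standard errors per step, since only the expectation is
monotone. Probability vectors must sum to 1 within 1e-9; logo columns sum to
1 within 1e-9; CH is validated in [0, 1] to 1e-12.

## Known limitations

* Persistence estimates are sampling-depth-bounded from below; no correction
  is attempted.
* The public pool is modeled as a fixed shared list with its own sampling
  weight; real public clonotypes arise from convergent recombination with
  sequence-dependent probabilities.
* The SVM evaluation trains on one feature vector per replicate (as few as 5
  training points per class); AUC estimates at small replicate counts are
  coarse-grained.
* Technical replicates are assumed pre-merged into biological replicates;
  the loader does not model them.
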