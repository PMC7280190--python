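# Methods

## The problem and the approach

Amplicon surveys of arbuscular mycorrhizal fungi (AMF) usually cluster reads
into OTUs at a fixed radius and classify one representative per cluster.
Because AMF are species-poor but often nearly identical at the marker locus
(LSU rDNA, the ~700 bp fragment between the LR1 and FLR4 primers), the ~3%
clustering radius itself can blur real taxa. This package implements an
OTU-free alternative: **every quality-passing read is classified
individually** against a curated reference database, and only the reads that
match nothing are grouped among themselves.

The pipeline stages are:

1. **refdb** — curate the reference database: load a taxon-labelled LSU
   FASTA, drop entries named "uncultured", reduce each sequence in silico to
   the fragment delimited by the primer pair (IUPAC-aware exact matching, 0
   mismatches beyond degeneracy, primer sites excluded), and deduplicate
   identical fragments into *univocal* records (representative = smallest
   accession, full provenance retained).
2. **preprocess** — demultiplex by exact 5' MID prefix (the MID map must be
   prefix-free) and discard reads failing any of: length < 200 nt, mean
   Phred < 25, any ambiguous base. The rules are strict `<` discards, so
   boundary reads (length 200, mean 25.0) pass; the first failing rule in
   that order is the recorded reason. Mean quality is the arithmetic mean of
   Phred integers (error-probability averaging behind a flag). Reads are
   discarded, never trimmed.
3. **taxa_assign** — align each read against every reference and label it
   with the best hit's taxon when coverage ≥ 80% of the read and identity ≥
   97% (both inclusive); reads meeting the criteria nowhere are tested for
   being chimeric joins of two reference taxa, and the remainder are grouped
   by single linkage under the same two thresholds into "de novo_k" taxa.
4. **abundance** — samples × taxa counts; rarefaction to 7,000
   reads/sample; retain taxa with ≥ 10 sequences in at least one replicate.
5. **stats** — alpha diversity and a group test, Bray-Curtis / PCoA /
   PERMANOVA, per-taxon Wilcoxon comparisons, and a LEfSe-style LDA effect
   size.

## Pairwise alignment

The aligner is an affine-gap local (Smith-Waterman/Gotoh) dynamic program
with BLASTN-like scoring: match +2, mismatch −3, a gap of length L costs
5 + 2L. Definitions:

- coverage = query bases inside the local alignment / query length × 100;
- identity = identical columns / all aligned columns × 100, gap columns
  counted in the denominator (a flag offers the matches/matched-columns
  variant).

Tie-breaking is pinned for reproducibility: the best cell is the first
strict maximum in row-major order and the traceback prefers diagonal moves,
then gaps in the query, then gaps in the subject. Best-hit selection over a
database orders by score, then identity, then coverage, then accession.

Two execution paths share this contract. The exact path fills the full DP
matrix (used by default at small scale and by every oracle-equivalence
test). The fast path, used by the pipeline on study-scale inputs, seeds
candidate subjects through an 11-mer inverted index (sampled query k-mers,
stride 8) and restricts the DP to a padded diagonal band around the shared
k-mer diagonals, returning early once the strongest-seeded candidate already
meets both thresholds — the same seed-and-extend character as the BLASTN
tool the contract mimics. At ≥ 97% identity a read shares the vast majority
of its 11-mers with its true source, so seeding is not the accuracy
bottleneck; on simulated study-scale data classification accuracy is
indistinguishable between paths.

## De novo grouping

Two unassigned reads are related when their alignment meets the same
coverage/identity thresholds, with the *shorter* read as the query (this
makes the relation symmetric; at equal lengths both orientations coincide).
De novo taxa are the connected components (single linkage) of this relation;
labels `de novo_k` are assigned by descending group size, ties by first-read
order. Exact all-pairs evaluation is used up to 300 reads; above that an
incremental variant links each read through a k-mer index over component
representatives. The incremental variant is a single-linkage approximation
(it can miss an edge between two already-formed components that only a weak
alignment would join); for well-separated taxa — mutual divergence a few
times the 3% threshold — it is exact in practice and is cross-checked
against the exact method in the tests.

## Chimera flagging

Chimera removal "with these criteria" is stated without further detail in
published descriptions of this approach; the procedure here is therefore
one concrete reading, switchable off. A read that failed classification is
split at every breakpoint on a 50-nt grid inside its central 60%; it is
flagged chimeric iff at some breakpoint both segments independently meet
the coverage/identity criteria against two *different* reference taxa. A
cheap screen precedes the full procedure: the outer 20% end segments of the
read (which lie outside the central breakpoint window, so each belongs
purely to one parent) must vote for different subjects with strong k-mer
support.

A purely reference-based test cannot flag a chimera whose parents are
absent from the database — and such chimeras are dangerous, because under
single linkage a chain of same-parent-pair chimeras at staggered
breakpoints can spuriously bridge two otherwise well-separated de novo
taxa (a near-boundary chimera can reach 97% identity against a pure read
of its major parent). The pipeline therefore tests unclassified reads
against the reference database *plus a panel of mutually dissimilar
unclassified reads built on the fly*: a read that survives the chimera test
and matches no existing panel lineage at the classification thresholds is
admitted as a new panel lineage. Abundant pure de novo lineages enter the
panel within the first few dozen reads, after which chimeras involving them
are flagged like any reference-parent chimera. For the panel test the
full-read condition is deliberately dropped (two ends belonging to
different lineages mark a chimera even when its overall identity to the
major parent sneaks past 97%).

Two safeguards keep the panel itself clean. First, the panel-path
bi-segment test runs with its segment-identity bar relaxed by 3 points
(94% by default): an error-laden chimera whose parent segments sit just
below the classification threshold would otherwise be admitted as a
spurious "lineage" ~96% identical to the true one, after which genuinely
pure reads — matching both entries — would be mass-flagged as chimeric.
Second, whenever a new lineage is admitted, every earlier panel lineage is
re-tested against the updated panel and dropped if it now looks chimeric;
this removes chimeras that arrived before any pure read of one of their
parents. The bi-segment test itself refuses to call a chimera between two
subjects that are mutually ≥94% identical (at ≥60% coverage): such
"parents" are one lineage, and a chimera between near-identical parents is
unresolvable in principle. Residual limitations: strongly conserved
regions between genuinely distinct lineages could still trigger a false
flag, and escaped chimeras end up as de novo singletons rather than
polluting known taxa — the conservative failure mode. On simulated
study-scale data (two seeds, 2% chimeras) the panel procedure flags 96-98%
of true chimeras with zero pure reads mis-flagged, and each
database-absent taxon is recovered as exactly one pure de novo group.

## Rarefaction and filtering

Rarefaction subsamples each sample without replacement to exactly 7,000
reads (`numpy`'s multivariate hypergeometric), reproducibly under a seed.
The study rarefied at 7,000 although some replicates held fewer reads and
did not report how those were handled; the policy here is explicit and
configurable (keep-with-warning, the default, or error). Rarefaction curves
use the analytic expectation E[S(d)] = Σ_t (1 − C(N−n_t, d)/C(N, d)),
computed with log-gamma for stability and cross-checked against Monte-Carlo
subsampling. The low-abundance filter keeps a taxon iff some replicate
holds ≥ 10 of its sequences (inclusive); the pipeline rarefies first and
filters second (order configurable and logged).

## Statistics

- **Alpha diversity**: observed richness; Shannon H = −Σ p ln p (nats;
  base-2 flag); "Simpson" means Gini-Simpson 1 − Σ p² (inverse Simpson
  behind a flag) — the convention of the analysis platform the study used.
  The group test is Kruskal-Wallis by default (ANOVA behind a flag); when
  every value is identical the p-value is reported as 1.
- **Beta diversity**: Bray-Curtis Σ|x−y|/Σ(x+y); PCoA by Gower
  double-centering of −½D² and eigendecomposition, coordinates scaled by
  √λ, negative eigenvalues reported but excluded from coordinates and the
  %-variance denominator; one-factor PERMANOVA (Anderson) with
  F = (SS_between/(g−1))/(SS_within/(n−g)) and
  p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) under raw label permutation.
  Permutations that recreate the observed partition tie with the observed F
  and are counted, so the attainable minimum p sits slightly above
  1/(1+n_perm) for small balanced designs.
- **Per-taxon Wilcoxon ("heat tree" stage)**: two-sided rank-sum per taxon,
  exact for ≤ 8 replicates per group, tie-corrected normal approximation
  otherwise; effect = log2((median_A+1)/(median_B+1)); Benjamini-Hochberg
  adjustment, significance at adjusted p < 0.05.
- **LEfSe-style LDA**: samples scaled to 10⁶; stage 1 keeps taxa whose
  Kruskal-Wallis adjusted p < 0.05; stage 2 fits a linear discriminant on 30
  stratified bootstrap resamples and scores each retained taxon as log10 of
  the largest among-class difference of its discriminant-projected class
  means (unit-norm axis, floored at 1), averaged over bootstraps; taxa with
  score ≥ 1.0 are reported, signed by the enriched class. The bootstrap
  count, flooring and 10⁶ scaling are pinned here; published analyses do
  not state the platform's scaling constant, so score *magnitudes* on real
  data may differ even when the ranking does not.
- "Adjusted p-value" always means Benjamini-Hochberg.

## The simulator

The generator emulates the targeted study design: 454-style pooled
sequencing of ~700 bp LSU amplicons over 4 groups (bulk soil Bs vs
root-associated Rs × sampling times 1S/2S) with 5 replicates each, at 9,000
reads per sample (the study's average raw depth, which leaves ≥ 7,000
classified reads after QC and chimera losses, matching its 7,000
normalization depth). Reference taxa mutate a common ancestor independently
at a per-site divergence (default 8%, giving ~85% pairwise identity — well
clear of the 97% threshold); optional withheld taxa are recorded in the
truth but left out of the written reference FASTA to emulate lineages absent
from public databases.

Per-base qualities follow a lognormal-dispersion model: each base draws an
error probability p_b with E[p_b] = `error_rate` (σ = 2 on the log scale)
and gets Q_b = −10 log10(p_b), clamped to [2, 40]; substitutions occur per
base at p_b. This keeps the quality string consistent with the realized
error process while the mean Phred at a 0.5% error rate is ≈ 32 — the
nonlinearity of the Phred scale means heterogeneous per-base quality, as on
real instruments, not a flat Q23. Chimeras join two parent taxa at a
uniform breakpoint in the central 60%. Junk reads violate exactly one QC
rule each (too short / low quality / one-to-three N bases), in equal
shares, so QC sensitivity is attributable per rule.

What the simulator does *not* model: 454 homopolymer/flowgram errors, PCR
bias and abundance-dependent chimera kinetics, length variation among taxa,
and intra-taxon polymorphism. Passing tests therefore demonstrate the
pipeline's logic and calibration, not robustness to homopolymer-heavy real
454 data.

## Problem sizes and numerical choices in the test suite

Oracle-equivalence checks run the exact aligner against a plain-Python DP
on sequences ≤ 300 nt and exact clustering against brute-force connected
components on ≤ 50 reads (100 random instances). Statistical calibration
uses 2,000 null simulations: PERMANOVA on 12 samples with 199 permutations;
Kruskal-Wallis on 4 groups of 25 — the chi-square approximation it relies
on is conservative at 5 per group (~3% observed type-I), so its calibration
is assessed in the asymptotic regime where it attains the nominal level.
End-to-end recovery runs the full pipeline on 20 samples × 9,000 reads of
700 bp at 0.5% error with 17 database taxa and 3 withheld. The
shift-detection check simulates counts as negative binomial with size 10
and mean 200 (CV ≈ 0.33, comparable to the pipeline's own rarefied
replicate dispersion) with a 4-fold shift in one taxon.

## Known limitations

- Primer sequences are inputs, not shipped defaults: the source study cites
  them from earlier work without printing them.
- The chimera procedure and the de novo linkage policy are pinned readings
  of one-sentence descriptions; both are configurable and their alternatives
  (no chimera check; exact vs indexed linkage) are exposed.
- Real-data headline numbers (total taxon counts, specific PERMANOVA F,
  specific LDA scores) depend on the original 454 dataset and 2014-era
  reference databases and are not reproducible at desk scale; the package's
  claims are therefore boundary behavior, oracle equivalence, calibration
  and recovery on simulated data.
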