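# Methods

`idrptm` implements a proteome-wide analysis of how intrinsic protein
disorder relates to post-translational modification (PTM) sites and to two
region-level sequence features — PEST regions and transmembrane (TM)
helices — across multi-species protein sequence sets, together with a
synthetic-proteome generator that plants every effect the statistics are
meant to measure. This note records the models, the defaults and why they
are what they are, and the choices made where the design was genuinely open.

## Data model

A proteome is an ordered set of identified amino-acid sequences for one
species. Sequences are normalised at ingestion (uppercased, terminal stop
characters stripped, ambiguity codes B/Z/U/O folded to X with a warning).
X participates in lengths and in wildcard positions but never satisfies a
literal residue class. All residue coordinates are 1-based inclusive,
matching the numbering conventions of the disorder and site predictors
whose outputs the annotation tables carry (per-residue disorder masks;
phosphorylation, ubiquitination and N-glycosylation sites; signal-peptide
and TM-helix segments). Those predictors are consumed, never re-implemented:
their role here is an input contract, validated at load (positions in
bounds, site residue types S/T/Y/K/N enforced, strict and lenient modes).

Proteins shorter than 50 or longer than 4000 residues are removed before
any statistics; both boundaries are kept (only strictly shorter/longer
records are removed).

## Redundancy clustering and the specific/common contrast

Near-duplicate sequences inside a proteome inflate every downstream count,
so statistics run on cluster representatives. Clustering is deliberately
simple and exact: pairwise global alignment; an edge whenever percent
identity (identical aligned pairs / aligned pairs) and percent match length
(aligned pairs / shorter sequence length) both reach their thresholds
(default 90/90); connected components as clusters; the longest member
(ties: smallest id) as representative. The partition, not the clustering
engine, is what the analysis consumes, and external cluster assignments
(e.g. genuine ortholog groups from a dedicated tool) can be loaded from TSV
in its place. Full-proteome scalability is a non-goal; an edit-distance
bound (identities of any alignment ≤ (la+lb−d)/2, d the unit-cost edit
distance, computed banded) discards almost all non-candidate pairs before
any alignment, which keeps desk-scale inputs fast without heuristics that
could change the partition.

**Alignment scoring.** Default: match +1, mismatch 0, gap open −5, gap
extend −1, all configurable. An affine opening cost is load-bearing: with a
linear gap cost equal to the extension cost, the optimal global alignment
of a short protein against a much longer one scatters the short sequence's
residues across the long one (every aligned column, even mismatched, is
cheaper than two gaps), manufacturing near-100% identity between unrelated
proteins of disparate lengths. The affine default keeps alignments
contiguous, so the 90/90 thresholds mean what they say.

For the conservation contrast, clusters confined to one species (including
singletons) are *specific*, clusters covering every species of the panel
are *common*, anything else is *intermediate* and excluded. Per-protein
metrics (disorder fraction; PTM densities per 400 aa) are compared between
the two categories with a one-tailed Welch unequal-variance t-test in the
direction specific > common; a permutation test of the mean difference
(exhaustive at small n) is available as an alternative, since "t-test" under
unequal group sizes is safest read as Welch.

## Sequence-defined scanners

Three features are defined by sequence alone and are implemented here.

**Plant O-glycosylation consensus** `[A/S/T/V]-P(1,4)-X(0,10)-[A/S/T/V]-P(1,4)`,
the hydroxyproline-directed motif of plant cell-wall proteins. The scan is
leftmost and non-overlapping; at each start position the canonical
instantiation ends as early as possible (shortest wildcard spacer), while
each proline element absorbs its whole run up to four. This makes tandem
repeats count as multiple sites (APAPAPAP → two), which is the reading
consistent with per-protein site counts on the ~1 site/protein scale; an
all-overlapping mode exists because the original script's conventions are
not published. One motif occurrence counts as one site; the anchor is the
first proline.

**N-glycosylation sequons** N-X-S/T with X ≠ P, all occurrences including
overlapping ones. Because N-glycosylation happens in the ER lumen, raw
sequons are gated by secretory evidence: a protein is admitted if it has a
signal peptide or at least one TM helix (variant: signal peptide only), and
within admitted proteins sequons anchored inside a TM helix (buried) or
inside the signal peptide itself (cleaved before maturity; default first 20
residues when the annotation does not state the cleavage site) are excluded.
"Combining" site predictions with secretory predictions admits several
readings; this gate is the least machinery that encodes the biology, and
every part of it is switchable.

**PEST regions.** Candidate regions are maximal stretches of ≥ 12 residues
between positively charged flanks (K, R, H; sequence termini also act as
flanks) containing at least one P, one of D/E and one of S/T. Each is scored
with the classic PEST-find score: 0.55 × (mass percent of D/E/P/S/T,
corrected by one equivalent of each class — the lightest member present is
subtracted) minus 0.5 × a hydrophobicity index (mole-fraction-weighted mean
of Kyte–Doolittle hydropathy rescaled to 0–90 via 10·KD + 45). Regions
scoring above +5 are reported. Standard average residue masses are used; X
gets the mean residue mass and neutral hydropathy. Exact tool-version
details of the reference implementation (e.g. terminus handling) are not
recoverable; the constants live in one place and the threshold is a
parameter.

## Statistics

**Per-400-aa densities.** Counts are normalised to a uniform 400-residue
length. Proteome-level densities are pooled (Σcounts × 400 / Σlength), not
means of per-protein densities — "normalised to a uniform length" reads
most naturally as a proteome-length normalisation, and pooling is what
makes the worked two-protein example (1 site/100 aa + 0 sites/300 aa → 1.0
per 400) come out. A per-protein-mean mode exists.

**Binned correlation.** Proteins are grouped by predicted site count
0,1,…,6 with counts ≥ 7 pooled into a final bin; each non-empty bin carries
the arithmetic mean of its members' disorder content (disordered residues /
length). The Pearson correlation is computed over (bin index, mean
disorder) — the pooled tail takes the index value 7 — and tested one-tailed
via t = r√(n−2)/√(1−r²) against Student t with n−2 degrees of freedom,
where n is the number of *non-empty* bins; series with fewer than three
points or zero variance are flagged not computable rather than reported.
Using the bin index (not the within-bin mean count) keeps the x-variable
well defined for the pooled tail; a switch selects the mean-count variant.
For n = 8 the implementation agrees with the closed-form even-degree t tail
to 10⁻¹² (tested), and recomputing p from published correlation values at
n = 8 reproduces the published one-significant-figure p-values for the
entries whose bin count was in fact 8 (a few published cells are consistent
only with smaller bin counts — empty bins were evidently dropped there too,
but the exact counts are unstated, so those cells are not asserted).

**Multiple testing.** Benjamini–Hochberg step-up, implemented directly
(sort ascending, q(i) = p(i)·m/i, enforce monotonicity downward from the
largest rank, cap at 1, return in input order) and cross-checked in tests
against an independently stated oracle and statsmodels. The default family
is the eight parameter tests within one species; a global family (all
species × parameters) is available — published FDR grids are not exactly
reproducible under either family, so the choice is surfaced rather than
hidden. Note the step-up adjustment is not idempotent in general; constant
vectors are fixed points and output never falls below input, and those are
the invariants tested.

**Rd/o.** For site-anchored PTMs only (phosphorylation, O-/N-glycosylation,
ubiquitination — not region-type features), Rd/o = (Nd/Ld)/(No/Lo) with Nd,
No the counted sites anchored on disordered/ordered residues and Ld, Lo the
pooled residue counts over the proteome. Group and total values pool the
four components across species and recompute the ratio — never the mean of
per-species ratios (the two differ; the worked example in the tests shows a
case where pooling gives 1.0 and the ratio mean does not). Degenerate cases
are explicit: No = 0 with Nd > 0 reports infinity, zero-length segments
report missing.

**Ubiquitination confidence band.** Only sites with scores in the
medium-confidence band 0.69 ≤ s ≤ 0.84 (both ends inclusive) count. As
printed, the band excludes higher-confidence sites; whether that was
intended is unknowable, so the band is a parameter and the printed text is
the default.

## Synthetic proteomes

The generator emulates the statistical structure the analysis assumes;
it makes no attempt at biological realism beyond that (no evolution models,
no real-predictor mimicry). Defaults are the study conditions; the sizes
used by tests and the acceptance script (2,000 proteins for parameter
recovery, 150 for redundancy recovery, 3 × 400 for the pipeline panel) are
the package's fixture scales.

* **Lengths**: log-normal, median 320 aa, σ 0.55, clipped to 50–4000.
* **Disorder**: per-protein fraction from Beta(mean·c, (1−mean)·c), c = 8,
  baseline mean 0.20 for common families; realised as contiguous segments
  (mean segment ≈ 40 aa, exact total within rounding) composed
  preferentially of disorder-promoting residues (A, R, G, Q, S, E, K, P),
  with ordered segments enriched in I, L, V, C, W, Y, F, N.
* **PTM sites**: for each type, the count contributed by a region is
  Binomial(region length, rate) with rate = base/400 in ordered and
  ρ·base/400 in disordered residues, then placed on legal residues (S/T/Y,
  K, N) of that region. Drawing counts against *region length* rather than
  legal-residue counts makes the planted ρ exactly the quantity
  (Nd/Ld)/(No/Lo) estimates, independent of the compositional bias between
  region types. Default ρ per type follows the proteome-wide enrichment
  scale reported for algae (S-pho 18.8, T-pho 10.5, Y-pho 1.3, O-gly-role
  3.3, N-gly-role 1.2, ubiquitination 12.5); base ordered densities are set
  so pooled per-400 densities land in the reported ranges. Ubiquitination
  sites carry in-band scores; ~30% additional decoy sites carry
  out-of-band scores so the confidence filter has something to reject.
* **Slope mode**: when a positive site-count/disorder slope is configured,
  construction inverts — counts are drawn first (Poisson at the base rate)
  and the protein's disorder target is baseline + slope × count, planting a
  linear bin-series relation for the correlation machinery to recover.
* **Secretory features**: a configurable fraction (default 0.25) gets a
  hydrophobic signal peptide (15–30 aa, forced ordered); TM helices (19–23
  aa, hydrophobic, placed only in ordered stretches) follow a Poisson law
  whose rate decays with the protein's disorder fraction (∝ (1−f)⁴,
  renormalised to the configured mean count). The decay is deliberate:
  membrane proteins as a low-disorder class is the negative TM–disorder
  association the analysis reports, and placement constraints alone do not
  reproduce its sign.
* **Families**: a configurable fraction of proteins (default 0.25) belongs
  to common families with one diverged member (5% substitutions) in every
  species; the rest are species-specific singleton families whose mean
  disorder is multiplied by 1.7, planting the conservation contrast.
* **Redundancy**: 10% of records are near-duplicates (2% point mutations,
  ≈98% identity) of other records, with ground-truth links.
* **Determinism**: one integer seed; per-protein streams derived by
  key-splitting (`SeedSequence([seed, tags…])`), so adding species or
  proteins never perturbs existing ones. Identical configs produce
  byte-identical outputs.

What passing recovery tests shows is that the estimators measure what they
claim on data that satisfies their assumptions — independent sites, clean
masks, exactly planted rates. Real proteomes violate these in ways the
generator does not emulate (predictor errors correlated with composition,
domain structure, shared evolutionary history), so recovery here bounds
implementation correctness, not real-data validity.

## Pipeline

Stages run in the analysis order: length filter → redundancy clustering and
representative selection → scanning/annotation join → per-species
statistics → cross-species classification and contrast. Every stage
persists TSV intermediates; p and FDR columns are written at full precision
with a one-significant-figure display column alongside. Provenance records
a config hash and the package version; timestamps are deliberately absent
from data files so identical configs are byte-identical. The specific/common
classification runs on the redundancy-filtered records (matching the stage
order); external cluster catalogs and planted ground truth are alternative
sources.

## Known limitations

* All-vs-all clustering is quadratic; it is meant for fixture-scale and
  representative-set inputs, not raw multi-million-residue proteomes.
* The PEST scorer follows the published score definition, not any specific
  tool release; scores near the threshold may differ from other
  implementations in terminus handling.
* The secretory gate is sequence-annotation-driven; no topology model is
  consulted, so sequons in extracellular loops of multi-pass proteins are
  handled only by the TM-anchor exclusion.
* The generator's count-first slope mode and rate-first enrichment mode are
  alternative constructions; configuring both a large slope and extreme ρ
  simultaneously is not supported as an exact joint plant.
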