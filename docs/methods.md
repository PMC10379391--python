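# Methods

## Scope and model

`paleovar` asks, for a catalog of germline variants of one gene, whether each
variant's alternate allele is (a) carried by other vertebrate species at the
orthologous position — evidence compatible with cross-species conservation —
and (b) carried by dated ancient-human samples — which bounds the variant's
age from below by the oldest carrier's date. The package treats both
questions as deterministic annotation problems over explicit inputs (a
variant table, a multiple alignment, per-sample pileups) plus one
statistical comparison (PV vs BV sharing rates).

## Catalog construction

* **Inclusion.** Only single-nucleotide variants and 1-bp indels are kept;
  any event spanning more than one base (`c.100_102del`, delins, multi-bp
  ins) is excluded with reason `multi_bp_span`. Clinical significance is
  matched case-insensitively against the canonical ClinVar strings:
  Pathogenic / Likely pathogenic (and the combined form) → PV; Benign /
  Likely benign → BV; everything else — uncertain significance, conflicting
  interpretations, risk factors — is excluded. Intronic variants
  (`c.211+1G>A`, `c.2996+264T>C`) are retained; UTR-anchored names (`c.-5`,
  `c.*12`) are not modeled and are logged as unparseable.
* **Coordinates.** Genomic coordinates are 0-based half-open internally;
  HGVS anchors stay 1-based. The transcript model (exons + CDS bounds)
  drives cDNA↔genomic mapping; on minus-strand transcripts alleles are
  reverse-complemented to the genome forward strand, and the mapping is
  verified in tests against an exhaustively enumerated coordinate table and
  by round-tripping through the inverse mapping.
* **Indel anchoring.** Insertions/duplications are anchored at the base
  *after* which material is inserted; deletions at the deleted base. When a
  reference sequence is supplied, 1-bp indels are left-normalized (VCF
  convention) so caller and catalog agree on representation.
* **Domains.** Protein-domain labels come from a configurable interval map
  on cDNA coordinates; intronic variants take the domain of their nearest
  exonic anchor (the HGVS anchor itself). The bundled *PALB2* map
  (coiled-coil 25–132, ETGE 199–282, ChAM 1183–1338, WD40 2557–3558) holds
  working boundaries consistent with the per-variant domain annotations of
  the bundled carrier table; it is not an authoritative domain definition.

## MAF projection and sharing calls

Blocks are tokenized with Biopython's MAF parser; only `s` rows are used
(`i`/`e`/`q` status lines carry no sequence). Rows recorded on the minus
strand are normalized at read time — text reverse-complemented into the
reference-forward frame, start converted to `srcSize − start − size` — so a
single frame serves all lookups; re-expressing any row on the other strand
is a no-op for every downstream call (a tested invariant). Blocks must not
overlap on the reference; an index of block start positions gives
logarithmic position lookup, with per-block column arrays mapping reference
offsets to alignment columns. Soft-masked bases are uppercased: masking is
annotation, not sequence. If a species appears twice in a block the first
row wins and a warning is issued.

SNV sharing requires the species base to equal the human ALT exactly;
matching the REF is `not_shared`; gap, `N`, and absent are `no_alignment`
(how `N` columns were counted is a genuine ambiguity; we chose the
conservative reading). Indel sharing demands a cleanly aligned event: for a
deletion, a species gap at the deleted base plus `k` adjacent reference-base
columns on each side where the species matches the reference (default
`k = 3`); for an insertion/duplication, exactly one extra species base equal
to the inserted base in reference-gap columns between the anchor and its
successor, with the same flank rule. When flanks cannot be established the
call is `no_alignment`, so raising `k` can only move calls toward
`no_alignment`, never from `not_shared` to `shared` (tested monotonicity).

Per-species sharing rate = shared count / catalog size: `no_alignment` cells
stay in the denominator, matching the rate definition "shared variants
divided by total PVs or BVs". Variant-level sharing counts species per
variant; both the number of species sharing ≥ 1 variant and the number of
variants shared with ≥ 1 species are reported, since either convention may
be wanted.

## Statistics

The PV and BV per-species rate vectors are compared with a two-sided
Mann–Whitney U test. With `n_a + n_b ≤ 20` the exact null distribution of
the rank-sum is computed by dynamic programming over the observed midrank
multiset, so ties are handled exactly; otherwise the normal approximation
with the standard tie correction and a continuity correction is used. The
two-sided p is `min(1, 2·min(P(U ≤ u), P(U ≥ u)))`. Exact mode is verified
against full enumeration of all rank assignments for every group size up to
6, and against scipy on tie-free data (scipy offers no tie-aware exact mode,
which is why the implementation is local). Species with zero alignment
coverage are included as rate 0 by default (configurable). α = 0.05; fewer
than two species per group is an input error.

## Ancient genotyping

A mapping/duplicate-marking/GATK chain is deliberately not reproduced; the
caller operates on per-sample pileup columns (base, base quality, distances
to both read termini in read orientation, orientation flag) so every
accept/reject decision is explainable:

* call an alternate allele at a column when ≥ `a` observations with quality
  ≥ `q` support one non-reference base (defaults `a = 2`, `q = 20`); columns
  with fewer than `d = 3` passing observations still report but carry
  `low_depth`, because ancient data are sparse;
* ties between alternate bases break deterministically (count, then
  lexicographic);
* deamination flagging: a C>T call whose every supporting read is
  forward-oriented within `w` bases of its 5′ terminus (default `w = 2`), or
  a G>A call supported only by reverse-orientation reads within `w` of their
  read-frame 5′ terminus, is `damage_suspect`. A single interior or
  opposite-orientation supporting read clears the flag. Damage-suspect hits
  on pathogenic variants are dropped from carrier records by default and
  logged.

Diploid genotypes are not modeled: the analysis needs carrier status
(presence of the alternate allele), not zygosity. Pileup observations carry
bases only, so the pileup arm calls substitutions; indel variants enter
timelines through the carrier-table path.

## Timelines and cohort summary

Carrier records group per variant; the **arisen time** is the oldest
carrier's date in years BP (order-free maximum). Timelines sort by carrier
count descending, then cDNA anchor ascending. Dates are point estimates;
"older than" entries are stored as a floor with a censored flag, rendered
`>floor` in tables, treated as ≥ floor in max/min and as older than any
cutoff ≤ floor. In variant-level tables that give only each variant's oldest
date, the remaining carriers expand as undated records and count as within
the recency cutoff — the only convention consistent with publishing a
carrier-level recency percentage alongside per-variant oldest dates.
Temporal percentages are computed over carriers; mutation-type, domain and
recurrence percentages over variants.

## Synthetic data: what it emulates, and what not

* **Sequences** evolve along a user newick tree (default: nine vertebrates
  from chimpanzee to coelacanth around a human reference, branch lengths in
  substitutions/site). Substitution is a per-branch single-event model: a
  site changes with probability `1 − exp(−m·t)` (`m` = CpG multiplier 4 at
  CpG context, else 1) and the target base is a transition with probability
  `κ/(κ+2)` (κ = 2). This creates the transition bias and CpG-elevated C>T
  that matter for the analysis, but it is not a full reversible CTMC — no
  multiple hits along one branch, no equilibrium frequencies — so branch
  lengths are event probabilities, not evolutionary distances. The two-taxon
  expectation `L(1 − e^{−t})` is the model's own closed form and is asserted
  within 3σ. 1-bp indels occur at rate 0.02/site/branch-unit, split evenly
  between deletion and insertion; the true column alignment is recorded by
  construction.
* **MAF emission** splits the alignment into 40–90-column blocks and
  re-expresses non-reference rows on the minus strand with probability 0.3.
  Block boundaries avoid a small window around planted indels so the flank
  context the sharing rule needs survives emission; all-gap rows are omitted
  (standard MAF practice). Reading the emitted MAF reproduces the truth
  alignment at every position (tested).
* **Catalog planting** puts 60 PV (5% shared) and 120 BV (70% shared, 30%
  intronic) on the locus: "shared" variants take an allele some species
  actually carries at that column, "unshared" ones an allele no species
  carries; per-species truth is then read off the true alignment. Planted
  deletions (4) split between columns with and without clean species gaps.
  Distractor rows (8 uncertain-significance, 4 multi-bp) exercise the
  exclusion logging. An optional per-species forcing mode places every
  variant where a chosen species differs and errors if the alignment cannot
  satisfy it. The PV/BV shared fractions are the standing effect size: they
  produce the strong benign-over-pathogenic sharing excess the comparison is
  meant to detect.
* **Ancient cohort**: 40 samples dated uniformly on 270–48,426 BP (the span
  of the real resource the arm emulates), ~6× coverage of 60-bp reads,
  base-error 0.002, terminal deamination rate 0.2 within 2 bases of the
  read 5′ terminus (C>T forward, genomic G>A on reverse reads — the same
  event seen from the other strand), carrier probability 0.04 per variant
  per sample with all reads of a carrier showing the alternate allele.
  At these conditions the defaults recover planted carriers with
  sensitivity ≈ 0.96–0.99 across seeds.
* **Not emulated:** read mapping and alignment error, duplicate reads,
  contamination, reference bias, population structure among samples,
  calibrated date uncertainty, multi-nucleotide and structural variation.
  Passing tests therefore demonstrate the correctness of the projection,
  calling, filtering and dating logic under a clean generative model — not
  robustness to upstream artifacts real resources contain.

Problem sizes were chosen so the full suite and the acceptance script each
run in minutes on one CPU: a 3 kb locus, 9 species, ~190 variants, 40
ancient samples. All randomness flows through one seeded generator;
identical seed and configuration give byte-identical output files.

## Known limitations

* The per-branch substitution model understates homoplasy on long branches;
  apparent sharing with distant species by recurrent mutation is therefore
  rarer in synthetic data than in reality.
* The exact Mann–Whitney DP is quadratic in total rank mass and intended
  for the ≤ 20-observation regime it is used in.
* The carrier-table expansion convention (undated co-carriers count as
  recent) is correct for the bundled table's published counts but is a
  convention, not an inference.
* Sharing rates use the full catalog as denominator; species with poor
  alignment coverage are penalized rather than excluded (configurable in
  the statistical comparison only).
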