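# paleovar

**Variant archaeology for a disease-gene catalog: cross-species allele
sharing and ancient-carrier dating.**

Where do the pathogenic germline variants seen in modern humans come from?
For a gene like *PALB2* — the BRCA2 partner whose truncating variants
predispose to breast, ovarian and pancreatic cancer — two histories are
possible: a variant allele may be ancient, inherited through cross-species
conservation (the non-reference allele is the ancestral state still carried
by other vertebrates), or it may have arisen recently within the human
lineage. `paleovar` implements the two complementary analyses that
distinguish these histories:

1. **Cross-species arm.** Each catalog variant (ClinVar-style: HGVS cDNA
   name, clinical significance, consequence) is mapped from transcript to
   genomic coordinates and projected through a multi-species whole-genome
   alignment (MAF). For species *s* and variant *v* with alternate allele
   ALT(*v*), the sharing call is

   * `shared` if *s* carries ALT(*v*) at the aligned position,
   * `not_shared` if *s* carries the reference or another base,
   * `no_alignment` if the position is gapped, `N`, or unaligned in *s*.

   1-bp indels are shared only when the event is cleanly visible: a gap (or
   extra base) aligned to the human event with *k* matching flanking columns
   on each side (default *k* = 3). Per-species sharing rates are
   `shared / catalog size`, and pathogenic (PV) vs benign (BV) rate
   distributions are compared with a two-sided Mann–Whitney U test (exact,
   tie-aware enumeration for small species panels).

2. **Ancient arm.** Dated ancient-human samples are genotyped over the locus
   with a transparent pileup threshold caller (min base quality 20, ≥ 2
   alt-supporting reads; sparse columns are reported with a `low_depth`
   flag). Post-mortem deamination artifacts — C>T supported only within a
   few bases of the read 5′ terminus, or G>A on reverse-orientation reads —
   are flagged and excluded from pathogenic-variant hits. Calls intersected
   with the catalog yield carrier records; each variant's **arisen time** is
   the date (years BP) of its oldest carrier, a lower bound on the variant's
   age.

A synthetic-data module generates every input with recorded ground truth —
sequences evolved along a phylogeny with transition bias and CpG-elevated
C>T, strand-flipped MAF blocks, a planted PV/BV catalog, and
deamination-damaged ancient reads — so the full pipeline is testable without
any external download.

## Worked example

The analysis scripts run the whole study end-to-end on the synthetic inputs
(seed 1):

```bash
python analysis/01_simulate.py
python analysis/02_build_catalog.py
python analysis/03_crossspecies_sharing.py
python analysis/04_compare_pv_bv.py
python analysis/05_ancient_carriers.py
python analysis/06_carrier_table_cohort.py
```

Outputs land in `results/`. What the scripts print (seed 1):

```
196 input rows -> 184 catalog variants (64 PV, 120 BV); 12 excluded:
  {'significance': 8, 'multi_bp_span': 4}
PV: 5/64 variants shared with >=1 species (7.8%); ... 0 mismatches vs planted truth
BV: 88/120 variants shared with >=1 species (73.3%); ... 0 mismatches vs planted truth
PV median rate 0.016 vs BV 0.121: U=7.0, p=0.006061 (exact), significant at alpha=0.05
planted-carrier recovery: sensitivity 0.982 (275/280), 1 spurious carrier records
```

The catalog filter keeps only Pathogenic/Likely pathogenic and Benign/Likely
benign 1-bp events (uncertain/conflicting significance and multi-bp spans
are logged and dropped); the sharing matrix recovered the generator's truth
table exactly; benign variants are far more shared across species than
pathogenic ones (exact Mann–Whitney, p < 0.05); and the damage-aware caller
recovered 98% of the planted ancient carriers at ~6× coverage with
deamination rate 0.2.

Script 06 runs the timeline-only path on the bundled variant-level carrier
table (50 *PALB2* pathogenic variants observed in ancient humans):

```
50 distinct PVs in 71 ancient carriers, dated 32895 to 689 BP
64 carriers (90.1%) within the last 10000 years
mutation types: {... 'stopgain': 32 ...}
domains: {... 'WD40': 18 ...}
16 variants (32.0%) in multiple individuals; carrier-count histogram
  {'1': 34, '2': 12, '3': 3, '4': 1}
```

A `paleovar` console script exposes the same stages as subcommands
(`simulate`, `catalog`, `crossspecies`, `stats`, `ancient`, `report`); see
`paleovar --help`.

## Layout

```
src/paleovar/      library: catalog, maf, crossspecies, stats, ancient,
                   synthetic, cli (+ bundled data/)
analysis/          numbered narrative drivers writing results/
tests/             pytest suite (unit, property, acceptance)
scripts/           acceptance.py
docs/methods.md    models, conventions, parameter choices, limitations
```
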