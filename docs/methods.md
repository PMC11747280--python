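# Methods

`breakscape` quantifies how chromosome architecture shapes the repair of
induced DNA double-strand breaks (DSBs). It implements three analysis
layers — ChIP enrichment around breaks, observed/expected (O/E) Hi-C
domain statistics, and translocation-junction analytics — plus a
synthetic-study generator with known injected effect sizes, so the whole
stack is testable end to end without sequencing data.

## The experimental design being modelled

The reference system is a human cell line carrying an inducible AsiSI
restriction enzyme (recognition site `GCGATCGC`, palindromic, 8 bp).
Induction cuts a reproducible set of genomic sites (~80 per cell at
genome scale), each of which nucleates a megabase-scale γH2AX "damage
domain". Conditions combine a damage state (`NT` untreated / `DSB`
induced) with a genotype: `WT`, cohesin-depleted (`RAD21-`, degron),
phosphorylation-deficient cohesin (`SMC1A_Pdef`), ATM kinase inhibition
(`ATMi`), and ligase-4 knockout (`LIG4-`, NHEJ-dead).

## Analysis layers

### ChIP enrichment (`breakscape.enrichment`)

* **Break calling.** A candidate cut is called broken when the mean
  MRE11-like coverage within ±`flank` (default 500 bp) of the cut exceeds
  `min_fc` (default 3) times the local background, the median coverage of
  a ±10×`flank` window with the core excluded.
* **Distance shells.** Every peak is assigned the shell of its summit's
  distance to the nearest called break: ≤10 kb, ≤250 kb, ≤1 Mb (disjoint,
  inclusive upper bounds) or control (>1 Mb, including peaks on
  break-free chromosomes). A cumulative mode is available behind a flag;
  disjoint is the default because it keeps the shell-vs-control tests
  independent.
* **Fold change.** Per-peak signal is the mean per-bp coverage over the
  peak interval (robust to peak-width variation, unlike summit height);
  FC = (treated + ε)/(untreated + ε) with ε = 0.1 for all ChIP ratios.
* **Anchors.** Cohesin anchors are RAD21 peaks whose summit lies within
  500 bp of a CTCF summit. Anchor enrichment is compared inside vs
  outside damaged γH2AX domains with a one-tailed Welch test.
* **γH2AX domain calling.** Per bin, z = (treated − untreated)/sd(untreated
  over the chromosome); runs of z > 1 containing a seed bin (z > 2)
  become domains, domains closer than 100 kb merge, domains shorter than
  100 kb are dropped. This caller presumes the untreated track carries
  the regional (biological) variability of the treated one, so that
  background z stays far below the seed threshold; with purely technical,
  condition-independent noise a per-bin z threshold of 2 would seed ~8%
  of background bins and is not usable (see generator notes below).

### Hi-C domain statistics (`breakscape.hic`)

* **O/E.** The expected profile is the raw per-diagonal mean of the
  contact matrix (zeros included, no smoothing); O/E divides each entry
  by the expected value at its separation. Entries at separations with
  zero expectation are masked (NaN). Because the profile is computed
  from the matrix itself, O/E is invariant to per-diagonal rescaling —
  a gain applied uniformly across a whole diagonal is absorbed into the
  expectation. This matters when interpreting genome-wide uniform gains
  (see limitations).
* **Domain scores.** Intra-domain: mean O/E over unordered within-domain
  bin pairs, main diagonal excluded (self-bins are dominated by technical
  signal; inclusion is available behind an option). Inter-domain: mean
  O/E over the cross rectangle between two non-overlapping domains on the
  same chromosome. The domain unit for Hi-C statistics is the TAD
  (damaged = contains ≥1 called break); γH2AX intervals are the domain
  unit for ChIP and junction contexts.
* **Fold changes.** Per domain (or pair), FC = score(DSB)/score(NT).
  Damaged-group FCs are tested against 1 with a one-tailed paired
  (one-sample) t; damaged vs control groups with one-tailed Welch.
  Control pair sets are sampled to match the genomic-separation
  distribution of the damaged pairs (nearest-separation matching without
  replacement, seeded), standing in for an unspecified matching rule.
* **Viewpoint tracks.** 4C-like per-bin log2((treated + 1)/(untreated + 1))
  of raw contacts from the row of the break-containing bin, ±2 Mb,
  clipped at chromosome ends.
* **Translocation windows.** On 250 kb inter-chromosomal matrices, the
  window score is the sum of the 5×5 bin block (1.25 Mb × 1.25 Mb)
  centred on the interaction point, edge-clipped; log2 fold changes of
  window sums add a 0.1 pseudocount.

### Junction analytics (`breakscape.junctions`)

* Records with prey within ±20 kb of the bait on the bait chromosome are
  bait-proximal and removed from class analysis; the remainder is
  cis-deletion (prey on the bait chromosome) or translocation.
* Damage context: `break_site` (prey within ±2.5 kb of a cut — a
  configurable default; the window size is not dictated by the assay),
  else `gh2ax_domain` (inside a damaged domain), else `outside`.
* Microhomology is the longest k with the bait flank's last k bases equal
  to the prey flank's first k bases; `N` never matches. Junction
  distances are reported in whole kbp (floor). Binned counts (1 kb)
  deduplicate by exact prey coordinate and strand — a stand-in for the
  upstream pipeline's molecule-level dedup, which is out of scope.
* Condition fold changes compare library-size-normalized per-site event
  rates (events per 1,000 library junctions), ε = 0.1 on the rates, with
  a one-tailed paired t across sites. Counts entering this comparison are
  *not* coordinate-deduplicated: synthetic libraries contain one record
  per molecule, so coordinate collisions are genuine independent events,
  and dedup would saturate at high rates.

### Statistics kernels (`breakscape.stats`)

Equal-n comparisons use the one-tailed paired t (t = mean(d)/(sd(d)/√n),
df = n − 1); unequal-n comparisons use one-tailed Welch with
Satterthwaite df. Box summaries use type-7 quantiles with whiskers at
q1 − IQR and q3 + IQR, not clamped to the data. Raw p-values are
reported without multiple-testing correction, with stars at 0.05 / 0.01 /
0.001. scipy supplies only the t distribution; the statistics themselves
are computed explicitly and cross-checked against scipy in the tests.

## The synthetic-study generator (`breakscape.simulate`)

Everything is a pure function of `(config, seed)`; sub-streams are keyed
per purpose so that, e.g., the γH2AX regional field of a genotype is
shared between its damage states while technical noise is not.

**Genome.** Default 2 chromosomes × 25 Mb — a deliberate scale-down of a
3 Gb genome chosen to keep a full study under a minute while leaving
enough TADs (~50) and breaks (8 of 16 AsiSI sites cut) for stable group
statistics. TADs tile each chromosome with sizes uniform in 0.6–1.4× the
1 Mb mean. Anchors sit at every TAD border plus two interior positions
per TAD. Cuts are placed 5 kb from an interior anchor (breaks in the
study frequently have cohesin/CTCF sites within 10 kb) and at least
2.4 Mb apart, echoing the study's preference for isolated baits at
reduced scale. Damage domains are ±1 Mb around each cut, matching the
observed ~1 Mb reach of damage-induced cohesin accumulation.

**ChIP tracks** (100 bp bins, rpkm-like units, Poisson counts at
`reads_scale` per density unit). RAD21/CTCF form 1 kb triangular peaks
(apex 30/25) at anchors over a flat 0.2 background; the triangular shape
is a modelling choice — the real decay shape away from anchors is not
characterized. Under damage, RAD21 peaks inside damaged domains are
multiplied by the genotype's enrichment factor (defaults mirror the
study conditions: WT 1.43, LIG4⁻ 1.73, SMC1A^Pdef 1.17, ATMi 1.30; an
optional distance-graded profile gives ≤10 kb / ≤250 kb / ≤1 Mb shells,
WT 1.43/1.34/1.20, ATMi 1.30/1.11/1.02). Non-colocalized (NIPBL-like)
RAD21 peaks gain the same damage factor — diffuse cohesin gain near
breaks associates with loading sites. MRE11 peaks (apex 20) appear only
at cut sites under damage. γH2AX is a +4.0 plateau over damaged domains
riding on a smooth lognormal regional field (sd 0.4, 50 kb correlation
length) that is *shared* between the damage states of a genotype: the
chromatin context that shapes γH2AX background is a property of the
genome, not of the treatment. This shared field is what makes the
z-score domain caller well calibrated — sd(untreated) reflects regional
variability while treated − untreated cancels it.

**Hi-C.** Intra-chromosomal expectation ∝ (d + 1)^(−α) (α = 1), times a
TAD boost of 2 for same-TAD pairs (removed under `RAD21-`), times the
damage effects: same damaged TAD × 1.02 (WT/SMC1A^Pdef; eliminated under
ATMi), distinct damaged TADs × γ (RAD21⁻ 1.16, SMC1A^Pdef 1.04, ATMi
1.03), distinct undamaged TADs × 1.06 under RAD21⁻. Totals are scaled to
`depth` expected counts per chromosome and drawn Poisson, symmetrized.
Inter-chromosomal matrices (250 kb) are a uniform baseline carrying a
per-site lognormal contact propensity (sd 0.5) at damaged-domain bins —
without site-to-site heterogeneity, translocation frequency could not
meaningfully track contact frequency — boosted ×γ_trans under damage
(WT 1.31, RAD21⁻ 1.39 with a 1.385 damage-independent baseline scale, so
the depleted-vs-WT damaged contrast lands near 1.47).

**Junction libraries.** Per library junction, the category is drawn
multinomially: translocation (rate 0.15 × condition multiplier; prey
sampled among other-chromosome cut sites ∝ the bait–prey trans-window
score), cis-deletion (0.05 × multiplier; prey among same-chromosome cuts
with distance-decay weights), genome background (0.02), and bait-proximal
rejoining (the remainder; an explicit `bait_proximal_fraction` instead
fixes the share and rescales the rest). Condition multipliers mirror the
study: translocations ×4.3 (RAD21⁻), ×1.9 (ATMi), ×2.1 (SMC1A^Pdef),
near zero (LIG4⁻); cis-deletions ×6.0 (RAD21⁻), ×2.1 (SMC1A^Pdef). Prey
positions scatter ±300 bp around the cut. Microhomology lengths are
geometric (WT p = 0.65, mean ≈ 0.54 bp — low, NHEJ-like; LIG4⁻ p = 0.35,
elevated usage), capped at 12, and 20 nt flank pairs are constructed to
embed exactly the drawn overlap.

## What passing tests do and do not show

The generator emulates the *statistical structure* of the study — TAD
blocks on a distance-decay background, anchor-concentrated cohesin gain
inside damage domains, contact-tracking translocation frequencies —
under Poisson noise. It does not model read-level artifacts (mappability,
GC bias, PCR duplicates), matrix balancing, replication timing, sister
chromatids, resection-scale junction structure, or γH2AX spreading
dynamics. Parameter-recovery tests therefore demonstrate that the
analysis stack is an unbiased, correctly calibrated estimator of the
effects it targets under the stated noise model — not that it would
reproduce the study's numbers from raw sequencing data.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open everywhere; 1-based printed
  coordinates are converted on ingestion (starts − 1).
* Counts are floats throughout; normalized matrices are fractional.
* Ragged final bins (resolution not dividing chromosome length) are
  handled by shortening the last bin, never by padding; all window
  operators clip at chromosome ends.
* ε pseudocounts: 0.1 for ChIP fold changes and junction rates, 1 for
  viewpoint log2FC, 0.1 for trans-window log2FC.
* Zero-variance untreated γH2AX makes the domain-caller z undefined and
  raises, advising noise injection.
* Degenerate t-tests (zero-variance differences) raise rather than
  returning p = 0 or 1.
* Bait-filter and distance-shell bounds are inclusive (≤).

## Known limitations

* O/E self-normalization absorbs genome-wide uniform gains: at this
  scale damaged TADs are ~16% of all TADs, so the full RAD21⁻ effect set
  measures ~1.11 (damaged pairs) and ~1.01 (control pairs) rather than
  the injected 1.16/1.06. In a 3 Gb genome damaged TADs are ~2% of the
  total and the dilution is negligible — the scale-down, not the
  estimator, is responsible.
* The intra-TAD contact deficit under cohesin depletion is a structural
  consequence of removing the TAD boost under O/E, not an injectable
  parameter; at the default geometry it measures ~0.8.
* Control γH2AX-sized intervals can be scarce on short chromosomes
  (damage domains plus margins may cover most of the genome); the
  generator then returns fewer control domains than requested.
* The paired t is applied to per-domain fold changes as if domains were
  independent; long-range intra-chromosomal correlations are ignored,
  as in the modelled analyses.
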