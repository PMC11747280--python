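# breakscape

Analytics for DNA double-strand-break (DSB) repair studies that combine
ChIP-seq, Hi-C and high-throughput translocation sequencing (HTGTS) —
the kind of integrative design used to dissect cohesin's dual role in
repair: as an architectural factor that keeps damaged chromatin domains
apart, and as an ATM-phosphorylation-dependent repair factor that
accumulates throughout γH2AX domains.

The package is aimed at computational biologists who have (or simulate)
site-specific break induction (e.g. AsiSI) across conditions — wild
type, cohesin depletion, phosphorylation-deficient SMC1A, ATM
inhibition, ligase-4 loss — and want the downstream statistics, not the
read processing.

## What it computes

**ChIP enrichment around breaks** (`breakscape.enrichment`): MRE11-based
break calling against local background; per-peak fold changes
FC = (treated + 0.1)/(untreated + 0.1) of mean per-bp coverage, grouped
into distance shells d ≤ 10 kb, 10 kb < d ≤ 250 kb, 250 kb < d ≤ 1 Mb vs
control (> 1 Mb); RAD21×CTCF anchor colocalization; γH2AX damage-domain
segmentation from a per-bin z-score; anchor enrichment inside vs outside
damaged domains (one-tailed Welch).

**Hi-C domain statistics** (`breakscape.hic`): observed/expected (O/E)
normalization with E(d) = the raw per-diagonal mean; intra-domain scores
(mean O/E over within-TAD bin pairs, diagonal excluded) and inter-domain
rectangle scores for DSB–DSB vs separation-matched control TAD pairs;
per-domain DSB/NT fold changes with paired and Welch tests; 4C-like
viewpoint tracks log2((t+1)/(u+1)) over ±2 Mb; 5×5-bin translocation
window sums on 250 kb trans matrices with log2((s_t+0.1)/(s_u+0.1)).

**Junction analytics** (`breakscape.junctions`): bait-proximal filtering
(±20 kb), cis-deletion vs translocation classification, damage-context
assignment (break site / γH2AX domain / outside), microhomology length
(longest bait-suffix = prey-prefix, N never matches), 1 kb binned unique
events, junction distances in kbp, and condition fold changes of
library-normalized per-site rates.

**Synthetic studies** (`breakscape.simulate`): a seeded generator
producing a TAD-partitioned genome with cohesin/CTCF anchors, AsiSI
sites, ChIP tracks, distance-decay contact matrices with TAD blocks and
break–break clustering, and junction libraries whose translocation
frequency tracks contact frequency — with every effect size an injected,
recoverable parameter. See `docs/methods.md` for the model.

## Worked example

The packaged demo config simulates a two-chromosome study (WT and
cohesin-depleted, six induced breaks) and runs every stage:

```sh
breakscape report \
  --config src/breakscape/data/demo_config.yaml --out-dir demo_out
```

prints (exactly reproducible — the run is a pure function of the seed):

```
== WT ==
DSB calling: 6 called (recall 1.00, precision 1.00)
RAD21 D10K: mean FC 1.437 (n=6) ***
RAD21 D250K: mean FC 1.404 (n=5) ***
RAD21 D1M: mean FC 1.430 (n=25) ***
RAD21 CTRL: mean FC 1.003 (n=48)
Anchors inside/outside damaged domains: 1.427 vs 1.006 (n=34/39) ***
Intra-TAD O/E FC: damaged 1.0121 (n=6), control 0.9997 (n=19)
Inter-domain O/E FC: DSB-DSB 0.9861 (n=6), Ctrl-Ctrl 1.0131 (n=6)

== RAD21- ==
...
RAD21- vs WT: translocations x4.25, cis-deletions x6.18
```

Reading it: in WT, cohesin (RAD21) signal rises ~1.4-fold at peaks near
breaks and at anchors inside damaged domains while control chromatin
stays at 1.0, yet intra-TAD contacts barely move (~1%) — accumulation
without architectural change. Under cohesin depletion the anchor
response is gone and aberrant joining explodes: ~4× more translocations
and ~6× more cis-deletions than WT at equal library size. Stars are
raw-p thresholds *P<0.05, **P<0.01, ***P<0.001.

Per-stage TSVs (per-peak enrichment, per-domain and per-pair O/E fold
changes, labelled junctions, microhomology histograms) are written under
`demo_out/`, along with `run_log.txt` recording every n and parameter.

The `simulate`, `dsb-call`, `enrich`, `hic` and `junctions` subcommands
expose the individual stages on the on-disk formats (BED, bedGraph,
contact-triplet dumps with a `#resolution=` header, junction TSV).

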