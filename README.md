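# fluorotype

Endpoint-fluorescence SNP genotype calling and genotyping-platform
comparison for two-channel chemistries (TaqMan-, KASP- and rhAmp-style
assays).

Plant breeders and molecular biologists who run targeted SNP panels score
genotypes from a scatter of two allele-specific reporter signals per well:
homozygote A11 clusters near the X-axis, homozygote A22 near the Y-axis,
heterozygote A12 along the diagonal, and no-template controls (NTCs) near
the origin.  Choosing between chemistries means comparing, across the same
sample panel, how cleanly each one separates those clusters and what it
costs per reaction.  `fluorotype` provides the whole analysis as a
reproducible pipeline:

* a **synthetic plate generator** with planted genotype truth (the standard
  layout: 94 samples + 2 NTCs × 29 assays × 3 platform profiles = 2,784
  wells per platform), since raw fluorescence exports of such comparisons
  are rarely deposited;
* a transparent, NTC-anchored **allele caller** (FAILED / INVALID /
  A11 / A12 / A22 with a posterior quality score) replacing proprietary
  cloud auto-callers;
* the standard **cluster-geometry metrics**, all anchored at the per-assay
  NTC centroid (x₁, y₁):
  * separation angle α = tan⁻¹(Δy/Δx), Δx = x − x₁, Δy = y − y₁
    (via atan2; smaller A11 angle = better allele discrimination),
  * NTC distance D = √(Δx² + Δy²) (proportional to fluorescence gain),
  * compactness S = sample SD of member-to-centroid distances;
* **platform comparison**: one-way CRD ANOVA per metric (each successful
  amplification — or each cluster — as a replication), Fisher LSD mean
  separation with letter groups, and pairwise genotype concordance over
  jointly called cells;
* a **cost model** reproducing per-reaction kit economics from list prices.

## Worked example

Run the built-in three-platform scenario end to end:

```bash
fluorotype report --paper-like --seed 0 --out-dir out/
```

This simulates the plates, calls every well, and writes plates, calls,
metrics, ANOVA/LSD tables, concordance, costs and a consolidated
`report.txt`.  Highlights of the actual output at seed 0:

```
Call rates
platform_id  n_points  n_failed  failed_pct  amplified_pct  n_invalid  n_called
       KASP      2726       178    6.529714      93.470286          8      2540
     TaqMan      2726       225    8.253852      91.746148         52      2449
      rhAmp      2726        84    3.081438      96.918562          4      2638

Platform means with LSD letters
          metric platform_id     mean letters  lsd_value  alpha
separation_angle      TaqMan 0.351405       a   0.005890   0.05
separation_angle        KASP 0.190389       b   0.005890   0.05
separation_angle       rhAmp 0.189604       b   0.005890   0.05
    ntc_distance       rhAmp 4.548222       a   0.135932   0.05
    ntc_distance      TaqMan 1.728324       b   0.135932   0.05
    ntc_distance        KASP 1.368815       c   0.135932   0.05
```

Reading it: each platform genotyped 2,726 sample wells (2,784 minus the 58
NTCs); the rhAmp-style profile amplifies the most wells.  For cluster
separation, TaqMan's mean A11 angle (0.351 rad) carries letter "a" while
rhAmp and KASP share "b" — they discriminate the homozygote from the
heterozygote cloud significantly better (smaller angle), but are not
distinguishable from each other at α = 0.05.  For NTC-to-cluster distance
all three differ, with rhAmp's high fluorescence gain giving by far the
longest separation (4.55 vs 1.73 / 1.37 fluorescence units).  And the kit
economics:

```
$ fluorotype cost
platform_id  raw_cost  cost_per_reaction
      rhAmp   0.11898               0.12
       KASP   0.15109               0.15
     TaqMan   0.40650               0.41
```

i.e. $0.12, $0.15 and $0.41 per 5 µl reaction — rhAmp cheapest, TaqMan most
expensive.

Subcommands `simulate`, `call`, `metrics`, `compare` and `cost` expose the
individual stages (`--help` on each); everything is deterministic given
`--seed`, and the same seed reproduces byte-identical outputs.  The library
API mirrors the CLI (`fluorotype.simulate_experiment`,
`fluorotype.call_experiment`, `fluorotype.compare_platforms`, ...).

See `docs/methods.md` for the cluster model, caller definition, statistics
and limitations.

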