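# nemafauna

Soil nematode succession analysis for decomposition hotspots and other
localized enrichment pulses.

Nematodes are the most abundant soil animals and respond to organic
enrichment in functionally partitioned ways: fast-reproducing cp-1
bacterivores (colonizer–persister class 1; "enrichment opportunists" such
as Rhabditidae) bloom on bacterial pulses, while sensitive K-selected
cp 3–5 omnivores and predators are suppressed and recover only late. This
package implements the full analysis used to track such succession beneath
decomposing vertebrate remains sampled at two depths (0–30 cm cores and
the 0–1 cm carcass–soil interface) over a staged calendar from placement
through late skeletonization:

- **functional annotation** — trophic group × cp class → guild (B1, F2,
  P2, …), with cp-1 restricted to bacterivores;
- **alpha diversity** — total abundance (per 100 cm³ soil), richness, and
  Shannon H′ = −Σ pᵢ ln pᵢ;
- **faunal profile** — weighted guild components
  e = 3.2 N(B1) + 0.8 N(F2), b = 0.8 (N(B2) + N(F2)),
  s = Σ w_cp N(cp 3–5) + 0.8 N(P2), giving the Enrichment Index
  EI = 100 e/(e+b) and Structure Index SI = 100 s/(s+b) (herbivores
  excluded by convention);
- **indicator-taxon screening** — per-day enrichment flags
  (impacted mean ≥ 5 and > control × scale) and suppression flags
  (control mean ≥ 5 and impacted < control / scale), scale 10 for B1 and
  2 otherwise, classified into four categories: B1 enrichment,
  suppression-then-enrichment, suppression only, non-B1 enrichment;
- **statistics** — two-way ANOVA (treatment × sampling day), per-day
  paired t-tests, and RDA on Euclidean distances with stage centroids and
  SD ellipses;
- **a synthetic succession generator** with planted response archetypes
  and analytic ground truth, used by the test suite to verify that the
  screening recovers exactly what was planted.

See `docs/methods.md` for the model, conventions, and limitations.

## Worked example

Simulate the default study (6 paired sites, 12 sampling days, both
strata), then screen the core stratum:

```sh
nemafauna simulate --out-dir demo --seed 42
nemafauna screen demo/annotations.csv demo/community.csv --stratum core \
    --out-flags flags.csv --out-categories cats.csv
```

The non-`none` rows of `cats.csv`:

```
           taxon     stratum                    category enrichment_days        suppression_days
     Rhabditidae core_0_30cm               b1_enrichment 15;21;40;78;110
  Diplogastridae core_0_30cm               b1_enrichment           15;21
    Acrobeloides core_0_30cm suppression_then_enrichment 153;188;250;317         15;21;40;78;110
  Prismatolaimus core_0_30cm suppression_then_enrichment             153         15;21;40;78;110
  Aphelenchoides core_0_30cm suppression_then_enrichment 153;188;250;317         15;21;40;78;110
       Filenchus core_0_30cm            suppression_only                 15;21;40;78;110;153;188
Tylencholaimidae core_0_30cm suppression_then_enrichment             153             15;21;40;78
     Dorylaimida core_0_30cm           non_b1_enrichment         250;317
         Seinura core_0_30cm           non_b1_enrichment         110;153
         Clarkus core_0_30cm           non_b1_enrichment             153
```

Reading: the Rhabditidae-like B1 opportunist exceeds ten times its control
mean from active decay (day 15) through early skeletonization (day 110);
the dominant resident fungivore (Filenchus-like) is suppressed below half
its control mean for most of the study without ever rebounding past it;
cp-2 generalists flip from suppression during decay to enrichment from
late skeletonization (day 153); K-selected taxa enrich only at the end.
Every category matches the generator's planted ground truth
(`demo/ground_truth.json`).

The faunal trajectory for impacted cores (`faunal_core_impacted.csv`
from `nemafauna all`, rounded to one decimal):

```
 study_day      e    b    s   EI   SI  n
         0   96.1 86.3 76.0 52.7 46.8  6
         2  102.3 89.5 97.1 53.3 52.0  6
         6  103.3 76.8 73.2 57.4 48.8  6
        15  714.9 40.1 50.9 94.7 55.9  6
        21 1009.5 38.5 41.6 96.3 51.9  6
        40 2583.6 24.9 34.0 99.0 57.7  6
        78 1316.8 40.7 40.6 97.0 50.0  6
       110  656.7 33.5 72.0 95.2 68.3  6
```

EI climbs from the mid-range baseline (~53, a mixed cp-2 community) to ~99
at peak advanced decay (day 40) as the bloom swamps the basal component —
the enriched-corner regime of the faunal profile. `nemafauna all` runs
every stage and writes the tables plus a run manifest; `validate`,
`alpha`, and `stats` expose the individual stages.

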