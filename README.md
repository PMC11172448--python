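# zebrafrail

Quantification of age-related sarcopenia and frailty in zebrafish
(*Danio rerio*). The package turns the raw read-outs of a zebrafish aging
study — open-field tracking trajectories, biometry, histology and electron
microscopy annotations — into the summary variables used to stage muscle
aging, and combines them into a deficit-accumulation **frailty index (FI)**.

It is written for experimental groups running zebrafish aging cohorts
(typical design: 2-, 10-, 30- and 60-month age groups) who want a
reproducible, scriptable alternative to spreadsheet pipelines.

## The frailty index

Each fish is described by four variables: total distance traveled (cm),
maximum speed (cm/s), mean speed (cm/s) from a 20-minute open-field
recording (after a 3-minute adaptation stage), and body mass index
BMI = weight / length² (g/cm²). The youngest cohort is the **reference
group**; its per-variable sample mean μ_v and SD σ_v define deficit bins
for the standardized deviation z = (x − μ_v)/σ_v of any fish:

| deviation d            | deficit score |
|------------------------|---------------|
| d ≤ 1 SD               | 0             |
| 1 < d ≤ 2              | 0.25          |
| 2 < d < 3              | 0.5           |
| d = 3                  | 0.75          |
| d > 3                  | 1             |

with d = |z| (absolute mode, default) or only the frailty-direction part of
z (directional mode: slower/shorter swimming and higher BMI count). The FI
is the plain mean of the per-variable scores, so FI ∈ [0, 1] and is exact
quarter arithmetic. `bins="practical"` merges the measure-zero d = 3 band
into 0.5.

Around the index the package provides the measurement formulas of the
histomorphometry workflow — collagen area fraction
(100 · collagen pixels / field pixels on Van Gieson masks), myocyte density
(count/µm²), TEM mitochondrial tallies on 5.15 µm × 5.15 µm fields with the
damaged-mitochondria percentage (100 · damaged / total), sarcomere A/H/I
band summaries, GFP-per-nucleus confocal ratios — plus one-way ANOVA with
Tukey's HSD post hoc test, and a synthetic cohort generator whose default
laws are the published per-group means and dispersions.

## Worked example

```python
from zebrafrail import ReferenceStats, deficit_score, generate_cohort, SimConfig
from zebrafrail.frailty import FrailtyConfig, cohort_frailty

# a 30-month fish's mean speed scored against the young reference law
score = deficit_score(2.635, mean=4.182, sd=1.017)
print("deficit score:", score)          # deficit score: 0.25

# synthetic cohorts from the packaged group laws, scored end to end
cfg = SimConfig(n_per_group=10, seed=42)
cohort, frame = generate_cohort(cfg=cfg, groups=["2", "10", "60"])
results, groups = cohort_frailty(frame, FrailtyConfig(mode="directional"))
for g in groups:
    print(f"{g.group_label:>2} mo  n={g.n}  FI = {g.mean:.3f} ± {g.sem:.3f} (SEM)")
```

prints

```
deficit score: 0.25
 2 mo  n=10  FI = 0.050 ± 0.016 (SEM)
10 mo  n=10  FI = 0.081 ± 0.016 (SEM)
60 mo  n=10  FI = 0.450 ± 0.047 (SEM)
```

The 30-month mean speed sits 1.52 reference SDs below the young mean, which
falls in the (1, 2] bin → 0.25. In the simulated cohorts the frailty index
rises with age: the 60-month group is markedly frailer than the 2- and
10-month groups, which sit near zero. (Reference fish are scored against
their own group's statistics, so small nonzero scores within the young
group are expected.)

A command-line pipeline mirrors the library:

```sh
zebrafrail --seed 7 --out sim simulate --n-per-group 8
zebrafrail --seed 7 --out run locomotion sim/trajectories
zebrafrail --seed 7 --out run frailty --cohort sim/cohort.csv --locomotion run/locomotion.csv
zebrafrail --seed 7 --out run stats --table tidy.csv
```

Every subcommand writes CSV outputs and a JSON manifest (inputs, config
hash, seed, library versions).

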