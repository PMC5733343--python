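# salixfate

Metabolic-fate triage of untargeted LC-MS feature tables from in-vitro
incubations of willow bark extract (WBE) with human fecal microbiota.

Herbal preparations reach the colon largely unabsorbed, where gut
bacteria transform their constituents — glycosides, flavonoids,
flavan-3-ols, salicylates — into smaller, often more bioavailable
metabolites. A standard way to study this is to incubate the extract
anaerobically with a human fecal suspension (HFS), sample at 0.5, 4 and
24 h in triplicate, and measure everything by untargeted LC-MS. This
package implements the data-analysis side of such an experiment for
willow bark extract, plus a simulator that generates the full design
with known kinetic ground truth, so the whole pipeline is testable
without any instrument data.

Intended users: metabolomics / pharmacognosy researchers running or
evaluating in-vitro fermentation screens of herbal extracts.

## What it computes

**Fate triage.** Each feature (an m/z–retention-time pair with peak
areas) is classified per extract concentration from group ratios and an
unpaired two-tailed Student's *t*-test (pooled variance, df = n₁+n₂−2):

- *increasing*: t24/t0 > 2, p < 0.05 — a formed microbial metabolite;
- *decreasing*: t24/t0 < 0.5, p < 0.05 — a consumed substrate;
- *intermediate*: t4/t0 > 2 (p < 0.05) and t4/t24 > 1.25 — rises then
  falls, i.e. formed and further degraded;
- plus *matrix* (present in fecal controls without extract), *fast
  metabolized* (present in the microbe-free extract control but never in
  fecal incubations), *insufficient data* and *unchanged*.

Every fate is crosschecked against the extract-in-buffer control: a
same-direction significant change there flags the feature as abiotic
(chemical instability, not metabolism).

**Annotation.** Features are neutralized ([M−H]⁻: neutral mass = m/z +
1.00727647 Da) and matched within 5 ppm against a bundled 58-compound
willow-bark library (theoretical monoisotopic masses computed from
molecular formulas with a bundled isotope table; optional retention-time
gating).

**Pathway overlays.** Three literature degradation routes (naringenin
glycosides, catechin/flavan-3-ols, salicylic alcohol) are bundled as
directed acyclic graphs with typed transformations (deglycosylation,
C-ring cleavage, dehydroxylation, oxidations). Triage fates project onto
node roles (precursor / intermediate / terminal metabolite) and each
edge gets a consistency verdict, summarised as coverage and
consistent/inconsistent fractions.

**OTU utilities.** The accompanying 16S rules: drop OTUs with ≤ 5 reads
total, total-sum normalize, list taxa > 1% in at least one sample.

## Worked example

Simulate the bundled demo experiment (36 features mapped onto library
compounds, lognormal noise σ = 0.2, detection limit 100 area units), run
the full pipeline, and overlay the catechin route:

```
$ salixfate run --seed 7 --out demo
fates: {'INCREASING': 23, 'DECREASING': 22, 'MATRIX': 10, 'FAST_METABOLIZED': 6,
        'INTERMEDIATE': 5, 'INSUFFICIENT_DATA': 4, 'UNCHANGED': 2}
fates: demo/fates.tsv
annotations: demo/annotations.tsv
overlay_catechin: demo/overlay_catechin.tsv
...

$ salixfate pathway demo/fates.tsv demo/annotations.tsv --name catechin --out overlay.tsv
catechin: coverage 1.00, 12 consistent, 0 inconsistent, 0 undetermined edges -> overlay.tsv
```

The 72 fate records are 36 features × 2 concentrations: the glycosides
and flavan-3-ols decrease, the ring-fission acids increase, naringenin
and the valerolactones appear as intermediates, the fecal-background
features are labelled matrix, the three fastest-degrading compounds are
only ever seen in the extract control (*fast metabolized*), and the
products formed only at 2 mg/ml yield *insufficient data* records at
10 mg/ml. The catechin overlay reports all 12 route edges as consistent
with those fates.

The library layer works the same from Python:

```python
>>> from salixfate import chem
>>> f = chem.parse_formula("C13H18O7")        # salicin
>>> chem.monoisotopic_mass(f)
286.10525287999997
>>> chem.ppm_delta(286.1055, 286.10525288)    # vs the published mass
0.8637380738467662
>>> chem.mz_from_neutral(286.10525288)        # expected [M-H]- ion
285.09797641312
```

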