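# parapatry

Tests of **competitive exclusion** and **character displacement** for pairs
of parapatric species — species whose ranges abut along narrow contact zones
but barely overlap, as in the tuco-tucos (*Ctenomys*) of the southern
Brazilian coastal plain. The package is aimed at biogeographers and
morphometricians who have (a) continuous habitat-suitability surfaces from a
niche model for each species plus occurrence localities, and/or (b) 2-D
landmark data from specimens collected in sympatry and allopatry.

## The two engines

**Geographic exclusion/release test.** Each species' suitability surface is
binarized with the *minimum-training-presence* rule (threshold = the lowest
suitability at any of that species' own localities). The intersection of the
two binary maps is the *area of potential sympatry*. Within it, unique
localities are counted per contact zone and *away* from all zones. For a
zone with n localities the null expectation for species A is

    E[A] = n · p₀,   p₀ = a_away / (a_away + b_away),

estimated from the away-from-zone counts to avoid circularity and a bias
toward the more widespread species. The observed zone count k is compared to
Binomial(n, p₀) with a two-sided exact test (minimum-likelihood rule: sum
the probabilities of all outcomes no more likely than the observed one).
A per-pixel *dominance map* (which species' model is higher inside potential
sympatry) and a descriptive *release* summary (suitability occupied inside
vs outside zones) complete the engine.

**Morphometric displacement test.** Landmark configurations are superimposed
by Generalized Procrustes Analysis (center, scale to unit centroid size,
rotate by the SVD solution, iterate the consensus), shape is corrected for
allometry by regressing every shape variable on centroid size and keeping
residuals, and the four groups (2 species × sympatric/allopatric) are
compared with:

* one-way ANOVA + Tukey HSD on size measures (centroid size, skull length,
  body mass);
* between-group PCA (axes of the unweighted group means; a rotation, so no
  distance distortion);
* Procrustes distances between group mean shapes with permutation tests;
* the displacement statistic **d_diff = d_sym − d_allo** (inter-species
  mean-shape distance in sympatry minus in allopatry), tested against a null
  that reshuffles the sympatric/allopatric labels *within each species*
  (p-values use the add-one convention, so they are never 0).

A synthetic-data module generates suitability surfaces, localities and
landmark samples with known ground truth, so the whole chain is testable
without the (unpublished) specimen data.

## Worked example

The exclusion test on directly supplied counts (species A: 18 unique
localities in potential sympatry away from the contact zones, 4 in the
northern and 2 in the southern zone; species B: 33 / 3 / 1):

```sh
$ cat counts.yaml
counts:
  a_away: 18
  b_away: 33
  zones:
    northern: [4, 3]
    southern: [2, 1]
$ parapatry exclusion --config counts.yaml --out report.json
zone northern: k=4 n=7 expected=(2.471, 4.529) P=0.2522
zone southern: k=2 n=3 expected=(1.059, 1.941) P=0.2858
```

Under the null p₀ = 18/51 ≈ 0.353, about 2.5 of the 7 northern-zone
localities would be species A; the observed 4 is not a significant excess
(P = 0.2522), and likewise in the south — no geographic signature of
competitive exclusion.

The displacement suite on a simulated 85-skull sample (defaults: 30
landmarks, groups 22/17/24/22, a 0.03 sympatric shape shift planted in
species B):

```python
>>> from parapatry.pipeline import run_displacement_pipeline
>>> rep = run_displacement_pipeline({"seed": 1, "simulate": {},
...                                  "n_perm": 1000, "n_boot": 1000})
>>> rep["displacement"]
{'d_sym': 0.0350, 'd_allo': 0.0237, 'd_diff': 0.0113, 'n_boot': 1000,
 'p': 0.005994, ...}
```

The two species' mean shapes are farther apart in sympatry (0.0350) than in
allopatry (0.0237); only 5 of 1000 within-species relabelings produced a
difference at least as large, so the divergence-in-sympatry is unlikely
under chance relabeling — the character-displacement signature the planted
shift should produce.

`parapatry simulate` writes synthetic ESRI ASCII grids, a locality CSV and a
TPS landmark file; `parapatry morpho run|gpa|bgpca|distances|displacement|size-anova`
expose the morphometric stages; `parapatry report` renders a JSON report as
tables.

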