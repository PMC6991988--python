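# adashape

Archetypoid analysis of 3D landmark shapes — data-driven taxonomies of
body-part shapes (feet, faces, bones …) built from extreme, *actual*
specimens rather than cluster centroids.

## The problem and the method

Product designers, ergonomists and morphometricians need a small set of
representative cases that spans the variability of a population.  Cluster
centroids sit in the middle of the data cloud and all look alike;
percentile mannequins are not additive across measurements; extreme
principal-component scores need not correspond to any real, coherent
specimen.  **Archetypoid analysis (ADA)** instead finds the p *purest*
cases — actual specimens on the boundary of the data's convex hull — and
explains every other case as a mixture of them: "this foot is 43% of
archetypoid 1 plus 57% of archetypoid 3" is a sentence a non-statistician
can act on.

For shapes described by k corresponding 3D landmarks, Euclidean
coordinates are not the right arena: translation, rotation and scale are
nuisance.  `adashape` works in Kendall shape space.  Each configuration
**X** (k × 3, mm) becomes a pre-shape Y = HX/‖HX‖ (H the Helmert
sub-matrix, ‖HX‖ the centroid size); a full Procrustes mean μ̂ is
estimated by generalized Procrustes analysis; each specimen is mapped to
Kent partial tangent coordinates at the mean,
v = (I − vec(S)vec(S)ᵀ)vec(YΓ̂); and multivariate ADA solves

    min Σᵢ ‖vᵢ − Σⱼ αᵢⱼ uⱼ‖²,   Σⱼ αᵢⱼ = 1,  αᵢⱼ ≥ 0,
    uⱼ ∈ {v₁, …, v_n} distinct,

a mixed-integer least-squares problem handled by a PAM-style BUILD + SWAP
search with exact simplex projections.  Because archetypoids are real
specimens, mapping results back to configuration space is a lookup, and
the archetypoids can be profiled afterwards on measurement tables
(foot length FL, ball width BW, ball girth BG, …) as percentile profiles
of the FL-normalized ratios.

See `docs/methods.md` for the model, optimizer, synthetic generator and
numerical choices in detail.

## Worked example

Simulate an ensemble with 3 planted archetypal shapes, fit, and export
the mixture compositions:

```sh
adashape simulate --n 40 --k 60 --seed 21 --outdir demo/sim
adashape fit --input demo/sim/landmarks.csv --p 3 --seed 22 --outdir demo/fit
adashape ternary --model demo/fit/model.json --outdir demo/tern
```

which prints

```
wrote 40 specimens x 60 landmarks to demo/sim
demo/fit: archetypoids (1-based) [1, 2, 3] ids ['spec-0000', 'spec-0001', 'spec-0002'] RSS 0.00106642 max|v| 0.5733
wrote demo/tern/ternary.csv (40 feet)
```

The fit recovered exactly the three planted pure specimens (the generator
places them first, so indices 1–3 are the ground truth).  `RSS` is the
summed squared tangent-space residual of expressing all 40 specimens as
mixtures of the three archetypoids; `max|v|` is the concentration
diagnostic (sin of the largest Procrustes angle to the mean shape — the
tangent-space approximation assumes it is not large).  The first rows of
`ternary.csv`:

```
a1,a2,a3,label,x,y
1.0,0.0,0.0,1,0.0,0.0
0.0,1.0,0.0,2,1.0,0.0
1.387803960405872e-12,7.530390979788175e-13,0.9999999999978592,3,0.49999999999968264,0.8660254037825845
```

Each row is one specimen's mixture weights (summing to 1), its max-alpha
assignment, and 2D equilateral-triangle coordinates for a ternary plot —
pure cases sit at the corners, the mean shape near the centroid.

Other verbs: `screeplot` (RSS over a range of p, with a
largest-second-difference elbow diagnostic), `profile` (percentile
profiles of the archetypoids on an FL-normalized measurement CSV), and
`--metadata`/`--stratum` on `fit` to analyze strata (e.g. women and men)
separately, each with its own Procrustes mean.

The same pipeline is available as a library:

```python
import adashape as ada

templates = ada.make_archetypal_shapes(3, 60, seed=0)
truth = ada.simulate_ensemble(templates, n=100, seed=1)   # 0.5 mm noise
result = ada.fit_shape_ada(truth.ensemble, p=3, seed=2)
print(result.archetypoid_indices, ada.recovery_score(result, truth))
```

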