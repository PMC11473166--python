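# rizmap

Quantification of **regenerative inflammation zones (RIZs)** in spot-based
spatial transcriptomics of regenerating and dystrophic muscle.

Necrotic lesions in dystrophic muscle are surrounded by a concentric,
multilayered architecture: a damage-clearing core of proinflammatory
macrophages and Langhans giant cells (**zone A**, markers *Ccl7*, *Ccl2*,
*Il1rn*), a barrier of resolution-related and growth-factor-expressing
macrophages (**zone B**, markers *Mmp12*, *Nckap1l*, *Itgb2*, *Atf3*), and a
periphery of newly regenerating myofibers (**zone C**, markers *Myh3*,
*Myog*, *Myl4*). Intermittent glucocorticoid treatment collapses this
architecture — zone C disappears and the A/B territories intermix. `rizmap`
turns that biology into reproducible numbers for spot or subspot lattices
(Visium-style MTX + `tissue_positions` inputs, ~100 um spacing).

## What it computes

For a gene x spot count matrix with spot positions, `rizmap`:

1. **normalizes** counts (median-total scaling + log1p) and computes
   control-matched **module scores** per spot for each zone panel
   (set mean minus expression-bin-matched control mean);
2. calls a per-spot **observed zone** by score argmax with abstention
   (top score >= tau and margin >= m, else `none`);
3. **detects lesion cores** as connected components of high zone-A-score
   spots (quantile rule, invariant to monotone score transforms), or takes a
   user-supplied core spot list;
4. builds the **expected zone model** from the signed Euclidean distance d
   to the core boundary (negative inside): A iff d <= 0, B iff
   0 < d <= w_B (default 100 um), C iff w_B < d <= w_C (default 440 um);
5. scores agreement as the **obs/exp ratio** — the fraction of
   expected-zone spots whose observed label matches, per zone and overall,
   with a label-permutation null;
6. measures architecture collapse via the **cross-zone Spearman
   correlation** of zone markers (organized tissue: disjoint territories,
   near-zero/negative; collapsed: elevated) with a condition-permutation
   test;
7. computes **boundary-referenced radial profiles** of labeled cell points
   (densities in 50-um signed-distance bins from -100 to +450 um, mean
   boundary distances within +-500 um) and **nearest-neighbor proximity
   fractions** (e.g. cells within 20 um of regenerating fibers) with a
   relabeling permutation null.

A first-class **synthetic-tissue generator** plants disk lesions on a
hex/square lattice, draws negative-binomial counts with zone-elevated means
(`organized` vs `collapsed` conditions) and per-zone Poisson cell layers,
and returns the ground truth for recovery experiments.

## Worked example

```python
import rizmap as rz

tissue = rz.simulate_tissue(seed=1, condition="organized")
adata = rz.normalize(tissue.adata)
scores = rz.score_panel(adata, tissue.panel, seed=1)
observed = rz.classify_observed_zone(scores)
lesions = rz.detect_cores(tissue.lattice, scores["A"], threshold_quantile=0.96)
expected, _ = rz.expected_zones_from_lesions(tissue.lattice, lesions)
agreement = rz.agreement_ratio(expected, observed)
print(agreement.per_zone)
print(f"overall obs/exp ratio: {agreement.overall_ratio:.3f}")
```

prints

```
      n_expected  n_match     ratio
zone
A             30       30  1.000000
B             24       24  1.000000
C            126      116  0.920635
overall obs/exp ratio: 0.944
```

i.e. every spot expected in the damage-clearing core (A) and the barrier
ring (B) is called correctly from expression alone, and 92% of the
regenerating periphery (C) matches; pooled over the 180 expected-zone spots
the obs/exp ratio is 0.944. On a `collapsed` tissue the same pipeline drives
the zone-C ratio to ~0.01 and `rz.zone_collapse_report` flags the collapse
(see `examples/03_collapse_contrast.py`).

The `examples/` directory holds one short narrative script per capability:
tissue simulation, zone agreement, the collapse contrast, radial profiles
and proximity testing. The same stages are exposed as a thin CLI
(`rizmap simulate|score|zones|stats|compare`); every report embeds its
configuration hash and reruns are byte-identical for a fixed seed.

## Documentation

`docs/methods.md` describes the model, the estimators, every tunable
parameter with its default and rationale, what the synthetic generator does
and does not emulate, and known limitations.
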