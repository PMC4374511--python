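# punctakit

Quantification of synaptic fluorescence puncta along neuronal cords.

Fluorescent synaptic-vesicle reporters (GFP::RAB-3, SNB-1::GFP and kin) form
discrete puncta along the *C. elegans* nerve cords, one per presynaptic
vesicle cluster. Mutations in vesicle-trafficking genes redistribute the
reporter — diffusely along the axon, into oversized puncta, or back into
cell bodies — and the standard way to put numbers on those phenotypes is a
**line scan**: the 1D intensity profile along a traced cord, from which one
computes

- **PN (puncta number)** — a candidate peak is a punctum when its peak
  punctal fluorescence over the average inter-punctal fluorescence (IPF)
  satisfies peak PF / avg IPF ≥ 2;
- **SE (synaptic enrichment)** — total PF / total IPF within a 100-µm cord
  window: high for punctate reporters, low for diffuse ones.

`punctakit` implements this analysis as a tested, reusable pipeline:
line-scan extraction from TIFF micrographs along a traced polyline, punctum
calling by the ratio rule (a nested fixed point, since PF and IPF regions
define each other), PN/SE per animal, and per-genotype summaries
(mean ± SD, n) with pairwise Student's t-tests (** p < 0.01, * p < 0.05,
NS). Because such studies rarely deposit raw images, it also ships a
synthetic-scene generator with ground-truth punctum tables emulating four
phenotype classes (`wild_type`, `diffuse_mutant`, `enlarged_puncta`,
`soma_retention`), so every stage can be validated end to end. See
`docs/methods.md` for the model, defaults, and design choices.

## Worked example

```python
import punctakit as pk

# one synthetic wild-type animal: 110 µm of cord at 0.1 µm/px
profile, truth = pk.make_profile(pk.get_preset("wild_type"), 110.0, 0.1, seed=1)
q = pk.quantify_animal(profile)
print(f"PN={q.pn} (truth {truth.n_puncta}), SE={q.se:.3f}, "
      f"avg IPF={q.avg_ipf:.1f}, window={q.window_um}")
```

prints

```
PN=34 (truth 36), SE=1.332, avg IPF=47.5, window=(5.0, 105.0)
```

34 puncta were called in the central 100-µm window (two of the 36
ground-truth puncta lie outside it), the reporter is 1.33× enriched in
puncta relative to the inter-punctal axon, and the converged IPF baseline
is ≈ 48 AU. Comparing genotypes:

```python
from punctakit.stats import compare_groups

se = {name: [pk.quantify_animal(pk.make_profile(pk.get_preset(name), 110.0, 0.1, s)[0]).se
             for s in range(1, 21)]
      for name in ("wild_type", "diffuse_mutant")}
res = compare_groups(se["wild_type"], se["diffuse_mutant"])
print(f"t={res.t_stat:.1f}, p={res.p_value:.2e}, {res.label}")
```

```
t=86.8, p=2.67e-45, **
```

— the diffuse mutant's SE (identically 0: no punctum ever clears the ratio
rule on a flat profile) differs from wild type at **, the analogue of the
figure-panel annotation such a contrast would carry.

The same workflow is available from the shell:

```sh
punctakit simulate --preset wild_type --n-animals 20 --outdir scenes/
punctakit quantify --profiles scenes/ --out quant.csv
punctakit compare --quant quant.csv --metric se --ref wild_type --out stats.csv
punctakit run --config demo.yaml --outdir run1/   # full reproducible run
```

`punctakit run` writes every intermediate artifact plus a manifest;
`punctakit run --manifest run1/manifest.json --outdir run2/` reproduces the
outputs byte for byte.

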