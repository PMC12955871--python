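# omtkit

Tools for analysing the regioselectivity and cascade kinetics of
O-methyltransferases (OMTs), built around the plant class I OMT from
*Selaginella moellendorffii* (SmOMT) and its coupled SAM-regeneration system
with a halide methyltransferase (HMT).

## What it computes

**Near-attack-conformation (NAC) regioselectivity.** An SN2 methyl transfer
from SAM to a substrate hydroxyl is feasible when, simultaneously,

* the nucleophile oxygen sits close to the catalytic histidine that
  deprotonates it — distance *d*(O···H–N), measured O→N on hydrogen-free
  models — and
* the attack angle at the SAM methyl carbon, ∠(O–C1–S), approaches the
  in-line 180°.

Frames of a conformational ensemble with *d* < 3.5 Å and
125° ≤ ∠(O–C1–S) ≤ 170° are counted as methylation-competent; per-site
competent fractions quantify which hydroxyl (2′-, 3′- or 4′-OH) the enzyme
methylates. The package reads multi-model PDB ensembles, measures per-frame
(d, θ), classifies frames, builds 2-D kernel-density maps over the reaction
coordinates, ranks sites, and provides Kabsch superposition and per-residue
RMSF.

**Synthetic ensembles.** A generator draws (d, θ) per site from truncated
normal distributions and embeds them as Cartesian atom quadruplets, giving
ensembles with exactly known ground truth for end-to-end validation.

**Fusion-construct geometry.** For fused OMT/HMT enzymes it computes the
two descriptors used to compare linker designs: the inter-tunnel distance
D_IC (between user-anchored active-site centroids) and the inter-segment
angle O_IC (0–180°, orientation-sensitive).

**Kinetics.** Michaelis–Menten fitting in statsmodels style
(`MichaelisMenten(...).fit()` → results with estimates, standard errors and
`summary()`), competitive SAH product inhibition
(Km,app = Km·(1 + [SAH]/Ki), hence Ki = [SAH]/(Km,app/Km − 1)), synthetic
rate data, and an ODE model of the coupled cycle

    substrate + SAM --OMT--> product + SAH
    SAH + CH3I      --HMT--> SAM

with rapid-equilibrium saturating rate laws and SAH inhibition of the OMT.

## Worked example

```python
import numpy as np
from omtkit.synth import SiteDistribution, generate_ensemble
from omtkit.nac import site_stats, rank_sites
from omtkit.kinetics import infer_ki

# ensemble of 20 000 conformations of a 3'-OH site: d ~ N(3.3 A, 0.3),
# theta ~ N(155 deg, 10) — the competent-geometry regime
dist = SiteDistribution("3'-OH", d_mean=3.3, d_sd=0.3,
                        theta_mean=155.0, theta_sd=10.0)
ens, truth = generate_ensemble([dist], n=20_000, seed=2024)
stats = site_stats(ens, truth.site_specs["3'-OH"], truth.region)
print(f"competent fraction: {stats.fraction:.3f}")

# SAH inhibition constant from the measured Km shift
# (51.7 uM -> 2794 uM at 1.5 mM SAH)
print(f"Ki(SAH) = {infer_ki(51.7, 2794.0, 1500.0):.1f} uM")
```

prints

```
competent fraction: 0.697
Ki(SAH) = 28.3 uM
```

The fraction matches the closed-form probability of the sampled
distribution (≈ 0.701) to within binomial sampling error; the Ki says SAH
binds the OMT roughly twice as tightly as the substrate itself
(Km = 51.7 µM), which is why in-situ SAM regeneration — keeping [SAH] low —
restores activity in the coupled system.

There is also a CLI (`omtkit nac|synth|fusion|kinetics ...`) that runs the
same operations from YAML configs and writes CSV/JSON artifacts plus a
run manifest; see `omtkit --help`.

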