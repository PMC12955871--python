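# Methods

## Near-attack-conformation model

The regioselectivity of an SN2 methyl transfer is treated as a purely
geometric property of the conformational ensemble. For each candidate
hydroxyl site and frame we measure two reaction coordinates:

* **d** — distance (Å) from the nucleophile oxygen to the catalytic
  histidine imidazole nitrogen. Crystallographic and most modelled
  ensembles lack hydrogens, so d is measured O→N (heavy-atom convention);
  the ~1.0 Å N–H bond offset is absorbed by the user-settable distance
  cutoff. When explicit hydrogens are present, `use_hydrogens=True`
  switches the minimum to run over the listed H acceptors as well. With
  both imidazole nitrogens (Nδ1/Nε2) listed, d is the minimum over them —
  either tautomer can accept the proton.
* **θ** — angle (degrees) at the SAM methyl carbon C1 between the oxygen
  and the sulfonium sulfur; in-line attack corresponds to θ → 180°.

A frame is *methylation-competent* when (d, θ) falls in the reactive region,
by default d < 3.5 Å (strict) and 125° ≤ θ ≤ 170° (inclusive) — the standard
NAC criteria for this chemistry. The boundaries are parameters, not
constants: they may be substrate-tuned. The per-site competent fraction is
exact integer arithmetic (count/frames); frames are equally weighted, with
no time-decorrelation or block averaging, because the quantity of interest
is a raw conformational fraction.

Angles are degrees externally and radians internally; all coordinates are
Å; no unit conversions exist anywhere else.

### KDE over (d, θ)

Density maps use a product Gaussian kernel with an independent Scott's-rule
bandwidth per axis, h = σ·n^(−1/6), evaluated on a default 100×100 grid
spanning [0, 8] Å × [0, 180]°. A degenerate axis (zero sample variance)
falls back to a bandwidth of 1% of the sample magnitude so the spike remains
representable on a finite grid. The vectorised evaluation is algebraically
identical to the explicit kernel sum (tested to 1e−12).

### Superposition and RMSF

Rigid-body fits use the Kabsch algorithm (via
`scipy.spatial.transform.Rotation.align_vectors`, proper rotation enforced);
the RMSD is recomputed from the fitted residuals because the solver's
reported residual loses precision near a perfect fit. RMSF superposes every
frame onto the ensemble mean, recomputes the mean from the aligned frames
and refits once (two-pass); per-atom fluctuations are averaged per residue.
Default selection is the backbone atoms N, CA, C, O; no mass weighting.

## Synthetic ensemble generator

The generator stands in for an MD conformational sample at desk scale. Per
site it draws d from a normal truncated below at 0.5 Å and θ from a normal
truncated to [0, 180]°, independently by default (an optional correlation
coefficient exists for stress tests; it uses rejection sampling and slightly
distorts the marginals). Each (d, θ) pair is embedded as four uniquely
selectable atoms: S at the origin, C1 at (1.80, 0, 0) (S–CH3 bond-like), O
in the xy-plane at 3.0 Å from C1 (van der Waals approach) making angle θ at
C1, and one histidine-like N at distance d from O perpendicular to O→C1.
The scaffold constants are fixed and, by construction, cancel out of the
measured (d, θ), so `measure_site ∘ embed_geometry` is the identity to
floating-point rounding. Sites occupy distinct chains; per-site random
streams derive from the master seed by fixed offsets, so adding a site never
perturbs another site's draws.

What the generator does *not* emulate: protein context, excluded volume,
temporal autocorrelation, and any coupling between sites or between d and θ
beyond the optional correlation. Passing tests therefore demonstrate the
correctness of the measurement/classification pipeline, not the realism of
any particular ensemble.

A note on file round trips: PDB coordinate columns carry 1e−3 Å precision,
so writing an ensemble to disk and re-reading it can flip the
classification of a frame whose (d, θ) lies within ~2×10⁻³ of a region
boundary. Tests assert classification equality only away from boundaries.

## Fusion-construct descriptors

D_IC is the distance between the centroids of two user-anchored atom sets
(the two active-site tunnels); O_IC is the angle between two user-defined
directed segments, kept orientation-sensitive on [0, 180°] so nearly
antiparallel arrangements are distinguishable from aligned ones. Tunnel
and segment *identification* is deliberately out of scope — anchors are
config inputs — because no algorithmic definition of the tunnels is
available to implement; the package computes geometry only.

## Kinetics

**Michaelis–Menten fitting** is nonlinear least squares on untransformed
rates (no Lineweaver–Burk), multi-start from three heuristic initial
guesses with the lowest-SSE solution kept, bounds at zero, and asymptotic
standard errors from J^T J. With per-observation inhibitor concentrations
the competitive model v = Vmax·s/(Km(1+I/Ki)+s) is fitted jointly for
(Vmax, Km, Ki). A warning is raised when the estimated Km exceeds the
largest tested concentration (Km and Vmax then trade off).

**SAH inhibition** is modelled as competitive with the acceptor substrate —
Km scaled by (1 + [SAH]/Ki), Vmax unchanged — because the observed effect
of SAH on SmOMT is entirely a Km increase (51.7 → 2794 µM at 1.5 mM SAH).
Inverting that pair gives Ki(SAH) = 1500/(2794/51.7 − 1) ≈ 28.3 µM. The
mechanistic form is an assumption: a Vmax effect, if present, is not
represented.

**The cascade** composes, for each enzyme, a product of saturating terms
(rapid-equilibrium random approximation; no bi-substrate mechanism is
available to fit):

    v_OMT = kcat_O·E_O · [S]/(Km_S(1+[SAH]/Ki)+[S]) · [SAM]/(Km_SAM+[SAM])
    v_HMT = kcat_H·E_H · [SAH]/(Km_SAH+[SAH]) · [D]/(Km_D+[D])

with dS = −v_OMT, dP = +v_OMT, dSAM = v_HMT − v_OMT, dSAH = v_OMT − v_HMT,
dD = −v_HMT − k_dec·[D]. S+P and SAM+SAH are conserved pointwise; with
k_dec = 0 the donor balance D₀−D = ΔSAM+ΔP holds along trajectories.
Integration is LSODA (stiff-capable) at rtol 1e−8 / atol 1e−10, in seconds
internally with hours at the interface; concentrations are µM throughout.

Default parameters (see `kinetics.REFERENCE_PARAMS`): Km_S = 51.7 µM and
Ki_SAH = 28.3 µM are the measured/inferred values for gallacetophenone.
The OMT turnover capacity (kcat_O·E_O = 0.088 µM/s) was set analytically —
from the closed-form Michaelis–Menten progress time
t = (ΔS + Km·ln(S₀/S))/Vmax — so that a 500 µM reaction with replete SAM
completes (95%) in about 2 h, and the HMT capacity (0.025 µM/s) so that the
coupled cycle completes in about 8 h: the completion timescales observed
for this system. Km_SAM = 30 µM, Km_SAH = 10 µM and Km_D = 100 µM are
plausible assumptions, flagged as such; none of the qualitative behaviour
tested (conservation, limits, monotonicity) depends on them.

Two structural properties anchor the model's interpretation: as HMT
capacity → ∞ the cascade collapses onto the single-enzyme SAM-replete curve
(SAH is drained as fast as it forms), and time-to-conversion is monotone
non-increasing in HMT capacity — together, the mechanism by which in-situ
SAM regeneration trades speed for SAH relief.

## Problem sizes and numerical conventions

Validation runs use 20 000 frames for fraction recovery (3σ binomial
agreement with the truncated-normal closed form), 10 000 draws for the
embed/measure round trip (1e−6), 20×20 grids for KDE brute-force equality
(1e−12), 200 simulated assays (8 concentrations × 3 replicates, 5%
multiplicative noise) for Km recovery, and a 5-point capacity sweep for the
monotonicity check. Ties in site ranking are broken alphabetically and
flagged ambiguous. Degenerate geometry (zero-length arms or segments,
θ ∈ {0°, 180°} embeddings) raises typed errors rather than returning NaN.

## Known limitations

* No free-energy or QM layer: competent fractions are geometric counts.
* The competitive-inhibition form and the bi-substrate simplification are
  assumptions, as noted above.
* The generator's independence and normality assumptions make it a pipeline
  validator, not an MD surrogate.
* CSV outputs quantise floats to 6 significant digits; PDB output to 1e−3 Å.
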