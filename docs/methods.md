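# Methods

`vesiq` quantifies vesicle-mediated trafficking of immunoglobulin (IgG)
cargo at brain microvessels from multi-channel 3D confocal stacks. Because
no public dataset accompanies this kind of *ex vivo* imaging, the package
pairs every analysis stage with a synthetic-scene generator whose ground
truth is recorded exactly; correctness is established by parameter
recovery rather than by comparison to a deposited image set. This note
documents the models, the defaults and why they were chosen, and what the
synthetic test bench does and does not demonstrate.

## The imaging model

A field of view contains one capillary. The generator renders, per channel,
a photon-density grid that is then passed through the acquisition model:

1. **Geometry.** The vessel is a straight (optionally sinusoidal) tube along
   the x axis: an interior of radius `vessel_inner_radius` (default 1.9 μm —
   a ~4 μm lumen), wrapped in a basal-lamina shell of thickness
   `shell_thickness` (default 0.6 μm, the apparent width of an
   immunostained CollagenIV band at confocal resolution, which is wider
   than the anatomical lamina because of the PSF). Everything outside the
   shell is brain parenchyma.
2. **Objects.** Vesicular puncta are isotropic Gaussian photon blobs with
   per-axis σ = radius/√2, so a scale-normalized blob detector reporting
   `radius = √2 · σ_best` recovers the drawn radius before PSF broadening.
   Radii are log-normal with median 0.30 μm and σ_ln = 0.35 (over 90% of
   objects below 0.5 μm — endosome-scale). Cargo intensities are log-normal
   with σ_ln = 1.15, so the central 99.7% of per-object photon counts spans
   three decades. Lysosome-marker objects share the radius law but use a
   tighter intensity law (median 8000 photons, σ_ln = 0.5): marker stains
   are exposed for uniform visibility, whereas the per-vesicle cargo load is
   the biological quantity that varies over decades.
3. **Placement.** Object centres are uniform over the interior
   cross-section, keeping `max(placement_clearance_um, radius)` clear of the
   shell wall (default floor 0.15 μm): a vesicle is bounded by the plasma
   membrane, so its centre cannot be closer to the lamina than its own
   radius. Setting the clearance to 0 places centres uniformly over the
   whole interior; the null-calibration scenario uses that, because the
   chance-colocalization null randomizes positions uniformly over the
   segmented interior and its calibration must be checked under a matching
   placement distribution.
4. **Colocalization.** A requested fraction (default 0.20) of *total cargo
   intensity* is co-placed at lysosome centres, whole object by whole
   object, walking cargo objects largest-first and finishing with the
   single object that lands the running total closest to the target. The
   achieved fraction is recorded in the manifest; it is within one small
   object of the target.
5. **Diffuse pools.** Uniform cargo photon densities inside the shell
   (`bl_accumulation`, default 2 photons/voxel) and in the parenchyma
   (`parenchyma_level`, default 1 photon/voxel) model extracellular
   accumulation. The pericyte-deficient scenario multiplies these by 100 and
   50, reduces puncta density to 0.3×, dilates the vessel 1.5× and removes
   lysosomal colocalization.
6. **Acquisition.** Anisotropic Gaussian PSF (σ_xy = 0.12 μm,
   σ_z = 0.35 μm, approximating a 1.4 NA confocal), Poisson shot noise, an
   additive detector offset (`background`, 5 photons/voxel), Gaussian read
   noise (σ = 2), rounding, and clipping to 12 bits in a 16-bit container.
   The default grid is 16 sections of 512×512 at 0.09 × 0.09 × 0.5 μm —
   one of the two printed acquisition geometries at desk scale; the other
   (1024×1024 at 90 nm, and 512×512 at 46.46 nm) are available as named
   presets.

Per-animal biological variability in cohorts is a log-normal multiplier
(sd 10%) on the intensity-scale parameters, drawn per animal from seeds
derived deterministically from (master seed, animal, vessel).

## The analysis pipeline

**Segmentation.** The basal lamina is an absolute intensity threshold on
the CollagenIV channel (a fixed value, or Otsu's between-class-variance
criterion; the chosen value is logged per stack), followed by removal of
connected components smaller than 1 μm³. For a discrete two-level image the
Otsu cutoff is placed midway across the empty gap between the classes.
"Inside the vessel" is computed by hole-filling the shell on 2D
cross-sections normal to the vessel axis (a tube lying in the imaging plane
produces closed annuli only in those sections), after bridging sub-voxel
gaps in the digitized shell with a dilate–fill–erode step at 0.3 μm
physical scale, then a 3×3×3 majority vote removes single-slice artefacts.
A 3D fill strategy is available for closed shells. Every voxel receives
exactly one label: INTERIOR, BASAL_LAMINA or PARENCHYMA.

**Geometry.** Volumes are voxel counts × voxel volume and always sum to the
field volume. The shell surface area counts exposed voxel faces; this is
exactly testable and adequate for normalization but biased high against a
smooth surface (a digitized cylinder reports roughly 4/π of its lateral
area). All reported fold changes are ratios between genotypes measured the
same way, so this bias cancels.

**Spot detection.** Scale-normalized Laplacian-of-Gaussian responses
(−σ²·∇²G_σ∗I) over a 5-rung geometric ladder spanning [0.5, 2] × the
expected radius (0.4 μm by default, from an expected diameter of 0.8 μm),
with per-axis filter widths set in physical units through the voxel
spacing (clamped at 0.4 voxel, below which the discrete operator is
unreliable). Local maxima of the scale-maximal response are thresholded at
the response median + 15·MAD — `k = 15` was calibrated on synthetic
fixtures so that ≥95% of pure-noise stacks yield zero detections while
objects with peak SNR ≥ 10 are kept (sensitivity 0.85–1.0) — then
non-maximum suppression at 0.4 μm keeps the higher-quality candidate (ties
broken lexicographically; flat plateaus contribute one representative).
Radius is √2 × the best scale; the centroid is an intensity-weighted
refinement; integrated intensity is the sum inside the spot sphere minus
the median of a concentric background shell (1–2 radii). A
maximum-intensity-projection mode performs the same detection in 2D.

Detected integrated intensity is a roughly constant fraction (~0.4) of an
object's total photons (the sphere truncates the Gaussian tails); all
downstream statistics — intensity fractions, decade spans, log-normal σ —
depend only on relative intensities and are unaffected.

**Colocalization.** A cargo object is colocalized when some marker centroid
lies within max(r_cargo + r_marker, 0.25 μm) of its centroid (closed
boundary; the floor is one lateral PSF width). The statistic is the fraction
of total cargo object intensity in colocalized objects. Chance level: marker
centroids are re-drawn uniformly over INTERIOR voxels (sub-voxel jitter,
radii and intensities kept) for `n_rand = 100` replicates; the corrected
fraction is observed − null mean, clamped to [0, observed] because the
reported quantity is a fraction. The signed, unclamped excess is also
reported: clamping makes the *mean* of a null-centred quantity positive by
construction, so calibration checks ("independent channels average to
zero") use the excess. Randomizing the cargo instead of the marker is
available as an option.

**Per-vessel metrics.** (i) cargo intensity per μm² of basal lamina, (ii)
cargo intensity per μm³ of parenchyma, (iii) interior puncta per μm³ of
filled vessel (INTERIOR + BASAL_LAMINA; a shell-only denominator is an
option). Compartment intensities subtract a per-stack background estimated
as the median cargo intensity over the interior *core* — INTERIOR voxels at
least 0.8 μm from any other compartment and at least 3 radii away from any
detected punctum. The lumen carries no diffuse cargo, so this median
estimates the detector offset; a whole-stack modal background (also
available) tracks the dominant compartment and would cancel exactly the
parenchymal signal being measured.

**Statistics.** Fisher's LSD: one-way ANOVA, then pairwise pooled-variance
t-tests on N−k degrees of freedom, two-sided, uncorrected (that is the
LSD). Fold changes are ratios of group means with a seeded bootstrap
percentile CI (2000 resamples; the CI is an addition beyond the original
reporting and is labelled as such in outputs). Mann-Whitney U uses the
exact null when the pooled sample is ≤ 16 without ties, otherwise the
normal approximation with tie and continuity corrections; at n = 8+8 the
approximation's worst-case two-sided deviation from the exact null is
0.0109 (enumerated over all U), at central U values. TEM count summaries
report medians and type-7 (linear interpolation) quartiles, mirroring
median/IQR presentations. Vessels are the statistical unit; the animal
label is carried descriptively but not modelled (no mixed effects).

## What the synthetic bench does and does not show

The generator emulates tube geometry, PSF anisotropy, Poisson–Gaussian
noise, decade-wide cargo loads, and genotype contrasts with per-animal
random effects. It does not emulate: curved or branching vessels, nuclei or
pericyte somata distorting the lamina (a decorative nuclei channel is
optional), non-uniform lamina staining, autofluorescence textures,
spectral bleed-through, or depth-dependent aberrations. Passing recovery
tests therefore demonstrates that the pipeline measures what it claims on
images of known content with realistic noise and optics — not that it is
robust to every artefact of real tissue. TEM count generation is
distribution-level only (negative binomial with configurable dispersion;
the means are plausible round numbers with the mutant phenotype, chosen
because the original reporting prints only medians and IQR bars).

## Numerical and design choices

- Coordinates are 0-based (z, y, x); physical positions are voxel-centre
  μm. All interfaces use μm.
- Seeds: every stochastic step takes an explicit seed; per-vessel and
  per-animal seeds derive from a master seed via `SeedSequence`, and
  identical (config, seed) reproduce byte-identical stacks and tables.
- Degenerate inputs: empty images yield empty spot sets (not errors); a
  shell that encloses nothing yields an empty INTERIOR with a warning; an
  empty cargo set, a zero-variance sample, or a zero reference-group mean
  raise errors.
- The whole-stack study sizes used in the acceptance checks are 30 vessels
  for steady-state recovery and 3 animals × 10 vessels per genotype for the
  cohort contrasts — the study design the scenarios model; the test suite's
  unit fixtures are smaller scenes chosen to exercise identical code paths.
- The colocalization acceptance statistic is the randomization-corrected
  fraction; the observed (uncorrected) fraction is recorded alongside it in
  all outputs, since published "fraction colocalized" values do not always
  state which is meant.

## Known limitations

- Sub-voxel axial sampling (0.5 μm sections vs 0.2–0.4 μm objects) makes
  the 3D scale estimate axially dominated and compresses the radius
  distribution; for size histograms, MIP-mode (2D) detection resolves the
  lateral scale and is the recommended measurement, which is also how the
  original 2D multiparametric analysis measured sizes.
- Faint objects below the detection floor (~peak SNR 2–3) are invisible, so
  puncta-density recovery is a lower bound (≈80% of the generative density
  at the default intensity law); the genotype *ordering* of densities is
  preserved.
- Voxel-face surface areas and face-count biases cancel in genotype ratios
  but make absolute per-μm² values convention-dependent.
- The randomization null assumes the compartment, not the cell, bounds
  vesicle positions; endothelial-layer confinement would require a
  cytoplasm mask the imaging cannot provide.
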