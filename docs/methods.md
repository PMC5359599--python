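# Methods

## The screen model

The pipeline analyses a phenotypic screen whose per-well readout is the
percentage of cells positive for a neutral-lipid stain. A 384-well plate
(16×24) carries compound wells, DMSO vehicle wells (negative controls,
baseline lipid content), and Matrigel-type wells (positive controls, strong
lipid-droplet induction). Each compound is assayed on two independent
replicate plates; replicate plates share the compound set but not well
positions.

Per plate, the percent-positive values x of the *scoring wells* are
summarized by mean, sample SD (n−1 denominator), median m and
MAD = median(|x − m|), and every non-empty well is scored

    z = (x − m) / (MAD · 1.4826).

The constant 1.4826 ≈ 1/Φ⁻¹(3/4) makes the MAD a consistent estimator of σ
under normality; it is exposed as `plate_stats.MAD_SCALE` so the formula is
auditable. A compound is a hit iff z > 5 (strict) in ≥ 2 replicates and its
cell death never exceeds 60% (strict) in any replicate; hits are ranked by
the arithmetic mean of z over *all* replicates, sub-threshold ones included
(averages are therefore defined for non-hits too). Ties in average Z break
lexicographically by compound id. Cell death in a well is estimated as
1 − total_cells / median(total_cells over that plate's negative controls),
clamped to [0, 1]; at least four usable control wells are required.

Design choices where the procedure was genuinely open:

* **Scoring scope.** Plate median/MAD are computed over compound wells only
  (default). Including the strong positive controls would inflate the
  plate's scale estimate and shrink every z; `scope="all_non_empty"` is one
  config switch away and covered by tests.
* **Even-length medians** are the midpoint of the two central order
  statistics.
* **MAD = 0 plates** (possible on idealized synthetic data) raise by
  default; `mad_zero="sd_fallback"` scores (x − mean)/sd with a warning.
* **Death exclusion** uses the maximum death fraction over replicates with
  a strict > 0.60 comparison, and is computed per replicate against that
  plate's own negative controls.

## Image quantification

The instrument-side analysis of the original assay is proprietary, so the
quantifier defines its own minimal deterministic pipeline:

1. Gaussian smoothing of the nuclear channel (σ = 1 px default);
2. global threshold — Otsu by default, fixed value optional; a constant
   image yields zero nuclei with a logged warning rather than an error;
3. 8-connected component labelling;
4. area filter (default 8–2000 px) — no watershed splitting of touching
   nuclei, which is sound on the generator's overlap-free placements.

Each nucleus's lipid signal is the mean of the lipid channel over the
nucleus mask expanded by 3 px (lipid droplets are cytoplasmic and
juxtanuclear). Expansion is *exclusive*: contested pixels go to the nearest
nucleus, so no droplet is counted toward two cells. A cell is positive when
this mean strictly exceeds a threshold τ calibrated per plate as
median + k·MAD (k = 3) of the pooled per-cell lipid means from ≥ 50
negative-control cells; when that pool is perfectly uniform (MAD = 0,
noise-free simulations) τ degrades to the median with a warning, and the
strict comparison keeps background-only cells negative. The per-cell
mean-intensity criterion is a declared substitute for the unknown
instrument definition of "Bodipy positive", not a reconstruction of it.

## The synthetic generator

The generator emulates the screen's statistical structure with per-cell
ground truth. Defaults are desk-scale — 300 cells/well on 512×512 px
images — so that full-plate image runs take seconds per well;
`simulate.full_scale()` restores the assay's 1500-cells/well density on
2048×2048 px frames. Role determines a well's true responder fraction:
baseline 5% (negative controls and unplanted compounds), 60% (positive
controls), baseline + `hit_effect` (default +50 points) for planted hits;
`death_by_compound` sets per-compound death fractions.

Image path: surviving cells = round(seeded · (1 − death)); centres are
drawn uniformly by rejection sampling with pairwise separation
≥ 2 nucleus radii (retry budget 50·n, then an error suggesting lower
density). Each cell is a responder with probability p_true; droplet counts
are Poisson (responder mean 8, background mean 0), with responders forced
to carry ≥ 1 droplet. Nuclei and droplets are rendered as compact-support
parabolic intensity bumps (nucleus radius 5 px, peak 12000; droplet radius
2 px, peak 20000) on a flat background (400) with additive Gaussian noise
(σ = 50 default; an optional linear illumination gradient sits behind a
config flag) and clipping to the unsigned-16-bit range. Droplet centres
are drawn uniformly within `droplet_scatter_factor` (default 0.6, max 3)
nucleus radii of their cell; together with the ≥ 1-droplet guarantee and
the exclusive perinuclear masks, the tight default makes noise-free images
encode the truth *exactly* — quantified total and positive counts equal the
planted values — which is what turns the generator into a benchmark with a
checkable right answer. Wider scatter (up to the 3-radius halo) is
available but re-introduces neighbour cross-talk by construction.

Summary path: per well, surviving n ~ Binomial(cells, 1 − d_true) and
positive k ~ Binomial(n, p_true), percent = 100k/n (zero and flagged when
n = 0). This binomial counting noise is the screen's natural null; the
null-specificity checks run on it (it is approximately Gaussian at
n = 300, p = 5%). Every draw is keyed by (seed, replicate, plate, stream),
so all operations are byte-reproducible and replicates are independent.

What the generator does **not** emulate: optical point-spread functions,
shot noise, uneven plating, edge effects, focus failures, debris, or any
compound-specific morphology. Passing tests therefore demonstrate the
correctness of the *rule set and its statistical behaviour*, not
segmentation performance on real micrographs; for real images the
fixed-threshold/no-watershed defaults would need revisiting (a watershed
flag and fixed-threshold option exist for that purpose).

## Numerical and validation choices

* Monte-Carlo checks use 3 standard-error tolerances on binomial moments.
* CSV floats are written at 6 significant digits, making byte-identity of
  outputs under a fixed seed well-defined.
* Null specificity is assessed on 100 simulated screens (320 compounds × 2
  replicates); under the binomial null, P(z > 5 in both replicates) is
  ≪ 10⁻⁴ per compound, so total hits ≈ 0 (≤ 3 allowed across the run).
* Planted-hit recovery uses responder shifts of ≥ 10 plate-MADs of
  percent-positive over 20 seeds (sensitivity ≥ 0.95 with zero false
  positives expected); cytotoxic planted hits at 80% death must always be
  excluded.
* Problem sizes for image-path validation are one noise-free 96-well plate
  (exactness) and an end-to-end two-replicate 96-well image run at default
  noise (hit recovery); both finish in well under a minute per plate.

## Known limitations

* Cell death is inferred from nuclei counts relative to negative controls;
  compounds that arrest proliferation without killing are indistinguishable
  from mildly toxic ones.
* Percent-positive is granular at 100/n; with few surviving cells the z
  scores of dead wells are noisy (they remain hit-ineligible through the
  death exclusion).
* The positivity threshold τ is calibrated per plate; systematic lipid
  staining differences between plates are absorbed, but within-plate
  spatial effects are not corrected (no B-score/row–column polish, by
  design).
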