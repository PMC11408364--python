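# Methods

## Model and procedure

zcoloc treats a confocal z-stack as a set of grayscale channel volumes on
one (nz, ny, nx) voxel grid, axis order (z, y, x), 0-based. A run is:

1. **Load** a multi-channel TIFF (hyperstack-style files with a channel
   axis, or plain multi-page files de-interleaved channel-fastest into a
   user-stated number of channels). Intensities are never rescaled on
   load; integer 8-/16-/32-bit and 32-bit float voxels are supported.
2. **Crop** to the optional ROI box. Boxes are half-open voxel intervals
   [min, max) per axis; a box partially outside the volume is clamped to
   the extent (as a user would drag box handles beyond the rendering), and
   a box with no overlap at all is an error. Physical-unit (micron) boxes
   are converted through the stack's voxel spacing when present.
3. **Threshold** each selected channel with a lower/upper pair. Two
   distinct semantics are applied deliberately:
   - *Weight masks* for co-occurrence: wᵢ = 1 iff lower < vᵢ ≤ upper. The
     bound asymmetry (strict below, inclusive above) means a voxel exactly
     at the lower threshold is background and one exactly at the upper
     threshold is signal; lower == upper yields an empty mask.
   - *Correlation preprocessing*: vᵢ > upper ↦ 0, then vᵢ ↦ max(vᵢ −
     lower, 0). Out-of-range voxels are set to zero, not excluded, so the
     correlation sums always run over every voxel of the cropped grid.
4. **Measure**: PCC for every pair of the 2–3 selected channels
   (C(k, 2) pairs, ascending index order), the global intersection
   coefficient I = |∩ masks| / |∪ masks| (three-channel union via
   inclusion–exclusion), per-channel coefficients iₖ = |∩ masks| /
   |mask k|, and the Venn partition of the union.
5. **Report**: unweighted 2-/3-circle Venn diagram, one 2D histogram per
   channel pair, and an XLSX workbook with a byte-stable CSV twin.

All accumulations are in double precision regardless of input bit depth,
so 32-bit inputs with large n cannot overflow the sums. Intersection
coefficients are exact integer ratios evaluated in double precision.

## Undefined results

A PCC is undefined when either preprocessed channel has zero variance; an
intersection coefficient is undefined when its denominator is empty (all
three when the union is empty, a single iₖ when only that channel's mask
is empty — I and the other coefficients are still computed and are then
0). Undefined values are carried as NaN markers and rendered as the
literal `n/a` in every output. They are never coerced to 0, because a
silent zero reads as "measured absence of colocalization" and corrupts
downstream interpretation.

## Parameters

| Parameter | Units | Default | Rationale |
|---|---|---|---|
| thresholds (per channel) | raw intensity | channel's full original range | matches on-load behaviour of interactive tools; `auto` excludes the top/bottom 0.1% |
| ROI box | voxels (half-open) | full extent | analysis of the whole stack unless restricted |
| 2D-histogram bins per axis | — | 256 (8-bit), 512 (deeper) | a full 16-bit 65536² grid is wasteful; edges are recorded in the output |
| Venn/report display precision | decimals | 4 | fixed display precision; stored values keep full precision |

The `auto` threshold uses **nearest-rank** percentiles: on the ascending
sorted n values, lower is the value at 1-based rank ⌈0.001·n⌉ and upper at
⌈0.999·n⌉. Nearest-rank was chosen over interpolated percentiles because
it is dialect-free and reproducible (no claim is made that it matches any
particular GUI widget bit-exactly). With the strict-lower/inclusive-upper
mask rule, exactly the bottom 0.1% of ranks are excluded at-or-below the
lower bound and the top 0.1% above the upper bound.

## Numerical and design choices

- **PCC over the full grid.** Voxels zeroed by preprocessing stay in the
  sums. A documented alternative — restricting to voxels with signal in
  at least one channel — is deliberately not the default, since the
  preprocessing rule says "set to 0", not "discard".
- **Venn normalization by the union.** Every region percentage divides by
  the union volume, so the seven (or three) regions sum to 100% and the
  all-channels region equals 100·I. Percentages are rounded half-even to
  four decimals at render time only.
- **2D histogram background rule.** A voxel is plotted iff at least one
  of the two channels is inside its valid (mask) range; voxels outside
  both ranges are background and are dropped. Counting uses raw
  intensities, not the PCC-preprocessed values. Consequently the plotted
  voxels are exactly the union of the two masks, and the three populated
  regions (valid-in-both / only-first / only-second) reproduce the Venn
  percentages of the same pair.
- **TIFF interleave.** Nothing in multi-page TIFF fixes how acquisition
  software interleaves channels; zcoloc trusts an explicit channel axis
  when present and otherwise requires the user's `--n-channels`, assuming
  channel-fastest page order (z0c1, z0c2, …). Stacks are written as
  ImageJ-style ZCYX hyperstacks (shaped-metadata fallback for uint32,
  which the ImageJ dialect cannot hold).
- **Metrics are voxel counts.** Voxel spacing is carried as metadata only;
  no physical-volume weighting is applied, since all coefficients are
  defined as voxel-count ratios.
- **Report determinism.** The timestamp is an input, never sampled inside
  the writer, so identical runs produce byte-identical CSV twins.

## Synthetic data generator

`synth_fixtures` emulates plateau-labelled structures: each channel is a
constant background plus solid boxes/spheres of constant intensity plus
optional seeded Gaussian noise, truncated to the bit-depth range. Shape
membership is decided per voxel center, so every mask volume, overlap
volume and coefficient has an exact integer/rational ground-truth value,
and thresholding at the background/plateau midpoint recovers the
ground-truth masks exactly on noiseless stacks. The generator requires
the plateau to exceed background + 5·noise_sd so midpoint thresholding stays
reliable at the noise levels generated.

What it does **not** emulate: the microscope's point-spread function,
Poisson shot noise, channel bleed-through/crosstalk, intensity gradients
with depth, or biologically realistic structure shapes. Passing tests
therefore demonstrate the correctness of the computations on images whose
ground truth is known, not the biological validity of any particular
threshold choice on real acquisitions — on real data, threshold selection
and prior denoising remain the user's responsibility and dominate the
result.

Default study conditions used by the tests and the acceptance script: the
engineered two-box fixture (|A| = 4000, |B| = 3000, |A∩B| = 2000 on a
10×20×25 grid, 8-bit, background 10, plateau 120) whose coefficients are
I = 0.4, i1 = 0.5, i2 = 2/3 exactly; and a 12×40×40 16-bit three-sphere
stack (background 100, plateau 2000, noise σ = 40) for the three-channel
path. Oracle-equivalence checks run 200 random 4×6×6 stacks against
literal set-arithmetic and per-voxel-formula oracles; these sizes keep the
whole suite in a few seconds while exercising every code path.

## Known limitations

- Only axis-aligned box ROIs; no rotated boxes, ellipsoids or freehand
  regions.
- No Manders/Spearman/overlap coefficients, no Costes automatic
  thresholding, no significance testing of PCC, no deconvolution.
- The channel-fastest de-interleave assumption for plain multi-page files
  can be wrong for some acquisition software; the channel axis in the
  file, when present, always wins.
- The interactive HTML fluorogram is a self-contained page with a cursor
  readout over the embedded image; the readout maps cursor position to
  bins approximately (plot margins are not subtracted).
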