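# atrialign

Automatic rigid alignment of left-atrial (LA) surface anatomies from
pre-procedural imaging (CT/MRI segmentations) with anatomies acquired by
electro-anatomical mapping (EAM) during ablation procedures — plus the
residual-distance metrics to judge the result and a synthetic labeled LA
phantom to validate everything against known ground truth.

Intended users: cardiac electrophysiology researchers fusing imaging-derived
substrate maps (scar, wall thickness) with mapping data, and developers of
registration pipelines who need a tested, scriptable, vendor-neutral
alignment step.

## Method

The imaging anatomy (moving) is registered onto the EAM anatomy (fixed) by
iterative closest-point registration with a **point-to-plane** metric: both
clouds are treated as samplings of smooth surfaces, and each iteration
minimises

```
E(R, t) = Σᵢ [ (R pᵢ + t − qᵢ) · nᵢ ]²
```

over rotations `R` and translations `t`, where `qᵢ` is the nearest fixed
point to the moving point `pᵢ` and `nᵢ` the fixed-surface normal at `qᵢ`.
Matches beyond 3× the median match distance are rejected (robustness to
partially mapped anatomies), and the linearised 6-parameter solve is
iterated to convergence with re-orthonormalisation, so every estimate is a
true rigid transform.

Alignment is **two-stage**: stage 1 runs on the full anatomies, letting the
pulmonary veins, appendage and mitral annulus — the most distinctive
landmarks — drive the pose; stage 2 re-runs the ICP with those structures
excluded, capped at 3 iterations, so the true atrial-body surface is
refined without being pulled by structures that imaging and mapping systems
segment differently. Quality is reported as residual Euclidean distances
after structure exclusion: median, mean, and % of surface below 2.5/5 mm.
Non-isotropic segmentation exports are first resampled to uniform point
spacing. See `docs/methods.md` for the full model, assumptions and
numerical choices.

## Worked example

Generate a labeled phantom, simulate an EAM acquisition of it under a known
displacement (12° rotation / 6 mm translation, 0.5 mm point noise, 85%
coverage), and align:

```bash
atrialign phantom generate --seed 7 --out la.ply
atrialign phantom acquire la.ply --transform true_transform.txt \
    --noise 0.5 --coverage 0.85 --seed 3 --out eam.xyzl
atrialign align --moving la.ply --fixed eam.xyzl --out run1
```

Output (exit code 0 = aligned and passed the automatic check):

```
wrote 1795 labeled points to la.ply
wrote 1526 points to eam.xyzl
... atrialign INFO alignment PASSED: median residual 0.88 mm
```

`run1/` then contains `transform.txt` (the estimated 4×4 rigid transform,
row-major, mm), `aligned.ply` (the imaging anatomy mapped into the EAM
frame), `distance_map.ply` (per-vertex residual scalar field for regional
visualisation) and `diagnostics.json`, whose summary for this run reads:

```
passed: True
median_mm: 0.876                 # body-surface median residual
pct_below: {'2.5': 87.6, '5': 91.5}
stage1 iters: 4  stage2 iters: 2
```

The 0.88 mm median matches the acquisition noise model's prediction for
0.5 mm point noise at 2 mm sampling; the ~12% of surface beyond 2.5 mm is
the unmapped 15% coverage gap, visible as a high-residual patch in
`distance_map.ply`.

A cohort experiment over many phantom pairs (per-case table + "average
median" summary):

```bash
atrialign experiment --n 20 --noise 0.5 --seed 1 --out exp/
```

The same functionality is available as a library
(`atrialign.align_two_stage`, `atrialign.residual_distances`,
`atrialign.generate_phantom`, ...), configured by a single YAML document
(see `atrialign.config`).

## File formats

- `xyzl`: whitespace-delimited ASCII, one `x y z [label]` point per line
  (mm, `#` comments); labels from
  `BODY LSPV LIPV RSPV RIPV LAA MV_ANNULUS`.
- `ply`: read ascii/binary-little-endian; written as double-precision ASCII
  with a per-vertex `label` property (lossless round-trip).
- `obj` / `stl`: geometry only (labels default to BODY on read).

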