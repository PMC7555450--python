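# Methods

This document records the models, conventions and numerical choices behind
`fragquant`, in enough detail to reimplement the package.

## 1. Data model

A *stack* is one fragment at one timepoint: three single-channel 3-D
arrays of shape `(z, y, x)` with named channels `live_green`, `til_red`,
`dead_apc`, a voxel size `(dx, dy, dz)` in µm, a time in hours and a
fragment id. On disk a stack is a multi-page TIFF (channel-major pages)
plus a JSON sidecar holding the channel order, shape, voxel size, time and
fragment id. Channel identity always comes from the sidecar names; page
order is an implementation detail. Reading a TIFF whose page count
disagrees with the sidecar fails with an error naming the missing
channels.

An *experiment layout* is a YAML file mapping fragment ids to conditions
(`isotype`, `anti_PD1`, `anti_CTLA4`) and stack paths. Loading validates
that conditions are known, ids unique, the layout non-empty, and (for
disk-backed layouts) that every referenced path exists — fail fast, before
any computation.

Indices are 0-based; coordinates refer to voxel centers. All volumes are
voxel counts × `dx·dy·dz` in µm³.

## 2. Voxel classification

Each channel is binarized with a strict threshold (`intensity > t`).
Per-channel binary masks are then cleaned by a minimum-area filter: within
each z-slice, connected components (8-connectivity by default,
4-connectivity optional) with physical area `< min_area_um2` are removed.
The filter is per-slice because optical sections are far apart (10 µm)
relative to lateral resolution, so 3-D connectivity would bridge unrelated
structures; a volumetric variant (`mode="3d"`, cutoff `min_area_um2 · dz`)
exists for isotropic data.

Cleaned masks `G` (green), `R` (red), `A` (APC) map to seven mutually
exclusive classes, in this precedence order:

| class         | rule          | interpretation                          |
|---------------|---------------|-----------------------------------------|
| `dying_til`   | `R ∧ A`       | apoptotic TIL (triple-positive included)|
| `til_on_live` | `R ∧ G`       | TIL overlying/contacting live tumor     |
| `til`         | `R` only      | viable TIL                              |
| `dying`       | `G ∧ A`       | early-apoptotic tumor (the signal)      |
| `dead`        | `A` only      | dead tissue of any cause                |
| `live`        | `G` only      | intact tumor                            |
| `background`  | none          |                                         |

The triple-positive → `dying_til` choice is deliberate: red identifies the
cell as a TIL regardless of residual green from the tumor it sits on, and
annexin V then reports that TIL's state. Every voxel gets exactly one
label (verified by a partition property test).

Thresholds are never chosen silently. For simulated data the *mid-gap*
rule is used: `t = (background + signal)/2` per channel, with the green
signal first attenuated by the photobleaching expected at the final
timepoint, so the margin survives the whole series. An Otsu-based
initializer is provided for real data but must be invoked explicitly.

## 3. Viability statistic

The per-fragment, per-timepoint response is the **dying tumor fraction**

```
f = V(dying) / [V(live) + V(dying) + V(til_on_live)]
```

The denominator is green-positive tissue: tumor that is demonstrably still
tumor at this timepoint. APC-only voxels are excluded by default because
they conflate drug-attributable death with fragmentation damage, the
loading-injured perimeter, and debris; `include_dead=True` switches to the
whole-fragment denominator `V(live)+V(dying)+V(dead)+V(til_on_live)` when
cumulative death is wanted. A zero denominator yields `NaN` plus an
`empty_tumor_mask` flag rather than an exception.

Trajectories are summarized per condition and timepoint as mean fraction
and standard error (sample SD / √n, `NaN` at n = 1). Treatment effect at a
chosen timepoint is expressed against the isotype control in both
conventions found in the literature:

* `ratio = f_treated / f_control`,
* `relative_increase = ratio − 1` (so 13% vs 8% is a "0.625-fold
  increase" in that convention, ratio 1.625).

A zero control produces an explicit `undefined` flag, never ±inf.

## 4. Group statistics

**Kruskal–Wallis** is implemented from first principles: midranks via a
sorted-walk over the pooled sample, `H = 12/(N(N+1)) Σ Rᵢ²/nᵢ − 3(N+1)`,
tie correction `C = 1 − Σ(t³−t)/(N³−N)`, `H' = H/C` (all-tied data gives
H = 0, p = 1 by convention). The default p-value is the χ² (k−1 df)
survival function; `exact=True` enumerates the multiset of group
assignments (capped at 5·10⁵ arrangements) for small samples, which
matters at n = 3 per group: the most extreme arrangement (H = 7.2) has
χ² p ≈ 0.0273 but exact p = 6/1680 ≈ 0.0036, and the exact probability of
χ² p < 0.05 under the null is 18/1680 ≈ 0.0107, not 0.05.
`scipy.stats.kruskal` is used only as a cross-check in tests.

**Growth tables** (columns `animal_id, group, day, volume_mm3`) get
per-day group means/SE/n, per-day Kruskal–Wallis with a Holm-adjusted
column, and percent volume reduction
`100·(1 − mean_treated/mean_control)` at a chosen day. Endpoint censoring
(animals removed once they hit a volume cap) is respected: each day uses
the animals actually measured that day. A synthetic exponential-growth
cohort generator exists for demonstration and testing.

## 5. Synthetic fragment generator

The simulator produces stacks *and* exact voxel-level truth, so the
pipeline can be validated without deposited data.

**Geometry.** A fragment is a star-convex body: radius
`R(û) = R₀ (1 + ε s(û))` where `s` is a degree-≤2 polynomial in the
direction cosines, normalized to max |s| = 1, and ε is
`radial_perturbation` (default 0.10, R₀ = 100 µm). *Radial depth* of a
voxel is `R(û) − r`; all death dynamics are functions of this depth,
which is what makes the closed-form checks exact.

**Death dynamics.** Each tumor voxel has an onset time
`t_on = (depth − damage_depth)/kill_speed`; the perimeter ring
(`depth ≤ damage_depth`, default 10 µm) has `t_on = −dying_duration`, i.e.
it is already dead at t = 0 — that models loading damage and is why the
dead class must be excluded from the response metric. A voxel is LIVE
before `t_on`, DYING (green + APC) for `dying_duration` (24 h), then DEAD
(APC only, green lost with membrane integrity). The kill front speed is
the main treatment knob: 0.05 µm/h × (1.0, 2.4, 4.0) for isotype /
anti-PD1 / anti-CTLA4.

**TILs.** Arrivals are Poisson on the fragment surface
(rate per µm² per hour, × (1.0, 2.0, 3.0) by condition), each a 5 µm
sphere burrowing inward at 2 µm/h. Tumor voxels within the 6 µm kill
radius of a TIL center get their `t_on` pulled to the contact time. TILs
turn annexin-positive after 48 h (becoming `dying_til`).

**Signal model.** Class-appropriate base intensities, green multiplied by
`exp(−bleach_rate · t)` (0.005 /h), then Gaussian background
(mean 100, SD 20) plus signal-proportional dispersion (5%), clipped at 0.
With all noise, bleaching and TILs off, rendering is an exact function of
the truth labels, which several tests exploit.

**Closed form.** For an unperturbed sphere the killed (dying + dead)
volume at time t is the shell between `R₀` and
`R₀ − (damage_depth + speed·t)`; tests compare the simulator against this
with a one-voxel-shell tolerance `4πR₀²·max(dx,dy,dz)`.

**What it does and does not emulate.** It reproduces the measurement
chain (co-localized dyes, bleaching, noise, anisotropic voxels, perimeter
artifact, TIL infiltration) with a deliberately simple biological core
(deterministic radial front, no proliferation, no convection, no optical
PSF, no z-attenuation, no cell-scale texture). It is a test harness for
the *quantification*, not a biological model.

## 6. Determinism and orchestration

One integer seed drives everything: `derive_seeds` splits it into
independent child seeds (< 2³¹) via `numpy.random.default_rng`, one per
fragment. Identical seeds give byte-identical CSVs (floats written with
`%.10g`) and identical acceptance JSON. The CLI (`fragquant simulate |
quantify | full`) takes a YAML config, writes outputs plus a
`manifest.json` (inputs, config SHA-256, package version, file list),
removes partial outputs on failure, and exits 0 on success, 1 on
configuration errors, 2 on runtime errors.

## 7. Open decisions and limitations

* The per-slice minimum-area filter is applied per channel *before*
  class logic; filtering the class masks instead would interact with
  precedence and was rejected for predictability.
* Mid-gap thresholds assume the generator's intensity model; real data
  needs per-experiment thresholds (Otsu initializer + inspection).
* The dying fraction is a per-timepoint state fraction, not a cumulative
  kill estimate; its denominator shrinks as tissue dies, so late-time
  values of different conditions should be compared at matched times.
* With n = 3 fragments per condition, per-timepoint Kruskal–Wallis has
  little power (min p ≈ 0.027 with χ², ≈ 0.0036 exact); multiplicity
  correction across ~25 timepoints leaves nothing significant — expected,
  and a reason the fold statistics at the final timepoint are the primary
  readout.
* The simulator's truth fraction is defined on the conserved
  live+dying+dead denominator; recovered-vs-true comparisons therefore
  use the pipeline's `include_dead=True` convention so both sides measure
  the same quantity.
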