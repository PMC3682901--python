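# rtrecur

Recurrence-pattern analysis for radiotherapy follow-up imaging.

When a tumor recurs after radiotherapy, the clinically decisive questions
are *where* it recurred relative to the treated volumes and *how much dose*
that region had received: an infield recurrence inside the high-dose boost
argues for dose escalation, while a marginal or outfield recurrence argues
for larger (or differently shaped) target volumes. Answering these
questions by hand — matching a follow-up CT to the planning CT, carrying
the delineated recurrence across, and reading doses off the plan — is slow
and error-prone. `rtrecur` automates the measurable parts of that workflow
for radiation oncologists and medical physicists doing pattern-of-failure
studies:

1. **Rigid registration** of the follow-up CT to the planning CT with
   Mattes mutual information, including a pre-initialization step for
   follow-up scans acquired in oblique positioning (axial rotations of
   20–60° are routine in abdominal protocols). The result is the
   nine-component transform `T = (tx, ty, tz, rpx, rpy, rpz, rx, ry, rz)`
   (translation, rotation point, z–y–x Euler angles in degrees).
2. **Subvoxel voxelization** of contoured structures: per-slice even-odd
   rasterization on a 2^level in-plane subgrid, refined until the volume
   converges, producing fractional-occupancy masks.
3. **DVH and dose statistics** of the recurrence region against each plan
   separately (base and sequential boost): D_min, D_max, volume-weighted
   D_median, the cumulative DVH, and V_thresh — the volume receiving at
   least a threshold dose, by default 80% of the plan's prescription
   (the 80%-isodose cut-off used for recurrence description).
4. **Location classification**: coverage of the recurrence by the boost
   volume and its distance-transform expansions (boost + 1 / 1.5 / 2 cm),
   outfield volume beyond the largest shell, and the maximal extension
   beyond the boost surface (3D and worst-axial-slice variants).
5. **Phantom fixtures**: fully synthetic DICOM cases (CT series, RTSTRUCT,
   RTDOSE) with analytically known volumes, dose statistics and
   ground-truth misalignments, so everything above is testable without any
   clinical data.

Clinical DICOM inputs are read with `pydicom`; the registration backend is
ITK via `SimpleITK`; distance transforms come from `scipy.ndimage`.
See `docs/methods.md` for conventions, numerical choices and limitations.

## Worked example

Generate a synthetic case (planning CT, follow-up CT rotated/shifted by a
known rigid motion, structures, base and boost dose grids) and analyze it:

```bash
rtrecur make-phantom case --seed 5
rtrecur analyze case/case.yaml --out out
```

which prints the per-case report (abridged):

```
patient_id: phantom-5
fx_base: 25
fx_boost: 5
recurrence_vol_ml: 7.34
base_min_gy: 44.5
base_max_gy: 44.5
base_median_gy: 44.5
base_pct_in_isodose: 100.0
boost_median_gy: 9.0
boost_pct_in_isodose: 100.0
in_boost: True
coverage_boost: 100.0
outfield_volume_ml: 0.0
max_extension_cm_3d: 0.0
voxelization_level: 2
transform_source: automatic
```

Reading: the recurrence measures 7.34 ml (the phantom's recurrence is a
12 mm sphere, 7.24 ml in closed form; the ~1% excess is voxelization plus
registration transport error). It received the full base prescription
(44.5 Gy everywhere, so median = min = max) and the full sequential boost
contribution (9 Gy); 100% of its volume lies inside both plans'
80%-isodose volumes and inside the boost volume itself with zero extension
beyond the boost surface — an infield recurrence. `voxelization_level: 2`
means the volume converged at a 4×4 in-plane subgrid per voxel, and the
reported transform is the recovered registration (near identity here, as
this phantom's ground-truth motion is identity).

The same machinery is available as a library:

```python
from rtrecur import (PhantomSpec, make_phantom, preinitialize,
                     register_rigid, voxelize, sample_dose, dose_stats)

phantom = make_phantom(PhantomSpec(seed=5))
init = preinitialize(phantom.planning_ct, phantom.followup_ct)
result = register_rigid(phantom.planning_ct, phantom.followup_ct, init=init)
mask = voxelize(phantom.structures["Recurrence"], phantom.planning_ct)
stats = dose_stats(sample_dose(phantom.doses["base"], mask), 0.8 * 44.5)
```

Other CLI commands: `rtrecur register <config>` (registration only, writes
the transform as key=value text), `rtrecur dvh <config> --structure PTV
--plan base` (cumulative DVH as CSV).

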