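# File formats

All on-disk formats are plain text (CSV, YAML, JSON) or HDF5; units are
bench units with explicit suffixes (`_cm`, `_deg`, `_ms`, `_mg`).
Loaders validate headers strictly.

## Body description (YAML)

Written by `flysim.body.save_yaml` / `flysim body build`:

```yaml
root: thorax
segments:
  - name: thorax
    parent: null            # exactly one root
    joint_axes: [[0,0,1], ...]      # unit vectors, body frame, 0-3 rows
    joint_limits_deg: [[-100, 100], ...]
    rest_pos_cm: [x, y, z]  # relative to parent frame
    rest_quat: [w, x, y, z]
    mass_mg: 0.34
    geom: {type: ellipsoid, size_cm: [a, b, c]}
tendon_couplings: [[j0, j1, ...], ...]   # disjoint joint-index groups
sites: [{name: ..., segment: ..., offset_cm: [x, y, z]}]
frozen_joints: [j, ...]
```

Round-trips are lossless to 1e−9.

## Wing-beat pattern (CSV)

One period, monotone phase in [0, 1):

```
phase,yaw_L_deg,roll_L_deg,pitch_L_deg,yaw_R_deg,roll_R_deg,pitch_R_deg
```

Mirror convention: `yaw_R = -yaw_L`, `roll_R = -roll_L`,
`pitch_R = +pitch_L`. `WingBeatPattern.from_csv` accepts a
`channel_map` to rename/remap differently-convented files.

## Flight trajectory (CSV)

```
t_ms,x_cm,y_cm,z_cm,qw,qx,qy,qz
```

Quaternions are (w, x, y, z), unit norm.

## Force traces (CSV)

Written by `flysim flight hover` (`force_traces.csv`): one row per
control step per wing per fluid component,

```
t_ms,wing,component,fx,fy,fz,tx,ty,tz
```

with forces in N and torques in N·m (world frame); `component` is one of
`viscous_resistance`, `quadratic_drag`, `magnus`, `kutta`, `added_mass`.

## Arena walking track (CSV)

150 fps, 13 keypoints (order: 3 head, 3 thorax, abdomen tip, leg tips
L1, R1, L2, R2, L3, R3), plus neighbour-fly positions:

```
t_ms,kp01_x_cm,kp01_y_cm,...,kp13_x_cm,kp13_y_cm,neighbor1_x_cm,neighbor1_y_cm,...
```

A column-mapping configuration can reorder externally tracked keypoints
on load.

## Lifted 3D snippet (HDF5)

Written by `Lifted3DSnippet.save`:

* `/keypoints3d` — float (n, 13, 3), cm, 2 ms steps
* `/labels` — uint8 (n, 6), 1 = swing, leg order L1 R1 L2 R2 L3 R3
* `/meta` — attributes `dt` (s), `body_height` (cm), `body_pitch` (rad)

## Contact scenario (YAML) and results (CSV)

Scenario: `contacts` (position_cm, normal, mu, gap_cm), `load_N`
(3-vector), `adhesion` (control, max_force_N per contact). Results CSV:

```
contact_id,fperp_N,fpar_N,margin_N,slipping
```

## Terrain heightfield (CSV)

Grid export of bump/trench terrains: first column `y_cm`, remaining
column headers are x positions in cm, cell values are heights in cm.
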