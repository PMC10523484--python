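# File formats

All tables are plain text, whitespace- or tab-separated, with `#`-prefixed
comment lines. Internal units are fixed: time in ns, distances in Å,
energies in kcal/mol, temperatures in K. Numeric output is written to 10
significant digits, so a write→read round trip is the identity to better
than 1e-9 relative.

## Work traces

### `tsv` dialect

One header line, one row per stored sample:

```
# optional comments
traj_id  time_ns  restraint_center_A  coordinate_A  work_kcal_per_mol
run0     0        10                  10.01          0
run0     0.0005   10.008              10.015         0.0123
...
```

Multiple trajectories live in one file, distinguished by `traj_id`; rows of
a trajectory must appear contiguously and in time order. Invariants
enforced on read: strictly increasing time, monotone non-decreasing
restraint center, accumulated work starting at 0 (±1e-9). Violations raise
a parse error naming the offending line.

### `smd_log` dialect

An engine-style log. Parsing is whitelist-based: only two record types are
interpreted, every other line is ignored as engine noise.

```
#SMDSTART <traj_id>          opens a trajectory block
SMD <time_fs> <center_A> <coordinate_A> <work_kcal_per_mol>
```

Time is given in fs and converted to ns on read (a 500 fs output cadence
parses to Δt = 0.0005 ns).

## Alchemical ΔU samples

Sign convention (both directions, both dialects): **ΔU = U(λ_to) −
U(λ_from)**, evaluated in whichever ensemble sampled it. `direction f`
means the sample was drawn in the λ_from ensemble, `direction r` in the
λ_to ensemble. This removes the sign ambiguity of two-sided estimators:
the reverse samples are *not* negated.

### `tsv` dialect

```
lambda_from  lambda_to  direction  du_kcal_per_mol
0            0.03125    f          0.412
0            0.03125    r          0.385
...
```

### `fepout` dialect

```
#FEPWINDOW <lambda_from> <lambda_to> <f|r>    opens a window/direction block
FepEnergy: <step> <du_kcal_per_mol>
```

All other lines are ignored (whitelist parsing). Windows are matched
across directions by their (λ_from, λ_to) pair and returned sorted by
λ_from; λ values outside [0, 1] and windows without forward samples are
rejected.

## Distance series

Two numeric columns, optional header:

```
time_ns  distance_A
0        14.08
0.0005   14.13
```

Distances must be strictly positive.

## Result records

Analysis results (cycle results, mode lists, rate ratios) serialize to
JSON with sorted keys — identical records produce byte-identical files —
or to a two-column `key<TAB>value` TSV with dotted/indexed keys for nested
fields, numbers formatted to 10 significant digits.
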