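# oxescape

Analysis pipeline for tracking how a small ligand — molecular oxygen in a
flavin-dependent amine oxidase — leaves an enzyme's buried active site, and
for quantifying how its supply limits apparent enzyme kinetics.

Directed evolution of biocatalysts such as MAO-N (*Aspergillus niger*
monoamine oxidase) can silently alter how well the enzyme captures its
oxygen co-substrate.  Two complementary computational views of that
question live here:

1. **Escape-pathway analysis of MD trajectories.**  For each tracked O2
   the pipeline measures the distance from the ligand's centre of mass to
   the binding-site centre (e.g. the FAD isoalloxazine ring) frame by
   frame, and declares an *escape* at the first excursion that stays above
   a channel-length threshold (default 16.31 Å, the mean channel length)
   for at least a persistence time (default 2 ns).  Ligands that never
   qualify are censored: counted among the tracked molecules, excluded
   from the mean escape time.  Each escape is assigned to a named exit
   channel (a residue list, as produced by tunnel-finding tools) by
   ranking pre-escape residue-contact occupancy — the number of analysis
   frames with a ligand-to-heavy-atom minimum distance within 4 Å.
2. **Oxygen-dependent apparent kinetics.**  Initial rates over an amine
   dilution series at fixed dissolved O2 follow Michaelis–Menten form with
   apparent constants.  Under a ping-pong (substituted-enzyme) scheme

       v = Vmax·[S]·[O2] / (KM_S·[O2] + KM_O·[S] + [S]·[O2])

   so Vmax_app = Vmax·[O2]/(KM_O+[O2]) and KM_app = KM_S·[O2]/(KM_O+[O2]):
   both rise with oxygenation while kcat,app/KM_app stays invariant — the
   diagnostic separating ping-pong from mechanisms whose apparent
   efficiency tracks [O2].  Henry's law (kH = 1.2×10⁻⁵ mol m⁻³ Pa⁻¹)
   converts sparging conditions to mM, and Beer–Lambert handles the
   coupled-assay absorbance slopes (ε = 29 400 L mol⁻¹ cm⁻¹ at 510 nm).

Because raw MD trajectories of this kind are rarely deposited, the package
includes a seeded Brownian-dynamics generator: a point ligand diffusing in
a spherical cavity with cylindrical exit tunnels (reflecting walls,
absorbing tunnel ends) whose ground truth — escape time and exit tunnel —
is known exactly, down to the closed-form mean first-passage time
L²/(2D) in the single-tunnel limit.  Every analysis stage is validated
against that ground truth.

## Worked example

```sh
oxescape generate --out scratch/demo --seed 7 --time-scale 0.25
oxescape analyze --bundle scratch/demo --out scratch/demo_out
```

which prints (seed 7, 25% of the full replicate durations):

```
wrote bundle to scratch/demo (2 variants, 2250 analysis frames per variant)
narrow: 3/12 escaped, mean escape time 21.40 ns
wide: 11/12 escaped, mean escape time 11.45 ns
```

Per variant, 6 replicates × 2 tracked oxygens are simulated; at full scale
the design pools 9000 analysis frames per variant at 0.2 ns spacing.  The
narrow variant (tunnel radius 1.5 Å) escapes less often and later than the
wide one (3.0 Å) — the uncensored contrast is sharper (≈65 ns vs ≈29 ns
mean first passage, see `scripts/acceptance.py`).  Each `scratch/demo_out/
<variant>/` holds the events table with exit-channel assignments, the
escape summary JSON, the cumulative escape curve, the pooled distance
histogram and the residue-contact ranking.

The kinetics side:

```sh
python analysis/04_apparent_kinetics.py
```

```
dissolved O2 (mM): {'unsparged': 0.1, 'air': 0.255, 'oxygen': 1.216}
 O2 (mM)  Vmax_app   KM_app     eff proj Vmax  proj KM
   0.100    0.2127    0.948  0.2244    0.2326    1.163
   0.255    0.4456    2.662  0.1674    0.4359    2.179
   1.216    0.8382    4.847  0.1729    0.7865    3.933
```

Both apparent constants rise with dissolved oxygen (columns `proj *` are
the exact algebraic projections the noisy fits chase), reproducing the
signature of an oxygen-limited oxidase assayed below its oxygen KM.

The numbered scripts under `analysis/` run the full study narrative:
generate the bundle, detect and summarise escapes, rank tunnel-lining
residues (including the engineered positions of the widened variant), and
fit the apparent kinetics.  Compact tables land in `results/`.

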