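# embryoquant

Quantification of fluorescence-reporter expression in 4D (3D + time)
recordings of developing *C. elegans* embryos.

Long-term recordings of embryogenesis face a dynamic-range problem: a
reporter may be undetectable at the 2-cell stage and saturating by
enclosure, and no single camera exposure covers both. `embryoquant`
implements the full workflow around that problem:

* **Adaptive acquisition** — a feedback controller sets each stack's
  exposure from the previous stack's robust count statistic (10th
  largest voxel), doubling below 25% of full scale and halving above
  75%, bounded to 15–200 ms.
* **Reconstruction** — per-stack background subtraction (filtered
  40–60 percentile average, min of inside/outside the embryo shell),
  division by exposure, and chained continuity factors at every
  exposure change, yielding one relative counts/ms series.
* **Time normalization** — four morphological anchors (first
  blastomeres, gastrulation, ventral enclosure, 2-fold tail) map wall
  clock onto a common 0–100 developmental axis, piecewise linearly.
* **Spatial profiles** — T (total), APT (20 anterior–posterior
  slices), XYZ (cube grid in the ABa/ABp/EMS/P2 founder frame),
  DVT/LRT (dorsal–ventral / left–right slices), and SC (per-cell, by
  Voronoi assignment of voxels to the nuclei of a superimposed
  reference 4D model). Every spatial profile conserves signal: its
  bins sum to T.
* **Comparison** — Pearson / Manders / Euclidean distances, PHYLIP
  export, UPGMA clustering, and the duplicate-recovery tree statistics
  r, d, D, q; plus correlation against staged bulk-expression tables
  with permutation significance.
* **Synthetic generator** — a seeded embryo simulator (lineage model,
  Gaussian PSF, linear camera with shot/read noise and saturation,
  background nuisances) providing ground truth for every stage.

See `docs/methods.md` for the model and parameter rationale.

## Worked example

`examples/01_simulate_and_reconstruct.py` simulates a brightening ABa
reporter and reconstructs it. The controller walks its whole exposure
ladder as the scene brightens:

```
exposure schedule chosen by the controller (ms):
[100. 200. 200. 200. 200. 200. 200. 100. 100. 100. 100. 100.  50.  50.
  50.  50.  50.  50.  50.  50.  50.  25.  25.  25.  25.  25.  25.  25.
  25.  25.  25.  25.  25.  15.  15.  15.  15.  15.  15.  15.]

reconstructed in-shell totals (counts/ms), first and last five:
[149.8 149.8 209.2 268.6 328. ] ... [10755.9 11052.1 11347.6 11643.7 11939.9]

dynamic-range benchmark: adaptive range 92682x, best fixed-exposure
range 5793x, gain 16.0-fold
```

`examples/02_expression_profiles.py` extracts profiles from an
anterior (ABa-lineage) reporter — the APT profile localizes all signal
in the anterior half:

```
AP distribution at t=50 (fraction of total per slice):
[0.012 0.184 0.149 0.127 0.026 0.14  0.175 0.131 0.047 0.008 0. ... 0.]
fraction of signal in the anterior half: 1.00
conservation holds: sum(APT bins) == T at 1e-6
```

`examples/03_single_cell.py` attributes 98% of an EMS-lineage
reporter's signal to EMS-derived cells, and
`examples/04_cluster_quality.py` clusters 10 twice-recorded genes into
a tree with d = 2.00, D = 7.16, q = 0.000 (every duplicate pair ends
up as siblings).

The same pipeline is scriptable from the shell:

```sh
embryoquant simulate --seed 5 --out rec/ --n-stacks 30
embryoquant reconstruct rec/ --out calibration.tsv
embryoquant profile rec/ --kind APT --out apt.tsv
embryoquant compare apt_a.tsv apt_b.tsv apt_c.tsv --out dist.phy
```

## Layout

```
src/embryoquant/   library (geometry, camera, acquisition, reconstruction,
                   timenorm, profiles, singlecell, synthetic, compare,
                   dynrange, io, cli)
tests/             pytest suite (unit, property-based, acceptance)
examples/          narrative scripts, one per capability
scripts/           acceptance benchmark driver
docs/methods.md    scientific methods note
```
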