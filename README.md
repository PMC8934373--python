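# chromarch

Quantitative analysis of 3D genome architecture and chromatin dynamics —
the measurement machinery used to characterize how nuclear lamina proteins
(lamin B1 in particular) organize the genome. It is aimed at researchers who
have binned Hi-C matrices, lamin ChIP log-ratio tracks, locus-tracking
movies or nucleus images and want the standard architecture statistics with
a fully testable, scriptable implementation.

Four analysis stages, plus matched synthetic-data generators with planted
ground truth for validating each one:

- **hic_metrics** — ICE matrix balancing, A/B compartments (PC1 of the O/E
  Pearson correlation, oriented by gene density), insulation-score TAD
  calling with the 200-kb size filter, TAD scores, compartment switching,
  trans-interaction and AB/(AA+BB) ratios (2-Mb exclusion).
- **lad_domains** — lamina-associated-domain calling on log2(ChIP/input)
  tracks (11-kb bins, gap penalty 5, maximal scoring segments), LAD
  count/length/coverage statistics, 4-way cLAD/ciLAD/fLAD/fiLAD
  classification across cell types, per-class signal comparison.
- **loci_dynamics** — spot detection (Fourier low-pass + 2D Gaussian fits),
  nearest-neighbour linking (5 px / 800 nm cap, 10-frame gap limit),
  time-averaged MSD with lags below N/10, and least-squares fits of the
  anomalous diffusion law MSD = D·t^α, per trajectory or per ensemble.
- **nuclear_geometry** — 5 equal-area radial shells, periphery/nucleoplasm
  locus classification at the 640-nm envelope threshold, chromosome
  territory relative volume / normalized radial position / overlap, with
  Fisher-exact condition comparisons.

The core model for locus motion is the anomalous diffusion law

    MSD(t) = D t^α ,

with the time-averaged MSD of an N-frame trajectory computed as

    MSD(nδt) = 1/(N−1−n) Σ_{j=1}^{N−1−n} [x(jδt+nδt)−x(jδt)]² + [y(jδt+nδt)−y(jδt)]² ,

lags restricted to n < N/10. α < 1 is subdiffusion (chromatin loci are
typically α ≈ 0.4–0.7); D is the generalized diffusion coefficient in
µm²/s^α. See `docs/methods.md` for every algorithm and default.

## Worked example

```python
import numpy as np
import chromarch as ca

# simulate a chromosome with planted TADs and call them back
bounds = [1_600_000 * k for k in range(1, 10)]
cfg = ca.HiCSimConfig(chrom_lengths={"chr1": 16_000_000}, bin_size=40_000,
                      c_tad=3.0, c_comp=1.0, tad_boundaries={"chr1": bounds},
                      depth=5e6, seed=1)
matrix, truth = ca.gen_contact_matrix(cfg)
profile = ca.insulation_profile(matrix)
tads = ca.call_tads(profile)
scores = ca.tad_score(matrix, tads)
print(f"called {len(tads)} TADs (planted 10 blocks)")
print(f"first TAD: {tads.intervals[0]}, score {scores[0]:.3f}")

# track simulated subdiffusive loci and fit MSD = D t^alpha
fbm = ca.FbmSimConfig(n_trajectories=50, n_frames=600, alpha=0.5, D=0.01,
                      seed=1)
ens, _ = ca.gen_fbm_trajectories(fbm)
fits = [ca.fit_power_law(ca.compute_msd(t)) for t in ens]
print(f"mean fitted alpha = {np.mean([f.alpha for f in fits]):.3f} "
      f"(true 0.5), mean D = {np.mean([f.D for f in fits]):.4f} (true 0.01)")
```

Output:

```
called 10 TADs (planted 10 blocks)
first TAD: ('chr1', 0, 1600000), score 0.085
mean fitted alpha = 0.511 (true 0.5), mean D = 0.0101 (true 0.01)
```

The 10 planted contact blocks are recovered exactly; each TAD holds ~8.5%
of its chromosome's cis contacts (10 equal blocks would give 10% minus the
inter-block decay contacts); the planted subdiffusion exponent and
coefficient are recovered to within a few percent.

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
chromarch run --seed 1 --out runs/demo          # full synthetic end-to-end
chromarch hic tads --matrix m.txt --out tads.bed
chromarch hic trans-ratio --matrix m.txt --out tr.tsv
chromarch lad call --track lamin.bedGraph --out lads.bed
chromarch dyn fit --trajectories t.csv --out fits.tsv
chromarch geom shells --image nucleus.tiff --out shells.tsv
```

File formats: sparse triplet text + chrom.sizes for matrices, bedGraph for
tracks, BED for domains, CSV (`traj_id,frame,x_um,y_um[,label]`, with
`#dt=`/`#pixel_nm=` headers) for trajectories, multi-page TIFF for images.
All coordinates are 0-based half-open.

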