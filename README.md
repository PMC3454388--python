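# nirsnet

Graph-theoretical analysis of resting-state fNIRS functional connectomes.

Functional near-infrared spectroscopy (fNIRS) measures cortical hemodynamics
optically: each source–detector channel records light attenuation at two
wavelengths (690/830 nm), from which concentration changes of oxy- and
deoxy-hemoglobin follow via the modified Beer-Lambert law. In the resting
state, the slow (< 0.1 Hz) covariation of these signals between channels
defines a functional brain network. `nirsnet` implements the full analysis
chain for such data, for researchers who want whole-head network topology
(small-worldness, hierarchy, modularity, hubs) and its reproducibility from
multichannel optical recordings:

1. **Preprocessing** — discard of the initial settling period (2 min),
   zero-phase 0.009–0.08 Hz band-pass of the optical densities, modified
   Beer-Lambert inversion (DPF 6, 3.2 cm separation), total-Hb = oxy + deoxy,
   and an automated robust-z artifact screen.
2. **Network construction** — Pearson correlation between all channel pairs,
   group averaging, and binarisation at each sparsity *S* on a 0.01-spaced
   grid by keeping the K = round(S·N(N−1)/2) strongest edges by |r|.
3. **Topology metrics** — clustering coefficient C<sub>p</sub>,
   characteristic path length L<sub>p</sub>, global/local efficiency,
   hierarchy coefficient β (from C(k) ∝ k<sup>−β</sup>), modularity Q, and
   nodal degree/efficiency/betweenness.
4. **Null models** — 1000 (configurable) degree-preserving Maslov–Sneppen
   rewirings per threshold; every metric is expressed as
   z = (x − μ<sub>rand</sub>)/σ<sub>rand</sub> with the two-tailed |z| > 1.96
   rule, giving the small-world ratios γ = C<sub>p</sub>/⟨C<sub>p,rand</sub>⟩
   and λ = L<sub>p</sub>/⟨L<sub>p,rand</sub>⟩ and significance ranges over
   sparsity.
5. **Hubs** — each nodal metric is collapsed to its area under the curve
   over sparsity; a node is a hub when its AUC is ≥ 1 SD above the network
   mean, reported per metric plus union and three-metric consensus.
6. **Reproducibility** — split-half analysis across subjects (7 + 8) and
   over time (two contiguous 4-min halves), spatial correlation of group
   matrices, across-node correlation of nodal profiles, and
   repeated-measures comparison of metric AUCs across the oxy/deoxy/total
   contrasts.

Because raw resting-state fNIRS cohorts are rarely shareable, the package
ships a **synthetic cohort generator** with known ground truth: 15 subjects ×
46 channels × 10 min at 25 Hz, with five planted modules (13/12/8/8/5
channels), one planted connector hub, a small-world blueprint topology,
anti-correlated deoxy-Hb, 1/f-like drift, cardiac (~1 Hz) and respiratory
(~0.3 Hz) nuisance, and optional motion spikes. Every stage of the pipeline
is validated against this ground truth and against brute-force oracles; see
`docs/methods.md` for the generative model and its limitations.

## Worked example

```python
import nirsnet as nn

model = nn.ConnectomeModel.from_synthetic(nn.CohortSpec())   # 15 x 46 x 10 min
res = model.fit(n_random=100, null_step=10, seed=0)
print(res.summary())
```

```
========================================================================
Resting-state fNIRS functional connectome
========================================================================
Subjects: 15    Channels: 46    Contrast: oxy
Sparsity grid: 0.01..0.99 step 0.01    Null replicates: 100
Config hash: 98a43757f9fa    Seed: 0
------------------------------------------------------------------------
At reference sparsity S = 0.10 (K = 104 edges):
  Cp = 0.2790   Lp = 2.6802   Eglob = 0.4367   Eloc = 0.3708
  beta = 0.7556   Q = 0.5285
  Modules at S = 0.10: 5 (Q = 0.5352, multistart)
  Small-world over S in [0.1, 0.4]: gamma = 1.390, lambda = 1.023 -> YES
  Cp significant vs null over 0.11 <= S <= 0.81 (mean z = 6.15)
  Q significant vs null over 0.11 <= S <= 0.61 (mean z = 6.83)
  Q significant vs null over 0.81 <= S <= 0.81 (mean z = 3.32)
------------------------------------------------------------------------
Hubs (mean + 1 SD on AUC over sparsity):
  degree       ch1, ch5, ch6, ch8, ch14, ch25, ch27, ch29, ch39, ch41
  efficiency   ch1, ch5, ch6, ch8, ch14, ch27, ch29, ch39, ch41
  betweenness  ch1, ch27, ch39
  consensus    ch1, ch27, ch39
========================================================================
```

Reading this: at 10% connection density the group network keeps the 104
strongest of 1035 possible edges. Its clustering is 1.4× that of
degree-matched random networks while its path length is only 2% longer
(γ = 1.39, λ = 1.02) — the small-world regime — and both C<sub>p</sub> and
the modular structure are significantly non-random over a broad sparsity
range. The maximum-modularity partition recovers five modules (Q = 0.54),
and the planted connector hub (ch1) appears in the hub consensus set by all
three centralities. `res.global_curves` holds every metric along the grid as
a DataFrame, `res.nulls` the z-scores and γ/λ curves,
`res.plot_metric_curves()` draws the profiles, and `res.save(outdir)` writes
the machine-readable bundle (TSV + JSON, each artifact stamped with the
config hash and channel order).

The same pipeline runs from the shell:

```bash
nirsnet simulate --n-subjects 15 --seed 0 --out cohort/
nirsnet run-all --seed 0 --n-random 100 --out results/
nirsnet repro --mode time --seed 0
```

Real recordings enter either through
`ConnectomeModel.from_recordings([...])` (two-wavelength optical densities)
or directly as `HemoglobinTimeSeries` if hemoglobin conversion already
happened upstream.

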