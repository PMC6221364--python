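# hbdyn

Quantitative analysis of early *hunchback* transcription downstream of the
Bicoid morphogen gradient in the young fruit-fly embryo.

In nuclear cycles 11–13 the embryo converts a shallow exponential activator
gradient — concentrations differing by only ~10% across one internuclear
distance — into a steep, stably positioned transcription boundary (Hill
coefficient H ≈ 7) within ~3 minutes of each interphase.  `hbdyn`
implements the full analysis chain used to quantify and model this
behaviour from MS2-MCP live-imaging data:

* **synthetic_embryo** — embryo-scale synthetic datasets: exponential
  gradient (decay length 20% EL), nuclei with mitotic-wave birth times,
  per-nucleus intensity traces with ground truth, rendered 3D image stacks;
* **spot_detection** — 3D spot detection (2× background threshold, ≥10
  connected voxels, summed raw-voxel intensity) and sibling-separation
  birth times;
* **trace_analysis** — per-trace features t_init / t_active / t_end
  (partitioning the interphase), ΣI and μI;
* **pattern_stats** — P_SPOT(t, x), P_ON(x), embryo alignment at
  P_ON = 0.5, sigmoid/Hill boundary fits, formation times,
  Kolmogorov–Smirnov zone partition;
* **promoter_model** — the stochastic N-binding-site promoter with
  diffusion-capped, concentration-dependent binding, occupancy-dependent
  unbinding (cooperativity), all-or-nothing activation, Poisson RNAP
  initiation, and MS2 loop-count signal synthesis (master equation,
  Gillespie simulation, and a deterministic spot-probability computation);
* **model_fitting** — boundary calibration (steady spot probability 1/2),
  steepness-maximizing kinetics fits under the 180 s formation-time
  constraint, model selection across N (LRT/BIC), Berg–Purcell sensing
  limits and readout-noise curves;
* **motif_scan** — Zelda/TAGteam motif scanning of the reconstructed
  24×MS2 cassette and construction of a ΔZelda variant.

The model at the core: a promoter with N identical Bicoid sites, per-free-
site binding rate k_b(x) = (1/t_bind)·c(x)/c_boundary capped by diffusion
(t_bind = 4 s), unbinding constants independent of position but dependent
on occupancy, transcription only from the fully bound state.  The measured
pattern P_SPOT(t, x) — the probability of a visible spot — is reproduced
either by simulating trajectories and thresholding the synthesized MS2
intensity, or exactly-in-expectation from an initiation-counting extension
of the master equation.

## Worked example

```python
import numpy as np
import hbdyn as h

# a six-site promoter without cooperativity, boundary occupancy 1/2
indep = h.calibrate_boundary(h.PromoterKinetics.uniform(6, 1.0),
                             observable="occupancy")
print(f"independent-sites steepness H = {h.hill_of_model(indep, 'occupancy'):.3f}")
print(f"closed form 2N(1-2^(-1/N))    = {h.hill_independent_sites(6):.3f}")

# how long must one site integrate to read the gradient to 10%?
t = h.berg_purcell_time(t_bind=4.0, relative_accuracy=0.1, occupancy=0.5)
print(f"Berg-Purcell integration time = {t/60:.1f} min")

# Zelda sites hiding in the classic MS2 cassette
hits = h.scan_motifs(h.build_cassette())
print(f"putative Zelda sites in 24xMS2 = {len(hits)} {h.motif_counts(hits)}")

# fit the six-site cooperative model under the pattern constraints
fm = h.fit_kinetics(6, seed=0)
print(f"N=6 fitted steepness H = {fm.achieved_hill:.2f} "
      f"(formation {fm.formation_dt:.0f} s)")
```

Output:

```
independent-sites steepness H = 1.309
closed form 2N(1-2^(-1/N))    = 1.309
Berg-Purcell integration time = 26.7 min
putative Zelda sites in 24xMS2 = 36 {'CAGGTCG': 12, 'TAGGTAC': 12, 'TAGGCAA': 12}
N=6 fitted steepness H = 6.10 (formation 180 s)
```

Reading: without cooperativity six sites can only produce a very shallow
pattern (H ≈ 1.31, the Berg–Purcell regime), and a single site would need
~27 minutes — several interphases — to sense the gradient to 10%.  With
occupancy-dependent cooperativity, binding still capped by diffusion and
the boundary pinned at spot probability 1/2, six sites reach H ≈ 6.1
within the 180 s the embryo demonstrably uses; matching the observed H ≈ 7
requires more sites (see `min_sites_for_steepness`).

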