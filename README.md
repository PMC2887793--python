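# netsync

Simulation of noisy Kuramoto phase oscillators on complex networks and
reconstruction of the physical wiring from the functional coherence it
induces.

Biological networks — neuronal circuits, gene-regulatory and signalling
networks — are observed mostly through their *dynamics*: recordings of
activity at the nodes, not the wiring between them. `netsync` studies the
forward and the inverse problem on a controlled model system. Oscillators
on the nodes of a known substrate graph evolve as

    dθ_i/dt = ω_i + K Σ_j A_ij sin(θ_j − θ_i) + ξ_i(t)

with intrinsic frequencies `ω_i ~ U[−0.1, 0.1]`, Gaussian white noise of
intensity `D = 0.01`, and coupling `K` along the edges `A_ij` of the
substrate (Barabási–Albert scale-free, random regular, or a power-law
family with exponential cutoff `P(k) ∝ k^−γ e^−k/κ` interpolating between
them at fixed mean degree 4). From sampled phases the package computes:

* the **global order parameter** `R = ⟨|N⁻¹ Σ_j e^{iθ_j}|⟩_t` and its
  finite-size-scaling collapse `R = N^{−β/ν} F((K−K_c)N^{1/ν})`, which
  locates the synchronization transition `K_c` and the exponents β, ν;
* the **pairwise phase coherence** `C_ij = |⟨e^{i(θ_i−θ_j)}⟩_t|` for every
  node pair — the weighted network of synchronization (WNS) — plus local
  order parameters, effective couplings `K·k_i·r_i`, maximum-coherence
  spanning trees, and the rank-similarity (CLRP) of two WNSs;
* the **reconstruction** of the substrate from a configuration-averaged
  WNS by thresholding at the antimode of the bimodal weight distribution,
  scored by ROC/AUC.

The headline physics: just below the transition (`K ≈ 0.01–0.02` here),
only physically connected pairs cohere, so the coherence pattern mirrors
the wiring and reconstruction is near-optimal; past the onset,
disconnected hubs begin to lock and inference degrades — most strongly
for heterogeneous (scale-free) substrates.

## Worked example

```python
import numpy as np
from netsync import (SimulationConfig, draw_initial_configuration,
                     generate_ba, integrate, pairwise_phase_coherence,
                     average_wns, mean_ppc_split, bimodal_threshold,
                     roc_curve)

net = generate_ba(512, 2, rng_seed=11)          # scale-free substrate, <k>=4
mats = []
for c in range(5):                               # 5 initial configurations
    init = draw_initial_configuration(512, rng_seed=100 + c)
    cfg = SimulationConfig(coupling=0.01, t_transient=500.0,
                           t_measure=2000.0, sample_stride=20,
                           rng_seed=900 + c)
    rec = integrate(net, cfg, init)
    mats.append(pairwise_phase_coherence(rec))

wns = average_wns(mats)
conn, disc = mean_ppc_split(wns, net)
est = bimodal_threshold(wns)
auc = roc_curve(wns, net).auc
print(f"connected-pair C_ij   {conn:.3f}")
print(f"disconnected-pair C_ij {disc:.3f}")
print(f"weight antimode        {est.threshold:.3f} (bimodal={est.bimodal})")
print(f"reconstruction AUC     {auc:.3f}")
```

Output (~40 s on one CPU):

```
connected-pair C_ij   0.207
disconnected-pair C_ij 0.087
weight antimode        0.265 (bimodal=True)
reconstruction AUC     0.971
```

Connected pairs are ~2.4× more coherent than the incoherent floor of
disconnected pairs, and ranking pairs by their averaged coherence
recovers the wiring with AUC ≈ 0.97 — the weak-coupling regime where
functional connectivity mirrors structure. The disconnected-pair level is
the finite-window coherence floor (≈ `√(πτ_D/2T)`, with τ_D = 1/2D), not
genuine correlation; see `docs/methods.md`.

A command-line umbrella covers the same pipeline for shell use:

```
netsync generate-network --model ba --n 512 --m 2 --seed 1 --out net.tsv
netsync simulate --network net.tsv -K 0.01 --seed 2 --out rec.tsv
netsync ppc --record rec.tsv --out wns.tsv
netsync reconstruct --wns wns.tsv --auto-threshold --truth net.tsv --out inferred.tsv
netsync fss --sizes 64,128,256 --replicates 5 --seed 3 --out curves.tsv
```

## Acceptance script

`scripts/acceptance.py` recomputes the study's headline quantities from
scratch — mean connected-pair coherence at K=0.01 and K=0.02, the critical
coupling by finite-size scaling, the onset coupling of the regular
substrate, and the reconstruction threshold from the bimodal weight
distribution — by running the full pipeline at desk scale:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It takes ~15 minutes on one CPU and writes one JSON object mapping each
quantity to its freshly computed value.

## Layout

| path | contents |
| --- | --- |
| `src/netsync/networks.py` | substrate generators (BA, regular, cutoff family), κ↔σ calibration |
| `src/netsync/dynamics.py` | stochastic Heun integrator (numba core), phase records |
| `src/netsync/coherence.py` | order parameters, PPC/WNS, skeleton trees, CLRP |
| `src/netsync/fss.py` | finite-size scaling: crossing search, exponents |
| `src/netsync/reconstruction.py` | thresholding, bimodal antimode, ROC/AUC |
| `src/netsync/experiments.py` | seeded ensemble drivers, tidy result tables |
| `src/netsync/io.py`, `cli.py` | plain-text formats and the `netsync` CLI |
| `docs/methods.md` | model, estimators, numerical choices, limitations |
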