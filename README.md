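# heatrewire

Simulation and analysis of **heat-diffusion adaptive rewiring** in
weighted undirected networks — a minimal model of structural plasticity
in brain-like networks.

At every step the network prunes the connection at a pivot node that
carries the least diffusion and creates a shortcut to the unconnected
node that would receive the most, where diffusion is measured by the
graph heat kernel

```
h(τ) = exp(−τ 𝓛),     𝓛 = D^{−1/2} (D − A) D^{−1/2}
```

after a *rewiring interval* τ of diffusion time. Despite its simplicity,
this single-parameter rule drives initially random networks to two very
different architectures:

* **small τ** → *modular* networks (dense clusters, high Newman
  modularity Q),
* **large τ** → *centralized* networks (a few heavy hubs, many sparse or
  isolated nodes, a large fraction of degree outliers),

with a sharp phase transition at an intermediate τ\* where the outcome
is maximally variable. Around that transition the rewiring process can
be characterized by three properties, quantified by the ordinary
least-squares fit `Q_8000 = α·Q_4000 + β` over networks rewired 4,000
steps at τ\* and then 4,000 more at a test interval τ_test:

* **specificity** (τ_test below τ\*): any starting structure is driven
  to the modular class — β ≫ α (near-horizontal fit);
* **robustness** (τ_test at or above τ\*): the established structure is
  dynamically maintained — α dominates (near-diagonal fit);
* **flexibility**: stochastic deviation from either rule, measured by a
  low squared Pearson correlation R² of the (Q_4000, Q_8000) pairs.
  Networks with skewed, lognormal weight distributions are markedly more
  flexible than normally weighted ones.

The package is aimed at researchers studying self-organization of
network architecture (structural plasticity, evolving network models,
network neuroscience) who want a fast, reproducible reimplementation of
the full simulation + analysis battery.

## Worked example

```python
import heatrewire as hr

# a connected random network: 100 nodes, 912 edges (mean degree 18.24),
# normal weights (mu=1, sigma=0.25) normalized to total weight 912
G0 = hr.generate_initial_network(100, hr.NORMAL_WEIGHTS, 1)

# 4,000 adaptive rewirings at a small rewiring interval
res = hr.run_rewiring(G0, hr.RewiringConfig(tau=3.0, p_random=0.2,
                                            steps=4000, seed=2))
part = hr.detect_communities(res.graph, seed=3)
print(f"Q = {part.q:.3f} ({hr.classify_topology(part.q)}), "
      f"outliers = {hr.outlier_proportion(res.graph):.3f}")
# Q = 0.713 (modular), outliers = 0.050

res = hr.run_rewiring(G0, hr.RewiringConfig(tau=5.0, p_random=0.2,
                                            steps=4000, seed=2))
part = hr.detect_communities(res.graph, seed=3)
print(f"Q = {part.q:.3f} ({hr.classify_topology(part.q)}), "
      f"outliers = {hr.outlier_proportion(res.graph):.3f}")
# Q = 0.144 (centralized), outliers = 0.400
```

The same network, rewired with the same rule, becomes modular at τ = 3
(Q ≈ 0.71, almost no degree outliers) and centralized at τ = 5
(Q ≈ 0.14, 40% of nodes with outlier degrees).

The command line mirrors the library:

```
heatrewire generate --n 100 --family normal --seed 1 --output net.tsv
heatrewire rewire --input net.tsv --tau 3 --steps 4000 --seed 2 --output out.tsv
heatrewire sweep --family normal --tau-min 3 --tau-max 5.5 --tau-step 0.25 \
    --reps 15 --outdir sweep/
heatrewire transition --sweep-csv sweep/sweep.csv
heatrewire two-stage --family normal --tau-test 3 --reps 60 --outdir ts/
```

Every command writes a `manifest.json` (parameters, seed, library
versions) from which the run can be reproduced bit-identically.

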