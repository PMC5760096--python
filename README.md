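# narxid

System identification of signaling-dependent gene expression from
unequally spaced, different-time-scale time series.

Cells encode stimulus identity in the temporal patterns of signaling
molecules (minutes) and decode them through gene expression (hours to a
day). Measuring both tiers on a common dense time grid is rarely feasible:
snapshot assays cost one experiment per time point, so fast species are
sampled densely early and slow species sparsely late, with different time
points per molecule. `narxid` identifies the quantitative input–output
systems connecting such tiers anyway, by treating unequally spaced series
as equally spaced series with missing time points and recovering the
missing values from the low-rank structure that linear dynamics impose.

## The model and the method

Each output molecule *p* follows a nonlinear ARX (NARX) model: every input
*u* passes through a static Hill nonlinearity

    f(u; n, K) = u^n / (u^n + K^n)

(EC50 `K`, Hill coefficient `n`: graded response at n ≈ 1, switch-like at
large n), and the transformed inputs drive a linear ARX recursion

    y_k = Σ_i a_i · y_{k−i} + Σ_q Σ_j b_j^q · f(u^q_{k−j}; n_q, K_q).

For series obeying this recursion, the stacked Hankel-like matrix
[Y U₁ … U_L] has rank m_y + L·c (width c), so missing time points are
recovered by iterative partial matrix shrinkage (IPMS): rank-capped SVD
truncation alternated with re-imposition of the Hankel structure and of the
observed entries, with the rank cap increased until the observations are
explained. Hill and ARX parameters are estimated by AIC-guided random
restarts around this recovery; candidate input sets are compared by
leave-one-stimulation-condition-out cross-validation (`RSS_LOO`, with the
one-standard-error parsimony rule); identified channels are summarized by
steady-state gain |Σb| / |1 − Σa| and time constant τ = 1/(2π f_cutoff)
from the transfer function G(z); and identified models compose into
cascaded predictive simulations with optional input ablation (the
in-silico analogue of a pathway inhibitor).

## Worked example

```python
import numpy as np
from narxid import (RunConfig, CandidateSpec, SamplingDesign,
                    gen_system, observe, to_grid, loo_select,
                    gain_phase_report)

rng = np.random.default_rng(7)
system = gen_system(rng, layers=1, inputs_per_output=1, dt=20.0, t_max=480.0)
# decoy candidate: an unconnected sustained molecule with its own kinetics
system.root_waveforms["u1"] = {
    "kind": "sustained", "tau": 60.0,
    "kinetics": {"condA": 1.2, "condB": 0.7, "condC": 1.6},
}

design = SamplingDesign.dense_sparse(["u0", "u1"], ["y1"], dt=20.0, t_max=480.0)
traces, truth = observe(system, design, rng, noise_sigma=0.01)
grid = to_grid(traces, dt=20.0)

cfg = RunConfig(dt=20.0, restarts=20, inner_combos=200, iv_cycles=2,
                tol=1e-6, max_iter=120, recovery_noise=0.01, seed=7)
spec = CandidateSpec(output="y1", candidates=("u0", "u1"),
                     conditions=("condA", "condB", "condC"))
sel = loo_select(grid, spec, cfg)
print("chosen inputs:", sel.chosen)
for subset, info in sel.per_subset.items():
    print(f"  {'+'.join(subset):7s} RSS_LOO = {info['rss_loo']:.4f}")
print(gain_phase_report([sel.final], convention="discrete", dt=20.0).round(4))
```

prints (about 90 s on one CPU):

```
chosen inputs: ('u0',)
  u0      RSS_LOO = 0.0085
  u1      RSS_LOO = 0.2301
  u0+u1   RSS_LOO = 0.0070
  input output    K       n    gain  time_constant_min
0    u0     y1  1.0  2.0987  2.1462           114.5376
```

The cross-validated selection identifies the transient input `u0` as the
upstream driver: the decoy alone fits ~27× worse, and the superset's small
advantage over `u0` alone is within one standard error of the minimum, so
the parsimony rule keeps the single true input. The report row gives the
identified channel's EC50 and Hill coefficient (true values 0.72 and 3.45
for this seed), its steady-state gain (true 1.66 — overestimated here by
~29%, the Hill/gain trade-off discussed in `docs/methods.md`), and the
time constant implied by the fitted ARX pole under the conventional
discrete-frequency reading.

There is also a CLI over the same functions:

```
narxid synth    --seed 1 --out-prefix study           # synthetic study CSV + truth
narxid recover  study_observations.csv --out wide.csv # signal recovery only
narxid identify --config cfg.yaml study_observations.csv --out-dir models/
narxid simulate models/model_y1.json --roots-csv roots.csv --ablate u0 --out sim.csv
narxid analyze  models/model_y1.json --out report.csv # gain / time-constant table
```

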