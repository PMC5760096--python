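"""Self-contained reproducibility benchmarks of the identification pipeline.

Each function builds its own synthetic ground truth, runs the relevant part
of the pipeline from scratch, and returns measured quantities.  They are
used both by the test suite and by ``scripts/acceptance.py``; every source
of randomness derives from the single seed passed in.

Problem sizes are scaled for a single CPU: identification benchmarks run on
a 0-480 min grid at 20-min steps (N = 25) with three stimulation
conditions, 20 random restarts and 200 (n, K) draws per refinement cycle,
instead of the full-scale 500-restart searches.
"""

from __future__ import annotations

import warnings

import numpy as np

from .analysis import simulate_cascade, simulate_narx
from .config import RunConfig
from .hankel import build_hankel, extract_arx, ipms_recover
from .model import IdentifiedModel
from .sysid import CandidateSpec, enumerate_subsets, final_fit, loo_select
from .synthetic import SamplingDesign, gen_system, observe
from .timeseries import locf_fill, to_grid

__all__ = [
    "STUDY_CANDIDATE_POOLS",
    "combination_count",
    "rank_law",
    "recovery_benchmark",
    "gain_recovery_benchmark",
    "selection_benchmark",
    "cascade_benchmark",
]

# candidate input pools of the motivating study: two signaling inputs for
# the three immediate-early genes, five candidates for the two late ones,
# and seven for the three long-time-scale transcripts
STUDY_CANDIDATE_POOLS = {
    "c-Jun": ["pERK", "pCREB"],
    "c-Fos": ["pERK", "pCREB"],
    "Egr1": ["pERK", "pCREB"],
    "FosB": ["pERK", "pCREB", "c-Jun", "c-Fos", "Egr1"],
    "JunB": ["pERK", "pCREB", "c-Jun", "c-Fos", "Egr1"],
    "Metrnl": ["pERK", "pCREB", "c-Jun", "c-Fos", "Egr1", "FosB", "JunB"],
    "Serpinb1a": ["pERK", "pCREB", "c-Jun", "c-Fos", "Egr1", "FosB", "JunB"],
    "Dclk1": ["pERK", "pCREB", "c-Jun", "c-Fos", "Egr1", "FosB", "JunB"],
}


def combination_count(pools: dict[str, list[str]] | None = None) -> int:
    """Total single-output input combinations enumerated by the selection."""
    pools = pools if pools is not None else STUDY_CANDIDATE_POOLS
    return sum(len(enumerate_subsets(p)) for p in pools.values())


def _simulate_arx_series(a, b, u, n):
    y = np.zeros(n)
    for k in range(1, n):
        acc = 0.0
        for i, ai in enumerate(a, start=1):
            if k - i >= 0:
                acc += ai * y[k - i]
        for j, bj in enumerate(b, start=1):
            if k - j >= 0:
                acc += bj * u[k - j]
        y[k] = acc
    return y


def rank_law(seed: int, m_y: int = 2, c: int = 5, n: int = 40) -> dict:
    """rank([Y U]) on noiseless fully observed ARX data vs the m_y + c law."""
    rng = np.random.default_rng([seed, 1])
    a = np.array([0.9, -0.2])[:m_y]
    b = np.array([0.4, 0.1])[:m_y]
    u = np.abs(rng.normal(0.5, 0.3, n))
    y = _simulate_arx_series(a, b, u, n)
    ones = np.ones(n, dtype=bool)
    rec = ipms_recover(
        [
            build_hankel({"s": y}, c, molecule="y", role="output"),
            build_hankel({"s": u}, c, molecule="u", role="transformed_input"),
        ],
        [{"s": ones}, {"s": ones}],
    )
    return {"rank": rec.rank_estimate, "expected": m_y + c, "width": c}


def recovery_benchmark(
    seed: int, n: int = 40, c: int = 8, hide_frac: float = 0.3
) -> dict:
    """Noiseless ARX series, ~30% entries hidden, recovered by IPMS.

    Returns the maximum absolute recovery error over all hidden entries and
    whether the observed entries came back bit-identical.
    """
    rng = np.random.default_rng([seed, 2])
    a = np.array([0.9, -0.2])
    b = np.array([0.4, 0.1])
    u = np.abs(rng.normal(0.5, 0.3, n))
    y = _simulate_arx_series(a, b, u, n)

    def hide(frac):
        mask = rng.random(n) >= frac
        mask[0] = True
        mask[-1] = True  # trailing inputs are otherwise structurally free
        return mask

    my, mu = hide(hide_frac), hide(hide_frac)
    rec = ipms_recover(
        [
            build_hankel({"s": locf_fill(y, my)}, c, molecule="y", role="output"),
            build_hankel(
                {"s": locf_fill(u, mu)}, c, molecule="u", role="transformed_input"
            ),
        ],
        [{"s": my}, {"s": mu}],
        tol=1e-9,
        max_iter=8000,
    )
    err = max(
        float(np.max(np.abs(rec.recovered_series[("y", "s")] - y))),
        float(np.max(np.abs(rec.recovered_series[("u", "s")] - u))),
    )
    preserved = bool(
        np.array_equal(rec.recovered_series[("y", "s")][my], y[my])
        and np.array_equal(rec.recovered_series[("u", "s")][mu], u[mu])
    )
    arx = extract_arx(rec, m_max=3)
    return {
        "max_abs_error": err,
        "observed_preserved": preserved,
        "rank": rec.rank_estimate,
        "m_y": arx.m_y,
    }


_BENCH_DT = 20.0
_BENCH_TMAX = 480.0
_BENCH_CONDITIONS = ("condA", "condB", "condC")


def _gain_cfg(seed: int, restarts: int, iv_cycles: int) -> RunConfig:
    return RunConfig(
        dt=_BENCH_DT,
        restarts=restarts,
        inner_combos=200,
        iv_cycles=iv_cycles,
        tol=1e-6,
        max_iter=120,
        recovery_noise=0.01,
        seed=seed,
    )


def gain_recovery_benchmark(
    seed: int,
    n_systems: int = 30,
    noise_sigma: float = 0.01,
    restarts: int = 20,
    iv_cycles: int = 2,
) -> dict:
    """Identify seeded synthetic single-input NARX systems end to end.

    Each system draws its Hill nonlinearity (n in [1.5, 8], K in [0.2, 0.8])
    and a stable first-order ARX stage; observations follow the scaled
    two-time-scale design with sigma = 0.01 noise.  Returns the per-system
    relative errors of the identified steady-state gain and their median;
    30 systems keep that median estimate stable, since the per-system error
    distribution is long-tailed (switch-like systems whose saturation the
    data never reach leave the gain under-determined).
    """
    errors = []
    for i in range(n_systems):
        rng = np.random.default_rng([seed, 3, i])
        sys_ = gen_system(
            rng, layers=1, inputs_per_output=1, dt=_BENCH_DT, t_max=_BENCH_TMAX
        )
        design = SamplingDesign.dense_sparse(
            ["u0"], ["y1"], dt=_BENCH_DT, t_max=_BENCH_TMAX
        )
        traces, _ = observe(sys_, design, rng, noise_sigma=noise_sigma)
        grid = to_grid(traces, dt=_BENCH_DT)
        cfg = _gain_cfg(int(rng.integers(2**31)), restarts, iv_cycles)
        spec = CandidateSpec(
            output="y1", candidates=("u0",), conditions=_BENCH_CONDITIONS
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = final_fit(grid, spec, ("u0",), cfg)
        g_est = abs(float(model.arx.b["u0"].sum())) / abs(
            1.0 - float(model.arx.a.sum())
        )
        g_true = sys_.true_gain("y1", "u0")
        errors.append(abs(g_est - g_true) / g_true)
    return {
        "relative_errors": errors,
        "median_relative_error": float(np.median(errors)),
    }


def selection_benchmark(
    seed: int,
    replicates: int = 20,
    noise_sigma: float = 0.01,
    restarts: int = 20,
    inner_combos: int = 50,
    iv_cycles: int = 2,
) -> dict:
    """Two-candidate input selection where only the first input is real.

    Each replicate generates a system driven by a transient input plus an
    unconnected sustained decoy, then runs the full leave-one-condition-out
    subset selection.  Returns the fraction of replicates choosing exactly
    the true single-input subset.
    """
    hits = 0
    chosen_sets = []
    for i in range(replicates):
        rng = np.random.default_rng([seed, 4, i])
        sys_ = gen_system(
            rng, layers=1, inputs_per_output=1, dt=_BENCH_DT, t_max=_BENCH_TMAX
        )
        # the decoy is an unconnected molecule with its own per-condition
        # kinetics, so it carries no information about the output's
        # condition-to-condition changes
        sys_.root_waveforms["u1"] = {
            "kind": "sustained",
            "tau": float(rng.uniform(30.0, 90.0)),
            "kinetics": {
                c: float(rng.uniform(0.6, 1.8)) for c in _BENCH_CONDITIONS
            },
        }
        design = SamplingDesign.dense_sparse(
            ["u0", "u1"], ["y1"], dt=_BENCH_DT, t_max=_BENCH_TMAX
        )
        traces, _ = observe(sys_, design, rng, noise_sigma=noise_sigma)
        grid = to_grid(traces, dt=_BENCH_DT)
        cfg = RunConfig(
            dt=_BENCH_DT,
            restarts=restarts,
            inner_combos=inner_combos,
            iv_cycles=iv_cycles,
            tol=1e-5,
            max_iter=60,
            hankel_width=6,
            recovery_noise=0.01,
            seed=int(rng.integers(2**31)),
        )
        spec = CandidateSpec(
            output="y1", candidates=("u0", "u1"), conditions=_BENCH_CONDITIONS
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = loo_select(grid, spec, cfg)
        chosen_sets.append(sel.chosen)
        hits += sel.chosen == ("u0",)
    return {
        "accuracy": hits / replicates,
        "chosen": chosen_sets,
        "replicates": replicates,
    }


def cascade_benchmark(seed: int) -> dict:
    """Integrated-cascade consistency and root-input ablation propagation.

    Builds a two-layer synthetic cascade, checks that the integrated
    simulation equals the manual composition of per-model simulations, and
    that zeroing one root input zeroes exactly the descendants reachable
    only through it.
    """
    rng = np.random.default_rng([seed, 5])
    # two independent two-layer chains plus one model reading both chains:
    # ablating the first chain's root must zero that chain (and only it)
    chain_a = gen_system(rng, layers=2, inputs_per_output=1,
                         dt=_BENCH_DT, t_max=_BENCH_TMAX)
    chain_b = gen_system(rng, layers=2, inputs_per_output=1,
                         dt=_BENCH_DT, t_max=_BENCH_TMAX)
    models = [_rename(m, "A") for m in chain_a.models] + [
        _rename(m, "B") for m in chain_b.models
    ]
    joint = gen_system(rng, layers=1, inputs_per_output=2,
                       dt=_BENCH_DT, t_max=_BENCH_TMAX).models[0]
    joint = IdentifiedModel(
        output="yJoint",
        inputs=["y2_A", "y2_B"],
        hill={"y2_A": joint.hill["u0"], "y2_B": joint.hill["u1"]},
        arx=_rename_arx(joint.arx, {"u0": "y2_A", "u1": "y2_B"}),
    )
    models.append(joint)
    roots = {
        "u0_A": chain_a.root_series("condA")["u0"],
        "u0_B": chain_b.root_series("condA")["u0"],
    }
    integrated = simulate_cascade(models, roots)

    # manual composition in dependency order
    series = dict(roots)
    by_output = {m.output: m for m in models}
    manual: dict[str, np.ndarray] = {}
    for m in models:  # listed upstream-first
        inputs = {name: series[name] for name in m.inputs}
        series[m.output] = manual[m.output] = simulate_narx(m, inputs)
    composition_max_diff = max(
        float(np.max(np.abs(integrated[k] - v))) for k, v in manual.items()
    )

    # ablate chain A's root: exactly its chain must go to zero
    ablated = simulate_cascade(models, roots, ablate=["u0_A"])
    reachable_only = _only_through(by_output, "u0_A")
    ablated_max = max(
        (float(np.max(np.abs(ablated[m]))) for m in reachable_only),
        default=0.0,
    )
    survivors = [m.output for m in models if m.output not in reachable_only]
    survivor_min_peak = min(
        (float(np.max(np.abs(ablated[m]))) for m in survivors), default=1.0
    )
    return {
        "composition_max_diff": composition_max_diff,
        "ablated_descendant_max": ablated_max,
        "n_ablated_descendants": len(reachable_only),
        "survivor_min_peak": survivor_min_peak,
    }


def _rename_arx(arx, mapping: dict[str, str]):
    from .hankel import ARXParams

    return ARXParams(
        a=arx.a.copy(),
        b={mapping.get(k, k): v.copy() for k, v in arx.b.items()},
        m_y=arx.m_y,
        m_u=arx.m_u,
        inputs=[mapping.get(k, k) for k in arx.inputs],
    )


def _rename(model: IdentifiedModel, tag: str) -> IdentifiedModel:
    mapping = {}
    for name in [model.output, *model.inputs]:
        mapping.setdefault(name, f"{name}_{tag}")
    return IdentifiedModel(
        output=mapping[model.output],
        inputs=[mapping[i] for i in model.inputs],
        hill={mapping[k]: v for k, v in model.hill.items()},
        arx=_rename_arx(model.arx, mapping),
    )


def _only_through(by_output: dict[str, IdentifiedModel], root: str) -> set[str]:
    """Outputs whose every signal path from the roots passes through ``root``."""

    def depends_only_on_root(name: str) -> bool:
        model = by_output.get(name)
        if model is None:  # a root input
            return name == root
        return all(depends_only_on_root(src) for src in model.inputs)

    return {out for out in by_output if depends_only_on_root(out)}
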