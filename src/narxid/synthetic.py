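"""Ground-truth NARX systems and study-like unequally spaced observations.

The generator emulates the structure of the motivating experiments: fast
transient signaling inputs (a pulse peaking within tens of minutes) and slow
sustained inputs, three stimulation conditions that rescale the same input
waveforms, downstream outputs produced by Hill + ARX dynamics, and a
sampling design that observes fast species densely early and slow species
sparsely over 0-720 min.  Every generated system is stable by construction
and serialized with its seed, so any observation set can be regenerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import simulate_cascade
from .hankel import ARXParams
from .hill import HillParams
from .model import IdentifiedModel
from .timeseries import GriddedSet, Trace

__all__ = [
    "SamplingDesign",
    "SyntheticSystem",
    "DEFAULT_PARAM_RANGES",
    "DEFAULT_CONDITION_SCALINGS",
    "gen_system",
    "observe",
]

# Stimulation conditions emulate distinct stimuli acting through different
# pathways: comparable response amplitudes but clearly different kinetics
# (pulse sharpness / rise time), as in the motivating experiments where each
# stimulus evokes its own temporal pattern rather than a scaled copy.
DEFAULT_CONDITION_SCALINGS = {"condA": 1.0, "condB": 0.85, "condC": 0.7}
DEFAULT_CONDITION_KINETICS = {"condA": 1.0, "condB": 1.8, "condC": 0.6}

# Sampling ranges for ground-truth parameters: graded-to-switch-like Hill
# nonlinearities, EC50 inside the dynamic range, first-order poles slow
# enough to be visible on a minutes grid, steady-state gains of order one.
DEFAULT_PARAM_RANGES = {
    "n": (1.5, 8.0),
    "K": (0.2, 0.8),
    "pole": (0.5, 0.9),
    "gain": (0.5, 2.0),
    "m_y": 1,
}


@dataclass(frozen=True)
class SamplingDesign:
    """Per-molecule observation times (minutes), all on a common grid."""

    times: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "times",
            {m: np.asarray(t, dtype=float) for m, t in self.times.items()},
        )

    @classmethod
    def study_like(
        cls, fast: list[str], slow: list[str], t_max: float = 720.0
    ) -> "SamplingDesign":
        """Dense-early/sparse-late design over 0-720 min.

        Fast species (signaling-like): every 5 min over 0-60, then sparse to
        t_max.  Slow species (expression-like): every 60 min to 240, then
        every 120 min.
        """
        fast_t = np.concatenate(
            [np.arange(0, 61, 5), np.array([90, 120, 180, 240, 360, 480, 600, 720])]
        )
        slow_t = np.concatenate(
            [np.arange(0, 241, 60), np.array([360, 480, 600, 720])]
        )
        times = {}
        for m in fast:
            times[m] = fast_t[fast_t <= t_max].copy()
        for m in slow:
            times[m] = slow_t[slow_t <= t_max].copy()
        return cls(times=times)

    @classmethod
    def dense_sparse(
        cls,
        fast: list[str],
        slow: list[str],
        dt: float,
        t_max: float,
        dense_until: float | None = None,
    ) -> "SamplingDesign":
        """Scaled two-time-scale design on an explicit grid.

        Fast species are observed at every grid step through the transient
        (up to ``dense_until``, default t_max/4) and every third step after;
        slow species at every third grid step throughout.  Endpoints are
        always observed.
        """
        if dense_until is None:
            dense_until = t_max / 4.0
        fast_t = np.unique(
            np.concatenate(
                [
                    np.arange(0.0, dense_until + 0.5 * dt, dt),
                    np.arange(0.0, t_max + 0.5 * dt, 3 * dt),
                    [t_max],
                ]
            )
        )
        slow_t = np.unique(
            np.concatenate([np.arange(0.0, t_max + 0.5 * dt, 3 * dt), [t_max]])
        )
        times = {m: fast_t.copy() for m in fast}
        times.update({m: slow_t.copy() for m in slow})
        return cls(times=times)

    @classmethod
    def uniform_random(
        cls,
        molecules: list[str],
        rng: np.random.Generator,
        dt: float,
        t_max: float,
        frac_observed: float,
    ) -> "SamplingDesign":
        """Observe a random fraction of grid points per molecule (0 always kept)."""
        grid = np.arange(0.0, t_max + 0.5 * dt, dt)
        times = {}
        for m in molecules:
            keep = rng.random(len(grid)) < frac_observed
            keep[0] = True
            keep[-1] = True
            times[m] = grid[keep]
        return cls(times=times)


@dataclass
class SyntheticSystem:
    """A ground-truth cascade of NARX models plus its root input waveforms."""

    models: list[IdentifiedModel]
    root_waveforms: dict[str, dict]  # name -> {"kind": ..., "tau": minutes}
    condition_scalings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_SCALINGS)
    )
    condition_kinetics: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_KINETICS)
    )
    dt: float = 5.0
    t_max: float = 720.0
    seed: int | None = None

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt)) + 1

    @property
    def grid_times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def molecules(self) -> list[str]:
        return list(self.root_waveforms) + [m.output for m in self.models]

    def root_series(self, condition: str) -> dict[str, np.ndarray]:
        scale = self.condition_scalings[condition]
        t = self.grid_times
        out = {}
        for name, wf in self.root_waveforms.items():
            # per-root kinetics override: each molecule may respond to the
            # conditions with its own rise/decay modulation, as different
            # pathway intermediates do under different stimuli
            mult = wf.get("kinetics", {}).get(
                condition, self.condition_kinetics.get(condition, 1.0)
            )
            tau = wf["tau"] * mult
            if wf["kind"] == "transient":
                u = (t / tau) * np.exp(1.0 - t / tau)  # peak 1 at t = tau
            elif wf["kind"] == "sustained":
                u = 1.0 - np.exp(-t / tau)
            else:
                raise ValueError(f"unknown waveform kind {wf['kind']!r}")
            out[name] = scale * u / max(u.max(), 1e-12)
        return out

    def simulate(self, condition: str) -> dict[str, np.ndarray]:
        """Noiseless full-grid series of every molecule under one condition."""
        return simulate_cascade(self.models, self.root_series(condition))

    def true_gain(self, output: str, channel: str) -> float:
        model = {m.output: m for m in self.models}[output]
        a_sum = float(model.arx.a.sum())
        return abs(float(model.arx.b[channel].sum())) / abs(1.0 - a_sum)


def _sample_arx(
    rng: np.random.Generator, inputs: list[str], ranges: dict
) -> ARXParams:
    m_y = int(ranges.get("m_y", 1))
    lo, hi = ranges["pole"]
    # real poles inside the unit circle -> stable by construction
    poles = rng.uniform(lo, hi, size=m_y)
    coeffs = np.poly(poles)  # z^m - a1 z^(m-1) - ... form
    a = -coeffs[1:]
    b = {}
    for name in inputs:
        gain = rng.uniform(*ranges["gain"])
        weights = rng.uniform(0.5, 1.0, size=m_y)
        weights *= gain * (1.0 - a.sum()) / weights.sum()
        b[name] = weights
    return ARXParams(a=a, b=b, m_y=m_y, m_u=m_y, inputs=list(inputs))


def gen_system(
    rng: np.random.Generator,
    layers: int = 1,
    inputs_per_output: int = 1,
    param_ranges: dict | None = None,
    outputs_per_layer: int = 1,
    dt: float = 5.0,
    t_max: float = 720.0,
    condition_scalings: dict[str, float] | None = None,
    max_retries: int = 100,
) -> SyntheticSystem:
    """Sample a stable, normalized ground-truth system.

    Layer 1 outputs read the root inputs; deeper layers read the previous
    layer's outputs (cycled when a layer has fewer sources than
    ``inputs_per_output`` requests).  Unstable draws are resampled, bounded
    by ``max_retries``.
    """
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    n_roots = inputs_per_output
    roots = {}
    for i in range(n_roots):
        kind = "transient" if i % 2 == 0 else "sustained"
        tau = rng.uniform(10.0, 30.0) if kind == "transient" else rng.uniform(30.0, 90.0)
        roots[f"u{i}"] = {"kind": kind, "tau": float(tau)}

    models: list[IdentifiedModel] = []
    prev_layer = list(roots)
    for layer in range(1, layers + 1):
        this_layer = []
        for oi in range(outputs_per_layer):
            name = f"y{layer}_{oi}" if outputs_per_layer > 1 else f"y{layer}"
            take = min(inputs_per_output, len(prev_layer))
            srcs = [prev_layer[(oi + k) % len(prev_layer)] for k in range(take)]
            for _ in range(max_retries):
                arx = _sample_arx(rng, srcs, ranges)
                if arx.is_stable():
                    break
            else:
                raise RuntimeError("could not sample a stable ARX system")
            hill = {
                s: HillParams(
                    n=float(rng.uniform(*ranges["n"])),
                    K=float(rng.uniform(*ranges["K"])),
                )
                for s in srcs
            }
            models.append(
                IdentifiedModel(
                    output=name, inputs=sorted(srcs), hill=hill, arx=arx
                )
            )
            this_layer.append(name)
        prev_layer = this_layer
    return SyntheticSystem(
        models=models,
        root_waveforms=roots,
        condition_scalings=dict(condition_scalings or DEFAULT_CONDITION_SCALINGS),
        dt=dt,
        t_max=t_max,
    )


def observe(
    system: SyntheticSystem,
    design: SamplingDesign,
    rng: np.random.Generator,
    noise_sigma: float = 0.01,
    conditions: list[str] | None = None,
) -> tuple[list[Trace], GriddedSet]:
    """Simulate, add observation noise, and subsample at the design times.

    Returns the unequally spaced traces (the pipeline's input) and the
    noiseless full-grid truth as a fully observed :class:`GriddedSet` (the
    test oracle).  Additive Gaussian noise applies to observed values only;
    values are floored at 0 so the Hill transform's domain is respected.
    """
    conditions = list(conditions or system.condition_scalings)
    truth = GriddedSet(dt=system.dt, n_steps=system.n_steps)
    traces = []
    for cond in conditions:
        sim = system.simulate(cond)
        for mol in system.molecules():
            truth.series[(mol, cond)] = sim[mol].copy()
            truth.mask[(mol, cond)] = np.ones(system.n_steps, dtype=bool)
        for mol, t_obs in design.times.items():
            idx_f = t_obs / system.dt
            idx = np.rint(idx_f).astype(int)
            if np.any(np.abs(idx_f - idx) > 1e-6) or np.any(idx >= system.n_steps):
                raise ValueError(
                    f"design times for {mol!r} are not on the system grid"
                )
            vals = sim[mol][idx]
            if noise_sigma > 0:
                vals = vals + rng.normal(0.0, noise_sigma, size=len(vals))
            vals = np.maximum(vals, 0.0)
            traces.append(
                Trace(molecule=mol, condition=cond, times=t_obs.copy(), values=vals)
            )
    return traces, truth
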