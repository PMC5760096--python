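"""NARX/ARX simulation and transfer-function characterization.

The linear ARX stage of an identified model is a discrete-time transfer
function per input channel,

    G(z) = (b1 z^-1 + ... + b_mu z^-mu) / (1 - a1 z^-1 - ... - a_my z^-my),

from which the steady-state gain (|G| at z = 1, the input->output amplitude
ratio at equilibrium), the frequency-response gain/phase curves, the cutoff
frequency and the time constant tau = 1/(2 pi f_cutoff) are computed.  All
identified channels behave as low-pass filters: gain falls off above the
cutoff.

Two frequency conventions are provided.  ``"substitution"`` (default) plugs
z = i*omega directly into G, the form used to produce the reported time
constants; ``"discrete"`` uses the conventional z = exp(i*omega*dt), under
which the low-frequency gain limit equals the steady-state gain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter

import numpy as np
import pandas as pd

from .hankel import ARXParams
from .hill import hill_transform
from .model import IdentifiedModel

__all__ = [
    "FreqCharacteristics",
    "simulate_arx",
    "simulate_narx",
    "simulate_cascade",
    "transfer_characteristics",
    "gain_phase_report",
]

_DIVERGENCE_LIMIT = 1e6


def simulate_arx(
    arx: ARXParams, transformed_inputs: dict[str, np.ndarray], n_steps: int | None = None
) -> np.ndarray:
    """Run the linear ARX recursion on already-transformed input series.

    The output is 0 before time 0 and inputs before index 0 contribute 0, so
    y[0] is always 0 and the recursion is fully determined by the inputs.
    """
    xs = [np.asarray(transformed_inputs[name], dtype=float) for name in arx.inputs]
    if n_steps is None:
        n_steps = len(xs[0]) if xs else 0
    y = np.zeros(n_steps)
    warned = False
    for k in range(1, n_steps):
        acc = 0.0
        for i in range(1, arx.m_y + 1):
            if k - i >= 0:
                acc += arx.a[i - 1] * y[k - i]
        for x, name in zip(xs, arx.inputs):
            bj = arx.b[name]
            for j in range(1, arx.m_u + 1):
                if k - j >= 0 and k - j < len(x):
                    acc += bj[j - 1] * x[k - j]
        y[k] = acc
        if not warned and abs(acc) > _DIVERGENCE_LIMIT:
            warnings.warn(
                "ARX simulation exceeds 1e6 on the normalized scale; "
                "system appears unstable",
                RuntimeWarning,
                stacklevel=2,
            )
            warned = True
    return y


def simulate_narx(
    model: IdentifiedModel,
    inputs: dict[str, np.ndarray],
    n_steps: int | None = None,
) -> np.ndarray:
    """Simulate one NARX model: Hill-transform each input, then run the ARX."""
    transformed = {
        name: hill_transform(np.asarray(inputs[name], dtype=float), model.hill[name])
        for name in model.inputs
    }
    return simulate_arx(model.arx, transformed, n_steps=n_steps)


def simulate_cascade(
    models: list[IdentifiedModel],
    root_inputs: dict[str, np.ndarray],
    overrides: dict[str, np.ndarray] | None = None,
    ablate: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Simulate a multi-layer cascade of identified models in dependency order.

    Each model's inputs must be root series, outputs of upstream models, or
    entries of ``overrides`` (measured/recovered series substituted for a
    simulated intermediate).  ``ablate`` zeroes the named root series before
    simulation — the in-silico analogue of a pharmacological inhibitor.
    Returns all series, roots included.
    """
    overrides = overrides or {}
    ablate = ablate or []
    by_output = {m.output: m for m in models}
    if len(by_output) != len(models):
        raise ValueError("duplicate output molecule in cascade")

    graph = {
        m.output: {i for i in m.inputs if i in by_output} for m in models
    }
    try:
        order = list(TopologicalSorter(graph).static_order())
    except CycleError as exc:
        raise ValueError(f"cascade dependency cycle: {exc.args}") from exc

    series: dict[str, np.ndarray] = {
        k: np.asarray(v, dtype=float).copy() for k, v in root_inputs.items()
    }
    for name in ablate:
        if name not in series:
            raise ValueError(f"cannot ablate unknown root input {name!r}")
        series[name] = np.zeros_like(series[name])

    for out in order:
        model = by_output[out]
        needed = {}
        for name in model.inputs:
            src = overrides.get(name)
            if src is None:
                src = series.get(name)
            if src is None:
                raise ValueError(
                    f"missing input series {name!r} for output {out!r}"
                )
            needed[name] = np.asarray(src, dtype=float)
        series[out] = simulate_narx(model, needed)
    return series


@dataclass
class FreqCharacteristics:
    """Steady-state gain, cutoff frequency and time constant of one channel.

    ``f_cutoff`` is in 1/min and ``tau`` in minutes; both are None when the
    gain never crosses the cutoff fraction inside the scanned band (a flat /
    pure-gain channel) or when the denominator is an integrator.
    """

    steady_state_gain: float
    f_cutoff: float | None
    tau: float | None
    omega: np.ndarray
    gain_curve: np.ndarray
    phase_curve: np.ndarray
    infinite_gain: bool = False
    band: tuple[float, float] = (0.0, 0.0)


def _gain_at(
    omega: np.ndarray, b: np.ndarray, a: np.ndarray, convention: str, dt: float
) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    if convention == "substitution":
        z = 1j * omega
    elif convention == "discrete":
        z = np.exp(1j * omega * dt)
    else:
        raise ValueError(f"unknown freq convention {convention!r}")
    num = np.zeros_like(z)
    for j, bj in enumerate(b, start=1):
        num += bj * z ** (-j)
    den = np.ones_like(z)
    for i, ai in enumerate(a, start=1):
        den -= ai * z ** (-i)
    return num / den


def transfer_characteristics(
    arx: ARXParams,
    channel: str,
    cutoff_fraction: float = 1.0 / math.sqrt(2.0),
    convention: str = "substitution",
    dt: float = 1.0,
    omega_band: tuple[float, float] = (1e-6, 1e2),
    n_omega: int = 2000,
) -> FreqCharacteristics:
    """Frequency characteristics of one input channel of an ARX model.

    The steady-state gain is |sum(b)| / |1 - sum(a)| (G at z = 1).  The
    cutoff is the smallest scanned angular frequency where the gain first
    drops to ``cutoff_fraction`` of the steady-state gain, refined by
    bisection to a relative 1e-6; tau = 1/(2 pi f_cutoff).
    """
    b = arx.b[channel]
    a = arx.a
    den0 = 1.0 - float(a.sum())
    omega = np.logspace(
        math.log10(omega_band[0]), math.log10(omega_band[1]), n_omega
    )
    if abs(den0) < 1e-12:
        g = _gain_at(omega, b, a, convention, dt)
        return FreqCharacteristics(
            steady_state_gain=math.inf,
            f_cutoff=None,
            tau=None,
            omega=omega,
            gain_curve=np.abs(g),
            phase_curve=np.angle(g),
            infinite_gain=True,
            band=omega_band,
        )
    g0 = abs(float(b.sum()) / den0)
    resp = _gain_at(omega, b, a, convention, dt)
    gain = np.abs(resp)
    phase = np.angle(resp)
    threshold = cutoff_fraction * g0

    below = gain <= threshold
    f_cutoff = None
    tau = None
    cross = np.flatnonzero(below[1:] & ~below[:-1])
    if below[0]:
        # below the threshold already at the band's low edge: no crossing
        # inside the band, so the time constant is not defined
        pass
    elif len(cross):
        lo, hi = omega[cross[0]], omega[cross[0] + 1]
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if abs(_gain_at(np.array([mid]), b, a, convention, dt)[0]) <= threshold:
                hi = mid
            else:
                lo = mid
            if hi / lo - 1.0 < 1e-6:
                break
        f_cutoff = hi / (2.0 * math.pi)
    if f_cutoff is not None:
        tau = 1.0 / (2.0 * math.pi * f_cutoff)
    return FreqCharacteristics(
        steady_state_gain=g0,
        f_cutoff=f_cutoff,
        tau=tau,
        omega=omega,
        gain_curve=gain,
        phase_curve=phase,
        band=omega_band,
    )


def gain_phase_report(
    models: list[IdentifiedModel],
    cutoff_fraction: float = 1.0 / math.sqrt(2.0),
    convention: str = "substitution",
    dt: float = 1.0,
) -> pd.DataFrame:
    """Per-channel summary table: input, output, K, n, gain, time constant.

    One row per (input, output) channel over all models; the layout of the
    headline dose-response / gain / time-constant table.
    """
    rows = []
    for m in models:
        for name in m.inputs:
            fc = transfer_characteristics(
                m.arx, name, cutoff_fraction=cutoff_fraction,
                convention=convention, dt=dt,
            )
            rows.append(
                {
                    "input": name,
                    "output": m.output,
                    "K": m.hill[name].K,
                    "n": m.hill[name].n,
                    "gain": fc.steady_state_gain,
                    "time_constant_min": fc.tau if fc.tau is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)
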