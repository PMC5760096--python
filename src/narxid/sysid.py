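"""The full NARX identification procedure.

For one output molecule and a candidate pool of input molecules the
procedure is:

* random-restart training (steps i-v): initialize Hill parameters, transform
  the observed inputs, recover all missing time points by low-rank Hankel
  completion, read off ARX coefficients, then refine the Hill parameters by
  scoring randomly drawn (n, K) combinations with AIC on the observed
  training points and re-recovering with the winner; keep the restart with
  the lowest training AIC;
* held-out scoring (steps vi-viii): with training data frozen, recover the
  held-out stimulation condition, simulate it with the trained parameters
  and accumulate the residual sum of squares at its observed output points
  (RSS_LOO);
* input selection (step ix): enumerate every non-empty subset of the
  candidate pool and choose the subset with minimal RSS_LOO (ties broken by
  smaller subset, then lexicographic input order);
* final fit (step x): re-run training on all conditions with the chosen
  inputs.

Training quality is judged by AIC (fit vs. parameter count) while input
selection is judged by cross-validated RSS: two different criteria, the
first cheap enough to run inside every restart.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .analysis import simulate_arx
from .config import RunConfig
from .hankel import (
    ARXParams,
    RecoveryResult,
    append_test_block,
    build_hankel,
    extract_arx,
    ipms_recover,
)
from .hill import HillParams, hill_transform, sample_params
from .model import IdentifiedModel
from .timeseries import GriddedSet, locf_fill

__all__ = [
    "CandidateSpec",
    "FitResult",
    "SelectionResult",
    "IdentificationError",
    "aic",
    "count_parameters",
    "enumerate_subsets",
    "fit_training",
    "loo_select",
    "final_fit",
]

_RSS_FLOOR = np.finfo(float).tiny


class IdentificationError(RuntimeError):
    """No restart of the identification search produced a usable model."""


@dataclass(frozen=True)
class CandidateSpec:
    """One output molecule, its ordered candidate-input pool and conditions."""

    output: str
    candidates: tuple[str, ...]
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("candidate pool must be non-empty")
        if self.output in self.candidates:
            raise ValueError("output cannot be its own candidate input")


@dataclass
class FitResult:
    """Best restart of the training search for one input subset."""

    hill: dict[str, HillParams]
    arx: ARXParams
    aic_training: float
    restart_index: int
    seed: int
    recovery: RecoveryResult | None = None

    def __post_init__(self) -> None:
        if set(self.hill) != set(self.arx.inputs):
            raise ValueError("hill keys must equal arx.inputs")


@dataclass
class SelectionResult:
    """Cross-validation scores per input subset and the final chosen model.

    ``argmin`` is the subset with the smallest RSS_LOO outright; ``chosen``
    is the selection used for the final fit — the smallest subset whose
    RSS_LOO lies within one standard error of the minimum (the standard
    cross-validation parsimony rule).  The two coincide whenever the
    minimizer is already minimal in size.
    """

    per_subset: dict[tuple[str, ...], dict] = field(default_factory=dict)
    chosen: tuple[str, ...] = ()
    argmin: tuple[str, ...] = ()
    final: IdentifiedModel | None = None


def aic(rss: float, n_params: int, n_data: int) -> float:
    """Gaussian-likelihood AIC for a least-squares fit.

    AIC = n_data * ln(rss / n_data) + 2 * n_params.  Only differences between
    models on the same data matter, so likelihood constants are dropped.
    A zero RSS is floored at machine-tiny to keep the logarithm finite.
    """
    if n_data <= 0:
        raise ValueError("n_data must be positive")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    rss = max(rss, _RSS_FLOOR)
    return n_data * math.log(rss / n_data) + 2 * n_params


def count_parameters(m_y: int, m_u: int, n_inputs: int) -> int:
    """ARX coefficients plus (n, K) per input channel."""
    return m_y + n_inputs * m_u + 2 * n_inputs


def enumerate_subsets(candidates: tuple[str, ...] | list[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets, smallest first then lexicographic.

    The enumeration order doubles as the selection tie-break: the first
    subset reaching the minimal RSS_LOO wins.
    """
    cands = sorted(candidates)
    out: list[tuple[str, ...]] = []
    for size in range(1, len(cands) + 1):
        out.extend(itertools.combinations(cands, size))
    return out


def _simulate_batch(a: np.ndarray, drive: np.ndarray) -> np.ndarray:
    """ARX recursion for a batch of precomputed exogenous drive series.

    ``a`` is (m_y,) shared across the batch or (n_batch, m_y) per row;
    ``drive[b, k]`` is sum_l sum_j b_lj x_l[k-j] for combo b; the output is 0
    before time 0.
    """
    n_batch, n = drive.shape
    y = np.zeros((n_batch, n))
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = np.broadcast_to(a, (n_batch, len(a)))
    m_y = a.shape[1]
    for k in range(1, n):
        acc = drive[:, k].copy()
        for i in range(1, min(m_y, k) + 1):
            acc += a[:, i - 1] * y[:, k - i]
        y[:, k] = acc
    return y


def _training_rss(
    arx: ARXParams,
    x_series: dict[str, dict[str, np.ndarray]],
    grid: GriddedSet,
    output: str,
    conditions: list[str],
) -> float:
    """RSS between simulation and the observed output points only.

    Recovered (imputed) output values are never scored; the residual is taken
    exactly where an experiment exists.
    """
    rss = 0.0
    for s in conditions:
        xs = {name: x_series[name][s] for name in arx.inputs}
        y_sim = simulate_arx(arx, xs)
        mask = grid.mask[(output, s)]
        y_obs = grid.series[(output, s)]
        rss += float(np.sum((y_sim[mask] - y_obs[mask]) ** 2))
    return rss


def _observed_count(grid: GriddedSet, output: str, conditions: list[str]) -> int:
    return int(sum(grid.mask[(output, s)].sum() for s in conditions))


def _transform_observed(
    grid: GriddedSet, name: str, conditions: list[str], params: HillParams
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Hill-transform the observed entries of one input and carry them forward."""
    series, masks = {}, {}
    for s in conditions:
        mask = grid.mask[(name, s)]
        vals = np.zeros(grid.n_steps)
        vals[mask] = hill_transform(grid.series[(name, s)][mask], params)
        series[s] = locf_fill(vals, mask)
        masks[s] = mask
    return series, masks


def _recover(
    grid: GriddedSet,
    output: str,
    inputs: list[str],
    conditions: list[str],
    hill: dict[str, HillParams],
    c: int,
    cfg: RunConfig,
    x_init: dict[str, dict[str, np.ndarray]] | None = None,
    y_init: dict[str, np.ndarray] | None = None,
) -> RecoveryResult:
    """One IPMS pass: output block plus one transformed-input block per input."""
    y_series, y_masks = {}, {}
    for s in conditions:
        mask = grid.mask[(output, s)]
        if y_init is not None:
            vals = y_init[s].copy()
            vals[mask] = grid.series[(output, s)][mask]
        else:
            vals = locf_fill(grid.series[(output, s)], mask)
        y_series[s] = vals
        y_masks[s] = mask
    blocks = [
        build_hankel(y_series, c, conditions, molecule=output, role="output")
    ]
    masks = [y_masks]
    for name in inputs:
        x_series, x_masks = _transform_observed(grid, name, conditions, hill[name])
        if x_init is not None:
            for s in conditions:
                vals = x_init[name][s].copy()
                m = x_masks[s]
                vals[m] = x_series[s][m]
                x_series[s] = vals
        blocks.append(
            build_hankel(x_series, c, conditions, molecule=name, role="transformed_input")
        )
        masks.append(x_masks)
    # the extracted lag order never exceeds m_max, so ranks beyond
    # m_max + L*c carry no model information; capping the sweep there keeps
    # the recovery affordable inside the restart loop
    r_cap = cfg.m_max + len(inputs) * c + 1
    return ipms_recover(
        blocks,
        masks,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        r_cap=r_cap,
        noise_tol=cfg.recovery_noise,
    )


class _ComboScorer:
    """Scores (n, K) combinations by free-run fit to the observed outputs.

    Every candidate gets its own least-squares ARX refit on the denoised
    recovery (the lag order stays fixed at the step-iii estimate), then is
    judged by the residual sum of squares of its free-run simulation at the
    observed training points; with a shared parameter count the AIC argmin
    is the RSS argmin.
    """

    def __init__(
        self,
        grid: GriddedSet,
        output: str,
        inputs: list[str],
        conditions: list[str],
        rec: RecoveryResult,
        arx: ARXParams,
        u_rec: dict[str, dict[str, np.ndarray]],
    ):
        self.grid = grid
        self.output = output
        self.inputs = inputs
        self.conditions = conditions
        self.u_rec = u_rec
        self.m_y, self.m_u = arx.m_y, arx.m_u
        lag = max(self.m_y, self.m_u)
        self.ks = np.arange(lag, grid.n_steps)
        y_dn = {s: rec.denoised_series[(output, s)] for s in conditions}
        y_lag_cols = []
        target = []
        for s in conditions:
            y = y_dn[s]
            y_lag_cols.append(
                np.stack([y[self.ks - i] for i in range(1, self.m_y + 1)], axis=1)
            )
            target.append(y[self.ks])
        self.y_lag = np.vstack(y_lag_cols)
        self.target = np.concatenate(target)
        # condition-stacked views for one batched free-run per evaluation
        self.mask_stack = np.stack(
            [grid.mask[(output, s)] for s in conditions]
        )
        self.y_obs_stack = np.stack(
            [grid.series[(output, s)] for s in conditions]
        )
        self.u_stack = {
            name: np.stack([u_rec[name][s] for s in conditions])
            for name in inputs
        }
        n_feats = self.m_y + len(inputs) * self.m_u
        self._feats = np.empty((len(self.target), n_feats))
        self._feats[:, : self.m_y] = self.y_lag

    def rss(self, combo: dict[str, HillParams]) -> float:
        m_y, m_u = self.m_y, self.m_u
        xs = {
            name: hill_transform(self.u_stack[name], combo[name])
            for name in self.inputs
        }
        feats = self._feats
        for li, name in enumerate(self.inputs):
            x = xs[name]
            for j in range(1, m_u + 1):
                col = x[:, self.ks - j]  # (conditions, rows-per-condition)
                feats[:, m_y + li * m_u + j - 1] = col.ravel()
        gram = feats.T @ feats
        rhs = feats.T @ self.target
        try:
            coef = np.linalg.solve(gram, rhs)
        except np.linalg.LinAlgError:
            coef, _, _, _ = np.linalg.lstsq(feats, self.target, rcond=None)
        a = coef[:m_y]
        drive = np.zeros_like(self.y_obs_stack)
        for li, name in enumerate(self.inputs):
            b = coef[m_y + li * m_u : m_y + (li + 1) * m_u]
            x = xs[name]
            for j in range(1, m_u + 1):
                drive[:, j:] += b[j - 1] * x[:, :-j]
        sims = _simulate_batch(a, drive)
        res = (sims - self.y_obs_stack)[self.mask_stack]
        total = float(np.sum(res**2))
        return total if np.isfinite(total) else np.inf

    def refine(
        self, combo: dict[str, HillParams], max_evals: int = 80
    ) -> dict[str, HillParams]:
        """Local Nelder-Mead polish in (n, log K**n) around a proposal.

        The random draws explore the admissible box; the polish descends to
        the nearby optimum so accuracy does not hinge on a lucky draw.
        Coordinates are clipped back into the sampling box (n in (1, 100],
        K**n in [0.001, 1]).
        """
        from scipy.optimize import minimize

        names = list(self.inputs)

        def decode(theta):
            out = {}
            for i, name in enumerate(names):
                n = float(np.clip(theta[2 * i], 1.0 + 1e-9, 100.0))
                kn = float(np.exp(np.clip(theta[2 * i + 1], math.log(1e-3), 0.0)))
                out[name] = HillParams(n=n, K=kn ** (1.0 / n))
            return out

        def objective(theta):
            return self.rss(decode(theta))

        x0 = []
        for name in names:
            p = combo[name]
            x0.extend([p.n, math.log(max(p.K**p.n, 1e-3))])
        sol = minimize(
            objective,
            np.asarray(x0),
            method="Nelder-Mead",
            options={"maxfev": max_evals, "xatol": 1e-3, "fatol": 1e-12},
        )
        refined = decode(sol.x)
        return refined if self.rss(refined) <= self.rss(combo) else combo


def _score_combos(
    grid: GriddedSet,
    output: str,
    inputs: list[str],
    conditions: list[str],
    rec: RecoveryResult,
    arx: ARXParams,
    u_rec: dict[str, dict[str, np.ndarray]],
    combos: list[dict[str, HillParams]],
) -> dict[str, HillParams]:
    """Pick and locally polish the best (n, K) combination (see _ComboScorer)."""
    scorer = _ComboScorer(grid, output, inputs, conditions, rec, arx, u_rec)
    best = min(combos, key=scorer.rss)
    return scorer.refine(best)


def _hill_inverse_clamped(x: np.ndarray, params: HillParams) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0 - 1e-9)
    return params.K * (x / (1.0 - x)) ** (1.0 / params.n)


def _refine_freerun(
    arx: ARXParams,
    x_series: dict[str, dict[str, np.ndarray]],
    grid: GriddedSet,
    output: str,
    conditions: list[str],
) -> ARXParams:
    """Polish (a, b) by Gauss-Newton on the free-running residual.

    One-step least squares minimizes the single-step prediction error, but
    both the training AIC and the cross-validated scoring judge the free-run
    simulation; a short nonlinear refinement of the coefficients against the
    free-run residual at observed output points removes that mismatch.  The
    result is kept only if it improves the residual and stays stable.
    """
    from scipy.optimize import least_squares

    names = arx.inputs
    m_y, m_u = arx.m_y, arx.m_u

    def unpack(theta):
        a = theta[:m_y]
        b = {
            name: theta[m_y + i * m_u : m_y + (i + 1) * m_u]
            for i, name in enumerate(names)
        }
        return ARXParams(a=a, b=b, m_y=m_y, m_u=m_u, inputs=list(names))

    def residuals(theta):
        cand = unpack(theta)
        out = []
        for s in conditions:
            xs = {name: x_series[name][s] for name in names}
            y_sim = simulate_arx(cand, xs)
            mask = grid.mask[(output, s)]
            out.append(y_sim[mask] - grid.series[(output, s)][mask])
        res = np.concatenate(out)
        return np.where(np.isfinite(res), np.clip(res, -1e6, 1e6), 1e6)

    theta0 = np.concatenate([arx.a] + [arx.b[name] for name in names])
    base = float(np.sum(residuals(theta0) ** 2))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sol = least_squares(residuals, theta0, method="lm", max_nfev=60)
    except Exception:
        return arx
    refined = unpack(sol.x)
    # identifiability gate: a refined pole whose time constant exceeds the
    # record length says nothing the data can support, and sends the
    # steady-state gain to infinity; keep the regression estimate instead
    pole_cap = math.exp(-1.0 / max(grid.n_steps - 1, 1))
    within = bool(np.all(np.abs(refined.characteristic_roots()) < pole_cap))
    if float(np.sum(residuals(sol.x) ** 2)) < base and within:
        return refined
    return arx


def _one_restart(
    grid: GriddedSet,
    output: str,
    inputs: list[str],
    conditions: list[str],
    cfg: RunConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, HillParams], ARXParams, float, RecoveryResult]:
    c = cfg.hankel_c(grid.n_steps)
    n_obs = _observed_count(grid, output, conditions)

    # step i: initial Hill parameters and first transformation
    hill = {name: sample_params(rng, "init") for name in inputs}
    # step ii: signal recovery of the training conditions
    rec = _recover(grid, output, inputs, conditions, hill, c, cfg)
    # step iii: ARX coefficients and lag order from the recovered matrix
    arx = extract_arx(rec, m_max=cfg.m_max)

    # step iv, run ``iv_cycles`` times: invert the current transform to get
    # the input before transformation, score randomly drawn (n, K)
    # combinations, re-recover with the winner.  Iterating makes the combo
    # scoring use a recovery produced under an increasingly apt transform.
    for _ in range(max(1, cfg.iv_cycles)):
        u_rec = {
            name: {
                s: _hill_inverse_clamped(rec.denoised_series[(name, s)], hill[name])
                for s in conditions
            }
            for name in inputs
        }
        combos = [
            {name: sample_params(rng, "search") for name in inputs}
            for _ in range(cfg.inner_combos)
        ]
        combos.append(dict(hill))  # keep the incumbent in the running
        best_combo = _score_combos(
            grid, output, inputs, conditions, rec, arx, u_rec, combos
        )
        # re-recover with the winning (n, K), warm-started from the current
        # recovered series, and re-extract the ARX coefficients
        x_init = {
            name: {
                s: hill_transform(u_rec[name][s], best_combo[name])
                for s in conditions
            }
            for name in inputs
        }
        y_rec = {s: rec.recovered_series[(output, s)] for s in conditions}
        rec = _recover(
            grid, output, inputs, conditions, best_combo, c, cfg,
            x_init=x_init, y_init=y_rec,
        )
        arx = extract_arx(rec, m_max=cfg.m_max)
        hill = best_combo

    x_final = {
        name: {s: rec.denoised_series[(name, s)] for s in conditions}
        for name in inputs
    }
    arx = _refine_freerun(arx, x_final, grid, output, conditions)
    rss = _training_rss(arx, x_final, grid, output, conditions)
    n_params = count_parameters(arx.m_y, arx.m_u, len(inputs))
    score = aic(rss, n_params, n_obs)
    plausible = _plausible_dynamics(arx, grid.n_steps) and _excited(x_final)
    return hill, arx, score, rec, plausible


def _excited(x_series: dict[str, dict[str, np.ndarray]], floor: float = 0.01) -> bool:
    """Whether every transformed input actually varies over the data.

    A switch threshold placed beyond the observed input range maps the whole
    training record to a nearly constant transform; the regression then
    compensates with an enormous, unidentifiable gain that extrapolates
    catastrophically.  Such channels carry no excitation and the restart is
    deprioritized.
    """
    for per_cond in x_series.values():
        span = max(float(x.max() - x.min()) for x in per_cond.values())
        if span < floor:
            return False
    return True


def _plausible_dynamics(arx: ARXParams, n_steps: int) -> bool:
    """Whether the AR part is an overdamped decay the record can resolve.

    Sparse output sampling aliases the within-interval dynamics: a
    sign-alternating pole (negative real part) or a pole whose time constant
    exceeds the record length can fit the observed samples as well as the
    true overdamped response while implying a wildly different gain.
    Restarts producing such poles are kept only if nothing better exists.
    """
    roots = arx.characteristic_roots()
    pole_cap = math.exp(-1.0 / max(n_steps - 1, 1))
    return bool(np.all(np.abs(roots) < pole_cap) and np.all(roots.real > -1e-9))


def fit_training(
    grid: GriddedSet,
    spec: CandidateSpec,
    inputs: list[str] | tuple[str, ...],
    training_conditions: list[str],
    cfg: RunConfig,
    seed_path: tuple[int, ...] = (),
) -> FitResult:
    """Random-restart NARX training on the given conditions (steps i-v).

    Each restart draws fresh Hill initializations; the restart with minimal
    training AIC wins.  ``seed_path`` namespaces the per-restart random
    streams so results are a pure function of (data, config, master seed)
    and independent of any execution order.
    """
    inputs = list(inputs)
    if not inputs:
        raise ValueError("inputs must be non-empty")
    if not set(inputs) <= set(spec.candidates):
        raise ValueError("inputs must come from the candidate pool")
    if not training_conditions:
        raise ValueError("need at least one training condition")
    best: FitResult | None = None
    best_key: tuple[bool, float] | None = None
    failures: list[str] = []
    for ri in range(cfg.restarts):
        rng = np.random.default_rng((cfg.seed, *seed_path, ri))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                hill, arx, score, rec, plausible = _one_restart(
                    grid, spec.output, inputs, training_conditions, cfg, rng
                )
        except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
            failures.append(f"restart {ri}: {exc}")
            continue
        if not np.isfinite(score):
            failures.append(f"restart {ri}: non-finite AIC")
            continue
        key = (not plausible, score)  # prefer plausible dynamics, then AIC
        if best_key is None or key < best_key:
            best_key = key
            best = FitResult(
                hill=hill,
                arx=arx,
                aic_training=score,
                restart_index=ri,
                seed=cfg.seed,
                recovery=rec,
            )
    if best is None:
        raise IdentificationError(
            f"all {cfg.restarts} restarts failed for output {spec.output!r} "
            f"with inputs {inputs}: " + "; ".join(failures[:5])
        )
    return best


def _loo_fold_rss(
    grid: GriddedSet,
    spec: CandidateSpec,
    subset: tuple[str, ...],
    test_condition: str,
    cfg: RunConfig,
    seed_path: tuple[int, ...],
) -> tuple[float, float]:
    """Steps vi-vii for one held-out condition: recover, simulate, score.

    Returns (held-out RSS, training AIC of the fold's fit).
    """
    training = [s for s in spec.conditions if s != test_condition]
    fit = fit_training(grid, spec, list(subset), training, cfg, seed_path=seed_path)

    # step vi: append the test condition, training rows frozen.  The held-out
    # output enters the matrix with no observed entries: its observations are
    # reserved for scoring, so the recovered test inputs cannot absorb them
    test_series = []
    test_masks = []
    test_series.append({test_condition: np.zeros(grid.n_steps)})
    test_masks.append({test_condition: np.zeros(grid.n_steps, dtype=bool)})
    for name in fit.arx.inputs:
        mask = grid.mask[(name, test_condition)]
        vals = np.zeros(grid.n_steps)
        vals[mask] = hill_transform(
            grid.series[(name, test_condition)][mask], fit.hill[name]
        )
        test_series.append({test_condition: vals})
        test_masks.append({test_condition: mask})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rec = append_test_block(
            fit.recovery,
            test_series,
            test_masks,
            tol=cfg.tol,
            max_iter=cfg.max_iter,
            r_cap=cfg.m_max + len(subset) * cfg.hankel_c(grid.n_steps) + 1,
            noise_tol=cfg.recovery_noise,
        )

    # step vii: simulate the test condition with the training parameters
    xs = {name: rec.denoised_series[(name, test_condition)] for name in fit.arx.inputs}
    y_sim = simulate_arx(fit.arx, xs)
    mask = grid.mask[(spec.output, test_condition)]
    y_obs = grid.series[(spec.output, test_condition)]
    rss = float(np.sum((y_sim[mask] - y_obs[mask]) ** 2))
    return rss, fit.aic_training


def loo_select(
    grid: GriddedSet, spec: CandidateSpec, cfg: RunConfig
) -> SelectionResult:
    """Leave-one-condition-out input selection (steps vi-ix) plus the final fit.

    Every non-empty subset of the candidate pool is scored by the sum of
    held-out residuals over all conditions.  The selection applies the
    one-standard-error parsimony rule: the smallest subset (ties broken
    lexicographically) whose score is within one standard error of the
    minimum wins — plain argmin systematically rewards supersets whose
    extra channels absorb recovery error without predictive substance.  A
    subset whose every fold fails is excluded with a warning.
    """
    if len(spec.conditions) < 2:
        raise ValueError("leave-one-out selection needs at least 2 conditions")
    result = SelectionResult()
    subsets = enumerate_subsets(spec.candidates)
    best_rss = np.inf
    for si, subset in enumerate(subsets):
        per_cond: dict[str, float] = {}
        fold_aics: list[float] = []
        failed = []
        for fi, s in enumerate(spec.conditions):
            try:
                per_cond[s], fold_aic = _loo_fold_rss(
                    grid, spec, subset, s, cfg, seed_path=(si, fi)
                )
                fold_aics.append(fold_aic)
            except IdentificationError as exc:
                failed.append(str(exc))
        if not per_cond:
            warnings.warn(
                f"subset {subset} excluded: every fold failed", RuntimeWarning
            )
            continue
        if failed:
            warnings.warn(
                f"subset {subset}: {len(failed)} fold(s) failed", RuntimeWarning
            )
        rss_loo = float(sum(per_cond.values()))
        result.per_subset[subset] = {
            "rss_loo": rss_loo,
            "per_condition": per_cond,
            "aic_training": float(min(fold_aics)),
        }
        if rss_loo < best_rss:  # strict: enumeration order is the tie-break
            best_rss = rss_loo
            result.argmin = subset
    if not result.per_subset:
        raise IdentificationError("no input subset could be identified")
    # parsimony (one-standard-error rule): the smallest subset whose score
    # is within one standard error of the minimizer's score; fold-to-fold
    # spread of the minimizer estimates the noise of the CV score itself
    folds = np.array(
        list(result.per_subset[result.argmin]["per_condition"].values())
    )
    se = (
        float(np.std(folds, ddof=1)) * math.sqrt(len(folds))
        if len(folds) > 1
        else 0.0
    )
    threshold = best_rss + se
    result.chosen = next(
        subset
        for subset in subsets  # already ordered smallest-first
        if subset in result.per_subset
        and result.per_subset[subset]["rss_loo"] <= threshold
    )
    result.final = final_fit(grid, spec, result.chosen, cfg)
    return result


def final_fit(
    grid: GriddedSet,
    spec: CandidateSpec,
    chosen_inputs: tuple[str, ...] | list[str],
    cfg: RunConfig,
) -> IdentifiedModel:
    """Step x: refit on all stimulation conditions with the chosen inputs."""
    if not chosen_inputs:
        raise ValueError("chosen_inputs must be non-empty")
    fit = fit_training(
        grid, spec, list(chosen_inputs), list(spec.conditions), cfg,
        seed_path=(len(spec.candidates) ** 2 + 1,),
    )
    return IdentifiedModel(
        output=spec.output,
        inputs=sorted(chosen_inputs),
        hill=fit.hill,
        arx=fit.arx,
        provenance={
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "restarts": cfg.restarts,
            "inner_combos": cfg.inner_combos,
            "aic_training": fit.aic_training,
            "restart_index": fit.restart_index,
            "conditions": list(spec.conditions),
        },
    )
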