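"""Hankel-matrix construction, low-rank signal recovery (IPMS), ARX extraction.

A time series obeying a linear ARX law makes the horizontally concatenated
Hankel-like matrix [Y U1 ... UL] low rank: with output lag order m_y, a
single persistently exciting input and width c, rank([Y U]) = m_y + c < 2c.
Missing time points are therefore recovered by completing the matrix to
(approximately) minimal partial nuclear norm subject to equality constraints
on the observed entries — the iterative partial matrix shrinkage (IPMS)
scheme: for an increasing rank cap r, alternate SVD truncation, re-imposition
of the Hankel structure (anti-diagonal averaging of repeated cells) and exact
re-imposition of observed entries.

Condition stacking: data from multiple stimulation conditions share one
system, so their per-condition Hankel matrices are stacked vertically before
completion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .timeseries import locf_fill

__all__ = [
    "HankelBlock",
    "RecoveryResult",
    "ARXParams",
    "build_hankel",
    "partial_nuclear_norm",
    "ipms_recover",
    "append_test_block",
    "extract_arx",
]


@dataclass
class HankelBlock:
    """Vertically stacked per-condition Hankel-like matrices of one series.

    For condition block row i, column j (0-based), the cell holds the series
    value at grid index i + j; all cells sharing (condition, k) are equal by
    construction.  ``series`` keeps the underlying per-condition arrays, which
    is the compact state the recovery iterates on.
    """

    molecule: str
    role: str  # "output" | "transformed_input"
    width: int
    condition_order: list[str]
    series: dict[str, np.ndarray]

    @property
    def n_steps(self) -> int:
        return len(next(iter(self.series.values())))

    @property
    def rows_per_condition(self) -> int:
        return self.n_steps - self.width + 1

    def matrix(self) -> np.ndarray:
        parts = [_hankel(self.series[c], self.width) for c in self.condition_order]
        return np.vstack(parts)

    def entry_index(self) -> np.ndarray:
        """(rows, width) array of flattened (condition, grid index) ids."""
        n, c = self.n_steps, self.width
        k = np.arange(n - c + 1)[:, None] + np.arange(c)[None, :]
        return np.vstack(
            [s * n + k for s in range(len(self.condition_order))]
        )


def _hankel(x: np.ndarray, c: int) -> np.ndarray:
    n = len(x)
    if not (2 <= c < n):
        raise ValueError(f"Hankel width c={c} must satisfy 2 <= c < N={n}")
    idx = np.arange(n - c + 1)[:, None] + np.arange(c)[None, :]
    return x[idx]


def build_hankel(
    series: dict[str, np.ndarray],
    c: int,
    condition_order: list[str] | None = None,
    molecule: str = "",
    role: str = "output",
) -> HankelBlock:
    """Build the stacked Hankel-like matrix block of one molecule.

    ``series`` maps condition -> length-N array (all conditions must share N).
    """
    order = list(condition_order) if condition_order else sorted(series)
    lengths = {len(series[s]) for s in order}
    if len(lengths) != 1:
        raise ValueError("all conditions must have the same grid length")
    n = lengths.pop()
    if not (2 <= c < n):
        raise ValueError(f"Hankel width c={c} must satisfy 2 <= c < N={n}")
    return HankelBlock(
        molecule=molecule,
        role=role,
        width=c,
        condition_order=order,
        series={s: np.asarray(series[s], dtype=float).copy() for s in order},
    )


@dataclass
class ARXParams:
    """Linear ARX coefficients: y_k = sum_i a_i y_{k-i} + sum_l sum_j b_lj x_l,k-j."""

    a: np.ndarray
    b: dict[str, np.ndarray]
    m_y: int
    m_u: int
    inputs: list[str]

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = {k: np.asarray(v, dtype=float) for k, v in self.b.items()}
        if len(self.a) != self.m_y:
            raise ValueError("len(a) must equal m_y")
        for name in self.inputs:
            if len(self.b[name]) != self.m_u:
                raise ValueError(f"len(b[{name}]) must equal m_u")

    def characteristic_roots(self) -> np.ndarray:
        """Roots of z**m_y - a_1 z**(m_y-1) - ... - a_m_y."""
        return np.roots(np.concatenate([[1.0], -self.a]))

    def is_stable(self) -> bool:
        return bool(np.all(np.abs(self.characteristic_roots()) < 1.0))


@dataclass
class RecoveryResult:
    """Completed Hankel blocks plus the recovered full-length series.

    ``recovered_series`` honors the observed entries exactly (noisy or not);
    ``denoised_series`` is the rank-truncated, structure-averaged completion
    before the final re-imposition — the low-rank matrix itself, which is
    what the ARX coefficients are read from.  The two coincide (to solver
    tolerance) when an exact structured completion exists.
    """

    blocks: list[HankelBlock]
    rank_estimate: int
    recovered_series: dict[tuple[str, str], np.ndarray]
    converged: bool
    iterations: int
    singular_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    denoised_series: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def condition_order(self) -> list[str]:
        return self.blocks[0].condition_order

    @property
    def width(self) -> int:
        return self.blocks[0].width


def partial_nuclear_norm(mat: np.ndarray, r: int) -> float:
    """Sum of singular values beyond the r largest."""
    s = np.linalg.svd(mat, compute_uv=False)
    return float(s[r:].sum())


_RANK_REL_TOL = 1e-6  # singular values above this fraction of s1 count toward rank


def _matrix_rank(s: np.ndarray) -> int:
    if len(s) == 0 or s[0] <= 0:
        return 0
    return int(np.sum(s > _RANK_REL_TOL * s[0]))


class _StructuredCompletion:
    """Shared machinery for IPMS on stacked multi-block Hankel matrices.

    State lives as per-(block, condition) series; the matrix view is
    assembled on demand and averaged back, which enforces the Hankel
    structure exactly at every step.
    """

    def __init__(
        self,
        blocks: list[HankelBlock],
        masks: list[dict[str, np.ndarray]],
        observed: list[dict[str, np.ndarray]],
    ):
        self.blocks = blocks
        self.masks = masks
        self.observed = observed
        self.order = blocks[0].condition_order
        self.n = blocks[0].n_steps
        self.c = blocks[0].width
        for b in blocks[1:]:
            if b.condition_order != self.order or b.n_steps != self.n or b.width != self.c:
                raise ValueError("blocks must share conditions, grid length and width")
        rows = self.n - self.c + 1
        idx = np.arange(rows)[:, None] + np.arange(self.c)[None, :]
        self._cell_k = idx.ravel()
        self._counts = np.bincount(self._cell_k, minlength=self.n).astype(float)
        self.state = [
            {s: b.series[s].copy() for s in self.order} for b in blocks
        ]
        # a transformed input is a Hill-function value, so its free entries
        # live in [0, 1] by definition; projecting onto that box keeps the
        # completion from inventing unphysical excursions at unobserved cells
        self.bounds: list[tuple[float, float] | None] = [
            (0.0, 1.0) if b.role == "transformed_input" else None for b in blocks
        ]
        self._impose_observed()

    def _impose_observed(self) -> None:
        for st, mask, obs, bound in zip(
            self.state, self.masks, self.observed, self.bounds
        ):
            for s in self.order:
                if bound is not None:
                    np.clip(st[s], bound[0], bound[1], out=st[s])
                m = mask[s]
                st[s][m] = obs[s][m]

    def assemble(self) -> np.ndarray:
        cols = []
        for st in self.state:
            cols.append(np.vstack([_hankel(st[s], self.c) for s in self.order]))
        return np.hstack(cols)

    def disassemble(self, mat: np.ndarray) -> None:
        """Average matrix cells sharing a (block, condition, k) id back to series."""
        rows = self.n - self.c + 1
        for bi, st in enumerate(self.state):
            sub = mat[:, bi * self.c : (bi + 1) * self.c]
            for si, s in enumerate(self.order):
                chunk = sub[si * rows : (si + 1) * rows]
                st[s] = (
                    np.bincount(self._cell_k, weights=chunk.ravel(), minlength=self.n)
                    / self._counts
                )

    def all_observed(self) -> bool:
        return all(
            mask[s].all() for mask in self.masks for s in self.order
        )

    def _snapshot(self) -> list[dict[str, np.ndarray]]:
        return [{s: st[s].copy() for s in self.order} for st in self.state]

    def _restore(self, snap: list[dict[str, np.ndarray]]) -> None:
        self.state = [{s: d[s].copy() for s in self.order} for d in snap]

    def _observation_rms(self) -> float:
        """RMS misfit of the current (pre-imposition) state at observed entries."""
        se = 0.0
        cnt = 0
        for st, mask, obs in zip(self.state, self.masks, self.observed):
            for s in self.order:
                m = mask[s]
                se += float(np.sum((st[s][m] - obs[s][m]) ** 2))
                cnt += int(m.sum())
        return math.sqrt(se / max(cnt, 1))

    def solve(
        self,
        tol: float,
        max_iter: int,
        r_cap: int | None = None,
        accept_ratio: float = 1e-6,
        noise_tol: float = 0.0,
    ) -> tuple[bool, int, np.ndarray, int | None]:
        """Run the rank-incrementing IPMS loop.

        Returns (converged, iterations, singular values, accepted rank).

        Each rank cap r starts from the carried-forward initialization rather
        than the previous stage's iterate: hard truncation at too-small r can
        drag the free entries into a spurious fixed point that poisons later
        stages.  A stage is accepted when either

        * the partial nuclear norm collapses relative to the total nuclear
          norm (``accept_ratio``) — an exact structured completion exists at
          rank r; or
        * ``noise_tol`` > 0 and the rank-r truncation reproduces the observed
          entries to RMS <= ``noise_tol`` — the completion explains the data
          to within the assumed measurement noise, the natural stopping rule
          when the equality constraints themselves carry noise.

        If no stage is accepted the best stage wins (smallest tail ratio, or
        smallest observation misfit when ``noise_tol`` > 0).  ``r_cap``
        bounds the sweep, keeping the recovery affordable inside restart
        loops.
        """
        mat = self.assemble()
        if self.all_observed():
            s = np.linalg.svd(mat, compute_uv=False)
            return True, 0, s, None
        r_max = min(mat.shape) - 1
        if r_cap is not None:
            r_max = min(r_max, max(1, r_cap))
        init = self._snapshot()
        best_score = np.inf
        best_state = init
        best_svals = np.linalg.svd(mat, compute_uv=False)
        best_rank: int | None = None
        total_iters = 0
        converged = False
        for r in range(1, r_max + 1):
            self._restore(init)
            prev_obj = np.inf
            rms = np.inf
            history: list[float] = []
            for _ in range(max_iter):
                total_iters += 1
                mat = self.assemble()
                u, s, vt = np.linalg.svd(mat, full_matrices=False)
                obj = float(s[r:].sum())
                low = (u[:, :r] * s[:r]) @ vt[:r]
                self.disassemble(low)
                rms = self._observation_rms()
                self._impose_observed()
                denom = max(float(s.sum()), 1e-300)
                # collapsed well past the acceptance level: exact completion
                if obj <= 0.01 * accept_ratio * denom:
                    break
                # linear convergence toward a positive plateau = this rank
                # cannot satisfy the constraints; stop burning iterations
                history.append(obj)
                if len(history) > 20 and obj > 0.995 * history[-21]:
                    break
                if abs(prev_obj - obj) <= tol * denom:
                    break
                prev_obj = obj
            mat = self.assemble()
            svals = np.linalg.svd(mat, compute_uv=False)
            ratio = float(svals[r:].sum()) / max(float(svals.sum()), 1e-300)
            score = rms if noise_tol > 0 else ratio
            if score < best_score:
                best_score = score
                best_state = self._snapshot()
                best_svals = svals
                best_rank = r
            if ratio <= accept_ratio or (noise_tol > 0 and rms <= noise_tol):
                converged = True
                best_state = self._snapshot()
                best_svals = svals
                best_rank = r
                break
        self._restore(best_state)
        return converged, total_iters, best_svals, best_rank

    def denoise(self, rank: int | None) -> list[dict[str, np.ndarray]]:
        """Rank-truncate the current matrix and average back, no re-imposition."""
        saved = self._snapshot()
        if rank is not None:
            mat = self.assemble()
            u, s, vt = np.linalg.svd(mat, full_matrices=False)
            low = (u[:, :rank] * s[:rank]) @ vt[:rank]
            self.disassemble(low)
            for st, bound in zip(self.state, self.bounds):
                if bound is not None:
                    for c in self.order:
                        np.clip(st[c], bound[0], bound[1], out=st[c])
        out = self._snapshot()
        self._restore(saved)
        return out

    def result(
        self,
        converged: bool,
        iterations: int,
        svals: np.ndarray,
        accepted_rank: int | None = None,
    ) -> RecoveryResult:
        denoised_state = self.denoise(accepted_rank)
        out_blocks = []
        recovered: dict[tuple[str, str], np.ndarray] = {}
        denoised: dict[tuple[str, str], np.ndarray] = {}
        for b, st, dn in zip(self.blocks, self.state, denoised_state):
            for s in self.order:
                denoised[(b.molecule, s)] = dn[s].copy()
            nb = HankelBlock(
                molecule=b.molecule,
                role=b.role,
                width=b.width,
                condition_order=list(b.condition_order),
                series={s: st[s].copy() for s in self.order},
            )
            out_blocks.append(nb)
            for s in self.order:
                recovered[(b.molecule, s)] = st[s].copy()
        # the accepted rank cap is the honest system-order estimate: after
        # observed (possibly noisy) entries are re-imposed, a raw singular
        # value count would report the noise rank, not the model rank
        rank = accepted_rank if accepted_rank is not None else _matrix_rank(svals)
        return RecoveryResult(
            blocks=out_blocks,
            rank_estimate=rank,
            recovered_series=recovered,
            converged=converged,
            iterations=iterations,
            singular_values=svals,
            denoised_series=denoised,
        )


def ipms_recover(
    blocks: list[HankelBlock],
    masks: list[dict[str, np.ndarray]],
    tol: float = 1e-9,
    max_iter: int = 500,
    r_cap: int | None = None,
    noise_tol: float = 0.0,
) -> RecoveryResult:
    """Complete [Y U1 ... UL] by iterative partial matrix shrinkage.

    ``blocks`` holds the output block first, then one block per transformed
    input, all built on the same grid/conditions; ``masks`` marks the observed
    entries of each block's series (the equality constraints, honored
    exactly).  Unobserved entries of the input blocks should be pre-filled
    (carried-forward initialization); they are the optimization variables.
    ``noise_tol`` is the assumed measurement-noise SD on the normalized
    scale: a rank cap already explaining the observations to that RMS is
    accepted (0 demands an essentially exact structured completion).

    Non-convergence within ``max_iter`` inner iterations per rank cap is
    reported via ``converged=False`` rather than raised.
    """
    observed = [
        {s: b.series[s].copy() for s in b.condition_order} for b in blocks
    ]
    prob = _StructuredCompletion(blocks, masks, observed)
    converged, iterations, svals, rank = prob.solve(
        tol, max_iter, r_cap=r_cap, noise_tol=noise_tol
    )
    return prob.result(converged, iterations, svals, accepted_rank=rank)


def append_test_block(
    trained: RecoveryResult,
    test_series: list[dict[str, np.ndarray]],
    test_masks: list[dict[str, np.ndarray]],
    tol: float = 1e-9,
    max_iter: int = 500,
    r_cap: int | None = None,
    noise_tol: float = 0.0,
) -> RecoveryResult:
    """Recover a held-out condition with the training recovery held fixed.

    The trained blocks enter as fully observed constraints (every training
    cell fixed), so only the test condition's missing entries are optimized.
    ``test_series``/``test_masks`` are per-block dicts of the single test
    condition, keyed by its condition name.
    """
    test_conditions = list(test_series[0])
    for s in test_conditions:
        if s in trained.condition_order:
            raise ValueError(f"test condition {s!r} already in training set")
    blocks = []
    masks = []
    for b, ts, tm in zip(trained.blocks, test_series, test_masks):
        order = list(b.condition_order) + test_conditions
        series = {s: b.series[s].copy() for s in b.condition_order}
        mask = {s: np.ones(b.n_steps, dtype=bool) for s in b.condition_order}
        for s in test_conditions:
            m = np.asarray(tm[s], dtype=bool)
            if m.any():
                series[s] = locf_fill(np.asarray(ts[s], dtype=float), m)
            else:
                # entirely unobserved series (e.g. a held-out output kept
                # blind for scoring): free entries, zero start
                series[s] = np.zeros(b.n_steps)
            mask[s] = m
        blocks.append(
            HankelBlock(
                molecule=b.molecule,
                role=b.role,
                width=b.width,
                condition_order=order,
                series=series,
            )
        )
        masks.append(mask)
    return ipms_recover(
        blocks, masks, tol=tol, max_iter=max_iter, r_cap=r_cap, noise_tol=noise_tol
    )


def extract_arx(
    recovered: RecoveryResult,
    m_max: int = 5,
    m_y: int | None = None,
    m_u: int | None = None,
) -> ARXParams:
    """Least-squares ARX coefficients from the recovered series.

    The output lag order follows the rank law rank([Y U1..UL]) = m_y + L*c:
    m_y = rank_estimate - L*c, clipped to [1, m_max].  By default m_u = m_y
    (a shared lag order).  Coefficients are solved by regressing y_k on its
    own lags and each transformed input's lags, pooled over all conditions.
    """
    out_block = recovered.blocks[0]
    in_blocks = recovered.blocks[1:]
    n_inputs = len(in_blocks)
    c = recovered.width
    if m_y is None:
        m_y = int(np.clip(recovered.rank_estimate - n_inputs * c, 1, m_max))
    if m_u is None:
        m_u = m_y
    lag = max(m_y, m_u)
    # coefficients are read from the low-rank (denoised) completion itself;
    # with noisy observed entries the re-imposed series would bias the
    # autoregression toward zero
    source = recovered.denoised_series or recovered.recovered_series
    rows_x = []
    rows_y = []
    for s in out_block.condition_order:
        y = source[(out_block.molecule, s)]
        xs = [source[(b.molecule, s)] for b in in_blocks]
        n = len(y)
        for k in range(lag, n):
            feats = [y[k - i] for i in range(1, m_y + 1)]
            for x in xs:
                feats.extend(x[k - j] for j in range(1, m_u + 1))
            rows_x.append(feats)
            rows_y.append(y[k])
    X = np.asarray(rows_x)
    yv = np.asarray(rows_y)
    coef, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            "ARX regression is rank deficient; smallest-norm solution returned",
            RuntimeWarning,
            stacklevel=2,
        )
    a = coef[:m_y]
    b = {}
    for li, blk in enumerate(in_blocks):
        start = m_y + li * m_u
        b[blk.molecule] = coef[start : start + m_u]
    params = ARXParams(
        a=a, b=b, m_y=m_y, m_u=m_u, inputs=[blk.molecule for blk in in_blocks]
    )
    if not params.is_stable():
        warnings.warn(
            "identified ARX system has characteristic roots with modulus >= 1",
            RuntimeWarning,
            stacklevel=2,
        )
    return params
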