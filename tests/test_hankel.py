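"""Hankel construction, low-rank recovery (IPMS) and ARX extraction."""

import numpy as np
import pytest

from narxid.hankel import (
    ARXParams,
    append_test_block,
    build_hankel,
    extract_arx,
    ipms_recover,
    partial_nuclear_norm,
)
from narxid.timeseries import locf_fill


def simulate_arx_series(a, b, u, n):
    """Reference ARX recursion (independent of the package simulator)."""
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


@pytest.fixture
def arx_pair():
    """Noiseless single-input ARX data (m_y = 2) with an exciting input."""
    rng = np.random.default_rng(0)
    n = 40
    a = np.array([0.9, -0.2])
    b = np.array([0.4, 0.1])
    u = np.abs(rng.normal(0.5, 0.3, n))
    y = simulate_arx_series(a, b, u, n)
    return a, b, u, y


class TestBuildHankel:
    def test_single_condition_structure(self):
        blk = build_hankel({"c": np.array([1.0, 2, 3, 4, 5])}, c=3, molecule="m")
        np.testing.assert_array_equal(
            blk.matrix(), [[1, 2, 3], [2, 3, 4], [3, 4, 5]]
        )

    def test_two_conditions_stack_vertically(self):
        s = {"A": np.arange(5.0), "B": np.arange(5.0) + 10}
        blk = build_hankel(s, c=3, condition_order=["A", "B"], molecule="m")
        m = blk.matrix()
        assert m.shape == (6, 3)
        assert m[0, 0] == 0 and m[3, 0] == 10

    def test_constant_series_rank_one(self):
        blk = build_hankel({"c": np.full(8, 0.7)}, c=3, molecule="m")
        assert np.linalg.matrix_rank(blk.matrix()) == 1

    def test_width_bounds_enforced(self):
        with pytest.raises(ValueError):
            build_hankel({"c": np.arange(5.0)}, c=5, molecule="m")
        with pytest.raises(ValueError):
            build_hankel({"c": np.arange(5.0)}, c=1, molecule="m")

    def test_repeated_cells_equal(self):
        rng = np.random.default_rng(3)
        blk = build_hankel({"c": rng.random(10)}, c=4, molecule="m")
        mat, idx = blk.matrix(), blk.entry_index()
        for k in np.unique(idx):
            vals = mat[idx == k]
            assert np.all(vals == vals[0])


class TestRankLaw:
    def test_rank_equals_my_plus_c(self, arx_pair):
        """rank [Y U] = m_y + c < 2c on noiseless fully observed ARX data."""
        a, b, u, y = arx_pair
        c = 5
        yb = build_hankel({"s": y}, c, molecule="y", role="output")
        ub = build_hankel({"s": u}, c, molecule="u", role="transformed_input")
        mat = np.hstack([yb.matrix(), ub.matrix()])
        s = np.linalg.svd(mat, compute_uv=False)
        rank = int(np.sum(s > 1e-6 * s[0]))
        assert rank == len(a) + c
        assert rank < 2 * c

    def test_fully_observed_recovery_reports_rank(self, arx_pair):
        a, b, u, y = arx_pair
        c = 5
        ones = np.ones(len(y), dtype=bool)
        rec = ipms_recover(
            [
                build_hankel({"s": y}, c, molecule="y", role="output"),
                build_hankel({"s": u}, c, molecule="u", role="transformed_input"),
            ],
            [{"s": ones}, {"s": ones}],
        )
        assert rec.converged
        assert rec.iterations == 0
        assert rec.rank_estimate == len(a) + c


def hide_entries(rng, n, frac):
    mask = rng.random(n) >= frac
    mask[0] = True
    mask[-1] = True  # the final sample is structurally needed to pin inputs
    return mask


class TestIpmsRecovery:
    def test_noiseless_recovery_exact(self, arx_pair):
        """30% hidden entries are recovered to < 1e-4 on noiseless ARX data."""
        a, b, u, y = arx_pair
        rng = np.random.default_rng(5)
        c = 8
        my = hide_entries(rng, len(y), 0.3)
        mu = hide_entries(rng, len(u), 0.3)
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
        assert rec.converged
        assert np.max(np.abs(rec.recovered_series[("y", "s")] - y)) < 1e-4
        assert np.max(np.abs(rec.recovered_series[("u", "s")] - u)) < 1e-4

    def test_observed_entries_bit_preserved(self, arx_pair):
        a, b, u, y = arx_pair
        rng = np.random.default_rng(6)
        c = 8
        my = hide_entries(rng, len(y), 0.3)
        mu = hide_entries(rng, len(u), 0.3)
        rec = ipms_recover(
            [
                build_hankel({"s": locf_fill(y, my)}, c, molecule="y", role="output"),
                build_hankel(
                    {"s": locf_fill(u, mu)}, c, molecule="u", role="transformed_input"
                ),
            ],
            [{"s": my}, {"s": mu}],
        )
        assert np.array_equal(rec.recovered_series[("y", "s")][my], y[my])
        assert np.array_equal(rec.recovered_series[("u", "s")][mu], u[mu])

    def test_fully_observed_input_returned_unchanged(self, arx_pair):
        a, b, u, y = arx_pair
        ones = np.ones(len(y), dtype=bool)
        rec = ipms_recover(
            [build_hankel({"s": y}, 5, molecule="y", role="output")], [{"s": ones}]
        )
        np.testing.assert_array_equal(rec.recovered_series[("y", "s")], y)

    def test_structure_consistency_after_recovery(self, arx_pair):
        """All matrix cells sharing a grid index are equal in the result."""
        a, b, u, y = arx_pair
        rng = np.random.default_rng(7)
        my = hide_entries(rng, len(y), 0.4)
        blk = build_hankel({"s": locf_fill(y, my)}, 6, molecule="y", role="output")
        rec = ipms_recover([blk], [{"s": my}])
        mat, idx = rec.blocks[0].matrix(), rec.blocks[0].entry_index()
        for k in np.unique(idx):
            vals = mat[idx == k]
            np.testing.assert_allclose(vals, vals[0], rtol=0, atol=0)

    def test_multi_condition_recovery(self):
        """Conditions stacked vertically share one system and recover jointly.

        Striped masks (~25-33% hidden, never clustered) keep every missing
        entry pinned by an ARX relation with observed neighbors; clustered
        random masks can make the completion genuinely non-unique.
        """
        rng = np.random.default_rng(8)
        a, b = np.array([0.7]), np.array([0.5])
        n = 30
        truth = {}
        for scale, s in zip((1.0, 0.5), ("A", "B")):
            u = scale * np.abs(rng.normal(0.5, 0.3, n))
            truth[s] = (u, simulate_arx_series(a, b, u, n))
        k = np.arange(n)
        mu = {"A": ~(k % 3 == 1), "B": ~(k % 3 == 2)}
        my = {"A": ~(k % 4 == 2), "B": ~(k % 4 == 1)}
        for m in (*mu.values(), *my.values()):
            m[0] = True
            m[-1] = True
        rec = ipms_recover(
            [
                build_hankel(
                    {s: locf_fill(truth[s][1], my[s]) for s in ("A", "B")},
                    8,
                    ["A", "B"],
                    molecule="y",
                    role="output",
                ),
                build_hankel(
                    {s: locf_fill(truth[s][0], mu[s]) for s in ("A", "B")},
                    8,
                    ["A", "B"],
                    molecule="u",
                    role="transformed_input",
                ),
            ],
            [my, mu],
            max_iter=8000,
        )
        for s in ("A", "B"):
            assert np.max(np.abs(rec.recovered_series[("y", s)] - truth[s][1])) < 1e-3

    def test_partial_nuclear_norm_matches_grid_search_oracle(self):
        """IPMS lands within 1% of the brute-force optimum for one free entry.

        A tiny series with a single hidden value: the partial nuclear norm of
        the IPMS completion is compared against a dense 1-D scan over that
        value.
        """
        rng = np.random.default_rng(11)
        y = simulate_arx_series([0.6], [0.4], np.abs(rng.normal(0.5, 0.3, 8)), 8)
        mask = np.ones(8, dtype=bool)
        mask[3] = False
        c = 3
        r = 2

        def tail(v):
            z = y.copy()
            z[3] = v
            return partial_nuclear_norm(
                build_hankel({"s": z}, c, molecule="y").matrix(), r
            )

        grid_vals = np.linspace(-2, 2, 40001)
        oracle = min(tail(v) for v in grid_vals)
        rec = ipms_recover(
            [build_hankel({"s": locf_fill(y, mask)}, c, molecule="y", role="output")],
            [{"s": mask}],
            tol=1e-12,
            max_iter=3000,
        )
        achieved = tail(rec.recovered_series[("y", "s")][3])
        assert achieved <= oracle * 1.01 + 1e-9


class TestExtractArx:
    def test_first_order_coefficients_exact(self):
        rng = np.random.default_rng(9)
        u = np.abs(rng.normal(0.5, 0.3, 30))
        y = simulate_arx_series([0.5], [0.3], u, 30)
        ones = np.ones(30, dtype=bool)
        rec = ipms_recover(
            [
                build_hankel({"s": y}, 6, molecule="y", role="output"),
                build_hankel({"s": u}, 6, molecule="u", role="transformed_input"),
            ],
            [{"s": ones}, {"s": ones}],
        )
        arx = extract_arx(rec, m_max=3)
        assert arx.m_y == 1
        np.testing.assert_allclose(arx.a, [0.5], atol=1e-6)
        np.testing.assert_allclose(arx.b["u"], [0.3], atol=1e-6)

    def test_null_channel_recovered_as_zero(self):
        """A nuisance input with true b = 0 gets a near-zero coefficient."""
        rng = np.random.default_rng(10)
        n = 40
        u1 = np.abs(rng.normal(0.5, 0.3, n))
        u2 = np.abs(rng.normal(0.5, 0.3, n))
        y = simulate_arx_series([0.6], [0.4], u1, n)
        ones = np.ones(n, dtype=bool)
        rec = ipms_recover(
            [
                build_hankel({"s": y}, 6, molecule="y", role="output"),
                build_hankel({"s": u1}, 6, molecule="u1", role="transformed_input"),
                build_hankel({"s": u2}, 6, molecule="u2", role="transformed_input"),
            ],
            [{"s": ones}] * 3,
        )
        arx = extract_arx(rec, m_max=2, m_y=1)
        np.testing.assert_allclose(arx.b["u2"], [0.0], atol=1e-4)
        np.testing.assert_allclose(arx.b["u1"], [0.4], atol=1e-4)

    def test_degenerate_all_zero_flagged(self):
        n = 20
        z = np.zeros(n)
        ones = np.ones(n, dtype=bool)
        rec = ipms_recover(
            [
                build_hankel({"s": z}, 5, molecule="y", role="output"),
                build_hankel({"s": z}, 5, molecule="u", role="transformed_input"),
            ],
            [{"s": ones}, {"s": ones}],
        )
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            extract_arx(rec, m_y=1)

    def test_unstable_system_warned(self):
        arx = ARXParams(a=np.array([1.05]), b={"u": np.array([0.1])}, m_y=1, m_u=1,
                        inputs=["u"])
        assert not arx.is_stable()


class TestAppendTestBlock:
    def _trained(self, rng, a, b, n=30, c=8):
        conds = {}
        for scale, s in zip((1.0, 0.6), ("A", "B")):
            u = scale * np.abs(rng.normal(0.5, 0.3, n))
            conds[s] = (u, simulate_arx_series(a, b, u, n))
        ones = np.ones(n, dtype=bool)
        rec = ipms_recover(
            [
                build_hankel(
                    {s: conds[s][1] for s in conds}, c, ["A", "B"],
                    molecule="y", role="output",
                ),
                build_hankel(
                    {s: conds[s][0] for s in conds}, c, ["A", "B"],
                    molecule="u", role="transformed_input",
                ),
            ],
            [{s: ones for s in conds}] * 2,
        )
        return rec

    def test_training_rows_bitwise_unchanged(self):
        rng = np.random.default_rng(12)
        a, b = np.array([0.7]), np.array([0.5])
        rec = self._trained(rng, a, b)
        before = {k: v.copy() for k, v in rec.recovered_series.items()}
        n = 30
        u_t = 0.4 * np.abs(rng.normal(0.5, 0.3, n))
        y_t = simulate_arx_series(a, b, u_t, n)
        m = hide_entries(rng, n, 0.5)
        out = append_test_block(
            rec,
            [{"T": y_t}, {"T": u_t}],
            [{"T": m}, {"T": m}],
            max_iter=2000,
        )
        for key, val in before.items():
            assert np.array_equal(out.recovered_series[key], val)

    def test_heldout_condition_recovered(self):
        """A 50%-missing held-out condition of the same system is recovered.

        Alternating masks hide every other sample; each missing value is
        then pinned by the ARX relation through its observed neighbors.
        """
        rng = np.random.default_rng(13)
        a, b = np.array([0.7]), np.array([0.5])
        rec = self._trained(rng, a, b)
        n = 30
        u_t = 0.4 * np.abs(rng.normal(0.5, 0.3, n))
        y_t = simulate_arx_series(a, b, u_t, n)
        malt = np.arange(n) % 2 == 0
        malt[-1] = True
        out = append_test_block(
            rec,
            [{"T": y_t}, {"T": u_t}],
            [{"T": malt}, {"T": malt.copy()}],
            tol=1e-10,
            max_iter=8000,
        )
        assert np.max(np.abs(out.recovered_series[("y", "T")] - y_t)) < 1e-3
        assert np.max(np.abs(out.recovered_series[("u", "T")] - u_t)) < 1e-3

    def test_duplicate_condition_rejected(self):
        rng = np.random.default_rng(14)
        rec = self._trained(rng, np.array([0.7]), np.array([0.5]))
        with pytest.raises(ValueError, match="already"):
            append_test_block(
                rec,
                [{"A": np.zeros(30)}, {"A": np.zeros(30)}],
                [{"A": np.ones(30, bool)}, {"A": np.ones(30, bool)}],
            )


def test_ipms_objective_monotone_at_fixed_rank(arx_pair):
    """The partial nuclear norm is non-increasing over inner iterations."""
    a, b, u, y = arx_pair
    rng = np.random.default_rng(15)
    my = hide_entries(rng, len(y), 0.3)
    mu = hide_entries(rng, len(u), 0.3)
    from narxid.hankel import _StructuredCompletion

    c = 8
    blocks = [
        build_hankel({"s": locf_fill(y, my)}, c, molecule="y", role="output"),
        build_hankel({"s": locf_fill(u, mu)}, c, molecule="u", role="transformed_input"),
    ]
    observed = [{"s": blk.series["s"].copy()} for blk in blocks]
    prob = _StructuredCompletion(blocks, [{"s": my}, {"s": mu}], observed)
    r = len(a) + c
    objs = []
    for _ in range(200):
        mat = prob.assemble()
        uu, ss, vt = np.linalg.svd(mat, full_matrices=False)
        objs.append(float(ss[r:].sum()))
        prob.disassemble((uu[:, :r] * ss[:r]) @ vt[:r])
        prob._impose_observed()
    diffs = np.diff(objs)
    assert np.all(diffs <= 1e-8)
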