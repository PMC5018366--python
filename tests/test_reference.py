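"""Reference surfaces: Bliss product, HSA minimum, Loewe dose equivalence."""

import numpy as np
import pytest

import combokit as ck
from combokit.reference import CellFlag

from conftest import random_curve

GRID = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0])


def brute_force_loewe(curve_a, curve_b, a, b, step=1e-6):
    """Independent oracle: scan the effect axis for a/A(E)+b/B(E)=1.

    Two-stage grid scan (coarse bracket then a fine grid at ``step``), so
    the returned effect is within one step of the true root.  Never calls
    the bisection solver.
    """
    lo = max(curve_a.e_inf, curve_b.e_inf)
    span = 100.0 - lo

    def ci(E):
        da = curve_a.ec50 * ((100.0 - E) / (E - curve_a.e_inf)) ** (1.0 / curve_a.h)
        db = curve_b.ec50 * ((100.0 - E) / (E - curve_b.e_inf)) ** (1.0 / curve_b.h)
        return a / da + b / db

    coarse = np.linspace(lo + 1e-9 * span, 100.0 - 1e-9 * span, 2001)
    vals = ci(coarse) - 1.0
    if vals[0] >= 0.0:
        return None  # effect unreachable: solver should cap
    idx = np.flatnonzero(vals >= 0.0)
    if idx.size == 0:  # root squeezed against E = 100 (tiny doses)
        lo_e, hi_e = coarse[-1], 100.0 - 1e-12 * span
    else:
        lo_e, hi_e = coarse[idx[0] - 1], coarse[idx[0]]
    fine = np.arange(lo_e, hi_e + step, step)
    fine = fine[fine <= hi_e]
    fv = np.abs(ci(fine) - 1.0)
    return float(fine[np.nanargmin(fv)])


class TestBliss:
    def test_product_law(self, curves):
        ca, cb = ck.HillCurve(0, 1, 1), ck.HillCurve(0, 1, 1)
        surf = ck.bliss_surface(ca, cb, [0.0, 1.0], [0.0, 1.0])
        # E_A = E_B = 50 at ec50 -> product 25
        assert surf.values[1, 1] == pytest.approx(25.0, abs=1e-12)

    def test_null_agent_leaves_partner_response(self):
        ca = ck.HillCurve(0, 1, 1)
        cb = ck.HillCurve(99.999999, 1, 1)  # essentially no effect
        surf = ck.bliss_surface(ca, cb, GRID, GRID)
        ea = ck.hill_response(ca, GRID)
        np.testing.assert_allclose(surf.values[1, :], ea, atol=1e-5)

    def test_negative_plateau_clamped_and_flagged(self):
        ca = ck.HillCurve(-20.0, 0.1, 2.0)  # strong over-kill plateau
        cb = ck.HillCurve(0.0, 1.0, 1.0)
        surf = ck.bliss_surface(ca, cb, GRID, GRID)
        interior = np.outer(GRID > 0, GRID > 0)
        assert np.all(surf.values[interior] >= 0.0)
        assert len(surf.flagged_cells(CellFlag.CLAMPED)) > 0


class TestHSA:
    def test_minimum_of_single_agents(self, curves):
        ca, cb = curves
        surf = ck.hsa_surface(ca, cb, GRID, GRID)
        ea, eb = ck.hill_response(ca, GRID), ck.hill_response(cb, GRID)
        expect = np.minimum(eb[:, None], ea[None, :])
        interior = np.outer(GRID > 0, GRID > 0)
        np.testing.assert_allclose(surf.values[interior], expect[interior])


class TestLoewe:
    def test_sham_combination_is_additive(self):
        """A drug combined with itself must reproduce its own curve at a+b."""
        c = ck.HillCurve(0.0, 1.0, 1.0)
        surf = ck.loewe_surface(c, c, GRID, GRID)
        expect = ck.hill_response(c, GRID[None, :] + GRID[:, None])
        assert abs(surf.values[3, 3] - 100.0 / 3.0) < 1e-8  # a=b=1 -> E(2)
        np.testing.assert_allclose(surf.values, expect, atol=1e-6)

    def test_equivalent_dose_scaling(self):
        # B is A at half potency: (a=1, b=2) is equivalent to A at dose 2
        ca = ck.HillCurve(0.0, 1.0, 1.0)
        cb = ck.HillCurve(0.0, 2.0, 1.0)
        surf = ck.loewe_surface(ca, cb, np.array([0.0, 1.0]), np.array([0.0, 2.0]))
        assert surf.values[1, 1] == pytest.approx(100.0 / 3.0, abs=1e-8)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            ca, cb = random_curve(rng), random_curve(rng)
            surf = ck.loewe_surface(ca, cb, GRID, GRID)
            for i, b in enumerate(GRID):
                for j, a in enumerate(GRID):
                    if a == 0 or b == 0:
                        continue
                    oracle = brute_force_loewe(ca, cb, a, b)
                    if oracle is None:
                        assert surf.flags[i, j] == int(CellFlag.CAPPED)
                    else:
                        assert surf.values[i, j] == pytest.approx(oracle, abs=1e-5)

    def test_unreachable_effect_capped(self):
        # weaker agent plateaus at 60: deep combinations demand E < 60
        ca = ck.HillCurve(0.0, 0.05, 3.0)
        cb = ck.HillCurve(60.0, 0.05, 3.0)
        big = np.array([0.0, 10.0, 100.0])
        surf = ck.loewe_surface(ca, cb, big, big)
        capped = surf.flagged_cells(CellFlag.CAPPED)
        assert capped  # some deep cell must be capped
        for i, j in capped:
            assert surf.values[i, j] == pytest.approx(60.0, abs=1e-9)

    def test_inactive_agent_falls_back_to_single_agent(self, curves):
        ca, _ = curves
        flat = ck.HillCurve(99.0, 1.0, 1.0)
        surf = ck.loewe_surface(ca, flat, GRID, GRID, inactive_b=True)
        ea = ck.hill_response(ca, GRID)
        interior = np.outer(GRID > 0, GRID > 0)
        expect = np.broadcast_to(ea[None, :], surf.values.shape)
        np.testing.assert_allclose(surf.values[interior], expect[interior])
        assert np.all(surf.flags[interior] == int(CellFlag.FALLBACK))

    def test_bad_tolerance_rejected(self, curves):
        with pytest.raises(ValueError):
            ck.loewe_surface(*curves, GRID, GRID, tol=0.0)


class TestCrossModel:
    def test_axis_agreement_exact(self, curves):
        ca, cb = curves
        surfs = [f(ca, cb, GRID, GRID)
                 for f in (ck.bliss_surface, ck.hsa_surface, ck.loewe_surface)]
        ea, eb = ck.hill_response(ca, GRID), ck.hill_response(cb, GRID)
        for s in surfs:
            np.testing.assert_array_equal(s.values[0, :], ea)
            np.testing.assert_array_equal(s.values[:, 0], eb)

    def test_bliss_below_hsa_and_monotone(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            ca, cb = random_curve(rng), random_curve(rng)
            b = ck.bliss_surface(ca, cb, GRID, GRID).values
            h = ck.hsa_surface(ca, cb, GRID, GRID).values
            assert np.all(b <= h + 1e-12)
            for v in (b, h):
                assert np.all(np.diff(v, axis=0) <= 1e-12)
                assert np.all(np.diff(v, axis=1) <= 1e-12)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            ck.Model.parse("zip")
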