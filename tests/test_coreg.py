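"""Dimensional stacking (CBDR), pairwise histograms, and interaction
classification, including planted-structure recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from olmens.coreg_analysis import (ConductanceHistogram, cbdr_order,
                                   classify_interaction,
                                   conductance_histogram, coreg_screen,
                                   clutter_score, stack_image)
from olmens.synthetic_data import planted_coreg_ensemble


def full_factorial(levels: dict) -> pd.DataFrame:
    rows = list(itertools.product(*[range(n) for n in levels.values()]))
    return pd.DataFrame(rows, columns=list(levels))


class TestCbdrOrder:
    def test_single_sensitive_parameter_first(self):
        levels = {"A": 3, "B": 3, "C": 3}
        coords = full_factorial(levels)
        values = coords["B"].to_numpy().astype(float)  # depends only on B
        order = cbdr_order(coords, values, levels=levels)
        assert order.order[0] == "B"

    def test_constant_values_return_name_sorted_order(self):
        levels = {"x": 2, "b": 2, "m": 2}
        coords = full_factorial(levels)
        order = cbdr_order(coords, np.ones(len(coords)), levels=levels)
        assert order.order == tuple(sorted(levels))

    def test_two_weighted_parameters_top_two(self):
        levels = {"A": 3, "B": 3, "C": 3, "D": 3}
        coords = full_factorial(levels)
        values = (10.0 * coords["C"] + 1.0 * coords["A"]).to_numpy(float)
        order = cbdr_order(coords, values, levels=levels)
        assert order.order[0] == "C"
        assert order.order[1] == "A"

    def test_beats_random_orderings(self):
        levels = {"A": 3, "B": 3, "C": 3, "D": 2}
        coords = full_factorial(levels)
        rng = np.random.default_rng(5)
        values = (3.0 * coords["A"] + coords["D"]
                  + rng.normal(0, 0.3, len(coords))).to_numpy(float)
        best = cbdr_order(coords, values, levels=levels)
        params = list(levels)
        for _ in range(100):
            perm = tuple(rng.permutation(params))
            c = clutter_score(stack_image(coords, values, perm, levels))
            assert best.clutter <= c + 1e-9

    def test_greedy_path_used_beyond_exhaustive_limit(self):
        levels = {f"p{i}": 2 for i in range(8)}
        coords = full_factorial(levels)
        values = coords["p3"].to_numpy(float)
        order = cbdr_order(coords, values, levels=levels, exhaustive_max=4)
        assert order.order[0] == "p3"

    def test_missing_coordinates_error(self):
        coords = full_factorial({"A": 2})
        with pytest.raises(KeyError):
            cbdr_order(coords, np.ones(2), params=["A", "Z"],
                       levels={"A": 2, "Z": 2})


class TestHistogram:
    GRID = {"A": (1.0, 2.0, 3.0), "B": (10.0, 20.0, 30.0)}

    def test_full_grid_uniform(self):
        members = pd.DataFrame(
            [(a, b) for a in self.GRID["A"] for b in self.GRID["B"]],
            columns=["A", "B"])
        h = conductance_histogram(members, "A", "B", self.GRID)
        assert np.all(h.counts == 1)
        assert h.percent.sum() == pytest.approx(100.0)

    def test_diagonal_membership(self):
        members = pd.DataFrame([(a, b) for a, b in
                                zip(self.GRID["A"], self.GRID["B"])] * 4,
                               columns=["A", "B"])
        h = conductance_histogram(members, "A", "B", self.GRID)
        assert np.all(np.diag(h.counts) == 4)
        assert h.counts.sum() == np.trace(h.counts)

    def test_empty_subset_all_zero(self):
        members = pd.DataFrame(columns=["A", "B"])
        h = conductance_histogram(members, "A", "B", self.GRID)
        assert h.counts.sum() == 0

    def test_conservation(self):
        rng = np.random.default_rng(3)
        members = pd.DataFrame({
            "A": rng.choice(self.GRID["A"], 57),
            "B": rng.choice(self.GRID["B"], 57)})
        h = conductance_histogram(members, "A", "B", self.GRID)
        assert h.counts.sum() == 57

    def test_unknown_parameter_error(self):
        with pytest.raises(KeyError):
            conductance_histogram(pd.DataFrame(columns=["A", "B"]),
                                  "A", "Z", self.GRID)


class TestClassification:
    def _hist(self, counts):
        counts = np.asarray(counts)
        na, nb = counts.shape
        return ConductanceHistogram(
            "A", "B", tuple(range(na)), tuple(range(nb)),
            counts, subset_size=int(counts.sum()))

    def test_diagonal_is_coregulation_with_unit_score(self):
        r = classify_interaction(self._hist(np.eye(4, dtype=int) * 5))
        assert r.label == "co-regulation"
        assert r.ridge_score == pytest.approx(1.0)

    def test_antidiagonal_negative_coregulation(self):
        r = classify_interaction(self._hist(np.eye(4, dtype=int)[::-1] * 5))
        assert r.label == "co-regulation"
        assert r.ridge_score == pytest.approx(-1.0)

    def test_uniform_sampling_scores_near_zero(self):
        """Over 100 seeded uniform draws the |score| stays below 0.1 on
        average and never flags a co-regulation."""
        scores = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            counts = rng.multinomial(400, np.full(16, 1 / 16)).reshape(4, 4)
            r = classify_interaction(self._hist(counts))
            scores.append(abs(r.ridge_score))
            assert r.label != "co-regulation"
        assert np.mean(scores) < 0.1

    def test_central_peak_is_local_preference(self):
        counts = np.array([[1, 2, 1], [2, 20, 2], [1, 2, 1]])
        r = classify_interaction(self._hist(counts))
        assert r.label == "local-preference"

    def test_degenerate_histogram_incomparable(self):
        with pytest.raises(ValueError):
            classify_interaction(self._hist(np.ones((1, 4), dtype=int)))

    def test_invariant_to_value_relabeling(self):
        """Classification depends on level ranks, not the unit labels."""
        counts = np.eye(3, dtype=int) * 7
        a = ConductanceHistogram("A", "B", (1.0, 2.0, 3.0), (1.0, 2.0, 3.0),
                                 counts, 21)
        b = ConductanceHistogram("A", "B", (0.001, 0.002, 0.003),
                                 (100.0, 200.0, 300.0), counts, 21)
        assert classify_interaction(a).ridge_score == \
            classify_interaction(b).ridge_score


class TestPlantedRecovery:
    def test_planted_pair_tops_screen(self):
        grid, coords, d_x, member = planted_coreg_ensemble(seed=0)
        df = grid.to_frame()
        members = df[member]
        levels = {p: int(coords[p].max()) + 1
                  for p in grid.design.conductances}
        order = cbdr_order(coords, np.where(member, d_x, np.nan),
                           params=[p for p, n in levels.items() if n > 1],
                           levels=levels)
        results = coreg_screen(members, order, grid.design.values,
                               control="AHP")
        coregs = [r for r in results if r.label == "co-regulation"]
        assert len(coregs) == 1
        assert {coregs[0].param_a, coregs[0].param_b} == {"Na_d", "KDRf"}

    def test_control_parameter_never_interacts(self):
        grid, coords, d_x, member = planted_coreg_ensemble(seed=1)
        df = grid.to_frame()
        members = df[member]
        levels = {p: int(coords[p].max()) + 1
                  for p in grid.design.conductances}
        order = cbdr_order(coords, np.where(member, d_x, np.nan),
                           params=[p for p, n in levels.items() if n > 1],
                           levels=levels)
        for r in coreg_screen(members, order, grid.design.values,
                              control="AHP"):
            if "AHP" in (r.param_a, r.param_b):
                assert r.label != "co-regulation"

    def test_full_grid_subset_shows_no_coregulation(self):
        grid, coords, d_x, _ = planted_coreg_ensemble(seed=2)
        df = grid.to_frame()  # entire grid: perfectly uniform histograms
        levels = {p: int(coords[p].max()) + 1
                  for p in grid.design.conductances}
        order = cbdr_order(coords, d_x,
                           params=[p for p, n in levels.items() if n > 1],
                           levels=levels)
        for r in coreg_screen(df, order, grid.design.values,
                              control="AHP"):
            assert r.label == "no-interaction"
            assert abs(r.ridge_score) < 1e-9

    def test_recovery_rate_over_seeds(self):
        """On 50 seeded planted ensembles the planted pair is flagged at
        |score| >= 0.4 in at least 95% of runs."""
        hits = 0
        for seed in range(50):
            grid, coords, d_x, member = planted_coreg_ensemble(
                values_per_conductance=3, seed=seed,
                conductances=("Na_d", "KDRf", "KDRs", "A", "h"))
            df = grid.to_frame()
            h = conductance_histogram(df[member], "Na_d", "KDRf",
                                      grid.design.values)
            r = classify_interaction(h)
            if r.label == "co-regulation" and abs(r.ridge_score) >= 0.4:
                hits += 1
        assert hits >= 48
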