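"""Torus-translation test: construction, null-map algebra, oracle
equivalence and statistical behaviour."""
import numpy as np
import pandas as pd
import pytest

from soilsucc import summary, torus
from soilsucc.io import OtuTable, ValidationError
from soilsucc.synth import (DomainSpec, Scenario, generate_community,
                            neutral_scenario)
from soilsucc.torus import (HabitatGrid, TransformedMap, build_composite_grid,
                            enumerate_null_maps, habitat_statistic, torus_test)

from conftest import make_metadata


# ---------------------------------------------------------------------------
# naive reference implementation: literal loops, explicit index arithmetic
# ---------------------------------------------------------------------------

def naive_transformed_labels(habitat, dx, dy, symmetry):
    H, W = habitat.shape
    sym = [[None] * W for _ in range(H)]
    for y in range(H):
        for x in range(W):
            if symmetry == "identity":
                sym[y][x] = habitat[y][x]
            elif symmetry == "rot180":
                sym[y][x] = habitat[H - 1 - y][W - 1 - x]
            elif symmetry == "mirror":
                sym[y][x] = habitat[y][W - 1 - x]
            elif symmetry == "mirror_rot180":
                sym[y][x] = habitat[H - 1 - y][x]
    out = [[None] * W for _ in range(H)]
    for y in range(H):
        for x in range(W):
            out[y][x] = sym[(y - dy) % H][(x - dx) % W]
    return out


def naive_torus_test(table, grid, alpha=0.05):
    """All 4WH-1 maps materialised, per-OTU/habitat python loops."""
    H, W = grid.habitat.shape
    rel = {s: table.counts[i] / table.counts[i].sum()
           for i, s in enumerate(table.sample_ids)}
    cell_rel = {}
    for s, (x, y) in grid.cell_of_sample.items():
        cell_rel[(x, y)] = rel[s]
    habitats = sorted(set(np.asarray(grid.habitat).ravel().tolist()))
    maps = []
    for symmetry in ("identity", "rot180", "mirror", "mirror_rot180"):
        for dy in range(H):
            for dx in range(W):
                if symmetry == "identity" and dx == 0 and dy == 0:
                    continue
                maps.append(naive_transformed_labels(grid.habitat, dx, dy, symmetry))
    rows = []
    for j, otu in enumerate(table.otu_ids):
        for h in habitats:
            obs_vals = [cell_rel[(x, y)][j] for y in range(H) for x in range(W)
                        if grid.habitat[y][x] == h]
            obs = sum(obs_vals) / len(obs_vals)
            null = []
            for m in maps:
                vals = [cell_rel[(x, y)][j] for y in range(H) for x in range(W)
                        if m[y][x] == h]
                null.append(sum(vals) / len(vals))
            tol = max(1e-12, 1e-9 * abs(obs))
            n_less = sum(1 for v in null if v < obs - tol)
            n_tie = sum(1 for v in null if abs(v - obs) <= tol)
            rank = n_less + 0.5 * n_tie
            n = len(null)
            if rank >= (1 - alpha / 2) * n:
                verdict = "positive"
            elif rank <= (alpha / 2) * n:
                verdict = "negative"
            else:
                verdict = "none"
            rows.append((otu, h, verdict))
    return pd.DataFrame(rows, columns=["otu_id", "habitat", "verdict"])


def random_grid_instance(rng, shape):
    """A full random habitat mosaic + table on a small grid."""
    H = W = shape
    habitats = ["A", "B", "C"]
    habitat = np.array(rng.choice(habitats, size=(H, W)), dtype=object)
    sample_ids = [f"c{y}_{x}" for y in range(H) for x in range(W)]
    cell_of_sample = {f"c{y}_{x}": (x, y) for y in range(H) for x in range(W)}
    grid = HabitatGrid(habitat, cell_of_sample)
    n_otus = int(rng.integers(2, 5))
    counts = rng.integers(0, 30, size=(len(sample_ids), n_otus))
    counts[:, 0] += 1
    counts[:, 1:] += rng.integers(0, 2, size=(len(sample_ids), n_otus - 1))
    # ensure nonzero totals per OTU
    counts[0, :] += 1
    table = OtuTable(sample_ids, [f"o{j}" for j in range(n_otus)], counts)
    return table, grid


# ---------------------------------------------------------------------------


class TestCompositeGrid:
    def test_2x2_layout(self, metadata_4x25):
        grid = build_composite_grid(metadata_4x25, "2x2")
        assert grid.shape == (10, 10)
        assert grid.habitat_cell_counts() == {f"stage{k}": 25 for k in range(4)}

    def test_1x4_layout(self, metadata_4x25):
        grid = build_composite_grid(metadata_4x25, "1x4")
        assert grid.shape == (20, 5)
        assert grid.habitat_cell_counts() == {f"stage{k}": 25 for k in range(4)}

    def test_incomplete_layout_rejected(self):
        meta = make_metadata(n_plots=3)
        with pytest.raises(ValidationError, match="needs 4 plots"):
            build_composite_grid(meta, "2x2")

    def test_unequal_plots_rejected(self):
        a = make_metadata(n_plots=1, shape=(5, 5), stages=["A"])
        b = make_metadata(n_plots=1, shape=(4, 5), stages=["B"])
        b["plot_id"] = "P9"
        b["sample_id"] = "x" + b["sample_id"]
        with pytest.raises(ValidationError, match="unequal"):
            build_composite_grid(pd.concat([a, b]), "1x2")


class TestNullMaps:
    def test_counts_10x10(self, metadata_4x25):
        grid = build_composite_grid(metadata_4x25, "2x2")
        assert len(enumerate_null_maps(grid, include_identity=True)) == 400
        assert len(enumerate_null_maps(grid)) == 399

    def test_counts_2x2(self):
        grid = HabitatGrid(np.array([["A", "B"], ["B", "A"]], dtype=object),
                           {"s1": (0, 0), "s2": (1, 0), "s3": (0, 1), "s4": (1, 1)})
        assert len(enumerate_null_maps(grid, include_identity=True)) == 16

    def test_habitat_counts_preserved_exhaustively(self, rng):
        _, grid = random_grid_instance(rng, 4)
        base = grid.habitat_cell_counts()
        for m in enumerate_null_maps(grid, include_identity=True):
            labels, counts = np.unique(m.apply(grid.habitat), return_counts=True)
            assert dict(zip(labels.tolist(), counts.tolist())) == base

    def test_transform_matches_naive_indexing(self, rng):
        _, grid = random_grid_instance(rng, 4)
        for m in [TransformedMap(1, 2, "rot180"), TransformedMap(3, 0, "mirror"),
                  TransformedMap(2, 3, "mirror_rot180"), TransformedMap(1, 1)]:
            expected = naive_transformed_labels(grid.habitat, m.dx, m.dy, m.symmetry)
            assert m.apply(grid.habitat).tolist() == expected


class TestHabitatStatistic:
    def test_uniform_otu_constant_everywhere(self, rng):
        _, grid = random_grid_instance(rng, 4)
        depths = np.full(16, 100)
        col = np.full(16, 1)  # relative abundance 0.01 in every cell
        for m in enumerate_null_maps(grid, include_identity=True)[:10]:
            stat = habitat_statistic(col, depths, m.apply(grid.habitat))
            for v in stat.values():
                assert v == pytest.approx(0.01)

    def test_specialist_only_in_habitat(self):
        habitat = np.array([["A", "A"], ["B", "B"]], dtype=object)
        grid = HabitatGrid(habitat, {f"s{i}": (i % 2, i // 2) for i in range(4)})
        col = np.array([5, 5, 0, 0])  # cells in row-major order: A, A, B, B
        depths = np.array([10, 10, 10, 10])
        stat = habitat_statistic(col, depths, habitat)
        assert stat["A"] == pytest.approx(0.5) and stat["B"] == 0.0

    def test_bruteforce_all_maps_4x4(self, rng):
        table, grid = random_grid_instance(rng, 4)
        R, _ = torus._cell_matrix(table, grid)
        maps = enumerate_null_maps(grid, include_identity=True)
        stacked, habitats = torus._stat_stack(R, grid, maps)
        depths = np.array([table.counts[table.sample_ids.index(s)].sum()
                           for s in sorted(grid.cell_of_sample,
                                           key=lambda s: (grid.cell_of_sample[s][1],
                                                          grid.cell_of_sample[s][0]))])
        cols = np.array([table.counts[table.sample_ids.index(s)]
                         for s in sorted(grid.cell_of_sample,
                                         key=lambda s: (grid.cell_of_sample[s][1],
                                                        grid.cell_of_sample[s][0]))])
        for mi, m in enumerate(maps):
            labels = m.apply(grid.habitat)
            for j in range(table.n_otus):
                stat = habitat_statistic(cols[:, j], depths, labels)
                for hi, h in enumerate(habitats):
                    assert stacked[mi, hi, j] == pytest.approx(stat[h], rel=1e-12)

    def test_conservation_across_maps(self, rng):
        table, grid = random_grid_instance(rng, 5)
        R, _ = torus._cell_matrix(table, grid)
        maps = enumerate_null_maps(grid, include_identity=True)
        stacked, habitats = torus._stat_stack(R, grid, maps)
        cells = grid.habitat_cell_counts()
        weights = np.array([cells[h] for h in habitats])
        totals = np.einsum("h,mhj->mj", weights, stacked)
        np.testing.assert_allclose(totals, np.broadcast_to(totals[0], totals.shape),
                                   rtol=1e-10)


class TestTorusTest:
    def test_constant_otu_never_flagged(self, metadata_4x25):
        grid = build_composite_grid(metadata_4x25, "2x2")
        counts = np.full((100, 2), 50)
        table = OtuTable(list(metadata_4x25["sample_id"]), ["c1", "c2"], counts)
        res = torus_test(table, grid)
        assert (res["verdict"] == "none").all()
        assert (res["null_rank"] == res["null_n"] / 2).all()

    def test_zero_total_otu_rejected(self, metadata_4x25):
        grid = build_composite_grid(metadata_4x25, "2x2")
        counts = np.ones((100, 2), dtype=int)
        counts[:, 1] = 0
        table = OtuTable(list(metadata_4x25["sample_id"]), ["a", "zero"], counts)
        with pytest.raises(ValueError, match="zero"):
            torus_test(table, grid)

    def test_matches_naive_oracle(self, rng):
        for shape in (4, 5):
            for _ in range(5):
                table, grid = random_grid_instance(rng, shape)
                fast = torus_test(table, grid)
                slow = naive_torus_test(table, grid)
                merged = fast.merge(slow, on=["otu_id", "habitat"],
                                    suffixes=("_fast", "_naive"))
                assert (merged["verdict_fast"] == merged["verdict_naive"]).all()

    def test_strong_specialist_detected(self):
        scen = Scenario(domains=(DomainSpec("bacteria", 40, 1.0, 8.0),),
                        env_effects={})
        com = generate_community(scen, seed=2)
        t = summary.filter_rare(com.tables["bacteria"])
        res = torus_test(t, com.grid)
        truth = com.truth["bacteria"].set_index("otu_id")
        pos = res[res["verdict"] == "positive"].set_index("otu_id")
        hits = 0
        for otu in t.otu_ids:
            pref = truth.loc[otu, "preferred_habitat"]
            sub = pos.loc[[otu]] if otu in pos.index else None
            if sub is not None and pref in set(np.atleast_1d(sub["habitat"])):
                hits += 1
        assert hits / t.n_otus >= 0.9

    def test_label_permutation_null_inflates_under_autocorrelation(self):
        """With spatially autocorrelated noise the torus null stays near the
        nominal rate while shuffling quadrat labels overstates significance."""
        com = generate_community(neutral_scenario(n_otus=150, corr_length=2.0),
                                 seed=9)
        t = com.tables["bacteria"]
        res = torus_test(t, com.grid)
        torus_rate = (res["verdict"] == "positive").mean()

        rng = np.random.default_rng(0)
        R, _ = torus._cell_matrix(t, com.grid)
        habitats = com.grid.habitats
        flat = np.asarray(com.grid.habitat).ravel()
        ind = np.stack([(flat == h) / (flat == h).sum() for h in habitats])
        obs = ind @ R
        null = np.stack([(ind[:, rng.permutation(len(flat))] @ R)
                         for _ in range(399)])
        n_less = (null < obs - 1e-12).sum(axis=0)
        n_tie = (np.abs(null - obs) <= 1e-12).sum(axis=0)
        label_rate = ((n_less + 0.5 * n_tie) >= 0.975 * 399).mean()
        assert label_rate > 1.5 * 0.025
        assert label_rate > 2 * torus_rate


class TestSummarize:
    def make_results(self, n_pos, n_none, habitat="A"):
        rows = []
        for i in range(n_pos):
            rows.append({"otu_id": f"p{i}", "habitat": habitat,
                         "verdict": "positive"})
        for i in range(n_none):
            rows.append({"otu_id": f"n{i}", "habitat": habitat, "verdict": "none"})
        return pd.DataFrame(rows)

    def test_counts_and_percentages(self):
        res = {"bacteria": self.make_results(3, 1), "fungi": self.make_results(1, 3)}
        summ = torus.summarize_associations(res)
        per = summ.per_domain.set_index("domain")
        assert per.loc["bacteria", "n_associated"] == 3
        assert per.loc["bacteria", "pct_associated"] == 75.0
        assert per.loc["fungi", "pct_associated"] == 25.0
        hab = summ.positive_by_habitat.set_index("habitat")
        assert hab.loc["A", "n_positive"] == 4
        assert hab.loc["A", "pct_of_tested"] == 50.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            torus.summarize_associations({})
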