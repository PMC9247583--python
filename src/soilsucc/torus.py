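"""Torus-translation habitat-association test at the OTU level.

The four succession plots are tiled into one composite quadrat lattice (by
default four 5x5 plots in a 2x2 arrangement, giving a 10x10 grid with one
habitat label per cell).  The observed statistic for OTU i and habitat h is
the mean per-cell relative abundance (count / sample depth) over the cells
labelled h.  The null distribution is produced by moving the *habitat map*
rather than the data: every torus translation of the map, combined with its
180-degree rotation, mirror image, and mirrored rotation, gives 4*W*H
transformed maps, each preserving the per-habitat cell counts.  Because
whole rows/columns of the map are shifted together, spatial autocorrelation
in both the habitat mosaic and the community field is respected, unlike a
naive quadrat-label permutation.

Significance is two-tailed by empirical quantile position among the null
values (identity map excluded by default), with mid-rank handling of ties:
a null value equal to the observed statistic counts one half.  An OTU whose
abundance field is constant therefore sits exactly mid-null and is never
flagged.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import percent
from .io import OtuTable, ValidationError

SYMMETRIES = ("identity", "rot180", "mirror", "mirror_rot180")

# relative tolerance for declaring the observed statistic tied with a null
# value (the same cell values averaged in a different order can differ by
# a few ulp)
_TIE_RTOL = 1e-9
_TIE_ATOL = 1e-12


@dataclass
class HabitatGrid:
    """Composite rectangular lattice: one habitat label and at most one
    sample per cell.

    ``habitat`` is an (H, W) array of habitat labels indexed [y, x];
    ``cell_of_sample`` maps sample_id -> (x, y) with x the column (west-east)
    and y the row (south-north).
    """

    habitat: np.ndarray
    cell_of_sample: dict[str, tuple[int, int]]
    layout: str = ""

    def __post_init__(self) -> None:
        self.habitat = np.asarray(self.habitat)
        seen: dict[tuple[int, int], str] = {}
        H, W = self.habitat.shape
        for s, (x, y) in self.cell_of_sample.items():
            if not (0 <= x < W and 0 <= y < H):
                raise ValidationError(f"sample {s!r} cell ({x},{y}) outside {W}x{H} grid")
            if (x, y) in seen:
                raise ValidationError(
                    f"cell ({x},{y}) assigned to both {seen[(x, y)]!r} and {s!r}")
            seen[(x, y)] = s

    @property
    def shape(self) -> tuple[int, int]:
        """(W, H)"""
        H, W = self.habitat.shape
        return W, H

    @property
    def habitats(self) -> list:
        return sorted(np.unique(self.habitat).tolist())

    def habitat_cell_counts(self) -> dict:
        labels, counts = np.unique(self.habitat, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


@dataclass(frozen=True)
class TransformedMap:
    """One element of the torus-translation null: a symmetry of the habitat
    map followed by a cyclic shift of (dx, dy) cells."""

    dx: int
    dy: int
    symmetry: str = "identity"

    def apply(self, habitat: np.ndarray) -> np.ndarray:
        out = np.asarray(habitat)
        if self.symmetry == "rot180":
            out = out[::-1, ::-1]
        elif self.symmetry == "mirror":
            out = out[:, ::-1]
        elif self.symmetry == "mirror_rot180":
            out = out[::-1, :]
        elif self.symmetry != "identity":
            raise ValueError(f"unknown symmetry {self.symmetry!r}")
        # roll columns by dx (x axis = axis 1) and rows by dy
        return np.roll(np.roll(out, self.dx, axis=1), self.dy, axis=0)

    @property
    def is_identity(self) -> bool:
        return self.symmetry == "identity" and self.dx == 0 and self.dy == 0


@dataclass
class AssociationSummary:
    """Per-domain and pooled habitat-association counts with printed-style
    percentages (half-up, 2 decimals)."""

    per_domain: pd.DataFrame       # domain, n_tested, n_associated, pct_associated
    positive_by_habitat: pd.DataFrame  # habitat, n_positive (pooled), pct_of_tested
    n_tested_total: int
    n_associated_all_habitats: int  # OTUs significant in every habitat


def build_composite_grid(metadata: pd.DataFrame, layout: str = "2x2",
                         plot_order: list[str] | None = None) -> HabitatGrid:
    """Tile equally-shaped rectangular plots into one composite lattice.

    ``layout`` is "RxC" (tiles rows x tiles columns); plots fill the layout
    in ``plot_order`` (default: sorted plot ids), west to east then south to
    north.
    """
    rows_str, _, cols_str = layout.partition("x")
    try:
        tiles_r, tiles_c = int(rows_str), int(cols_str)
    except ValueError:
        raise ValueError(f"layout must look like '2x2', got {layout!r}") from None
    plots = plot_order or sorted(metadata["plot_id"].unique())
    if len(plots) != tiles_r * tiles_c:
        raise ValidationError(
            f"layout {layout} needs {tiles_r * tiles_c} plots, got {len(plots)}")
    shapes = {}
    for p in plots:
        grp = metadata[metadata["plot_id"] == p]
        shapes[p] = (grp["row"].max() + 1, grp["col"].max() + 1)
    if len(set(shapes.values())) != 1:
        raise ValidationError(f"plots have unequal shapes: {shapes}")
    ph, pw = next(iter(shapes.values()))
    H, W = tiles_r * ph, tiles_c * pw
    habitat = np.empty((H, W), dtype=object)
    cell_of_sample: dict[str, tuple[int, int]] = {}
    for k, p in enumerate(plots):
        tr, tc = divmod(k, tiles_c)
        grp = metadata[metadata["plot_id"] == p]
        stage = grp["stage"].iloc[0]
        habitat[tr * ph:(tr + 1) * ph, tc * pw:(tc + 1) * pw] = stage
        for _, r in grp.iterrows():
            x, y = tc * pw + int(r["col"]), tr * ph + int(r["row"])
            cell_of_sample[r["sample_id"]] = (x, y)
    return HabitatGrid(habitat, cell_of_sample, layout=layout)


def enumerate_null_maps(grid: HabitatGrid,
                        include_identity: bool = False) -> list[TransformedMap]:
    """All 4*W*H transformed maps (identity dropped unless requested).

    Coinciding maps from symmetric habitat mosaics are kept as-is so the
    null size is always exactly 4*W*H (- 1).
    """
    W, H = grid.shape
    if W < 2 or H < 2:
        raise ValueError("grid must be at least 2x2")
    maps = [TransformedMap(dx, dy, sym)
            for sym in SYMMETRIES for dy in range(H) for dx in range(W)]
    if not include_identity:
        maps = [m for m in maps if not m.is_identity]
    return maps


def _cell_matrix(table: OtuTable, grid: HabitatGrid) -> tuple[np.ndarray, np.ndarray]:
    """Relative abundances arranged per grid cell.

    Returns (R, flat_index) where R is (n_cells, n_otus) in row-major cell
    order and flat_index maps cell -> position.  Every sample must sit on
    the grid and every cell must hold a sample.
    """
    W, H = grid.shape
    if len(grid.cell_of_sample) != W * H:
        raise ValidationError("grid has empty cells; torus test needs one sample per cell")
    order = np.empty(W * H, dtype=np.int64)
    sample_pos = {s: i for i, s in enumerate(table.sample_ids)}
    for s, (x, y) in grid.cell_of_sample.items():
        if s not in sample_pos:
            raise ValidationError(f"grid sample {s!r} absent from OTU table")
        order[y * W + x] = sample_pos[s]
    R = table.relative_abundance()[order]
    return R, order


def habitat_statistic(otu_column: np.ndarray, depths: np.ndarray,
                      habitat_map: np.ndarray) -> dict:
    """Mean per-cell relative abundance within each habitat.

    ``otu_column`` and ``depths`` are in row-major cell order of the
    flattened ``habitat_map``.
    """
    rel = np.asarray(otu_column, dtype=float) / np.asarray(depths, dtype=float)
    flat = np.asarray(habitat_map).ravel()
    out = {}
    for h in np.unique(flat):
        mask = flat == h
        if not mask.any():
            raise ValueError(f"habitat {h!r} has no cells")
        out[h] = float(rel[mask].mean())
    return out


def _stat_stack(R: np.ndarray, grid: HabitatGrid,
                maps: list[TransformedMap]) -> tuple[np.ndarray, list]:
    """Statistic for every (map, habitat, OTU): shape (n_maps, n_hab, n_otus)."""
    habitats = grid.habitats
    n_maps, n_hab = len(maps), len(habitats)
    W, H = grid.shape
    ind = np.empty((n_maps * n_hab, W * H))
    for mi, m in enumerate(maps):
        flat = m.apply(grid.habitat).ravel()
        for hi, h in enumerate(habitats):
            mask = flat == h
            ind[mi * n_hab + hi] = mask / mask.sum()
    stats = ind @ R  # (n_maps*n_hab, n_otus)
    return stats.reshape(n_maps, n_hab, R.shape[1]), habitats


def torus_test(table: OtuTable, grid: HabitatGrid, alpha: float = 0.05,
               exclude_identity: bool = True) -> pd.DataFrame:
    """Two-tailed torus-translation test for every OTU x habitat.

    Returns a tidy frame with columns ``otu_id, habitat, observed, null_n,
    null_rank, verdict, alpha``.  ``null_rank`` is the mid-rank of the
    observed statistic among the null values (number of null values below
    it, ties counting one half); positive/negative verdicts correspond to
    the rank falling above the 1 - alpha/2 (below the alpha/2) quantile.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if (table.depths == 0).any():
        bad = [s for s, d in zip(table.sample_ids, table.depths) if d == 0]
        raise ValueError(f"sample(s) with zero depth: {bad}")
    if (table.counts.sum(axis=0) == 0).any():
        j = int(np.argmax(table.counts.sum(axis=0) == 0))
        raise ValueError(f"OTU {table.otu_ids[j]!r} has zero total count; filter first")
    R, _ = _cell_matrix(table, grid)
    null_maps = enumerate_null_maps(grid, include_identity=not exclude_identity)
    stats_obs, habitats = _stat_stack(R, grid, [TransformedMap(0, 0, "identity")])
    stats_null, _ = _stat_stack(R, grid, null_maps)
    obs = stats_obs[0]                          # (n_hab, n_otus)
    tol = np.maximum(_TIE_ATOL, _TIE_RTOL * np.abs(obs))
    n_less = (stats_null < obs - tol).sum(axis=0)
    n_tie = (np.abs(stats_null - obs) <= tol).sum(axis=0)
    n_null = len(null_maps)
    rank = n_less + 0.5 * n_tie                 # mid-rank in [0, n_null]
    hi_cut = (1 - alpha / 2) * n_null
    lo_cut = (alpha / 2) * n_null
    verdict = np.where(rank >= hi_cut, "positive",
                       np.where(rank <= lo_cut, "negative", "none"))
    n_hab, n_otus = obs.shape
    return pd.DataFrame({
        "otu_id": np.repeat(table.otu_ids, n_hab),
        "habitat": np.tile(habitats, n_otus),
        "observed": obs.T.ravel(),
        "null_n": n_null,
        "null_rank": rank.T.ravel(),
        "verdict": verdict.T.ravel(),
        "alpha": alpha,
    })


def associated_otus(results: pd.DataFrame) -> pd.Series:
    """Per OTU, whether it carries >= 1 non-none verdict."""
    return (results["verdict"] != "none").groupby(results["otu_id"]).any()


def summarize_associations(results_by_domain: dict[str, pd.DataFrame]) -> AssociationSummary:
    """Pool per-domain torus results into the headline summary.

    Per domain: OTUs tested, OTUs associated with >= 1 habitat, and the
    percentage.  Pooled over domains: positively-associated OTU counts per
    habitat and their percentages of the pooled tested total.  Percentages
    are rounded half-up to two decimals.
    """
    if not results_by_domain:
        raise ValueError("no results to summarize")
    dom_rows = []
    pooled_pos: dict[str, int] = {}
    n_tested_total = 0
    n_all_hab = 0
    for domain, res in results_by_domain.items():
        if res.empty:
            raise ValueError(f"empty result frame for domain {domain!r}")
        assoc = associated_otus(res)
        n_tested = len(assoc)
        n_assoc = int(assoc.sum())
        dom_rows.append({"domain": domain, "n_tested": n_tested,
                         "n_associated": n_assoc,
                         "pct_associated": percent(n_assoc, n_tested)})
        n_tested_total += n_tested
        pos = res[res["verdict"] == "positive"]
        for h, n in pos.groupby("habitat").size().items():
            pooled_pos[h] = pooled_pos.get(h, 0) + int(n)
        n_hab = res["habitat"].nunique()
        per_otu_sig = (res["verdict"] != "none").groupby(res["otu_id"]).sum()
        n_all_hab += int((per_otu_sig == n_hab).sum())
    habs = sorted(set().union(*(r["habitat"].unique() for r in results_by_domain.values())))
    hab_df = pd.DataFrame({
        "habitat": habs,
        "n_positive": [pooled_pos.get(h, 0) for h in habs],
    })
    hab_df["pct_of_tested"] = [percent(n, n_tested_total) for n in hab_df["n_positive"]]
    return AssociationSummary(pd.DataFrame(dom_rows), hab_df,
                              n_tested_total, n_all_hab)
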