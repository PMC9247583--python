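"""Community summaries: rare-OTU filtering, core/dominant subsets, richness
comparisons, Venn partitioning across stages, accumulation curves and
composition stacks.

Abundance subsets follow the convention of ranking taxa by total reads:
"core" keeps the top 10% of OTUs and "dominant" the top 0.5%.  The rare-OTU
filter removes OTUs whose overall relative abundance is below 0.01% of the
grand read total; an OTU exactly at the threshold is retained.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import OtuTable

CORE_FRACTION = 0.10
DOMINANT_FRACTION = 0.005
RARE_THRESHOLD = 1e-4


@dataclass(frozen=True)
class SubsetRule:
    """Which OTUs to keep: all, the core (top 10% by total reads) or the
    dominant (top 0.5%) fraction.  Ties at the rank boundary are broken by
    OTU id ascending so the selection is reproducible."""

    kind: str = "all"  # all | core | dominant
    fraction: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("all", "core", "dominant"):
            raise ValueError(f"unknown subset kind {self.kind!r}")
        if self.fraction is not None and not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")

    @property
    def effective_fraction(self) -> float:
        if self.fraction is not None:
            return self.fraction
        return {"all": 1.0, "core": CORE_FRACTION, "dominant": DOMINANT_FRACTION}[self.kind]


@dataclass
class VennPartition:
    """Counts of OTUs per non-empty stage subset (2^k - 1 regions)."""

    region_counts: dict[frozenset, int]
    absent_count: int  # OTUs with zero total everywhere (reported separately)

    @property
    def total_present(self) -> int:
        return sum(self.region_counts.values())

    def unique_count(self) -> int:
        """OTUs confined to exactly one stage, summed over stages."""
        return sum(n for s, n in self.region_counts.items() if len(s) == 1)

    def shared_all_count(self) -> int:
        """OTUs present in every stage."""
        k = max((len(s) for s in self.region_counts), default=0)
        full = [s for s in self.region_counts if len(s) == k]
        return self.region_counts[full[0]] if k and len(full) == 1 else 0


def filter_rare(table: OtuTable, threshold: float = RARE_THRESHOLD) -> OtuTable:
    """Drop OTUs whose overall relative abundance is below ``threshold``.

    Relative abundance is (OTU total reads) / (grand total reads) on the
    input table.  The boundary is inclusive: abundance == threshold is kept.
    """
    if not (0 <= threshold < 1):
        raise ValueError("threshold must be in [0, 1)")
    totals = table.counts.sum(axis=0)
    grand = totals.sum()
    keep = totals / grand >= threshold
    if not keep.any():
        raise ValueError("rare-OTU filter removed every OTU")
    kept_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    return table.select_otus(kept_ids)


def select_subset(table: OtuTable, rule: SubsetRule) -> OtuTable:
    if table.n_otus == 0:
        raise ValueError("empty OTU table")
    if rule.kind == "all" and rule.fraction is None:
        return table
    n_keep = max(1, math.ceil(rule.effective_fraction * table.n_otus))
    totals = table.counts.sum(axis=0)
    order = sorted(range(table.n_otus), key=lambda j: (-totals[j], table.otu_ids[j]))
    kept = sorted(order[:n_keep], key=lambda j: table.otu_ids[j])
    return table.select_otus([table.otu_ids[j] for j in kept])


def richness(table: OtuTable) -> pd.Series:
    """Number of OTUs observed (count > 0) per sample."""
    return pd.Series((table.counts > 0).sum(axis=1), index=table.sample_ids,
                     name="richness")


def kruskal_wallis(values, groups, pairwise: bool = False) -> dict:
    """Tie-corrected Kruskal-Wallis H test across >=2 groups.

    Returns ``{"H", "p", "df", "pairwise"}``; the pairwise entry is a
    DataFrame of Dunn's z-tests with Holm-adjusted p-values when requested.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for g, s in zip(labels, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if np.ptp(values) == 0:  # all observations identical: no separation
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*samples)
        H = float(H)
        p = float(p)
    out = {"H": H, "p": p, "df": len(samples) - 1, "pairwise": None}
    if pairwise:
        out["pairwise"] = _dunn_holm(values, groups, labels)
    return out


def _dunn_holm(values: np.ndarray, groups: np.ndarray, labels) -> pd.DataFrame:
    from statsmodels.stats.multitest import multipletests

    n = len(values)
    ranks = stats.rankdata(values)
    # tie correction term of Dunn's variance
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12 * (n - 1))
    var_base = n * (n + 1) / 12 - tie_term
    rows = []
    for a, b in combinations(labels, 2):
        ra, rb = ranks[groups == a], ranks[groups == b]
        se = math.sqrt(var_base * (1 / len(ra) + 1 / len(rb)))
        z = (ra.mean() - rb.mean()) / se
        rows.append({"group_a": a, "group_b": b, "z": z,
                     "p_raw": 2 * stats.norm.sf(abs(z))})
    df = pd.DataFrame(rows)
    df["p_holm"] = multipletests(df["p_raw"], method="holm")[1]
    return df


def venn_partition(table: OtuTable, stage_of_sample: dict) -> VennPartition:
    """Assign each OTU to the subset of stages where its summed count > 0."""
    stages = sorted(set(stage_of_sample.values()))
    if not stages:
        raise ValueError("need at least one stage")
    masks = {h: np.array([stage_of_sample[s] == h for s in table.sample_ids])
             for h in stages}
    present = {h: table.counts[m].sum(axis=0) > 0 for h, m in masks.items()}
    region_counts = {frozenset(sub): 0
                     for r in range(1, len(stages) + 1)
                     for sub in combinations(stages, r)}
    absent = 0
    for j in range(table.n_otus):
        region = frozenset(h for h in stages if present[h][j])
        if region:
            region_counts[region] += 1
        else:
            absent += 1
    return VennPartition(region_counts, absent)


def accumulation_curve(table: OtuTable, n_perm: int = 100,
                       seed: int = 0, method: str = "random") -> pd.DataFrame:
    """Sample-based species accumulation curve.

    ``method="random"``: for ``n_perm`` random orderings of samples, the
    cumulative number of distinct OTUs after 1..n samples, reported as the
    per-depth mean and sd.  ``method="exact"``: the analytic mean over all
    orderings, ``E[S(d)] = sum_j 1 - C(n - k_j, d)/C(n, d)`` with ``k_j``
    the number of samples containing OTU j (sd column is NaN).  Either way
    the mean at full depth equals the table's total richness exactly.
    """
    presence = table.counts > 0
    if method == "exact":
        n = table.n_samples
        k = presence.sum(axis=0)
        from scipy.special import gammaln

        def log_comb(a, b):
            return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

        means = []
        for d in range(1, n + 1):
            with np.errstate(invalid="ignore"):
                miss = np.where(n - k >= d,
                                np.exp(log_comb(n - k, d) - log_comb(n, d)), 0.0)
            means.append(float((k > 0).sum() - miss[k > 0].sum()))
        return pd.DataFrame({"n_samples": np.arange(1, n + 1),
                             "mean_richness": means,
                             "sd_richness": np.nan})
    if method != "random":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    curves = np.empty((n_perm, table.n_samples), dtype=np.int64)
    for i in range(n_perm):
        order = rng.permutation(table.n_samples)
        seen = np.logical_or.accumulate(presence[order], axis=0)
        curves[i] = seen.sum(axis=1)
    return pd.DataFrame({
        "n_samples": np.arange(1, table.n_samples + 1),
        "mean_richness": curves.mean(axis=0),
        "sd_richness": curves.std(axis=0, ddof=0),
    })


def rarefaction_curve(table: OtuTable, depths: np.ndarray) -> pd.DataFrame:
    """Read-based rarefaction: expected pooled richness at given read depths.

    Uses the exact hypergeometric expectation
    ``E[S(d)] = sum_j 1 - C(T - t_j, d) / C(T, d)`` over the pooled table,
    where ``t_j`` is OTU j's total and ``T`` the grand total.
    """
    totals = table.counts.sum(axis=0)
    T = totals.sum()
    from scipy.special import gammaln

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rows = []
    for d in np.asarray(depths, dtype=np.int64):
        if d < 0 or d > T:
            raise ValueError(f"depth {d} outside [0, {T}]")
        with np.errstate(invalid="ignore"):
            miss = np.where(T - totals >= d,
                            np.exp(log_comb(T - totals, d) - log_comb(T, d)), 0.0)
        rows.append({"depth": int(d), "expected_richness": float((1 - miss).sum())})
    return pd.DataFrame(rows)


def composition_stack(table: OtuTable, stage_of_sample: dict,
                      taxonomy: pd.Series | None = None,
                      top_k: int = 30) -> pd.DataFrame:
    """Per-stage relative abundance of the overall top-k taxa plus "other".

    ``taxonomy`` maps otu_id -> taxon name at the desired rank; OTUs with no
    entry are binned as "unclassified".  Without a taxonomy, OTU ids are the
    taxa.  Rows (stages) sum to 1.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if taxonomy is None:
        taxa = pd.Series(table.otu_ids, index=table.otu_ids)
    else:
        taxa = pd.Series(table.otu_ids, index=table.otu_ids).map(taxonomy)
        taxa = taxa.fillna("unclassified")
    counts = table.to_dataframe()
    by_taxon = counts.T.groupby(taxa.loc[counts.columns].to_numpy()).sum().T
    stage = pd.Series({s: stage_of_sample[s] for s in table.sample_ids})
    per_stage = by_taxon.groupby(stage.loc[by_taxon.index].to_numpy()).sum()
    top = per_stage.sum(axis=0).sort_values(ascending=False, kind="stable")
    keep = list(top.index[:top_k])
    out = per_stage[keep].copy()
    out["other"] = per_stage.drop(columns=keep).sum(axis=1)
    out = out.div(out.sum(axis=1), axis=0)
    out.index.name = "stage"
    return out
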