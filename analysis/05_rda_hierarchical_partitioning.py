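#!/usr/bin/env python
"""Hellinger RDA of each domain's composition on the 11 environmental
covariates: constrained variance, 999-permutation significance (global and
per predictor), and hierarchical partitioning of predictor importance.

Reads results/data/, writes results/ordination/.
"""
from pathlib import Path

import pandas as pd

from soilsucc import io, ordination, summary

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 7


def main() -> None:
    out = ROOT / "ordination"
    out.mkdir(parents=True, exist_ok=True)
    env = io.read_env_table(ROOT / "data" / "env.tsv")
    for domain in ("bacteria", "fungi"):
        t = io.read_otu_table(ROOT / "data" / f"counts_{domain}.tsv",
                              domain_label=domain)
        ft = summary.filter_rare(t)
        X = env.aligned_to(ft)
        res = ordination.rda_analysis(ft, X, n_perm=999, seed=SEED)
        o = res["ordination"]
        hp = res["hierarchical_partition"]
        print(f"{domain}: constrained R2 = {100 * o.constrained_R2:.1f}% "
              f"(adjusted {100 * o.adjusted_R2:.1f}%), global p = {o.global_p:.3g}")
        table1 = pd.DataFrame({"predictor": list(o.per_predictor_p),
                               "p_value": list(o.per_predictor_p.values())})
        table1["significance"] = table1["p_value"].map(
            ordination.significance_stars)
        table1.to_csv(out / f"rda_pvalues_{domain}.tsv", sep="\t", index=False)
        o.site_scores.assign(sample_id=ft.sample_ids).to_csv(
            out / f"rda_sites_{domain}.tsv", sep="\t", index=False)
        hp.contributions.sort_values("independent_contribution",
                                     ascending=False).to_csv(
            out / f"hierpart_{domain}.tsv", sep="\t", index=False)
        top = hp.contributions.nlargest(2, "independent_contribution")
        print("  top predictors by independent contribution: "
              + ", ".join(f"{r.predictor} ({100 * r.independent_contribution:.1f}%)"
                          for r in top.itertuples()))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
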