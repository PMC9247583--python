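#!/usr/bin/env python
"""Community-level summaries per domain: rare-OTU filtering, per-quadrat
richness with a Kruskal-Wallis comparison across succession stages, Venn
partitioning of OTUs among stages, and sample-based accumulation curves.

Reads results/data/, writes results/summaries/.
"""
from pathlib import Path

import pandas as pd

from soilsucc import io, summary

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "summaries"
    out.mkdir(parents=True, exist_ok=True)
    meta = io.read_metadata(ROOT / "data" / "metadata.tsv")
    stage_of = dict(zip(meta["sample_id"], meta["stage"]))
    for domain in ("bacteria", "fungi"):
        t = io.read_otu_table(ROOT / "data" / f"counts_{domain}.tsv",
                              domain_label=domain)
        ft = summary.filter_rare(t)
        print(f"{domain}: {t.n_otus} -> {ft.n_otus} OTUs after <0.01% filter")

        rich = summary.richness(ft)
        kw = summary.kruskal_wallis(
            rich.to_numpy(), [stage_of[s] for s in ft.sample_ids], pairwise=True)
        print(f"  richness Kruskal-Wallis H={kw['H']:.2f}, p={kw['p']:.3g}")
        df = rich.rename_axis("sample_id").reset_index()
        df["stage"] = df["sample_id"].map(stage_of)
        df.to_csv(out / f"richness_{domain}.tsv", sep="\t", index=False)
        kw["pairwise"].to_csv(out / f"richness_dunn_{domain}.tsv",
                              sep="\t", index=False)

        venn = summary.venn_partition(ft, stage_of)
        rows = [{"stages": "+".join(sorted(k)), "n_otus": v}
                for k, v in sorted(venn.region_counts.items(),
                                   key=lambda kv: (len(kv[0]), sorted(kv[0])))]
        pd.DataFrame(rows).to_csv(out / f"venn_{domain}.tsv", sep="\t",
                                  index=False)
        print(f"  Venn: {venn.unique_count()} stage-unique, "
              f"{venn.shared_all_count()} shared by all four stages")

        acc = summary.accumulation_curve(ft, n_perm=200, seed=0)
        acc.to_csv(out / f"accumulation_{domain}.tsv", sep="\t", index=False)
        stack = summary.composition_stack(ft, stage_of)
        stack.to_csv(out / f"composition_{domain}.tsv", sep="\t")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
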