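#!/usr/bin/env python
"""Torus-translation habitat-association test at the OTU level, per domain,
plus the pooled summary (percent associated, positives per stage) and a
check against the generator's ground truth.

Reads results/data/, writes results/torus/.
"""
from pathlib import Path

import pandas as pd

from soilsucc import io, summary, torus

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "torus"
    out.mkdir(parents=True, exist_ok=True)
    meta = io.read_metadata(ROOT / "data" / "metadata.tsv")
    grid = torus.build_composite_grid(meta, layout="2x2")
    results = {}
    for domain in ("bacteria", "fungi"):
        t = io.read_otu_table(ROOT / "data" / f"counts_{domain}.tsv",
                              domain_label=domain)
        ft = summary.filter_rare(t)
        res = torus.torus_test(ft, grid, alpha=0.05)
        res.to_csv(out / f"associations_{domain}.tsv", sep="\t", index=False)
        results[domain] = res

        truth = pd.read_csv(ROOT / "data" / f"truth_{domain}.tsv", sep="\t")
        truth = truth.set_index("otu_id").reindex(ft.otu_ids)
        pos = res[res["verdict"] == "positive"].groupby("otu_id")["habitat"].agg(set)
        spec = truth[truth["is_specialist"].fillna(False)]
        hits = sum(r["preferred_habitat"] in pos.get(o, set())
                   for o, r in spec.iterrows())
        if len(spec):
            print(f"{domain}: {hits}/{len(spec)} tested specialists recovered "
                  f"with their true habitat ({100 * hits / len(spec):.1f}%)")

    summ = torus.summarize_associations(results)
    summ.per_domain.to_csv(out / "association_summary.tsv", sep="\t", index=False)
    summ.positive_by_habitat.to_csv(out / "association_by_habitat.tsv",
                                    sep="\t", index=False)
    for _, r in summ.per_domain.iterrows():
        print(f"{r['domain']}: {r['n_associated']}/{r['n_tested']} OTUs "
              f"associated with >=1 stage ({r['pct_associated']}%)")
    print(f"{summ.n_associated_all_habitats} OTUs significant in all four "
          f"stages (pooled)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
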