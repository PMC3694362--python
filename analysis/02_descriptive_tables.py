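"""Descriptive statistics: prevalence with Wald CIs and burden summaries.

Recomputes the study's recomputable descriptive numbers from the published
margins (prevalence CIs, mean ticks/deer, census mean), then produces the
same tables for the simulated cohort from step 01.

Writes summaries per grouping key and prevalence.json under results/descriptives/.
"""

import json
from pathlib import Path

import pandas as pd

from tickburden import studydata
from tickburden.descriptives import prevalence_ci, summarize_burdens

OUT = Path("results/descriptives")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    par = studydata.PARASITISM

    print("published margins, recomputed:")
    prev = {}
    for label, (k, n) in (
        ("total", (182, 306)), ("male", (146, 182)), ("female", (36, 124)),
    ):
        p, lo, hi = prevalence_ci(k, n).rounded()
        prev[label] = {"k": k, "n": n, "prevalence_pct": p, "ci": [lo, hi]}
        print(f"  prevalence {label:6s}: {p}% (95% CI {lo}-{hi})")
    print(f"  mean counted ticks/deer : {par['ticks_counted'] / 306:.1f}")
    print(f"  mean collected ticks/deer: {par['ticks_collected'] / 306:.1f}")
    print(f"  deer census mean (2002-2010): {studydata.CENSUS['deer'].mean():.1f}")
    (OUT / "prevalence.json").write_text(json.dumps(prev, indent=2) + "\n")

    hosts_path = Path("results/sim/hosts.csv")
    if hosts_path.exists():
        hosts = pd.read_csv(hosts_path)
        for key in ("sex", "age_class", "year", "season"):
            table = summarize_burdens(hosts, by=[key])
            table.to_csv(OUT / f"summary_by_{key}.csv", index=False)
        print(f"simulated-cohort summaries written to {OUT}/ (by sex, age, year, season)")
    else:
        print("no simulated cohort found; run 01_simulate_cohort.py first")


if __name__ == "__main__":
    main()
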