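"""Survival of Scn1b-null mice vs PV-interneuron-restricted deletion.

Simulates the two lethal cohorts (constitutive null, median ~P18, n=60;
PV-Cre conditional, median ~P25, n=62), estimates Kaplan-Meier medians
and runs the Mantel-Cox log-rank test.  Writes results/survival.csv.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from ephysepi import stats_survival as st
from ephysepi import synthetic as sd


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    records = sd.simulate_survival(
        {"null": (sd.discrete_hazard(18, 2.0), 60),
         "pv_cre": (sd.discrete_hazard(25, 3.0), 62)},
        seed=args.seed)
    rows = []
    for g in ("null", "pv_cre"):
        curve, median = st.km_estimate(records, g)
        rows.append({"group": g, "n": sum(r.group == g for r in records),
                     "deaths": sum(r.event for r in records if r.group == g),
                     "median_day": median})
    chi2, p = st.logrank(records)
    out = Path(args.out)
    out.mkdir(exist_ok=True)
    df = pd.DataFrame(rows)
    df["logrank_chi2"] = chi2
    df["logrank_p"] = p
    df.to_csv(out / "survival.csv", index=False)
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        out / "survival_records.csv", index=False)
    print(df.to_string(index=False))
    print(f"\nMedian survival separates by ~1 week; "
          f"log-rank chi2={chi2:.1f}, p={p:.2e}.")


if __name__ == "__main__":
    main()
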