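"""Red List summary of the synthetic assessment table.

Reproduces the tabulation layer of a global extinction-risk assessment:
category counts under both possibly-extinct scenarios, the three
threatened-proportion estimators (data-deficiency bounds), threat and
habitat profiles under the standard roll-ups, and a chi-squared
comparison of threat prevalences between extinct-or-possibly-extinct
and threatened species.

Usage: python analysis/02_redlist_summary.py [--data results/data]
"""

import argparse
from pathlib import Path

import pandas as pd

from surrosai import chisq_compare, profile, proportion_threatened, tally
from surrosai import io as sio
from surrosai.redlist import THREATENED

# roll-up of threat codes to the display groups used for freshwater faunas
THREAT_ROLLUP = {
    "pollution": ["9"],
    "dams and water management": ["7.2"],
    "agriculture": ["2.1", "2.2", "2.3"],
    "invasive species and disease": ["8.1", "8.3", "8.4", "8.5", "8.6"],
    "hunting and fishing": ["5.1", "5.4"],
    "logging": ["5.2", "5.3"],
    "urban development": ["1"],
    "climate change and severe weather": ["11"],
}
HABITAT_ROLLUP = {
    "permanent rivers": ["5.1"],
    "permanent lakes": ["5.5"],
    "seasonal rivers": ["5.2"],
    "permanent pools": ["5.7"],
    "bogs and marshes": ["5.4"],
    "springs and oases": ["5.9"],
    "karst": ["5.18"],
    "forest": ["1"],
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    records = sio.read_assessments(Path(args.data) / "assessments.csv")
    rows = []
    for scenario in ("baseline", "pe_as_extinct"):
        t = tally(records, scenario)
        row = {"scenario": scenario, **{f"n_{c}": n for c, n in t.counts.items()},
               "N": t.N}
        for est in ("lower", "midpoint", "upper"):
            row[f"pct_threatened_{est}"] = round(
                100 * proportion_threatened(t, est), 1
            )
        rows.append(row)
    tallies = pd.DataFrame(rows)
    tallies.to_csv(out / "category_tallies.csv", index=False)

    base = tallies.iloc[0]
    print(f"{base['N']} species assessed; "
          f"best estimate {base['pct_threatened_midpoint']}% threatened "
          f"(bounds {base['pct_threatened_lower']}-{base['pct_threatened_upper']}% "
          f"from {base['n_DD']} data-deficient species)")

    threatened = frozenset(THREATENED)
    lost = frozenset({"EX", "EW"})
    prof_rows = []
    for axis, rollup in (("threats", THREAT_ROLLUP), ("habitats", HABITAT_ROLLUP)):
        p = profile(records, axis, rollup, subset=threatened, group="threatened")
        for g, v in sorted(p.proportions.items(), key=lambda kv: -kv[1]):
            prof_rows.append({"axis": axis, "group": g, "proportion": round(v, 3),
                              "denominator": p.denominator})
        if axis == "threats":
            print(f"threat profile over {p.denominator} coded threatened species; "
                  f"{p.multi_coded_fraction:.0%} face more than one threat group")
    pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)

    # are any threats over-represented among lost species vs threatened ones?
    lost_recs = [r for r in records if r.category in lost or
                 (r.category == "CR" and r.tags)]
    thr_recs = [r for r in records if r.category in threatened and not r.tags]
    lost_coded = [r for r in lost_recs if r.threats]
    thr_coded = [r for r in thr_recs if r.threats]
    if len(lost_coded) >= 5:
        chi_rows = []
        for g, prefixes in THREAT_ROLLUP.items():
            def hits(recs):
                return sum(
                    any(c == p or c.startswith(p + ".")
                        for c in r.threats for p in prefixes)
                    for r in recs
                )
            try:
                chi2, df, pval = chisq_compare(
                    hits(lost_coded), len(lost_coded), hits(thr_coded), len(thr_coded)
                )
            except ValueError:
                continue
            chi_rows.append({"threat": g, "chi2": round(chi2, 3), "p": round(pval, 4)})
        pd.DataFrame(chi_rows).to_csv(out / "threat_chisq.csv", index=False)
        print(f"chi-squared threat comparisons written for {len(chi_rows)} groups "
              f"({len(lost_coded)} lost vs {len(thr_coded)} threatened species)")
    else:
        print("too few extinct/possibly-extinct species for chi-squared comparisons")


if __name__ == "__main__":
    main()
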