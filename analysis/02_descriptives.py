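"""Baseline characteristics by referral status (development step 1).

Scores the eligible cohort, derives the analysis variables, and tabulates
the referred / not-referred descriptive comparison in the style of the
reference cohort's baseline table.
"""

import argparse
from pathlib import Path

import pandas as pd

import sciatica_triage as st

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort_eligible.csv"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

df, _ = st.read_cohort(args.cohort)
df = st.prepare_cohort(df)

rows = []
ref = df[df["referred"] == True]  # noqa: E712 - boolean dtype
non = df[df["referred"] == False]  # noqa: E712

def add_mean(label, col):
    rows.append({
        "characteristic": label,
        "referred": f"{ref[col].mean():.1f} ({ref[col].astype(float).std():.1f})",
        "not_referred": f"{non[col].mean():.1f} ({non[col].astype(float).std():.1f})",
    })

def add_prop(label, series_ref, series_non):
    rows.append({
        "characteristic": label,
        "referred": f"{int(series_ref.sum())} ({100 * series_ref.mean():.1f})",
        "not_referred": f"{int(series_non.sum())} ({100 * series_non.mean():.1f})",
    })

add_mean("Age (years), mean (SD)", "age")
add_prop("Female", ref["sex"] == "female", non["sex"] == "female")
add_mean("Leg pain usual intensity, mean (SD)", "leg_pain_usual")
add_prop("Leg pain worse than back pain",
         ref["leg_worse_than_back"].dropna().astype(bool),
         non["leg_worse_than_back"].dropna().astype(bool))
for lvl in ("low", "medium", "high"):
    add_prop(f"STarT Back risk: {lvl}",
             ref["startback_risk"].dropna() == lvl,
             non["startback_risk"].dropna() == lvl)
add_prop("Myotomal weakness",
         ref["myotomal_weakness"].dropna().astype(bool),
         non["myotomal_weakness"].dropna().astype(bool))
add_prop("Sensory deficits", ref["c_sensory"].dropna().astype(bool),
         non["c_sensory"].dropna().astype(bool))
add_prop("Neural tension positive",
         ref["neural_tension_positive"].dropna().astype(bool),
         non["neural_tension_positive"].dropna().astype(bool))

table = pd.DataFrame(rows)
table.to_csv(args.outdir / "descriptives_by_referral.csv", index=False)
print(f"n referred = {len(ref)}, n not referred = {len(non)}")
print(table.to_string(index=False))
print(f"\nwrote {args.outdir/'descriptives_by_referral.csv'}")
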