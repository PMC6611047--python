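"""Block-wise selection of factors associated with specialist referral
(development step 2a).

Runs univariable fits per domain, the collinearity screen (with current
leg pain as the clinically chosen representative of the correlated
pain/symptom block), within-block multivariable models, and backward
elimination in the overall model.  Writes the full selection trace.
"""

import argparse
from pathlib import Path

import yaml

import sciatica_triage as st

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort_eligible.csv"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

df, _ = st.read_cohort(args.cohort)
df = st.prepare_cohort(df)

trace = st.blockwise_selection(df)
(args.outdir / "selection_trace.yaml").write_text(
    yaml.safe_dump(trace.to_dict(), sort_keys=False)
)
print(trace.report())
print(f"\nfinal model variables: {trace.final_variables}")
print(f"wrote {args.outdir/'selection_trace.yaml'}")
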