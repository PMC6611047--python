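"""Internal validation of the final referral model (development step 2b).

Apparent AUC with DeLong CI, 500-replicate enhanced-bootstrap optimism
correction, and the apparent calibration slope.
"""

import argparse
import json
from pathlib import Path

import sciatica_triage as st

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort_eligible.csv"))
parser.add_argument("--replicates", type=int, default=500)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

df, _ = st.read_cohort(args.cohort)
df = st.prepare_cohort(df)

report = st.bootstrap_optimism(df, n_replicates=args.replicates, seed=args.seed)
(args.outdir / "validation.json").write_text(json.dumps(report.to_dict(), indent=2))
print(report)
print(f"wrote {args.outdir/'validation.json'}")
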