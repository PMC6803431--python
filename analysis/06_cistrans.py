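"""Cis/trans decomposition of GH regulatory divergence, per sex.

Combines the parental expression divergence A = log2(NN/BB) from the
group summaries with the hybrid allelic divergence B = log2(mat/pat)
from the adult ASE cohorts, and classifies the interaction by the sign
of B and A-B. Output: results/cistrans.json.
"""

import json
from pathlib import Path

import pandas as pd

from tilapia_gh.ase import cohort_bias_test
from tilapia_gh.cistrans import decompose
from tilapia_gh.expression import GroupExpressionSummary

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    summary_df = pd.read_csv(RESULTS / "group_summary.tsv", sep="\t")
    summaries = [
        GroupExpressionSummary(r.group, r.sex, int(r.n), r.mean_rq, r.sd_rq)
        for r in summary_df.itertuples()
    ]
    ase_calls = pd.read_csv(RESULTS / "ase_calls.tsv", sep="\t")

    out = {}
    for sex in ("male", "female"):
        cohort = ase_calls[(ase_calls.sex == sex) & (ase_calls.condition == "adult")]
        ase_res = cohort_bias_test(cohort["maternal_fraction"], f"{sex}/adult")
        res = decompose(summaries, ase_res, sex)
        print(f"{sex}: A={res.A:.3f}, B={res.B:.3f}, A-B={res.trans:.3f} "
              f"-> {res.category}")
        out[sex] = {"A": res.A, "B": res.B, "trans": res.trans,
                    "category": res.category, "extended": res.extended}

    (RESULTS / "cistrans.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
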