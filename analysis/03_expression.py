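"""Relative GH expression and inheritance-mode classification.

Normalises GH Ct to the reference gene (2^-ddCt, calibrated on the
blue-tilapia group), summarises each group x sex, and classifies the
hybrid against the midparent value. Outputs: results/rq.tsv,
results/group_summary.tsv, results/inheritance.json.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from tilapia_gh.expression import (
    classify_by_sex,
    delta_delta_ct,
    read_ct_table,
    summarize_groups,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ct = read_ct_table(RESULTS / "sim" / "ct.tsv")
    rq = delta_delta_ct(ct, calibrator_group="BB")
    rq.to_csv(RESULTS / "rq.tsv", sep="\t", index=False)

    summaries = summarize_groups(rq)
    pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
        RESULTS / "group_summary.tsv", sep="\t", index=False
    )
    for s in summaries:
        print(f"{s.group} {s.sex}: mean RQ {s.mean_rq:.2f} +/- {s.sem_rq:.2f} (n={s.n})")

    calls = classify_by_sex(rq)
    payload = {}
    for sex, call in calls.items():
        print(f"{sex}: {call.category} (MPV {call.mpv:.2f}, "
              f"p vs MPV {call.p_values['vs_mpv']:.2g})")
        payload[sex] = {"category": call.category, "nonadditive": call.nonadditive,
                        "mpv": call.mpv, "p_values": call.p_values}
    (RESULTS / "inheritance.json").write_text(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
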