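"""Allele-specific expression: per-individual and cohort-level bias.

Tests every hybrid individual's maternal/paternal read counts against
1:1 (exact binomial), summarises each sex x condition cohort (one-sample
t of maternal % vs 50), and compares fed vs fasted cohorts. Outputs:
results/ase_calls.tsv, results/ase_cohorts.json.
"""

import json
from pathlib import Path

from tilapia_gh.ase import (
    call_individuals,
    cohort_bias_test,
    condition_comparison,
    read_allele_counts,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_allele_counts(RESULTS / "sim" / "allele_counts.tsv")
    calls = call_individuals(records)
    calls.to_csv(RESULTS / "ase_calls.tsv", sep="\t", index=False)

    cohorts = {}
    for (sex, condition), sub in calls.groupby(["sex", "condition"], sort=False):
        res = cohort_bias_test(sub["maternal_fraction"], f"{sex}/{condition}")
        n_mat = (sub.direction == "maternal-biased").sum()
        n_pat = (sub.direction == "paternal-biased").sum()
        print(f"{res.cohort}: maternal {res.mean_maternal_pct:.2f}% "
              f"(p={res.p_value:.2g}); {n_mat} maternal-biased, "
              f"{n_pat} paternal-biased of {res.n}")
        cohorts[res.cohort] = {"mean_maternal_pct": round(res.mean_maternal_pct, 2),
                               "sd_pct": round(res.sd_pct, 2), "n": res.n,
                               "p_value": res.p_value, "direction": res.direction}

    fed = calls[calls.condition == "fed"]["maternal_fraction"]
    fasted = calls[calls.condition == "fasted"]["maternal_fraction"]
    cmp_res = condition_comparison(fed, fasted)
    print(f"fed vs fasted: p={cmp_res['p_value']:.2g} -> {cmp_res['decision']}")

    (RESULTS / "ase_cohorts.json").write_text(
        json.dumps({"cohorts": cohorts, "fed_vs_fasted": cmp_res}, indent=2)
    )


if __name__ == "__main__":
    main()
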