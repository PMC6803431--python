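"""End-to-end orchestration: simulate -> SNPs -> expression -> growth ->
ASE -> cis/trans, with plain TSV/JSON intermediates so every stage can be
re-run and audited independently."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import ase as ase_mod
from . import cistrans as ct_mod
from . import expression as expr_mod
from . import growth as growth_mod
from .align import align_pair
from .errors import ValidationError
from .primers import STUDY_PRIMERS, amplicon_size, site_in_amplicon, write_primer_table
from .simulate import ScenarioConfig, UTR5_LEN, generate_bundle
from .variants import call_fixed_differences, read_parental_fasta, write_snp_report

log = logging.getLogger("tilapia_gh")


@dataclass(frozen=True)
class RunConfig:
    outdir: Path
    seed: int = 0
    alpha: float = 0.05
    epsilon: float = 0.1
    calibrator: str = expr_mod.PATERNAL_GROUP

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def run_pipeline(config: RunConfig, scenario: ScenarioConfig | None = None) -> dict:
    """Run every stage on a freshly simulated scenario; returns the report
    dict (also written to <outdir>/report.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = scenario or ScenarioConfig(seed=config.seed)

    bundle = generate_bundle(scenario, outdir / "sim")
    for p in (bundle.parental_fasta_path, bundle.ct_table_path,
              bundle.allele_counts_path, bundle.growth_table_path):
        log.info("stage=simulate seed=%d wrote %s sha=%s", scenario.seed, p, _hash_file(p))

    # --- SNPs and primer arithmetic
    nile, blue = read_parental_fasta(bundle.parental_fasta_path)
    alignment = align_pair(nile, blue)
    sites = call_fixed_differences(alignment, utr5_len=UTR5_LEN)
    write_snp_report(sites, outdir / "snps.tsv")
    write_primer_table(STUDY_PRIMERS, outdir / "primers.tsv")
    pyr = STUDY_PRIMERS["pyr-GH"]
    assay_site = next((s for s in sites if site_in_amplicon(s.position, pyr)), None)
    snp_block = {
        "n_sites": len(sites),
        "positions": [s.position for s in sites],
        "alleles": {str(s.position): f"{s.nile_allele}/{s.blue_allele}" for s in sites},
        "amplicons_bp": {name: amplicon_size(p) for name, p in STUDY_PRIMERS.items()},
        "pyrosequencing_site": None if assay_site is None else {
            "position": assay_site.position,
            "offset_in_amplicon": site_in_amplicon(assay_site.position, pyr),
        },
    }
    log.info("stage=snps n_sites=%d", len(sites))

    # --- expression
    ct = expr_mod.read_ct_table(bundle.ct_table_path)
    rq = expr_mod.delta_delta_ct(ct, calibrator_group=config.calibrator)
    rq.to_csv(outdir / "rq.tsv", sep="\t", index=False)
    summaries = expr_mod.summarize_groups(rq)
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
        outdir / "group_summary.tsv", sep="\t", index=False
    )
    calls = expr_mod.classify_by_sex(rq, alpha=config.alpha)
    expr_block = {
        sex: {"category": c.category, "nonadditive": c.nonadditive,
              "mpv": c.mpv, "p_values": c.p_values}
        for sex, c in calls.items()
    }
    log.info("stage=expression calls=%s", {s: c.category for s, c in calls.items()})

    # --- growth
    records = growth_mod.read_growth_table(bundle.growth_table_path)
    metrics = growth_mod.growth_metrics(records)
    metrics.to_csv(outdir / "growth_metrics.tsv", sep="\t", index=False)
    growth_block = {
        "group_mean_final_g": metrics.groupby("group")["final_g"].mean().to_dict(),
        "group_mean_sgr": metrics.groupby("group")["sgr_pct_per_day"].mean().to_dict(),
        "comparison": growth_mod.compare_growth(metrics, alpha=config.alpha),
    }

    # --- ASE
    count_records = ase_mod.read_allele_counts(bundle.allele_counts_path)
    ind_calls = ase_mod.call_individuals(count_records, alpha=config.alpha)
    ind_calls.to_csv(outdir / "ase_calls.tsv", sep="\t", index=False)
    cohorts = {}
    for (sex, condition), sub in ind_calls.groupby(["sex", "condition"], sort=False):
        res = ase_mod.cohort_bias_test(sub["maternal_fraction"], f"{sex}/{condition}")
        cohorts[f"{sex}/{condition}"] = {
            "mean_maternal_pct": round(res.mean_maternal_pct, 2),
            "sd_pct": round(res.sd_pct, 2),
            "n": res.n,
            "p_value": res.p_value,
            "direction": res.direction,
        }
    fed = ind_calls[ind_calls["condition"] == "fed"]["maternal_fraction"]
    fasted = ind_calls[ind_calls["condition"] == "fasted"]["maternal_fraction"]
    condition_block = (
        ase_mod.condition_comparison(fed, fasted, alpha=config.alpha)
        if len(fed) >= 2 and len(fasted) >= 2 else None
    )
    ase_block = {"cohorts": cohorts, "fed_vs_fasted": condition_block}

    # --- cis/trans (adult cohorts, per sex)
    cistrans_block = {}
    for sex in ("male", "female"):
        key = f"{sex}/adult"
        if key not in cohorts:
            continue
        cohort_res = ase_mod.cohort_bias_test(
            ind_calls[(ind_calls["sex"] == sex) & (ind_calls["condition"] == "adult")]
            ["maternal_fraction"], key,
        )
        res = ct_mod.decompose(summaries, cohort_res, sex, epsilon=config.epsilon)
        cistrans_block[sex] = {
            "A": res.A, "B": res.B, "trans": res.trans,
            "category": res.category, "extended": res.extended,
        }
    log.info("stage=cistrans categories=%s",
             {s: v["category"] for s, v in cistrans_block.items()})

    report = {
        "seed": scenario.seed,
        "alpha": config.alpha,
        "epsilon": config.epsilon,
        "calibrator": config.calibrator,
        "snps": snp_block,
        "expression": expr_block,
        "growth": growth_block,
        "ase": ase_block,
        "cistrans": cistrans_block,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
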