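"""Seeded generator of study-shaped synthetic inputs.

Emulates the hybrid-tilapia GH design: two purebred parental lines (Nile
tilapia NN, maternal; blue tilapia BB, paternal) and their F1 hybrid NB;
parental GH cDNAs differing at exactly four coding positions (53, 327,
501, 603, with C/G at 501); pituitary qPCR Ct tables whose hybrid group
sits above the midparent expression level; per-individual pyrosequencing
allele counts with maternal bias and beta-binomial overdispersion; and
lognormal growth-trial weights ordered hybrid > Nile > blue.

Every table draws from its own substream of one global seed, so adding a
table never perturbs the others, and a fixed config+seed reproduces the
output files byte for byte.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .variants import SnpSite, write_parental_fasta

UTR5_LEN = 26  # 5' segment upstream of the CDS so the cloning primer span (-26..-8) is placeable
CDS_LEN = 751  # 3'-most coordinate covered by the study's primers

GROUPS = ("NN", "BB", "NB")
SEXES = ("male", "female")
GENES = ("GH", "ref")

# Fixed per-table substream codes: new tables append, existing codes never move.
_STREAMS = {"sequences": 0, "ct": 1, "allele_counts": 2, "growth": 3}

DEFAULT_SNP_POSITIONS = (53, 327, 501, 603)
DEFAULT_ALLELE_PAIRS = (("A", "G"), ("T", "C"), ("C", "G"), ("T", "A"))

# Adult cohort allelic fractions: cohort means are exactly 87.10% (males)
# and 82.33% (females), with one paternal-biased individual per sex.
# Juvenile fed/fasted cohorts (n=5) have matched means so feeding status
# leaves the allelic ratio unchanged; the fed cohort carries one balanced
# individual (four of five maternal-dominated).
DEFAULT_ASE_PRESETS: dict[str, dict] = {
    "male_adult": {
        "sex": "male", "condition": "adult",
        "fractions": (0.98, 0.975, 0.97, 0.965, 0.96, 0.376),
    },
    "female_adult": {
        "sex": "female", "condition": "adult",
        "fractions": (0.95, 0.94, 0.93, 0.92, 0.91, 0.2898),
    },
    "fed_juvenile": {
        "sex": "male", "condition": "fed",
        "fractions": (0.90, 0.88, 0.86, 0.84, 0.52),
    },
    "fasted_juvenile": {
        "sex": "male", "condition": "fasted",
        "fractions": (0.90, 0.88, 0.87, 0.85, 0.83),
    },
}

# Group-level Ct means (cycles). The reference gene is flat across groups;
# GH Ct is lowest (highest expression) in the hybrid. Males: hybrid above
# both parents (overdominant); females: hybrid at the maternal level, both
# above the paternal line (maternal dominance). Both sexes sit above the
# midparent value.
DEFAULT_CT_MEANS: dict[tuple[str, str, str], float] = {
    ("NN", "male", "GH"): 24.0, ("BB", "male", "GH"): 26.0, ("NB", "male", "GH"): 22.5,
    ("NN", "female", "GH"): 23.2, ("BB", "female", "GH"): 26.0, ("NB", "female", "GH"): 23.2,
    **{(g, s, "ref"): 18.0 for g in GROUPS for s in SEXES},
}

# Growth presets: final-weight means are the study's printed cohort means;
# initial means back-solved from the printed weight-gain percentages;
# sd 45 g gives an SEM near 10 g at n=20, matching the printed SEMs.
DEFAULT_GROWTH: dict[str, tuple[float, float, float, int]] = {
    # group: (initial mean g, final mean g, sd g, trial days)
    "NB": (25.84, 399.31, 45.0, 120),
    "NN": (25.81, 378.95, 45.0, 120),
    "BB": (26.15, 305.25, 45.0, 120),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of one synthetic study scenario."""

    seed: int = 0
    group_means_ct: dict = field(default_factory=lambda: dict(DEFAULT_CT_MEANS))
    ct_sd: float = 0.25
    n_per_group: int = 5
    ase_presets: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_ASE_PRESETS.items()
    })
    overdispersion_rho: float = 0.02
    read_depth: int = 2000
    growth: dict = field(default_factory=lambda: dict(DEFAULT_GROWTH))
    growth_n: int = 20

    def __post_init__(self) -> None:
        if self.ct_sd < 0:
            raise ValidationError("ct_sd must be >= 0")
        if self.read_depth < 1:
            raise ValidationError("read_depth must be >= 1")
        if not 0 <= self.overdispersion_rho < 1:
            raise ValidationError("overdispersion_rho must lie in [0, 1)")
        for name, preset in self.ase_presets.items():
            for p in preset["fractions"]:
                if not 0 < p < 1:
                    raise ValidationError(f"preset {name}: fractions must lie in (0,1)")
        for group, (w0, w1, sd, days) in self.growth.items():
            if w0 <= 0 or w1 <= 0 or sd < 0:
                raise ValidationError(f"growth {group}: weights must be positive")
            if days <= 0:
                raise ValidationError(f"growth {group}: days must be positive")


@dataclass(frozen=True)
class FixtureBundle:
    """Paths of one generated scenario plus the truth used to build it."""

    parental_fasta_path: Path
    ct_table_path: Path
    allele_counts_path: Path
    growth_table_path: Path
    truth_path: Path
    truth: dict


def _rng(seed: int, table: str, subkey: str | None = None) -> np.random.Generator:
    entropy: tuple[int, ...] = (int(seed), _STREAMS[table])
    if subkey is not None:
        entropy += (zlib.crc32(subkey.encode()),)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def generate_parental_cds(
    seed: int,
    length: int = CDS_LEN,
    snp_positions=DEFAULT_SNP_POSITIONS,
    allele_pairs=DEFAULT_ALLELE_PAIRS,
    utr5_len: int = UTR5_LEN,
) -> tuple[str, str, list[SnpSite]]:
    """Two parental cDNAs identical except at the given signed positions.

    Returns (nile_seq, blue_seq, sites). The default fixture differs at
    the study's four coding positions with the C (Nile) / G (blue) pair
    at 501.
    """
    from .coords import signed_to_index

    positions = list(snp_positions)
    if len(set(positions)) != len(positions):
        raise ValidationError("duplicate SNP positions")
    if len(positions) != len(allele_pairs):
        raise ValidationError("one allele pair per SNP position required")
    rng = _rng(seed, "sequences")
    total = utr5_len + length
    bases = np.array(list("ACGT"))
    nile = rng.choice(bases, size=total)
    blue = nile.copy()
    sites: list[SnpSite] = []
    for pos, (a_nile, a_blue) in zip(positions, allele_pairs):
        if a_nile == a_blue:
            raise ValidationError(f"position {pos}: allele pair must differ")
        if pos < -utr5_len or pos > length:
            raise ValidationError(f"position {pos} outside [-{utr5_len}, {length}]")
        idx = signed_to_index(pos, utr5_len)  # raises CoordinateError on 0
        nile[idx] = a_nile
        blue[idx] = a_blue
        sites.append(SnpSite(pos, a_nile, a_blue))
    return "".join(nile), "".join(blue), sites


def simulate_allele_counts(
    preset: str,
    depth: int | None = None,
    rho: float | None = None,
    seed: int | None = None,
    config: ScenarioConfig | None = None,
) -> pd.DataFrame:
    """Per-individual pyrosequencing maternal/paternal read counts.

    The maternal count for an individual with true fraction p is
    beta-binomial(depth, p, rho); rho = 0 degenerates to a plain
    binomial. Columns: individual, sex, condition, mat_count, pat_count.
    """
    config = config or ScenarioConfig()
    if preset not in config.ase_presets:
        raise ConfigError(f"unknown ASE preset {preset!r}; "
                          f"have {sorted(config.ase_presets)}")
    depth = config.read_depth if depth is None else int(depth)
    rho = config.overdispersion_rho if rho is None else float(rho)
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    if not 0 <= rho < 1:
        raise ValidationError("rho must lie in [0, 1)")
    rng = _rng(config.seed if seed is None else seed, "allele_counts", subkey=preset)
    spec = config.ase_presets[preset]
    rows = []
    for i, p in enumerate(spec["fractions"], start=1):
        if rho == 0:
            mat = int(rng.binomial(depth, p))
        else:
            a = p * (1 - rho) / rho
            b = (1 - p) * (1 - rho) / rho
            mat = int(rng.binomial(depth, rng.beta(a, b)))
        rows.append((f"{preset}_{i}", spec["sex"], spec["condition"], mat, depth - mat))
    return pd.DataFrame(
        rows, columns=["individual", "sex", "condition", "mat_count", "pat_count"]
    )


def simulate_ct_table(config: ScenarioConfig, n_tech_reps: int = 3) -> pd.DataFrame:
    """Long-format qPCR Ct table: n_per_group biological samples per
    group x sex, each with triplicate technical replicates per gene."""
    for g in GROUPS:
        for s in SEXES:
            for gene in GENES:
                if (g, s, gene) not in config.group_means_ct:
                    raise ConfigError(f"missing Ct mean for {(g, s, gene)}")
    rng = _rng(config.seed, "ct")
    rows = []
    for g in GROUPS:
        for s in SEXES:
            for i in range(1, config.n_per_group + 1):
                sample = f"{g}_{s}_{i}"
                for gene in GENES:
                    mu = config.group_means_ct[(g, s, gene)]
                    for rep in range(1, n_tech_reps + 1):
                        ct = float(rng.normal(mu, config.ct_sd))
                        rows.append((sample, g, s, "adult", gene, rep, ct))
    return pd.DataFrame(
        rows, columns=["sample", "group", "sex", "age_class", "gene", "replicate", "ct"]
    )


def simulate_growth(config: ScenarioConfig) -> pd.DataFrame:
    """Growth-trial table with lognormal initial/final weights.

    Lognormal parameters are chosen so the arithmetic mean and sd of each
    group's final weight equal the configured values; initial-weight sd
    is scaled down by the initial/final mean ratio.
    """
    rng = _rng(config.seed, "growth")
    rows = []
    for g in GROUPS:
        if g not in config.growth:
            raise ConfigError(f"missing growth preset for group {g}")
        w0_mean, w1_mean, sd, days = config.growth[g]
        for i in range(1, config.growth_n + 1):
            w1 = _lognormal_with_moments(rng, w1_mean, sd)
            w0 = _lognormal_with_moments(rng, w0_mean, sd * w0_mean / w1_mean)
            rows.append((f"{g}_{i}", g, w0, w1, days))
    return pd.DataFrame(
        rows, columns=["individual", "group", "initial_g", "final_g", "days"]
    )


def _lognormal_with_moments(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return float(mean)
    var = sd * sd
    sigma2 = math.log(1 + var / (mean * mean))
    mu = math.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def generate_bundle(config: ScenarioConfig, outdir: str | Path) -> FixtureBundle:
    """Write every fixture table plus a truth sidecar into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    nile, blue, sites = generate_parental_cds(config.seed)
    fasta = outdir / "parental_gh.fasta"
    write_parental_fasta(nile, blue, fasta)

    ct = simulate_ct_table(config)
    ct_path = outdir / "ct.tsv"
    ct.to_csv(ct_path, sep="\t", index=False)

    counts = pd.concat(
        [simulate_allele_counts(name, config=config) for name in config.ase_presets],
        ignore_index=True,
    )
    counts_path = outdir / "allele_counts.tsv"
    counts.to_csv(counts_path, sep="\t", index=False)

    growth = simulate_growth(config)
    growth_path = outdir / "growth.tsv"
    growth.to_csv(growth_path, sep="\t", index=False)

    truth = {
        "seed": config.seed,
        "utr5_len": UTR5_LEN,
        "snp_sites": [
            {"position": s.position, "nile": s.nile_allele, "blue": s.blue_allele}
            for s in sites
        ],
        "group_means_ct": {f"{g}|{s}|{gene}": mu
                           for (g, s, gene), mu in config.group_means_ct.items()},
        "ct_sd": config.ct_sd,
        "n_per_group": config.n_per_group,
        "ase_presets": {k: {"sex": v["sex"], "condition": v["condition"],
                            "fractions": list(v["fractions"])}
                        for k, v in config.ase_presets.items()},
        "overdispersion_rho": config.overdispersion_rho,
        "read_depth": config.read_depth,
        "growth": {g: list(v) for g, v in config.growth.items()},
        "growth_n": config.growth_n,
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))

    return FixtureBundle(fasta, ct_path, counts_path, growth_path, truth_path, truth)


def config_from_truth(truth: dict) -> ScenarioConfig:
    """Rebuild a ScenarioConfig from a truth sidecar (round-trip)."""
    means = {tuple(k.split("|")): v for k, v in truth["group_means_ct"].items()}
    return ScenarioConfig(
        seed=truth["seed"],
        group_means_ct=means,
        ct_sd=truth["ct_sd"],
        n_per_group=truth["n_per_group"],
        ase_presets={k: {"sex": v["sex"], "condition": v["condition"],
                         "fractions": tuple(v["fractions"])}
                     for k, v in truth["ase_presets"].items()},
        overdispersion_rho=truth["overdispersion_rho"],
        read_depth=truth["read_depth"],
        growth={g: tuple(v) for g, v in truth["growth"].items()},
        growth_n=truth["growth_n"],
    )
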