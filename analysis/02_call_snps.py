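"""Align the parental cDNAs, call fixed differences, check assay coverage.

Reads results/sim/parental_gh.fasta, globally aligns the two sequences,
reports every substitution column as a SNP in signed CDS coordinates,
and verifies that the pyrosequencing amplicon covers the assayed C/G
site. Also tabulates the amplicon size of every primer pair from its
spans. Outputs: results/snps.tsv, results/amplicons.tsv.
"""

from pathlib import Path

import pandas as pd

from tilapia_gh.align import align_pair
from tilapia_gh.primers import STUDY_PRIMERS, amplicon_size, site_in_amplicon
from tilapia_gh.simulate import UTR5_LEN
from tilapia_gh.variants import call_fixed_differences, read_parental_fasta, write_snp_report

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    nile, blue = read_parental_fasta(RESULTS / "sim" / "parental_gh.fasta")
    alignment = align_pair(nile, blue)
    sites = call_fixed_differences(alignment, utr5_len=UTR5_LEN)
    write_snp_report(sites, RESULTS / "snps.tsv")
    print(f"{len(sites)} fixed differences between the parental cDNAs:")
    for s in sites:
        print(f"  position {s.position}: Nile {s.nile_allele} / blue {s.blue_allele}")

    rows = []
    for name, pair in STUDY_PRIMERS.items():
        rows.append((name, pair.forward_span[0], pair.reverse_span[1], amplicon_size(pair)))
    amps = pd.DataFrame(rows, columns=["assay", "start", "end", "amplicon_bp"])
    amps.to_csv(RESULTS / "amplicons.tsv", sep="\t", index=False)
    print(amps.to_string(index=False))

    pyr = STUDY_PRIMERS["pyr-GH"]
    for s in sites:
        offset = site_in_amplicon(s.position, pyr)
        if offset is not None:
            print(f"pyrosequencing assay covers site {s.position} "
                  f"(offset {offset} in the {amplicon_size(pyr)}-bp amplicon)")


if __name__ == "__main__":
    main()
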