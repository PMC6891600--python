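"""Published reference data bundled with the package.

The mature-peptide set below is the panel of twelve venom peptides of the
assassin bug *Platymeris rhadamanthus* whose intact masses were measured by
LC-MS before and after reduction/2-iodoethanol alkylation. It carries, per
peptide: the mature sequence, the published fold assignment, the number of
cysteines inferred to form intrachain disulfide bonds, and the published
theoretical and observed monoisotopic masses (Da). Missing observed masses
are recorded as None. Pr2a/Pr2b carry a putative lysine carbamylation whose
inclusion in the published theoretical masses is undeterminable, so they are
flagged and excluded from mass-reproduction checks.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["REFERENCE_MATURE_PEPTIDES", "load_reference_peptides"]

# Columns: id, sequence, published fold, n_disulfides, theoretical native,
# observed native, theoretical RA, observed RA, carbamylated flag.
REFERENCE_MATURE_PEPTIDES = [
    ("U-RDTX-Pr1a", "DEKDCIARGQKCVGENKPCCKGTTCMYYANRCVGV", "ICK", 3,
     3835.69, 3835.62, 4105.89, 4105.81, False),
    ("U-RDTX-Pr11a.2", "TIEKSCKPGTTFKHKDGCNTCKCSDDGKNALCTSKLCL", "pacifastin", 3,
     4070.88, 4070.81, 4341.09, 4340.99, False),
    ("U-RDTX-Pr10a.2", "TMKQSCKPGATFKHKDGCNTCKCSDDGKSARCTARLCW", "pacifastin", 3,
     4158.86, 4158.78, 4429.06, 4428.96, False),
    ("U-RDTX-Pr2a", "EEHGCIPPFQPCEGVNSRCCGLYVCFNKICLATP", "ICK", 3,
     3763.65, 3763.59, 4033.86, 4033.77, True),
    ("U-RDTX-Pr11a.1", "SRACSKPGQTVLAPDGCNHCRCSEKGILMACTKMMCPPR", "pacifastin", 3,
     4172.89, 4172.82, 4443.10, 4442.99, False),
    ("U-RDTX-Pr2b", "HGCIPPFQPCEGVNSRCCGLYVCFNKICLATP", "ICK", 3,
     3505.57, 3505.51, 3775.77, 3775.68, True),
    ("U-RDTX-Pr7a", "GGCIQRYGKCSTENSNCCAPSECYFSFNQCF", "ICK", 3,
     3439.33, 3439.26, 3709.53, 3709.43, False),
    ("U-RDTX-Pr5a", "CIPAANPCRGNAKCCGNYVCKNGRCLPRS", "ICK", 3,
     3061.39, 3061.31, 3331.59, 3331.52, False),
    ("U-RDTX-Pr9a", "MMPVCFEGEKLNKDQTKCIKA", "unknown", 1,
     2410.16, 2410.13, 2500.23, 2500.19, False),
    ("U-RDTX-Pr4a", "GEDVCIPSGQKCGPYMNMGCCKGLVCMSYAARCVSMGGIPR", "ICK", 3,
     4264.84, 4264.77, 4535.05, 4534.09, False),
    ("U-RDTX-Pr21.2", "MDCKPGKKFKIDCNTCICSKEGKAAACTQKLCLK", "pacifastin", 3,
     3699.79, 3699.72, 3970.00, None, False),
    ("U-RDTX-Pr12a.1", "CRPGALTVAPDGCNMCTCLSNGKLGRCTHDLICPPR", "pacifastin", 3,
     3765.73, None, 4035.93, 4035.85, False),
]


def load_reference_peptides() -> pd.DataFrame:
    """The reference mature-peptide panel as a DataFrame."""
    return pd.DataFrame(
        REFERENCE_MATURE_PEPTIDES,
        columns=[
            "id", "sequence", "published_fold", "n_disulfides",
            "published_native", "observed_native",
            "published_ra", "observed_ra", "carbamylated",
        ],
    )
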