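"""MS identification filtering, top-3 quantification and venom-origin testing.

Protein identifications from venom LC-MS/MS are accepted under a two-branch
rule: either three or more peptides observed above a confidence threshold
(default 95%), or at least one such peptide together with a predicted
secretion signal (SignalP D-score above 0.7). Accepted proteins are
quantified by averaging the three highest precursor-count values among their
peptides (the 'best flier' convention), and the per-sample protein signal is
expressed as a percentage of the sample's maximum quant.

The glandular origin of a venom sample is then inferred by joining the
detected proteins to the gland transcriptomes: if the sample is dominated by
one gland's secretory products, the PMG TPM values of its detected proteins
will stochastically dominate their AMG TPM values (or vice versa). This is
tested with a two-group Kruskal-Wallis test on the pooled PMG vs AMG TPM
vectors, with a paired Wilcoxon signed-rank variant reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gland_specificity import kruskal_wallis

__all__ = [
    "IdentificationResult",
    "identification_filter",
    "top3_quantify",
    "filter_evidence",
    "quantify_sample",
    "SampleOriginResult",
    "sample_origin_test",
]


@dataclass(frozen=True)
class IdentificationResult:
    accepted: bool
    reason: str  # "multi-peptide", "signal-peptide", or "rejected"
    n_confident_peptides: int


def identification_filter(
    peptide_confidences: Sequence[float],
    signal_dscore: Optional[float] = None,
    conf_threshold: float = 95.0,
    min_peptides: int = 3,
    dscore_threshold: float = 0.7,
) -> IdentificationResult:
    """Two-branch protein identification rule.

    Accept iff the number of peptides with confidence (percent scale)
    strictly above ``conf_threshold`` is at least ``min_peptides``, or at
    least one such peptide exists and the secretion-signal D-score exceeds
    ``dscore_threshold``.
    """
    conf = np.asarray(peptide_confidences, dtype=float)
    if conf.size == 0:
        raise ValueError("evidence must contain at least one peptide")
    if np.any((conf < 0) | (conf > 100)):
        raise ValueError("confidences must be on the 0-100 percent scale")
    n_conf = int((conf > conf_threshold).sum())
    if n_conf >= min_peptides:
        return IdentificationResult(True, "multi-peptide", n_conf)
    if n_conf >= 1 and signal_dscore is not None and signal_dscore > dscore_threshold:
        return IdentificationResult(True, "signal-peptide", n_conf)
    return IdentificationResult(False, "rejected", n_conf)


def top3_quantify(precursor_counts: Sequence[float]) -> tuple[float, bool]:
    """Mean of the three largest precursor-count values.

    With fewer than three peptides the mean of all available values is
    returned, flagged as under-evidenced (second element True).
    """
    vals = np.asarray(precursor_counts, dtype=float)
    if vals.size == 0:
        raise ValueError("no precursor counts supplied")
    top = np.sort(vals)[::-1][:3]
    return float(top.mean()), vals.size < 3


def filter_evidence(
    evidence: pd.DataFrame,
    conf_threshold: float = 95.0,
    min_peptides: int = 3,
    dscore_threshold: float = 0.7,
) -> pd.DataFrame:
    """Apply the identification rule per (sample, protein) group.

    ``evidence`` needs columns sample_id, protein_id, confidence,
    precursor_count and optionally dscore (constant within a protein).
    Returns one row per group with acceptance, reason, quant (top-3 mean)
    and the under-evidence flag.
    """
    rows = []
    for (sample, protein), grp in evidence.groupby(["sample_id", "protein_id"], sort=True):
        dscore = None
        if "dscore" in grp.columns and grp["dscore"].notna().any():
            dscore = float(grp["dscore"].dropna().iloc[0])
        res = identification_filter(
            grp["confidence"], dscore, conf_threshold, min_peptides, dscore_threshold
        )
        quant, under = top3_quantify(grp["precursor_count"])
        rows.append(
            {
                "sample_id": sample,
                "protein_id": protein,
                "n_peptides": len(grp),
                "n_confident": res.n_confident_peptides,
                "accepted": res.accepted,
                "reason": res.reason,
                "quant": quant,
                "under_evidence": under,
            }
        )
    return pd.DataFrame(rows)


def quantify_sample(accepted: pd.DataFrame) -> pd.DataFrame:
    """Scale accepted proteins' quants to percent of the sample maximum.

    Adds ``percent_of_max`` and an ``is_top`` flag marking exactly one
    protein per sample (quant ties broken by protein id).
    """
    df = accepted[accepted["accepted"]].copy()
    out = []
    for sample, grp in df.groupby("sample_id", sort=True):
        grp = grp.copy()
        qmax = grp["quant"].max()
        grp["percent_of_max"] = 100.0 * grp["quant"] / qmax if qmax > 0 else 0.0
        top_id = grp.sort_values(["quant", "protein_id"], ascending=[False, True])[
            "protein_id"
        ].iloc[0]
        grp["is_top"] = grp["protein_id"] == top_id
        out.append(grp)
    return pd.concat(out, ignore_index=True) if out else df.assign(
        percent_of_max=pd.Series(dtype=float), is_top=pd.Series(dtype=bool)
    )


@dataclass
class SampleOriginResult:
    """Inferred glandular origin of one venom sample."""

    sample_id: str
    n_proteins: int
    tested: bool
    h: float = float("nan")
    p: float = float("nan")
    p_paired: float = float("nan")  # Wilcoxon signed-rank on per-protein pairs
    dominant_gland: str = "undetermined"
    top_protein: Optional[str] = None
    table: Optional[pd.DataFrame] = None  # (tpm_pmg, tpm_amg, percent_of_max)


def sample_origin_test(
    sample_quant: pd.DataFrame,
    abundance: pd.DataFrame,
    alpha: float = 0.05,
    min_proteins: int = 3,
) -> SampleOriginResult:
    """Infer which gland a venom sample's detected proteins came from.

    ``sample_quant`` is one sample's accepted-protein table (protein_id,
    quant, percent_of_max); ``abundance`` maps protein_id to tpm_pmg /
    tpm_amg. The pooled PMG and AMG TPM vectors of the detected proteins are
    compared by Kruskal-Wallis; the dominant gland is the one with the higher
    median TPM among detected proteins, reported only when the test is
    significant at ``alpha``.
    """
    if sample_quant["sample_id"].nunique() > 1:
        raise ValueError("sample_origin_test expects a single sample")
    sample_id = str(sample_quant["sample_id"].iloc[0])
    joined = sample_quant.merge(
        abundance.rename(columns={"contig_id": "protein_id"})[
            ["protein_id", "tpm_pmg", "tpm_amg"]
        ],
        on="protein_id",
        how="inner",
    )
    n = len(joined)
    if n < min_proteins:
        return SampleOriginResult(sample_id, n, tested=False, table=joined)

    pmg = joined["tpm_pmg"].to_numpy(dtype=float)
    amg = joined["tpm_amg"].to_numpy(dtype=float)
    res = kruskal_wallis(pmg, amg)
    try:
        p_paired = float(stats.wilcoxon(pmg, amg).pvalue)
    except ValueError:  # all differences zero
        p_paired = 1.0
    dominant = "undetermined"
    if res.p < alpha:
        dominant = "PMG" if np.median(pmg) > np.median(amg) else "AMG"
    top = joined.sort_values(["quant", "protein_id"], ascending=[False, True])[
        "protein_id"
    ].iloc[0]
    return SampleOriginResult(
        sample_id=sample_id,
        n_proteins=n,
        tested=True,
        h=res.h,
        p=res.p,
        p_paired=p_paired,
        dominant_gland=dominant,
        top_protein=str(top),
        table=joined[["protein_id", "tpm_pmg", "tpm_amg", "quant", "percent_of_max"]]
        if "percent_of_max" in joined.columns
        else joined,
    )
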