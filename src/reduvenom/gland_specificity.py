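"""Gland-preference classification, family-level tests and orthologue concordance.

Venom-gland transcriptomes of heteropterans show a bimodal structure: venom
transcripts are highly expressed in exactly one of the two gland compartments
(PMG or AMG), while housekeeping transcripts sit at similar, much lower
abundance in both. A protein is called gland-specific when its TPM is more
than a fold-change threshold (default 100x) higher in one gland, with a
pseudo-count guarding zeros. With a single sequencing replicate per gland,
preferential expression is tested at the level of protein families (the PMG
and AMG TPM vectors of a family's members, Kruskal-Wallis), not of single
transcripts. Cross-species conservation is measured by calling reciprocal
best hits between two species' venom proteins and asking whether each
orthologue pair shows the same gland preference in both species.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HOUSEKEEPING_TPM_BAND",
    "classify_gland_preference",
    "classify_table",
    "KruskalResult",
    "kruskal_wallis",
    "family_preference_tests",
    "reciprocal_best_hits",
    "ConcordanceResult",
    "orthologue_concordance",
]

#: TPM band in which transcripts expressed similarly in both glands are
#: flagged as putative housekeeping genes.
HOUSEKEEPING_TPM_BAND = (10.0, 2000.0)


def classify_gland_preference(
    tpm_pmg: float,
    tpm_amg: float,
    fold_threshold: float = 100.0,
    pseudo: float = 0.5,
) -> tuple[str, float]:
    """Label a protein PMG-specific, AMG-specific or shared.

    Fold change is (max + pseudo) / (min + pseudo), so a transcript detected
    in only one gland gets a finite, large fold change. Labels require the
    fold change to exceed ``fold_threshold``.
    """
    if tpm_pmg < 0 or tpm_amg < 0:
        raise ValueError("TPM values must be non-negative")
    hi, lo = max(tpm_pmg, tpm_amg), min(tpm_pmg, tpm_amg)
    fold = (hi + pseudo) / (lo + pseudo)
    if fold > fold_threshold:
        label = "PMG-specific" if tpm_pmg > tpm_amg else "AMG-specific"
    else:
        label = "shared"
    return label, fold


def classify_table(
    abundance: pd.DataFrame,
    fold_threshold: float = 100.0,
    pseudo: float = 0.5,
) -> pd.DataFrame:
    """Per-protein preference labels, fold changes and housekeeping flags.

    Expects ``tpm_pmg`` and ``tpm_amg`` columns; adds ``preference``,
    ``fold_change`` and ``housekeeping`` (both TPMs inside the housekeeping
    band and label shared).
    """
    df = abundance.copy()
    labels, folds = [], []
    for p, a in zip(df["tpm_pmg"], df["tpm_amg"]):
        lab, fold = classify_gland_preference(p, a, fold_threshold, pseudo)
        labels.append(lab)
        folds.append(fold)
    df["preference"] = labels
    df["fold_change"] = folds
    lo, hi = HOUSEKEEPING_TPM_BAND
    df["housekeeping"] = (
        (df["preference"] == "shared")
        & df["tpm_pmg"].between(lo, hi)
        & df["tpm_amg"].between(lo, hi)
    )
    return df


@dataclass(frozen=True)
class KruskalResult:
    h: float
    p_chi2: float
    p_exact: Optional[float] = None  # exhaustive permutation p, small n only

    @property
    def p(self) -> float:
        return self.p_chi2


def _h_statistic(pooled_ranks: np.ndarray, n_a: int) -> float:
    """Tie-corrected Kruskal-Wallis H for a two-group split given pooled ranks."""
    n = len(pooled_ranks)
    ra = pooled_ranks[:n_a]
    rb = pooled_ranks[n_a:]
    mean_rank = (n + 1) / 2.0
    h = (12.0 / (n * (n + 1))) * (
        n_a * (ra.mean() - mean_rank) ** 2 + (n - n_a) * (rb.mean() - mean_rank) ** 2
    )
    _, counts = np.unique(pooled_ranks, return_counts=True)
    tie_term = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie_term if tie_term > 0 else 0.0


def kruskal_wallis(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_max_n: int = 10,
) -> KruskalResult:
    """Two-group Kruskal-Wallis test with tie correction.

    The p-value uses the chi-squared approximation with 1 degree of freedom.
    When the pooled sample size is at most ``exact_max_n`` an exact p is also
    computed by enumerating every assignment of the pooled ranks to the two
    groups. Identical pooled values give H = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return KruskalResult(0.0, 1.0, 1.0 if len(pooled) <= exact_max_n else None)
    h, p = stats.kruskal(a, b)
    p_exact = None
    n = len(pooled)
    if n <= exact_max_n:
        ranks = stats.rankdata(pooled)
        h_obs = _h_statistic(np.concatenate([ranks[: len(a)], ranks[len(a):]]), len(a))
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), len(a)):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            h_perm = _h_statistic(np.concatenate([ranks[sel], ranks[~sel]]), len(a))
            count += h_perm >= h_obs - 1e-12
            total += 1
        p_exact = count / total
    return KruskalResult(float(h), float(p), p_exact)


def family_preference_tests(
    abundance: pd.DataFrame,
    family_map: Optional[pd.DataFrame] = None,
    min_members: int = 3,
) -> pd.DataFrame:
    """Per-family preferential-expression tests.

    ``abundance`` needs protein_id, tpm_pmg, tpm_amg and either a ``family``
    column or a separate ``family_map`` (protein_id, family). Families with at
    least ``min_members`` members are tested (member PMG TPMs vs member AMG
    TPMs, Kruskal-Wallis); smaller families are reported untested. Direction
    is the gland with the larger median member TPM. Benjamini-Hochberg FDR is
    reported alongside the raw p-values.
    """
    df = abundance.copy()
    if family_map is not None:
        known = set(df["protein_id"])
        unknown = set(family_map["protein_id"]) - known
        if unknown:
            import warnings

            warnings.warn(f"family map contains unknown protein ids: {sorted(unknown)[:5]}")
        df = df.merge(family_map, on="protein_id", how="inner")
    if "family" not in df.columns:
        raise ValueError("no family assignments supplied")

    rows = []
    for family, grp in df.groupby("family", sort=True):
        pmg = grp["tpm_pmg"].to_numpy(dtype=float)
        amg = grp["tpm_amg"].to_numpy(dtype=float)
        direction = "PMG" if np.median(pmg) > np.median(amg) else "AMG"
        if np.median(pmg) == np.median(amg):
            direction = "tied"
        row = {
            "family": family,
            "n_members": len(grp),
            "direction": direction,
            "tested": len(grp) >= min_members,
            "H": np.nan,
            "p": np.nan,
            "p_exact": np.nan,
        }
        if row["tested"]:
            res = kruskal_wallis(pmg, amg)
            row.update(H=res.h, p=res.p_chi2, p_exact=res.p_exact)
        rows.append(row)
    out = pd.DataFrame(rows)
    tested = out["tested"] & out["p"].notna()
    out["p_bh"] = np.nan
    if tested.any():
        out.loc[tested, "p_bh"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


def _top_hits(hits: pd.DataFrame) -> pd.Series:
    """Best subject per query: highest score, ties broken by subject id."""
    df = hits.rename(
        columns={"qseqid": "query", "sseqid": "subject", "bitscore": "score"}
    )
    for col in ("query", "subject", "score"):
        if col not in df.columns:
            raise ValueError(f"similarity table lacks a '{col}' column")
    df = df.sort_values(
        ["query", "score", "subject"], ascending=[True, False, True], kind="mergesort"
    )
    return df.groupby("query", sort=True)["subject"].first()


def reciprocal_best_hits(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame
) -> pd.DataFrame:
    """Reciprocal-best-hit pairs from two directional similarity tables.

    Accepts columns query/subject/score (or BLAST tabular qseqid/sseqid/
    bitscore). Pair (a, b) is returned iff b is a's single best hit A->B and
    a is b's single best hit B->A; each id ends up in at most one pair.
    """
    best_ab = _top_hits(hits_ab)
    best_ba = _top_hits(hits_ba)
    pairs = [
        (a, b)
        for a, b in best_ab.items()
        if best_ba.get(b) == a
    ]
    return pd.DataFrame(pairs, columns=["id_a", "id_b"])


@dataclass(frozen=True)
class ConcordanceResult:
    n_pairs: int
    n_concordant: int
    fraction: float
    n_same_direction: Optional[int] = None
    fraction_same_direction: Optional[float] = None
    n_excluded: int = 0


def orthologue_concordance(pairs: pd.DataFrame) -> ConcordanceResult:
    """Fraction of orthologue pairs with the same gland preference in both species.

    ``pairs`` needs ``label_a`` and ``label_b`` preference labels; pairs with a
    missing label are excluded and counted. When per-species TPM columns
    (tpm_pmg_a, tpm_amg_a, tpm_pmg_b, tpm_amg_b) are present, a looser
    same-direction-of-bias concordance is reported as well.
    """
    if len(pairs) == 0:
        raise ValueError("no orthologue pairs supplied")
    ok = pairs["label_a"].notna() & pairs["label_b"].notna()
    kept = pairs[ok]
    if len(kept) == 0:
        raise ValueError("no pairs with labels in both species")
    concordant = int((kept["label_a"] == kept["label_b"]).sum())
    n_dir = frac_dir = None
    dir_cols = {"tpm_pmg_a", "tpm_amg_a", "tpm_pmg_b", "tpm_amg_b"}
    if dir_cols <= set(kept.columns):
        dir_a = kept["tpm_pmg_a"] > kept["tpm_amg_a"]
        dir_b = kept["tpm_pmg_b"] > kept["tpm_amg_b"]
        n_dir = int((dir_a == dir_b).sum())
        frac_dir = n_dir / len(kept)
    return ConcordanceResult(
        n_pairs=len(kept),
        n_concordant=concordant,
        fraction=concordant / len(kept),
        n_same_direction=n_dir,
        fraction_same_direction=frac_dir,
        n_excluded=int((~ok).sum()),
    )
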