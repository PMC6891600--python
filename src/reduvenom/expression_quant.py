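"""Transcript-abundance estimation and a from-first-principles TMM check.

The study design behind this module: paired-end reads from two venom-gland
libraries (posterior main gland, PMG; anterior main gland, AMG) are mapped
against a small database of venom-protein ORFs, giving per-contig fragment
counts. Counts are length-normalised to fragments per kilobase (FPK) using
the ORF length, then scaled to transcripts per million (TPM) by dividing by
the whole-transcriptome total FPK (sigma-FPK). Because the whole-transcriptome
total is estimated from two independent assemblies of the same reads, the
arithmetic mean of the two assembly totals is the denominator.

The TMM (trimmed mean of M-values) scaling factor is implemented by hand as a
bias check between the two libraries: after dropping contigs with a zero count
in either library, each contig gets an M-value (log2 ratio of library-relative
fractions, AMG over PMG), an A-value (half the log2 product of the fractions)
and a precision weight (inverse delta-method variance of M under binomial
counting). The top and bottom 30% of M and top and bottom 5% of A are trimmed
and the factor is 2 to the power of the weighted mean of the surviving M.
A factor near 1 means per-contig fractions need no compositional correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LIBRARIES",
    "InsufficientDataError",
    "fpk",
    "SigmaFpk",
    "sigma_fpk",
    "tpm_normalise",
    "build_abundance_table",
    "TmmResult",
    "tmm_scaling_factor",
    "MAPPING_PROVENANCE",
]

LIBRARIES = ("pmg", "amg")

#: Read-mapping parameters used upstream of the count tables this module
#: consumes. Recorded as provenance metadata only; mapping itself is out of
#: scope for the package.
MAPPING_PROVENANCE = {
    "similarity_threshold": 0.9,
    "minimum_overlap": 0.8,
    "maximum_hit_sequences": 1,
}


class InsufficientDataError(ValueError):
    """Too few informative contigs for a robust scaling factor."""


def fpk(fragments, orf_length):
    """Fragments per kilobase: fragments / (ORF length in kb).

    Accepts scalars or arrays; lengths are nucleotides and must be positive.
    """
    frag = np.asarray(fragments, dtype=float)
    length = np.asarray(orf_length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("ORF lengths must be positive")
    if np.any(frag < 0):
        raise ValueError("fragment counts must be non-negative")
    out = frag / (length / 1000.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SigmaFpk:
    """Whole-transcriptome total FPK per library, per reference assembly.

    ``totals`` maps assembly name -> {library -> total FPK}. The per-library
    normalising denominator is the arithmetic mean over the supplied
    assemblies (the study convention uses exactly two; one is accepted and
    used directly).
    """

    totals: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        if not self.totals:
            raise ValueError("at least one assembly total required")
        for assembly, per_lib in self.totals.items():
            for lib, tot in per_lib.items():
                if tot <= 0:
                    raise ValueError(f"sigma-FPK {assembly}/{lib} must be > 0")

    def mean(self, library: str) -> float:
        vals = [per_lib[library] for per_lib in self.totals.values()]
        return float(np.mean(vals))


def sigma_fpk(assembly_tables: Mapping[str, pd.DataFrame]) -> SigmaFpk:
    """Total FPK per library from one or two whole-assembly count tables.

    Each table needs columns ``orf_length`` and ``fragments_<lib>`` for each
    library in :data:`LIBRARIES`.
    """
    totals = {}
    for assembly, df in assembly_tables.items():
        totals[assembly] = {
            lib: float(np.sum(fpk(df[f"fragments_{lib}"], df["orf_length"])))
            for lib in LIBRARIES
        }
    return SigmaFpk(totals)


def tpm_normalise(target_fpk, sigma: SigmaFpk, library: str):
    """TPM = FPK / mean sigma-FPK x 10^6 for the given library."""
    if sigma is None:
        raise ValueError("sigma-FPK totals are required for TPM normalisation")
    denom = sigma.mean(library)
    vals = np.asarray(target_fpk, dtype=float) / denom * 1e6
    return float(vals) if vals.ndim == 0 else vals


def build_abundance_table(
    counts: pd.DataFrame,
    sigma: Optional[SigmaFpk] = None,
) -> pd.DataFrame:
    """Attach FPK and TPM columns to a per-contig fragment-count table.

    ``counts`` needs columns contig_id, orf_length, fragments_pmg,
    fragments_amg. When ``sigma`` is None the table itself is treated as the
    complete reference, so each library's TPM column sums to 10^6.
    """
    df = counts.copy()
    if sigma is None:
        sigma = sigma_fpk({"self": df})
    for lib in LIBRARIES:
        df[f"fpk_{lib}"] = fpk(df[f"fragments_{lib}"], df["orf_length"])
        df[f"tpm_{lib}"] = tpm_normalise(df[f"fpk_{lib}"], sigma, lib)
    return df


@dataclass
class TmmResult:
    """Per-contig M/A/weight diagnostics and the between-library scaling factor."""

    contig_ids: np.ndarray  # contigs surviving the zero filter
    m_values: np.ndarray  # log2(f_amg / f_pmg)
    a_values: np.ndarray  # 0.5 * log2(f_amg * f_pmg)
    weights: np.ndarray  # inverse delta-method variance of M
    retained: np.ndarray  # bool: inside both trim windows
    normalisation_log2: float  # sum(w M)/sum(w) over retained
    scaling_factor: float  # 2 ** normalisation_log2, AMG relative to PMG
    n_zero_filtered: int
    provenance: dict = field(default_factory=lambda: dict(MAPPING_PROVENANCE))

    def to_dict(self) -> dict:
        return {
            "scaling_factor": self.scaling_factor,
            "normalisation_log2": self.normalisation_log2,
            "n_contigs_used": int(self.retained.sum()),
            "n_contigs_after_zero_filter": int(len(self.contig_ids)),
            "n_zero_filtered": self.n_zero_filtered,
            "provenance": self.provenance,
        }


def _trim_mask(values: np.ndarray, ids: np.ndarray, fraction: float) -> np.ndarray:
    """Keep ranks strictly inside the two-sided trim window.

    Rank-based trimming: sort by (value, id) -- id breaks ties
    deterministically -- and drop floor(n * fraction) entries from each tail.
    """
    n = len(values)
    k = int(np.floor(n * fraction))
    order = np.lexsort((ids, values))
    mask = np.zeros(n, dtype=bool)
    mask[order[k: n - k]] = True
    return mask


def tmm_scaling_factor(
    counts_amg: Sequence[float],
    counts_pmg: Sequence[float],
    contig_ids: Optional[Sequence] = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    min_contigs: int = 10,
) -> TmmResult:
    """Weighted, doubly-trimmed mean of M-values between the two libraries.

    Returns the scaling factor for the AMG library with reference to the PMG.
    Contigs with a zero count in either library are excluded before M/A are
    formed; at least ``min_contigs`` must survive.
    """
    amg = np.asarray(counts_amg, dtype=float)
    pmg = np.asarray(counts_pmg, dtype=float)
    if amg.shape != pmg.shape:
        raise ValueError("count vectors must have equal length")
    if np.any(amg < 0) or np.any(pmg < 0):
        raise ValueError("counts must be non-negative")
    ids = (
        np.asarray(contig_ids)
        if contig_ids is not None
        else np.arange(len(amg))
    )

    keep = (amg > 0) & (pmg > 0)
    n_zero = int((~keep).sum())
    amg_k, pmg_k, ids_k = amg[keep], pmg[keep], ids[keep]
    if len(amg_k) < min_contigs:
        raise InsufficientDataError(
            f"only {len(amg_k)} contigs have nonzero counts in both libraries "
            f"(need >= {min_contigs})"
        )
    # Library totals over the filtered set, so a contig absent from one
    # library cannot perturb the factor at all.
    total_amg = amg_k.sum()
    total_pmg = pmg_k.sum()

    f_amg = amg_k / total_amg
    f_pmg = pmg_k / total_pmg
    m = np.log2(f_amg / f_pmg)
    a = 0.5 * np.log2(f_amg * f_pmg)
    # Delta-method variance of M for binomial sampling of fragment counts.
    w = 1.0 / (
        (total_amg - amg_k) / (total_amg * amg_k)
        + (total_pmg - pmg_k) / (total_pmg * pmg_k)
    )

    retained = _trim_mask(m, ids_k, trim_m) & _trim_mask(a, ids_k, trim_a)
    if not retained.any() or w[retained].sum() <= 0:
        raise InsufficientDataError("trimming removed all contigs")

    norm_log2 = float(np.sum(w[retained] * m[retained]) / np.sum(w[retained]))
    return TmmResult(
        contig_ids=ids_k,
        m_values=m,
        a_values=a,
        weights=w,
        retained=retained,
        normalisation_log2=norm_log2,
        scaling_factor=float(2.0 ** norm_log2),
        n_zero_filtered=n_zero,
    )
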