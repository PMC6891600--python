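"""Proteolytic maturation of multidomain venom precursors.

Venom pacifastins and redulysins are translated as precursors: a secretion
signal peptide followed by a propeptide that is cut into mature products at
short sequence motifs. Observed conventions in reduviid venom:

* pacifastin domains are released at classical dibasic sites (KR/RR/KK/RK)
  and, unusually, at monobasic sites following a Pro-Pro-Arg (PPR) tripeptide
  which remains on the C-terminus of the upstream mature peptide;
* redulysins (trialysin homologues) are activated by removal of an anionic
  prodomain at a DEER-type site (DEER, or NEER/NEELGR variants), exposing a
  lysine-rich lytic domain.

All coordinates in the public API are 1-based inclusive; slicing is half-open
only internally. Cleavage motifs are retained on the upstream product by
default, mirroring the observed PPR-terminated mature peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import peptide_chem
from .peptide_chem import (
    EXACT,
    ModificationScheme,
    average_mass,
    isoelectric_point,
    monoisotopic_mass,
    validate_sequence,
)

__all__ = [
    "PrecursorRecord",
    "CleavageRule",
    "MatureProduct",
    "ActivationReport",
    "AmbiguousActivationError",
    "DIBASIC_RULE",
    "PPR_RULE",
    "ACTIVATION_RULE",
    "DEFAULT_RULES",
    "find_cleavage_sites",
    "digest",
    "activation_report",
    "read_precursors_fasta",
    "read_rules_tsv",
    "products_to_frame",
]


@dataclass(frozen=True)
class CleavageRule:
    """A proteolytic cleavage motif.

    ``motifs`` lists the alternative residue patterns recognised by the rule;
    scission occurs ``cut_offset`` residues after the last motif residue
    (0 = immediately after the motif). ``motif_retained_on`` records whether
    the motif stays on the upstream product or is removed (annotation only;
    the default digest retains motifs upstream, and ``removed`` rules flag
    their products).
    """

    name: str
    motifs: tuple[str, ...]
    cut_offset: int = 0
    motif_retained_on: str = "upstream"

    def __post_init__(self) -> None:
        if not self.motifs or any(len(m) < 2 for m in self.motifs):
            raise ValueError("each motif must be at least 2 residues")
        if self.cut_offset < 0:
            raise ValueError("cut_offset must be >= 0")


DIBASIC_RULE = CleavageRule("dibasic", ("KR", "RR", "KK", "RK"))
PPR_RULE = CleavageRule("PPR", ("PPR",))
ACTIVATION_RULE = CleavageRule("DEER-family", ("DEER", "NEER", "NEELGR"))
DEFAULT_RULES = (PPR_RULE, DIBASIC_RULE, ACTIVATION_RULE)


@dataclass
class PrecursorRecord:
    """A venom precursor with an already-delimited signal peptide.

    ``signal_peptide_end`` is the 1-based index of the last signal-peptide
    residue (0 when the record is already a propeptide). ``annotations`` holds
    (start, end, label) domain spans, 1-based inclusive; they do not influence
    cleavage, which depends on sequence alone.
    """

    id: str
    sequence: str
    signal_peptide_end: int = 0
    annotations: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence)
        if not 0 <= self.signal_peptide_end < len(self.sequence):
            raise ValueError(
                f"{self.id}: signal_peptide_end {self.signal_peptide_end} outside "
                f"[0, {len(self.sequence)})"
            )
        for start, end, label in self.annotations:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(f"{self.id}: span ({start}, {end}, {label}) out of bounds")

    @property
    def propeptide(self) -> str:
        return self.sequence[self.signal_peptide_end:]


@dataclass
class MatureProduct:
    """A contiguous proteolytic product of a precursor."""

    parent_id: str
    start: int  # 1-based inclusive, in full-precursor coordinates
    end: int
    sequence: str
    mass: float
    pi: float
    rule: str  # name of the rule that generated the C-terminal boundary
    n_disulfides: int = 0
    flags: tuple[str, ...] = ()


class AmbiguousActivationError(ValueError):
    """Zero or multiple activation motifs where exactly one is required."""

    def __init__(self, precursor_id: str, candidates: list[tuple[int, str]]):
        self.candidates = candidates
        msg = (
            f"{precursor_id}: expected exactly one activation motif, found "
            f"{len(candidates)}: {candidates}"
        )
        super().__init__(msg)


def find_cleavage_sites(
    precursor: PrecursorRecord,
    rules: Sequence[CleavageRule] = DEFAULT_RULES,
) -> list[tuple[int, CleavageRule]]:
    """Locate every scission point downstream of the signal peptide.

    Returns (position, rule) pairs sorted by position, where ``position`` is
    the 1-based index (in full-precursor coordinates) of the last residue of
    the upstream product; the peptide bond after that residue is hydrolysed.
    Motifs must lie entirely within the propeptide. When several rules yield
    the same scission point the earliest rule in ``rules`` wins. A cut at the
    propeptide's C-terminus is not a cut and is ignored.
    """
    seq = precursor.sequence
    offset = precursor.signal_peptide_end
    hits: dict[int, CleavageRule] = {}
    for rule in rules:
        for motif in rule.motifs:
            start = seq.find(motif, offset)
            while start != -1:
                cut = start + len(motif) + rule.cut_offset  # residues before scission
                if cut < len(seq):  # a terminal "cut" releases nothing
                    hits.setdefault(cut, rule)
                start = seq.find(motif, start + 1)
    return [(pos, hits[pos]) for pos in sorted(hits)]


def digest(
    precursor: PrecursorRecord,
    rules: Sequence[CleavageRule] = DEFAULT_RULES,
    scheme: ModificationScheme = EXACT,
    disulfides: str | None = "auto",
    mass_kind: str = "mono",
) -> list[MatureProduct]:
    """Partition the propeptide at every scission point into mature products.

    Products tile the propeptide exactly. Each product's mass is computed via
    the peptide-chemistry layer: monoisotopic by default (``mass_kind="mono"``)
    with ``floor(n_cys / 2)`` disulfide bonds when ``disulfides="auto"``, or
    average chain mass with ``mass_kind="average"`` (for kDa-scale proteins).
    """
    sites = find_cleavage_sites(precursor, rules)
    cuts = [precursor.signal_peptide_end] + [pos for pos, _ in sites] + [len(precursor.sequence)]
    rule_names = [rule.name for _, rule in sites] + ["C-terminus"]
    products = []
    for (a, b), rule_name in zip(zip(cuts, cuts[1:]), rule_names):
        frag = precursor.sequence[a:b]
        n_ds = frag.count("C") // 2 if disulfides == "auto" else 0
        if mass_kind == "average":
            mass = average_mass(frag)
        else:
            mass = monoisotopic_mass(frag, n_ds, scheme)
        products.append(
            MatureProduct(
                parent_id=precursor.id,
                start=a + 1,
                end=b,
                sequence=frag,
                mass=mass,
                pi=isoelectric_point(frag),
                rule=rule_name,
                n_disulfides=n_ds,
            )
        )
    return products


@dataclass
class ActivationReport:
    """Prodomain-removal summary for a redulysin-like precursor."""

    prodomain: MatureProduct
    activated: MatureProduct
    prodomain_kda: float  # average mass, one decimal
    activated_kda: float
    prodomain_pi: float  # one decimal
    activated_pi: float
    degenerate_prodomain: bool = False


def activation_report(
    precursor: PrecursorRecord,
    rule: CleavageRule = ACTIVATION_RULE,
) -> ActivationReport:
    """Split a precursor at its single DEER-type activation site.

    Returns the prodomain (upstream, motif retained) and the activated domain
    (downstream), each with average mass in kDa and pI rounded to one decimal
    for comparison against gel-scale ranges. Raises
    :class:`AmbiguousActivationError` when the propeptide carries zero or
    multiple activation motifs. A motif with nothing upstream of it in the
    propeptide yields a motif-only prodomain, flagged degenerate.
    """
    sites = find_cleavage_sites(precursor, [rule])
    if len(sites) != 1:
        raise AmbiguousActivationError(precursor.id, [(p, r.name) for p, r in sites])
    cut, _ = sites[0]
    seq = precursor.sequence
    pro_seq = seq[precursor.signal_peptide_end:cut]
    act_seq = seq[cut:]
    degenerate = pro_seq in rule.motifs

    def _product(frag: str, start0: int, flags: tuple[str, ...]) -> MatureProduct:
        return MatureProduct(
            parent_id=precursor.id,
            start=start0 + 1,
            end=start0 + len(frag),
            sequence=frag,
            mass=average_mass(frag),
            pi=isoelectric_point(frag),
            rule=rule.name,
            flags=flags,
        )

    pro = _product(pro_seq, precursor.signal_peptide_end,
                   ("degenerate_prodomain",) if degenerate else ())
    act = _product(act_seq, cut, ())
    return ActivationReport(
        prodomain=pro,
        activated=act,
        prodomain_kda=round(pro.mass / 1000.0, 1),
        activated_kda=round(act.mass / 1000.0, 1),
        prodomain_pi=round(pro.pi, 1),
        activated_pi=round(act.pi, 1),
        degenerate_prodomain=degenerate,
    )


def read_precursors_fasta(path) -> list[PrecursorRecord]:
    """Read precursors from FASTA; a ``signal_end=N`` header key sets the
    signal-peptide boundary."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        keys = peptide_chem._parse_header_keys(rec.description)
        records.append(
            PrecursorRecord(
                id=rec.id,
                sequence=str(rec.seq),
                signal_peptide_end=int(keys.get("signal_end", 0)),
            )
        )
    return records


def read_rules_tsv(path) -> list[CleavageRule]:
    """Read cleavage rules from TSV: name, motifs (comma-separated),
    cut_offset, motif_retained_on."""
    df = pd.read_csv(path, sep="\t")
    rules = []
    for _, row in df.iterrows():
        rules.append(
            CleavageRule(
                name=str(row["name"]),
                motifs=tuple(str(row["motifs"]).split(",")),
                cut_offset=int(row.get("cut_offset", 0) or 0),
                motif_retained_on=str(row.get("motif_retained_on", "upstream")),
            )
        )
    return rules


def products_to_frame(products: Iterable[MatureProduct]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parent": p.parent_id,
                "start": p.start,
                "end": p.end,
                "sequence": p.sequence,
                "mass": p.mass,
                "pi": p.pi,
                "rule": p.rule,
                "n_disulfides": p.n_disulfides,
                "flags": ";".join(p.flags),
            }
            for p in products
        ]
    )
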