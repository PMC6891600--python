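"""Mass, modification, pI and cysteine-framework calculations for mature venom peptides.

Heteropteran venom peptides are short, disulfide-rich and secreted. Comparing
native and reduced/alkylated (RA) LC-MS masses of the same peptide reveals how
many of its cysteines were engaged in intrachain disulfide bonds: reduction
opens each bond (restoring two hydrogens) and 2-iodoethanol alkylation then
adds a hydroxyethyl group to every freed half-cystine. This module implements
that arithmetic, the six-cysteine framework classifier used to sort peptides
into inhibitor-cystine-knot (ICK/knottin) versus pacifastin folds, and a
Henderson-Hasselbalch isoelectric-point solver.

Masses are monoisotopic unless stated otherwise. Two disulfide conventions are
supported: ``exact`` subtracts the true mass of two hydrogen atoms per bond
(2 x 1.007825 Da) while ``paper_compat`` subtracts 2.000 Da per bond, the
rounded convention under which published theoretical masses for these peptides
reproduce at two-decimal precision.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "MONOISOTOPIC_RESIDUE_MASS",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MONOISOTOPIC",
    "WATER_AVERAGE",
    "HALF_CYSTINE_INCREMENT",
    "CARBAMYL_INCREMENT",
    "STANDARD_RESIDUES",
    "ModificationScheme",
    "EXACT",
    "PAPER_COMPAT",
    "PkaSet",
    "EMBOSS_PKA",
    "PeptideRecord",
    "InvalidSequenceError",
    "DisulfideConstraintError",
    "validate_sequence",
    "monoisotopic_mass",
    "average_mass",
    "reduced_alkylated_mass",
    "HalfCystineInference",
    "infer_half_cystines",
    "classify_cysteine_framework",
    "net_charge",
    "isoelectric_point",
    "build_mass_table",
    "read_peptides_fasta",
    "read_peptides_tsv",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# Standard residue monoisotopic masses (Da), i.e. amino acid minus water.
MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

# Average (isotope-abundance-weighted) residue masses (Da), for kDa-scale
# protein reports where monoisotopic resolution is not meaningful.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MONOISOTOPIC = 18.010565
WATER_AVERAGE = 18.01528
HYDROGEN_MONOISOTOPIC = 1.007825

#: Mass added per half-cystine on reduction + 2-iodoethanol alkylation
#: (hydroxyethylation; net of the hydrogen restored by reduction).
HALF_CYSTINE_INCREMENT = 45.034

#: Optional lysine carbamylation adduct (HNCO addition).
CARBAMYL_INCREMENT = 43.00581


class InvalidSequenceError(ValueError):
    """Sequence is empty or contains a non-standard residue."""


class DisulfideConstraintError(ValueError):
    """More disulfide bonds requested than the cysteine content allows."""


def validate_sequence(sequence: str) -> str:
    """Upper-case and validate a single-letter amino-acid string."""
    if not isinstance(sequence, str) or not sequence:
        raise InvalidSequenceError("sequence must be a non-empty string")
    seq = sequence.upper()
    bad = set(seq) - set(STANDARD_RESIDUES)
    if bad:
        raise InvalidSequenceError(
            f"non-standard residue(s) {sorted(bad)} in sequence {sequence!r}"
        )
    return seq


@dataclass(frozen=True)
class ModificationScheme:
    """Disulfide/alkylation mass conventions.

    Parameters
    ----------
    mode:
        ``"exact"`` subtracts 2 x 1.007825 Da per disulfide bond (the two
        hydrogen atoms lost on oxidation). ``"paper_compat"`` subtracts a
        rounded 2.000 Da per bond; published theoretical masses for these
        venom peptides follow this convention.
    half_cystine_increment:
        Da added per alkylated half-cystine (fixed at 45.034 in both modes).
    """

    mode: str = "exact"
    half_cystine_increment: float = HALF_CYSTINE_INCREMENT

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "paper_compat"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def disulfide_correction(self) -> float:
        """Da subtracted per disulfide bond from the reduced-chain mass."""
        return 2 * HYDROGEN_MONOISOTOPIC if self.mode == "exact" else 2.000


EXACT = ModificationScheme("exact")
PAPER_COMPAT = ModificationScheme("paper_compat")


def _scheme(scheme) -> ModificationScheme:
    if isinstance(scheme, ModificationScheme):
        return scheme
    return ModificationScheme(str(scheme))


def monoisotopic_mass(
    sequence: str,
    n_disulfides: int = 0,
    scheme: ModificationScheme | str = EXACT,
    n_carbamyl: int = 0,
) -> float:
    """Monoisotopic mass (Da) of a peptide with ``n_disulfides`` intrachain bonds.

    ``n_carbamyl`` optionally adds carbamylation adducts (+43.00581 Da each);
    none are applied by default.
    """
    seq = validate_sequence(sequence)
    sch = _scheme(scheme)
    if n_disulfides < 0 or 2 * n_disulfides > seq.count("C"):
        raise DisulfideConstraintError(
            f"{n_disulfides} disulfides impossible for {seq.count('C')} cysteines"
        )
    mass = sum(MONOISOTOPIC_RESIDUE_MASS[r] for r in seq) + WATER_MONOISOTOPIC
    return mass - n_disulfides * sch.disulfide_correction + n_carbamyl * CARBAMYL_INCREMENT


def average_mass(sequence: str) -> float:
    """Average (chemical) mass (Da) of the reduced peptide chain."""
    seq = validate_sequence(sequence)
    return sum(AVERAGE_RESIDUE_MASS[r] for r in seq) + WATER_AVERAGE


def reduced_alkylated_mass(
    sequence: str,
    n_half_cystines: int,
    scheme: ModificationScheme | str = EXACT,
    n_carbamyl: int = 0,
) -> float:
    """Mass after reduction and 2-iodoethanol alkylation of ``n_half_cystines``.

    The convention treats the native (disulfide-bonded) mass as the baseline
    and adds 45.034 Da per half-cystine, i.e. per cysteine that was engaged in
    a bond (n_half_cystines = 2 x n_disulfides).
    """
    if n_half_cystines < 0 or n_half_cystines % 2:
        raise DisulfideConstraintError("n_half_cystines must be a non-negative even count")
    sch = _scheme(scheme)
    native = monoisotopic_mass(sequence, n_half_cystines // 2, sch, n_carbamyl)
    return native + sch.half_cystine_increment * n_half_cystines


@dataclass(frozen=True)
class HalfCystineInference:
    n_half_cystines: int
    mass_shift: float
    residual: float
    consistent: bool


def infer_half_cystines(
    native_mass: float,
    ra_mass: float,
    tolerance: float = 0.1,
    increment: float = HALF_CYSTINE_INCREMENT,
) -> HalfCystineInference:
    """Infer the number of disulfide-engaged cysteines from a native/RA mass pair.

    The shift between the reduced/alkylated and native observed masses is an
    integer multiple of the per-half-cystine increment; the nearest integer is
    returned, flagged inconsistent when the residual exceeds ``tolerance``.
    """
    if native_mass <= 0 or ra_mass <= 0:
        raise ValueError("masses must be positive")
    if ra_mass < native_mass - tolerance:
        raise ValueError("RA mass below native mass beyond tolerance")
    shift = ra_mass - native_mass
    n = int(round(shift / increment))
    residual = abs(shift - n * increment)
    return HalfCystineInference(n, shift, residual, residual <= tolerance)


def classify_cysteine_framework(sequence: str) -> str:
    """Classify a six-cysteine framework as ``ICK``, ``pacifastin`` or ``unknown``.

    ICK (Ptu1-like knottin): six cysteines with exactly one adjacent CC pair,
    arranged C-x+-C-x+-CC-x+-C-x+-C. Pacifastin: six cysteines, no adjacent
    pair, with the CxxCxC core (exactly two residues between C2 and C3 and one
    between C3 and C4). Anything else, including sequences with more or fewer
    than six cysteines, is ``unknown``: only six-cysteine frameworks are
    classified.
    """
    seq = validate_sequence(sequence)
    positions = [i for i, r in enumerate(seq) if r == "C"]
    if len(positions) != 6:
        return "unknown"
    gaps = [b - a - 1 for a, b in zip(positions, positions[1:])]
    if gaps[2] == 0 and all(g >= 1 for g in (gaps[0], gaps[1], gaps[3], gaps[4])):
        return "ICK"
    if all(g >= 1 for g in gaps) and gaps[1] == 2 and gaps[2] == 1:
        return "pacifastin"
    return "unknown"


@dataclass(frozen=True)
class PkaSet:
    """Acid-dissociation constants for termini and ionisable side chains."""

    n_term: float = 8.6
    c_term: float = 3.6
    D: float = 3.9
    E: float = 4.1
    C: float = 8.5
    Y: float = 10.1
    H: float = 6.5
    K: float = 10.8
    R: float = 12.5
    name: str = "EMBOSS"

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.type == "float":
                v = getattr(self, f.name)
                if not (0.0 < v < 14.0):
                    raise ValueError(f"pKa {f.name}={v} outside (0, 14)")


EMBOSS_PKA = PkaSet()

_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("K", "R", "H")


def net_charge(sequence: str, ph: float, pka: PkaSet = EMBOSS_PKA) -> float:
    """Henderson-Hasselbalch net charge of the peptide at a given pH."""
    seq = validate_sequence(sequence)
    charge = 1.0 / (1.0 + 10 ** (ph - pka.n_term))
    charge -= 1.0 / (1.0 + 10 ** (pka.c_term - ph))
    for res in _BASIC:
        charge += seq.count(res) / (1.0 + 10 ** (ph - getattr(pka, res)))
    for res in _ACIDIC:
        charge -= seq.count(res) / (1.0 + 10 ** (getattr(pka, res) - ph))
    return charge


def isoelectric_point(
    sequence: str, pka: PkaSet = EMBOSS_PKA, tol: float = 0.001
) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so the zero is unique.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class PeptideRecord:
    """A mature venom peptide with its disulfide bookkeeping and masses."""

    id: str
    sequence: str
    n_disulfides: int = 0
    observed_native_mass: Optional[float] = None
    observed_ra_mass: Optional[float] = None
    fold_class: str = field(default="", repr=False)
    theoretical_native_mass: float = field(default=float("nan"), repr=False)
    theoretical_ra_mass: float = field(default=float("nan"), repr=False)
    scheme: ModificationScheme = field(default=EXACT, repr=False)

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence)
        if self.n_disulfides < 0 or 2 * self.n_disulfides > self.n_cys:
            raise DisulfideConstraintError(
                f"{self.id}: {self.n_disulfides} bonds vs {self.n_cys} cysteines"
            )
        self.fold_class = classify_cysteine_framework(self.sequence)
        self.theoretical_native_mass = monoisotopic_mass(
            self.sequence, self.n_disulfides, self.scheme
        )
        self.theoretical_ra_mass = reduced_alkylated_mass(
            self.sequence, 2 * self.n_disulfides, self.scheme
        )

    @property
    def n_cys(self) -> int:
        return self.sequence.count("C")

    @property
    def n_half_cystines(self) -> int:
        return 2 * self.n_disulfides


def build_mass_table(
    records: Iterable[PeptideRecord],
    tolerance: float = 0.1,
) -> pd.DataFrame:
    """Tabulate theoretical vs observed masses with a consistency flag.

    One row per peptide: fold class, cysteine content, theoretical and observed
    native and RA masses, and whether every available observed mass sits within
    ``tolerance`` Da of its theoretical counterpart.
    """
    rows = []
    for rec in records:
        consistent = True
        for obs, theo in (
            (rec.observed_native_mass, rec.theoretical_native_mass),
            (rec.observed_ra_mass, rec.theoretical_ra_mass),
        ):
            if obs is not None and abs(obs - theo) > tolerance:
                consistent = False
        rows.append(
            {
                "id": rec.id,
                "fold": rec.fold_class,
                "n_cys": rec.n_cys,
                "n_disulfides": rec.n_disulfides,
                "theoretical_native": rec.theoretical_native_mass,
                "observed_native": rec.observed_native_mass,
                "theoretical_ra": rec.theoretical_ra_mass,
                "observed_ra": rec.observed_ra_mass,
                "consistent": consistent,
            }
        )
    return pd.DataFrame(rows)


def _parse_header_keys(description: str) -> dict:
    out = {}
    for token in description.split():
        if "=" in token:
            k, v = token.split("=", 1)
            out[k] = v
    return out


def read_peptides_fasta(path, scheme: ModificationScheme = EXACT) -> list[PeptideRecord]:
    """Read peptides from FASTA; a ``disulfides=N`` header key sets the bond count."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        keys = _parse_header_keys(rec.description)
        records.append(
            PeptideRecord(
                id=rec.id,
                sequence=str(rec.seq),
                n_disulfides=int(keys.get("disulfides", 0)),
                scheme=scheme,
            )
        )
    return records


def read_peptides_tsv(path, scheme: ModificationScheme = EXACT) -> list[PeptideRecord]:
    """Read peptides from TSV with columns id, sequence, n_disulfides
    and optional observed_native, observed_ra."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        records.append(
            PeptideRecord(
                id=str(row["id"]),
                sequence=str(row["sequence"]),
                n_disulfides=int(row.get("n_disulfides", 0) or 0),
                observed_native_mass=_opt(row.get("observed_native")),
                observed_ra_mass=_opt(row.get("observed_ra")),
                scheme=scheme,
            )
        )
    return records


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None
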