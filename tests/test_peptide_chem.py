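"""Mass/modification arithmetic, framework classification and pI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reduvenom import peptide_chem as pc

SEQS = st.text(alphabet=pc.STANDARD_RESIDUES, min_size=1, max_size=50)


class TestMonoisotopicMass:
    def test_glycine_exact(self):
        # Elemental composition C2H5NO2 summed from monoisotopic atomic masses.
        assert pc.monoisotopic_mass("G", 0, pc.EXACT) == pytest.approx(75.032, abs=1e-3)

    @pytest.mark.parametrize(
        "seq,n_ds,expected",
        [
            ("MMPVCFEGEKLNKDQTKCIKA", 1, 2410.16),
            ("DEKDCIARGQKCVGENKPCCKGTTCMYYANRCVGV", 3, 3835.69),
        ],
    )
    def test_published_native_masses(self, seq, n_ds, expected):
        mass = pc.monoisotopic_mass(seq, n_ds, pc.PAPER_COMPAT)
        assert round(mass, 2) == pytest.approx(expected, abs=0.0100001)

    @pytest.mark.parametrize(
        "seq,n_half,expected",
        [
            ("DEKDCIARGQKCVGENKPCCKGTTCMYYANRCVGV", 6, 4105.89),
            ("MMPVCFEGEKLNKDQTKCIKA", 2, 2500.23),
        ],
    )
    def test_published_ra_masses(self, seq, n_half, expected):
        mass = pc.reduced_alkylated_mass(seq, n_half, pc.PAPER_COMPAT)
        assert round(mass, 2) == pytest.approx(expected, abs=0.0100001)

    @given(SEQS)
    @settings(deadline=None)
    def test_agrees_with_pyteomics_at_zero_disulfides(self, seq):
        """Independent oracle: pyteomics elemental-composition masses."""
        from pyteomics import mass as pmass

        ours = pc.monoisotopic_mass(seq, 0)
        theirs = pmass.fast_mass(seq, ion_type="M")
        assert ours == pytest.approx(theirs, abs=5e-3)

    @given(SEQS, SEQS)
    @settings(deadline=None)
    def test_additivity(self, s1, s2):
        m = pc.monoisotopic_mass
        assert m(s1 + s2) == pytest.approx(
            m(s1) + m(s2) - pc.WATER_MONOISOTOPIC, abs=1e-9
        )

    def test_mode_difference_is_2h_minus_2_per_bond(self):
        seq = "CCAACCAACC"
        for n_ds in range(4):
            diff = pc.monoisotopic_mass(seq, n_ds, pc.PAPER_COMPAT) - pc.monoisotopic_mass(
                seq, n_ds, pc.EXACT
            )
            assert diff == pytest.approx(0.015650 * n_ds, abs=1e-9)

    def test_cysteine_free_ra_equals_native(self):
        seq = "MKLAAGPTW"
        for scheme in (pc.EXACT, pc.PAPER_COMPAT):
            assert pc.reduced_alkylated_mass(seq, 0, scheme) == pc.monoisotopic_mass(
                seq, 0, scheme
            )

    def test_errors(self):
        with pytest.raises(pc.InvalidSequenceError):
            pc.monoisotopic_mass("")
        with pytest.raises(pc.InvalidSequenceError):
            pc.monoisotopic_mass("ACDX")
        with pytest.raises(pc.DisulfideConstraintError):
            pc.monoisotopic_mass("ACDC", 2)  # only 2 cysteines
        with pytest.raises(pc.DisulfideConstraintError):
            pc.reduced_alkylated_mass("CC", 3)  # odd half-cystine count


class TestInferHalfCystines:
    @pytest.mark.parametrize(
        "native,ra,expected",
        [
            (3061.31, 3331.52, 6),  # observed mass pair, 3-bond knottin
            (1000.00, 1090.07, 2),  # 90.07 / 45.034 = 2.0001
            (500.0, 500.0, 0),
        ],
    )
    def test_known_shifts(self, native, ra, expected):
        res = pc.infer_half_cystines(native, ra)
        assert res.n_half_cystines == expected
        assert res.consistent

    @given(SEQS, st.integers(min_value=0, max_value=5))
    @settings(deadline=None)
    def test_round_trip_identity(self, seq, n_ds):
        """infer(native(s, d), ra(s, 2d)) == 2d whenever d bonds are possible."""
        if 2 * n_ds > seq.count("C"):
            return
        native = pc.monoisotopic_mass(seq, n_ds)
        ra = pc.reduced_alkylated_mass(seq, 2 * n_ds)
        res = pc.infer_half_cystines(native, ra)
        assert res.n_half_cystines == 2 * n_ds
        assert res.residual < 1e-9

    def test_inconsistent_shift_flagged(self):
        res = pc.infer_half_cystines(1000.0, 1022.5)  # 22.5 Da: no integer multiple
        assert not res.consistent

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            pc.infer_half_cystines(-1.0, 45.0)


class TestFrameworkClassifier:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("DEKDCIARGQKCVGENKPCCKGTTCMYYANRCVGV", "ICK"),
            ("TIEKSCKPGTTFKHKDGCNTCKCSDDGKNALCTSKLCL", "pacifastin"),
            ("MMPVCFEGEKLNKDQTKCIKA", "unknown"),
            ("AAAA", "unknown"),  # no cysteines
            ("CCCCCCC", "unknown"),  # seven cysteines
        ],
    )
    def test_examples(self, seq, expected):
        assert pc.classify_cysteine_framework(seq) == expected

    def test_reference_panel_composition(self, reference_peptides):
        """11/12 peptides have six cysteines; 6 classify ICK, 5 pacifastin."""
        folds = [pc.classify_cysteine_framework(s) for s in reference_peptides["sequence"]]
        six_cys = [s.count("C") == 6 for s in reference_peptides["sequence"]]
        assert sum(six_cys) == 11
        assert folds.count("ICK") == 6
        assert folds.count("pacifastin") == 5
        assert folds.count("unknown") == 1
        assert folds == list(reference_peptides["published_fold"])


class TestIsoelectricPoint:
    def test_non_ionisable_midpoint(self):
        pka = pc.EMBOSS_PKA
        expected = (pka.n_term + pka.c_term) / 2
        assert pc.isoelectric_point("GAVLIPFM") == pytest.approx(expected, abs=0.01)

    def test_monotone_in_basic_residues(self):
        assert pc.isoelectric_point("KKKAAA") > pc.isoelectric_point("DDDAAA")

    def test_grid_oracle_all_residues(self):
        """Bisection matches a fine-grid scan of the net-charge zero crossing."""
        seq = "ACDEFGHIKLMNPQRSTVWY"
        grid = np.arange(0.0, 14.0, 0.001)
        charges = np.array([pc.net_charge(seq, ph) for ph in grid])
        crossing = grid[np.argmin(np.abs(charges))]
        assert pc.isoelectric_point(seq) == pytest.approx(crossing, abs=0.01)

    def test_pka_set_validation(self):
        with pytest.raises(ValueError):
            pc.PkaSet(K=15.0)


class TestPeptideRecordAndTable:
    def test_record_invariants(self):
        rec = pc.PeptideRecord("p1", "CIPAANPCRGNAKCCGNYVCKNGRCLPRS", 3,
                               observed_native_mass=3061.31, observed_ra_mass=3331.52)
        assert rec.n_cys == 6
        assert rec.fold_class == "ICK"
        assert rec.theoretical_ra_mass >= rec.theoretical_native_mass
        assert rec.theoretical_ra_mass - rec.theoretical_native_mass == pytest.approx(
            45.034 * rec.n_half_cystines, abs=1e-9
        )

    def test_mass_table_consistency_flag(self):
        good = pc.PeptideRecord("ok", "MMPVCFEGEKLNKDQTKCIKA", 1,
                                observed_native_mass=2410.13)
        bad = pc.PeptideRecord("off", "MMPVCFEGEKLNKDQTKCIKA", 1,
                               observed_native_mass=2409.5)
        table = pc.build_mass_table([good, bad], tolerance=0.1)
        assert table.set_index("id")["consistent"].to_dict() == {"ok": True, "off": False}

    def test_fasta_round_trip(self, tmp_path):
        path = tmp_path / "peps.fasta"
        path.write_text(">p1 disulfides=3\nCIPAANPCRGNAKCCGNYVCKNGRCLPRS\n")
        (rec,) = pc.read_peptides_fasta(path)
        assert rec.n_disulfides == 3
        assert rec.fold_class == "ICK"
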