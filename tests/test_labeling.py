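"""Combinatorial selective labeling: pair codes, assignment, scheme design."""

import itertools

import pytest
from hypothesis import given, strategies as st

from vsdkit import labeling as lb


def brute_force_best_coverage(sequence, stock, max_samples):
    """Independent oracle: enumerate every token matrix up to max_samples."""
    aas = sorted(set(sequence))
    best = 0.0
    for n in range(1, max_samples + 1):
        per_type = [
            [tuple(v) for v in itertools.product(sorted(stock.tokens_for(a)), repeat=n)]
            for a in aas
        ]
        for combo in itertools.product(*per_type):
            scheme = lb.LabelingScheme(dict(zip(aas, combo)))
            best = max(best, lb.assignment_table(scheme, sequence).coverage)
    return best


class TestLabelingType:
    def test_flag_universe_is_closed(self):
        flags = {
            t.token: (t.has15N, t.has13CO, t.has13CA) for t in lb.LabelingType
        }
        assert flags == {
            "X": (False, False, False),
            "N": (True, False, False),
            "C": (False, True, False),
            "D": (True, True, True),
        }

    def test_unknown_token_rejected(self):
        with pytest.raises(lb.UnknownResidueTypeError):
            lb.LabelingType.from_token("Z")


class TestEncodePair:
    @pytest.mark.parametrize(
        "prev,curr,symbol",
        # full 4x4 token table, derived by brute force from the flag
        # definitions: NH iff curr has 15N; +1 for prev 13C', +2 for prev 13CA
        [(p, c, (0 if c in "XC" else 1 + (1 if p in "CD" else 0) + (2 if p == "D" else 0)))
         for p in "XNCD" for c in "XNCD"],
    )
    def test_token_table(self, prev, curr, symbol):
        scheme = lb.LabelingScheme({"A": (prev,), "G": (curr,)})
        assert lb.encode_pair(scheme, "A", "G") == (symbol,)

    def test_sequence_start_has_no_sequential_bits(self):
        scheme = lb.LabelingScheme({"M": ("D",)})
        assert lb.encode_pair(scheme, None, "M") == (1,)

    def test_proline_never_visible(self):
        scheme = lb.LabelingScheme({"P": ("D",), "A": ("D",)})
        assert lb.encode_pair(scheme, "A", "P") == (0,)

    def test_unknown_residue_rejected(self):
        scheme = lb.LabelingScheme({"A": ("D",)})
        with pytest.raises(lb.UnknownResidueTypeError):
            lb.encode_pair(scheme, "A", "B")

    @given(st.permutations(range(3)))
    def test_sample_permutation_equivariance(self, perm):
        scheme = lb.LabelingScheme({"A": ("X", "N", "D"), "G": ("N", "C", "D")})
        permuted = lb.LabelingScheme(
            {
                aa: tuple(scheme.assignment[aa][i] for i in perm)
                for aa in scheme.assignment
            }
        )
        code = lb.encode_pair(scheme, "A", "G")
        code_p = lb.encode_pair(permuted, "A", "G")
        assert tuple(code[i] for i in perm) == code_p


class TestAssignmentTable:
    def test_all_d_single_sample_toy(self):
        # "MAG" all-D: M has no predecessor (NH only), A and G share code 4
        table = lb.assignment_table(
            lb.LabelingScheme({aa: ("D",) for aa in "MAG"}), "MAG"
        )
        status = dict(zip(table.table.aa, table.table.status))
        assert status == {"M": "assigned", "A": "ambiguous", "G": "ambiguous"}
        assert table.coverage == pytest.approx(1 / 3)

    def test_homopolymer_interior_always_ambiguous(self):
        scheme = lb.LabelingScheme({"A": ("D", "N")})
        table = lb.assignment_table(scheme, "AAAA")
        interior = table.table[table.table.residue_id > 1]
        assert (interior.status == "ambiguous").all()

    def test_repeated_type_pairs_never_assignable(self):
        # both GA pairs in MGAFGA share codes under every 2-sample scheme
        stock = lb.LabelingStock.uniform("MGAF")
        aas = sorted(set("MGAFGA"))
        per_type = [
            [tuple(v) for v in itertools.product(sorted(stock.tokens_for(a)), repeat=2)]
            for a in aas
        ]
        for combo in itertools.product(*per_type):
            scheme = lb.LabelingScheme(dict(zip(aas, combo)))
            table = lb.assignment_table(scheme, "MGAFGA").table
            a_rows = table[table.aa == "A"]
            assert not (a_rows.status == "assigned").any()

    def test_invisible_iff_all_zero_code(self):
        scheme = lb.LabelingScheme({"A": ("X",), "G": ("D",)})
        table = lb.assignment_table(scheme, "AGA").table
        assert list(table.status) == ["invisible", "assigned", "invisible"]

    def test_empty_sequence_rejected(self):
        scheme = lb.LabelingScheme({"A": ("D",)})
        with pytest.raises(ValueError):
            lb.assignment_table(scheme, "")

    @given(st.integers(0, 2**16 - 1))
    def test_adding_a_sample_never_decreases_coverage(self, bits):
        # random 2-sample scheme over 4 types from the seed bits
        tokens = "XNCD"
        aas = "AGLS"
        assign = {}
        for i, aa in enumerate(aas):
            assign[aa] = (
                tokens[(bits >> (4 * i)) & 3],
                tokens[(bits >> (4 * i + 2)) & 3],
            )
        seq = "ALGSLAGS"
        cov2 = lb.assignment_table(lb.LabelingScheme(assign), seq).coverage
        extended = {aa: v + ("D",) for aa, v in assign.items()}
        cov3 = lb.assignment_table(lb.LabelingScheme(extended), seq).coverage
        assert cov3 >= cov2


class TestDesignScheme:
    @pytest.mark.parametrize("seq", ["MAGAM", "AGA", "MAGL", "LLAG"])
    def test_exact_matches_brute_force(self, seq):
        stock = lb.LabelingStock.uniform(sorted(set(seq)))
        scheme = lb.design_scheme(seq, stock, max_samples=2)
        cov = lb.assignment_table(scheme, seq).coverage
        assert cov == pytest.approx(brute_force_best_coverage(seq, stock, 2))

    def test_n15_only_stock(self):
        # with X/N only, coverage equals the fraction of residues whose
        # on/off 15N pattern is unique (no HNCO/HNCA bits ever set)
        seq = "MAGL"
        stock = lb.LabelingStock.uniform(sorted(set(seq)), tokens="XN")
        scheme = lb.design_scheme(seq, stock, max_samples=2)
        for sample in lb.predict_spectra(scheme, seq).values():
            assert not sample.hnco.any()
            assert not sample.hnca.any()
        cov = lb.assignment_table(scheme, seq).coverage
        assert cov == pytest.approx(brute_force_best_coverage(seq, stock, 2))

    def test_price_breaks_ties(self):
        # D everywhere and N-for-G both reach full coverage on "MA G" toys;
        # pricing D astronomically must steer the design away from it
        seq = "MAG"
        stock_cheap_n = lb.LabelingStock(
            {aa: frozenset("XNCD") for aa in "MAG"},
            prices={(aa, "D"): 100.0 for aa in "MAG"},
        )
        scheme = lb.design_scheme(seq, stock_cheap_n, max_samples=2)
        best_cov = brute_force_best_coverage(seq, lb.LabelingStock.uniform("MAG"), 2)
        assert lb.assignment_table(scheme, seq).coverage == pytest.approx(best_cov)
        price = scheme.total_price(stock_cheap_n)
        # any scheme at that coverage using <= 1 D token costs <= 100
        assert price <= 200.0

    def test_hopeless_stock_reported(self):
        stock = lb.LabelingStock({"A": frozenset("X"), "G": frozenset("X")})
        with pytest.raises(lb.NoInformativeSchemeError):
            lb.design_scheme("AGA", stock, max_samples=2)

    def test_determinism(self):
        seq = "MAGL"
        stock = lb.LabelingStock.uniform(sorted(set(seq)))
        a = lb.design_scheme(seq, stock, max_samples=2)
        b = lb.design_scheme(seq, stock, max_samples=2)
        assert a.to_frame().equals(b.to_frame())


class TestPredictSpectra:
    def test_all_x_scheme_gives_empty_lists(self):
        scheme = lb.LabelingScheme({"A": ("X",), "G": ("X",)})
        for df in lb.predict_spectra(scheme, "AGAG").values():
            assert df.empty

    def test_all_d_single_sample(self):
        scheme = lb.LabelingScheme({aa: ("D",) for aa in "AGL"})
        spec = lb.predict_spectra(scheme, "AGL")[0]
        assert list(spec.residue_id) == [1, 2, 3]
        assert spec.trosy.all()
        # residue 1 has no predecessor: no HNCO/HNCA
        assert not spec[spec.residue_id == 1].hnco.iloc[0]
        assert spec[spec.residue_id > 1].hnco.all()
        assert spec[spec.residue_id > 1].hnca.all()

    @given(st.integers(0, 2**20 - 1))
    def test_hnco_subset_of_trosy(self, bits):
        tokens = "XNCD"
        aas = "AGLSP"
        assign = {
            aa: (tokens[(bits >> (4 * i)) & 3], tokens[(bits >> (4 * i + 2)) & 3])
            for i, aa in enumerate(aas)
        }
        seq = "ALGSPLAGS"
        for df in lb.predict_spectra(lb.LabelingScheme(assign), seq).values():
            assert set(df[df.hnco].residue_id) <= set(df[df.trosy].residue_id)
            assert not df[df.aa == "P"].shape[0]

    def test_consistent_with_encode_pair(self):
        scheme = lb.LabelingScheme({"A": ("N", "D"), "G": ("C", "X")})
        seq = "AGAG"
        spectra = lb.predict_spectra(scheme, seq)
        for i, aa in enumerate(seq):
            prev = seq[i - 1] if i else None
            code = lb.encode_pair(scheme, prev, aa)
            for s, sym in enumerate(code):
                row = spectra[s][spectra[s].residue_id == i + 1]
                assert (len(row) == 1) == (sym > 0)
                if sym > 0:
                    assert row.hnco.iloc[0] == (sym in (2, 4))
                    assert row.hnca.iloc[0] == (sym in (3, 4))


class TestIO:
    def test_scheme_csv_round_trip(self, tmp_path):
        scheme = lb.LabelingScheme({"A": ("N", "D"), "G": ("C", "X")})
        path = tmp_path / "scheme.csv"
        scheme.to_csv(path)
        again = lb.LabelingScheme.from_csv(path)
        assert again.to_frame().equals(scheme.to_frame())

    def test_fasta_reader(self, tmp_path):
        path = tmp_path / "seq.fasta"
        path.write_text(">toy\nMAGL\nKV\n")
        assert lb.read_fasta_sequence(path) == "MAGLKV"
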