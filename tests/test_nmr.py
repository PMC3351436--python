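"""CSP, intensity, exchange and hydration metrics: formulas and invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allodyn.core_io import PeakTable
from allodyn.nmr import (
    csp,
    csp_significance,
    ephogsy_classify,
    exchange_flags,
    intensity_change,
)


class TestCSP:
    def test_identical_tables_give_zero_everywhere(self, peak_table_factory):
        table = peak_table_factory([30, 31, 32])
        records = csp(table, table)
        assert all(r.combined == 0.0 and r.delta_h == 0.0 and r.delta_n == 0.0
                   for r in records)

    def test_proton_only_shift_collapses_to_delta_h(self, peak_table_factory):
        apo = peak_table_factory([30], dh=[8.0], dn=[115.0])
        holo = peak_table_factory([30], dh=[8.1], dn=[115.0])
        for alpha in (0.1, 0.154, 1.0):
            (rec,) = csp(apo, holo, alpha=alpha)
            assert rec.combined == pytest.approx(0.1, abs=1e-12)

    def test_combined_formula_value(self, peak_table_factory):
        # sqrt(0.03^2 + (0.154*0.5)^2) = sqrt(0.0009 + 0.005929) = 0.08264...
        apo = peak_table_factory([129], dh=[8.0], dn=[115.0])
        holo = peak_table_factory([129], dh=[8.03], dn=[115.5])
        (rec,) = csp(apo, holo, alpha=0.154)
        assert rec.combined == pytest.approx(np.hypot(0.03, 0.077), rel=1e-12)
        assert rec.combined == pytest.approx(0.08264, abs=5e-6)

    def test_invariant_under_uniform_referencing_offset(self, peak_table_factory):
        rng = np.random.default_rng(8)
        dh, dn = rng.uniform(7, 10, 6), rng.uniform(105, 130, 6)
        apo = peak_table_factory(range(1, 7), dh=dh, dn=dn)
        holo = peak_table_factory(range(1, 7), dh=dh + rng.normal(0, 0.05, 6),
                                  dn=dn + rng.normal(0, 0.3, 6))
        shifted_apo = peak_table_factory(range(1, 7), dh=dh + 0.37, dn=dn - 2.1)
        shifted_holo = peak_table_factory(
            range(1, 7), dh=holo.data["dH"].to_numpy() + 0.37,
            dn=holo.data["dN"].to_numpy() - 2.1)
        base = [r.combined for r in csp(apo, holo)]
        moved = [r.combined for r in csp(shifted_apo, shifted_holo)]
        assert np.allclose(base, moved, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(dh=st.floats(-1, 1), dn=st.floats(-5, 5),
           extra=st.floats(0.001, 1.0))
    def test_combined_monotone_in_either_shift(self, dh, dn, extra):
        def table(h, n):
            return PeakTable(pd.DataFrame(
                {"residue": [1], "dH": [h], "dN": [n], "intensity": [1.0]}))

        def comb(a, b):
            return csp(table(8.0, 115.0), table(8.0 + a, 115.0 + b))[0].combined

        base = comb(dh, dn)
        assert comb(dh + np.sign(dh or 1) * extra, dn) >= base
        assert comb(dh, dn + np.sign(dn or 1) * extra) >= base

    def test_disjoint_tables_rejected(self, peak_table_factory):
        with pytest.raises(ValueError, match="no residues"):
            csp(peak_table_factory([1, 2]), peak_table_factory([3, 4]))


class TestCSPSignificance:
    def _records(self, combined, peak_table_factory):
        apo = peak_table_factory(range(1, len(combined) + 1))
        holo = peak_table_factory(range(1, len(combined) + 1),
                                  dh=apo.data["dH"].to_numpy() + np.asarray(combined))
        return csp(apo, holo)

    def test_flat_distribution_flags_nothing(self, peak_table_factory):
        records = self._records([0.02] * 10, peak_table_factory)
        assert not any(r.significant for r in csp_significance(records))

    def test_single_spike_is_flagged(self, peak_table_factory):
        # spike 10x the flat baseline; enough peaks that it dominates the SD
        records = self._records([0.02] * 19 + [0.2], peak_table_factory)
        flagged = [r.residue for r in csp_significance(records) if r.significant]
        assert flagged == [20]

    def test_iterative_exclusion_catches_all_implanted(self, peak_table_factory):
        rng = np.random.default_rng(0)
        baseline = np.abs(rng.normal(0.01, 0.004, 50))
        baseline[[10, 25, 40]] = [0.25, 0.31, 0.28]
        records = self._records(baseline, peak_table_factory)
        flagged = [r.residue for r in csp_significance(records, k=3.0)
                   if r.significant]
        assert flagged == [11, 26, 41]

    def test_fixed_cutoff_mode(self, peak_table_factory):
        records = self._records([0.02, 0.08, 0.15], peak_table_factory)
        flagged = [r.residue for r in
                   csp_significance(records, method="fixed", cutoff=0.1)
                   if r.significant]
        assert flagged == [3]


class TestIntensityChange:
    def test_global_rescale_invariance(self, peak_table_factory):
        rng = np.random.default_rng(3)
        base = rng.uniform(0.5, 2.0, 8)
        apo = peak_table_factory(range(1, 9), intensity=base)
        holo = peak_table_factory(range(1, 9), intensity=7.3 * base)
        for change in intensity_change(apo, holo):
            assert change.ratio == pytest.approx(1.0, rel=1e-12)
            assert change.category == "unchanged"

    def test_low_apo_peak_recovering_is_increased(self, peak_table_factory):
        # one broadened peak at 0.2x baseline recovers to baseline in holo
        apo_i = np.ones(10)
        apo_i[4] = 0.2
        apo = peak_table_factory(range(1, 11), intensity=apo_i)
        holo = peak_table_factory(range(1, 11), intensity=np.ones(10))
        by_res = {c.residue: c for c in intensity_change(apo, holo)}
        assert by_res[5].category == "increased"
        assert all(by_res[r].category == "unchanged" for r in by_res if r != 5)

    def test_missing_peaks_get_directional_classes(self, peak_table_factory):
        apo = peak_table_factory([1, 2, 3], intensity=[1.0, np.nan, 1.2])
        holo = peak_table_factory([1, 2, 3], intensity=[np.nan, 1.0, 1.1])
        by_res = {c.residue: c for c in intensity_change(apo, holo)}
        assert by_res[1].category == "disappeared"
        assert by_res[2].category == "appeared"
        assert np.isnan(by_res[1].ratio)

    def test_sidechains_normalized_separately(self, peak_table_factory):
        residues = [1, 2, 50, 51, 52, 53, 54]
        sc = [False, False, True, True, True, True, True]
        apo = peak_table_factory(residues, intensity=[1, 1, 10, 10, 10, 10, 10],
                                 sidechain=sc)
        holo = peak_table_factory(residues, intensity=[1, 1, 30, 10, 10, 10, 10],
                                  sidechain=sc)
        by_res = {(c.residue, c.sidechain): c for c in intensity_change(apo, holo)}
        assert by_res[(50, True)].category == "increased"
        assert by_res[(51, True)].category == "unchanged"
        assert by_res[(1, False)].category == "unchanged"


class TestExchangeFlags:
    def test_uniform_ratio_flags_nothing(self, relaxation_factory):
        ds = relaxation_factory(range(1, 11), r2=12.0, r1rho=12.0)
        flags = exchange_flags(ds)
        assert all(f.ratio == 1.0 and not f.flagged for f in flags)

    def test_clear_outlier_is_flagged(self, relaxation_factory):
        rng = np.random.default_rng(1)
        r1rho = np.full(20, 12.0)
        r2 = 12.0 * (1 + rng.normal(0, 0.05, 20))
        r2[7] = 24.0  # ratio 2.0 against baseline ~1.0
        ds = relaxation_factory(range(1, 21), r2=r2, r1rho=r1rho)
        flagged = [f.residue for f in exchange_flags(ds, k=1.0) if f.flagged]
        assert flagged == [8]

    def test_flag_set_monotone_in_k(self, relaxation_factory):
        rng = np.random.default_rng(5)
        r2 = 12.0 * (1 + np.abs(rng.normal(0, 0.2, 30)))
        ds = relaxation_factory(range(1, 31), r2=r2, r1rho=np.full(30, 12.0))
        previous = None
        for k in (0.5, 1.0, 2.0, 4.0):
            current = {f.residue for f in exchange_flags(ds, k=k) if f.flagged}
            if previous is not None:
                assert current <= previous
            previous = current

    def test_error_propagation_in_quadrature(self, relaxation_factory):
        ds = relaxation_factory([1] * 1 + [2, 3, 4, 5], r2=12.0, r1rho=10.0,
                                R2_err=0.6, R1rho_err=0.5)
        f = exchange_flags(ds)[0]
        expected = 1.2 * np.sqrt((0.6 / 12) ** 2 + (0.5 / 10) ** 2)
        assert f.error == pytest.approx(expected, rel=1e-12)


class TestHydration:
    def _tables(self, noe_a, noe_h, roe_a=None, roe_h=None, peak=None):
        n = len(noe_a)
        make = peak
        residues = list(range(1, n + 1))
        return (make(residues, intensity=noe_a), make(residues, intensity=roe_a or noe_a),
                make(residues, intensity=noe_h), make(residues, intensity=roe_h or noe_h))

    def test_no_change_when_holo_equals_apo(self, peak_table_factory):
        a, ra, h, rh = self._tables([1.0, 2.0, 0.5], [1.0, 2.0, 0.5],
                                    peak=peak_table_factory)
        recs = ephogsy_classify(a, ra, h, rh)
        assert not any(r.noe_changed or r.roe_changed for r in recs)

    @pytest.mark.parametrize("factor,expect", [(1.6, True), (1.4, False)])
    def test_fifty_percent_change_rule(self, peak_table_factory, factor, expect):
        noe_a = [1.0] * 21
        noe_h = [1.0] * 21
        noe_h[4] = factor  # the normalizer moves little with 21 peaks
        a, ra, h, rh = self._tables(noe_a, noe_h, peak=peak_table_factory)
        recs = {r.residue: r for r in ephogsy_classify(a, ra, h, rh)}
        # compare the residue's normalized ratio against the 50% rule directly
        assert recs[5].noe_changed == (abs(recs[5].noe_holo / recs[5].noe_apo - 1) > 0.5)
        assert recs[5].noe_changed is expect

    def test_three_level_classes_and_roe_exclusion(self, peak_table_factory):
        noe = [0.1, 0.5, 2.0, 0.1, 2.2, 0.6]
        roe = [0.1, 0.1, 0.1, 0.1, 3.0, 0.1]
        a, ra, h, rh = self._tables(noe, noe, roe_a=roe, roe_h=roe,
                                    peak=peak_table_factory)
        recs = {r.residue: r for r in ephogsy_classify(a, ra, h, rh,
                                                       thresholds=(0.4, 1.0))}
        assert recs[1].noe_class == "low"
        assert recs[2].noe_class == "medium"
        assert recs[3].noe_class == "high"
        assert recs[3].water_proximal          # high NOE, quiet ROE
        assert not recs[5].water_proximal      # high NOE but ROE correlation
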