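"""Cohort assignment, the correlation boundary, and gene selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize

from funcdiv.data_model import VERTEBRATES, Cohort, OrthologueSet
from funcdiv.diversity import score_all
from funcdiv.selection import (
    ZeroVarianceError,
    assign_cohort,
    build_orthologue_sets,
    cohort_summary,
    contributing_species,
    correlate_and_select,
    critical_r,
    eligible,
    pearson_r,
)

from conftest import make_record


def make_oset(species_ids, symbol="S", one_to_one=True):
    records = {
        sid: make_record(gene_id=f"{sid}_{symbol}", species_id=sid,
                         human_symbol=symbol, one_to_one=one_to_one)
        for sid in species_ids
    }
    if "hsapiens" not in records:
        records["hsapiens"] = make_record(
            gene_id=f"hs_{symbol}", species_id="hsapiens", human_symbol=symbol
        )
    oset = OrthologueSet(human_symbol=symbol, records=records)
    oset.cohort = assign_cohort(oset)
    oset.contributing_species = contributing_species(oset, oset.cohort)
    return oset


ALL_NINE = (
    "celegans", "dmelanogaster", "cintestinalis", "trubripes",
    "xtropicalis", "ggallus", "mmusculus", "mmulatta", "hsapiens",
)


class TestCohorts:
    def test_all_nine_species_is_worm_first(self):
        assert make_oset(ALL_NINE).cohort is Cohort.WORM_FIRST

    def test_fly_plus_vertebrates_is_fly_first(self):
        oset = make_oset(("dmelanogaster",) + VERTEBRATES)
        assert oset.cohort is Cohort.FLY_FIRST

    def test_ciona_plus_five_vertebrates_is_unassigned(self):
        oset = make_oset(("cintestinalis",) + VERTEBRATES[1:])
        assert oset.cohort is Cohort.UNASSIGNED
        assert not eligible(oset)

    def test_all_six_vertebrates_is_vertebrate_cohort(self):
        oset = make_oset(VERTEBRATES)
        assert oset.cohort is Cohort.VERTEBRATE
        assert eligible(oset)
        assert oset.n_orthologues == 6

    def test_ciona_cohort_flag_routes_ciona_first_genes(self):
        records = {
            sid: make_record(gene_id=sid, species_id=sid, human_symbol="S")
            for sid in ("cintestinalis",) + VERTEBRATES
        }
        oset = OrthologueSet(human_symbol="S", records=records)
        assert assign_cohort(oset) is Cohort.VERTEBRATE  # spec default path
        assert assign_cohort(oset, ciona_cohort=True) is Cohort.CIONA_FIRST

    def test_worm_first_needs_six_orthologues(self):
        six = make_oset(("celegans", "dmelanogaster", "trubripes",
                         "ggallus", "mmusculus", "hsapiens"))
        assert six.cohort is Cohort.WORM_FIRST and eligible(six)
        five = make_oset(("celegans", "dmelanogaster", "trubripes",
                          "ggallus", "hsapiens"))
        assert five.cohort is Cohort.WORM_FIRST and not eligible(five)

    def test_non_one_to_one_records_do_not_count(self):
        records = {
            sid: make_record(gene_id=sid, species_id=sid, human_symbol="S",
                             one_to_one=(sid != "celegans"))
            for sid in ALL_NINE
        }
        oset = OrthologueSet(human_symbol="S", records=records)
        oset.cohort = assign_cohort(oset)
        assert oset.cohort is Cohort.FLY_FIRST  # worm record is not one-to-one

    def test_build_orthologue_sets_drops_groups_without_human(self, caplog):
        recs = [
            make_record(gene_id="m", species_id="mmusculus", human_symbol="NOHUM"),
            make_record(gene_id="h", species_id="hsapiens", human_symbol="OK"),
        ]
        with caplog.at_level("WARNING"):
            osets = build_orthologue_sets(recs)
        assert [o.human_symbol for o in osets] == ["OK"]


class TestPearson:
    def test_perfect_linearity(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_anti_linearity(self):
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_reference_value_from_definition(self):
        # oracle: direct evaluation of the product-moment definition
        assert pearson_r([29, 60, 171], [1.0, 2.0, 2.5]) == pytest.approx(
            0.875368, abs=1e-5
        )

    def test_zero_variance_signalled(self):
        with pytest.raises(ZeroVarianceError):
            pearson_r([1, 2, 3], [5, 5, 5])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])

    @given(
        data=st.lists(
            st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
            min_size=4, max_size=12,
        ),
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
    )
    @settings(max_examples=150, derandomize=True)
    def test_affine_invariance_and_antisymmetry(self, data, a, b):
        xs = [d[0] for d in data]
        ys = [d[1] for d in data]
        try:
            r = pearson_r(xs, ys)
        except ZeroVarianceError:
            return
        scaled = [a * x + b for x in xs]
        try:
            r_scaled = pearson_r(scaled, ys)
        except ZeroVarianceError:
            return
        assert r_scaled == pytest.approx(r, abs=1e-6)
        assert pearson_r(xs, [-y for y in ys]) == pytest.approx(-r, abs=1e-9)


def r_crit_by_density_inversion(n, alpha=0.05):
    """Independent oracle: bisect the exact null density of r.

    Under the null the sample correlation of n bivariate-normal pairs has
    density proportional to (1 - r^2)^((n - 4) / 2) on (-1, 1); the critical
    value solves P(|R| > c) = alpha.
    """
    df = n - 2
    norm, _ = integrate.quad(lambda r: (1 - r * r) ** ((df - 2) / 2), -1, 1)

    def upper_tail(c):
        val, _ = integrate.quad(lambda r: (1 - r * r) ** ((df - 2) / 2), c, 1)
        return 2 * val / norm

    return optimize.brentq(lambda c: upper_tail(c) - alpha, 1e-9, 1 - 1e-9, xtol=1e-10)


class TestCriticalR:
    @pytest.mark.parametrize("n", range(4, 13))
    def test_matches_exact_density_inversion_to_3dp(self, n):
        assert critical_r(n) == pytest.approx(r_crit_by_density_inversion(n), abs=5e-4)

    def test_derived_value_n4(self):
        # t_c(df=2) = 4.3027 -> 4.3027 / sqrt(4.3027^2 + 2)
        assert critical_r(4) == pytest.approx(0.950, abs=1e-3)

    def test_monotonically_decreasing_in_n(self):
        values = [critical_r(n) for n in range(3, 30)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            critical_r(2)

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            critical_r(9, alpha=0.0)


class TestCorrelateAndSelect:
    def test_perfectly_correlated_gene_is_selected(self, species_table):
        oset = make_oset(ALL_NINE, symbol="PERF")
        scores = score_all([oset.records[sid] for sid in ALL_NINE])
        # overwrite df to be linear in cell-type number
        from funcdiv.diversity import DiversityScore

        scores = [
            DiversityScore(s.gene_id, s.species_id, s.human_symbol,
                           species_table.cell_types(s.species_id) / 50.0)
            for s in scores
        ]
        (res,) = correlate_and_select([oset], scores, species_table)
        assert res.r == pytest.approx(1.0)
        assert res.selected

    def test_constant_df_gene_excluded(self, species_table, caplog):
        oset = make_oset(ALL_NINE, symbol="FLAT")
        scores = score_all([oset.records[sid] for sid in ALL_NINE])  # all zero D_F
        with caplog.at_level("INFO"):
            results = correlate_and_select([oset], scores, species_table)
        assert results == []

    def test_missing_score_excludes_gene_with_log(self, species_table, caplog):
        oset = make_oset(ALL_NINE, symbol="MISS")
        scores = score_all([oset.records[sid] for sid in ALL_NINE[:-1]])
        with caplog.at_level("WARNING"):
            results = correlate_and_select([oset], scores, species_table)
        assert results == []
        assert any("MISS" in m for m in caplog.messages)

    def test_selection_monotone_in_planted_signal(self, species_table):
        """Selection frequency is non-decreasing as rho rises 0 -> 0.95."""
        from funcdiv.data_model import Cohort as C
        from funcdiv.simulate import SimConfig, simulate_dataset

        freqs = []
        for rho in (0.0, 0.5, 0.8, 0.95):
            cfg = SimConfig(
                seed=11, n_genes=300, frac_signal=1.0, rho=rho, dropout=0.0,
                cohort_mix={C.WORM_FIRST: 1.0}, clique_sizes=(), noise_edge_rate=0.0,
            )
            data = simulate_dataset(cfg)
            results = correlate_and_select(
                build_orthologue_sets(data.records),
                score_all(data.records),
                species_table,
            )
            freqs.append(np.mean([r.selected for r in results]))
        assert all(a <= b + 0.02 for a, b in zip(freqs, freqs[1:]))
        assert freqs[-1] > 0.8

    def test_cohort_summary_shape(self, species_table, small_dataset):
        results = correlate_and_select(
            build_orthologue_sets(small_dataset.records),
            score_all(small_dataset.records),
            species_table,
        )
        summary = cohort_summary(results)
        assert list(summary.columns) == [
            "cohort", "n_orthologues", "r_crit_2dp", "genes_selected"
        ]
        # every (cohort, n) row's selected count matches a direct recount
        for _, row in summary.iterrows():
            direct = sum(
                r.selected
                for r in results
                if str(r.cohort) == row["cohort"] and r.n == row["n_orthologues"]
            )
            assert row["genes_selected"] == direct
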