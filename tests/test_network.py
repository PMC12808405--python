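import numpy as np
import pytest
import statsmodels.api as sm
from statsmodels.formula.api import ols as sm_ols
from statsmodels.stats.outliers_influence import OLSInfluence

from cohortlink.network import (
    ASSAY_PAIRS,
    EdgeCandidate,
    EdgeCriteria,
    adjust_and_filter,
    assemble_network,
    build_network,
    candidates_to_frame,
    classify_slope_pattern,
    edge_line_data,
    enumerate_candidates,
    fit_all,
    fit_edge,
    prepare_network_tables,
)
from cohortlink.preprocess import NETWORK_MIN_PREVALENCE
from cohortlink.stats import SlopeEstimate, bh_adjust
from cohortlink.tables import AnalyteTable


def _immune(analyte_ids, values, assay, sample_ids):
    return AnalyteTable(
        sample_ids=tuple(sample_ids),
        analyte_ids=tuple(analyte_ids),
        values=np.asarray(values, dtype=float),
        assay=assay,
        value_kind="percent_frequency",
    )


@pytest.fixture(scope="module")
def analysis_tables(small_study):
    return prepare_network_tables(small_study.tables)


@pytest.fixture(scope="module")
def fitted_candidates(analysis_tables, small_study):
    cands = enumerate_candidates(
        analysis_tables, small_study.metadata, both_orientations=True
    )
    return fit_all(cands, analysis_tables, small_study.metadata)


class TestEnumerate:
    def test_pair_product_single_orientation(self, small_study, rng):
        ids = small_study.metadata.sample_ids
        n = len(ids)
        blood = _immune(["b1", "b2", "b3"], rng.uniform(1, 50, (n, 3)), "blood_cells", ids)
        colon = _immune(["c1", "c2"], rng.uniform(1, 50, (n, 2)), "colonic_cells", ids)
        cands = enumerate_candidates(
            {"blood_cells": blood, "colonic_cells": colon}, small_study.metadata
        )
        assert len(cands) == 6
        assert all(c.response_assay == "blood_cells" for c in cands)
        assert all(c.assay_pair == ("blood_cells", "colonic_cells") for c in cands)

    def test_both_orientations_doubles(self, small_study, rng):
        ids = small_study.metadata.sample_ids
        n = len(ids)
        blood = _immune(["b1", "b2", "b3"], rng.uniform(1, 50, (n, 3)), "blood_cells", ids)
        colon = _immune(["c1", "c2"], rng.uniform(1, 50, (n, 2)), "colonic_cells", ids)
        cands = enumerate_candidates(
            {"blood_cells": blood, "colonic_cells": colon},
            small_study.metadata,
            both_orientations=True,
        )
        assert len(cands) == 12
        assert sum(c.response_assay == "colonic_cells" for c in cands) == 6

    def test_only_declared_assay_pairs(self, fitted_candidates):
        assert {c.assay_pair for c in fitted_candidates} <= set(ASSAY_PAIRS)
        # microbe-microbe pairs never appear
        for c in fitted_candidates:
            assert not (
                c.response_assay.endswith("microbes")
                and c.predictor_assay.endswith("microbes")
            )

    def test_low_prevalence_microbes_dropped(self, analysis_tables, small_study):
        cands = enumerate_candidates(analysis_tables, small_study.metadata)
        tested = {
            c.predictor_analyte
            for c in cands
            if c.predictor_assay == "fecal_microbes"
        }
        t = analysis_tables["fecal_microbes"]
        vals = np.asarray(t.values)
        for j, analyte in enumerate(t.analyte_ids):
            prevalent = (vals[:, j] > 0).sum() >= NETWORK_MIN_PREVALENCE
            assert (analyte in tested) == prevalent


class TestFitEdge:
    def _oracle_frame(self, cand, tables, meta):
        import pandas as pd

        frame = meta.frame.loc[list(cand.samples), ["age", "day", "gender", "cohort"]].copy()
        frame["y"] = (
            tables[cand.response_assay]
            .subset_samples(cand.samples)
            .column(cand.response_analyte)
        )
        frame["x"] = (
            tables[cand.predictor_assay]
            .subset_samples(cand.samples)
            .column(cand.predictor_analyte)
        )
        return frame

    def test_immune_pair_matches_statsmodels(self, analysis_tables, small_study):
        cands = [
            c
            for c in enumerate_candidates(analysis_tables, small_study.metadata)
            if c.assay_pair == ("blood_cells", "colonic_cells")
        ][:5]
        for cand in cands:
            fit_edge(cand, analysis_tables, small_study.metadata)
            frame = self._oracle_frame(cand, analysis_tables, small_study.metadata)
            full = sm_ols(
                "y ~ age + day + C(gender) + C(cohort) + x + x:C(cohort)", frame
            ).fit()
            red = sm_ols("y ~ age + day + C(gender) + C(cohort)", frame).fit()
            f_ref, p_ref, _ = full.compare_f_test(red)
            assert cand.partial_f == pytest.approx(f_ref, rel=1e-8)
            assert cand.partial_f_p == pytest.approx(p_ref, rel=1e-6, abs=1e-15)
            ref_dffits = np.nanmax(np.abs(OLSInfluence(full).dffits[0]))
            assert cand.max_abs_dffits == pytest.approx(ref_dffits, rel=1e-8)

    def test_microbe_pair_carries_reads(self, analysis_tables, small_study):
        cand = next(
            c
            for c in enumerate_candidates(analysis_tables, small_study.metadata)
            if c.assay_pair == ("colonic_cells", "fecal_microbes")
        )
        fit_edge(cand, analysis_tables, small_study.metadata)
        assert "reads" in cand.coefficients
        frame = self._oracle_frame(cand, analysis_tables, small_study.metadata)
        frame["reads"] = (
            small_study.metadata.reads("fecal_microbes").loc[list(cand.samples)].astype(float)
        )
        full = sm_ols(
            "y ~ reads + age + day + C(gender) + C(cohort) + x + x:C(cohort)", frame
        ).fit()
        red = sm_ols("y ~ reads + age + day + C(gender) + C(cohort)", frame).fit()
        assert cand.partial_f_p == pytest.approx(
            full.compare_f_test(red)[1], rel=1e-6, abs=1e-15
        )

    def test_per_cohort_slopes_match_per_cohort_refits_in_sign(self, fitted_candidates):
        # slope estimates carry one entry per cohort, in canonical order
        cand = next(c for c in fitted_candidates if c.fitted and not c.unevaluable)
        assert [s.level for s in cand.slopes] == [
            "HIV- non-MSM",
            "HIV- MSM",
            "HIV+ MSM",
        ]

    def test_small_sample_marked_unevaluable(self, analysis_tables, small_study):
        cand = enumerate_candidates(analysis_tables, small_study.metadata)[0]
        # 10 samples spanning all three cohorts: the full design has
        # 9 columns (intercept, age, day, gender, 2 cohorts, x, 2
        # interactions), so n <= p + 1 and the fit is not evaluable
        frame = small_study.metadata.frame
        picked = []
        for cohort, k in (("HIV- non-MSM", 4), ("HIV- MSM", 3), ("HIV+ MSM", 3)):
            picked += list(frame.index[frame["cohort"] == cohort][:k])
        cand.samples = tuple(sorted(picked))
        fit_edge(cand, analysis_tables, small_study.metadata)
        assert cand.fitted and cand.unevaluable
        assert not cand.retained


class TestAdjustAndFilter:
    def test_q_is_bh_within_assay_pair(self, fitted_candidates):
        adjust_and_filter(fitted_candidates)
        fitted = [c for c in fitted_candidates if c.fitted and not c.unevaluable]
        pairs = np.array(["|".join(c.assay_pair) for c in fitted])
        q_ref = bh_adjust(np.array([c.partial_f_p for c in fitted]), pairs)
        np.testing.assert_allclose([c.q for c in fitted], q_ref, atol=1e-12)

    def test_exclusion_reasons_respect_thresholds(self, fitted_candidates):
        crit = EdgeCriteria(fdr=0.05, slope_p=0.005, dffits_max=2.0, skew_max=3.0)
        retained = adjust_and_filter(fitted_candidates, crit)
        for c in fitted_candidates:
            if not c.fitted or c.unevaluable:
                continue
            assert ("fdr" in c.exclusions) == (not c.q < crit.fdr)
            assert ("slope" in c.exclusions) == (not c.min_slope_p < crit.slope_p)
            assert ("influence" in c.exclusions) == (c.max_abs_dffits > crit.dffits_max)
            assert ("skew" in c.exclusions) == (
                max(c.skew_response, c.skew_predictor) > crit.skew_max
            )
            assert (c in retained) == (c.exclusions == ())

    def test_all_pass_with_vacuous_thresholds(self, fitted_candidates):
        crit = EdgeCriteria(fdr=2.0, slope_p=2.0, dffits_max=np.inf, skew_max=np.inf)
        retained = adjust_and_filter(fitted_candidates, crit)
        evaluable = [c for c in fitted_candidates if c.fitted and not c.unevaluable]
        assert len(retained) == len(evaluable)

    def test_none_pass_with_impossible_influence_threshold(self, fitted_candidates):
        retained = adjust_and_filter(fitted_candidates, EdgeCriteria(dffits_max=-1.0))
        assert retained == []
        # restore the default criteria markings for later tests
        adjust_and_filter(fitted_candidates)


class TestPattern:
    def _cand(self, slopes):
        c = EdgeCandidate(
            assay_pair=("blood_cells", "colonic_cells"),
            response_assay="blood_cells",
            response_analyte="a",
            predictor_assay="colonic_cells",
            predictor_analyte="b",
            samples=("s1",),
        )
        c.slopes = [
            SlopeEstimate(level=lev, slope=sl, se=1.0, p=p)
            for lev, sl, p in zip(
                ("HIV- non-MSM", "HIV- MSM", "HIV+ MSM"),
                *zip(*slopes),
            )
        ]
        return c

    def test_two_threshold_rule(self):
        # significant positive, non-significant, significant negative
        c = self._cand([(1.0, 0.01), (1.0, 0.5), (-1.0, 0.001)])
        assert classify_slope_pattern(c, alpha=0.05) == "p~n"

    def test_boundary_alpha_is_strict(self):
        c = self._cand([(1.0, 0.05), (1.0, 0.049), (-1.0, 0.2)])
        assert classify_slope_pattern(c, alpha=0.05) == "~p~"

    def test_missing_cohort_is_tilde(self):
        c = self._cand([(1.0, 0.01), (1.0, 0.01), (1.0, 0.01)])
        c.slopes = c.slopes[:2]
        assert classify_slope_pattern(c) == "pp~"


class TestAssembly:
    def test_planted_cross_assay_edges_recovered(self, small_study, analysis_tables):
        graph, _ = build_network(small_study.tables, small_study.metadata)
        # demo effect: colonic pop_003 tracks blood pop_004 in both MSM cohorts
        assert graph.has_edge("blood_cells:pop_004", "colonic_cells:pop_003")
        attrs = graph.edges["blood_cells:pop_004", "colonic_cells:pop_003"]
        assert attrs["pattern"] == "~pp"
        # demo effect: a colonic ASV tracks colonic pop_005 in HIV+ MSM only
        asv_node = next(
            (u, v)
            for u, v in graph.edges
            if "colonic_cells:pop_005" in (u, v)
            and any(n.startswith("colonic_microbes:") for n in (u, v))
        )
        assert graph.edges[asv_node]["pattern"] == "~~n"

    def test_orientations_deduplicated_keeping_smaller_q(self, fitted_candidates):
        retained = adjust_and_filter(fitted_candidates)
        graph = assemble_network(retained)
        seen = {}
        for e in retained:
            key = frozenset(e.node_ids)
            seen.setdefault(key, []).append(e)
        assert graph.number_of_edges() == len(seen)
        for key, group in seen.items():
            u, v = tuple(key)
            best_q = min(e.q for e in group)
            assert graph.edges[u, v]["q"] == pytest.approx(best_q)
            assert graph.edges[u, v]["n_orientations"] == len(group)

    def test_node_degree_attribute_matches_recount(self, fitted_candidates):
        graph = assemble_network(adjust_and_filter(fitted_candidates))
        for node in graph.nodes:
            assert graph.nodes[node]["degree"] == graph.degree[node]
            assert graph.nodes[node]["assay"] in {
                "blood_cells",
                "colonic_cells",
                "fecal_microbes",
                "colonic_microbes",
            }

    def test_null_study_yields_sparse_network(self, null_study):
        graph, candidates = build_network(null_study.tables, null_study.metadata)
        evaluable = [c for c in candidates if c.fitted and not c.unevaluable]
        assert graph.number_of_edges() <= 0.01 * len(evaluable) + 1


class TestEdgeLineData:
    def test_reference_cohort_line_reproduces_prediction(self, fitted_candidates):
        cand = next(c for c in fitted_candidates if c.fitted and not c.unevaluable)
        lines = edge_line_data(cand)
        assert list(lines["cohort"]) == ["HIV- non-MSM", "HIV- MSM", "HIV+ MSM"]
        coefs = cand.coefficients
        expect = coefs["(Intercept)"] + sum(
            coefs.get(name, 0.0) * mean for name, mean in cand.covariate_means.items()
        )
        ref_row = lines.iloc[0]
        assert ref_row["intercept"] == pytest.approx(expect)
        assert ref_row["slope"] == pytest.approx(cand.slopes[0].slope)
        assert ref_row["solid"] == (cand.slopes[0].p < 0.05)


class TestAuditFrame:
    def test_columns_and_consistency(self, fitted_candidates):
        adjust_and_filter(fitted_candidates)
        frame = candidates_to_frame(fitted_candidates)
        assert len(frame) == len(fitted_candidates)
        for col in ("assay_pair", "q", "pattern", "exclusions", "retained"):
            assert col in frame.columns
        assert frame["retained"].sum() == sum(c.retained for c in fitted_candidates)
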