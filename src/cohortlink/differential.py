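"""Cohort, tissue and behavior differential scans.

Immune populations are screened for cohort differences with the
confounder-adjusted nested comparison ``analyte ~ age + day + gender +
cohort`` versus the same model without ``cohort`` (partial F-test), with
Tukey-corrected pairwise cohort contrasts.  Populations measured in both
blood and biopsy are compared with paired t-tests, FDR-adjusted across
populations.  ASVs are screened on unrarefied relative abundance with
sequencing depth as a covariate (``pph ~ cohort + reads``), FDR-adjusted
within tissue.  Behavior associations are assessed in the MSM cohorts only,
via the partial F of the questionnaire answer given HIV status (and reads
for microbes), deliberately uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .preprocess import (
    DIFFERENTIAL_MIN_PREVALENCE,
    PrevalenceRule,
    prevalence_filter,
    to_relative_abundance_pph,
)
from .stats import DesignSpec
from .tables import COHORTS, MICROBE_ASSAYS, AnalyteTable, SampleMetadata, TableError

GENDER_LEVELS = ("F", "M")

CONFOUNDER_TERMS = (
    ("age", "numeric"),
    ("day", "numeric"),
    ("gender", "categorical"),
    ("cohort", "categorical"),
)


@dataclass
class DifferentialResult:
    analyte: str
    assay: str
    p: float
    q: float = np.nan
    contrasts: list = field(default_factory=list)
    directions: dict = field(default_factory=dict)


@dataclass
class BehaviorResult:
    analyte: str
    assay: str
    question: str
    n: int
    p: float
    direction: float  # coefficient of answering "yes"
    significant: bool


def _model_frame(meta: SampleMetadata) -> pd.DataFrame:
    return meta.frame[["age", "day", "gender", "cohort"]].copy()


def _cohort_specs(with_reads: bool):
    terms = list(CONFOUNDER_TERMS)
    if with_reads:
        terms = [("reads", "numeric")] + terms
    levels = {"gender": GENDER_LEVELS, "cohort": COHORTS}
    full = DesignSpec("analyte", tuple(terms), levels)
    return full, full.dropping("cohort")


def immune_cohort_scan(
    table: AnalyteTable, meta: SampleMetadata, alpha: float = 0.05
) -> list:
    """Per-analyte cohort effect: partial F of ``cohort`` given age, day and
    gender, with Tukey HSD pairwise cohort contrasts at ``alpha``."""
    data = _model_frame(meta)
    if data["cohort"].nunique() < 2:
        raise TableError("cohort scan needs at least 2 cohorts")
    full_spec, reduced_spec = _cohort_specs(with_reads=False)
    results = _cohort_scan(table, data, full_spec, reduced_spec, alpha)
    _attach_fdr(results)
    return results


def asv_cohort_scan(
    counts: AnalyteTable, meta: SampleMetadata, alpha: float = 0.05
) -> list:
    """Cohort scan of ASV relative abundance with a sequencing-depth covariate.

    ASVs are first filtered to those non-zero in at least
    ``DIFFERENTIAL_MIN_PREVALENCE`` samples within the tissue; the response
    is unrarefied parts-per-hundred and the nested comparison is
    ``pph ~ cohort + reads`` against ``pph ~ reads``, so pure depth
    artifacts are absorbed by the covariate.  FDR is applied within the
    tissue (this table).
    """
    if counts.assay not in MICROBE_ASSAYS:
        raise TableError("asv_cohort_scan expects a microbe count table")
    reads = meta.reads(counts.assay).reindex(list(counts.sample_ids))
    if reads.isna().any():
        missing = reads.index[reads.isna()].tolist()
        raise TableError(f"read counts missing for samples {missing[:5]}")
    pph = to_relative_abundance_pph(counts)
    rule = PrevalenceRule(DIFFERENTIAL_MIN_PREVALENCE, scope="per_tissue_differential")
    pph, _dropped = prevalence_filter(pph, rule)
    data = _model_frame(meta)
    data["reads"] = reads.to_numpy(dtype=float)
    if data["cohort"].nunique() < 2:
        raise TableError("cohort scan needs at least 2 cohorts")
    full_spec, reduced_spec = _cohort_specs(with_reads=True)
    results = _cohort_scan(pph, data, full_spec, reduced_spec, alpha)
    _attach_fdr(results)
    return results


def _cohort_scan(table, data, full_spec, reduced_spec, alpha):
    vals = np.asarray(table.values, dtype=float)
    results = []
    for j, analyte in enumerate(table.analyte_ids):
        y = vals[:, j]
        full = stats.fit_linear_model(y, full_spec, data)
        reduced = stats.fit_linear_model(y, reduced_spec, data)
        comp = stats.partial_f_test(full, reduced)
        contrasts = stats.tukey_pairwise(full, "cohort", COHORTS)
        directions = {}
        for c in contrasts:
            if c.adjusted_p < alpha:
                hi, lo = (c.pair[0], c.pair[1]) if c.estimate > 0 else (c.pair[1], c.pair[0])
                directions[c.pair] = f"{hi} > {lo}"
        results.append(
            DifferentialResult(
                analyte=analyte,
                assay=table.assay,
                p=comp.p,
                contrasts=contrasts,
                directions=directions,
            )
        )
    return results


def _attach_fdr(results) -> None:
    if not results:
        return
    q = stats.bh_adjust([r.p for r in results])
    for r, qi in zip(results, q):
        r.q = float(qi)


def tissue_paired_scan(blood: AnalyteTable, colon: AnalyteTable) -> pd.DataFrame:
    """Paired t-tests of each population measured in both tissues.

    Pairs samples by participant id and analytes by name; BH-FDR across
    analytes.  Analytes with fewer than 2 complete pairs are skipped.
    """
    shared_analytes = [a for a in blood.analyte_ids if a in set(colon.analyte_ids)]
    shared_samples = [s for s in blood.sample_ids if s in set(colon.sample_ids)]
    if len(shared_samples) < 2:
        raise TableError("paired scan needs at least 2 shared samples")
    b = blood.subset_samples(shared_samples)
    c = colon.subset_samples(shared_samples)
    rows = []
    for analyte in shared_analytes:
        t, p = stats.paired_t_test(b.column(analyte), c.column(analyte))
        rows.append({"analyte": analyte, "n_pairs": len(shared_samples), "t": t, "p": p})
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["q"] = stats.bh_adjust(frame["p"].to_numpy())
    return frame


def behavior_scan(
    tables: dict,
    meta: SampleMetadata,
    questions=None,
    alpha: float = 0.05,
) -> list:
    """Behavior associations among MSM participants, uncorrected.

    For each questionnaire answer and analyte, compares
    ``analyte ~ HIV + answer`` to ``analyte ~ HIV`` (microbes additionally
    carry ``reads`` in both models) by partial F; microbe responses are
    unrarefied parts-per-hundred.  Only MSM participants with an answer on
    record enter each model; questions left with a single answer level are
    skipped.
    """
    if questions is None:
        questions = meta.behavior_questions
    msm_ids = [
        s for s, is_msm in zip(meta.sample_ids, meta.frame["msm_status"] == 1) if is_msm
    ]
    results = []
    for assay, table in tables.items():
        is_microbe = assay in MICROBE_ASSAYS
        if is_microbe:
            table = to_relative_abundance_pph(table)
            table, _ = prevalence_filter(
                table, PrevalenceRule(DIFFERENTIAL_MIN_PREVALENCE)
            )
        sample_set = set(table.sample_ids)
        for question in questions:
            answers = meta.behavior(question)
            answered = [
                s for s in msm_ids if s in sample_set and pd.notna(answers.get(s))
            ]
            if len(answered) < 4:
                continue
            sub = table.subset_samples(answered)
            data = meta.frame.loc[answered, ["hiv_status"]].astype(float)
            data["answer"] = answers.loc[answered].astype(str)
            if data["answer"].nunique() < 2:
                continue  # constant answer among respondents
            terms = [("hiv_status", "numeric")]
            if is_microbe:
                data["reads"] = (
                    meta.reads(assay).loc[answered].to_numpy(dtype=float)
                )
                terms.append(("reads", "numeric"))
            reduced_spec = DesignSpec("analyte", tuple(terms), {})
            full_spec = DesignSpec(
                "analyte",
                tuple(terms) + (("answer", "categorical"),),
                {"answer": ("no", "yes")},
            )
            if data["hiv_status"].nunique() < 2:
                # all respondents share HIV status: drop the constant term
                reduced_spec = reduced_spec.dropping("hiv_status")
                full_spec = full_spec.dropping("hiv_status")
            vals = np.asarray(sub.values, dtype=float)
            for j, analyte in enumerate(sub.analyte_ids):
                y = vals[:, j]
                full = stats.fit_linear_model(y, full_spec, data)
                reduced = stats.fit_linear_model(y, reduced_spec, data)
                comp = stats.partial_f_test(full, reduced)
                direction = (
                    full.coef("answer[yes]") if "answer[yes]" in full.names else np.nan
                )
                results.append(
                    BehaviorResult(
                        analyte=analyte,
                        assay=assay,
                        question=question,
                        n=len(answered),
                        p=comp.p,
                        direction=float(direction),
                        significant=comp.p < alpha,
                    )
                )
    return results
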