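"""Cross-assay immune-microbe association network.

For every pair of analytes drawn from five fixed assay pairs
(blood cells:colonic cells, blood cells:colonic microbes, blood
cells:fecal microbes, colonic cells:colonic microbes, colonic cells:fecal
microbes), a cohort-interaction regression

    analyte1 ~ [reads +] age + day + gender + cohort + analyte2 + analyte2 x cohort

is compared by partial F-test against the same model without the analyte2
terms; ``reads`` (sequencing depth of the microbe assay) enters both models
whenever a microbe is involved.  Candidate relationships become network
edges when their assay-pair-wise FDR q < 0.05, at least one per-cohort
slope has p < 0.005, no observation has |DFFITS| > 2, and neither analyte's
distribution has skewness > 3.  Each retained edge carries a three-character
slope pattern (one of ``p``/``n``/``~`` per cohort at slope p < 0.05).

Microbe analytes are analyzed as arcsinh-transformed parts per hundred and
must be present (non-zero) in at least 24 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import stats
from .preprocess import (
    NETWORK_MIN_PREVALENCE,
    PrevalenceRule,
    arcsinh_pph,
    prevalence_filter,
    to_relative_abundance_pph,
)
from .stats import fit_ols
from .tables import COHORTS, MICROBE_ASSAYS, AnalyteTable, SampleMetadata, TableError

ASSAY_PAIRS = (
    ("blood_cells", "colonic_cells"),
    ("blood_cells", "colonic_microbes"),
    ("blood_cells", "fecal_microbes"),
    ("colonic_cells", "colonic_microbes"),
    ("colonic_cells", "fecal_microbes"),
)

GENDER_LEVELS = ("F", "M")


@dataclass
class EdgeCriteria:
    """Thresholds governing edge inclusion."""

    fdr: float = 0.05
    slope_p: float = 0.005
    dffits_max: float = 2.0
    skew_max: float = 3.0
    #: "signed" excludes on skewness > skew_max; "absolute" on |skewness|
    skew_mode: str = "signed"
    pattern_alpha: float = 0.05


@dataclass
class EdgeCandidate:
    """One directed response/predictor pair within an assay pair."""

    assay_pair: tuple
    response_assay: str
    response_analyte: str
    predictor_assay: str
    predictor_analyte: str
    samples: tuple
    # filled by fitting
    fitted: bool = False
    unevaluable: bool = False
    partial_f_p: float = np.nan
    partial_f: float = np.nan
    slopes: list = field(default_factory=list)
    max_abs_dffits: float = np.nan
    skew_response: float = np.nan
    skew_predictor: float = np.nan
    coefficients: dict = field(default_factory=dict)
    covariate_means: dict = field(default_factory=dict)
    # filled by adjust_and_filter
    q: float = np.nan
    exclusions: tuple = ()
    pattern: str = ""

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def retained(self) -> bool:
        return self.fitted and not self.unevaluable and self.exclusions == ()

    @property
    def node_ids(self) -> tuple:
        return (
            f"{self.response_assay}:{self.response_analyte}",
            f"{self.predictor_assay}:{self.predictor_analyte}",
        )

    @property
    def min_slope_p(self) -> float:
        return min((s.p for s in self.slopes), default=np.nan)


def prepare_network_tables(tables: dict) -> dict:
    """Put every table on its analysis scale.

    Immune tables stay as percent frequencies; microbe count tables become
    arcsinh-transformed parts per hundred.
    """
    out = {}
    for assay, table in tables.items():
        if assay in MICROBE_ASSAYS:
            if table.value_kind == "counts":
                table = arcsinh_pph(to_relative_abundance_pph(table))
            elif table.value_kind == "pph":
                table = arcsinh_pph(table)
            elif table.value_kind != "arcsinh_pph":
                raise TableError(
                    f"microbe table {assay} has value_kind {table.value_kind!r}"
                )
        out[assay] = table
    return out


def enumerate_candidates(
    tables: dict,
    meta: SampleMetadata,
    min_prevalence: int = NETWORK_MIN_PREVALENCE,
    both_orientations: bool = False,
) -> list:
    """Candidate stubs: the Cartesian product of analytes within each pair.

    ``tables`` must already be on the analysis scale (see
    :func:`prepare_network_tables`).  Microbe analytes present (non-zero) in
    fewer than ``min_prevalence`` samples are dropped.  With
    ``both_orientations`` each analyte pair appears twice, once per choice
    of response; the duplicate orientations are merged again at assembly.
    """
    filtered = {}
    for assay, table in tables.items():
        if assay in MICROBE_ASSAYS:
            table, _ = prevalence_filter(table, PrevalenceRule(min_prevalence))
        filtered[assay] = table

    candidates = []
    meta_ids = set(meta.sample_ids)
    for assay_a, assay_b in ASSAY_PAIRS:
        if assay_a not in filtered or assay_b not in filtered:
            continue
        ta, tb = filtered[assay_a], filtered[assay_b]
        shared = sorted(set(ta.sample_ids) & set(tb.sample_ids) & meta_ids)
        if not shared:
            continue
        orientations = [(assay_a, ta, assay_b, tb)]
        if both_orientations:
            orientations.append((assay_b, tb, assay_a, ta))
        for resp_assay, resp_t, pred_assay, pred_t in orientations:
            for resp_analyte in resp_t.analyte_ids:
                for pred_analyte in pred_t.analyte_ids:
                    candidates.append(
                        EdgeCandidate(
                            assay_pair=(assay_a, assay_b),
                            response_assay=resp_assay,
                            response_analyte=resp_analyte,
                            predictor_assay=pred_assay,
                            predictor_analyte=pred_analyte,
                            samples=tuple(shared),
                        )
                    )
    return candidates


# ---------------------------------------------------------------------------
# fitting


class _PairContext:
    """Shared design columns for all candidates of one assay pair."""

    def __init__(self, samples, meta: SampleMetadata, reads_assay):
        frame = meta.frame.loc[list(samples)]
        cols = [np.ones(len(frame))]
        names = ["(Intercept)"]
        if reads_assay is not None:
            reads = meta.reads(reads_assay).loc[list(samples)]
            if reads.isna().any():
                missing = reads.index[reads.isna()].tolist()
                raise TableError(
                    f"read counts for {reads_assay} missing for {missing[:5]}"
                )
            cols.append(reads.to_numpy(dtype=float))
            names.append("reads")
        cols.append(frame["age"].to_numpy(dtype=float))
        names.append("age")
        cols.append(frame["day"].to_numpy(dtype=float))
        names.append("day")
        present_genders = set(frame["gender"])
        for lev in GENDER_LEVELS[1:]:
            if lev in present_genders and len(present_genders) > 1:
                cols.append((frame["gender"] == lev).to_numpy(dtype=float))
                names.append(f"gender[{lev}]")
        self.cohort_dummies = []
        present = set(frame["cohort"])
        self.cohort_levels = [c for c in COHORTS if c in present]
        for lev in self.cohort_levels[1:]:
            d = (frame["cohort"] == lev).to_numpy(dtype=float)
            cols.append(d)
            names.append(f"cohort[{lev}]")
            self.cohort_dummies.append((lev, d))
        self.base_X = np.column_stack(cols)
        self.base_names = names
        self.samples = tuple(samples)
        self._reduced_cache: dict = {}

    def reduced_fit(self, key, y):
        fit = self._reduced_cache.get(key)
        if fit is None:
            fit = fit_ols(self.base_X, y, self.base_names)
            self._reduced_cache[key] = fit
        return fit

    def full_design(self, x):
        cols = [self.base_X, x[:, None]]
        names = self.base_names + ["x"]
        for lev, d in self.cohort_dummies:
            cols.append((x * d)[:, None])
            names.append(f"x:cohort[{lev}]")
        return np.column_stack(cols), names


def _reads_assay_for(candidate: EdgeCandidate):
    """Which assay's sequencing depth covariate a candidate model carries."""
    for assay in (candidate.response_assay, candidate.predictor_assay):
        if assay in MICROBE_ASSAYS:
            return assay
    return None


def fit_edge(
    candidate: EdgeCandidate,
    tables: dict,
    meta: SampleMetadata,
    context: _PairContext = None,
) -> EdgeCandidate:
    """Fit the full and reduced models for one candidate, in place.

    Records the partial-F p-value, per-cohort slopes, the maximum |DFFITS|
    over observations of the full model, and the skewness of both analytes'
    analyzed values.  Rank-deficient designs mark the candidate
    unevaluable.
    """
    if context is None:
        context = _PairContext(candidate.samples, meta, _reads_assay_for(candidate))
    resp_table = tables[candidate.response_assay].subset_samples(candidate.samples)
    pred_table = tables[candidate.predictor_assay].subset_samples(candidate.samples)
    y = resp_table.column(candidate.response_analyte).astype(float)
    x = pred_table.column(candidate.predictor_analyte).astype(float)
    return _fit_edge_arrays(candidate, y, x, context)


def _fit_edge_arrays(candidate, y, x, context: _PairContext, skews=None) -> EdgeCandidate:
    X_full, names = context.full_design(x)
    if len(y) <= X_full.shape[1] + 1:
        candidate.fitted = True
        candidate.unevaluable = True
        return candidate
    full = fit_ols(X_full, y, names)
    if full.rank_deficient:
        candidate.fitted = True
        candidate.unevaluable = True
        return candidate
    reduced = context.reduced_fit(
        (candidate.response_assay, candidate.response_analyte), y
    )
    comp = stats.partial_f_test(full, reduced)
    slopes = stats.cohort_slopes(full, "x", "cohort", context.cohort_levels)
    infl = stats.dffits(full)
    candidate.fitted = True
    candidate.partial_f_p = comp.p
    candidate.partial_f = comp.F
    candidate.slopes = slopes
    candidate.max_abs_dffits = float(np.nanmax(np.abs(infl)))
    if skews is None:
        skews = (stats.sample_skewness(y), stats.sample_skewness(x))
    candidate.skew_response, candidate.skew_predictor = skews
    candidate.coefficients = dict(zip(full.names, full.beta))
    candidate.covariate_means = {
        name: float(col.mean())
        for name, col in zip(context.base_names, context.base_X.T)
        if name != "(Intercept)" and not name.startswith("cohort[")
    }
    return candidate


def fit_all(candidates, tables: dict, meta: SampleMetadata) -> list:
    """Fit every candidate, sharing design columns within each assay pair."""
    contexts: dict = {}
    resp_cache: dict = {}
    pred_cache: dict = {}
    skew_cache: dict = {}
    for cand in candidates:
        key = (cand.assay_pair, cand.samples)
        ctx = contexts.get(key)
        if ctx is None:
            ctx = _PairContext(cand.samples, meta, _reads_assay_for(cand))
            contexts[key] = ctx
        ykey = (cand.response_assay, cand.response_analyte, cand.samples)
        y = resp_cache.get(ykey)
        if y is None:
            y = (
                tables[cand.response_assay]
                .subset_samples(cand.samples)
                .column(cand.response_analyte)
                .astype(float)
            )
            resp_cache[ykey] = y
        xkey = (cand.predictor_assay, cand.predictor_analyte, cand.samples)
        x = pred_cache.get(xkey)
        if x is None:
            x = (
                tables[cand.predictor_assay]
                .subset_samples(cand.samples)
                .column(cand.predictor_analyte)
                .astype(float)
            )
            pred_cache[xkey] = x
        for k, arr in ((ykey, y), (xkey, x)):
            if k not in skew_cache:
                skew_cache[k] = stats.sample_skewness(arr)
        _fit_edge_arrays(cand, y, x, ctx, skews=(skew_cache[ykey], skew_cache[xkey]))
    return list(candidates)


# ---------------------------------------------------------------------------
# filtering


def adjust_and_filter(candidates, criteria: EdgeCriteria = None) -> list:
    """FDR within assay pair, then slope / influence / skew exclusions.

    Every fitted candidate receives a q-value; exclusion reasons are
    recorded on each candidate.  Returns the retained candidates (the
    network's edge records).
    """
    if criteria is None:
        criteria = EdgeCriteria()
    fitted = [c for c in candidates if c.fitted and not c.unevaluable]
    if fitted:
        pair_labels = np.array(["|".join(c.assay_pair) for c in fitted])
        q = stats.bh_adjust(np.array([c.partial_f_p for c in fitted]), pair_labels)
        for c, qi in zip(fitted, q):
            c.q = float(qi)
    retained = []
    for c in fitted:
        reasons = []
        if not (c.q < criteria.fdr):
            reasons.append("fdr")
        if not (c.min_slope_p < criteria.slope_p):
            reasons.append("slope")
        if c.max_abs_dffits > criteria.dffits_max:
            reasons.append("influence")
        skews = (c.skew_response, c.skew_predictor)
        if criteria.skew_mode == "absolute":
            skews = tuple(abs(s) for s in skews)
        if max(skews) > criteria.skew_max:
            reasons.append("skew")
        c.exclusions = tuple(reasons)
        c.pattern = classify_slope_pattern(c, alpha=criteria.pattern_alpha)
        if not reasons:
            retained.append(c)
    return retained


def classify_slope_pattern(edge: EdgeCandidate, alpha: float = 0.05) -> str:
    """Three-character cohort slope pattern, in canonical cohort order.

    ``p``: slope > 0 with p < alpha; ``n``: slope < 0 with p < alpha;
    ``~``: not significantly different from zero.
    """
    by_level = {s.level: s for s in edge.slopes}
    chars = []
    for cohort in COHORTS:
        s = by_level.get(cohort)
        if s is None:
            chars.append("~")
        elif s.p < alpha and s.slope > 0:
            chars.append("p")
        elif s.p < alpha and s.slope < 0:
            chars.append("n")
        else:
            chars.append("~")
    return "".join(chars)


# ---------------------------------------------------------------------------
# assembly


def assemble_network(edges) -> nx.Graph:
    """Undirected graph over analytes from retained edge records.

    Node ids are ``assay:analyte``; nodes carry assay and degree
    attributes.  When both orientations of the same analyte pair were
    retained, the orientation with the smaller q survives as the edge and
    the other is archived in the edge's ``n_orientations`` count.
    """
    best: dict = {}
    for e in edges:
        key = frozenset(e.node_ids)
        if key in best:
            best[key].append(e)
        else:
            best[key] = [e]
    graph = nx.Graph()
    archived = []
    for key, group in best.items():
        group.sort(key=lambda e: (e.q, e.partial_f_p))
        e = group[0]
        archived.extend(group[1:])
        u, v = e.node_ids
        for node, assay, analyte in (
            (u, e.response_assay, e.response_analyte),
            (v, e.predictor_assay, e.predictor_analyte),
        ):
            if node not in graph:
                graph.add_node(node, assay=assay, analyte=analyte)
        slope_attrs = {}
        for s in e.slopes:
            tag = s.level.replace(" ", "_")
            slope_attrs[f"slope[{tag}]"] = float(s.slope)
            slope_attrs[f"slope_se[{tag}]"] = float(s.se)
            slope_attrs[f"slope_p[{tag}]"] = float(s.p)
        graph.add_edge(
            u,
            v,
            q=float(e.q),
            partial_f_p=float(e.partial_f_p),
            n=e.n,
            pattern=e.pattern,
            response=f"{e.response_assay}:{e.response_analyte}",
            predictor=f"{e.predictor_assay}:{e.predictor_analyte}",
            max_abs_dffits=float(e.max_abs_dffits),
            skew_response=float(e.skew_response),
            skew_predictor=float(e.skew_predictor),
            n_orientations=len(group),
            **slope_attrs,
        )
    for node in graph.nodes:
        graph.nodes[node]["degree"] = graph.degree[node]
    graph.graph["n_archived"] = len(archived)
    return graph


def edge_line_data(edge: EdgeCandidate, alpha: float = 0.05) -> pd.DataFrame:
    """Per-cohort fitted lines for plotting one edge.

    Intercepts are evaluated at the sample means of the covariates; the
    ``solid`` flag marks cohorts whose slope differs from zero at
    ``alpha``.
    """
    coefs = edge.coefficients
    base = coefs.get("(Intercept)", 0.0)
    for name, mean in edge.covariate_means.items():
        base += coefs.get(name, 0.0) * mean
    rows = []
    for s in edge.slopes:
        intercept = base + coefs.get(f"cohort[{s.level}]", 0.0)
        rows.append(
            {
                "cohort": s.level,
                "intercept": intercept,
                "slope": s.slope,
                "slope_p": s.p,
                "solid": s.p < alpha,
            }
        )
    return pd.DataFrame(rows)


def build_network(
    tables: dict,
    meta: SampleMetadata,
    min_prevalence: int = NETWORK_MIN_PREVALENCE,
    criteria: EdgeCriteria = None,
    both_orientations: bool = True,
):
    """End-to-end network construction.

    Returns ``(graph, candidates)`` where ``candidates`` carry every fitted
    statistic and exclusion reason (the full audit trail).
    """
    analysis_tables = prepare_network_tables(tables)
    candidates = enumerate_candidates(
        analysis_tables, meta, min_prevalence, both_orientations=both_orientations
    )
    fit_all(candidates, analysis_tables, meta)
    retained = adjust_and_filter(candidates, criteria)
    graph = assemble_network(retained)
    return graph, candidates


def candidates_to_frame(candidates) -> pd.DataFrame:
    """Flat edge table of all fitted candidates (audit trail export)."""
    rows = []
    for c in candidates:
        row = {
            "assay_pair": "|".join(c.assay_pair),
            "response": f"{c.response_assay}:{c.response_analyte}",
            "predictor": f"{c.predictor_assay}:{c.predictor_analyte}",
            "n": c.n,
            "partial_f_p": c.partial_f_p,
            "q": c.q,
            "min_slope_p": c.min_slope_p,
            "max_abs_dffits": c.max_abs_dffits,
            "skew_response": c.skew_response,
            "skew_predictor": c.skew_predictor,
            "pattern": c.pattern,
            "unevaluable": c.unevaluable,
            "exclusions": ";".join(c.exclusions),
            "retained": c.retained,
        }
        for s in c.slopes:
            tag = s.level.replace(" ", "_")
            row[f"slope[{tag}]"] = s.slope
            row[f"slope_p[{tag}]"] = s.p
        rows.append(row)
    return pd.DataFrame(rows)
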