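"""Synthetic three-cohort study generator.

Emulates the design of the real study: 70 participants in three cohorts
(HIV- non-MSM n=21, HIV- MSM n=16, HIV+ MSM n=33), immune-cell population
frequencies in blood (49 analytes) and colonic biopsy (48), and 16S ASV
count tables from feces (163 ASVs) and colonic biopsy (122), with age,
collection day (1-1457), gender, and per-sample sequencing depth as
covariates.  Ground-truth effects (cohort shifts, cross-assay slopes with
cohort-specific coefficients, behavior-linked shifts) are planted on
request and returned as an immutable registry so that downstream stages can
be tested for recovery.

Immune frequencies are generated on the raw percent scale (linear
predictor + Gaussian noise, truncated to [0, 100]).  ASV tables are drawn
as per-sample multinomials over a log-normal expected composition; a
cross-assay effect targeting an ASV pins that ASV's expected
arcsinh-transformed parts-per-hundred to a per-cohort linear function of
the source analyte, so the network stage's model is correctly specified
under the alternative.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables import (
    ASSAYS,
    COHORTS,
    IMMUNE_ASSAYS,
    MICROBE_ASSAYS,
    AnalyteTable,
    SampleMetadata,
    TableError,
    write_analyte_table,
    write_metadata,
)

DEFAULT_COHORT_SIZES = {"HIV- non-MSM": 21, "HIV- MSM": 16, "HIV+ MSM": 33}
DEFAULT_N_ANALYTES = {
    "blood_cells": 49,
    "colonic_cells": 48,
    "fecal_microbes": 163,
    "colonic_microbes": 122,
}
# per-(cohort, gender) visit-age mean/sd in years; the control cohort pools
# women and men who have sex with women, which differ in age
DEFAULT_AGE_PARAMS = {
    ("HIV- non-MSM", "F"): (33.4, 5.0),
    ("HIV- non-MSM", "M"): (40.2, 12.5),
    ("HIV- MSM", "M"): (42.5, 11.0),
    ("HIV+ MSM", "M"): (48.4, 10.5),
}
#: behavior-questionnaire keys asked of MSM participants
BEHAVIOR_QUESTIONS = (
    "rai",
    "partners_3plus",
    "lubricant_use",
    "recent_sti",
    "condomless_sex",
)


class SimulationError(ValueError):
    """Invalid simulation configuration or planted-effect registry."""


@dataclass(frozen=True)
class SimulationConfig:
    cohort_sizes: dict = field(default_factory=lambda: dict(DEFAULT_COHORT_SIZES))
    n_analytes: dict = field(default_factory=lambda: dict(DEFAULT_N_ANALYTES))
    age_params: dict = field(default_factory=lambda: dict(DEFAULT_AGE_PARAMS))
    day_range: tuple = (1, 1457)
    #: per microbe assay: (mean reads per sample, negative-binomial size)
    depth_params: dict = field(
        default_factory=lambda: {
            "fecal_microbes": (40000.0, 10.0),
            "colonic_microbes": (12000.0, 8.0),
        }
    )
    #: log-normal location/scale of per-ASV baseline abundance
    baseline_abundance: tuple = (0.0, 1.5)
    #: per-sample log-scale overdispersion of ASV compositions
    asv_noise_sd: float = 0.6
    #: residual sd of immune frequencies, percent
    noise_sd: float = 2.0
    #: fraction of immune analytes given small age/day/gender effects
    confounder_fraction: float = 0.2
    #: fraction of colonic ASV ids shared with the fecal pool
    tissue_overlap: float = 0.85
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.cohort_sizes.values()):
            raise SimulationError("cohort sizes must be >= 0")
        if any(v < 1 for v in self.n_analytes.values()):
            raise SimulationError("analyte counts must be >= 1")
        unknown = set(self.cohort_sizes) - set(COHORTS)
        if unknown:
            raise SimulationError(f"unknown cohorts: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return sum(self.cohort_sizes.values())


@dataclass(frozen=True)
class PlantedEffect:
    """One ground-truth effect planted into a synthetic study.

    ``cross_assay_slope`` effects make the target analyte (on its analysis
    scale: percent for immune analytes, arcsinh-pph for ASVs) depend
    linearly on the source analyte with one slope per cohort (in
    :data:`COHORTS` order).  ``cohort_shift`` adds per-cohort mean offsets;
    ``behavior_shift`` offsets samples answering ``behavior_key`` with
    "yes".
    """

    kind: str
    target_assay: str
    target_analyte: str
    source_assay: str = None
    source_analyte: str = None
    per_cohort_slopes: tuple = None
    shift_sizes: dict = None
    behavior_key: str = None
    behavior_delta: float = 0.0
    #: baseline of the target on its analysis scale (arcsinh-pph for ASVs)
    target_baseline: float = None
    #: residual sd of the target on its analysis scale (ASV targets only;
    #: immune targets use the global noise_sd)
    target_noise_sd: float = 0.0

    def __post_init__(self):
        if self.kind not in {"cohort_shift", "cross_assay_slope", "behavior_shift"}:
            raise SimulationError(f"unknown effect kind {self.kind!r}")
        if self.kind == "cross_assay_slope":
            if self.source_assay is None or self.source_analyte is None:
                raise SimulationError("cross_assay_slope needs a source analyte")
            if self.source_assay == self.target_assay:
                raise SimulationError(
                    "cross_assay_slope must reference two distinct assays"
                )
            if self.per_cohort_slopes is None or len(self.per_cohort_slopes) != len(COHORTS):
                raise SimulationError("per_cohort_slopes must give one slope per cohort")
        if self.kind == "cohort_shift" and not self.shift_sizes:
            raise SimulationError("cohort_shift needs shift_sizes")
        if self.kind == "behavior_shift" and not self.behavior_key:
            raise SimulationError("behavior_shift needs behavior_key")


@dataclass(frozen=True)
class SyntheticStudy:
    metadata: SampleMetadata
    tables: dict
    tree: TreeNode
    effects: tuple
    config: SimulationConfig
    seed: int


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


# ---------------------------------------------------------------------------
# metadata


def generate_metadata(config: SimulationConfig) -> SampleMetadata:
    """Draw per-sample cohort, gender, age, collection day, read depths, and
    behavior answers."""
    if config.n_samples == 0:
        raise SimulationError("configuration yields zero samples")
    rng = _rng(config.seed, 0)
    rows = []
    i = 0
    for cohort in COHORTS:
        for _ in range(config.cohort_sizes.get(cohort, 0)):
            i += 1
            sample_id = f"S{i:03d}"
            if cohort == "HIV- non-MSM":
                # control cohort pools 10 women and 11 MSW
                gender = "F" if rng.random() < 10.0 / 21.0 else "M"
            else:
                gender = "M"
            mean, sd = config.age_params[(cohort, gender)]
            age = float(np.clip(rng.normal(mean, sd), 18.0, 90.0))
            day = int(rng.integers(config.day_range[0], config.day_range[1] + 1))
            row = {
                "sample_id": sample_id,
                "cohort": cohort,
                "gender": gender,
                "age": round(age, 1),
                "day": day,
            }
            for assay, (mu, size) in config.depth_params.items():
                p = size / (size + mu)
                row[f"reads_{assay}"] = int(rng.negative_binomial(size, p))
            rows.append(row)
    frame = pd.DataFrame(rows).set_index("sample_id")
    # behavior questionnaire: MSM participants only, with per-question
    # nonresponse so each question is answered by a subset
    msm = frame["cohort"] != "HIV- non-MSM"
    for q in BEHAVIOR_QUESTIONS:
        answered = msm & (rng.random(len(frame)) < 0.8)
        yes = rng.random(len(frame)) < 0.5
        col = np.where(answered, np.where(yes, "yes", "no"), None)
        frame[f"behavior_{q}"] = col
    return SampleMetadata(frame)


# ---------------------------------------------------------------------------
# analyte ids


def immune_analyte_ids(assay: str, n: int) -> list:
    # population names are shared across blood and biopsy (the same gated
    # population measured in two tissues), enabling the paired tissue scan
    return [f"pop_{j:03d}" for j in range(1, n + 1)]


def microbe_analyte_ids(config: SimulationConfig) -> dict:
    """Overlapping fecal/colonic ASV id sets drawn from one global pool."""
    n_fec = config.n_analytes["fecal_microbes"]
    n_col = config.n_analytes["colonic_microbes"]
    n_shared = min(int(round(config.tissue_overlap * n_col)), n_fec, n_col)
    pool_size = n_fec + (n_col - n_shared)
    pool = [f"asv_{j:04d}" for j in range(1, pool_size + 1)]
    fecal = pool[:n_fec]
    colonic = pool[n_fec - n_shared:]
    return {"pool": pool, "fecal_microbes": fecal, "colonic_microbes": colonic}


# ---------------------------------------------------------------------------
# tables


def generate_tables(
    config: SimulationConfig, metadata: SampleMetadata, effects=()
) -> SyntheticStudy:
    """Generate all four analyte tables plus phylogeny for ``metadata``.

    Immune assays are generated first (cohort/confounder linear predictor +
    Gaussian noise on the percent scale), then ASV tables (multinomial over
    a log-normal composition), then cross-assay effects targeting immune
    analytes are applied so microbe-sourced effects see their generated
    source values.
    """
    effects = tuple(effects)
    rng = _rng(config.seed, 1)
    meta = metadata.frame
    n = len(meta)
    cohort_idx = meta["cohort"].map({c: k for k, c in enumerate(COHORTS)}).to_numpy()

    ids = {a: immune_analyte_ids(a, config.n_analytes[a]) for a in IMMUNE_ASSAYS}
    ids.update(microbe_analyte_ids(config))
    _validate_effects(effects, ids, metadata)

    tables: dict = {}
    # --- immune assays (without cross-assay terms yet)
    immune_noise = {}
    for assay in ("blood_cells", "colonic_cells"):
        aids = ids[assay]
        p = len(aids)
        baseline = rng.uniform(2.0, 40.0, size=p)
        has_conf = rng.random(p) < config.confounder_fraction
        b_age = np.where(has_conf, rng.normal(0.0, 0.08, size=p), 0.0)
        b_day = np.where(has_conf, rng.normal(0.0, 0.003, size=p), 0.0)
        b_gender = np.where(has_conf, rng.normal(0.0, 1.5, size=p), 0.0)
        age_c = meta["age"].to_numpy() - meta["age"].mean()
        day_c = meta["day"].to_numpy() - meta["day"].mean()
        male = (meta["gender"] == "M").to_numpy(dtype=float)
        mu = (
            baseline[None, :]
            + age_c[:, None] * b_age[None, :]
            + day_c[:, None] * b_day[None, :]
            + male[:, None] * b_gender[None, :]
        )
        for eff in effects:
            if eff.kind == "cohort_shift" and eff.target_assay == assay:
                j = aids.index(eff.target_analyte)
                shift = np.array([eff.shift_sizes.get(c, 0.0) for c in COHORTS])
                mu[:, j] += shift[cohort_idx]
            if eff.kind == "behavior_shift" and eff.target_assay == assay:
                j = aids.index(eff.target_analyte)
                yes = (meta[f"behavior_{eff.behavior_key}"] == "yes").to_numpy()
                mu[:, j] += eff.behavior_delta * yes
        noise = rng.normal(0.0, config.noise_sd, size=(n, p))
        immune_noise[assay] = noise
        tables[assay] = AnalyteTable(
            sample_ids=metadata.sample_ids,
            analyte_ids=tuple(aids),
            values=np.clip(mu + noise, 0.0, 100.0),
            assay=assay,
            value_kind="percent_frequency",
        )

    # --- ASV tables
    pool = ids["pool"]
    base_log = rng.normal(
        config.baseline_abundance[0], config.baseline_abundance[1], size=len(pool)
    )
    base_by_id = dict(zip(pool, base_log))
    for assay in ("fecal_microbes", "colonic_microbes"):
        aids = ids[assay]
        p = len(aids)
        log_mu = np.tile([base_by_id[a] for a in aids], (n, 1))
        for eff in effects:
            if eff.kind == "cohort_shift" and eff.target_assay == assay:
                j = aids.index(eff.target_analyte)
                shift = np.array([eff.shift_sizes.get(c, 0.0) for c in COHORTS])
                log_mu[:, j] += shift[cohort_idx]
            if eff.kind == "behavior_shift" and eff.target_assay == assay:
                j = aids.index(eff.target_analyte)
                yes = (meta[f"behavior_{eff.behavior_key}"] == "yes").to_numpy()
                log_mu[:, j] += eff.behavior_delta * yes
        log_mu += rng.normal(0.0, config.asv_noise_sd, size=(n, p))
        intensity = np.exp(log_mu)

        # cross-assay effects targeting this assay pin the target ASV's
        # expected arcsinh-pph to its per-cohort line in the source
        pinned = {}
        for eff in effects:
            if eff.kind != "cross_assay_slope" or eff.target_assay != assay:
                continue
            if eff.source_assay in MICROBE_ASSAYS:
                raise SimulationError(
                    "microbe-to-microbe cross-assay effects are not supported"
                )
            src = _analysis_scale_column(tables[eff.source_assay], eff.source_analyte)
            base = eff.target_baseline if eff.target_baseline is not None else 1.0
            slopes = np.asarray(eff.per_cohort_slopes, dtype=float)
            # center the source so the baseline is the target's mean level;
            # the per-cohort slope of target on source is unaffected
            a_target = base + slopes[cohort_idx] * (src - src.mean())
            if eff.target_noise_sd:
                a_target = a_target + rng.normal(0.0, eff.target_noise_sd, size=n)
            # invert arcsinh, cap below 95 pph so renormalization stays sane
            pph = np.clip(np.sinh(np.clip(a_target, 0.0, None)), 0.0, 95.0)
            pinned[aids.index(eff.target_analyte)] = pph
        if pinned:
            free = np.ones(p, dtype=bool)
            for j in pinned:
                free[j] = False
            w_free = intensity[:, free].sum(axis=1)
            pph_pinned = np.zeros((n, len(pinned)))
            for k, (j, pph) in enumerate(pinned.items()):
                pph_pinned[:, k] = pph
            total_pinned = pph_pinned.sum(axis=1)
            total_pinned = np.minimum(total_pinned, 99.0)
            for k, (j, pph) in enumerate(pinned.items()):
                intensity[:, j] = w_free * pph / np.maximum(100.0 - total_pinned, 1.0)

        comp = intensity / intensity.sum(axis=1, keepdims=True)
        depths = metadata.reads(assay).to_numpy(dtype=np.int64)
        counts = np.vstack(
            [rng.multinomial(depths[i], comp[i]) for i in range(n)]
        )
        tables[assay] = AnalyteTable(
            sample_ids=metadata.sample_ids,
            analyte_ids=tuple(aids),
            values=counts,
            assay=assay,
            value_kind="counts",
        )

    # --- cross-assay effects targeting immune analytes (sources now exist)
    for eff in effects:
        if eff.kind != "cross_assay_slope" or eff.target_assay not in IMMUNE_ASSAYS:
            continue
        table = tables[eff.target_assay]
        src = _analysis_scale_column(tables[eff.source_assay], eff.source_analyte)
        slopes = np.asarray(eff.per_cohort_slopes, dtype=float)
        j = list(table.analyte_ids).index(eff.target_analyte)
        vals = np.asarray(table.values).copy()
        base = eff.target_baseline
        if base is not None:
            # replace the analyte entirely: baseline + line + fresh noise
            vals[:, j] = (
                base
                + slopes[cohort_idx] * (src - src.mean())
                + immune_noise[eff.target_assay][:, j]
            )
        else:
            vals[:, j] = vals[:, j] + slopes[cohort_idx] * src
        vals[:, j] = np.clip(vals[:, j], 0.0, 100.0)
        tables[eff.target_assay] = dataclasses.replace(table, values=vals)

    tree = generate_phylogeny(len(pool), seed=config.seed, leaf_names=pool)
    return SyntheticStudy(
        metadata=metadata,
        tables=tables,
        tree=tree,
        effects=effects,
        config=config,
        seed=config.seed,
    )


def _analysis_scale_column(table: AnalyteTable, analyte: str) -> np.ndarray:
    """A source analyte's values on the scale the network stage analyzes."""
    col = table.column(analyte).astype(float)
    if table.value_kind == "counts":
        totals = np.asarray(table.values, dtype=float).sum(axis=1)
        return np.arcsinh(100.0 * col / np.maximum(totals, 1.0))
    return col


def _validate_effects(effects, ids, metadata: SampleMetadata) -> None:
    for eff in effects:
        for assay, analyte in (
            (eff.target_assay, eff.target_analyte),
            (eff.source_assay, eff.source_analyte),
        ):
            if assay is None:
                continue
            if assay not in ASSAYS:
                raise SimulationError(f"unknown assay {assay!r}")
            if analyte not in ids[assay]:
                raise SimulationError(
                    f"effect references unknown analyte {analyte!r} in {assay}"
                )
        if eff.kind == "behavior_shift":
            if f"behavior_{eff.behavior_key}" not in metadata.frame.columns:
                raise SimulationError(
                    f"unknown behavior question {eff.behavior_key!r}"
                )


def generate_study(config: SimulationConfig, effects=()) -> SyntheticStudy:
    """Metadata + tables + phylogeny in one deterministic call."""
    return generate_tables(config, generate_metadata(config), effects)


# ---------------------------------------------------------------------------
# phylogeny


def generate_phylogeny(n_leaves: int, seed: int, leaf_names=None) -> TreeNode:
    """Random bifurcating tree with exponential branch lengths.

    Leaves are joined pairwise at random (a coalescent-style topology).
    """
    if n_leaves < 2:
        raise SimulationError("a phylogeny needs at least 2 leaves")
    rng = _rng(seed, 2)
    if leaf_names is None:
        leaf_names = [f"asv_{j:04d}" for j in range(1, n_leaves + 1)]
    if len(leaf_names) != n_leaves:
        raise SimulationError("leaf_names length must equal n_leaves")
    nodes = [TreeNode(name=name, length=None) for name in leaf_names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        for child in (left, right):
            extra = float(rng.exponential(0.1)) + 1e-3
            child.length = extra if child.length is None else child.length + extra
        parent = TreeNode(children=[left, right], length=None)
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# serialization


def write_study(study: SyntheticStudy, out_dir) -> dict:
    """Write metadata, tables, tree and the planted-effect registry.

    Returns a mapping of logical name to written path.
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_metadata(study.metadata, out / "metadata.tsv")
    paths["metadata"] = out / "metadata.tsv"
    for assay, table in study.tables.items():
        path = out / f"{assay}.tsv"
        write_analyte_table(table, path)
        paths[assay] = path
    tree_path = out / "tree.nwk"
    study.tree.write(str(tree_path))
    paths["tree"] = tree_path
    registry = {
        "seed": study.seed,
        "effects": [dataclasses.asdict(e) for e in study.effects],
        "config": _config_dict(study.config),
    }
    reg_path = out / "planted_effects.json"
    reg_path.write_text(json.dumps(registry, indent=2, default=str))
    paths["registry"] = reg_path
    return paths


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["age_params"] = {f"{c}|{g}": v for (c, g), v in config.age_params.items()}
    return d


def demo_effects(config: SimulationConfig) -> tuple:
    """A small planted-effect registry used by the demo pipeline.

    One MSM-enriched fecal ASV, one cohort-shifted colonic immune
    population, one behavior-linked blood analyte, and two cross-assay
    relationships with cohort-specific slopes.
    """
    ids = {a: immune_analyte_ids(a, config.n_analytes[a]) for a in IMMUNE_ASSAYS}
    ids.update(microbe_analyte_ids(config))
    if (
        min(config.n_analytes[a] for a in IMMUNE_ASSAYS) < 5
        or config.n_analytes["colonic_microbes"] < 6
    ):
        raise SimulationError(
            "demo effects need at least 5 analytes per immune assay "
            "and 6 colonic microbes"
        )
    return (
        PlantedEffect(
            kind="cohort_shift",
            target_assay="fecal_microbes",
            target_analyte=ids["fecal_microbes"][0],
            shift_sizes={"HIV- MSM": 2.0, "HIV+ MSM": 2.0},
        ),
        PlantedEffect(
            kind="cohort_shift",
            target_assay="colonic_cells",
            target_analyte=ids["colonic_cells"][0],
            shift_sizes={"HIV+ MSM": -8.0},
        ),
        PlantedEffect(
            kind="behavior_shift",
            target_assay="blood_cells",
            target_analyte=ids["blood_cells"][1],
            behavior_key="rai",
            behavior_delta=6.0,
        ),
        PlantedEffect(
            kind="cross_assay_slope",
            target_assay="colonic_cells",
            target_analyte=ids["colonic_cells"][2],
            source_assay="blood_cells",
            source_analyte=ids["blood_cells"][3],
            per_cohort_slopes=(0.0, 1.5, 1.5),
            target_baseline=20.0,
        ),
        PlantedEffect(
            kind="cross_assay_slope",
            target_assay="colonic_microbes",
            target_analyte=ids["colonic_microbes"][5],
            source_assay="colonic_cells",
            source_analyte=ids["colonic_cells"][4],
            per_cohort_slopes=(0.0, 0.0, -0.3),
            target_baseline=2.0,
            target_noise_sd=0.3,
        ),
    )
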