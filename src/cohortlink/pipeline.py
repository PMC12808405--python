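"""End-to-end orchestration: simulate -> preprocess -> diversity ->
differential -> network, with a run manifest for reproducibility.

The manifest records the configuration hash, seed, package version and a
sha256 checksum for every stage output; re-running with the same
configuration and seed reproduces the manifest byte for byte (no
wall-clock fields are recorded, by design).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd

from . import __version__
from .diversity import canberra_matrix, pcoa, permanova, unweighted_unifrac, weighted_unifrac
from .differential import (
    asv_cohort_scan,
    behavior_scan,
    immune_cohort_scan,
    tissue_paired_scan,
)
from .network import EdgeCriteria, build_network, candidates_to_frame, edge_line_data
from .preprocess import (
    DEFAULT_RAREFACTION_DEPTHS,
    arcsinh_pph,
    rarefy,
    to_relative_abundance_pph,
)
from .simulate import SimulationConfig, demo_effects, generate_study, write_study
from .tables import MICROBE_ASSAYS, network_to_edge_table, network_to_graphml, write_analyte_table

log = logging.getLogger("cohortlink")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {"planted_demo": True},
    "diversity": {
        "n_permutations": 199,
        "use_tree": True,
        "rarefy_depths": dict(DEFAULT_RAREFACTION_DEPTHS),
    },
    "network": {
        "min_prevalence": 24,
        "fdr": 0.05,
        "slope_p": 0.005,
        "dffits": 2.0,
        "skew": 3.0,
    },
}


def load_config(path=None) -> dict:
    """Read a TOML run configuration, merged over the defaults."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        import tomllib

        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(config.get(key), dict):
                config[key].update(val)
            else:
                config[key] = val
    _validate_config(config)
    return config

def _validate_config(config: dict) -> None:
    problems = []
    net = config.get("network", {})
    for key in ("fdr", "slope_p"):
        v = net.get(key)
        if v is not None and not (0 < v < 1):
            problems.append(f"network.{key} must be in (0, 1), got {v!r}")
    if config.get("seed") is not None and not isinstance(config["seed"], int):
        problems.append("seed must be an integer")
    div = config.get("diversity", {})
    if div.get("n_permutations", 1) < 1:
        problems.append("diversity.n_permutations must be >= 1")
    if problems:
        raise PipelineError("invalid configuration: " + "; ".join(problems))


def _simulation_config(config: dict, seed: int) -> SimulationConfig:
    sim = dict(config.get("simulate", {}))
    sim.pop("planted_demo", None)
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    extra = set(sim) - known
    if extra:
        raise PipelineError(f"unknown simulate options: {sorted(extra)}")
    if "cohort_sizes" in sim:
        sim["cohort_sizes"] = dict(sim["cohort_sizes"])
    return SimulationConfig(seed=seed, **sim)


def run_all(config: dict, out_dir, seed: int = None) -> dict:
    """Run every stage and write a manifest; returns the manifest dict."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))
    outputs = {}

    stage = "simulate"
    try:
        sim_config = _simulation_config(config, seed)
        effects = (
            demo_effects(sim_config)
            if config.get("simulate", {}).get("planted_demo", True)
            else ()
        )
        study = generate_study(sim_config, effects)
        paths = write_study(study, out / "simulated")
        outputs.update({f"simulate/{k}": p for k, p in paths.items()})

        stage = "preprocess"
        pre_dir = out / "preprocess"
        pre_dir.mkdir(exist_ok=True)
        for assay in MICROBE_ASSAYS & set(study.tables):
            pph = to_relative_abundance_pph(study.tables[assay])
            asinh = arcsinh_pph(pph)
            for tag, tbl in (("pph", pph), ("arcsinh_pph", asinh)):
                path = pre_dir / f"{assay}.{tag}.tsv"
                write_analyte_table(tbl, path)
                outputs[f"preprocess/{assay}.{tag}"] = path

        stage = "diversity"
        div_dir = out / "diversity"
        div_dir.mkdir(exist_ok=True)
        div_cfg = config.get("diversity", {})
        n_perm = int(div_cfg.get("n_permutations", 199))
        rows = []
        for assay in ("blood_cells", "colonic_cells"):
            d = canberra_matrix(study.tables[assay])
            log.info(
                "adonis: %s canberra ~ age + day + gender + msm_status + hiv_status",
                assay,
            )
            res = permanova(
                d,
                study.metadata.frame,
                ["age", "day", "gender", "msm_status", "hiv_status"],
                n_perm=n_perm,
                seed=seed,
            )
            rows += _permanova_rows(res, assay, "canberra")
            ord_res = pcoa(d)
            ord_res.coordinates.iloc[:, :2].to_csv(
                div_dir / f"{assay}.canberra.pcoa.tsv", sep="\t"
            )
            outputs[f"diversity/{assay}.pcoa"] = div_dir / f"{assay}.canberra.pcoa.tsv"
        if div_cfg.get("use_tree", True) and study.tree is not None:
            depths = div_cfg.get("rarefy_depths", DEFAULT_RAREFACTION_DEPTHS)
            for assay in ("fecal_microbes", "colonic_microbes"):
                depth = int(depths[assay]) if isinstance(depths, dict) else int(depths)
                rare, excluded = rarefy(study.tables[assay], depth, seed=seed)
                if excluded:
                    log.warning("%s: %d samples below depth %d excluded", assay, len(excluded), depth)
                if rare.n_samples < 6:
                    log.warning("%s: too few samples after rarefaction; skipped", assay)
                    continue
                for metric, fn in (
                    ("unweighted_unifrac", unweighted_unifrac),
                    ("weighted_unifrac", weighted_unifrac),
                ):
                    d = fn(rare, study.tree)
                    log.info("adonis: %s %s ~ msm_status + hiv_status", assay, metric)
                    res = permanova(
                        d,
                        study.metadata.frame.loc[list(rare.sample_ids)],
                        ["msm_status", "hiv_status"],
                        n_perm=n_perm,
                        seed=seed,
                    )
                    rows += _permanova_rows(res, assay, metric)
        else:
            log.warning("no phylogenetic tree: UniFrac stage skipped")
        adonis_path = div_dir / "adonis.tsv"
        pd.DataFrame(rows).to_csv(adonis_path, sep="\t", index=False)
        outputs["diversity/adonis"] = adonis_path

        stage = "differential"
        diff_dir = out / "differential"
        diff_dir.mkdir(exist_ok=True)
        for assay in ("blood_cells", "colonic_cells"):
            log.info("differential: %s analyte ~ age + day + gender + cohort", assay)
            res = immune_cohort_scan(study.tables[assay], study.metadata)
            path = diff_dir / f"{assay}.cohort.tsv"
            _differential_frame(res).to_csv(path, sep="\t", index=False)
            outputs[f"differential/{assay}.cohort"] = path
        paired = tissue_paired_scan(
            study.tables["blood_cells"], study.tables["colonic_cells"]
        )
        paired_path = diff_dir / "tissue_paired.tsv"
        paired.to_csv(paired_path, sep="\t", index=False)
        outputs["differential/tissue_paired"] = paired_path
        for assay in ("fecal_microbes", "colonic_microbes"):
            log.info("differential: %s pph ~ cohort + reads", assay)
            res = asv_cohort_scan(study.tables[assay], study.metadata)
            path = diff_dir / f"{assay}.cohort.tsv"
            _differential_frame(res).to_csv(path, sep="\t", index=False)
            outputs[f"differential/{assay}.cohort"] = path
        behavior = behavior_scan(study.tables, study.metadata)
        behavior_path = diff_dir / "behavior.tsv"
        pd.DataFrame([dataclasses.asdict(b) for b in behavior]).to_csv(
            behavior_path, sep="\t", index=False
        )
        outputs["differential/behavior"] = behavior_path

        stage = "network"
        net_dir = out / "network"
        net_dir.mkdir(exist_ok=True)
        net_cfg = config.get("network", {})
        criteria = EdgeCriteria(
            fdr=float(net_cfg.get("fdr", 0.05)),
            slope_p=float(net_cfg.get("slope_p", 0.005)),
            dffits_max=float(net_cfg.get("dffits", 2.0)),
            skew_max=float(net_cfg.get("skew", 3.0)),
            skew_mode=net_cfg.get("skew_mode", "signed"),
        )
        log.info(
            "network: analyte1 ~ [reads +] age + day + gender + cohort "
            "+ analyte2 + analyte2 x cohort vs reduced without analyte2 terms"
        )
        graph, candidates = build_network(
            study.tables,
            study.metadata,
            min_prevalence=int(net_cfg.get("min_prevalence", 24)),
            criteria=criteria,
        )
        graphml_path = net_dir / "network.graphml"
        network_to_graphml(graph, graphml_path)
        outputs["network/graphml"] = graphml_path
        edges_path = net_dir / "edges.tsv"
        network_to_edge_table(graph).to_csv(edges_path, sep="\t", index=False)
        outputs["network/edges"] = edges_path
        cand_path = net_dir / "candidates.tsv"
        candidates_to_frame(candidates).to_csv(cand_path, sep="\t", index=False)
        outputs["network/candidates"] = cand_path
        lines = []
        for c in candidates:
            if c.retained:
                frame = edge_line_data(c)
                frame.insert(0, "response", f"{c.response_assay}:{c.response_analyte}")
                frame.insert(1, "predictor", f"{c.predictor_assay}:{c.predictor_analyte}")
                lines.append(frame)
        lines_path = net_dir / "edge_lines.tsv"
        (
            pd.concat(lines, ignore_index=True)
            if lines
            else pd.DataFrame(
                columns=["response", "predictor", "cohort", "intercept", "slope", "slope_p", "solid"]
            )
        ).to_csv(lines_path, sep="\t", index=False)
        outputs["network/edge_lines"] = lines_path
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "cohortlink",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {
            key: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
            for key, p in sorted(outputs.items())
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(pathlib.Path(path).read_bytes())
    return h.hexdigest()


def _permanova_rows(res, assay, metric):
    rows = []
    for t in res.terms:
        rows.append(
            {
                "assay": assay,
                "metric": metric,
                "term": t.term,
                "df": t.df,
                "ss": t.ss,
                "pseudo_f": t.pseudo_f,
                "r2": t.r2,
                "p": t.p,
            }
        )
    return rows


def _differential_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"analyte": r.analyte, "assay": r.assay, "p": r.p, "q": r.q}
        for c in r.contrasts:
            tag = f"{c.pair[0]}_vs_{c.pair[1]}".replace(" ", "_")
            row[f"diff[{tag}]"] = c.estimate
            row[f"p_adj[{tag}]"] = c.adjusted_p
        row["directions"] = "; ".join(r.directions.values())
        rows.append(row)
    return pd.DataFrame(rows)
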