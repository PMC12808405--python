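"""Transforms and filters applied to ASV count tables before statistics.

Counts become relative abundance in parts per hundred (pph), pph is
arcsinh-transformed (``log(x + sqrt(x^2 + 1))``, defined at zero so no
pseudocount is needed), low-prevalence ASVs are dropped, and tables can be
rarefied to a fixed depth by without-replacement subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .tables import AnalyteTable, TableError

#: Minimum non-zero samples for an ASV in the per-tissue differential scan
#: (20% of the 70-participant study).
DIFFERENTIAL_MIN_PREVALENCE = 14
#: Minimum non-zero samples for a microbe to enter the association network.
NETWORK_MIN_PREVALENCE = 24

#: Default rarefaction depths (reads per sample).
DEFAULT_RAREFACTION_DEPTHS = {"fecal_microbes": 17401, "colonic_microbes": 5458}


@dataclass(frozen=True)
class PrevalenceRule:
    min_nonzero_samples: int
    scope: str = "network"

    def __post_init__(self):
        if self.min_nonzero_samples < 0:
            raise TableError("min_nonzero_samples must be >= 0")


def to_relative_abundance_pph(counts: AnalyteTable) -> AnalyteTable:
    """Rescale each sample's counts to sum to 100 (parts per hundred)."""
    if counts.value_kind != "counts":
        raise TableError(f"expected counts, got {counts.value_kind!r}")
    vals = np.asarray(counts.values, dtype=float)
    totals = vals.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise TableError(
            f"sample {counts.sample_ids[zero[0]]!r} has zero total count"
        )
    return replace(counts, values=100.0 * vals / totals[:, None], value_kind="pph")


def arcsinh_pph(table: AnalyteTable) -> AnalyteTable:
    """Elementwise ``log(x + sqrt(x^2 + 1))``; maps 0 to 0 exactly."""
    if table.value_kind != "pph":
        raise TableError(f"expected pph, got {table.value_kind!r}")
    vals = np.asarray(table.values, dtype=float)
    if np.any(vals < 0):
        raise TableError("arcsinh transform requires non-negative abundances")
    return replace(table, values=np.arcsinh(vals), value_kind="arcsinh_pph")


def prevalence_filter(table: AnalyteTable, rule: PrevalenceRule):
    """Keep analytes non-zero in at least ``rule.min_nonzero_samples`` samples.

    Returns ``(filtered_table, dropped_analyte_ids)``.
    """
    vals = np.asarray(table.values)
    nonzero = (vals > 0).sum(axis=0)
    keep = nonzero >= rule.min_nonzero_samples
    kept_ids = [a for a, k in zip(table.analyte_ids, keep) if k]
    dropped = [a for a, k in zip(table.analyte_ids, keep) if not k]
    return table.subset_analytes(kept_ids), dropped


def rarefy(table: AnalyteTable, depth: int, seed: int):
    """Subsample each sample's reads without replacement to ``depth``.

    Samples with fewer than ``depth`` total reads are excluded.  Returns
    ``(rarefied_table, excluded_sample_ids)``.  Column counts follow a
    multivariate hypergeometric draw, so rarefied counts never exceed the
    originals and each retained sample sums exactly to ``depth``.
    """
    if table.value_kind != "counts":
        raise TableError(f"expected counts, got {table.value_kind!r}")
    if depth <= 0:
        raise TableError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    vals = np.asarray(table.values, dtype=np.int64)
    totals = vals.sum(axis=1)
    keep = totals >= depth
    excluded = [s for s, k in zip(table.sample_ids, keep) if not k]
    rows = []
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    for i in np.flatnonzero(keep):
        rows.append(rng.multivariate_hypergeometric(vals[i], depth))
    new_vals = (
        np.asarray(rows, dtype=np.int64)
        if rows
        else np.zeros((0, table.n_analytes), dtype=np.int64)
    )
    out = replace(table, sample_ids=tuple(kept_ids), values=new_vals)
    return out, excluded
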