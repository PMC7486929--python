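"""In-silico pseudo-tumor construction by max-pooling cells.

A pseudo-tumor's per-gene expression is the maximum over its constituent
cells (cell lines or single cells). Two experiment designs probe whether a
heterogeneity score tracks cellular composition:

* size series — pseudo-tumors of 5, 10, ..., 5k cells drawn at random, so
  larger samples mix more cells;
* diversity series — m pseudo-tumors of m cells each, the i-th drawing its
  cells from exactly i distinct source groups (cell lines / cancer types),
  so composition diversity rises while size stays fixed.

A synthetic single-cell generator (group templates plus per-cell noise)
provides the raw material so no external accession is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import round_half_up

__all__ = [
    "CellPopulation",
    "SimulatedSample",
    "max_pool",
    "simulate_size_series",
    "simulate_diversity_series",
    "synthetic_cells",
    "pooled_expression_matrix",
    "score_series",
]


@dataclass
class CellPopulation:
    """A genes-by-cells expression matrix with one group label per cell."""

    data: pd.DataFrame  # genes x cells, log2-scale, non-negative
    group_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene ids in cell population")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate cell ids in cell population")
        missing = set(self.data.columns) - set(self.group_of)
        if missing:
            raise ValueError(f"cells without a group label: {sorted(missing)[:5]}")
        self.group_of = dict(self.group_of)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.data.columns:
            seen.setdefault(self.group_of[c], None)
        return list(seen)


@dataclass
class SimulatedSample:
    """One max-pooled pseudo-tumor."""

    sample_id: str
    member_cells: list[str]
    n_cells: int
    n_groups: int
    expression: np.ndarray  # length-m per-gene maxima


def max_pool(pop: CellPopulation, member_cells: Sequence[str], sample_id: str = "sim") -> SimulatedSample:
    """Pool cells into one pseudo-tumor by the per-gene maximum."""
    members = list(member_cells)
    if not members:
        raise ValueError("member_cells is empty")
    unknown = [c for c in members if c not in pop.data.columns]
    if unknown:
        raise KeyError(f"unknown cell ids: {unknown[:5]}")
    values = pop.data[members].to_numpy(dtype=float).max(axis=1)
    n_groups = len({pop.group_of[c] for c in members})
    return SimulatedSample(
        sample_id=sample_id,
        member_cells=members,
        n_cells=len(members),
        n_groups=n_groups,
        expression=values,
    )


def simulate_size_series(
    pop: CellPopulation, step: int = 5, seed: int | None = None
) -> list[SimulatedSample]:
    """Pseudo-tumors of step, 2*step, ..., k*step cells, drawn uniformly.

    k = round(total cells / step), capped at floor(total / step) so each
    sample can be drawn without replacement. Draws are independent across
    samples (a larger sample is not a superset of a smaller one).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    total = pop.n_cells
    if total < step:
        raise ValueError(f"population has {total} cells, fewer than step={step}")
    k = min(round_half_up(total / step), total // step)
    rng = np.random.default_rng(seed)
    cells = np.asarray(pop.cell_ids)
    samples = []
    for n in range(1, k + 1):
        members = list(rng.choice(cells, size=step * n, replace=False))
        samples.append(max_pool(pop, members, sample_id=f"size_{step * n}"))
    return samples


def simulate_diversity_series(
    pop: CellPopulation, m: int, seed: int | None = None
) -> list[SimulatedSample]:
    """m pseudo-tumors of m cells each; sample i draws from i distinct groups.

    For sample i, i groups are chosen uniformly without replacement among
    groups holding enough cells; the m cells are split as evenly as possible
    over the chosen groups, remainders going to the groups drawn first, and
    drawn without replacement within each group.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    groups = pop.groups
    if m > len(groups):
        raise ValueError(f"m={m} exceeds the {len(groups)} available groups")
    if m > pop.n_cells:
        raise ValueError(f"m={m} exceeds the {pop.n_cells} available cells")
    by_group: dict[str, list[str]] = {g: [] for g in groups}
    for c in pop.cell_ids:
        by_group[pop.group_of[c]].append(c)
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(1, m + 1):
        base, rem = divmod(m, i)
        counts = [base + (1 if j < rem else 0) for j in range(i)]
        eligible = [g for g in groups if len(by_group[g]) >= counts[0]]
        if len(eligible) < i:
            raise ValueError(
                f"sample {i}: only {len(eligible)} groups hold >= {counts[0]} cells"
            )
        chosen = list(rng.choice(np.asarray(eligible), size=i, replace=False))
        members: list[str] = []
        for g, c in zip(chosen, counts):
            members.extend(rng.choice(np.asarray(by_group[g]), size=c, replace=False))
        samples.append(max_pool(pop, members, sample_id=f"div_{i}"))
        assert samples[-1].n_groups == i
    return samples


# template decomposition: marker-module elevation vs dense per-gene effect,
# both scaled by group_effect_sd
MARKER_WEIGHT = 1.5
DENSE_WEIGHT = 0.25


def synthetic_cells(
    n_groups: int,
    cells_per_group: int,
    n_genes: int,
    group_effect_sd: float = 2.0,
    noise_sd: float = 0.5,
    seed: int | None = None,
) -> CellPopulation:
    """Generate a synthetic single-cell population on the log2 scale.

    The population mimics a panel of cell lines from distinct cancer types.
    Every cell shares a per-gene baseline ~ Normal(5, 1). Each group's
    template adds, on top of the baseline, (a) an elevation
    |Normal(0, 1.5 * group_effect_sd)| on the group's own marker-gene block
    (the genes are partitioned into n_groups disjoint blocks, one per
    group), emulating type-specific marker expression, and (b) a dense
    per-gene effect ~ Normal(0, 0.25 * group_effect_sd) on all genes,
    emulating diffuse between-type expression differences. Each cell is its
    group's template plus i.i.d. Normal(0, noise_sd) noise; all values are
    truncated at 0. Deterministic per seed.

    The sparse marker structure matters: it makes the set of genes a
    max-pooled pseudo-tumor elevates grow with the diversity of its member
    cells, which is what heterogeneity scoring is meant to detect.
    """
    if min(n_groups, cells_per_group, n_genes) < 1:
        raise ValueError("counts must all be >= 1")
    if group_effect_sd < 0 or noise_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    baseline = np.clip(rng.normal(5.0, 1.0, size=n_genes), 0.0, None)
    templates = baseline[:, None] + rng.normal(
        0.0, DENSE_WEIGHT * group_effect_sd, size=(n_genes, n_groups)
    )
    block = max(n_genes // n_groups, 1)
    for g in range(n_groups):
        lo = g * block
        hi = n_genes if g == n_groups - 1 else min((g + 1) * block, n_genes)
        if lo < hi:
            templates[lo:hi, g] += np.abs(
                rng.normal(0.0, MARKER_WEIGHT * group_effect_sd, size=hi - lo)
            )
    templates = np.clip(templates, 0.0, None)
    columns: dict[str, np.ndarray] = {}
    group_of: dict[str, str] = {}
    for g in range(n_groups):
        group = f"group{g + 1}"
        noise = rng.normal(0.0, noise_sd, size=(n_genes, cells_per_group))
        cells = np.clip(templates[:, [g]] + noise, 0.0, None)
        for c in range(cells_per_group):
            cid = f"{group}_cell{c + 1}"
            columns[cid] = cells[:, c]
            group_of[cid] = group
    data = pd.DataFrame(columns, index=gene_ids)
    return CellPopulation(data=data, group_of=group_of)


def score_series(pop: CellPopulation, samples: Sequence[SimulatedSample]) -> pd.DataFrame:
    """Tumor-referenced heterogeneity scores for a pseudo-tumor series.

    The scored cohort is the source cell population plus the pooled
    samples, all treated as tumors (a cell-line panel has no normal
    controls), so the reference mean approximates the cell-population
    average and pooling more, or more diverse, cells moves a pseudo-tumor
    monotonically away from it. Returns the score rows for the pooled
    samples only, in series order.
    """
    from .core import depth_scores
    from .matrix import ExpressionMatrix, SampleLabels

    pooled = pooled_expression_matrix(pop, samples)
    clash = set(pooled.columns) & set(pop.data.columns)
    if clash:
        raise ValueError(f"sample ids collide with cell ids: {sorted(clash)[:5]}")
    cohort = pd.concat([pooled, pop.data], axis=1)
    expr = ExpressionMatrix(cohort, scale="log2")
    labels = SampleLabels({c: "tumor" for c in cohort.columns})
    table = depth_scores(expr, labels, mode="tumor_mean")
    table = table.set_index("sample_id").loc[list(pooled.columns)].reset_index()
    table["n_cells"] = [s.n_cells for s in samples]
    table["n_groups"] = [s.n_groups for s in samples]
    return table


def pooled_expression_matrix(
    pop: CellPopulation, samples: Sequence[SimulatedSample]
) -> pd.DataFrame:
    """Assemble pooled pseudo-tumors into a genes-by-samples DataFrame."""
    return pd.DataFrame(
        {s.sample_id: s.expression for s in samples}, index=pop.gene_ids
    )
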