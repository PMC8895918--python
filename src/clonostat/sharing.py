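"""Clonotype sharing between individuals and cross-individual lineages.

Public clonotypes — identical CDR3 sequences observed in more than one
mouse — are counted by occupancy (the number of individuals carrying
them). At the lineage level, clonotypes of all samples of one strain x
isotype are pooled, clustered with the 95%-identity lineage criteria,
and each retained lineage is traced back to the samples contributing
its nodes, giving per-lineage occupancy over blood/spleen samples and
per-sample lineage abundance profiles compared with the Morisita-Horn
index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import morisita_horn
from .lineage import NodeKey, build_lineages, collapse_nt_clonotypes


# ---------------------------------------------------------------------------
# clonotype sharing

@dataclass
class SharingTable:
    """Occupancy of clonotypes across the individuals of one group.

    ``occupancy`` maps each distinct clonotype to the number of
    individuals carrying it; ``ratios`` (percent, indexed k = 1..n)
    sums to 100; ``unshared_pct`` is the k = 1 entry.
    """

    occupancy: dict[Hashable, int]
    ratios: pd.Series
    n_individuals: int

    @property
    def unshared_pct(self) -> float:
        return float(self.ratios.loc[1])


def _clonotype_keys(df: pd.DataFrame, level: str) -> set[Hashable]:
    if level == "aa":
        return set(df["cdr3_aa"])
    if level == "nt":
        return set(zip(df["v_gene"], df["j_gene"], df["cdr3_nt"]))
    raise ValueError(f"unknown level {level!r}")


def sharing_ratios(
    subsets: Mapping[str, pd.DataFrame], level: str = "aa"
) -> SharingTable:
    """Ratio of clonotypes shared by exactly k of the given individuals.

    ``subsets`` maps individual id -> clone table (same strain, tissue
    and isotype). Sharing is presence/absence on clonotype identity,
    unweighted by abundance.
    """
    if len(subsets) < 2:
        raise ValueError("sharing needs at least two individuals")
    occupancy: dict[Hashable, int] = {}
    for _, df in sorted(subsets.items()):
        for key in _clonotype_keys(df, level):
            occupancy[key] = occupancy.get(key, 0) + 1
    n = len(subsets)
    ks = pd.Series(list(occupancy.values()))
    counts = ks.value_counts().reindex(range(1, n + 1), fill_value=0)
    ratios = 100.0 * counts / counts.sum()
    return SharingTable(occupancy=occupancy, ratios=ratios, n_individuals=n)


# ---------------------------------------------------------------------------
# cross-individual lineages

@dataclass
class CrossLineage:
    """One clonal lineage pooled across all samples of a strain x isotype.

    ``presence[sample]`` is True when at least one node traces back to
    that sample by identical (V, J, CDR3 nt); ``abundance[sample]`` is
    the summed within-sample frequency of the lineage's nodes.
    """

    lineage_id: str
    nodes: frozenset[NodeKey]
    presence: dict[str, bool]
    abundance: dict[str, float]

    @property
    def size(self) -> int:
        return len(self.nodes)


def build_cross_lineages(
    samples: Mapping[str, pd.DataFrame],
    threshold_pct: float = 95.0,
    min_nodes: int = 3,
) -> list[CrossLineage]:
    """Pool samples, cluster lineages, and trace nodes back per sample.

    ``samples`` maps sample id -> clone table (all blood and spleen
    samples of one strain x isotype). Clonotypes are deduplicated by
    (V, J, CDR3 nt) before clustering; only components with >=
    ``min_nodes`` nodes are retained. Node frequency within a sample is
    its clone count over that sample's total clone count.
    """
    pooled = pd.concat(list(samples.values()), ignore_index=True)
    net = build_lineages(pooled, threshold_pct=threshold_pct, min_nodes=min_nodes)

    per_sample: dict[str, dict[NodeKey, float]] = {}
    for sid, df in samples.items():
        total = float(df["count"].sum())
        collapsed = collapse_nt_clonotypes(df)
        per_sample[sid] = {
            (r.v_gene, r.j_gene, r.cdr3_nt): r.count / total
            for r in collapsed.itertuples()
        }

    lineages = []
    for i, nodes in enumerate(net.lineages):
        presence, abundance = {}, {}
        for sid in samples:
            freqs = per_sample[sid]
            mass = sum(freqs.get(node, 0.0) for node in nodes)
            presence[sid] = mass > 0.0
            abundance[sid] = mass
        lineages.append(
            CrossLineage(
                lineage_id=f"L{i + 1:04d}", nodes=nodes,
                presence=presence, abundance=abundance,
            )
        )
    return lineages


def lineage_occupancy(
    lineages: Sequence[CrossLineage], sample_tissues: Mapping[str, str]
) -> pd.DataFrame:
    """Percent of lineages present in each (n blood, n spleen) cell.

    ``sample_tissues`` maps sample id -> "blood" or "spleen". Each
    lineage lands in exactly one cell, so the matrix sums to 100.
    Rows are blood-sample counts, columns spleen-sample counts.
    """
    blood = sorted(s for s, t in sample_tissues.items() if t == "blood")
    spleen = sorted(s for s, t in sample_tissues.items() if t == "spleen")
    matrix = pd.DataFrame(
        0.0, index=range(len(blood) + 1), columns=range(len(spleen) + 1)
    )
    matrix.index.name = "n_blood"
    matrix.columns.name = "n_spleen"
    if not lineages:
        return matrix
    for lin in lineages:
        nb = sum(lin.presence.get(s, False) for s in blood)
        ns = sum(lin.presence.get(s, False) for s in spleen)
        matrix.loc[nb, ns] += 1
    return 100.0 * matrix / len(lineages)


def lineage_abundance_mhsi(
    lineages: Sequence[CrossLineage], sample_a: str, sample_b: str
) -> float:
    """Morisita-Horn similarity of two samples' lineage abundance profiles.

    Per sample, each lineage's abundance is its nodes' summed frequency;
    the vectors are normalized within the sample before applying the
    index.
    """
    a = np.array([lin.abundance.get(sample_a, 0.0) for lin in lineages])
    b = np.array([lin.abundance.get(sample_b, 0.0) for lin in lineages])
    if a.sum() == 0.0 or b.sum() == 0.0:
        raise ValueError("sample with zero lineage mass")
    return morisita_horn(a / a.sum(), b / b.sum())


def node_size_distribution(lineages: Sequence[CrossLineage]) -> pd.Series:
    """Lineage counts per node-count (histogram over lineage sizes)."""
    if not lineages:
        return pd.Series(dtype=int)
    sizes = pd.Series([lin.size for lin in lineages])
    return sizes.value_counts().sort_index()


def fraction_at_size(lineages: Sequence[CrossLineage], size: int = 2) -> float:
    """Fraction of lineages with exactly ``size`` nodes."""
    dist = node_size_distribution(lineages)
    if dist.empty:
        return 0.0
    return float(dist.get(size, 0) / dist.sum())


# ---------------------------------------------------------------------------
# group comparison

@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    significant: bool
    method: str


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], paired: bool = False,
    alpha: float = 0.05,
) -> TestResult:
    """Two-sided Wilcoxon comparison of two groups of observations.

    Unpaired groups use the rank-sum (Mann-Whitney) test, paired groups
    the signed-rank test; exact null distributions for n <= 25, normal
    approximation with continuity correction beyond. Paired samples
    whose differences are all zero carry no signal and report p = 1
    with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one observation")
    if paired:
        if a.size != b.size:
            raise ValueError("paired groups must have equal lengths")
        diffs = a - b
        if np.all(diffs == 0):
            warnings.warn("all paired differences are zero; p-value undefined, reporting 1")
            return TestResult(0.0, 1.0, False, "wilcoxon-signed-rank")
        method = "exact" if a.size <= 25 else "approx"
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method, correction=True)
        return TestResult(float(res.statistic), float(res.pvalue),
                          res.pvalue < alpha, "wilcoxon-signed-rank")
    method = "exact" if max(a.size, b.size) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue),
                      res.pvalue < alpha, "wilcoxon-rank-sum")
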