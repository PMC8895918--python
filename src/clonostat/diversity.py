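"""Repertoire diversity and similarity statistics.

Implements the statistics used to compare IgH repertoires between
samples: pooled V/D/J gene-usage frequency profiles and their Pearson
correlation, CDR3 clonotype abundance profiles, the Morisita-Horn
similarity index (MHSI), normalized Shannon diversity entropy (NSDE),
and Chao1 richness with rarefaction/extrapolation curves and coverage.

The Morisita-Horn index between two clonotype frequency vectors p and q
(each normalized over its own sample, indexed over the union of
clonotypes) is

    MHSI = 2 sum_i p_i q_i / (sum_i p_i^2 + sum_i q_i^2),

ranging from 0 (disjoint repertoires) to 1 (identical frequency
profiles). NSDE is Shannon entropy normalized by its maximum,
-sum_i p_i ln p_i / ln N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# gene usage

D_EMPTY = "D-empty"


@dataclass(frozen=True)
class GeneUsageProfile:
    """Per-segment-class gene frequencies for one sample x isotype subset.

    ``v``, ``d`` and ``j`` each map gene name to frequency and each sum
    to 1; clones whose CDR3 contains no D segment contribute to the
    ``"D-empty"`` key of ``d``.
    """

    v: dict[str, float]
    d: dict[str, float]
    j: dict[str, float]

    def __post_init__(self) -> None:
        for name, block in (("v", self.v), ("d", self.d), ("j", self.j)):
            total = sum(block.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name}-gene frequencies sum to {total}, not 1")


def gene_usage(subset: pd.DataFrame, weighted: bool = True) -> GeneUsageProfile:
    """V/D/J usage frequencies of a clone table.

    Frequencies are weighted by clone counts by default ("frequency of
    clones"); ``weighted=False`` counts each unique row once.
    """
    if len(subset) == 0:
        raise ValueError("empty subset has no gene usage")
    w = subset["count"].to_numpy(dtype=float) if weighted else np.ones(len(subset))

    def freqs(calls: pd.Series, empty_key: str | None = None) -> dict[str, float]:
        names = calls.fillna("").astype(str)
        if empty_key is not None:
            names = names.replace("", empty_key)
        totals = pd.Series(w).groupby(names.to_numpy()).sum()
        totals = totals / totals.sum()
        return {str(k): float(v) for k, v in totals.sort_index().items()}

    return GeneUsageProfile(
        v=freqs(subset["v_gene"]),
        d=freqs(subset.get("d_gene", pd.Series([""] * len(subset))), empty_key=D_EMPTY),
        j=freqs(subset["j_gene"]),
    )


def pooled_usage_vectors(a: GeneUsageProfile, b: GeneUsageProfile) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated V+D+J frequency vectors over the union of gene names."""
    xs, ys = [], []
    for block_a, block_b in ((a.v, b.v), (a.d, b.d), (a.j, b.j)):
        names = sorted(set(block_a) | set(block_b))
        xs.extend(block_a.get(n, 0.0) for n in names)
        ys.extend(block_b.get(n, 0.0) for n in names)
    return np.asarray(xs), np.asarray(ys)


def gene_usage_correlation(a: GeneUsageProfile, b: GeneUsageProfile) -> float:
    """Pearson correlation of the pooled V+D+J frequency vectors."""
    x, y = pooled_usage_vectors(a, b)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate gene-usage profile (zero variance)")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# clonotype profiles

class ClonotypeProfile:
    """Abundance map over unique clonotypes of one sample x isotype subset.

    Keys are CDR3 aa strings (level ``"aa"``) or ``(v_gene, j_gene,
    cdr3_nt)`` triples (level ``"nt"``); values are positive integer
    clone counts. Frequencies ``p_i = n_i / sum n_i`` are derived.
    """

    def __init__(self, abundances: Mapping[Hashable, int]):
        if not abundances:
            raise ValueError("empty clonotype profile")
        clean: dict[Hashable, int] = {}
        for key, n in abundances.items():
            n = int(n)
            if n < 1:
                raise ValueError(f"clonotype {key!r} has nonpositive count {n}")
            clean[key] = n
        self._counts = clean
        self._total = sum(clean.values())

    @classmethod
    def from_records(cls, df: pd.DataFrame, level: str = "aa") -> "ClonotypeProfile":
        """Aggregate a clone table into a clonotype profile."""
        if level == "aa":
            grouped = df.groupby("cdr3_aa")["count"].sum()
            return cls(grouped.to_dict())
        if level == "nt":
            grouped = df.groupby(["v_gene", "j_gene", "cdr3_nt"])["count"].sum()
            return cls({tuple(k): v for k, v in grouped.items()})
        raise ValueError(f"unknown level {level!r}")

    @property
    def counts(self) -> dict[Hashable, int]:
        return dict(self._counts)

    @property
    def total(self) -> int:
        return self._total

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, key: Hashable) -> bool:
        return key in self._counts

    def freq(self, key: Hashable) -> float:
        return self._counts.get(key, 0) / self._total

    def count_array(self) -> np.ndarray:
        return np.fromiter(self._counts.values(), dtype=np.int64, count=len(self._counts))

    def freq_array(self) -> np.ndarray:
        arr = self.count_array().astype(float)
        return arr / arr.sum()


def morisita_horn(p: np.ndarray, q: np.ndarray) -> float:
    """Morisita-Horn similarity of two aligned frequency vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    denom = float(p @ p + q @ q)
    if denom == 0.0:
        raise ValueError("both frequency vectors are zero")
    return float(2.0 * (p @ q) / denom)


def mhsi(a: ClonotypeProfile, b: ClonotypeProfile) -> float:
    """Morisita-Horn similarity index of two clonotype profiles.

    Symmetric, 1 for identical frequency profiles, 0 for disjoint
    clonotype sets.
    """
    keys = sorted(set(a.counts) | set(b.counts))
    p = np.array([a.freq(k) for k in keys])
    q = np.array([b.freq(k) for k in keys])
    return morisita_horn(p, q)


def nsde(profile: ClonotypeProfile) -> float:
    """Normalized Shannon diversity entropy of a clonotype profile.

    Equals 1 for a perfectly even repertoire, approaches 0 under clonal
    dominance. A single-clonotype repertoire has no evenness and returns
    0 by convention.
    """
    n = len(profile)
    if n == 1:
        warnings.warn("NSDE of a single-clonotype profile is 0 by convention")
        return 0.0
    p = profile.freq_array()
    return float(-(p * np.log(p)).sum() / np.log(n))


# ---------------------------------------------------------------------------
# richness

def _f_counts(counts: np.ndarray) -> tuple[int, int, int]:
    s_obs = int(len(counts))
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs, f1, f2


def chao1(profile: ClonotypeProfile | np.ndarray) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    ``S_obs + f1^2 / (2 f2)`` when doubletons exist, else the
    bias-corrected ``S_obs + f1 (f1 - 1) / 2``. Never below ``S_obs``.
    """
    counts = profile.count_array() if isinstance(profile, ClonotypeProfile) else np.asarray(profile)
    if counts.size == 0:
        raise ValueError("empty profile")
    s_obs, f1, f2 = _f_counts(counts)
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def chao1_variance(counts: np.ndarray) -> float:
    """Classic variance estimate of the Chao1 richness estimator."""
    _, f1, f2 = _f_counts(counts)
    if f2 > 0:
        r = f1 / f2
        return f2 * (r**2 / 2 + r**3 + r**4 / 4)
    if f1 > 0:
        est = chao1(counts)
        return f1 * (f1 - 1) / 2 + f1 * (2 * f1 - 1) ** 2 / 4 - f1**4 / (4 * est)
    return 0.0


@dataclass
class RarefactionResult:
    """Interpolated/extrapolated clonotype accumulation for one subset.

    ``curve`` has columns (fraction_pct, size, mean, sem, phase) where
    phase is "interpolated" (<= sample size; bootstrap mean and SEM) or
    "extrapolated" (Chao1-based accumulation; SEM from the Chao1
    variance propagated through the accumulation multiplier).
    """

    curve: pd.DataFrame
    s_obs: int
    s_chao: float
    coverage_pct: float


def _subsample_richness_curve(counts: np.ndarray, sizes: np.ndarray, reps: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Mean/SEM of clonotype richness at each subsample size.

    Each replicate permutes the expanded clone multiset once and reads
    richness off prefixes, i.e. subsampling without replacement with the
    draws coupled across sizes — every replicate's curve is nondecreasing.
    """
    clone_ids = np.repeat(np.arange(len(counts)), counts)
    richness = np.empty((reps, len(sizes)), dtype=float)
    for r in range(reps):
        perm = rng.permutation(clone_ids)
        _, first_idx = np.unique(perm, return_index=True)
        first_idx.sort()
        richness[r] = np.searchsorted(first_idx, sizes, side="left")
    mean = richness.mean(axis=0)
    sem = richness.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else np.zeros(len(sizes))
    return mean, sem


def _analytic_interpolation(counts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Exact expected richness under subsampling without replacement.

    E[S_m] = S_obs - sum_i C(n - n_i, m) / C(n, m) (hypergeometric form).
    """
    n = int(counts.sum())
    out = np.empty(len(sizes))
    for k, m in enumerate(sizes):
        with np.errstate(invalid="ignore"):
            log_absent = (
                gammaln(n - counts + 1) - gammaln(n - counts - m + 1)
                - (gammaln(n + 1) - gammaln(n - m + 1))
            )
        absent = np.where(n - counts >= m, np.exp(log_absent), 0.0)
        out[k] = len(counts) - absent.sum()
    return out


def rarefaction_curve(
    profile: ClonotypeProfile | pd.DataFrame,
    increment_pct: float = 1.0,
    reps: int = 100,
    extrap_factor: float = 5.0,
    seed: int | None = 0,
    method: str = "bootstrap",
    level: str = "aa",
) -> RarefactionResult:
    """Clonotype accumulation curve with Chao1 extrapolation and coverage.

    Interpolates by subsampling clones without replacement at
    ``increment_pct`` steps of the total clone count (``reps``
    replicates each, seeded), then extrapolates to ``extrap_factor``
    times the sample size with the Chao1-based species-accumulation
    form. ``method="analytic"`` replaces the bootstrap with the exact
    hypergeometric expectation (SEM reported as 0).
    """
    if isinstance(profile, pd.DataFrame):
        profile = ClonotypeProfile.from_records(profile, level=level)
    counts = profile.count_array()
    n = int(counts.sum())
    step = int(np.floor(n * increment_pct / 100.0))
    if step < 1:
        raise ValueError(f"{n} clones is fewer than one {increment_pct}% increment")

    fractions = np.arange(increment_pct, 100.0 + increment_pct / 2, increment_pct)
    sizes = np.minimum(np.round(n * fractions / 100.0).astype(int), n)
    sizes[-1] = n

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        mean, sem = _subsample_richness_curve(counts, sizes, reps, rng)
        # the full sample always contains every observed clonotype
        mean[-1], sem[-1] = float(len(counts)), 0.0
    elif method == "analytic":
        mean = _analytic_interpolation(counts, sizes)
        sem = np.zeros(len(sizes))
    else:
        raise ValueError(f"unknown method {method!r}")

    s_obs, f1, _ = _f_counts(counts)
    s_chao = chao1(counts)
    interp = pd.DataFrame(
        {"fraction_pct": fractions, "size": sizes, "mean": mean, "sem": sem,
         "phase": "interpolated"}
    )

    extra_fracs = np.arange(100.0 + 10.0, extrap_factor * 100.0 + 5.0, 10.0)
    extra_sizes = np.round(n * extra_fracs / 100.0).astype(int)
    f0 = s_chao - s_obs
    if f0 > 0 and f1 > 0:
        m_star = extra_sizes - n
        mult = 1.0 - (1.0 - f1 / (n * f0 + f1)) ** m_star
        extra_mean = s_obs + f0 * mult
        extra_sem = np.sqrt(chao1_variance(counts)) * mult
    else:
        extra_mean = np.full(len(extra_sizes), float(s_obs))
        extra_sem = np.zeros(len(extra_sizes))
    extrap = pd.DataFrame(
        {"fraction_pct": extra_fracs, "size": extra_sizes, "mean": extra_mean,
         "sem": extra_sem, "phase": "extrapolated"}
    )

    curve = pd.concat([interp, extrap], ignore_index=True)
    return RarefactionResult(
        curve=curve,
        s_obs=s_obs,
        s_chao=float(s_chao),
        coverage_pct=float(100.0 * s_obs / s_chao),
    )
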