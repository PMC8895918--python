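"""End-to-end orchestration: filter, subset, analyze, and write reports.

``run_pipeline`` consumes AIRR clone tables (or in-memory tables),
applies the qualified-CDR3 filter and the technical-replicate policy,
splits clones into sample x isotype subsets, and runs the diversity,
lineage, sharing and cross-lineage analyses, writing each result as a
TSV plus a JSON manifest that fully determines the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .demux import filter_qualified, select_technical_duplicate
from .diversity import (
    ClonotypeProfile,
    gene_usage,
    gene_usage_correlation,
    mhsi,
    nsde,
    rarefaction_curve,
)
from .io import read_airr
from .lineage import build_lineages, degree_stats, mutated_ratio, nn_distribution
from .sharing import (
    build_cross_lineages,
    fraction_at_size,
    lineage_abundance_mhsi,
    lineage_occupancy,
    node_size_distribution,
    sharing_ratios,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run (echoed into the manifest)."""

    input_paths: list[str] = field(default_factory=list)
    column_map: dict[str, str] | None = None
    out_dir: str = "clonostat_out"
    run_diversity: bool = True
    run_rarefaction: bool = True
    run_lineage: bool = True
    run_sharing: bool = True
    run_cross_lineage: bool = True
    identity_threshold_pct: float = 95.0
    lineage_min_nodes: int = 2
    cross_lineage_min_nodes: int = 3
    degree_cap: int = 8
    rarefaction_increment_pct: float = 1.0
    rarefaction_reps: int = 100
    rarefaction_extrap_factor: float = 5.0
    replicate_criterion: str = "clones"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.identity_threshold_pct <= 100:
            raise ValueError("identity threshold must be in (0, 100]")
        if self.lineage_min_nodes < 2 or self.cross_lineage_min_nodes < 2:
            raise ValueError("min_nodes thresholds must be >= 2")
        if self.degree_cap < 1:
            raise ValueError("degree cap must be >= 1")
        if self.rarefaction_increment_pct <= 0 or self.rarefaction_reps < 1:
            raise ValueError("invalid rarefaction parameters")


def _subset_id(meta: pd.Series) -> str:
    return f"{meta.get('sample_id', 'sample')}_{meta.get('isotype', 'all')}"


def load_clone_table(cfg: RunConfig) -> pd.DataFrame:
    frames = [read_airr(p, column_map=cfg.column_map) for p in cfg.input_paths]
    if not frames:
        raise ValueError("no input files")
    return pd.concat(frames, ignore_index=True)


def _apply_replicate_policy(df: pd.DataFrame, criterion: str) -> pd.DataFrame:
    """Keep one technical replicate per (mouse, tissue, isotype).

    Applies only when a ``replicate`` column marks replicates; the
    replicate maximizing the criterion wins.
    """
    if "replicate" not in df.columns:
        return df
    kept = []
    for _, group in df.groupby(["mouse_id", "tissue", "isotype"], dropna=False):
        reps = [rep for _, rep in group.groupby("replicate")]
        kept.append(select_technical_duplicate(reps, criterion=criterion))
    return pd.concat(kept, ignore_index=True)


def run_pipeline(
    cfg: RunConfig, tables: pd.DataFrame | None = None
) -> dict[str, pd.DataFrame]:
    """Execute the configured analysis stages and write the report bundle.

    Returns the result tables keyed by report name; each is also written
    as ``<out_dir>/<name>.tsv`` together with ``manifest.json``. Stages
    never mutate upstream tables, and re-running with the same inputs
    and seed reproduces every output.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    df = tables.copy() if tables is not None else load_clone_table(cfg)
    df, dropped = filter_qualified(df)
    df = _apply_replicate_policy(df, cfg.replicate_criterion)
    for col, default in (("sample_id", "sample"), ("mouse_id", "mouse"),
                         ("strain", ""), ("tissue", ""), ("batch", ""),
                         ("isotype", "all")):
        if col not in df.columns:
            df[col] = default

    results: dict[str, pd.DataFrame] = {}
    subsets = {
        key: sub.reset_index(drop=True)
        for key, sub in df.groupby(["sample_id", "isotype"], sort=True)
        if len(sub) > 0
    }
    meta = {
        key: sub.iloc[0][["mouse_id", "strain", "tissue", "batch"]]
        for key, sub in subsets.items()
    }

    if cfg.run_diversity:
        rows, curves = [], []
        profiles = {}
        for (sample_id, isotype), sub in subsets.items():
            profile = ClonotypeProfile.from_records(sub, level="aa")
            profiles[(sample_id, isotype)] = profile
            row = {
                "sample_id": sample_id, "isotype": isotype,
                "mouse_id": meta[(sample_id, isotype)]["mouse_id"],
                "tissue": meta[(sample_id, isotype)]["tissue"],
                "n_clones": int(sub["count"].sum()),
                "s_obs": len(profile), "nsde": nsde(profile),
            }
            if cfg.run_rarefaction:
                try:
                    rr = rarefaction_curve(
                        profile,
                        increment_pct=cfg.rarefaction_increment_pct,
                        reps=cfg.rarefaction_reps,
                        extrap_factor=cfg.rarefaction_extrap_factor,
                        seed=cfg.seed,
                    )
                except ValueError as err:
                    logger.warning("rarefaction skipped for %s %s: %s",
                                   sample_id, isotype, err)
                else:
                    row.update(s_chao=rr.s_chao, coverage_pct=rr.coverage_pct)
                    curve = rr.curve.copy()
                    curve.insert(0, "isotype", isotype)
                    curve.insert(0, "sample_id", sample_id)
                    curves.append(curve)
            rows.append(row)
        results["diversity_summary"] = pd.DataFrame(rows)
        if curves:
            results["rarefaction"] = pd.concat(curves, ignore_index=True)

        keys = sorted(subsets)
        labels = [f"{s}_{i}" for s, i in keys]
        usage = {k: gene_usage(subsets[k]) for k in keys}
        pearson = pd.DataFrame(1.0, index=labels, columns=labels)
        mh = pd.DataFrame(1.0, index=labels, columns=labels)
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                r = gene_usage_correlation(usage[keys[a]], usage[keys[b]])
                m = mhsi(profiles[keys[a]], profiles[keys[b]])
                pearson.iloc[a, b] = pearson.iloc[b, a] = r
                mh.iloc[a, b] = mh.iloc[b, a] = m
        results["gene_usage_pearson"] = pearson
        results["mhsi_aa"] = mh

    if cfg.run_lineage:
        lin_rows, node_rows, nn_frames = [], [], []
        for (sample_id, isotype), sub in subsets.items():
            net = build_lineages(sub, threshold_pct=cfg.identity_threshold_pct,
                                 min_nodes=cfg.lineage_min_nodes)
            stats_ = degree_stats(net, cap=cfg.degree_cap)
            row = {
                "sample_id": sample_id, "isotype": isotype,
                "n_nt_clonotypes": net.n_clonotypes,
                "n_lineages": len(net.lineages),
                "mutated_ratio_pct": mutated_ratio(net),
                "max_degree": stats_.max_degree,
            }
            for deg in range(1, cfg.degree_cap + 1):
                label = f"degree_{deg}{'_plus' if deg == cfg.degree_cap else ''}_ratio"
                row[label] = float(stats_.ratios.get(deg, 0.0)) if len(stats_.ratios) else 0.0
            lin_rows.append(row)
            degrees = dict(net.graph.degree())
            for li, nodes in enumerate(net.lineages):
                for v, j, nt in sorted(nodes):
                    node_rows.append({
                        "sample_id": sample_id, "isotype": isotype,
                        "lineage_id": f"{sample_id}_{isotype}_L{li + 1:04d}",
                        "v_gene": v, "j_gene": j, "cdr3_nt": nt,
                        "cdr3_length": len(nt),
                        "count": net.graph.nodes[(v, j, nt)]["count"],
                        "degree": degrees[(v, j, nt)],
                    })
            nn = nn_distribution(sub)
            nn.insert(0, "isotype", isotype)
            nn.insert(0, "sample_id", sample_id)
            nn_frames.append(nn)
        results["lineage_summary"] = pd.DataFrame(lin_rows)
        results["lineage_nodes"] = pd.DataFrame(node_rows)
        results["nn_distribution"] = pd.concat(nn_frames, ignore_index=True)

    if cfg.run_sharing:
        share_rows = []
        for (strain, tissue, isotype), sub in df.groupby(["strain", "tissue", "isotype"]):
            by_mouse = {m: g for m, g in sub.groupby("mouse_id")}
            if len(by_mouse) < 2:
                continue
            table = sharing_ratios(by_mouse, level="aa")
            for k, pct in table.ratios.items():
                share_rows.append({
                    "strain": strain, "tissue": tissue, "isotype": isotype,
                    "n_individuals": table.n_individuals,
                    "k": int(k), "ratio_pct": float(pct),
                })
        results["sharing"] = pd.DataFrame(share_rows)

    if cfg.run_cross_lineage:
        cl_node_rows, occ_frames, mhsi_rows, size_rows = [], [], [], []
        for (strain, isotype), sub in df.groupby(["strain", "isotype"]):
            samples = {s: g for s, g in sub.groupby("sample_id")}
            if len(samples) < 2:
                continue
            lineages = build_cross_lineages(
                samples, threshold_pct=cfg.identity_threshold_pct,
                min_nodes=cfg.cross_lineage_min_nodes,
            )
            tissues = {s: g["tissue"].iloc[0] for s, g in samples.items()}
            occ = lineage_occupancy(lineages, tissues).reset_index()
            occ.insert(0, "isotype", isotype)
            occ.insert(0, "strain", strain)
            occ_frames.append(occ)
            for lin in lineages:
                for v, j, nt in sorted(lin.nodes):
                    present = sorted(s for s, p in lin.presence.items() if p)
                    cl_node_rows.append({
                        "strain": strain, "isotype": isotype,
                        "lineage_id": lin.lineage_id, "v_gene": v,
                        "j_gene": j, "cdr3_nt": nt,
                        "n_samples_present": len(present),
                        "samples": ";".join(present),
                    })
            for size, n in node_size_distribution(lineages).items():
                size_rows.append({"strain": strain, "isotype": isotype,
                                  "n_nodes": int(size), "n_lineages": int(n)})
            sample_ids = sorted(samples)
            if lineages:
                for a in range(len(sample_ids)):
                    for b in range(a + 1, len(sample_ids)):
                        try:
                            value = lineage_abundance_mhsi(
                                lineages, sample_ids[a], sample_ids[b])
                        except ValueError:
                            continue
                        mhsi_rows.append({
                            "strain": strain, "isotype": isotype,
                            "sample_a": sample_ids[a], "sample_b": sample_ids[b],
                            "mhsi": value,
                        })
        results["cross_lineage_nodes"] = pd.DataFrame(cl_node_rows)
        if occ_frames:
            results["lineage_occupancy"] = pd.concat(occ_frames, ignore_index=True)
        results["lineage_size_distribution"] = pd.DataFrame(size_rows)
        results["lineage_mhsi"] = pd.DataFrame(mhsi_rows)

    for name, table in results.items():
        index = name in ("gene_usage_pearson", "mhsi_aa")
        table.to_csv(out / f"{name}.tsv", sep="\t", index=index)
    manifest = {
        "package": "clonostat",
        "version": __version__,
        "config": asdict(cfg),
        "dropped_rows": dropped,
        "n_qualified_clones": int(df["count"].sum()),
        "n_subsets": len(subsets),
        "outputs": sorted(results),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results
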