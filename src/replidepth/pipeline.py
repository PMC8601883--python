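"""Config-driven orchestration of the full replicate/depth/threshold analysis.

Stages: (optional) synthetic simulation -> decontamination + index-hop
check -> rarefaction grid over the depth x threshold design ->
alpha diversity at the contrast depths with extrapolation and IQR outlier
calls -> replicate accumulation and occupancy at the focal cell ->
beta diversity (LCBD, ordination, dispersion) with the depth-contrast
dispersion test.  Every output is a plain TSV; a JSON manifest records
the config, seed, package version and per-depth retained-replicate
counts so any run is regenerable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeding import child_rng
from .accumulation import accumulation_curve, occupancy_abundance_fit, occupancy_records, occupancy_spectrum
from .alpha import (
    alpha_indices,
    depth_contrast_tests,
    extrapolated_richness,
    iqr_outliers,
)
from .beta import beta_dispersion, jaccard_distance, lcbd
from .decontam import index_hop_check, prevalence_scores, remove_contaminants
from .filtering import rarefaction_grid, rarefy_table, retained_counts, rarefy, apply_min_read_threshold
from .synthetic import SyntheticConfig, simulate_experiment
from .tables import ReplicateMetadata, TaxonTable, read_metadata, read_taxon_table, write_metadata, write_taxon_table

logger = logging.getLogger("replidepth")

__all__ = ["PipelineConfig", "run_pipeline", "depth_dispersion_contrast"]


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through YAML."""

    synthetic: SyntheticConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    depths: list[int] = field(default_factory=lambda: list(range(1000, 20001, 1000)))
    thresholds: list[int] = field(default_factory=lambda: [2, 5, 10])
    repeats: int = 25
    bootstraps: int = 100
    nboot: int = 50
    knots: int = 40
    permutations: int = 999
    alpha_level: float = 0.05
    contrast_depths: tuple[int, int] = (1000, 10000)
    focal_depth: int = 5000
    focal_threshold: int = 5
    decontam_threshold: float = 0.1
    seed: int = 0
    outdir: str = "replidepth_out"

    def __post_init__(self) -> None:
        if self.synthetic is None and self.counts_path is None:
            raise ValueError("config needs either a synthetic section or a counts_path")
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        self.contrast_depths = tuple(self.contrast_depths)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrast_depths"] = list(self.contrast_depths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def depth_dispersion_contrast(
    table: TaxonTable,
    replicate_ids: list[str],
    d1: int,
    d2: int,
    threshold: int,
    n_perm: int = 999,
    seed: int = 0,
):
    """Dispersion contrast between two rarefaction depths for one extract.

    Replicates deep enough for both depths are rarefied once per depth,
    pooled into one binary-Jaccard embedding with depth as the grouping
    factor, and tested for homogeneity of dispersion.  Returns the
    DispersionResult, or None if fewer than two replicates survive.
    """
    from .beta import DistanceMatrix  # local to avoid cycle in docs builds

    sub = table.select_replicates(replicate_ids)
    deep = [r for r, tot in zip(sub.replicate_ids, sub.depths) if tot >= max(d1, d2)]
    if len(deep) < 2:
        return None
    sub = sub.select_replicates(deep)
    cols = []
    labels = []
    groups = []
    for d in (d1, d2):
        rt = rarefy_table(sub, d, threshold, seed=seed + d)
        for rid in rt.replicate_ids:
            cols.append(rt.column(rid))
            labels.append(f"{rid}@{d}")
            groups.append(f"d{d}")
    pooled = TaxonTable(list(sub.taxon_ids), labels, np.column_stack(cols))
    D = jaccard_distance(pooled)
    return beta_dispersion(D, groups, n_perm=n_perm, seed=seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a manifest dict (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "replidepth",
        "version": __version__,
        "config": config.to_dict(),
        "outputs": {},
    }

    def _save(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        _write_tsv(df, path)
        manifest["outputs"][name] = path.name

    # -- stage: input -----------------------------------------------------
    if config.synthetic is not None:
        table, meta, truth = simulate_experiment(config.synthetic)
        write_taxon_table(table, out / "counts.tsv")
        write_metadata(meta, out / "metadata.tsv")
        truth.to_json(out / "ground_truth.json")
        manifest["outputs"]["counts"] = "counts.tsv"
        manifest["outputs"]["metadata"] = "metadata.tsv"
        spike = truth.spike_taxon
    else:
        table = read_taxon_table(config.counts_path)
        meta = read_metadata(config.metadata_path)
        spike = None
    meta.validate_against(table)

    # -- stage: decontamination ------------------------------------------
    stage = "decontam"
    try:
        if meta.negative_control_ids:
            calls = prevalence_scores(table, meta, config.decontam_threshold)
            _save(
                "contaminant_calls",
                pd.DataFrame([dataclasses.asdict(c) for c in calls]),
            )
            clean = remove_contaminants(table, calls, config.decontam_threshold, meta)
            manifest["n_contaminants_flagged"] = sum(c.is_contaminant for c in calls)
        else:
            logger.warning("no negative controls; skipping decontamination")
            clean = table.drop_replicates(meta.positive_control_ids)
            manifest["n_contaminants_flagged"] = None
        if spike is not None and meta.positive_control_ids:
            hop = index_hop_check(table, meta, spike)
            manifest["index_hop"] = dataclasses.asdict(hop)
        clean = clean.drop_taxa([t for t in ([spike] if spike else []) if t in clean.taxon_ids])
        sample_ids = [r for r in clean.replicate_ids if r in set(meta.sample_ids)]
        clean = clean.select_replicates(sample_ids)
    except Exception as err:  # pragma: no cover - error surface
        raise RuntimeError(f"stage {stage} failed: {err}") from err

    # -- stage: rarefaction grid -----------------------------------------
    stage = "filter"
    grid = rarefaction_grid(clean, config.depths, config.thresholds, config.repeats, config.seed)
    _save("rarefaction_grid", grid)
    rar = retained_counts(grid)
    _save("retained_replicates", rar)
    for _, row in rar.iterrows():
        logger.info("depth %d: %d replicates retained", row["depth"], row["retained"])
    manifest["retained_per_depth"] = {int(r["depth"]): int(r["retained"]) for _, r in rar.iterrows()}
    if rar["retained"].sum() == 0:
        manifest["all_dropped_out"] = True
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return manifest

    extracts = meta.extracts()
    extracts = {e: [r for r in rids if r in clean.replicate_ids] for e, rids in extracts.items()}

    # -- stage: alpha -----------------------------------------------------
    stage = "alpha"
    d1, d2 = config.contrast_depths
    t_focal = config.focal_threshold
    alpha_rows = []
    for ext, rids in extracts.items():
        for rid in rids:
            col = clean.column(rid)
            total = int(col.sum())
            for d in (d1, d2):
                if total < d:
                    continue
                vals = np.zeros(3)
                for rep in range(config.repeats):
                    rng = child_rng(config.seed, "alpha", rid, d, rep)
                    sub = apply_min_read_threshold(rarefy(col, d, rng), t_focal)
                    s, h, si = alpha_indices(sub)
                    vals += (s, h, si)
                vals /= config.repeats
                alpha_rows.append((rid, ext, d, t_focal, *vals))
    alpha_df = pd.DataFrame(
        alpha_rows,
        columns=["replicate_id", "extract_id", "depth", "threshold", "observed", "shannon", "simpson"],
    )
    _save("alpha", alpha_df)
    contrasts = depth_contrast_tests(alpha_df, d1, d2)
    _save("alpha_depth_contrasts", contrasts)

    # extrapolated richness per replicate at its raw depth, IQR outliers per extract
    ext_rows = []
    for ext, rids in extracts.items():
        values = []
        for rid in rids:
            col = clean.column(rid)
            n = int(col.sum())
            s2n, s_hat = extrapolated_richness(col, n)
            values.append(s2n)
            ext_rows.append((rid, ext, n, float(s2n), float(s_hat), False))
        if len(values) >= 4:
            flags = iqr_outliers(values)
            for k in range(len(values)):
                idx = len(ext_rows) - len(values) + k
                ext_rows[idx] = ext_rows[idx][:5] + (bool(flags[k]),)
    extrap_df = pd.DataFrame(
        ext_rows,
        columns=["replicate_id", "extract_id", "n", "richness_2n", "chao1_asymptote", "iqr_outlier"],
    )
    _save("extrapolation", extrap_df)

    # -- stage: accumulation / occupancy ---------------------------------
    stage = "accumulate"
    acc_rows = []
    occ_frames = []
    fit_rows = []
    for ext, rids in extracts.items():
        sub = clean.select_replicates(rids)
        cell = rarefy_table(sub, config.focal_depth, t_focal, seed=config.seed)
        if cell.n_replicates < 1:
            continue
        curve = accumulation_curve(cell, config.bootstraps, seed=config.seed)
        for k, m, s in zip(curve.k, curve.mean, curve.sd):
            acc_rows.append((ext, int(k), float(m), float(s), curve.saturation_label))
        hist, frac = occupancy_spectrum(cell)
        occ = occupancy_records(cell)
        occ.insert(0, "extract_id", ext)
        occ_frames.append(occ)
        if len(occ) >= 3 and occ["mean_reads"].nunique() > 1:
            fit = occupancy_abundance_fit(occ)
            fit_rows.append((ext, frac, *fit.values()))
    _save(
        "accumulation",
        pd.DataFrame(acc_rows, columns=["extract_id", "k", "mean_richness", "sd", "saturation"]),
    )
    if occ_frames:
        _save("occupancy", pd.concat(occ_frames, ignore_index=True))
    _save(
        "occupancy_abundance",
        pd.DataFrame(
            fit_rows,
            columns=["extract_id", "singleton_occupancy_fraction", "slope", "intercept", "t", "p", "adjusted_r2"],
        ),
    )

    # -- stage: beta ------------------------------------------------------
    stage = "beta"
    cell = rarefy_table(clean, config.focal_depth, t_focal, seed=config.seed)
    lcbd_df = pd.DataFrame()
    if cell.n_replicates >= 2:
        results, ss_total, bd_total = lcbd(
            cell, n_perm=config.permutations, alpha=config.alpha_level, seed=config.seed
        )
        lcbd_df = pd.DataFrame([dataclasses.asdict(r) for r in results])
        lcbd_df["extract_id"] = [meta.extract_of(r) for r in lcbd_df["replicate_id"]]
        _save("lcbd", lcbd_df)
        manifest["bd_total"] = bd_total
        groups = {r: meta.extract_of(r) for r in cell.replicate_ids}
        if len(set(groups.values())) >= 2:
            disp = beta_dispersion(
                jaccard_distance(cell), groups, n_perm=config.permutations, seed=config.seed
            )
            _save(
                "dispersion",
                pd.DataFrame(
                    {
                        "replicate_id": disp.labels,
                        "extract_id": disp.groups,
                        "distance_to_median": disp.distances,
                    }
                ),
            )
            _save("dispersion_tukey", disp.tukey)
            manifest["dispersion"] = {
                "F": disp.f_statistic,
                "p_parametric": disp.p_parametric,
                "p_permutation": disp.p_permutation,
            }

    # depth-contrast dispersion per extract
    contrast_rows = []
    for ext, rids in extracts.items():
        res = depth_dispersion_contrast(
            clean, rids, d1, d2, t_focal, n_perm=config.permutations, seed=config.seed
        )
        if res is not None:
            contrast_rows.append((ext, res.f_statistic, res.p_parametric, res.p_permutation))
    _save(
        "dispersion_depth_contrast",
        pd.DataFrame(contrast_rows, columns=["extract_id", "F", "p_parametric", "p_permutation"]),
    )

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
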