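"""End-to-end orchestration: one config, ordered stages, manifest, seeds.

``run_all`` executes qc → phenotyping → malignancy → spatial → differential
on a dataset directory, writing each stage's tables as TSV under the output
directory as soon as the stage completes (so a failed run can resume from its
last checkpoint).  A manifest (config hash, package version, fanned-out
per-stage seeds) accompanies every run; a run is reproducible from its
manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, differential, io, malignancy, phenotyping, qc, spatial
from .errors import ConfigError

STAGE_ORDER = ("qc", "phenotyping", "malignancy", "spatial", "differential")


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan a global seed out to a per-stage seed via SHA-256 (< 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (1 << 31)


@dataclass
class RunConfig:
    """All knobs for one pipeline run; serializable to/from YAML."""

    data_dir: str
    out_dir: str
    seed: int = 0
    pixel_size: float = io.DEFAULT_PIXEL_SIZE
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGE_ORDER})
    # qc
    min_counts: int = 20
    area_factor: float = 5.0
    min_fov_cells: int = 5
    theta: float = 100.0
    # phenotyping
    reference_profiles: str | None = None  # TSV phenotype × gene; None → truth labels
    phenotype_map: str | None = None
    # malignancy
    seed_gene: str = "VEGFA"
    seed_cell_type: str = "proximal tubule"
    lasso_folds: int = 10
    # spatial
    radius_um: float = spatial.DEFAULT_RADIUS_UM
    knn_k: int = 3
    n_perm: int = 1000
    min_high: int = 5
    gene_sets: str | None = None
    lr_pairs: str | None = None
    # differential
    contrast: tuple[str, str] = ("io_naive_nonsarc", "io_exposed")
    fdr_alpha: float = 0.1
    enrich_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        errors = [f"unknown config key: {k}" for k in sorted(unknown)]
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        errors += cfg.validate()
        if errors:
            raise ConfigError("invalid run config:\n  " + "\n  ".join(errors))
        return cfg

    def validate(self) -> list[str]:
        errors = []
        if not Path(self.data_dir).exists():
            errors.append(f"data_dir does not exist: {self.data_dir}")
        if self.min_counts < 0 or self.min_fov_cells < 0:
            errors.append("QC thresholds must be nonnegative")
        if self.area_factor <= 0:
            errors.append("area_factor must be > 0")
        if self.radius_um < 0 or self.knn_k < 1 or self.n_perm < 1:
            errors.append("spatial parameters out of range")
        if len(self.contrast) != 2:
            errors.append("contrast must name exactly two cohorts")
        for key in self.stages:
            if key not in STAGE_ORDER:
                errors.append(f"unknown stage: {key}")
        return errors

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrast"] = list(self.contrast)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def _require(condition: bool, stage: str, needed_by: str) -> None:
    if not condition:
        raise ConfigError(
            f"stage {needed_by!r} requires output of stage {stage!r}, which is disabled or missing"
        )


def run_all(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the output directory."""
    errors = config.validate()
    if errors:
        raise ConfigError("invalid run config:\n  " + "\n  ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = {s: config.stages.get(s, True) for s in STAGE_ORDER}

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": {s: stage_seed(config.seed, s) for s in STAGE_ORDER},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    adata = io.load_dataset(config.data_dir, pixel_size=config.pixel_size)

    if stages["qc"]:
        adata, cell_rep, fov_rep = qc.run_qc(
            adata,
            min_counts=config.min_counts,
            area_factor=config.area_factor,
            min_fov_cells=config.min_fov_cells,
            theta=config.theta,
        )
        pd.DataFrame(
            [
                {"filter": "cells", "n_in": cell_rep.n_cells_in, "n_out": cell_rep.n_cells_out,
                 "removed_low_count": cell_rep.removed_low_count,
                 "removed_large_area": cell_rep.removed_large_area},
                {"filter": "fovs", "n_in": fov_rep.n_cells_in, "n_out": fov_rep.n_cells_out,
                 "fovs_dropped": ";".join(fov_rep.fovs_dropped)},
            ]
        ).to_csv(out / "qc_report.tsv", sep="\t", index=False)

    if stages["phenotyping"]:
        _require(stages["qc"], "qc", "phenotyping")
        reference = _load_reference(config, adata)
        labels, posterior = phenotyping.assign_phenotypes(adata.X, list(adata.var_names), reference)
        adata.obs["phenotype"] = labels
        if config.phenotype_map:
            mapping = io.read_phenotype_map(config.phenotype_map)
            adata.obs = io.collapse_phenotypes(
                adata.obs.reset_index(names="cell_id"), mapping
            ).set_index("cell_id")
        adata.obs[["fov_id", "phenotype"]].reset_index(names="cell_id").to_csv(
            out / "phenotypes.tsv", sep="\t", index=False
        )

    model = None
    if stages["malignancy"]:
        _require(stages["phenotyping"], "phenotyping", "malignancy")
        seeds = malignancy.seed_labels(
            adata, gene=config.seed_gene, cell_type=config.seed_cell_type
        )
        markers = malignancy.select_candidate_markers(adata, seeds)
        sub = adata[seeds.index]
        cols = [list(adata.var_names).index(g) for g in markers]
        model = malignancy.fit_lasso(
            np.asarray(sub.layers[qc.NORMALIZED_LAYER])[:, cols],
            seeds.to_numpy(dtype=object),
            markers,
            folds=config.lasso_folds,
            seed=stage_seed(config.seed, "malignancy"),
        )
        calls = malignancy.predict_malignant(model, adata)
        calls.reset_index(names="cell_id").to_csv(out / "malignancy_calls.tsv", sep="\t", index=False)
        adata.obs["malignant_call"] = (calls["call"] == malignancy.MALIGNANT).to_numpy()

    doce_df = moran_df = enrich_df = None
    gene_sets = io.read_gene_sets(config.gene_sets) if config.gene_sets else None
    pairs = io.read_lr_pairs(config.lr_pairs) if config.lr_pairs else None
    if stages["spatial"]:
        _require(stages["phenotyping"], "phenotyping", "spatial")
        doce_df = spatial.doce_table(adata, r=config.radius_um)
        io.write_result_table(doce_df, out / "doce.tsv")
        if gene_sets:
            enrich_df = spatial.enrichment_scan(
                adata, gene_sets, n_perm=config.n_perm, min_high=config.min_high,
                seed=stage_seed(config.seed, "spatial"),
            )
            io.write_result_table(enrich_df, out / "enrichment.tsv")
        if pairs is not None:
            moran_df = spatial.moran_pair_scan(adata, pairs, k=config.knn_k)
            io.write_result_table(moran_df, out / "moran.tsv")

    if stages["differential"]:
        _require(stages["phenotyping"], "phenotyping", "differential")
        contrast = tuple(config.contrast)
        cells = adata.obs.reset_index(names="cell_id")
        present = set(cells["cohort"].unique())
        if not set(contrast) <= present:
            raise ConfigError(f"contrast cohorts {contrast} not present in data ({sorted(present)})")
        abund = differential.abundance_scan(cells, contrast, alpha=config.fdr_alpha)
        io.write_result_table(abund, out / "abundance.tsv")
        de = differential.pseudobulk_de(
            np.asarray(adata.layers[qc.NORMALIZED_LAYER]), list(adata.var_names),
            cells, contrast, alpha=config.fdr_alpha,
        )
        io.write_result_table(de, out / "pseudobulk_de.tsv")
        fov_groups = cells.groupby("fov_id", observed=True)["cohort"].first()
        fov_meta = cells[["fov_id", "sample_id", "cohort"]].drop_duplicates()
        if doce_df is not None:
            io.write_result_table(
                differential.compare_doce(doce_df, fov_groups, contrast, alpha=config.fdr_alpha),
                out / "doce_comparison.tsv",
            )
        if moran_df is not None:
            io.write_result_table(
                differential.compare_moran(moran_df, fov_groups, contrast, alpha=config.fdr_alpha),
                out / "moran_comparison.tsv",
            )
        if enrich_df is not None:
            io.write_result_table(
                differential.compare_enrichment(enrich_df, fov_meta, contrast, alpha=config.enrich_alpha),
                out / "enrichment_counts.tsv",
            )
        if (doce_df is None or moran_df is None) and not stages["spatial"]:
            _require(False, "spatial", "differential")
    return out


def _load_reference(config: RunConfig, adata) -> phenotyping.ReferenceProfiles:
    if config.reference_profiles:
        prof = pd.read_csv(config.reference_profiles, sep="\t", index_col=0)
        return phenotyping.ReferenceProfiles(
            profiles=prof, target_library_size=float(prof.sum(axis=1).max())
        )
    truth_path = Path(config.data_dir) / "truth_cells.csv"
    if not truth_path.exists():
        raise ConfigError(
            "phenotyping needs reference_profiles (TSV phenotype × gene) or a "
            "truth_cells.csv next to the data"
        )
    truth = pd.read_csv(truth_path).set_index("cell_id")
    labels = truth.loc[[c for c in adata.obs_names if c in truth.index], "true_phenotype"]
    expr = pd.DataFrame(
        np.asarray(adata[labels.index].X.todense()), index=labels.index, columns=adata.var_names
    )
    return phenotyping.build_reference(expr, labels)
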