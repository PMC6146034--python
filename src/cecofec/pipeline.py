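"""End-to-end pipeline: simulate/load -> filter -> normalize -> analyse.

``run_pipeline`` drives every stage from one :class:`PipelineConfig` and
writes a report bundle of TSV tables shaped like the outputs a paired
cecum/feces study reports: a filter summary, per-sample alpha indices with
the paired-ANOVA summary, per-level differential-abundance tables,
ordination coordinates, and the sPLS-DA selection tables, plus a
machine-readable JSON-lines run log.  All randomness flows from the seeds
in the config, so a config produces a byte-identical bundle on every run.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cecofec import __version__
from cecofec.alpha import alpha_diversity, alpha_paired_anova
from cecofec.core_tables import (
    OtuTable,
    TableError,
    build_paired_design,
    drop_unpaired_samples,
    filter_by_prevalence,
    filter_rare_otus,
    filter_samples_by_depth,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    read_tree,
    write_metadata,
    write_otu_table,
    write_taxonomy,
)
from cecofec.css import css_normalize
from cecofec.diff_abundance import BootstrapConfig, run_diff_abundance
from cecofec.ordination import paired_pca, pcoa, weighted_unifrac, within_animal_deviations
from cecofec.splsda import explained_variance, feature_contributions, fit_splsda
from cecofec.synthetic import SyntheticParams, generate_dataset
from cecofec.taxonomy import aggregate_to_rank

FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """Flat, YAML-serializable configuration of the whole pipeline."""

    # input files (ignored when simulate is true)
    otu_table: str | None = None
    metadata: str | None = None
    taxonomy: str | None = None
    tree: str | None = None
    # synthetic-data generation
    simulate: bool = True
    n_animals: int = 21
    n_otus: int = 596
    frac_differential: float = 0.30
    origin_effect_size: float = 0.5
    animal_sd: float = 0.25
    regime_effect_size: float = 0.15
    depth_min: int = 16415
    depth_max: int = 68080
    dispersion: float = 10.0
    seed: int = 0
    # filtering
    min_depth: int = 5000
    min_otu_fraction: float = 1e-4
    min_prevalence: float = 0.05
    # normalization
    css_quantile: float | None = None  # None = adaptive
    css_scale: float = 1000.0
    # alpha diversity
    rarefaction_depth: int = 15000
    rarefaction_seed: int = 0
    # differential abundance
    bootstrap_B: int = 1000
    fdr_alpha: float = 0.05
    p_rule: str = "proportion"
    bootstrap_seed: int = 0
    # ordination / sPLS-DA
    unifrac_normalized: bool = False
    keepx: tuple[int, ...] = (70, 50)
    splsda_scale: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 0 or not 0 <= self.min_otu_fraction <= 1 or not 0 <= self.min_prevalence <= 1:
            raise TableError("filter thresholds out of range")
        if self.rarefaction_depth < 1 or self.bootstrap_B < 1:
            raise TableError("rarefaction depth and bootstrap B must be >= 1")
        if not 0 < self.fdr_alpha < 1:
            raise TableError("fdr_alpha must be in (0, 1)")
        self.keepx = tuple(int(k) for k in self.keepx)
        if not self.simulate and not all((self.otu_table, self.metadata, self.taxonomy, self.tree)):
            raise TableError("either set simulate: true or provide all four input paths")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise TableError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["keepx"] = list(self.keepx)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    def synthetic_params(self) -> SyntheticParams:
        return SyntheticParams(
            n_animals=self.n_animals,
            n_otus=self.n_otus,
            frac_differential=self.frac_differential,
            origin_effect_size=self.origin_effect_size,
            animal_sd=self.animal_sd,
            regime_effect_size=self.regime_effect_size,
            depth_range=(self.depth_min, self.depth_max),
            dispersion=self.dispersion,
            seed=self.seed,
        )


class RunLog:
    """JSON-lines machine log (deterministic) + timed stderr messages."""

    def __init__(self, path: Path | None, echo: bool = True):
        self.path = path
        self.echo = echo
        self.records: list[dict] = []
        self._t0 = time.monotonic()

    def event(self, stage: str, **fields) -> None:
        record = {"stage": stage, **fields}
        self.records.append(record)
        if self.echo:
            elapsed = time.monotonic() - self._t0
            print(f"[{elapsed:8.2f}s] {stage}: {fields}", file=sys.stderr)

    def write(self) -> None:
        if self.path is None:
            return
        with open(self.path, "w") as fh:
            for record in self.records:
                fh.write(json.dumps(record, sort_keys=True, default=str) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def load_inputs(cfg: PipelineConfig):
    """Return (table, metadata, taxonomy, tree, truth_or_None)."""
    if cfg.simulate:
        table, meta, taxonomy, tree, truth = generate_dataset(cfg.synthetic_params())
        return table, meta, taxonomy, tree, truth
    table = read_otu_table(cfg.otu_table)
    meta = read_metadata(cfg.metadata)
    taxonomy = read_taxonomy(cfg.taxonomy)
    tree = read_tree(cfg.tree)
    return table, meta, taxonomy, tree, None


def run_pipeline(cfg: PipelineConfig, outdir) -> Path:
    """Run every stage and write the report bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog(outdir / "run_log.jsonl")
    log.event("config", version=__version__, **{k: v for k, v in asdict(cfg).items()})

    table, meta, taxonomy, tree, truth = load_inputs(cfg)
    log.event("inputs", n_samples=table.n_samples, n_otus=table.n_otus,
              simulated=cfg.simulate)
    if truth is not None:
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                {
                    "differential_otu_ids": sorted(truth.differential_otu_ids),
                    "log_fold_effects": {k: truth.log_fold_effects[k]
                                         for k in sorted(truth.log_fold_effects)},
                    "regime_affected_otu_ids": sorted(truth.regime_affected_otu_ids),
                },
                fh, indent=1, sort_keys=True,
            )

    # --- filtering ------------------------------------------------------
    depths = dict(zip(table.sample_ids, table.sample_depths().tolist()))
    t_depth = filter_samples_by_depth(table, cfg.min_depth)
    removed_samples = [s for s in table.sample_ids if s not in t_depth.sample_ids]
    for s in removed_samples:
        log.event("filter", record=s, reason="depth", depth=depths[s],
                  min_depth=cfg.min_depth)
    t_rare = filter_rare_otus(t_depth, cfg.min_otu_fraction)
    log.event("filter_summary", samples_removed_depth=len(removed_samples),
              otus_removed_rare=t_depth.n_otus - t_rare.n_otus,
              n_samples=t_rare.n_samples, n_otus=t_rare.n_otus)

    design = build_paired_design({s: meta[s] for s in t_rare.sample_ids}, t_rare)
    for animal, reason in design.excluded:
        log.event("filter", record=animal, reason=f"unpaired: {reason}")
    filtered = drop_unpaired_samples(t_rare, design)
    log.event("paired_design", n_animals=design.n_animals,
              n_samples=filtered.n_samples)
    if design.n_animals < 3:
        raise TableError("fewer than 3 complete pairs survive filtering")

    summary_rows = (
        [{"record": s, "kind": "sample", "reason": "depth", "detail": depths[s]}
         for s in removed_samples]
        + [{"record": a, "kind": "animal", "reason": r} for a, r in design.excluded]
    )
    pd.DataFrame(summary_rows, columns=["record", "kind", "reason", "detail"]).to_csv(
        outdir / "filter_summary.tsv", sep="\t", index=False
    )
    write_otu_table(filtered, outdir / "filtered_otu_table.tsv")

    # --- CSS normalization ---------------------------------------------
    normalized = css_normalize(filtered, quantile=cfg.css_quantile, scale=cfg.css_scale)
    log.event("css", quantile=normalized.factors.quantile, scale=cfg.css_scale)
    _write_tsv(normalized.to_dataframe(), outdir / "css_abundances.tsv")
    pd.DataFrame(
        {"sample_id": list(normalized.sample_ids), "css_factor": normalized.factors.factors}
    ).to_csv(outdir / "css_factors.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)

    # --- alpha diversity ------------------------------------------------
    indices = alpha_diversity(filtered, cfg.rarefaction_depth, cfg.rarefaction_seed)
    _write_tsv(indices, outdir / "alpha_indices.tsv")
    alpha_rows = []
    for index_name in ("observed_otus", "shannon"):
        result = alpha_paired_anova(indices[index_name], design)
        for regime, row in result.group_stats.iterrows():
            alpha_rows.append({"index": index_name, "regime": regime, **row.to_dict()})
        for term, (F, df1, df2, p) in result.terms.items():
            log.event("alpha_anova", index=index_name, term=term, F=F,
                      df=f"{df1},{df2}", p=p)
    pd.DataFrame(alpha_rows).to_csv(outdir / "alpha_summary.tsv", sep="\t",
                                    index=False, float_format=FLOAT_FORMAT)

    # --- differential abundance ----------------------------------------
    boot = BootstrapConfig(B=cfg.bootstrap_B, alpha_fdr=cfg.fdr_alpha,
                           seed=cfg.bootstrap_seed, p_rule=cfg.p_rule)
    prevalent = filter_by_prevalence(filtered, cfg.min_prevalence)
    css_df = normalized.to_dataframe()[list(prevalent.otu_ids)]
    otu_result = run_diff_abundance(css_df, design, boot, level="otu")
    log.event("diffabund", level="otu", n_features=len(css_df.columns),
              n_significant=int(otu_result.table["significant"].sum()))
    for rank in ("phylum", "genus"):
        rank_table = aggregate_to_rank(filtered, taxonomy, rank)
        rank_result = run_diff_abundance(rank_table, design, boot, level=rank)
        log.event("diffabund", level=rank, n_features=len(rank_table.taxa),
                  n_significant=int(rank_result.table["significant"].sum()))
        _write_tsv(rank_result.table, outdir / f"diffabund_{rank}.tsv")

    # --- ordination ------------------------------------------------------
    dm = weighted_unifrac(normalized, tree, normalize_branch=cfg.unifrac_normalized)
    pcoa_result = pcoa(dm)
    _write_tsv(pcoa_result.coordinates, outdir / "pcoa_coordinates.tsv")
    pd.DataFrame({"eigenvalue": pcoa_result.eigenvalues}).to_csv(
        outdir / "pcoa_eigenvalues.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    neg_mass = float(np.abs(pcoa_result.eigenvalues[pcoa_result.eigenvalues < 0]).sum())
    log.event("pcoa", negative_eigenvalue_mass=neg_mass,
              top_proportions=[round(float(x), 4) for x in pcoa_result.proportion_explained[:2]])

    W = within_animal_deviations(normalized, design)
    pca_result = paired_pca(W, n_components=2)
    _write_tsv(pca_result.coordinates, outdir / "paired_pca_coordinates.tsv")
    pd.DataFrame({"eigenvalue": pca_result.eigenvalues}).to_csv(
        outdir / "paired_pca_eigenvalues.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    log.event("paired_pca",
              proportions=[round(float(x), 4) for x in pca_result.proportion_explained])

    # --- sPLS-DA ---------------------------------------------------------
    origin_of = {s: meta[s].origin for s in W.sample_ids}
    labels = [origin_of[s] for s in W.sample_ids]
    # constant (zero-variance) columns carry no discriminative signal and
    # cannot be unit-scaled; drop them before the fit
    W_df = W.to_dataframe()
    variable = W_df.columns[W_df.std(axis=0, ddof=1) > 0]
    if len(variable) < len(W_df.columns):
        log.event("splsda_filter", constant_features_dropped=len(W_df.columns) - len(variable))
        W_df = W_df[variable]
    keepx = tuple(min(k, W_df.shape[1]) for k in cfg.keepx)
    model = fit_splsda(W_df, labels, keepx, scale=cfg.splsda_scale)
    contributions = feature_contributions(model, W_df, labels)
    _write_tsv(model.x_loadings, outdir / "splsda_loadings.tsv")
    _write_tsv(model.x_variates, outdir / "splsda_variates.tsv")
    contributions.to_csv(outdir / "splsda_selected.tsv", sep="\t", index=False,
                         float_format=FLOAT_FORMAT)
    pd.DataFrame({"component": np.arange(1, model.n_components + 1),
                  "explained_x_variance": model.explained_x_variance}).to_csv(
        outdir / "splsda_explained_variance.tsv", sep="\t", index=False,
        float_format=FLOAT_FORMAT)
    log.event("splsda", keepx=list(keepx),
              explained=[round(float(x), 4) for x in model.explained_x_variance])

    # OTU-level table with the sPLS-DA membership flag
    comp1 = set(model.selected_features(1))
    otu_table_out = otu_result.table.copy()
    otu_table_out["splsda_component1"] = [
        "YES" if f in comp1 else "NO" for f in otu_table_out.index
    ]
    _write_tsv(otu_table_out, outdir / "diffabund_otu.tsv")
    overlap = sum(1 for f in comp1 if otu_result.table.loc[f, "significant"]) if comp1 else 0
    log.event("overlap", splsda_component1=len(comp1),
              also_bootstrap_significant=overlap)

    log.write()
    return outdir


def write_simulated_inputs(params: SyntheticParams, outdir) -> Path:
    """Generate a synthetic dataset and write the four standard input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, meta, taxonomy, tree, truth = generate_dataset(params)
    write_otu_table(table, outdir / "otu_table.tsv")
    write_metadata(meta, outdir / "metadata.tsv")
    write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
    tree.write(str(outdir / "tree.nwk"))
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "differential_otu_ids": sorted(truth.differential_otu_ids),
                "log_fold_effects": {k: truth.log_fold_effects[k]
                                     for k in sorted(truth.log_fold_effects)},
                "regime_affected_otu_ids": sorted(truth.regime_affected_otu_ids),
            },
            fh, indent=1, sort_keys=True,
        )
    return outdir
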