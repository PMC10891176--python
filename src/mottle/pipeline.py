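"""End-to-end orchestration: images -> metrics -> traits -> phylogenetic tests.

The pipeline runs five stages, each writing its table before the next
starts so a run can resume from intermediates:

1. ``generate``  (synthetic mode) write images/masks/tree/factors;
2. ``metrics``   per-specimen colour + pattern metrics (+ wing area);
3. ``aggregate`` species x wing x metric table of means and cv;
4. ``test``      simulation-based phylogenetic ANOVA per hypothesis x
                 wing x metric x statistic-type, with post hoc tests;
5. ``summarize`` heatmap-style effect-size matrix and CSV twin.

Multiple testing: Holm correction is applied within each hypothesis x
statistic-type family (the set of metric x wing cells tested together);
raw simulation p-values are reported alongside, since family boundaries
are a judgement call.  Wing area (ROI pixel count / px_per_mm^2) rides
along as a seventh metric to support size-effect checks.

Everything is deterministic given the config seed: per-test seeds are
expanded from it with a fixed counter scheme.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import io as mio
from .aggregate import aggregate, trait_vector
from .colour import summarize_colour
from .granularity import pattern_metrics
from .phylo import Phylogeny, holm_adjust, phyl_anova
from .synth import default_strategy_specs, generate_dataset

logger = logging.getLogger(__name__)


class SyntheticBlock(BaseModel):
    """Synthetic study conditions: a two-strategy species assembly."""

    n_per_group: int = 20
    n_specimens: int = 30
    cv_marking_aposematic: float = 0.10
    cv_marking_camouflaged: float = 0.35
    wings: list[str] = Field(default_factory=lambda: ["forewing", "hindwing"])
    write_images: bool = True


class ManifestBlock(BaseModel):
    """Paths to a real (or pre-written) dataset, relative to the config."""

    specimen_csv: str
    tree_newick: str
    factors_csv: str
    min_side_px: int = 100


class PipelineConfig(BaseModel):
    out_dir: str
    seed: int = 0
    nsim: int = 1000
    target_px_per_mm: float = 10.0
    n_levels: int = 20
    hue_mode: Literal["linear", "circular"] = "linear"
    min_n: int = 14
    alpha: float = 0.05
    synthetic: Optional[SyntheticBlock] = None
    manifest: Optional[ManifestBlock] = None
    make_figure: bool = True

    @model_validator(mode="after")
    def _exactly_one_input(self):
        if (self.synthetic is None) == (self.manifest is None):
            raise ValueError("config needs exactly one of 'synthetic' or 'manifest'")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        payload = yaml.safe_load(path.read_text())
        cfg = cls.model_validate(payload)
        # paths are relative to the config file
        base = path.parent
        cfg.out_dir = str((base / cfg.out_dir).resolve())
        if cfg.manifest is not None:
            m = cfg.manifest
            m.specimen_csv = str((base / m.specimen_csv).resolve())
            m.tree_newick = str((base / m.tree_newick).resolve())
            m.factors_csv = str((base / m.factors_csv).resolve())
        return cfg


def _test_seed(master: int, counter: int) -> int:
    return int(np.random.SeedSequence([master % 2**31, counter]).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# Stages

def stage_generate(config: PipelineConfig):
    """Build (and optionally write) the synthetic dataset."""
    syn = config.synthetic
    specs = default_strategy_specs(
        n_per_group=syn.n_per_group,
        n_specimens=syn.n_specimens,
        seed=config.seed,
        cv_marking_aposematic=syn.cv_marking_aposematic,
        cv_marking_camouflaged=syn.cv_marking_camouflaged,
    )
    dataset = generate_dataset(specs, seed=config.seed, wings=tuple(syn.wings))
    if syn.write_images:
        data_dir = Path(config.out_dir) / "data"
        manifest = data_dir / "specimens.csv"
        if manifest.exists():
            logger.info("generate: reusing existing %s", manifest)
            return dataset, manifest
        mio.write_dataset(dataset, data_dir)
        logger.info("generate: wrote %d images under %s", len(dataset.images), data_dir)
        return dataset, manifest
    return dataset, None


def compute_specimen_metrics(img, roi, record, n_levels=20, hue_mode="linear") -> dict:
    """All per-specimen metrics for one calibrated image + ROI."""
    colour = summarize_colour(img, roi, hue_mode=hue_mode)
    pattern = pattern_metrics(img, roi, n_levels=n_levels)
    return {
        "specimen_id": record["specimen_id"],
        "species": record["species"],
        "wing": record["wing"],
        "hue": colour.hue_mean,
        "saturation": colour.sat_mean,
        "brightness": colour.bright_mean,
        "dominance": pattern.dominance,
        "marking_size": pattern.marking_size,
        "contrast": pattern.contrast,
        "wing_area": roi.area_mm2(img.px_per_mm),
        "hue_seam": colour.seam_straddle,
        "pattern_degenerate": pattern.degenerate,
    }


def stage_metrics(config: PipelineConfig, dataset=None, manifest=None) -> pd.DataFrame:
    out_csv = Path(config.out_dir) / "metrics.csv"
    if out_csv.exists():
        logger.info("metrics: reusing %s", out_csv)
        return pd.read_csv(out_csv)
    if manifest is not None:
        images = mio.iter_manifest(
            manifest,
            target_px_per_mm=config.target_px_per_mm,
            min_side_px=(config.manifest.min_side_px if config.manifest else 100),
        )
    elif dataset is not None:
        images = iter(dataset.images)
    else:
        raise ValueError("metrics stage needs a dataset or a manifest")
    with warnings.catch_warnings():
        # hue seam straddles are recorded per row; don't spam per image
        warnings.simplefilter("ignore")
        rows = [
            compute_specimen_metrics(
                img, roi, rec, n_levels=config.n_levels, hue_mode=config.hue_mode
            )
            for img, roi, rec in images
        ]
    df = pd.DataFrame(rows)
    if df["hue_seam"].any():
        logger.warning(
            "hue values straddle the 0/360 seam in %d specimen rows; linear hue "
            "statistics (and hue cv) are sensitive to the wrap-around",
            int(df["hue_seam"].sum()),
        )
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_csv, index=False)
    return df


def stage_aggregate(config: PipelineConfig, metrics_df: pd.DataFrame) -> pd.DataFrame:
    out_csv = Path(config.out_dir) / "traits.csv"
    if out_csv.exists():
        logger.info("aggregate: reusing %s", out_csv)
        return pd.read_csv(out_csv)
    table = aggregate(metrics_df, min_n=config.min_n)
    table.to_csv(out_csv, index=False)
    return table


def stage_test(
    config: PipelineConfig,
    traits: pd.DataFrame,
    tree: Phylogeny,
    factors: dict,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the phylANOVA battery; returns (results, posthoc) tables."""
    results_csv = Path(config.out_dir) / "results.csv"
    posthoc_csv = Path(config.out_dir) / "posthoc.csv"
    if results_csv.exists() and posthoc_csv.exists():
        logger.info("test: reusing %s", results_csv)
        return pd.read_csv(results_csv), pd.read_csv(posthoc_csv)

    wings = sorted(traits["wing"].unique())
    metrics = sorted(traits["metric"].unique())
    rows = []
    posthoc_rows = []
    counter = 0
    for hypothesis in sorted(factors):
        factor = factors[hypothesis]
        for stat in ("x", "cv"):
            for wing in wings:
                for metric in metrics:
                    counter += 1
                    trait = trait_vector(traits, wing, metric, stat)
                    if len(trait) < 3:
                        logger.warning(
                            "skipping %s/%s/%s/%s: only %d species with data",
                            hypothesis, wing, metric, stat, len(trait),
                        )
                        continue
                    seed = _test_seed(config.seed, counter)
                    res = phyl_anova(
                        tree, factor, trait, nsim=config.nsim, seed=seed
                    )
                    rows.append(
                        {
                            "hypothesis": hypothesis,
                            "wing": wing,
                            "metric": metric,
                            "stat": stat,
                            "F": res.F_obs,
                            "p_phylo": res.p_phylo,
                            "eta2": res.eta2,
                            "SSB": res.SSB,
                            "SSW": res.SSW,
                            "nsim": res.nsim,
                            "seed": seed,
                            "n_species": res.n_species,
                            "n_dropped": res.n_dropped,
                            "degenerate": res.degenerate,
                        }
                    )
                    if res.posthoc is not None:
                        ph = res.posthoc.copy()
                        ph.insert(0, "hypothesis", hypothesis)
                        ph.insert(1, "wing", wing)
                        ph.insert(2, "metric", metric)
                        ph.insert(3, "stat", stat)
                        posthoc_rows.append(ph)

    results = pd.DataFrame(rows)
    # Holm within each hypothesis x statistic-type family
    results["p_holm_family"] = np.nan
    for (_, _), idx in results.groupby(["hypothesis", "stat"]).groups.items():
        results.loc[idx, "p_holm_family"] = holm_adjust(
            results.loc[idx, "p_phylo"].to_numpy()
        )
    results["significant"] = results["p_holm_family"] < config.alpha
    posthoc = (
        pd.concat(posthoc_rows, ignore_index=True)
        if posthoc_rows
        else pd.DataFrame(
            columns=["hypothesis", "wing", "metric", "stat",
                     "level_a", "level_b", "t", "p", "p_holm"]
        )
    )
    results.to_csv(results_csv, index=False)
    posthoc.to_csv(posthoc_csv, index=False)
    return results, posthoc


def render_summary(
    results: pd.DataFrame,
    out_dir: str | Path,
    alpha: float = 0.05,
    make_figure: bool = True,
) -> pd.DataFrame:
    """Effect-size matrix (rows metric x stat, columns hypothesis x wing).

    Writes ``summary.csv`` always and ``summary.png`` (an eta^2 heatmap
    with significance markers) unless figures are disabled.  Hypothesis
    columns with no tested cells are omitted with a log line.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if results.empty:
        raise ValueError("no test results to summarise")
    summary = results[
        ["hypothesis", "wing", "metric", "stat", "eta2", "p_phylo",
         "p_holm_family", "significant"]
    ].copy()
    summary.to_csv(out_dir / "summary.csv", index=False)

    if make_figure:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        pivot = summary.pivot_table(
            index=["metric", "stat"], columns=["hypothesis", "wing"],
            values="eta2", aggfunc="first",
        )
        dropped = [c for c in pivot.columns if pivot[c].isna().all()]
        if dropped:
            logger.info("summary: omitting empty columns %s", dropped)
            pivot = pivot.drop(columns=dropped)
        sig = summary.pivot_table(
            index=["metric", "stat"], columns=["hypothesis", "wing"],
            values="significant", aggfunc="first",
        ).reindex_like(pivot)
        values = pivot.to_numpy(float)
        vmax = np.nanmax(values) if np.isfinite(values).any() else 1.0
        vmax = vmax if vmax > 0 else 1.0
        fig, ax = plt.subplots(
            figsize=(1.2 * max(1, len(pivot.columns)) + 3, 0.4 * len(pivot) + 2)
        )
        im = ax.imshow(values, cmap="viridis", vmin=0.0, vmax=vmax, aspect="auto")
        ax.set_xticks(range(len(pivot.columns)))
        ax.set_xticklabels(
            [f"{h}\n{w}" for h, w in pivot.columns], fontsize=8
        )
        ax.set_yticks(range(len(pivot)))
        ax.set_yticklabels([f"{m}.{s}" for m, s in pivot.index], fontsize=8)
        for i in range(len(pivot)):
            for j in range(len(pivot.columns)):
                if bool(sig.to_numpy()[i, j]):
                    ax.text(j, i, "*", ha="center", va="center",
                            color="white", fontsize=12)
        fig.colorbar(im, ax=ax, label="eta squared")
        ax.set_title(f"Effect sizes (phylogenetic ANOVA); * = Holm p < {alpha}")
        fig.tight_layout()
        fig.savefig(out_dir / "summary.png", dpi=150)
        plt.close(fig)
    return summary


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run all stages; returns the summary matrix (tidy form)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run.log").write_text(
        "mottle pipeline run\n" + yaml.safe_dump(config.model_dump()) + "\n"
    )
    if config.synthetic is not None:
        dataset, manifest = stage_generate(config)
        tree, factors = dataset.tree, dataset.factors
        if manifest is not None:
            metrics_df = stage_metrics(config, manifest=manifest)
        else:
            metrics_df = stage_metrics(config, dataset=dataset)
    else:
        m = config.manifest
        tree = mio.read_tree(m.tree_newick)
        factors = mio.read_factors(m.factors_csv)
        metrics_df = stage_metrics(config, manifest=m.specimen_csv)
    traits = stage_aggregate(config, metrics_df)
    results, _ = stage_test(config, traits, tree, factors)
    return render_summary(results, out, alpha=config.alpha, make_figure=config.make_figure)
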