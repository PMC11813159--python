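"""End-to-end orchestration: simulate -> indices -> correlogram -> stage
statistics -> model training, with reproducible seeds and file outputs.

Every artifact file carries a header comment with the seed and a hash of the
run configuration, so reruns are verifiable and a stage rerun in isolation
reproduces its ``run_all`` output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bandsearch, indices, models, stats
from .spectra import SpectraSet, TraitTable, read_spectra, read_traits
from .synthetic import GeneratorConfig, generate_dataset

__all__ = ["RunConfig", "RunBundle", "run_all", "index_regression_summary"]

logger = logging.getLogger("fruitspec")

_DEFAULT_TRAITS = {"mango": ["SPAD", "TSS", "firmness"],
                   "strawberry": ["L", "b", "TSS", "firmness"]}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    If ``spectra_path``/``traits_path`` are unset, a synthetic dataset for
    ``fruit_type`` is generated under ``seed``.
    """

    fruit_type: str = "mango"
    seed: int = 0
    out_dir: str | Path = "fruitspec_out"
    traits: list[str] | None = None
    spectra_path: str | None = None
    traits_path: str | None = None
    index_family: str = "ratio"
    top_k: int = 12
    min_separation: float = 10.0
    threshold: float = 0.5
    families: tuple[str, ...] = ("rf", "dt")
    model_grids: dict | None = None
    folds: int = 5
    selection_on: str = "train"
    write_figures: bool = False

    def trait_list(self) -> list[str]:
        return list(self.traits) if self.traits else list(_DEFAULT_TRAITS[self.fruit_type])

    def config_hash(self) -> str:
        payload = {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in asdict(self).items()}
        digest = hashlib.sha1(json.dumps(payload, sort_keys=True, default=str).encode())
        return digest.hexdigest()[:8]


@dataclass
class RunBundle:
    """In-memory results of a full run, mirroring the written artifacts."""

    config: RunConfig
    spectra: SpectraSet
    traits: TraitTable
    stage_summary: pd.DataFrame
    pearson: pd.DataFrame
    correlograms: dict[str, bandsearch.CorrelogramResult]
    best_pairs: pd.DataFrame
    index_summary: pd.DataFrame
    model_report: pd.DataFrame
    artifact_paths: list[Path] = field(default_factory=list)


def index_regression_summary(s: SpectraSet, t: TraitTable,
                             traits: list[str] | None = None) -> pd.DataFrame:
    """R² of the simple linear regression trait ~ index for every registry
    index and trait (squared Pearson correlation)."""
    trait_names = traits if traits is not None else t.trait_names
    idx_df = indices.index_table(s)
    rows = []
    for index_name in idx_df.columns:
        v = idx_df[index_name].to_numpy(dtype=float)
        row: dict[str, object] = {"index": index_name}
        vc = v - v.mean()
        ss_v = float(vc @ vc)
        for trait in trait_names:
            y = t.values(trait)
            yc = y - y.mean()
            ss_y = float(yc @ yc)
            if not np.all(np.isfinite(v)) or ss_v == 0 or ss_y == 0:
                row[trait] = np.nan
            else:
                r = float(vc @ yc) / np.sqrt(ss_v * ss_y)
                row[trait] = r * r
        rows.append(row)
    return pd.DataFrame(rows).set_index("index")


def _write_frame(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool) -> Path:
    with open(path, "w") as fh:
        fh.write(f"# fruitspec seed={cfg.seed} config={cfg.config_hash()}\n")
        df.to_csv(fh, index=index, float_format="%.17g")
    return path


def _load_inputs(cfg: RunConfig) -> tuple[SpectraSet, TraitTable]:
    if cfg.spectra_path and cfg.traits_path:
        return (read_spectra(cfg.spectra_path, fruit_type=cfg.fruit_type),
                read_traits(cfg.traits_path))
    gen = GeneratorConfig.mango(seed=cfg.seed) if cfg.fruit_type == "mango" \
        else GeneratorConfig.strawberry(seed=cfg.seed)
    ds = generate_dataset(gen)
    return ds.spectra, ds.traits


def run_all(cfg: RunConfig) -> RunBundle:
    """Execute every pipeline stage and write the artifact files.

    Artifacts (under ``cfg.out_dir``): per-trait stage summaries, trait
    Pearson matrix, per-trait correlogram matrices and selected band pairs,
    the per-index regression summary, and the model report.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    current = {"name": "load"}

    def stage(name: str):
        current["name"] = name
        t0 = time.perf_counter()

        def done(shape) -> None:
            logger.info("stage=%s shape=%s elapsed=%.2fs", name, shape,
                        time.perf_counter() - t0)

        return done

    try:
        done = stage("load")
        spectra, traits = _load_inputs(cfg)
        if not traits.aligned_with(spectra):
            raise ValueError("spectra and trait files are not aligned")
        done((spectra.n_samples, len(spectra.grid)))

        trait_names = cfg.trait_list()

        done = stage("stage_stats")
        summary = pd.concat(
            [stats.describe_by_stage(traits, tr) for tr in trait_names],
            ignore_index=True,
        )
        pearson = stats.pearson_matrix(traits)
        paths.append(_write_frame(summary, out / f"{cfg.fruit_type}_stage_summary.csv",
                                  cfg, index=False))
        paths.append(_write_frame(pearson, out / f"{cfg.fruit_type}_trait_pearson.csv",
                                  cfg, index=True))
        done(summary.shape)

        done = stage("correlogram")
        correlograms: dict[str, bandsearch.CorrelogramResult] = {}
        pair_rows = []
        for tr in trait_names:
            c = bandsearch.build_correlogram(spectra, traits, tr, family=cfg.index_family)
            pairs = bandsearch.select_best_pairs(c, k=cfg.top_k,
                                                 min_separation=cfg.min_separation)
            correlograms[tr] = c
            matrix_path = out / f"{cfg.fruit_type}_{tr}_correlogram.csv"
            fig_path = (out / f"{cfg.fruit_type}_{tr}_correlogram.png"
                        if cfg.write_figures else None)
            with open(matrix_path, "w") as fh:
                fh.write(f"# fruitspec seed={cfg.seed} config={cfg.config_hash()}\n")
            wl = [f"{w:g}" for w in c.wavelengths]
            pd.DataFrame(c.r2, index=pd.Index(wl, name="lambda1_nm"), columns=wl).to_csv(
                matrix_path, mode="a", float_format="%.17g", na_rep="")
            if fig_path is not None:
                bandsearch._render_contour(c, fig_path)
                paths.append(fig_path)
            paths.append(matrix_path)
            pair_rows.extend(
                {"trait": tr, "rank": r + 1, "lambda1_nm": l1, "lambda2_nm": l2, "r2": v}
                for r, (l1, l2, v) in enumerate(pairs)
            )
        best_pairs = pd.DataFrame(pair_rows)
        paths.append(_write_frame(best_pairs, out / f"{cfg.fruit_type}_best_pairs.csv",
                                  cfg, index=False))
        done((len(correlograms), len(spectra.grid), len(spectra.grid)))

        done = stage("index_regression")
        index_summary = index_regression_summary(spectra, traits, trait_names)
        paths.append(_write_frame(index_summary,
                                  out / f"{cfg.fruit_type}_index_regression.csv",
                                  cfg, index=True))
        done(index_summary.shape)

        done = stage("models")
        fit_results = []
        for tr in trait_names:
            fit_results.extend(models.run_trait_models(
                spectra, traits, tr, families=cfg.families, threshold=cfg.threshold,
                seed=cfg.seed, folds=cfg.folds, grids=cfg.model_grids,
                selection_on=cfg.selection_on,
            ))
        model_report = models.results_frame(fit_results)
        paths.append(_write_frame(model_report,
                                  out / f"{cfg.fruit_type}_model_report.csv",
                                  cfg, index=False))
        done(model_report.shape)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current['name']!r} failed: {exc}") from exc

    return RunBundle(
        config=cfg, spectra=spectra, traits=traits, stage_summary=summary,
        pearson=pearson, correlograms=correlograms, best_pairs=best_pairs,
        index_summary=index_summary, model_report=model_report,
        artifact_paths=paths,
    )
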