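"""End-to-end pipeline: simulate -> extract -> classify -> interpret ->
mask-PCA -> report, orchestrated from one hierarchical config.

Every stage draws its randomness from a seed derived from the single
top-level seed, each output file is listed in the run manifest with a
content digest, and re-running the same config + seed reproduces all
outputs bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    SplitPlan,
    evaluate_participants,
    evaluate_population,
    rau,
    within_across,
)
from .cohort import CohortConfig, make_cohort
from .features import featurize_cohort
from .filterbank import FilterbankSpec
from .interpret import ReverseCorrelator, mask_consistency
from .io import hash_file, save_features, save_masks
from .maskpca import MaskPCA, associate_sleepiness
from .stm import project, relative_difference

log = logging.getLogger("voxstm")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "demo_config", "demo_filterbank_spec"]


@dataclass(frozen=True)
class ClassifyConfig:
    population_repeats: int = 50
    participant_repeats: int = 50
    test_fraction: float = 0.25
    population_components: int = 250
    participant_components: int = 30
    within_across_repeats: int = 10
    run_loso: bool = True
    run_within_across: bool = True


@dataclass(frozen=True)
class InterpretConfig:
    probes_per_frame: int = 100
    amplitude: float = 1.0
    correct_only: bool = False


@dataclass(frozen=True)
class MaskPcaConfig:
    n_components: int = 2


@dataclass(frozen=True)
class PipelineConfig:
    """Hierarchical configuration of one full run."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    filterbank: FilterbankSpec = field(default_factory=FilterbankSpec)
    frame_length: float = 15.0
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    interpret: InterpretConfig = field(default_factory=InterpretConfig)
    maskpca: MaskPcaConfig = field(default_factory=MaskPcaConfig)
    write_wavs: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kw = {}
        if "cohort" in d:
            kw["cohort"] = CohortConfig(**d.pop("cohort"))
        if "filterbank" in d:
            fb = d.pop("filterbank")
            for key in ("scales", "rate_magnitudes"):
                if key in fb:
                    fb[key] = tuple(fb[key])
            kw["filterbank"] = FilterbankSpec(**fb)
        if "classify" in d:
            kw["classify"] = ClassifyConfig(**d.pop("classify"))
        if "interpret" in d:
            kw["interpret"] = InterpretConfig(**d.pop("interpret"))
        if "maskpca" in d:
            kw["maskpca"] = MaskPcaConfig(**d.pop("maskpca"))
        kw.update(d)
        cfg = cls(**kw)
        if "seed" in kw and "cohort" not in kw:
            cfg = replace(cfg, cohort=replace(cfg.cohort, seed=cfg.seed))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


def demo_filterbank_spec() -> FilterbankSpec:
    """Reduced filterbank for demo-scale runs.

    32 channels over the same 5.3-octave span, 20-ms hop (50 Hz frame
    rate), 3 scales around the planted 2 cyc/oct ripple and rates to 16 Hz
    — small enough to run a whole cohort in seconds while keeping the
    planted 2-8 Hz / ~2 cyc/oct effects inside the analysis range.
    """
    return FilterbankSpec(
        n_channels=32,
        hop=0.020,
        scales=(0.5, 1.0, 2.0),
        rate_magnitudes=(0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
    )


def demo_config(seed: int = 0, n_participants: int = 4, **cohort_overrides) -> PipelineConfig:
    """Small end-to-end configuration (minutes, not hours)."""
    cohort = CohortConfig(
        n_participants=n_participants,
        session_duration=60.0,
        seed=seed,
        **cohort_overrides,
    )
    return PipelineConfig(
        seed=seed,
        cohort=cohort,
        filterbank=demo_filterbank_spec(),
        classify=ClassifyConfig(
            population_repeats=8,
            participant_repeats=8,
            population_components=20,
            participant_components=12,
            within_across_repeats=5,
        ),
        interpret=InterpretConfig(probes_per_frame=10),
    )


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    seeds: dict
    versions: dict
    outputs: dict = field(default_factory=dict)  # path -> sha256
    timings: dict = field(default_factory=dict)  # stage -> seconds
    summary: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2, sort_keys=True, default=str)


def _stage_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    names = ["simulate", "classify", "interpret", "maskpca"]
    states = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(names))]
    return dict(zip(names, states))


def run_pipeline(config: PipelineConfig | str | Path, out_dir) -> RunManifest:
    """Execute every stage in order and write tables, masks and manifest.

    Any stage failure aborts with the stage name; outputs written so far
    are preserved in `out_dir`.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(
        config=asdict(config),
        seeds=seeds,
        versions={"voxstm": __version__, "numpy": np.__version__},
    )
    stage = "setup"
    outputs: list[Path] = []
    try:
        # ---- simulate ----------------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        cohort = make_cohort(replace(config.cohort, seed=seeds["simulate"]))
        cohort_dir = out / "cohort"
        if config.write_wavs:
            table = cohort.write(cohort_dir)
        else:
            cohort_dir.mkdir(exist_ok=True)
            table = cohort.table
            table.to_csv(cohort_dir / "cohort.csv", index=False)
        outputs.append(cohort_dir / "cohort.csv")
        manifest.timings[stage] = time.perf_counter() - t0
        log.info("simulate: %d recordings", len(table))

        # ---- extract -----------------------------------------------------
        stage = "extract"
        t0 = time.perf_counter()
        X, meta = featurize_cohort(cohort, config.filterbank, config.frame_length)
        feat_path = out / "features.h5"
        save_features(feat_path, X, meta, config.filterbank)
        outputs.append(feat_path)
        # Fig-2-style acoustic difference maps on the synthetic cohort.
        before = X[meta.state == "before"].mean(axis=0)
        after = X[meta.state == "after"].mean(axis=0)
        for plane in ("rate-scale", "frequency-rate"):
            diff = relative_difference(
                project(before, plane, config.filterbank),
                project(after, plane, config.filterbank),
            )
            path = out / f"difference_{plane.replace('-', '_')}.csv"
            pd.DataFrame(diff.values, index=diff.row_axis, columns=diff.col_axis).to_csv(path)
            outputs.append(path)
        manifest.timings[stage] = time.perf_counter() - t0
        log.info("extract: %s frames x %s features", *X.shape)

        # ---- classify ----------------------------------------------------
        stage = "classify"
        t0 = time.perf_counter()
        y = meta.state.to_numpy()
        groups = meta.participant_id.to_numpy()
        ccfg = config.classify
        rows = []
        pop_hold = evaluate_population(
            X,
            y,
            groups,
            SplitPlan("holdout_repeated", ccfg.population_repeats, ccfg.test_fraction,
                      seeds["classify"]),
            n_components=ccfg.population_components,
        )
        rows.append(("population", "holdout", None, pop_hold))
        if ccfg.run_loso:
            pop_loso = evaluate_population(
                X, y, groups, SplitPlan("loso", seed=seeds["classify"]),
                n_components=ccfg.population_components,
            )
            rows.append(("population", "loso", None, pop_loso))
        part_evals = evaluate_participants(
            X,
            y,
            groups,
            n_repeats=ccfg.participant_repeats,
            test_fraction=ccfg.test_fraction,
            n_components=ccfg.participant_components,
            seed=seeds["classify"],
            keep_models=True,
        )
        for ev in part_evals:
            rows.append(("participant", "holdout", ev.participant, ev.result))
        res_df = pd.DataFrame(
            [
                {
                    "level": lvl,
                    "cv": cv,
                    "participant": p if p is not None else -1,
                    "bacc_mean": r.mean,
                    "bacc_sd": r.sd,
                    "rau_mean": rau(np.clip(r.mean, 0, 1)),
                    "t_vs_chance": r.t_stat,
                    "p_vs_chance": r.p_value,
                    "n_splits": len(r.baccs),
                }
                for lvl, cv, p, r in rows
            ]
        )
        res_path = out / "classification.csv"
        res_df.to_csv(res_path, index=False)
        outputs.append(res_path)
        if ccfg.run_within_across:
            wa = within_across(
                X,
                meta.session_index.to_numpy(),
                groups,
                n_sessions_per_state=config.cohort.n_sessions_per_state,
                n_repeats=ccfg.within_across_repeats,
                n_components=ccfg.participant_components,
                seed=seeds["classify"],
            )
            wa_path = out / "within_across.csv"
            wa.per_participant.to_csv(wa_path, index=False)
            outputs.append(wa_path)
            manifest.summary["within_across_t"] = wa.t_stat
            manifest.summary["within_across_p"] = wa.p_value
        manifest.timings[stage] = time.perf_counter() - t0
        manifest.summary["population_holdout_bacc"] = pop_hold.mean
        part_means = [ev.result.mean for ev in part_evals]
        manifest.summary["participant_bacc_mean"] = float(np.mean(part_means))
        log.info("classify: population holdout BAcc %.3f", pop_hold.mean)

        # ---- interpret ---------------------------------------------------
        stage = "interpret"
        t0 = time.perf_counter()
        icfg = config.interpret
        mean_masks, replicate_masks, consistency_rows = {}, {}, []
        for ev in part_evals:
            frames = X[ev.frame_index]
            labels = y[ev.frame_index]
            reps = []
            for k, clf in enumerate(ev.models):
                rc = ReverseCorrelator(
                    probes_per_frame=icfg.probes_per_frame,
                    amplitude=icfg.amplitude,
                    correct_only=icfg.correct_only,
                    random_state=seeds["interpret"] + 1000 * ev.participant + k,
                )
                rc.fit(clf, frames, labels)
                reps.append(rc.mask_)
            reps = np.asarray(reps)
            key = f"participant_{ev.participant:03d}"
            replicate_masks[key] = reps
            mean_masks[ev.participant] = reps.mean(axis=0)
            if len(reps) >= 2:
                cs = mask_consistency(reps)
                consistency_rows.append(
                    {
                        "participant": ev.participant,
                        "mean_r": cs.mean,
                        "sd_r": cs.sd,
                        "min_r": cs.min,
                        "n_significant": cs.n_significant,
                        "n_pairs": len(cs.correlations),
                    }
                )
        masks_path = out / "masks.h5"
        save_masks(
            masks_path,
            {**replicate_masks, **{f"mean_{k:03d}": v for k, v in mean_masks.items()}},
            config.filterbank,
            {"probes_per_frame": icfg.probes_per_frame, "amplitude": icfg.amplitude},
        )
        outputs.append(masks_path)
        cons_path = out / "mask_consistency.csv"
        pd.DataFrame(consistency_rows).to_csv(cons_path, index=False)
        outputs.append(cons_path)
        manifest.timings[stage] = time.perf_counter() - t0

        # ---- mask PCA ----------------------------------------------------
        stage = "maskpca"
        t0 = time.perf_counter()
        pids = sorted(mean_masks)
        M = np.asarray([mean_masks[p] for p in pids])
        model = MaskPCA(n_components=config.maskpca.n_components).fit(M)
        coords_df = pd.DataFrame(
            model.coords_,
            columns=[f"dim{j + 1}" for j in range(model.n_components_)],
        )
        coords_df.insert(0, "participant", pids)
        coords_path = out / "maskpca_coordinates.csv"
        coords_df.to_csv(coords_path, index=False)
        outputs.append(coords_path)
        ev_path = out / "maskpca_explained_variance.csv"
        pd.DataFrame(
            {
                "dim": np.arange(1, model.n_components_ + 1),
                "explained_variance_ratio": model.explained_variance_ratio_,
            }
        ).to_csv(ev_path, index=False)
        outputs.append(ev_path)
        for dim in range(min(2, model.n_components_)):
            grid = model.idealized_masks(dim)
            vmap = project(grid.variance_map, "rate-scale", config.filterbank)
            vpath = out / f"variance_map_dim{dim + 1}_rate_scale.csv"
            pd.DataFrame(vmap.values, index=vmap.row_axis, columns=vmap.col_axis).to_csv(vpath)
            outputs.append(vpath)
        sss_after = (
            cohort.profiles.set_index("participant_id").loc[pids, "sss_after"].to_numpy()
        )
        n_reps = min(len(v) for v in replicate_masks.values())
        rep_coords = np.asarray(
            [
                model.transform(
                    np.asarray([replicate_masks[f"participant_{p:03d}"][k] for p in pids])
                )
                for k in range(n_reps)
            ]
        )
        assoc = associate_sleepiness(model, sss_after, replicate_coords=rep_coords)
        assoc_path = out / "sleepiness_association.json"
        with open(assoc_path, "w") as f:
            json.dump(
                {
                    "per_dim_r": assoc.per_dim_r.tolist(),
                    "per_dim_p": assoc.per_dim_p.tolist(),
                    "r2_mean": assoc.r2_mean,
                    "r2_sd": assoc.r2_sd,
                    "r2_t": assoc.r2_t,
                    "r2_p": assoc.r2_p,
                    "mode": assoc.mode,
                },
                f,
                indent=2,
            )
        outputs.append(assoc_path)
        manifest.timings[stage] = time.perf_counter() - t0
        manifest.summary["maskpca_explained_variance"] = (
            model.explained_variance_ratio_.tolist()
        )
        manifest.summary["sss_dim_r"] = assoc.per_dim_r.tolist()

        # ---- report ------------------------------------------------------
        stage = "report"
        report = out / "report.md"
        with open(report, "w") as f:
            f.write("# voxstm run report\n\n")
            f.write(f"Seed: {config.seed}; {len(table)} recordings, "
                    f"{X.shape[0]} frames x {X.shape[1]} features.\n\n")
            f.write("## Classification (balanced accuracy)\n\n")
            f.write("```\n" + res_df.to_string(index=False) + "\n```")
            f.write("\n\n## Interpretation-PCA explained variance\n\n")
            for j, v in enumerate(model.explained_variance_ratio_):
                f.write(f"- dim {j + 1}: {100 * v:.1f}%\n")
            f.write("\n## Sleepiness association\n\n")
            f.write(
                f"- per-dimension r: {np.round(assoc.per_dim_r, 3).tolist()}\n"
                f"- linear-model R^2: mean {assoc.r2_mean:.3f}, sd {assoc.r2_sd:.3f} "
                f"({assoc.mode})\n"
            )
        outputs.append(report)
    except Exception as err:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    for path in outputs:
        manifest.outputs[str(path.relative_to(out))] = hash_file(path)
    manifest.save(out / "manifest.json")
    return manifest
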