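"""End-to-end orchestration: dataset generation, training, evaluation.

The scaled-down in-silico reproduction experiment generates randomized
training and test volumes from the training-distribution sampler,
simulates their multi-illumination multispectral absorbed-energy stacks,
trains the configured spectral-decoloring estimators on L1-normalized
tube-voxel spectra, and reports error summaries against the linear
unmixing baseline.  Every random stream is keyed by
(master seed, stage, volume id), so a run is fully reproducible from its
manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .decoloring import (
    EstimatorConfig,
    LabeledSpectraSet,
    LinearUnmixer,
    extract_samples,
)
from .evaluation import ErrorSummary, report_table, summarize_errors, table_to_tsv
from .fluence import IlluminationGeometry, simulate_stack
from .phantoms import SamplerConfig, build_layout, sample_training_volume
from .spectra import ChromophoreMixture, ScatteringModelParams, WavelengthGrid, \
    bundled_endmembers

logger = logging.getLogger("milsd")

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "run_ood_experiment"]

_STAGE_TRAIN, _STAGE_TEST, _STAGE_MODEL, _STAGE_OOD = 0, 1, 2, 3


@dataclass
class ExperimentConfig:
    """Configuration of one in-silico experiment.

    The defaults are the desk-scale reproduction settings: ~300 training
    and 100 test volumes on the 2D diffusion backend with the default
    16-wavelength grid and four illumination positions.
    """

    family: str = "sulfate"
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    illumination: IlluminationGeometry = field(default_factory=IlluminationGeometry)
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    scattering: ScatteringModelParams = field(default_factory=ScatteringModelParams)
    backend: str = "diffusion"
    n_photons: int = 1_000_000
    n_train_volumes: int = 300
    n_test_volumes: int = 100
    models: tuple[str, ...] = ("rf", "nn")
    modes: tuple[str, ...] = ("milsd", "lsd")
    include_lu: bool = True
    nn_epochs: int = 100
    master_seed: int = 0
    out_dir: str | None = None

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid.values)
        return d


@dataclass
class ExperimentResult:
    summaries: dict  # (model, mode, set) -> ErrorSummary
    estimators: dict  # (model, mode) -> fitted estimator
    datasets: dict  # (stage, mode) -> LabeledSpectraSet
    manifest: dict


def _volume_seed(master: int, stage: int, vol: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=(master, stage, vol))


def _generate_split(cfg: ExperimentConfig, stage: int, n_volumes: int,
                    augment_train: bool) -> dict:
    """Generate volumes, simulate stacks, extract both feature modes."""
    parts: dict[str, list[LabeledSpectraSet]] = {m: [] for m in cfg.modes}
    t0 = time.time()
    for vol in range(n_volumes):
        ss = _volume_seed(cfg.master_seed, stage, vol)
        sub = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
        phantom = sample_training_volume(
            cfg.sampler, np.random.default_rng(ss), family=cfg.family,
            grid=cfg.grid, scattering=cfg.scattering)
        stack = simulate_stack(phantom, cfg.illumination, backend=cfg.backend,
                               n_photons=cfg.n_photons, seed=sub)
        for mode in cfg.modes:
            parts[mode].append(extract_samples(
                stack, mode=mode,
                augment_mirror=(augment_train and mode == "milsd"),
                volume_id=vol))
    sets = {m: LabeledSpectraSet.concatenate(p) for m, p in parts.items()}
    for mode, s in sets.items():
        logger.info("stage %d (%s): %d volumes, %d samples, %d dropped, %.1f s",
                    stage, mode, n_volumes, len(s), s.n_dropped, time.time() - t0)
    return sets


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the full generate / simulate / train / evaluate pipeline.

    Returns error summaries per (model, mode) on the held-out test set,
    plus the linear-unmixing baseline evaluated on the same
    mean-illumination spectra as LSD (equal delivered energy, no method
    gets an SNR advantage).
    """
    t_start = time.time()
    train_sets = _generate_split(cfg, _STAGE_TRAIN, cfg.n_train_volumes,
                                 augment_train=True)
    test_sets = _generate_split(cfg, _STAGE_TEST, cfg.n_test_volumes,
                                augment_train=False)

    summaries: dict = {}
    estimators: dict = {}
    for kind in cfg.models:
        for mode in cfg.modes:
            # stable across processes (Python's hash() is salted)
            tag = zlib.crc32(f"{kind}-{mode}".encode()) & 0xFFFF
            seed = int(_volume_seed(cfg.master_seed, _STAGE_MODEL, tag)
                       .generate_state(1)[0] & 0x7FFFFFFF)
            est_cfg = EstimatorConfig(
                kind=kind, mode=mode, seed=seed,
                n_wavelengths=len(cfg.grid),
                n_illuminations=cfg.illumination.n_positions,
                epochs=cfg.nn_epochs)
            est = est_cfg.build()
            t0 = time.time()
            est.fit(train_sets[mode].features, train_sets[mode].labels)
            t_fit = time.time() - t0
            t0 = time.time()
            pred = est.predict(test_sets[mode].features)
            t_pred = time.time() - t0
            s = summarize_errors(pred, test_sets[mode].labels)
            summaries[(kind, mode, "insilico-test")] = s
            estimators[(kind, mode)] = est
            logger.info("%s-%s: fit %.1f s, predict %.2f s (%d samples), "
                        "median |err| %.2f pp", kind, mode, t_fit, t_pred,
                        len(pred), s.abs_q2)

    if cfg.include_lu:
        if "lsd" not in cfg.modes:
            raise ValueError("LU baseline needs the 'lsd' mean-illumination mode")
        lu = LinearUnmixer(bundled_endmembers(cfg.family, cfg.grid)).fit()
        t0 = time.time()
        pred = lu.predict(test_sets["lsd"].features)
        s = summarize_errors(pred, test_sets["lsd"].labels)
        summaries[("lu", "lsd", "insilico-test")] = s
        estimators[("lu", "lsd")] = lu
        logger.info("lu-lsd: predict %.1f s, median |err| %.2f pp",
                    time.time() - t0, s.abs_q2)

    manifest = {
        "config": cfg.to_manifest(),
        "package_version": _version(),
        "n_train_samples": {m: len(s) for m, s in train_sets.items()},
        "n_test_samples": {m: len(s) for m, s in test_sets.items()},
        "dropped": {m: s.n_dropped for m, s in train_sets.items()},
        "runtime_s": round(time.time() - t_start, 1),
    }
    result = ExperimentResult(
        summaries=summaries, estimators=estimators,
        datasets={("train", m): s for m, s in train_sets.items()}
        | {("test", m): s for m, s in test_sets.items()},
        manifest=manifest)
    if cfg.out_dir:
        _write_artifacts(cfg, result)
    return result


def _version() -> str:
    import milsd
    return milsd.__version__


def _write_artifacts(cfg: ExperimentConfig, result: ExperimentResult) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = report_table(result.summaries)
    (out / "summaries.tsv").write_text(table_to_tsv(df))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    logger.info("artifacts written to %s", out)


def run_ood_experiment(
    cfg: ExperimentConfig,
    estimators: dict,
    tube_saturations: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    backgrounds: tuple[ChromophoreMixture, ...] | None = None,
) -> dict:
    """Evaluate transversal-trained estimators on longitudinal
    (layout C) synthetic scenes, which are out-of-distribution.

    One scene per (tube saturation, background): the in-plane shallow
    and deep tubes of one array, both at the scan's target saturation,
    matching the physical longitudinal protocol.  Returns summaries per
    (model, mode, 'ood-layout-C').
    """
    if not estimators:
        raise ValueError("run_ood_experiment requires trained estimators")
    backgrounds = backgrounds or (
        ChromophoreMixture(0.0, 0.01, cfg.family),
        ChromophoreMixture(1.0, 0.01, cfg.family),
    )
    parts: dict[str, list[LabeledSpectraSet]] = {m: [] for m in cfg.modes}
    vol = 0
    for bg in backgrounds:
        for sat in tube_saturations:
            phantom = build_layout("C", [sat, sat], bg, grid=cfg.grid,
                                   scattering=cfg.scattering,
                                   extent_mm=cfg.sampler.extent_mm,
                                   pitch_mm=cfg.sampler.pitch_mm)
            ss = _volume_seed(cfg.master_seed, _STAGE_OOD, vol)
            stack = simulate_stack(phantom, cfg.illumination, backend=cfg.backend,
                                   n_photons=cfg.n_photons,
                                   seed=int(ss.generate_state(1)[0] & 0x7FFFFFFF))
            for mode in cfg.modes:
                parts[mode].append(extract_samples(stack, mode=mode, volume_id=vol))
            vol += 1
    sets = {m: LabeledSpectraSet.concatenate(p) for m, p in parts.items()}

    summaries: dict = {}
    for (kind, mode), est in estimators.items():
        s = summarize_errors(est.predict(sets[mode].features), sets[mode].labels)
        summaries[(kind, mode, "ood-layout-C")] = s
        logger.info("OOD %s-%s: median |err| %.2f pp", kind, mode, s.abs_q2)
    return summaries
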