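"""End-to-end orchestration: simulate -> window -> transform -> enhance ->
CNN features -> SVM evaluation, from a single run configuration.

Stages are cached on disk keyed by a content hash of their resolved
parameters, so the experimental grid (3 transforms x 3 windows x 2 CV
schemes x several tasks) re-uses upstream artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.pipeline import Pipeline

from . import io, simulate
from .cnn import CNNFeatureExtractor
from .enhance import PCAEnhancer
from .evaluate import CVScheme, EvalReport, BayesSVC, cross_validate, multiclass_evaluate
from .images import render_image
from .tfr import cwt, default_freq_grid, stft, wsst

log = logging.getLogger(__name__)

TRANSFORMS = {"cwt": cwt, "stft": stft, "wsst": wsst}


@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run."""

    channel: str = "CF"  # LF, RF, or CF
    window_s: float = 10.0
    transform: str = "cwt"  # cwt, stft, or wsst
    band: str = "full"
    pca: bool = True
    pca_retain: float = 0.95
    # "train": refit the PCA basis on each training fold (no leakage).
    # "all": fit once on the full image set before cross-validation; kept
    # only for comparison, since it leaks test pixels into the basis.
    pca_population: str = "train"
    weights_mode: str = "random"
    cnn_train: str = "fc"  # "none" or "fc"
    cnn_epochs: int = 8
    task: tuple[str, ...] = ("ALS", "HC")  # label pair, ("NDD", "HC"), or ("multiclass",)
    cv_kind: str = "kfold"
    cv_k: int = 5
    cv_unit: str = "subject"
    bayes_iters: int = 30
    seed: int = 0
    fs: float = 300.0
    duration_s: float = 300.0
    n_per_group: dict = field(default_factory=lambda: dict(simulate.DEFAULT_COHORT))
    cache_dir: str | None = None

    def resolved(self) -> dict:
        d = asdict(self)
        d["task"] = list(self.task)
        return d

    def content_hash(self, *keys: str) -> str:
        d = self.resolved()
        sub = {k: d[k] for k in keys} if keys else d
        return hashlib.sha256(
            json.dumps(sub, sort_keys=True).encode()
        ).hexdigest()[:16]


def build_images(
    config: RunConfig, records=None, groups: set[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Windows -> spectrograms -> rasters for a cohort.

    Returns (pixels (n, 227, 227, 3) float32, group labels, subject ids).
    ``groups`` restricts transformation to a subset of phenotypes.  Cached
    under ``config.cache_dir`` keyed by the image-stage parameters.
    """
    cache_path = None
    if config.cache_dir is not None and records is None:
        key = config.content_hash(
            "channel", "window_s", "transform", "band", "seed", "fs",
            "duration_s", "n_per_group",
        ) + ("" if groups is None else "_" + "-".join(sorted(groups)))
        cache_path = Path(config.cache_dir) / f"images_{key}.npz"
        if cache_path.exists():
            log.info("image cache hit: %s", cache_path)
            z = np.load(cache_path, allow_pickle=False)
            return z["pixels"], z["labels"], np.asarray(z["units"])
    if records is None:
        records = simulate.generate_cohort(
            config.n_per_group, duration_s=config.duration_s, fs=config.fs,
            seed=config.seed,
        )
    if groups is not None:
        records = [r for r in records if r.group in groups]
    freqs = default_freq_grid(fmax=min(50.0, config.fs / 2))
    pixels, labels, units = [], [], []
    fn = TRANSFORMS[config.transform]
    for rec in records:
        for win in io.segment_windows(rec, config.channel, config.window_s):
            # the constant load offset carries no gait information and, under
            # finite-support transforms, leaks into the lowest octaves
            x = win.samples - win.samples.mean()
            if fn is stft:
                t = fn(x, win.fs)
            else:
                t = fn(x, win.fs, freqs)
            img = render_image(t, band=config.band)
            pixels.append(img.pixels.astype(np.float32))
            labels.append(rec.group)
            units.append(rec.subject_id)
        log.info("transformed record %s (%s)", rec.subject_id, rec.group)
    X = np.stack(pixels)
    y = np.array(labels)
    u = np.array(units)
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(cache_path, pixels=X, labels=y, units=u)
    return X, y, u


def make_pipeline(config: RunConfig) -> Pipeline:
    """The per-fold estimator chain: [PCA enhancement] -> CNN -> SVM."""
    steps = []
    if config.pca and config.pca_population == "train":
        steps.append(("enhance", PCAEnhancer(retain=config.pca_retain)))
    steps.append(
        (
            "cnn",
            CNNFeatureExtractor(
                weights_mode=config.weights_mode, seed=config.seed,
                train=config.cnn_train, epochs=config.cnn_epochs,
            ),
        )
    )
    steps.append(("svm", BayesSVC(n_iter=config.bayes_iters, random_state=config.seed)))
    return Pipeline(steps)


def run(config: RunConfig, records=None) -> EvalReport:
    """Execute the full chain for one configuration and return its report."""
    task = tuple(config.task)
    groups = None
    if task != ("multiclass",) and "NDD" not in task:
        groups = set(task)
    X, y, units = build_images(config, records=records, groups=groups)
    census = {g: int((y == g).sum()) for g in np.unique(y)}
    log.info("window census at %.0f s: %s (total %d)", config.window_s, census, y.size)
    if task == ("multiclass",):
        mask = np.ones(y.size, dtype=bool)
        y_task = y
    elif "NDD" in task:
        mask = np.ones(y.size, dtype=bool)
        y_task = np.where(y == "HC", "HC", "NDD")
    else:
        mask = np.isin(y, task)
        y_task = y
    if config.pca and config.pca_population == "all":
        # leaky comparison arm: basis fit on every image, train and test
        X = PCAEnhancer(retain=config.pca_retain).fit(X).transform(X)
    scheme = CVScheme(
        kind=config.cv_kind, k=config.cv_k, unit=config.cv_unit, seed=config.seed
    )
    pipe = make_pipeline(config)
    if task == ("multiclass",):
        report = multiclass_evaluate(X[mask], y_task[mask], units[mask], scheme, pipe)
    else:
        report = cross_validate(
            X[mask], y_task[mask], units[mask], scheme, pipe,
            task=" vs ".join(task),
        )
    report.meta["config"] = config.resolved()
    report.meta["census"] = census
    return report
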