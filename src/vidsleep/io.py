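"""File formats and configuration for the wake/sleep pipeline.

Everything on disk is plain text: hypnograms, actigraphy traces and
feature tables are CSV; configuration and run manifests are YAML; the
classifier model file is the YAML layout written by
:meth:`vidsleep.classifier.LDAModel.save`.  Conventions are 0-based and
half-open everywhere; onset times are seconds from recording start.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .exceptions import HypnogramParseError, InvalidConfigError
from .classifier import SLEEP, WAKE

__all__ = [
    "STAGE_LABELS",
    "read_hypnogram",
    "write_hypnogram",
    "binarize_labels",
    "load_config",
    "default_config",
    "write_manifest",
    "LoadedRecording",
]

logger = logging.getLogger("vidsleep")

STAGE_LABELS = ("W", "N1", "N2", "N3", "R", "U")

EXCLUDED = "excluded"
_BINARY_MAP = {"W": WAKE, "N1": SLEEP, "N2": SLEEP, "N3": SLEEP, "R": SLEEP, "U": EXCLUDED}


@dataclass
class LoadedRecording:
    """A recording assembled from files, duck-typing the synthetic one."""

    subject_id: str
    hypnogram: np.ndarray
    actigraphy: "object"  # ActigraphySignal


def read_hypnogram(path, epoch_length_s: float = 30.0) -> pd.DataFrame:
    """Read and validate a hypnogram CSV.

    Expected header: ``epoch_index,onset_s,label`` with contiguous 0-based
    indices and labels from W/N1/N2/N3/R/U.  Validation errors cite the
    1-based file line of the offending row.
    """
    try:
        df = pd.read_csv(path, dtype={"label": str})
    except Exception as e:  # noqa: BLE001 - surface as a parse error
        raise HypnogramParseError(f"{path}: cannot parse CSV ({e})") from e
    for col in ("epoch_index", "onset_s", "label"):
        if col not in df.columns:
            raise HypnogramParseError(f"{path}: missing column '{col}'")
    for row, (idx, label) in enumerate(zip(df["epoch_index"], df["label"])):
        line = row + 2  # header is line 1
        if idx != row:
            raise HypnogramParseError(
                f"{path}: line {line}: epoch_index {idx} not contiguous (expected {row})"
            )
        if label not in STAGE_LABELS:
            raise HypnogramParseError(
                f"{path}: line {line}: unknown label {label!r} "
                f"(allowed: {', '.join(STAGE_LABELS)})"
            )
    return df


def write_hypnogram(labels, path, epoch_length_s: float = 30.0) -> None:
    labels = np.asarray(labels, dtype=str)
    idx = np.arange(len(labels))
    pd.DataFrame(
        {"epoch_index": idx, "onset_s": idx * epoch_length_s, "label": labels}
    ).to_csv(path, index=False)


def binarize_labels(labels) -> np.ndarray:
    """Project stage labels onto {wake, sleep, excluded}.

    W maps to wake; N1/N2/N3/R collapse into a single sleep state; U is
    excluded from training and scoring.  The class split is logged for
    comparison with expected prevalences.
    """
    labels = np.asarray(labels, dtype=str)
    out = np.empty(len(labels), dtype=object)
    for i, lab in enumerate(labels):
        if lab not in _BINARY_MAP:
            raise HypnogramParseError(f"unknown stage label {lab!r} at epoch {i}")
        out[i] = _BINARY_MAP[lab]
    n = max(1, len(out))
    frac = {c: float(np.mean(out == c)) for c in (WAKE, SLEEP, EXCLUDED)}
    logger.info(
        "label split: wake %.1f%% / sleep %.1f%% / excluded %.1f%%",
        100 * frac[WAKE], 100 * frac[SLEEP], 100 * frac[EXCLUDED],
    )
    if frac[EXCLUDED] == 1.0:
        logger.warning("all epochs are unable-to-score; nothing to classify")
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Pipeline defaults: 30-s epochs at 10 Hz, 95th-percentile activity
    threshold, 10-min smoothing window, equal class priors."""
    return {
        "epoch_length_s": 30.0,
        "frame_rate": 10.0,
        "percentile": 95.0,
        "smoothing_window_min": 10.0,
        "binary_mact": False,
        "feature_set": "mact+pslp",
        "threshold": 0.5,
        "ridge_fraction": 1e-6,
        "motion": {
            "block_size": 16,
            "search_bound": 8,
            "noise_threshold": 1.0,
        },
        "simulation": {},  # overrides for SimulationConfig fields
    }


def load_config(path=None) -> dict:
    """Merge a YAML config file over the defaults (shallow per section)."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise InvalidConfigError(f"{path}: config must be a mapping")
    for key, val in user.items():
        if key in ("motion", "simulation") and isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if cfg["epoch_length_s"] <= 0 or cfg["frame_rate"] <= 0:
        raise InvalidConfigError("epoch_length_s and frame_rate must be positive")
    if not 0.0 < cfg["threshold"] < 1.0:
        raise InvalidConfigError("threshold must lie in (0, 1)")
    return cfg


def config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(out_dir, cfg: dict, seed: int | None, extra: dict | None = None) -> str:
    """Write a run manifest (config hash, seed, version, file list).

    Deliberately excludes wall-clock time so identical runs produce
    byte-identical outputs.
    """
    from . import __version__

    payload = {
        "vidsleep_version": __version__,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "config": cfg,
    }
    if extra:
        payload.update(extra)
    path = os.path.join(out_dir, "manifest.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path


def load_cohort_dir(path, frame_rate: float = 10.0) -> dict[str, LoadedRecording]:
    """Load a cohort directory written by the ``simulate`` command:
    ``<subject>_hypnogram.csv`` + ``<subject>_actigraphy.csv`` pairs."""
    from .motion import ActigraphySignal

    subjects = sorted(
        f[: -len("_hypnogram.csv")]
        for f in os.listdir(path)
        if f.endswith("_hypnogram.csv")
    )
    if not subjects:
        raise InvalidConfigError(f"no '<subject>_hypnogram.csv' files in {path}")
    cohort = {}
    for sid in subjects:
        hyp = read_hypnogram(os.path.join(path, f"{sid}_hypnogram.csv"))
        sig = ActigraphySignal.from_csv(
            os.path.join(path, f"{sid}_actigraphy.csv"), frame_rate=frame_rate
        )
        cohort[sid] = LoadedRecording(
            subject_id=sid, hypnogram=hyp["label"].to_numpy(), actigraphy=sig
        )
    return cohort
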