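"""File formats and run manifests.

Stable plain-text interchange formats:

* partition CSV — one row per partition: ``partition_id, well, ch1..chC``;
* truth sidecar JSON — codebook, expected copies, partitions, seed;
* label counts CSV — ``label, partitions`` with labels quoted as digit
  strings (leading zeros survive spreadsheet round trips);
* crosstalk matrix CSV — bare C x C numbers;
* YAML/JSON configs for simulation and studies;
* a run manifest JSON recording version, config hash, seeds and input
  digests for reproducibility audits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codebook import Codebook, enumerate_codebook
from .signal import AmplitudeMatrix, CrosstalkMatrix, LabelCounts, ThresholdSet
from .simulate import NoiseModel, TruthSpec

__all__ = [
    "read_partitions_csv",
    "write_partitions_csv",
    "read_label_counts",
    "write_label_counts",
    "read_thresholds",
    "load_config",
    "ConfigError",
    "truth_to_dict",
    "truth_from_dict",
    "simulation_from_config",
    "write_manifest",
]


class ConfigError(ValueError):
    """A configuration file violates the published schema."""


# --- partition tables ------------------------------------------------------

def write_partitions_csv(matrix: AmplitudeMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, index=False, float_format="%.6g")


def read_partitions_csv(path: str | Path) -> AmplitudeMatrix:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"partition CSV {path} is empty")
    return AmplitudeMatrix.from_dataframe(df)


# --- label counts ----------------------------------------------------------

def write_label_counts(counts: LabelCounts, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(counts.counts.items()), columns=["label", "partitions"]
    )
    df.to_csv(path, index=False, quoting=2)  # QUOTE_NONNUMERIC keeps zeros


def read_label_counts(path: str | Path) -> LabelCounts:
    df = pd.read_csv(path, dtype={"label": str})
    if "label" not in df.columns or "partitions" not in df.columns:
        raise ValueError("label counts CSV needs 'label' and 'partitions' columns")
    counts = dict(zip(df["label"], df["partitions"].astype(int)))
    channels = len(next(iter(counts)))
    return LabelCounts(counts, channels)


# --- thresholds ------------------------------------------------------------

def read_thresholds(path: str | Path) -> ThresholdSet:
    d = json.loads(Path(path).read_text())
    if isinstance(d, dict) and "cuts" in d:
        return ThresholdSet(tuple(tuple(c) for c in d["cuts"]))
    raise ValueError("thresholds JSON must be an object with a 'cuts' list")


# --- configs ---------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    try:
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return data


def _codebook_from_config(spec: Any, base: Path) -> Codebook:
    if isinstance(spec, str):
        p = base / spec if not Path(spec).is_absolute() else Path(spec)
        return Codebook.from_json(p)
    if isinstance(spec, dict):
        if "tags" in spec:
            return Codebook.from_dict(spec)
        try:
            return enumerate_codebook(
                int(spec["channels"]),
                int(spec.get("levels_per_site", 2)),
                int(spec.get("max_sites", 2)),
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"bad codebook spec: {exc}") from exc
    raise ConfigError("codebook must be a path or a mapping")


def simulation_from_config(
    config: Mapping[str, Any], base: Path | None = None
) -> tuple[TruthSpec, NoiseModel, CrosstalkMatrix | None]:
    """Build a simulation from a parsed YAML/JSON config mapping."""
    base = base or Path(".")
    try:
        codebook = _codebook_from_config(config["codebook"], base)
        raw_copies = config["copies"]
    except KeyError as exc:
        raise ConfigError(f"simulation config missing key: {exc}") from exc
    if isinstance(raw_copies, (int, float)):
        copies = {t.name: float(raw_copies) for t in codebook.tags}
    elif isinstance(raw_copies, dict):
        copies = {str(k): float(v) for k, v in raw_copies.items()}
    else:
        raise ConfigError("copies must be a number or a {tag: copies} mapping")
    try:
        truth = TruthSpec(
            codebook=codebook,
            copies=copies,
            partitions=int(config.get("partitions", 26_000)),
            seed=int(config.get("seed", 0)),
        )
        noise = NoiseModel(**config.get("noise", {}))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulation config: {exc}") from exc
    xt = None
    if "crosstalk" in config:
        spec = config["crosstalk"]
        if isinstance(spec, str):
            xt = CrosstalkMatrix.from_csv(base / spec)
        elif isinstance(spec, dict) and "alpha" in spec:
            mode = spec.get("mode", "adjacent")
            maker = (
                CrosstalkMatrix.adjacent_bleed
                if mode == "adjacent"
                else CrosstalkMatrix.uniform_bleed
            )
            xt = maker(codebook.channels, float(spec["alpha"]))
        elif isinstance(spec, list):
            xt = CrosstalkMatrix(np.asarray(spec, dtype=float))
        else:
            raise ConfigError("crosstalk must be a path, matrix, or {alpha, mode}")
    return truth, noise, xt


# --- truth sidecar ---------------------------------------------------------

def truth_to_dict(truth: TruthSpec) -> dict:
    return {
        "codebook": truth.codebook.to_dict(),
        "copies": dict(truth.copies),
        "partitions": truth.partitions,
        "seed": truth.seed,
    }


def truth_from_dict(d: dict) -> TruthSpec:
    return TruthSpec(
        codebook=Codebook.from_dict(d["codebook"]),
        copies=d["copies"],
        partitions=int(d["partitions"]),
        seed=d.get("seed"),
    )


# --- manifest --------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
    inputs: Mapping[str, str | Path] | None = None,
    outputs: Mapping[str, str | Path] | None = None,
) -> Path:
    """Write ``manifest.json`` describing one CLI run.

    Output digests are deterministic for a fixed config + seed; the manifest
    timestamp is informational only.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "tool": "dpcrmux",
        "version": __version__,
        "command": command,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {k: _sha256(Path(v)) for k, v in (inputs or {}).items()},
        "outputs": {k: _sha256(Path(v)) for k, v in (outputs or {}).items()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1) + "\n")
    return path
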