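"""File contracts for the pipeline: CSV schemas, config loading, run metadata.

All interchange files are plain CSV (RFC 4180) with a single leading comment
line ``# dsadyn config_hash=<12 hex> seed=<int>`` so artifacts from different
runs cannot be silently mixed; readers skip comment lines and
:func:`check_provenance` raises when hashes disagree.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dtw import DEFAULT_PIPELINE_WINDOW, DtwConfig
from .gapstat import ReferenceConfig
from .preprocess import PreprocessConfig
from .synth import ArchetypeParams, CovariateModel, SamplingSchedule

__all__ = [
    "PipelineConfig",
    "load_config",
    "config_hash",
    "write_csv",
    "read_csv",
    "check_provenance",
]

MFI_COLUMNS = ["case_id", "specificity", "day", "mfi"]
COVARIATE_COLUMNS = [
    "case_id",
    "age",
    "gender",
    "prev_tx",
    "crossmatch",
    "rejection_30d",
    "gf_5y",
    "followup_days",
    "true_group",
]


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs, with the defaults of the method."""

    n_per_group: list[int] = field(default_factory=lambda: [18, 15, 23, 16, 16])
    rng_seed: int = 0
    k: int | str = "auto"
    k_max: int = 10
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    dtw: DtwConfig = field(
        default_factory=lambda: DtwConfig(window=DEFAULT_PIPELINE_WINDOW)
    )
    gapstat: ReferenceConfig = field(default_factory=ReferenceConfig)
    schedule: SamplingSchedule = field(default_factory=SamplingSchedule)

    def to_dict(self) -> dict:
        return {
            "n_per_group": list(self.n_per_group),
            "rng_seed": self.rng_seed,
            "k": self.k,
            "k_max": self.k_max,
            "preprocess": asdict(self.preprocess),
            "dtw": asdict(self.dtw),
            "gapstat": asdict(self.gapstat),
            "schedule": asdict(self.schedule),
        }


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML/JSON config; missing keys fall back to defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("n_per_group", "rng_seed", "k", "k_max"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "preprocess" in raw:
        cfg.preprocess = PreprocessConfig(**raw["preprocess"])
    if "dtw" in raw:
        cfg.dtw = DtwConfig(**raw["dtw"])
    if "gapstat" in raw:
        cfg.gapstat = ReferenceConfig(**raw["gapstat"])
    if "schedule" in raw:
        cfg.schedule = SamplingSchedule(**raw["schedule"])
    return cfg


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: str | Path, cfg_hash: str, seed: int) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# dsadyn config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def _read_header(path: Path) -> dict:
    with open(path) as fh:
        first = fh.readline()
    meta = {}
    if first.startswith("# dsadyn"):
        for tok in first.split()[2:]:
            key, _, val = tok.partition("=")
            meta[key] = val
    return meta


def read_csv(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a pipeline CSV, validating schema and basic value constraints."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
    if "day" in df.columns:
        days = pd.to_numeric(df["day"], errors="coerce")
        if days.isna().any():
            row = int(days.index[days.isna()][0]) + 2
            raise ValueError(f"{path}: non-numeric day at data row {row}")
        if not (days == days.round()).all():
            raise ValueError(f"{path}: day column must hold integers")
        df["day"] = days.astype(int)
    if "mfi" in df.columns:
        mfi = pd.to_numeric(df["mfi"], errors="coerce")
        if mfi.isna().any():
            row = int(mfi.index[mfi.isna()][0]) + 2
            raise ValueError(f"{path}: non-numeric MFI at data row {row}")
        if (mfi < 0).any():
            row = int(mfi.index[mfi < 0][0]) + 2
            raise ValueError(f"{path}: negative MFI at data row {row}")
        df["mfi"] = mfi
    return df


def check_provenance(*paths: str | Path) -> str:
    """Assert all files carry the same config hash; return it."""
    hashes = {}
    for p in paths:
        meta = _read_header(Path(p))
        if "config_hash" in meta:
            hashes[str(p)] = meta["config_hash"]
    if len(set(hashes.values())) > 1:
        raise ValueError(f"artifacts from different runs mixed: {hashes}")
    return next(iter(hashes.values()), "")
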