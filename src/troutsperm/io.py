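"""CSV and configuration I/O with reproducibility metadata.

Every output file begins with ``#``-prefixed metadata lines recording the
package version, the seed and a hash of the effective configuration, so any
result file can be traced back to the exact run that produced it.  Columns
encode their units in their names (``_um``, ``_Pa_s``, ``_pN``) to prevent
silent unit bugs; CSVs are UTF-8 with '.' decimal separators.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .design import EffectConfig, StudyDesign

__all__ = ["config_hash", "write_csv", "read_csv", "read_metadata",
           "PipelineConfig", "load_config"]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(*objs: Any) -> str:
    """Stable short hash of any nesting of dataclasses/mappings/sequences."""
    payload = json.dumps([_jsonable(o) for o in objs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: str | Path, *, seed: int | None = None,
              cfg_hash: str | None = None, extra: Mapping[str, Any] | None = None
              ) -> Path:
    """Write a CSV with a ``#`` metadata header block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"generator": f"troutsperm {__version__}"}
    if seed is not None:
        meta["seed"] = seed
    if cfg_hash is not None:
        meta["config_hash"] = cfg_hash
    meta.update(extra or {})
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_metadata(path: str | Path) -> dict[str, str]:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition(":")
            meta[k.strip()] = v.strip()
    return meta


@dataclasses.dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, loadable from one YAML file."""

    design: StudyDesign = dataclasses.field(default_factory=StudyDesign)
    effects: EffectConfig = dataclasses.field(default_factory=EffectConfig)
    viscosity_table: str | None = None        # path to temp_C,mu_Pa_s CSV; None = built-in water
    viscosity_mode: str = "bracket_mean"
    df_method: str = "satterthwaite"
    alpha: float = 0.05
    seed: int = 0

    def hash(self) -> str:
        return config_hash(self)


def _coerce_float_keys(d: Mapping) -> dict[float, float]:
    return {float(k): float(v) for k, v in d.items()}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a :class:`PipelineConfig` from YAML (missing keys take defaults)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    design_kw = dict(raw.get("design", {}))
    for key in ("acclimation_temps", "activation_temps"):
        if key in design_kw:
            design_kw[key] = tuple(float(t) for t in design_kw[key])
    effects_kw = dict(raw.get("effects", {}))
    for key in ("vap_median_um_s", "vap_cold_temp_multiplier", "vap_warm_temp_multiplier"):
        if key in effects_kw:
            effects_kw[key] = _coerce_float_keys(effects_kw[key])
    preset = effects_kw.pop("preset", None)
    if preset is not None:
        base = getattr(EffectConfig, preset)()
        effects = base.with_updates(**effects_kw) if effects_kw else base
    else:
        effects = EffectConfig(**effects_kw)
    top = {k: raw[k] for k in ("viscosity_table", "viscosity_mode", "df_method",
                               "alpha", "seed") if k in raw}
    return PipelineConfig(design=StudyDesign(**design_kw), effects=effects, **top)
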