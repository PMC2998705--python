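"""Pipeline configuration: the study's thresholds as defaults, plus a flat
``key = value`` config-file format (no nesting, locale-independent)."""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

from .errors import ConfigError, InputError
from .simulate import DEFAULT_REFERENCE_GENE


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults are the study settings: ANOVA/BH significance 0.01, profile
    correlation gates r > 0.8 (up) and r < −0.4 (down), fourfold-change
    annotation, 20th-percentile raw-signal filter, 0.5-cycle replicate-SD QC
    flag, and the 40S ribosomal protein S7 reference transcript."""

    seed: int = 0
    bootstrap_b: int = 1000
    alpha: float = 0.01
    r_up: float = 0.8
    r_down: float = -0.4
    fc_min: float = 4.0
    signal_percentile: float = 20.0
    qc_ct_sd: float = 0.5
    reference_gene_id: str = DEFAULT_REFERENCE_GENE

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha: must be in (0,1)")
        if not (0 < self.signal_percentile < 100):
            raise ConfigError("signal_percentile: must be in (0,100)")
        if not (-1 <= self.r_down <= self.r_up <= 1):
            raise ConfigError("r thresholds: need -1 <= r_down <= r_up <= 1")
        if self.fc_min < 1:
            raise ConfigError("fc_min: must be >= 1")
        if self.qc_ct_sd < 0:
            raise ConfigError("qc_ct_sd: must be >= 0")
        if self.bootstrap_b < 100:
            raise ConfigError("bootstrap_b: must be >= 100")


_FIELD_TYPES = {f.name: f.type for f in fields(PipelineConfig)}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key = value`` config file; unknown keys are errors."""
    values: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise InputError(f"{path}: line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in _FIELD_TYPES:
            raise ConfigError(f"{path}: line {lineno}: unknown key {key!r}")
        ftype = _FIELD_TYPES[key]
        try:
            if ftype == "int":
                values[key] = int(value)
            elif ftype == "float":
                values[key] = float(value)
            else:
                values[key] = value
        except ValueError as exc:
            raise ConfigError(f"{path}: line {lineno}: {key}: {exc}") from exc
    cfg = replace(PipelineConfig(), **values)
    cfg.validate()
    return cfg
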