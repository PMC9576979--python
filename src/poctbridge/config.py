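"""Application configuration: YAML file plus environment overrides.

The config mirrors a deployed logger box: where to listen for the analyzer,
where to forward records (exactly one sink), panel definitions and simulator
settings.  The HTTP sink token can be supplied or overridden through the
``POCTBRIDGE_TOKEN`` environment variable and is never logged.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .panels import CartridgePanel, DEFAULT_PANELS, panels_from_mapping

__all__ = ["SinkSettings", "GeneratorSettings", "AppConfig", "load_config"]

TOKEN_ENV_VAR = "POCTBRIDGE_TOKEN"


class SinkSettings(BaseModel):
    kind: Literal["file", "http"] = "file"
    # file sink
    directory: Optional[Path] = None
    format: Literal["jsonl", "csv"] = "jsonl"
    # http sink
    url: Optional[str] = None
    token: Optional[str] = None

    @model_validator(mode="after")
    def _check_kind(self) -> "SinkSettings":
        if self.kind == "file" and self.directory is None:
            raise ValueError("file sink requires 'directory'")
        if self.kind == "http":
            if self.url is None:
                raise ValueError("http sink requires 'url'")
            if self.token is None:
                env = os.environ.get(TOKEN_ENV_VAR)
                if env is None:
                    raise ValueError(
                        f"http sink requires 'token' or ${TOKEN_ENV_VAR}"
                    )
                object.__setattr__(self, "token", env)
        return self


class GeneratorSettings(BaseModel):
    seed: int = 1
    n_cg4: int = Field(default=16, ge=0)
    n_chem8: int = Field(default=10, ge=0)
    device_serial: str = "SIM-000001"


class AppConfig(BaseModel):
    listen_host: str = "0.0.0.0"
    listen_port: int = Field(default=8080, ge=1, le=65535)
    sink: Optional[SinkSettings] = None
    panels_file: Optional[Path] = None
    generator: GeneratorSettings = GeneratorSettings()
    ack_timeout_s: float = Field(default=10.0, gt=0)
    log_level: str = "INFO"

    def load_panels(self) -> dict[str, CartridgePanel]:
        if self.panels_file is None:
            return dict(DEFAULT_PANELS)
        with open(self.panels_file, encoding="utf-8") as fh:
            return panels_from_mapping(yaml.safe_load(fh))


def load_config(path: str | Path) -> AppConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return AppConfig.model_validate(data)
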