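"""Application configuration: a portable ``key = value`` text file.

CLI flags override config values; config values override the defaults
below. Recognised keys: ``store_path``, ``p_threshold``,
``default_min_bp_overlap``, ``log_level``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

__all__ = ["AppConfig", "load_config"]


@dataclass
class AppConfig:
    store_path: str = "regionkb.sqlite"
    p_threshold: float = 0.05
    default_min_bp_overlap: int = 1
    log_level: str = "WARNING"

    def __post_init__(self):
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie strictly between 0 and 1")


def load_config(path: str | os.PathLike | None) -> AppConfig:
    """Parse a key=value config file; missing file or None gives defaults."""
    cfg = {}
    if path is not None and os.path.exists(path):
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, _, val = line.partition("=")
                cfg[key.strip()] = val.strip()
    kwargs = {}
    if "store_path" in cfg:
        kwargs["store_path"] = cfg["store_path"]
    if "p_threshold" in cfg:
        kwargs["p_threshold"] = float(cfg["p_threshold"])
    if "default_min_bp_overlap" in cfg:
        kwargs["default_min_bp_overlap"] = int(cfg["default_min_bp_overlap"])
    if "log_level" in cfg:
        kwargs["log_level"] = cfg["log_level"]
    return AppConfig(**kwargs)
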