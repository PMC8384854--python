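"""TPS landmark file reader/writer.

The TPS format is the de-facto interchange format of geometric morphometrics:
one record per configuration, ``LM=k`` (2D) or ``LM3=k`` (3D) followed by one
whitespace-separated coordinate row per landmark and an ``ID=`` provenance
line.  The default 6-decimal writer round-trips bit-identically
(write -> read -> write).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List

from .geometry import LandmarkConfiguration

__all__ = ["write_tps", "read_tps"]


def write_tps(configs: Iterable[LandmarkConfiguration], path, fmt: str = "%.6f") -> None:
    """Write configurations to a TPS file.

    `fmt` controls coordinate formatting; the default keeps 6 decimals (the
    conventional TPS precision).  Pass ``"%.17g"`` for lossless output.
    """
    lines = []
    for cfg in configs:
        tag = "LM3" if cfg.ndim == 3 else "LM"
        lines.append(f"{tag}={cfg.k}")
        for row in cfg.coords:
            lines.append(" ".join(fmt % v for v in row))
        lines.append(f"ID={cfg.label}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tps(path) -> List[LandmarkConfiguration]:
    """Read a TPS file into LandmarkConfigurations (order preserved)."""
    configs: List[LandmarkConfiguration] = []
    k = None
    ndim = None
    rows: list[list[float]] = []
    label = ""

    def flush():
        nonlocal k, rows, label, ndim
        if k is None:
            return
        if len(rows) != k:
            raise ValueError(f"TPS record {label!r}: expected {k} landmarks, got {len(rows)}")
        configs.append(LandmarkConfiguration(coords=rows, label=label))
        k, ndim, rows, label = None, None, [], ""

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM3=") or upper.startswith("LM="):
            flush()
            k = int(line.split("=", 1)[1])
            ndim = 3 if upper.startswith("LM3=") else 2
        elif upper.startswith("ID="):
            label = line.split("=", 1)[1]
            flush()
        elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
            continue  # other TPS keys (SCALE=, IMAGE=, ...) are ignored
        else:
            vals = [float(v) for v in line.split()]
            if ndim is not None and len(vals) != ndim:
                raise ValueError(f"TPS row with {len(vals)} values, expected {ndim}")
            rows.append(vals)
    flush()
    return configs
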