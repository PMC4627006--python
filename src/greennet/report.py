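"""Metric report container shared by the class- and landscape-level engines."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

__all__ = ["MetricsReport"]


@dataclass
class MetricsReport:
    """Named metric values with units, at class or landscape level.

    ``entries`` maps ``(level, class_label, metric)`` presentation rows to
    ``(value, units)``; ``provenance`` records every parameter the values
    depend on (connectivity rule, thresholds, boundary flag, ...), so a run
    is reproducible from the report alone.
    """

    level: str  # "class" or "landscape"
    entries: dict[str, tuple[float, str]] = field(default_factory=dict)
    class_label: str = "all"
    provenance: dict[str, Any] = field(default_factory=dict)

    def add(self, metric: str, value: float, units: str) -> None:
        self.entries[metric] = (float(value), units)

    def __getitem__(self, metric: str) -> float:
        return self.entries[metric][0]

    def __contains__(self, metric: str) -> bool:
        return metric in self.entries

    def metrics(self) -> list[str]:
        return list(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "level": self.level,
                "class": self.class_label,
                "metric": m,
                "value": v,
                "units": u,
            }
            for m, (v, u) in self.entries.items()
        ]
        return pd.DataFrame(rows, columns=["level", "class", "metric", "value", "units"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_provenance(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.provenance, indent=2, sort_keys=True) + "\n")

    @staticmethod
    def concat_csv(reports: list["MetricsReport"], path: str | Path) -> None:
        pd.concat([r.to_frame() for r in reports], ignore_index=True).to_csv(
            path, index=False
        )
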