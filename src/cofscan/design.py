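"""Screen layout: replicates, timepoints, conditions, growth schedule."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

TIMEPOINTS = ("T0", "T1", "T2", "T3")
CONDITIONS = ("glucose", "galactose")


@dataclass(frozen=True)
class ScreenDesign:
    """Layout of a pooled competitive-growth screen.

    The pool is sampled at T0 (before the culture is split), then subjected
    to serial growth-and-dilution cycles in two parallel conditions: glucose
    (kinase repressed) and galactose (LIMK1 induced).  Each cycle grows the
    culture from OD 0.1 back to OD 1-2, i.e. roughly 3.3-4.3 pooled
    doublings; T1-T3 are sampled after cycles 1-3, so three cycles span
    ~10 pooled doublings.

    Parameters
    ----------
    n_replicates : independent replicate screens (default 3).
    doublings_per_cycle : pooled population doublings per growth cycle
        (default 3.5, the middle of the OD 0.1 -> 1-2 window).
    n_cycles : growth/dilution cycles after T0 (default 3; one timepoint per
        cycle).
    depth : sequencing reads per sample (default 1e6, >= 60x per variant).
    bottleneck_cells : optional number of cells kept at each dilution; when
        set, a binomial bottleneck resamples the pool at every cycle.
    """

    n_replicates: int = 3
    timepoints: tuple[str, ...] = TIMEPOINTS
    conditions: tuple[str, ...] = CONDITIONS
    doublings_per_cycle: float = 3.5
    n_cycles: int = 3
    depth: int = 1_000_000
    bottleneck_cells: int | None = None

    def __post_init__(self):
        if self.n_cycles != len(self.timepoints) - 1:
            raise ValueError("need exactly one timepoint per cycle plus T0")
        if self.doublings_per_cycle <= 0:
            raise ValueError("doublings_per_cycle must be positive")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")

    # ---- sample bookkeeping -------------------------------------------------

    def sample_id(self, replicate: int, condition: str, timepoint: str) -> str:
        if condition not in self.conditions:
            raise ValueError(f"unknown condition {condition!r}")
        if timepoint not in self.timepoints:
            raise ValueError(f"unknown timepoint {timepoint!r}")
        return f"rep{replicate}_{condition}_{timepoint}"

    def samples(self) -> list[tuple[int, str, str]]:
        """(replicate, condition, timepoint) for every sample, T0 included.

        T0 precedes the culture split, but it is carried per condition so
        that each (replicate, condition, timepoint) maps to exactly one
        sample; both conditions of a replicate share identical T0
        frequencies.
        """
        return [
            (r, c, t)
            for r in range(1, self.n_replicates + 1)
            for c in self.conditions
            for t in self.timepoints
        ]

    def sample_ids(self) -> list[str]:
        return [self.sample_id(r, c, t) for r, c, t in self.samples()]

    def doublings_at(self, timepoint: str) -> float:
        """Cumulative pooled doublings elapsed at a timepoint (T0 = 0)."""
        return self.timepoints.index(timepoint) * self.doublings_per_cycle

    # ---- YAML round trip ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["timepoints"] = list(self.timepoints)
        d["conditions"] = list(self.conditions)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenDesign":
        d = yaml.safe_load(Path(path).read_text())
        d["timepoints"] = tuple(d.get("timepoints", TIMEPOINTS))
        d["conditions"] = tuple(d.get("conditions", CONDITIONS))
        return cls(**d)
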