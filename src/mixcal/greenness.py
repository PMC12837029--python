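"""Multi-criteria solvent greenness scoring and radar-table export.

Each solvent is scored 1 (least favorable) to 10 (most favorable) on five
safety/environmental criteria; the index is the (optionally weighted) mean
score normalized to [0, 1].  Published whole-method scores obtained from
external tools (e.g. AGREE, BAGI) can be recorded alongside but are never
computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["CRITERIA", "SolventProfile", "greenness_index", "radar_table"]

CRITERIA = (
    "toxicity",
    "flammability",
    "environmental_impact",
    "volatility_exposure",
    "corrosiveness",
)


@dataclass(frozen=True)
class SolventProfile:
    name: str
    toxicity: int
    flammability: int
    environmental_impact: int
    volatility_exposure: int
    corrosiveness: int

    def __post_init__(self):
        for c in CRITERIA:
            v = getattr(self, c)
            if not (isinstance(v, (int,)) and 1 <= v <= 10):
                raise ValueError(f"{self.name}: criterion {c} must be an integer in [1, 10]")

    @property
    def scores(self) -> tuple[int, ...]:
        return tuple(getattr(self, c) for c in CRITERIA)


def greenness_index(
    profile: SolventProfile,
    weights: tuple[float, ...] | None = None,
    rescale: bool = False,
) -> float:
    """Weighted mean score / 10 (equal weights by default), in [0.1, 1.0].

    ``rescale=True`` min-max rescales scores from [1, 10] onto [0, 1] first,
    so the index spans the full unit interval.
    """
    scores = profile.scores
    if weights is None:
        weights = (1.0 / len(CRITERIA),) * len(CRITERIA)
    else:
        if len(weights) != len(CRITERIA):
            raise ValueError(f"need {len(CRITERIA)} weights")
        if any(w < 0 for w in weights):
            raise ValueError("weights must be >= 0")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
    if rescale:
        vals = [(s - 1) / 9.0 for s in scores]
        return float(sum(w * v for w, v in zip(weights, vals)))
    return float(sum(w * s for w, s in zip(weights, scores)) / 10.0)


def radar_table(profiles: list[SolventProfile]) -> pd.DataFrame:
    """Long-format (solvent, criterion, score) table for radar plotting."""
    if not profiles:
        raise ValueError("need at least one solvent profile")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate solvent names")
    rows = [
        {"solvent": p.name, "criterion": c, "score": getattr(p, c)}
        for p in profiles
        for c in CRITERIA
    ]
    return pd.DataFrame(rows)


def profiles_from_table(table: pd.DataFrame) -> list[SolventProfile]:
    """Inverse of :func:`radar_table` (lossless round trip)."""
    out = []
    for name, grp in table.groupby("solvent", sort=False):
        kw = {row["criterion"]: int(row["score"]) for _, row in grp.iterrows()}
        out.append(SolventProfile(name=name, **kw))
    return out
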