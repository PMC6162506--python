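"""Synthetic flow-cytometry event generator.

Real cytometry pulse signals have Gaussian-like intensity traces, and a
stained population forms a roughly Gaussian cluster in channel space; the
generator therefore draws each population from a multivariate normal over
the six channels (FSC, SSC, FITC, PE, APC, PerCP), adds a detector noise
floor, truncates negative intensities to zero and attaches class labels.

Two ready-made mixtures mirror the compositions used throughout the
package's experiments: a four-population peripheral-blood mixture
(lymphocytes / neutrophils / monocytes / debris at 110:172:30:88) and a
three-population lymphocyte sub-mixture (T / B / NK at 306:232:62).
Cluster locations are fixture constants chosen so the populations
separate principally in the (FITC, SSC) plane, with deliberate mild
overlap between lymphocytes and debris so that classification is
non-trivial and parameter tuning matters.

Per-population event counts use largest-remainder apportionment (with a
floor of one event per population), so class counts are exact and
deterministic rather than multinomial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .events import EventTable

__all__ = [
    "PopulationSpec",
    "MixtureSpec",
    "default_pbmc_mixture",
    "default_lymphocyte_mixture",
    "generate",
    "apportion",
    "load_mixture",
    "save_mixture",
]

CHANNELS = ["FSC", "SSC", "FITC", "PE", "APC", "PerCP"]


@dataclass
class PopulationSpec:
    """One cell population: mixing proportion and Gaussian cluster shape."""

    name: str
    proportion: float
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not 0 < self.proportion <= 1:
            raise ValueError(f"{self.name}: proportion must lie in (0, 1]")
        if self.covariance.shape != (self.mean.size, self.mean.size):
            raise ValueError(f"{self.name}: covariance shape mismatch")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError(f"{self.name}: covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariance).min() < -1e-10:
            raise ValueError(f"{self.name}: covariance must be positive semidefinite")

    @classmethod
    def from_spreads(
        cls, name: str, proportion: float, mean: Sequence[float], sd: Sequence[float]
    ) -> "PopulationSpec":
        """Diagonal-covariance population from per-channel standard deviations."""
        sd = np.asarray(sd, dtype=float)
        return cls(name, proportion, np.asarray(mean, dtype=float), np.diag(sd**2))


@dataclass
class MixtureSpec:
    """Channel roster, population list and global noise model."""

    channel_names: list[str]
    populations: list[PopulationSpec]
    noise_floor: float = 0.0  # additive white-noise s.d., intensity units
    truncate_at_zero: bool = True

    def __post_init__(self) -> None:
        total = sum(p.proportion for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population proportions sum to {total}, not 1")
        n_ch = len(self.channel_names)
        for p in self.populations:
            if p.mean.size != n_ch:
                raise ValueError(f"{p.name}: mean length != {n_ch} channels")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be nonnegative")

    @property
    def label_names(self) -> list[str]:
        return [p.name for p in self.populations]


# Cluster means/spreads below are fixture constants (arbitrary intensity
# units on a 0-1000 scale), placed so (FITC, SSC) separates the groups
# while debris's broad FITC tail brushes the lymphocyte cluster.
_PBMC = [
    ("lymphocyte", 110 / 400, [300, 130, 580, 210, 300, 160], [45, 35, 100, 50, 60, 40]),
    ("neutrophil", 172 / 400, [560, 640, 140, 120, 100, 110], [70, 80, 45, 40, 35, 35]),
    ("monocyte", 30 / 400, [620, 380, 360, 420, 210, 130], [60, 55, 55, 60, 45, 40]),
    ("debris", 88 / 400, [220, 110, 500, 140, 160, 110], [120, 90, 190, 85, 75, 65]),
]

_LYMPHOCYTE = [
    ("T", 306 / 600, [310, 130, 650, 120, 110, 140], [40, 30, 60, 40, 35, 35]),
    ("B", 232 / 600, [300, 125, 130, 640, 120, 150], [40, 30, 45, 65, 35, 35]),
    ("NK", 62 / 600, [320, 140, 140, 130, 620, 130], [45, 32, 45, 40, 65, 35]),
]


def _build(roster) -> MixtureSpec:
    pops = [
        PopulationSpec.from_spreads(name, prop, mean, sd)
        for name, prop, mean, sd in roster
    ]
    largest_mean = max(float(np.max(p.mean)) for p in pops)
    return MixtureSpec(list(CHANNELS), pops, noise_floor=0.02 * largest_mean)


def default_pbmc_mixture() -> MixtureSpec:
    """Four-population peripheral-blood mixture at proportions
    0.275 / 0.43 / 0.075 / 0.22 (lymphocyte / neutrophil / monocyte / debris)."""
    return _build(_PBMC)


def default_lymphocyte_mixture() -> MixtureSpec:
    """Three-population lymphocyte sub-mixture (T / B / NK) at
    proportions 0.51 / 0.3867 / 0.1033."""
    return _build(_LYMPHOCYTE)


def apportion(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Largest-remainder apportionment of ``n`` among ``proportions``,
    with a floor of one unit per population (requires ``n >= len(p)``)."""
    p = np.asarray(proportions, dtype=float)
    if n < p.size:
        raise ValueError(f"n={n} smaller than the number of populations ({p.size})")
    quotas = n * p
    counts = np.floor(quotas).astype(int)
    remainders = quotas - counts
    # hand out the leftover units to the largest remainders (stable order)
    for idx in np.argsort(-remainders, kind="stable")[: n - counts.sum()]:
        counts[idx] += 1
    while (counts == 0).any():
        counts[int(np.argmax(counts))] -= 1
        counts[int(np.argmin(counts))] += 1
    return counts


def generate(spec: MixtureSpec, n: int, seed: int) -> EventTable:
    """Draw a labeled event table of exactly ``n`` events.

    Counts per population come from :func:`apportion`; events are drawn
    from each population's Gaussian, white noise of s.d. ``noise_floor``
    is added, negatives are truncated at zero when ``truncate_at_zero``,
    and rows are shuffled by the seeded generator.
    """
    rng = np.random.default_rng(seed)
    counts = apportion(n, [p.proportion for p in spec.populations])
    blocks, labels = [], []
    for k, (pop, count) in enumerate(zip(spec.populations, counts)):
        x = rng.multivariate_normal(pop.mean, pop.covariance, size=count)
        if spec.noise_floor > 0:
            x = x + rng.normal(0.0, spec.noise_floor, size=x.shape)
        blocks.append(x)
        labels.append(np.full(count, k, dtype=int))
    values = np.vstack(blocks)
    labels = np.concatenate(labels)
    if spec.truncate_at_zero:
        np.maximum(values, 0.0, out=values)
    order = rng.permutation(n)
    return EventTable(values[order], list(spec.channel_names), labels[order], spec.label_names)


def save_mixture(spec: MixtureSpec, path: str | Path) -> None:
    doc = {
        "channel_names": spec.channel_names,
        "noise_floor": spec.noise_floor,
        "truncate_at_zero": spec.truncate_at_zero,
        "populations": [
            {
                "name": p.name,
                "proportion": p.proportion,
                "mean": p.mean.tolist(),
                "covariance": p.covariance.tolist(),
            }
            for p in spec.populations
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc))


def load_mixture(path: str | Path) -> MixtureSpec:
    doc = yaml.safe_load(Path(path).read_text())
    return MixtureSpec(
        channel_names=list(doc["channel_names"]),
        populations=[
            PopulationSpec(
                p["name"], p["proportion"], np.asarray(p["mean"]), np.asarray(p["covariance"])
            )
            for p in doc["populations"]
        ],
        noise_floor=float(doc.get("noise_floor", 0.0)),
        truncate_at_zero=bool(doc.get("truncate_at_zero", True)),
    )
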