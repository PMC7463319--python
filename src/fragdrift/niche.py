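"""Climate-suitability utilities: Kappa thresholds, niche overlap, delta-CSI.

These operate on already-computed habitat-suitability values — a per-site
climate suitability index (CSI, the modelled probability of occurrence
under current and future climate) and gridded suitability surfaces.  The
species-distribution model that produces them is upstream and out of scope
here; the utilities cover the post-model arithmetic:

* Cohen's Kappa of thresholded predictions against presence/absence
  labels, and the Kappa-maximising threshold over a probability grid;
* binary niche overlap between a current and a future surface, normalised
  by the current niche (the fraction of today's suitable area that stays
  suitable), with Schoener's D on the mass-normalised surfaces as a
  continuous companion;
* per-site percent change in suitability, delta-CSI = 100 * (future -
  current)/current, printed to one decimal with half-away-from-zero
  rounding.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "SuitabilityRecord",
    "ThresholdedNiche",
    "cohen_kappa",
    "best_threshold",
    "niche_overlap",
    "schoener_d",
    "delta_csi",
    "delta_csi_table",
    "load_site_suitability",
    "read_surface",
    "write_surface",
]


@dataclass(frozen=True)
class SuitabilityRecord:
    """A site with current and future climate suitability indices."""

    site: str
    csi_current: float
    csi_future: float

    def __post_init__(self) -> None:
        for v in (self.csi_current, self.csi_future):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"CSI must lie in [0, 1] for site {self.site!r}")


@dataclass(frozen=True)
class ThresholdedNiche:
    """A suitability surface binarised at a probability threshold."""

    threshold: float
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


def cohen_kappa(predictions, labels, threshold: float) -> float:
    """Cohen's kappa of thresholded suitability predictions vs labels."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("kappa undefined: labels contain a single class")
    pred = (np.asarray(predictions, dtype=float) >= threshold).astype(int)
    return float(cohen_kappa_score(labels, pred))


def best_threshold(predictions, labels, grid_step: float = 0.01) -> tuple[float, float]:
    """Kappa-maximising threshold over a regular probability grid.

    Returns (threshold, kappa); ties break toward the lower threshold.
    """
    if not 0.0 < grid_step < 1.0:
        raise ValueError("grid step must lie in (0, 1)")
    grid = np.arange(grid_step, 1.0, grid_step)
    best_t, best_k = grid[0], -np.inf
    for t in grid:
        k = cohen_kappa(predictions, labels, float(t))
        if k > best_k + 1e-12:
            best_t, best_k = float(t), k
    return best_t, best_k


def niche_overlap(current: np.ndarray, future: np.ndarray, threshold: float) -> float:
    """Fraction of the current niche that remains suitable in the future.

    |cells >= threshold in both| / |cells >= threshold in current|; the
    asymmetric normalisation answers "how much of today's suitable area
    survives".  Raises if the current niche is empty.
    """
    current = np.asarray(current, dtype=float)
    future = np.asarray(future, dtype=float)
    if current.shape != future.shape:
        raise ValueError("surfaces must share a grid")
    cur = current >= threshold
    if not cur.any():
        raise ValueError("current niche is empty at this threshold")
    fut = future >= threshold
    return float((cur & fut).sum() / cur.sum())


def schoener_d(current: np.ndarray, future: np.ndarray) -> float:
    """Schoener's D = 1 - 0.5 * sum |p1 - p2| on mass-normalised surfaces."""
    p1 = np.asarray(current, dtype=float).ravel()
    p2 = np.asarray(future, dtype=float).ravel()
    p1 = p1 / p1.sum()
    p2 = p2 / p2.sum()
    return float(1.0 - 0.5 * np.abs(p1 - p2).sum())


def _round_half_away(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)) * (
        -1.0 if x < 0 else 1.0
    )


def delta_csi(record: SuitabilityRecord) -> float:
    """Percent change in climate suitability, to one decimal.

    100 * (future - current)/current, rounded half-away-from-zero (the
    convention of the published site tables).  Undefined for a zero
    current index.
    """
    if record.csi_current == 0:
        raise ValueError(f"delta-CSI undefined for zero current CSI ({record.site!r})")
    pct = 100.0 * (record.csi_future - record.csi_current) / record.csi_current
    return _round_half_away(pct, 1)


def delta_csi_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``delta_csi`` column to a table with csi_current/csi_future."""
    out = df.copy()
    out["delta_csi"] = [
        delta_csi(SuitabilityRecord(str(r.get("site", i)), r["csi_current"], r["csi_future"]))
        for i, r in df.iterrows()
    ]
    return out


def load_site_suitability() -> pd.DataFrame:
    """Bundled per-site suitability table for the studied Banksia marginata
    remnants: site name, code, group (fragmented/unmodified), current and
    future (2090s, RCP 8.5) climate suitability index, and the published
    percent change."""
    with importlib.resources.files("fragdrift.data").joinpath(
        "site_suitability.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def write_surface(surface: np.ndarray, path: str | Path) -> None:
    """Plain-text grid: one row per line, whitespace-separated."""
    np.savetxt(path, np.asarray(surface, dtype=float), fmt="%.6f")


def read_surface(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=float)
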