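"""Bundled study-site tables for the Banksia marginata remnant survey.

Small plain-text tables shipped with the package: sampling-site locations
with sample and census sizes, and per-site microsatellite diversity
summaries (mean alleles, rarefied richness, He, Ho, FIS, clone counts).
They parameterise the synthetic generators (a site's He and allele count
profile) and the drift-simulation founding pools; the climate-suitability
table lives in :mod:`fragdrift.niche`.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .genotypes import SiteInfo

__all__ = ["load_sites", "load_site_diversity"]


def _read(name: str) -> pd.DataFrame:
    with importlib.resources.files("fragdrift.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_sites() -> list[SiteInfo]:
    """Sampling sites: code, WGS84 coordinates, census size."""
    df = _read("sites.tsv")
    return [
        SiteInfo(
            code=str(r["code"]),
            latitude=float(r["latitude"]),
            longitude=float(r["longitude"]),
            census=str(r["census"]),
        )
        for _, r in df.iterrows()
    ]


def load_site_diversity() -> pd.DataFrame:
    """Per-site diversity summary (A, r, He, Ho, FIS, clone count), indexed
    by site code."""
    return _read("site_diversity.tsv").set_index("code")
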