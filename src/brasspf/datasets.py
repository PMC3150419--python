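"""Packaged example schedules: five Indian provinces, 1996-1998.

Period ASFRs come from the Sample Registration System (SRS, 1997 vintage)
and mean children ever born from the 1998 Demographic and Health Survey;
both are transcribed from the published worked-example tables.  The CEB
standard errors behind the published stochastic runs were never released,
so these fixtures support the deterministic adjustment only.
"""

from __future__ import annotations

from importlib import resources

PROVINCES = ("bihar", "uttar_pradesh", "goa", "madhya_pradesh", "tamil_nadu")


def list_provinces() -> tuple:
    return PROVINCES


def province_path(name: str):
    """Filesystem path of a packaged province CSV."""
    key = name.lower().replace(" ", "_").replace("-", "_")
    if key not in PROVINCES:
        raise KeyError(f"unknown province {name!r}; available: {PROVINCES}")
    return resources.files("brasspf.data") / f"{key}.csv"


def load_province(name: str):
    """Load one province as ``(FertilitySchedule, ParitySchedule)``."""
    from .io import read_schedule_csv

    return read_schedule_csv(province_path(name), schema="combined")


def load_all_provinces() -> dict:
    """All five provinces, keyed by name."""
    return {name: load_province(name) for name in PROVINCES}
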