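"""Bundled reference datasets.

Small text fixtures transcribed from the published study of magnetic-pulse
treated pear (*Pyrus communis* L.) microplants: the 89-metabolite GC-MS
inventory, the relative-intensity table of the two unknown silylated
carbohydrate peaks CB(A)/CB(B) against the 4-desoxy- and 2-deoxy-D-glucose
standards, the theoretical intensities of those ions, and the printed
group summaries of the intensity and m/z ANOVA comparison.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from .chemometrics import GroupSummary
from .spectra import (
    IonKey,
    MetaboliteRecord,
    SpectrumLibrary,
    parse_metabolite_table,
    read_msp,
)

__all__ = [
    "load_metabolite_table",
    "load_carbohydrate_library",
    "load_theoretical_intensities",
    "CARBOHYDRATE_ION_KEYS",
    "FULL_ION_KEYS",
    "INTENSITY_SUMMARY_CBA",
    "INTENSITY_SUMMARY_CBB",
    "MZ_SUMMARY_CBA",
    "MZ_SUMMARY_CBB",
]

#: The six common carbohydrate product-ion slots used for the CB(A)/CB(B)
#: comparison (slashed pairs are one slot; the primary mass wins).
CARBOHYDRATE_ION_KEYS = tuple(
    IonKey.parse(s) for s in ("45", "73", "103", "147", "205/204", "361/359")
)

#: The full 15-slot ion set used when correlating silylated-carbohydrate
#: spectra against library standards.
FULL_ION_KEYS = tuple(
    IonKey.parse(s)
    for s in (
        "45", "73", "103", "117", "129/133", "147", "189/191", "205",
        "217", "243/245", "271", "305/308", "319/320", "331/333", "359/361",
    )
)

# Printed group summaries of the CB(A)/CB(B) relative-intensity and m/z
# datasets (sample standard deviations, denominator n-1).
INTENSITY_SUMMARY_CBA = GroupSummary(n=10, mean=22.69459, sd=30.22574)
INTENSITY_SUMMARY_CBB = GroupSummary(n=16, mean=18.47876, sd=24.44037)
MZ_SUMMARY_CBA = GroupSummary(n=10, mean=221.2, sd=237.09623)
MZ_SUMMARY_CBB = GroupSummary(n=16, mean=201.875, sd=97.17261)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("sdmet").joinpath("data", name)))


def load_metabolite_table() -> list[MetaboliteRecord]:
    """The 89-row metabolite inventory (names and retention times verbatim,
    including the source's typographic quirks)."""
    return parse_metabolite_table(_data_path("table1_metabolites.csv"))


def load_carbohydrate_library() -> SpectrumLibrary:
    """Relative-intensity spectra of CB_A, CB_B, 4DG and 2DG over the six
    common product ions."""
    return read_msp(_data_path("table4_carbohydrates.msp"))


def load_theoretical_intensities() -> dict[int, float]:
    """Theoretical intensities (2.6388e-17 * sqrt(D_QC)) keyed by m/z."""
    payload = json.loads(_data_path("table4_itheor.json").read_text())
    return {int(k): float(v) for k, v in payload["itheor"].items()}
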