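"""Bundled example datasets.

``rp_table2`` — 216 retinitis pigmentosa patients at the Massachusetts
Eye and Ear Infirmary, classified by genetic type (DOM, AR, SL, ISO) and
number of affected eyes; the standard worked example for the homogeneity
tests.

``ome_table4`` / ``ome_mstar`` — a 24-child otitis media with effusion
(OME) trial, 14-day status by age group.  The source reports this dataset
twice with disagreeing counts for the oldest age group (N = 31 vs
N = 37); both presentations are shipped and neither is privileged.  Use
for demonstration only.
"""

from __future__ import annotations

from .table import BilateralTable

__all__ = ["load", "rp_table2", "ome_table4", "ome_mstar", "FIXTURES"]


def rp_table2() -> BilateralTable:
    """Retinitis pigmentosa: affected eyes (0/1/2) by genetic type."""
    return BilateralTable(
        [[15, 7, 3, 67],
         [6, 5, 2, 24],
         [7, 9, 14, 57]],
        labels=["DOM", "AR", "SL", "ISO"],
    )


def ome_table4() -> BilateralTable:
    """OME status at 14 days by age group (tabular presentation, N=31)."""
    return BilateralTable(
        [[2, 5, 6],
         [2, 1, 0],
         [11, 3, 1]],
        labels=["<2y", "2-5y", ">=6y"],
    )


def ome_mstar() -> BilateralTable:
    """OME data as the flat column-major vector presentation (N=37)."""
    return BilateralTable.from_flat(
        (2, 2, 11, 5, 1, 3, 6, 0, 7),
        labels=["<2y", "2-5y", ">=6y"],
    )


FIXTURES = {
    "rp_table2": rp_table2,
    "ome_table4": ome_table4,
    "ome_mstar": ome_mstar,
}


def load(name: str) -> BilateralTable:
    """Load a bundled dataset by name."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
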