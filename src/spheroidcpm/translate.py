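"""Translation of RT-qPCR relative quantities (RQ) into model parameters.

Zone-specific parameters derive from day-7 gene expression: Col1a1 sets the
structural-ECM secretion probability P_ECMst, Col2a1 sets P_ECMv, Mmp13 (a
collagenase) sets the ECM decay speed v_d, Pcna sets the growth speed v_g,
ItgaV sets the cell–ECM contact energy, and Cdh2 (N-cadherin) sets J(cell-cell)
*inversely* — more cadherin means stronger adhesion, i.e. lower contact energy.

The conversion is anchored linear scaling: each parameter has an anchor pair
(reference value, reference RQ); a proportional parameter scales as
``value = anchor_value · rq / anchor_rq`` and an inverse one as
``value = anchor_value · anchor_rq / rq``.  Applied to the bundled RQ ratios,
this reproduces every zone-specific published parameter value.

The bundled :func:`default_rq_table` is *synthetic*: it is back-solved from the
published parameter columns (SZ = 1 by convention), not measured data, and
exists so the translation path can be exercised and round-trip-tested without
the wet-lab RQ values.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .params import ParameterSet, Zone, build_parameter_set

PROPORTIONAL = "proportional"
INVERSE = "inverse"


@dataclass(frozen=True)
class TranslationAnchor:
    """Anchored linear conversion for one parameter."""

    parameter: str          # ParameterSet field name
    gene: str
    direction: str          # proportional | inverse
    anchor_value: float     # parameter value in the reference zone
    anchor_rq: float = 1.0  # RQ of the reference zone (SZ at day 7)

    def __post_init__(self) -> None:
        if self.direction not in (PROPORTIONAL, INVERSE):
            raise ValueError("direction must be 'proportional' or 'inverse'")
        if self.anchor_rq <= 0:
            raise ValueError("anchor RQ must be positive")


DEFAULT_ANCHORS: tuple[TranslationAnchor, ...] = (
    TranslationAnchor("P_ECMst", "Col1a1", PROPORTIONAL, 3.2),
    TranslationAnchor("P_ECMv", "Col2a1", PROPORTIONAL, 3.2),
    TranslationAnchor("v_d", "Mmp13", PROPORTIONAL, 0.003),
    TranslationAnchor("v_g", "Pcna", PROPORTIONAL, 0.080),
    TranslationAnchor("J_cell_cell", "Cdh2", INVERSE, 5.0),
    TranslationAnchor("J_cell_ecm", "ItgaV", PROPORTIONAL, 10.0),
)

# Synthetic day-7 RQ ratios back-solved from the published parameter columns
# (reference: SZ = 1.0).  Not measured data.
_BACKSOLVED_RQ = {
    "Cdh2": {"SZ": 1.0, "MZ": 2.0, "DZ": 2.0},
    "Col1a1": {"SZ": 1.0, "MZ": 0.67 / 3.2, "DZ": 3.0 / 3.2},
    "Col2a1": {"SZ": 1.0, "MZ": 9.3 / 3.2, "DZ": 8.3 / 3.2},
    "Mmp13": {"SZ": 1.0, "MZ": 9.0, "DZ": 0.097 / 0.003},
    "Pcna": {"SZ": 1.0, "MZ": 0.75, "DZ": 0.75},
    "ItgaV": {"SZ": 1.0, "MZ": 1.0, "DZ": 1.0},
}


def default_rq_table(day: int = 7) -> pd.DataFrame:
    """Synthetic back-solved RQ table (columns: zone, gene, day, rq)."""
    rows = [(zone, gene, day, rq)
            for gene, per_zone in _BACKSOLVED_RQ.items()
            for zone, rq in per_zone.items()]
    return pd.DataFrame(rows, columns=["zone", "gene", "day", "rq"])


def rq_to_parameter(rq: float, anchor: TranslationAnchor) -> float:
    """Convert one RQ value to a parameter value via its anchor."""
    if rq <= 0:
        raise ValueError(f"RQ must be positive, got {rq}")
    if anchor.direction == PROPORTIONAL:
        return anchor.anchor_value * (rq / anchor.anchor_rq)
    return anchor.anchor_value * (anchor.anchor_rq / rq)


def translate_parameters(rq_table: pd.DataFrame, zone: Zone | str,
                         anchors: tuple[TranslationAnchor, ...] = DEFAULT_ANCHORS,
                         day: int = 7) -> dict[str, float]:
    """Parameter overrides for ``zone`` from an RQ table (zone, gene, day, rq)."""
    zone = Zone.coerce(zone)
    sub = rq_table[(rq_table["zone"] == zone.value) & (rq_table["day"] == day)]
    rq_of = dict(zip(sub["gene"], sub["rq"]))
    out = {}
    for anchor in anchors:
        if anchor.gene in rq_of:
            out[anchor.parameter] = rq_to_parameter(float(rq_of[anchor.gene]), anchor)
    return out


def translated_parameter_set(zone: Zone | str,
                             rq_table: pd.DataFrame | None = None,
                             day: int = 7) -> ParameterSet:
    """Full parameter set for ``zone`` with RQ-derived values applied on top."""
    table = rq_table if rq_table is not None else default_rq_table(day)
    return build_parameter_set(zone, translate_parameters(table, zone, day=day))
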