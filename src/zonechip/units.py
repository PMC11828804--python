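"""Unit conversions used at CLI/config boundaries.

Internally everything is SI (m, s, mol/m³, Pa). User-facing interfaces speak
the conventions of the microfluidics lab bench: µL/min for pump rates, %O2
for gas levels, mM for media glucose (1 mM = 1 mol/m³), mm for dimensions.
"""

from __future__ import annotations

UL_PER_MIN_TO_M3_PER_S = 1e-9 / 60.0


def ul_min_to_m3s(q_ul_min: float) -> float:
    """Convert a flow rate from µL/min to m³/s."""
    return q_ul_min * UL_PER_MIN_TO_M3_PER_S


def m3s_to_ul_min(q_m3s: float) -> float:
    """Convert a flow rate from m³/s to µL/min."""
    return q_m3s / UL_PER_MIN_TO_M3_PER_S


def mm(x_m: float) -> float:
    """Metres → millimetres (for log/pretty-print output only)."""
    return x_m * 1e3
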