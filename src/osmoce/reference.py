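"""Reported osmotic-strain reference values for cartilage under clearing agents.

Published cumulative axial-strain extrema (600 s of observation, costal
cartilage) for glycerol-water solutions of several concentrations and for
~40% iohexol (Omnipaque), as reported in the phase-resolved OCE literature.
These are literature inputs, not quantities this package computes; they are
used for sanity ratios between concentration regimes and for anchoring the
simulator's default strain magnitudes.
"""

from __future__ import annotations

__all__ = ["REPORTED_EXTREMA", "extrema_ratio"]

#: cumulative-strain extrema {agent: {"max": dilatation, "min": shrinkage}};
#: None marks values not determinable (minimum deeper than the analyzable range)
REPORTED_EXTREMA: dict[str, dict[str, float | None]] = {
    "saline": {"max": 3e-4, "min": None},
    "glycerol_7": {"max": 2.5e-3, "min": None},
    "glycerol_25": {"max": None, "min": -0.006},
    "glycerol_35": {"max": 0.20, "min": -0.14},
    "glycerol_100": {"max": 0.4, "min": -0.36},
    "omnipaque": {"max": 0.15, "min": -0.06},
    "glycerol_elution": {"max": None, "min": -1.6e-3},
}

#: mean amplitude of the thin (~60-80 µm) subsurface shrinkage layer seen for
#: weakly hyper/hypotonic solutions
SUBSURFACE_SHRINKAGE = {
    "saline": 0.05,
    "glycerol_7": 0.06,
    "distilled_water": 0.04,
}


def extrema_ratio(agent_a: str, agent_b: str, which: str = "min") -> float:
    """|extremum(a)| / |extremum(b)| for two concentration regimes."""
    va = REPORTED_EXTREMA[agent_a][which]
    vb = REPORTED_EXTREMA[agent_b][which]
    if va is None or vb is None:
        raise ValueError("extremum not determinable for one of the agents")
    return abs(va) / abs(vb)
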