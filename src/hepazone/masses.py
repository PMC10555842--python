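"""Mass arithmetic for the three-channel dimethyl multiplexing scheme.

Multiplexed DIA co-analyses a dimethyl-labelled bulk reference proteome
(the Δ0 channel) together with two labelled single-cell samples (Δ4 and
Δ8) in a single run.  Each channel carries a dimethyl group on peptide
N-termini and lysine side chains, built from a different isotopologue of
formaldehyde and cyanoborohydride:

* Δ0 — CH2O  + NaBH3CN : adds C2H4 per labelling site
* Δ4 — CD2O  + NaBH3CN : four hydrogens replaced by deuterium
* Δ8 — 13CD2O + NaBD3CN : two 13C and six deuterium substitutions

The channel spacings are therefore pure isotope mass differences and can
be computed exactly from a pinned monoisotopic mass table, which makes
them a self-contained analytic check of the labelling design.
"""

from __future__ import annotations

__all__ = ["MONOISOTOPIC_DA", "dimethyl_shift", "channel_table"]

# Monoisotopic masses in Da (CODATA/AME-derived standard values, >=6 decimals).
MONOISOTOPIC_DA: dict[str, float] = {
    "H": 1.0078250319,   # 1H
    "D": 2.0141017781,   # 2H
    "C12": 12.0,         # 12C (exact by definition)
    "C13": 13.0033548378,
    "N": 14.0030740052,
    "O": 15.9949146221,
}

_VALID_CHANNELS = (0, 4, 8)


def dimethyl_shift(channel: int) -> float:
    """Mass value (Da) printed for a dimethyl channel.

    ``channel=0`` returns the fixed-modification mass of double light
    dimethylation (one C2H4 addition per site, 28.0313 Da).  ``channel=4``
    and ``channel=8`` return the spacing of that channel from the Δ0
    reference: 4·(m(D)−m(H)) and 2·(m(13C)−m(12C)) + 6·(m(D)−m(H)).

    Full double precision is returned; round to 4 decimals for display.
    """
    m = MONOISOTOPIC_DA
    if channel == 0:
        return 2.0 * m["C12"] + 4.0 * m["H"]
    if channel == 4:
        return 4.0 * (m["D"] - m["H"])
    if channel == 8:
        return 2.0 * (m["C13"] - m["C12"]) + 6.0 * (m["D"] - m["H"])
    raise ValueError(f"unknown dimethyl channel {channel!r}; expected one of {_VALID_CHANNELS}")


def channel_table() -> dict[int, float]:
    """All three channel mass values, keyed by channel label."""
    return {c: dimethyl_shift(c) for c in _VALID_CHANNELS}
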