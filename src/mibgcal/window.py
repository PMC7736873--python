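"""Photopeak energy-window representation and text parsing.

Acquisition protocols write the 123I photopeak window as ``center keV ±
half-width %`` in several dialects ("159 ± 10%", "159keV±10%", "159:10");
all are accepted. The center is matched exactly when windows are compared
— 158 keV is not rounded to 159.
"""

from __future__ import annotations

import re
from dataclasses import dataclass


@dataclass(frozen=True)
class EnergyWindow:
    """Photopeak acceptance window: ``center_kev`` ± ``halfwidth_pct`` %."""

    center_kev: float = 159.0
    halfwidth_pct: float = 10.0

    def __post_init__(self) -> None:
        if self.halfwidth_pct <= 0:
            raise ValueError("energy-window half-width must be positive")
        if self.center_kev <= 0:
            raise ValueError("energy-window center must be positive")

    def __str__(self) -> str:
        c = f"{self.center_kev:g}"
        return f"{c} keV ± {self.halfwidth_pct:g}%"


_WINDOW_RE = re.compile(
    r"""^\s*(?P<center>\d+(?:\.\d+)?)\s*(?:k(?:eV)?)?\s*
        (?:±|\+/?-|:)\s*
        (?P<half>\d+(?:\.\d+)?)\s*%?\s*$""",
    re.IGNORECASE | re.VERBOSE,
)


def parse_window(text) -> EnergyWindow | None:
    """Parse an energy-window description; ``None`` for missing data.

    Accepts :class:`EnergyWindow` (returned unchanged), ``(center, half)``
    pairs, and the textual dialects above. Empty/NA text parses to ``None``
    (missing); unparseable non-empty text raises ``ValueError``.
    """
    if text is None:
        return None
    if isinstance(text, EnergyWindow):
        return text
    if isinstance(text, (tuple, list)) and len(text) == 2:
        return EnergyWindow(float(text[0]), float(text[1]))
    s = str(text).strip()
    if s == "" or s.lower() in {"na", "nan", "none", "missing", "-"}:
        return None
    m = _WINDOW_RE.match(s)
    if not m:
        raise ValueError(f"cannot parse energy window: {text!r}")
    return EnergyWindow(float(m.group("center")), float(m.group("half")))
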