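"""Taxonomy of elementary information processes (EIPs).

Strategy cost is operationalized as a count of atomic mental operations in
the classic process-tracing tradition: reading a piece of information,
comparing two quantities, taking a difference, adding, multiplying (or
dividing), eliminating an item from consideration, and announcing a choice.
"""

from __future__ import annotations

import enum

__all__ = ["Eip"]


class Eip(str, enum.Enum):
    READ = "READ"
    COMPARE = "COMPARE"
    DIFFERENCE = "DIFFERENCE"
    ADD = "ADD"
    PRODUCT = "PRODUCT"
    ELIMINATE = "ELIMINATE"
    CHOOSE = "CHOOSE"
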