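"""Ordinal Demirjian calcification stages.

Permanent-tooth development on a panoramic radiograph is graded into eight
calcification stages A-H (A = first cusp-tip calcification, H = root apex
closed, i.e. the tooth is fully developed).  A ninth pre-calcification state,
"0" (crypt visible, no calcification), precedes A.  A tooth that cannot be
scored at all (absent, unreadable) carries the distinct MISSING marker, which
is *not* ordered with the true stages.
"""

from __future__ import annotations

import enum
from functools import total_ordering


@total_ordering
class StageCode(enum.Enum):
    """One tooth's developmental stage: 0 < A < B < ... < H, plus MISSING."""

    CRYPT = "0"
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"
    G = "G"
    H = "H"
    MISSING = "NA"

    @property
    def rank(self) -> int:
        """Position on the ordinal scale (0 for stage 0, 8 for H)."""
        if self is StageCode.MISSING:
            raise ValueError("MISSING has no rank on the stage scale")
        return _RANK[self]

    def __lt__(self, other: object) -> bool:
        if not isinstance(other, StageCode):
            return NotImplemented
        return self.rank < other.rank  # raises on MISSING, intentionally

    def __str__(self) -> str:
        return self.value


#: the nine scorable stages in ordinal order (MISSING excluded)
STAGES: tuple[StageCode, ...] = tuple(s for s in StageCode if s is not StageCode.MISSING)

_RANK = {s: i for i, s in enumerate(STAGES)}

#: tokens accepted (case-insensitively) as "tooth not scorable"
MISSING_TOKENS = frozenset({"", "NA", "N/A", "."})


def parse_stage(token: str) -> StageCode:
    """Parse a stage token from a delimited file; '' / 'NA' map to MISSING."""
    t = token.strip().upper()
    if t in MISSING_TOKENS:
        return StageCode.MISSING
    try:
        return StageCode(t)
    except ValueError:
        raise ValueError(f"unrecognised stage token {token!r}") from None
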