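"""ATC code grammar and prefix-pattern matching.

The WHO Anatomical Therapeutic Chemical (ATC) classification is a
hierarchical code: one anatomical-group letter, two digits (therapeutic
group), one letter (pharmacological subgroup), one letter (chemical
subgroup) and two digits (substance).  Truncations at levels 1-4 are
legal classification codes; a full substance code is seven characters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: The 14 anatomical main groups defined by the classification.
ANATOMICAL_GROUPS = "ABCDGHJLMNPRSV"

# letter, two digits, then optional letter / letter / two digits.
# Legal truncation lengths: 1, 3, 4, 5, 7.  Patterns in a catalog are
# restricted to lengths 3-7; query codes must be full (length 7).
_ATC_RE = re.compile(rf"^[{ANATOMICAL_GROUPS}]\d\d(?:[A-Z](?:[A-Z](?:\d\d)?)?)?$")

FULL_CODE_LENGTH = 7


def is_valid_atc(code: str) -> bool:
    """True if *code* is a syntactically valid (possibly truncated) ATC code."""
    return isinstance(code, str) and len(code) >= 3 and bool(_ATC_RE.match(code))


def is_full_code(code: str) -> bool:
    """True if *code* is a valid full seven-character substance code."""
    return (
        isinstance(code, str)
        and len(code) == FULL_CODE_LENGTH
        and bool(_ATC_RE.match(code))
    )


class InvalidATCError(ValueError):
    """Raised for strings that do not conform to the ATC grammar."""


class TruncatedQueryError(ValueError):
    """Raised when a truncated code is used where a full code is required."""


def require_full_code(code: str) -> str:
    """Validate and return *code* uppercased; full seven-character codes only."""
    code = str(code).strip().upper()
    if len(code) != FULL_CODE_LENGTH:
        raise TruncatedQueryError(
            f"query code {code!r} must be a full {FULL_CODE_LENGTH}-character ATC code"
        )
    if not _ATC_RE.match(code):
        raise InvalidATCError(f"{code!r} does not conform to the ATC grammar")
    return code


@dataclass(frozen=True, order=True)
class ATCPattern:
    """A catalog matching pattern: a truncated prefix or an exact full code.

    ``match_mode`` is derived from length: codes shorter than seven
    characters match by leading substring, full codes match exactly.
    """

    code: str

    def __post_init__(self) -> None:
        code = self.code
        if code != code.strip().upper():
            raise InvalidATCError(f"pattern {code!r} must be uppercase, no whitespace")
        if not is_valid_atc(code):
            raise InvalidATCError(f"pattern {code!r} does not conform to the ATC grammar")

    @property
    def match_mode(self) -> str:
        return "exact" if len(self.code) == FULL_CODE_LENGTH else "prefix"

    def matches(self, full_code: str) -> bool:
        """Match against a full seven-character code (not validated here)."""
        return full_code.startswith(self.code)
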