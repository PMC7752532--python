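"""Text normalization shared by the terminology and the matcher.

Every surface form and every post text is pushed through the same
normalization key before substring comparison: Unicode NFC, case folding
(a no-op for Hangul), whitespace collapsed to single spaces, and outer
whitespace stripped. Matching therefore never depends on case or on how
runs of whitespace were typed.
"""

from __future__ import annotations

import re
import unicodedata

_WS = re.compile(r"\s+")

#: Placeholder character used to overwrite masked stop-phrase regions.
#: It never occurs in any terminology surface form, so a masked region
#: can never take part in a concept match.
MASK_CHAR = "�"


def normalize(text: str) -> str:
    """Return the canonical matching key for *text*."""
    return _WS.sub(" ", unicodedata.normalize("NFC", text).casefold()).strip()
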