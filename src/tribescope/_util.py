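"""Small shared helpers: seed fan-out and logging."""

from __future__ import annotations

import hashlib
import logging

logger = logging.getLogger("tribescope")


def child_seed(seed: int, *names: str) -> int:
    """Derive an independent substream seed from a global seed and a name path.

    Stable hashing means adding a new named substream never perturbs the
    draws of existing ones. The result fits in a signed 32-bit integer.
    """
    key = f"{int(seed)}:" + "/".join(names)
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")
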