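"""Small shared helpers."""

from __future__ import annotations

import zlib


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from a global one, below 2**31.

    The derivation is a documented fixed function of the stage name, so
    each pipeline stage is independently reproducible from the global seed.
    """
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)
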