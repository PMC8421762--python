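"""Stable seed derivation for reproducible, column-order-invariant randomness."""

import hashlib


def derive_seed(*parts) -> int:
    """Derive a deterministic 31-bit seed from a master seed plus context labels.

    Hash-based (SHA-256), so independent of Python's per-process hash
    randomization and of the order in which other streams are consumed.
    Keying substreams by item_id is what makes importance computations
    invariant to the column order of the input table.
    """
    key = "\x1f".join(str(p) for p in parts)
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
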