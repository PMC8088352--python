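"""Deterministic derivation of per-stage / per-subject seeds from one root seed."""

from __future__ import annotations

_MASK = (1 << 64) - 1


def splitmix64(state: int) -> int:
    """One step of the splitmix64 sequence; returns a 64-bit value."""
    state = (state + 0x9E3779B97F4A7C15) & _MASK
    z = state
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
    return z ^ (z >> 31)


def derive_seed(root_seed: int, *indices: int) -> int:
    """Derive a child seed from a root seed and a path of integer indices.

    The same ``(root_seed, *indices)`` always yields the same child, and
    distinct paths yield (with overwhelming probability) distinct children,
    so pipeline stages can be re-run standalone yet reproducibly.
    """
    state = splitmix64(root_seed & _MASK)
    for idx in indices:
        state = splitmix64(state ^ ((idx & _MASK) * 0xD1342543DE82EF95 & _MASK))
    return state
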