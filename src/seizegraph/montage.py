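"""The 22-channel bipolar TCP montage and scalp-midline homolog pairing.

Channels are voltage differences between 10-20 electrodes (e.g. ``FP1-F7``).
Left-hemisphere electrodes carry odd digits, right-hemisphere electrodes even
digits, and midline electrodes end in ``Z``; reflecting a recording across
the scalp midline therefore amounts to swapping each bipolar channel with its
homolog obtained by mirroring both constituent electrodes.
"""

from __future__ import annotations

import numpy as np

# Standard 22-channel bipolar listing (temporal-central-parasagittal montage).
TUSZ_CHANNELS: tuple[str, ...] = (
    "FP1-F7", "F7-T3", "T3-T5", "T5-O1",
    "FP2-F8", "F8-T4", "T4-T6", "T6-O2",
    "A1-T3", "T3-C3", "C3-CZ", "CZ-C4", "C4-T4", "T4-A2",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
)

# Approximate 2D scalp positions (unit head radius) of the electrodes used by
# the montage above; bipolar channel positions are midpoints of their pair.
ELECTRODE_XY: dict[str, tuple[float, float]] = {
    "FP1": (-0.31, 0.95), "FP2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.52), "FZ": (0.0, 0.50),
    "F4": (0.45, 0.52), "F8": (0.81, 0.59),
    "A1": (-1.10, 0.0), "T3": (-1.00, 0.0), "C3": (-0.50, 0.0),
    "CZ": (0.0, 0.0), "C4": (0.50, 0.0), "T4": (1.00, 0.0), "A2": (1.10, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.45, -0.52), "PZ": (0.0, -0.50),
    "P4": (0.45, -0.52), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

_DIGIT_MIRROR = {"1": "2", "2": "1", "3": "4", "4": "3",
                 "5": "6", "6": "5", "7": "8", "8": "7"}


def mirror_electrode(name: str) -> str:
    """Mirror a 10-20 electrode label across the midline (``Z`` is fixed)."""
    name = name.upper()
    if name.endswith("Z"):
        return name
    head, digit = name[:-1], name[-1]
    if digit not in _DIGIT_MIRROR:
        raise ValueError(f"unrecognized electrode label: {name!r}")
    return head + _DIGIT_MIRROR[digit]


def channel_position(channel: str) -> np.ndarray:
    """Midpoint scalp position of a bipolar channel."""
    try:
        a, b = channel.upper().split("-")
        pa, pb = ELECTRODE_XY[a], ELECTRODE_XY[b]
    except (ValueError, KeyError) as err:
        raise ValueError(f"unknown bipolar channel: {channel!r}") from err
    return 0.5 * (np.asarray(pa) + np.asarray(pb))


def midline_pair_map(channel_names: list[str] | tuple[str, ...],
                     override: dict[int, int] | None = None) -> list[tuple[int, int]]:
    """Left/right homolog index pairs for a list of bipolar channels.

    Each channel is mirrored electrode-wise; if the mirrored channel (in
    either electrode order) is present in the list, the two indices form a
    swap pair.  Channels that mirror onto themselves (pure midline channels)
    map to themselves and are returned as ``(i, i)``.  ``override`` replaces
    the derived pairing wholesale after validation.

    Raises ``ValueError`` for channel names that cannot be parsed or whose
    homolog is missing from the list.
    """
    names = [c.upper() for c in channel_names]
    index = {c: i for i, c in enumerate(names)}
    if len(index) != len(names):
        raise ValueError("duplicate channel names")

    if override is not None:
        seen: set[int] = set()
        for i, j in override.items():
            if not (0 <= i < len(names) and 0 <= j < len(names)):
                raise ValueError("override index out of range")
            if override.get(j, i) != i:
                raise ValueError("override is not an involution")
            seen.update((i, j))
        return sorted({tuple(sorted((i, j))) for i, j in override.items()})

    pairs: set[tuple[int, int]] = set()
    for i, chan in enumerate(names):
        a, b = chan.split("-")
        ma, mb = mirror_electrode(a), mirror_electrode(b)
        if (ma, mb) == (a, b):
            pairs.add((i, i))
            continue
        homolog = f"{ma}-{mb}" if f"{ma}-{mb}" in index else f"{mb}-{ma}"
        if homolog not in index:
            raise ValueError(f"homolog of {chan!r} not in channel list")
        j = index[homolog]
        pairs.add((min(i, j), max(i, j)))
    return sorted(pairs)


def reflection_permutation(channel_names: list[str] | tuple[str, ...],
                           pairs: list[tuple[int, int]] | None = None) -> np.ndarray:
    """Index permutation realizing the midline reflection (an involution)."""
    if pairs is None:
        pairs = midline_pair_map(channel_names)
    perm = np.arange(len(channel_names))
    for i, j in pairs:
        perm[i], perm[j] = j, i
    return perm
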