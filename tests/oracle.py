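"""Brute-force reference implementation of the spectral metrics.

Independent of the library path on purpose: every spectral box at every
level is materialised as an explicit value-range (one interval per band)
and pixels are assigned by range membership, with plain-Python loops and
no bit tricks.  Used only to cross-check the fast implementation on tiny
frames.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _pixels(frame) -> list[tuple[int, ...]]:
    a = np.asarray(frame)
    if a.ndim == 2:
        a = a[..., None]
    return [tuple(int(v) for v in px) for px in a.reshape(-1, a.shape[-1])]


def brute_box_histogram(frame, S: int, j: int) -> list[int]:
    """Counts of pixels per occupied level-j box, enumerating every box."""
    pixels = _pixels(frame)
    n = len(pixels[0])
    width = 2 ** (S - j)
    counts = []
    for corner in itertools.product(range(2**j), repeat=n):
        c = 0
        for px in pixels:
            if all(b * width <= v < (b + 1) * width for b, v in zip(corner, px)):
                c += 1
        if c:
            counts.append(c)
    return counts


def brute_entropy(counts: list[int]) -> float:
    total = sum(counts)
    return sum((c / total) * math.log2(total / c) for c in counts if c)


def brute_metrics(frame, S: int) -> dict[str, float]:
    """sfd_esr / sfd_dsr / ew_sfd / full-depth entropy via exhaustive boxes."""
    pixels = _pixels(frame)
    n = len(pixels[0])
    esr = dsr = ew = 0.0
    for j in range(1, S):
        counts = brute_box_histogram(frame, S, j)
        sbm = len(counts)
        f = min(1.0, brute_entropy(counts) / (j * n))
        esr += math.log(sbm) / math.log((2.0**S) ** n)
        dsr += math.log(sbm) / math.log((2.0**j) ** n)
        if f * sbm >= 1.0:
            ew += math.log(f * sbm) / math.log((2.0**j) ** n)
    full = brute_entropy(
        [len([p for p in pixels if p == u]) for u in set(pixels)]
    )
    return {
        "sfd_esr": n * esr / (S - 1),
        "sfd_dsr": n * dsr / (S - 1),
        "ew_sfd": n * ew / (S - 1),
        "entropy_bits": full,
    }
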