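"""Hemispheric network generation: selector operators and subnetwork extraction.

With the left-block-first node ordering, the left and right hemispheric
subnetworks of a brain network with adjacency ``A`` and attributes ``F`` are

    A_l = L A L.T,   A_r = R A R.T,   F_l = L F,   F_r = R F,

where the selectors ``L`` and ``R`` are the (m/2, m) binary matrices picking
the first and second halves of the node set. Inter-hemispheric (callosal)
edges appear in neither subnetwork; they remain represented only in the
full-brain graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_data import BrainNetwork

__all__ = ["Selector", "build_selectors", "extract_hemispheres"]


@dataclass(frozen=True)
class Selector:
    """Binary hemispheric selection operator of shape (m/2, m)."""

    matrix: np.ndarray
    side: str  # "left" | "right"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


def build_selectors(m: int) -> tuple[Selector, Selector]:
    """Return the explicit left/right selector matrices for an m-node network.

    ``(L)_ij = 1`` iff ``j == i``; ``(R)_ij = 1`` iff ``j == i + m/2``.
    """
    if m < 2 or m % 2 != 0:
        raise ValueError(f"m must be even and >= 2, got {m}")
    half = m // 2
    left = np.zeros((half, m))
    right = np.zeros((half, m))
    idx = np.arange(half)
    left[idx, idx] = 1.0
    right[idx, idx + half] = 1.0
    return Selector(left, "left"), Selector(right, "right")


def extract_hemispheres(net: BrainNetwork) -> tuple[BrainNetwork, BrainNetwork]:
    """Split a brain network into its left and right hemispheric subnetworks.

    Equivalent to conjugating the adjacency by the selectors of
    :func:`build_selectors`; implemented as block slicing (identical result,
    linear cost). Inter-hemispheric edges are discarded.
    """
    if net.m % 2 != 0:
        raise ValueError(
            f"hemispheric split needs an even node count, got m={net.m}"
        )
    half = net.m // 2
    left = BrainNetwork(
        net.adjacency[:half, :half].copy(),
        net.attributes[:half].copy(),
        label=net.label,
        subject_id=net.subject_id,
        attribute_names=net.attribute_names,
    )
    right = BrainNetwork(
        net.adjacency[half:, half:].copy(),
        net.attributes[half:].copy(),
        label=net.label,
        subject_id=net.subject_id,
        attribute_names=net.attribute_names,
    )
    return left, right
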