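"""Geometric descriptors of fusion-enzyme constructs.

When two enzymes of a cascade (here an O-methyltransferase and the SAM
regenerating halide methyltransferase) are fused by a peptide linker, the
relative placement of their active sites governs substrate channelling.  Two
descriptors summarise a predicted fusion structure:

* ``D_IC`` — the distance (Angstrom) between the two active-site tunnels,
  each represented by the centroid of user-supplied anchor atoms;
* ``O_IC`` — the angle (degrees, 0-180, orientation-sensitive) between two
  user-defined line segments on the structure.

Tunnel/segment *identification* is out of scope: anchors come from the user's
config, and this module only computes the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnchorError, DegenerateGeometryError
from .nac import angle_deg
from .structio import Frame, Selector, select

__all__ = ["AnchorSet", "SegmentSpec", "centroid", "d_ic", "o_ic"]


@dataclass
class AnchorSet:
    """A labelled group of selectors whose resolved atoms define a point
    (their unweighted centroid)."""

    label: str
    selectors: list[Selector]


@dataclass
class SegmentSpec:
    """A directed line segment between two anchor centroids."""

    label: str
    start_anchor: AnchorSet
    end_anchor: AnchorSet


def centroid(frame: Frame, anchors: AnchorSet) -> np.ndarray:
    """Unweighted mean coordinate of all atoms resolved by the anchor set."""
    atoms = []
    for sel in anchors.selectors:
        atoms.extend(select(frame, sel))
    if not atoms:
        raise AnchorError(f"anchor set {anchors.label!r} resolved to no atoms")
    return np.mean([a.xyz for a in atoms], axis=0)


def d_ic(frame: Frame, tunnel_a: AnchorSet, tunnel_b: AnchorSet) -> float:
    """Inter-tunnel distance: Euclidean distance between anchor centroids (A)."""
    return float(np.linalg.norm(centroid(frame, tunnel_a) - centroid(frame, tunnel_b)))


def o_ic(frame: Frame, seg_x: SegmentSpec, seg_y: SegmentSpec) -> float:
    """Inter-segment angle in degrees, orientation-sensitive in [0, 180].

    Antiparallel segments give 180 deg (not folded to [0, 90]), so nearly
    opposed active-site orientations are distinguishable from aligned ones.
    """
    def _direction(seg: SegmentSpec) -> np.ndarray:
        v = centroid(frame, seg.end_anchor) - centroid(frame, seg.start_anchor)
        if np.linalg.norm(v) == 0.0:
            raise DegenerateGeometryError(f"segment {seg.label!r} has zero length")
        return v

    u = _direction(seg_x)
    v = _direction(seg_y)
    return angle_deg(u, np.zeros(3), v)
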