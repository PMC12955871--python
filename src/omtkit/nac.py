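"""Near-attack-conformation (NAC) analysis of methyltransferase ensembles.

An SN2 methyl transfer from SAM to a substrate hydroxyl is geometrically
feasible only when two reaction coordinates are simultaneously favourable:

* ``d`` — the distance from the nucleophile oxygen to the catalytic histidine
  imidazole nitrogen that deprotonates it (written d(O...H-N); measured
  O -> N on hydrogen-free models, with the ~1 A N-H offset absorbed by the
  distance cutoff);
* ``theta`` — the attack angle at the SAM methyl carbon C1 between the
  oxygen and the sulfonium sulfur, ideally approaching the in-line 180 deg.

Frames of a conformational ensemble whose (d, theta) fall inside a reactive
region (default: d < 3.5 A, 125 deg <= theta <= 170 deg) are counted as
methylation-competent; per-site competent fractions quantify the enzyme's
regioselectivity among candidate hydroxyls (e.g. 2'/3'/4'-OH of a catechol
acceptor).  The module also provides 2-D kernel density maps over (d, theta),
Kabsch superposition, and per-residue RMSF profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    InsufficientFramesError,
    PairingError,
    SelectionError,
    UnderdeterminedError,
)
from .structio import Ensemble, Frame, Selector, select

__all__ = [
    "SiteSpec",
    "GeometryRecord",
    "ReactiveRegion",
    "SiteStats",
    "RMSFProfile",
    "angle_deg",
    "measure_site",
    "classify",
    "site_stats",
    "rank_sites",
    "superpose",
    "rmsf",
    "records_to_frame",
]

BACKBONE_NAMES = ["N", "CA", "C", "O"]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class SiteSpec:
    """A named methylation site: which atoms play which catalytic role.

    Each selector must resolve to exactly one atom per frame (``n_sels``:
    one atom per listed selector — typically the histidine ND1 and NE2).
    ``h_sels`` optionally lists explicit hydroxyl/imidazole hydrogens for
    inputs that have them; see :func:`measure_site`.
    """

    label: str
    o_sel: Selector
    n_sels: list[Selector]
    c1_sel: Selector
    s_sel: Selector
    h_sels: list[Selector] = field(default_factory=list)


@dataclass(frozen=True)
class GeometryRecord:
    """Per-frame, per-site reaction coordinates (d in Angstrom, theta in deg)."""

    frame_index: int
    site_label: str
    d: float
    theta: float

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError("distance d must be positive")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError("theta must lie in [0, 180] degrees")


@dataclass(frozen=True)
class ReactiveRegion:
    """The (d, theta) box that calls a conformation methylation-competent.

    Distance bound is strict (<); the angle window is inclusive.  Defaults are
    the standard NAC criteria for SN2 methyl transfer: d < 3.5 A and
    125 deg <= theta <= 170 deg.  They are defaults, not constants: the box
    may be substrate- or enzyme-tuned.
    """

    d_max: float = 3.5
    theta_min: float = 125.0
    theta_max: float = 170.0

    def __post_init__(self) -> None:
        if not self.d_max > 0:
            raise ValueError("d_max must be positive")
        if not (0.0 <= self.theta_min < self.theta_max <= 180.0):
            raise ValueError("need 0 <= theta_min < theta_max <= 180")


@dataclass
class SiteStats:
    """Reactive fraction and KDE map for one site over an ensemble."""

    site_label: str
    n_frames: int
    n_reactive: int
    fraction: float
    records: list[GeometryRecord]
    kde: np.ndarray          # (len(d_axis), len(theta_axis)) density grid
    d_axis: np.ndarray
    theta_axis: np.ndarray


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation (Angstrom)."""

    residue_ids: list[tuple[str, int]]
    rmsf: np.ndarray


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle at *vertex* between points *a* and *b*, in degrees in [0, 180]."""
    u = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    v = np.asarray(b, dtype=float) - np.asarray(vertex, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length arm in angle computation")
    cos = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def _resolve_one(frame: Frame, sel: Selector, site: str, role: str) -> np.ndarray:
    atoms = select(frame, sel)
    if len(atoms) != 1:
        raise SelectionError(
            f"site {site!r}: {role} selector {sel} resolved to "
            f"{len(atoms)} atoms in frame {frame.index} (need exactly 1)"
        )
    return atoms[0].xyz


def measure_site(frame: Frame, site: SiteSpec, use_hydrogens: bool = False) -> GeometryRecord:
    """Measure the (d, theta) reaction coordinates of one site in one frame.

    ``d`` is the minimum distance from the nucleophile oxygen to the resolved
    histidine nitrogens (heavy-atom convention).  With ``use_hydrogens=True``
    and ``h_sels`` present in the site, the minimum runs over the listed
    hydrogen acceptors as well.  ``theta`` is the angle at C1 between the
    oxygen and the sulfur.
    """
    o = _resolve_one(frame, site.o_sel, site.label, "nucleophile O")
    c1 = _resolve_one(frame, site.c1_sel, site.label, "methyl C1")
    s = _resolve_one(frame, site.s_sel, site.label, "sulfur S")
    acceptor_sels = list(site.n_sels)
    if use_hydrogens and site.h_sels:
        acceptor_sels = acceptor_sels + list(site.h_sels)
    if not acceptor_sels:
        raise SelectionError(f"site {site.label!r}: no acceptor selectors")
    dists = [
        float(np.linalg.norm(o - _resolve_one(frame, sel, site.label, "acceptor")))
        for sel in acceptor_sels
    ]
    return GeometryRecord(
        frame_index=frame.index,
        site_label=site.label,
        d=min(dists),
        theta=angle_deg(o, c1, s),
    )


def classify(rec: GeometryRecord, region: ReactiveRegion = ReactiveRegion()) -> bool:
    """True iff the record lies in the reactive region (d strict, theta inclusive)."""
    return rec.d < region.d_max and region.theta_min <= rec.theta <= region.theta_max


# ---------------------------------------------------------------------------
# KDE over the (d, theta) plane
# ---------------------------------------------------------------------------

def scott_bandwidth(x: np.ndarray) -> float:
    """Scott's-rule bandwidth for one axis of a 2-D product-Gaussian KDE.

    h = sigma * n**(-1/6)  (n**(-1/(dims+4)) with dims=2).  For degenerate
    samples (sigma == 0) a tiny floor keeps the kernel well defined.
    """
    n = len(x)
    sigma = float(np.std(x, ddof=1)) if n > 1 else 0.0
    if sigma == 0.0:
        # degenerate sample: a 1%-of-magnitude bandwidth keeps the spike
        # representable on a finite grid instead of underflowing to zero
        return 0.01 * max(abs(float(np.mean(x))), 1.0)
    return sigma * n ** (-1.0 / 6.0)


def kde2d(
    d_vals: np.ndarray,
    theta_vals: np.ndarray,
    d_axis: np.ndarray,
    theta_axis: np.ndarray,
) -> np.ndarray:
    """Product-Gaussian KDE of (d, theta) samples evaluated on a grid.

    Separate Scott bandwidth per axis; returns a density grid of shape
    (len(d_axis), len(theta_axis)) normalised so its integral over the plane
    is 1 (up to truncation of the grid window).
    """
    d_vals = np.asarray(d_vals, dtype=float)
    theta_vals = np.asarray(theta_vals, dtype=float)
    n = len(d_vals)
    hd = scott_bandwidth(d_vals)
    ht = scott_bandwidth(theta_vals)
    # separable kernel: density = (Kd @ Kt.T) / n
    zd = (d_axis[:, None] - d_vals[None, :]) / hd
    zt = (theta_axis[:, None] - theta_vals[None, :]) / ht
    kd = np.exp(-0.5 * zd**2) / (hd * np.sqrt(2 * np.pi))
    kt = np.exp(-0.5 * zt**2) / (ht * np.sqrt(2 * np.pi))
    return (kd @ kt.T) / n


def default_axes(n_d: int = 100, n_theta: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Default KDE grid: [0, 8] A x [0, 180] deg."""
    return np.linspace(0.0, 8.0, n_d), np.linspace(0.0, 180.0, n_theta)


# ---------------------------------------------------------------------------
# per-site statistics and ranking
# ---------------------------------------------------------------------------

def site_stats(
    ens: Ensemble,
    site: SiteSpec,
    region: ReactiveRegion = ReactiveRegion(),
    d_axis: np.ndarray | None = None,
    theta_axis: np.ndarray | None = None,
    use_hydrogens: bool = False,
) -> SiteStats:
    """Per-frame geometry, competent-conformation fraction and KDE for a site.

    The fraction is exact integer arithmetic (reactive count / frame count);
    the KDE uses the product-Gaussian kernel of :func:`kde2d`.
    """
    if d_axis is None or theta_axis is None:
        dax, tax = default_axes()
        d_axis = dax if d_axis is None else np.asarray(d_axis, float)
        theta_axis = tax if theta_axis is None else np.asarray(theta_axis, float)
    records = [measure_site(f, site, use_hydrogens=use_hydrogens) for f in ens.frames]
    n_reactive = sum(classify(r, region) for r in records)
    d_vals = np.array([r.d for r in records])
    t_vals = np.array([r.theta for r in records])
    return SiteStats(
        site_label=site.label,
        n_frames=len(records),
        n_reactive=n_reactive,
        fraction=n_reactive / len(records),
        records=records,
        kde=kde2d(d_vals, t_vals, d_axis, theta_axis),
        d_axis=np.asarray(d_axis, float),
        theta_axis=np.asarray(theta_axis, float),
    )


def records_to_frame(records: list[GeometryRecord], region: ReactiveRegion = ReactiveRegion()) -> pd.DataFrame:
    """Tabulate geometry records as (frame, site, d_angstrom, theta_deg, reactive)."""
    return pd.DataFrame(
        {
            "frame": [r.frame_index for r in records],
            "site": [r.site_label for r in records],
            "d_angstrom": [r.d for r in records],
            "theta_deg": [r.theta for r in records],
            "reactive": [classify(r, region) for r in records],
        }
    )


@dataclass
class SiteRanking:
    """Sites ordered by competent fraction (descending)."""

    ordered: list[tuple[str, float]]
    tied_labels: set[str]

    @property
    def top_site(self) -> str:
        return self.ordered[0][0]


def rank_sites(stats: list[SiteStats]) -> SiteRanking:
    """Rank sites by reactive fraction, descending; ties broken alphabetically
    by label and flagged as ambiguous."""
    if not stats:
        raise ValueError("need at least one site")
    ordered = sorted(stats, key=lambda s: (-s.fraction, s.site_label))
    tied: set[str] = set()
    by_frac: dict[float, list[str]] = {}
    for s in stats:
        by_frac.setdefault(s.fraction, []).append(s.site_label)
    for labels in by_frac.values():
        if len(labels) > 1:
            tied.update(labels)
    return SiteRanking(
        ordered=[(s.site_label, s.fraction) for s in ordered],
        tied_labels=tied,
    )


# ---------------------------------------------------------------------------
# superposition and RMSF
# ---------------------------------------------------------------------------

def _paired_coords(mobile: Frame, reference: Frame, sel: Selector) -> tuple[np.ndarray, np.ndarray]:
    mob = select(mobile, sel)
    ref = select(reference, sel)
    if len(mob) != len(ref):
        raise PairingError(
            f"selection resolves to {len(mob)} atoms in mobile but {len(ref)} in reference"
        )
    if len(mob) < 3:
        raise UnderdeterminedError("rigid-body superposition needs >= 3 atom pairs")
    return (
        np.array([a.xyz for a in mob]),
        np.array([a.xyz for a in ref]),
    )


def _kabsch(mob: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of mob onto ref; returns (R, t, rmsd)."""
    mc = mob.mean(axis=0)
    rc = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mob - mc)
    R = rot.as_matrix()  # proper rotation enforced by align_vectors
    t = rc - R @ mc
    # rmsd from the residuals directly: the rssd returned by align_vectors
    # loses ~7 digits to cancellation near a perfect fit
    resid = mob @ R.T + t - ref
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return R, t, rmsd


def superpose(mobile: Frame, reference: Frame, sel: Selector) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch superposition of *mobile* onto *reference* over a selection.

    Returns (rotation matrix, translation vector, rmsd in Angstrom) such that
    ``R @ x + t`` maps mobile coordinates onto the reference; rmsd is the
    root-mean-square deviation of the selected pairs after the fit.
    """
    mob, ref = _paired_coords(mobile, reference, sel)
    return _kabsch(mob, ref)


def apply_rigid(frame: Frame, R: np.ndarray, t: np.ndarray) -> Frame:
    """Return a copy of *frame* with ``R @ x + t`` applied to every atom."""
    from dataclasses import replace

    atoms = [replace(a, xyz=R @ a.xyz + t) for a in frame.atoms]
    return Frame(index=frame.index, atoms=atoms)


def rmsf(ens: Ensemble, sel: Selector | None = None) -> RMSFProfile:
    """Per-residue RMSF of an ensemble after superposition onto its mean.

    Each frame is first superposed onto the ensemble mean structure; the mean
    is then recomputed from the aligned frames and the frames refit once
    (two-pass).  RMSF_i = sqrt(mean over frames of |x_fi - <x_i>|^2); atom
    values are averaged per residue.  Default selection: backbone atoms
    N, CA, C, O.  No mass weighting.
    """
    if sel is None:
        sel = Selector(atom_names=list(BACKBONE_NAMES))
    if len(ens.frames) < 2:
        raise InsufficientFramesError("RMSF needs at least two frames")
    sel_atoms = select(ens.frames[0], sel)
    if not sel_atoms:
        raise SelectionError(f"RMSF selection {sel} matched no atoms")
    coords = np.array([[a.xyz for a in select(f, sel)] for f in ens.frames])
    if coords.shape[1] < 3:
        raise UnderdeterminedError("RMSF superposition needs >= 3 selected atoms")

    def _align_all(frames_xyz: np.ndarray, target: np.ndarray) -> np.ndarray:
        out = np.empty_like(frames_xyz)
        for i, xyz in enumerate(frames_xyz):
            R, t, _ = _kabsch(xyz, target)
            out[i] = xyz @ R.T + t
        return out

    mean0 = coords.mean(axis=0)
    aligned = _align_all(coords, mean0)
    mean1 = aligned.mean(axis=0)
    aligned = _align_all(coords, mean1)
    mean2 = aligned.mean(axis=0)

    per_atom = np.sqrt(np.mean(np.sum((aligned - mean2) ** 2, axis=2), axis=0))

    residues: dict[tuple[str, int], list[float]] = {}
    order: list[tuple[str, int]] = []
    for atom, val in zip(sel_atoms, per_atom):
        key = (atom.chain, atom.resseq)
        if key not in residues:
            residues[key] = []
            order.append(key)
        residues[key].append(float(val))
    return RMSFProfile(
        residue_ids=order,
        rmsf=np.array([np.mean(residues[k]) for k in order]),
    )
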