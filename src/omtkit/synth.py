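"""Synthetic conformational ensembles with prescribed reaction coordinates.

Desk-scale stand-in for an MD conformational sample: per site, the internal
coordinates (d, theta) are drawn from truncated normal distributions and then
embedded as Cartesian atom quadruplets (S, C1, O, N) on a minimal scaffold,
so that :func:`omtkit.nac.measure_site` recovers the drawn values exactly.
Ground truth (the sampled pairs and their reactive flags) is carried
alongside the ensemble, enabling end-to-end recovery tests of the whole
geometry pipeline.

The generator makes no claim of physical realism beyond the marginal (d,
theta) distributions: there is no protein context, no excluded volume and,
by default, no d-theta correlation (an optional correlation coefficient is
provided for stress tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import DegenerateEmbeddingError
from .nac import ReactiveRegion, SiteSpec, classify, GeometryRecord
from .structio import Atom, Ensemble, Frame, Selector

__all__ = [
    "SiteDistribution",
    "EnsembleTruth",
    "sample_internal",
    "embed_geometry",
    "generate_ensemble",
    "site_spec_for_chain",
]

# scaffold constants (Angstrom): S-CH3 bond-like and van der Waals approach.
# Fixed and, by construction, irrelevant to (d, theta) recovery.
R_SC = 1.80
R_OC = 3.00

D_FLOOR = 0.5  # truncation floor for sampled distances


@dataclass(frozen=True)
class SiteDistribution:
    """Marginal (d, theta) distribution for one site.

    d ~ Normal(d_mean, d_sd) truncated below at 0.5 A; theta ~
    Normal(theta_mean, theta_sd) truncated to [0, 180] deg; ``rho`` sets the
    correlation of the underlying bivariate normal (default 0 = independent,
    which is also the only mode with exactly truncated-normal marginals).
    """

    site_label: str
    d_mean: float
    d_sd: float
    theta_mean: float
    theta_sd: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.d_sd <= 0 or self.theta_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if not self.d_mean > D_FLOOR:
            raise ValueError(f"d_mean must exceed the truncation floor {D_FLOOR} A")
        if not 0.0 <= self.theta_mean <= 180.0:
            raise ValueError("theta_mean must lie in [0, 180]")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")


@dataclass
class EnsembleTruth:
    """Ground truth for a generated ensemble.

    ``table`` has columns (frame, site, d_angstrom, theta_deg, reactive); the
    reactive flags are consistent with classifying the sampled pairs under
    ``region``.  ``site_specs`` maps site label -> the SiteSpec that resolves
    that site's embedded atoms.
    """

    table: pd.DataFrame
    region: ReactiveRegion
    site_specs: dict[str, SiteSpec]

    def fraction(self, site_label: str) -> float:
        sub = self.table[self.table["site"] == site_label]
        return float(sub["reactive"].mean())


def sample_internal(dist: SiteDistribution, n: int, seed: int) -> np.ndarray:
    """Draw n independent (d, theta) pairs; deterministic for a fixed seed.

    Returns an (n, 2) array.  With rho == 0 the marginals are exact truncated
    normals; with rho != 0 correlated normals are drawn and out-of-bounds
    pairs rejected (resampled), which slightly distorts the marginals — a
    stress-test mode, not the default study condition.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if dist.rho == 0.0:
        a_d = (D_FLOOR - dist.d_mean) / dist.d_sd
        d = truncnorm.rvs(a_d, np.inf, loc=dist.d_mean, scale=dist.d_sd,
                          size=n, random_state=rng)
        a_t = (0.0 - dist.theta_mean) / dist.theta_sd
        b_t = (180.0 - dist.theta_mean) / dist.theta_sd
        theta = truncnorm.rvs(a_t, b_t, loc=dist.theta_mean, scale=dist.theta_sd,
                              size=n, random_state=rng)
        return np.column_stack([d, theta])
    cov = np.array(
        [
            [dist.d_sd**2, dist.rho * dist.d_sd * dist.theta_sd],
            [dist.rho * dist.d_sd * dist.theta_sd, dist.theta_sd**2],
        ]
    )
    mean = np.array([dist.d_mean, dist.theta_mean])
    out = np.empty((0, 2))
    while len(out) < n:
        draw = rng.multivariate_normal(mean, cov, size=2 * (n - len(out)) + 8)
        ok = (draw[:, 0] > D_FLOOR) & (draw[:, 1] >= 0.0) & (draw[:, 1] <= 180.0)
        out = np.vstack([out, draw[ok]])
    return out[:n]


def embed_geometry(
    d: float,
    theta: float,
    chain: str = "A",
    resseq: int = 1,
    serial_start: int = 1,
    frame_index: int = 1,
) -> Frame:
    """Embed one (d, theta) pair as a four-atom Cartesian frame.

    Construction: S at the origin; C1 at (R_SC, 0, 0); O in the xy-plane at
    distance R_OC from C1 such that the angle at C1 between (S-C1) and (O-C1)
    equals theta; a single histidine-like N at distance d from O along a unit
    vector perpendicular to the O->C1 direction (in-plane).  By construction
    ``measure_site`` returns (d, theta) exactly (to floating-point rounding).
    """
    if not d > 0:
        raise DegenerateEmbeddingError("d must be positive")
    if not 0.0 < theta < 180.0:
        raise DegenerateEmbeddingError("theta must lie strictly inside (0, 180)")
    th = np.radians(theta)
    s_xyz = np.zeros(3)
    c1 = np.array([R_SC, 0.0, 0.0])
    # angle at C1 between u_S = (S - C1)/|.| = (-1,0,0) and direction to O
    o = c1 + R_OC * (np.cos(th) * np.array([-1.0, 0.0, 0.0]) + np.sin(th) * np.array([0.0, 1.0, 0.0]))
    w = (c1 - o) / np.linalg.norm(c1 - o)          # O -> C1 direction
    p = np.cross(w, np.array([0.0, 0.0, 1.0]))     # in-plane, perpendicular to w
    p /= np.linalg.norm(p)
    n_xyz = o + d * p
    atoms = [
        Atom(serial=serial_start, name="S", resname="SAM", chain=chain, resseq=resseq, xyz=s_xyz, element="S"),
        Atom(serial=serial_start + 1, name="C1", resname="SAM", chain=chain, resseq=resseq, xyz=c1, element="C"),
        Atom(serial=serial_start + 2, name="O", resname="SUB", chain=chain, resseq=resseq + 1, xyz=o, element="O"),
        Atom(serial=serial_start + 3, name="NE2", resname="HIS", chain=chain, resseq=resseq + 2, xyz=n_xyz, element="N"),
    ]
    return Frame(index=frame_index, atoms=atoms)


def site_spec_for_chain(label: str, chain: str) -> SiteSpec:
    """SiteSpec resolving the atoms embedded by :func:`embed_geometry` on *chain*."""
    return SiteSpec(
        label=label,
        o_sel=Selector(chain=chain, atom_names=["O"]),
        n_sels=[Selector(chain=chain, atom_names=["NE2"])],
        c1_sel=Selector(chain=chain, atom_names=["C1"]),
        s_sel=Selector(chain=chain, atom_names=["S"]),
    )


def _site_seed(master_seed: int, site_index: int) -> int:
    # fixed per-index offset stream: adding a site never perturbs another
    return (master_seed * 100_003 + 7_919 * site_index) % (2**31 - 1)


def generate_ensemble(
    dists: list[SiteDistribution],
    n: int,
    seed: int,
    region: ReactiveRegion = ReactiveRegion(),
) -> tuple[Ensemble, EnsembleTruth]:
    """Generate an n-frame ensemble with one embedded atom set per site.

    Sites occupy distinct chains (A, B, ...) so their selectors resolve
    uniquely.  Returns the ensemble together with its ground truth.
    """
    labels = [d.site_label for d in dists]
    if len(set(labels)) != len(labels):
        raise ValueError("site labels must be unique")
    if len(dists) > 26:
        raise ValueError("at most 26 sites (one chain letter each)")

    samples = {
        dist.site_label: sample_internal(dist, n, _site_seed(seed, i))
        for i, dist in enumerate(dists)
    }
    chains = {dist.site_label: chr(ord("A") + i) for i, dist in enumerate(dists)}

    frames = []
    rows = []
    for f in range(n):
        atoms: list[Atom] = []
        serial = 1
        for dist in dists:
            label = dist.site_label
            d_val, t_val = samples[label][f]
            sub = embed_geometry(
                d_val, t_val, chain=chains[label], serial_start=serial, frame_index=f + 1
            )
            atoms.extend(sub.atoms)
            serial += len(sub.atoms)
            rec = GeometryRecord(frame_index=f + 1, site_label=label, d=float(d_val), theta=float(t_val))
            rows.append(
                {
                    "frame": f + 1,
                    "site": label,
                    "d_angstrom": float(d_val),
                    "theta_deg": float(t_val),
                    "reactive": classify(rec, region),
                }
            )
        frames.append(Frame(index=f + 1, atoms=atoms))

    truth = EnsembleTruth(
        table=pd.DataFrame(rows),
        region=region,
        site_specs={lab: site_spec_for_chain(lab, chains[lab]) for lab in labels},
    )
    return Ensemble(frames=frames), truth
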