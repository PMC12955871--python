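"""Methylation kinetics: Michaelis-Menten fits, SAH product inhibition and
the two-enzyme SAM-regeneration cascade.

The chemistry being modelled
----------------------------

An O-methyltransferase (OMT) transfers the SAM methyl group to its acceptor
substrate, releasing SAH.  SAH is itself a potent OMT inhibitor; because its
effect is reported entirely as an increase in the apparent Michaelis
constant, it is modelled as competitive with the acceptor:

    Km_app = Km * (1 + [SAH] / Ki)        (Vmax unchanged)

which inverts to ``Ki = [SAH] / (Km_app/Km - 1)``.  A halide
methyltransferase (HMT) can regenerate SAM in situ from SAH and a methyl
donor (e.g. CH3I), relieving both the SAH inhibition and the need for
stoichiometric SAM.  The coupled cycle

    substrate + SAM --OMT--> product + SAH
    SAH + donor     --HMT--> SAM (+ halide)

is simulated as an ODE system with rapid-equilibrium saturating terms for
each substrate of each enzyme.  Concentrations are in uM; turnover numbers
in 1/s; external time in hours (integration runs in seconds internally).

Rate-law fitting follows the statsmodels convention: build a
:class:`MichaelisMenten` model from observed initial rates, call
``fit()`` and read estimates, standard errors and diagnostics off the
returned :class:`MMResults` (``summary()`` prints a table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .errors import FitError, NoInhibitionError, SimulationError

__all__ = [
    "MMParams",
    "InhibitionParams",
    "CascadeParams",
    "CascadeTrajectory",
    "mm_rate",
    "apparent_km",
    "infer_ki",
    "MichaelisMenten",
    "MMResults",
    "synth_rate_data",
    "cascade_rhs",
    "simulate_cascade",
    "simulate_single_enzyme",
    "time_to_conversion",
    "REFERENCE_PARAMS",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten parameters.

    Either ``vmax`` (uM/min or any consistent rate unit) is given directly,
    or ``kcat`` (1/s) together with ``enzyme_conc`` (uM), in which case
    vmax = kcat * enzyme_conc (uM/s).
    """

    km: float
    vmax: float | None = None
    kcat: float | None = None
    enzyme_conc: float | None = None

    def __post_init__(self) -> None:
        if self.km <= 0:
            raise ValueError("km must be positive")
        if self.vmax is None and (self.kcat is None or self.enzyme_conc is None):
            raise ValueError("provide vmax, or kcat together with enzyme_conc")
        if self.vmax is not None and self.vmax <= 0:
            raise ValueError("vmax must be positive")
        if self.kcat is not None and self.kcat <= 0:
            raise ValueError("kcat must be positive")

    @property
    def vmax_value(self) -> float:
        if self.vmax is not None:
            return self.vmax
        return self.kcat * self.enzyme_conc


@dataclass(frozen=True)
class InhibitionParams:
    """Competitive inhibitor: inhibition constant and concentration (uM)."""

    ki: float
    inhibitor_conc: float

    def __post_init__(self) -> None:
        if self.ki <= 0:
            raise ValueError("ki must be positive")
        if self.inhibitor_conc < 0:
            raise ValueError("inhibitor concentration must be >= 0")


def mm_rate(s, p: MMParams):
    """Michaelis-Menten initial rate v = Vmax * s / (Km + s); s in uM, s >= 0."""
    s = np.asarray(s, dtype=float)
    out = p.vmax_value * s / (p.km + s)
    return float(out) if out.ndim == 0 else out


def apparent_km(km: float, inh: InhibitionParams) -> float:
    """Apparent Km under a competitive inhibitor: Km * (1 + [I]/Ki)."""
    return km * (1.0 + inh.inhibitor_conc / inh.ki)


def infer_ki(km: float, km_app: float, inhibitor_conc: float) -> float:
    """Invert the competitive-Km shift for the inhibition constant.

    Ki = [I] / (Km_app/Km - 1).  Requires Km_app > Km > 0 and [I] > 0.
    """
    if not km > 0 or not inhibitor_conc > 0:
        raise ValueError("km and inhibitor_conc must be positive")
    if not km_app > km:
        raise NoInhibitionError(
            f"apparent Km ({km_app}) does not exceed Km ({km}); no inhibition to invert"
        )
    return inhibitor_conc / (km_app / km - 1.0)


# ---------------------------------------------------------------------------
# statsmodels-style fitting
# ---------------------------------------------------------------------------

class MichaelisMenten:
    """Michaelis-Menten (optionally competitively inhibited) rate model.

    Parameters
    ----------
    rate : array-like
        Observed initial rates v.
    conc : array-like
        Substrate concentrations s (uM); needs >= 4 distinct values spanning
        below and above Km for a well-posed fit.
    inhibitor_conc : array-like, optional
        Per-observation inhibitor concentration (uM).  When present (and not
        all zero) the model is v = Vmax*s / (Km*(1+I/Ki) + s) and Ki is
        estimated jointly.

    Examples
    --------
    >>> m = MichaelisMenten.from_dataframe(df)  # columns s_uM, v[, inhibitor_uM]
    >>> res = m.fit()
    >>> res.params["km"], res.bse["km"]
    """

    def __init__(self, rate, conc, inhibitor_conc=None):
        self.v = np.asarray(rate, dtype=float)
        self.s = np.asarray(conc, dtype=float)
        if self.v.shape != self.s.shape:
            raise ValueError("rate and conc must have equal length")
        if len(np.unique(self.s)) < 4:
            raise ValueError("need >= 4 distinct substrate concentrations")
        if np.any(self.s < 0) or np.any(~np.isfinite(self.v)):
            raise ValueError("concentrations must be >= 0 and rates finite")
        if inhibitor_conc is not None:
            self.inhibitor = np.asarray(inhibitor_conc, dtype=float)
            if self.inhibitor.shape != self.s.shape:
                raise ValueError("inhibitor_conc must match the data length")
            if not np.any(self.inhibitor > 0):
                self.inhibitor = None
        else:
            self.inhibitor = None

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        conc_col: str = "s_uM",
        rate_col: str = "v",
        inhibitor_col: str = "inhibitor_uM",
    ) -> "MichaelisMenten":
        inh = df[inhibitor_col].to_numpy() if inhibitor_col in df.columns else None
        return cls(df[rate_col].to_numpy(), df[conc_col].to_numpy(), inh)

    @property
    def param_names(self) -> list[str]:
        return ["vmax", "km"] + (["ki"] if self.inhibitor is not None else [])

    def predict(self, params: np.ndarray, s=None, inhibitor=None) -> np.ndarray:
        s = self.s if s is None else np.asarray(s, dtype=float)
        if self.inhibitor is not None:
            inh = self.inhibitor if inhibitor is None else np.asarray(inhibitor, float)
            vmax, km, ki = params
            return vmax * s / (km * (1.0 + inh / ki) + s)
        vmax, km = params
        return vmax * s / (km + s)

    def _starts(self) -> list[np.ndarray]:
        vhat = float(np.max(self.v))
        base = self.s if self.inhibitor is None else self.s[self.inhibitor == 0]
        if base.size == 0:
            base = self.s
        km_guesses = [float(np.median(base)), float(np.max(base)) / 2.0, float(np.min(base[base > 0], initial=1.0)) * 5.0]
        starts = []
        for i, kmg in enumerate(km_guesses):
            p = [vhat * (1.0 + 0.25 * i), max(kmg, 1e-6)]
            if self.inhibitor is not None:
                imax = float(np.max(self.inhibitor))
                p.append(max(imax / (2.0 ** (i + 1)), 1e-3))
            starts.append(np.array(p))
        return starts

    def fit(self) -> "MMResults":
        """Multi-start Levenberg-style least squares on untransformed rates."""
        best = None
        for x0 in self._starts():
            try:
                sol = least_squares(
                    lambda p: self.predict(p) - self.v,
                    x0,
                    bounds=(1e-12, np.inf),
                    method="trf",
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitError("Michaelis-Menten fit failed to converge from all starts")

        params = dict(zip(self.param_names, best.x))
        n, p = len(self.v), len(best.x)
        ssr = float(2.0 * best.cost)
        dof = max(n - p, 1)
        jac = best.jac
        try:
            cov = np.linalg.inv(jac.T @ jac) * ssr / dof
            bse = dict(zip(self.param_names, np.sqrt(np.diag(cov))))
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            bse = {k: float("nan") for k in self.param_names}

        if params["km"] > float(np.max(self.s)):
            warnings.warn(
                "estimated Km exceeds the largest tested concentration; "
                "the design may not identify Km and Vmax separately",
                UserWarning,
                stacklevel=2,
            )
        return MMResults(
            model=self, params=params, bse=bse, cov=cov,
            ssr=ssr, nobs=n, converged=True,
        )


@dataclass
class MMResults:
    """Estimates, asymptotic standard errors and fit diagnostics."""

    model: MichaelisMenten
    params: dict[str, float]
    bse: dict[str, float]
    cov: np.ndarray
    ssr: float
    nobs: int
    converged: bool

    def predict(self, s, inhibitor=None):
        x = np.array([self.params[k] for k in self.model.param_names])
        inh = np.zeros_like(np.asarray(s, float)) if (self.model.inhibitor is not None and inhibitor is None) else inhibitor
        return self.model.predict(x, s=s, inhibitor=inh)

    def summary(self) -> str:
        lines = [
            "Michaelis-Menten fit" + (" (competitive inhibition)" if "ki" in self.params else ""),
            f"  nobs: {self.nobs}    SSR: {self.ssr:.6g}    converged: {self.converged}",
            f"  {'param':<6s} {'estimate':>12s} {'std err':>12s}",
        ]
        for k in self.model.param_names:
            lines.append(f"  {k:<6s} {self.params[k]:>12.6g} {self.bse[k]:>12.4g}")
        return "\n".join(lines)


def synth_rate_data(
    p: MMParams,
    s_grid,
    replicates: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
    inh: InhibitionParams | None = None,
) -> pd.DataFrame:
    """Simulated initial-rate table with multiplicative Gaussian noise.

    v = model(s) * (1 + eps), eps ~ Normal(0, noise_cv); negative draws are
    clipped at 0 and flagged.  Columns: s_uM, v, inhibitor_uM, clipped.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    s = np.repeat(np.asarray(s_grid, dtype=float), replicates)
    km_eff = p.km if inh is None else apparent_km(p.km, inh)
    v_true = p.vmax_value * s / (km_eff + s)
    v = v_true * (1.0 + rng.normal(0.0, noise_cv, size=len(s))) if noise_cv > 0 else v_true.copy()
    clipped = v < 0
    v[clipped] = 0.0
    return pd.DataFrame(
        {
            "s_uM": s,
            "v": v,
            "inhibitor_uM": 0.0 if inh is None else inh.inhibitor_conc,
            "clipped": clipped,
        }
    )


# ---------------------------------------------------------------------------
# SAM-regeneration cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CascadeParams:
    """Parameters of the coupled OMT/HMT methylation cycle.

    Rate laws (rapid-equilibrium products of saturating terms):

        v_OMT = kcat_omt*E_omt * [S]/(Km_S*(1+[SAH]/Ki_SAH)+[S]) * [SAM]/(Km_SAM+[SAM])
        v_HMT = kcat_hmt*E_hmt * [SAH]/(Km_SAH+[SAH]) * [D]/(Km_D+[D])

    All concentrations uM, kcat 1/s, donor decay first-order 1/s.  Defaults
    describe the gallacetophenone system: Km_S = 51.7 uM and Ki_SAH =
    28.3 uM are measured/inferred values; the OMT turnover capacity is
    calibrated so the SAM-supplemented reaction completes in about 2 h, the
    HMT capacity so the coupled cycle completes in about 8 h; the remaining
    HMT-side constants are plausible assumptions (see docs/methods.md).
    """

    kcat_omt: float = 0.044
    e_omt: float = 2.0
    km_s: float = 51.7
    km_sam: float = 30.0
    ki_sah: float = 28.3
    kcat_hmt: float = 0.0125
    e_hmt: float = 2.0
    km_sah: float = 10.0
    km_donor: float = 100.0
    donor_decay: float = 0.0
    s0: float = 500.0
    p0: float = 0.0
    sam0: float = 0.0
    sah0: float = 100.0
    donor0: float = 2000.0

    def __post_init__(self) -> None:
        for name in ("kcat_omt", "e_omt", "km_s", "km_sam", "ki_sah",
                     "kcat_hmt", "e_hmt", "km_sah", "km_donor", "donor_decay",
                     "s0", "p0", "sam0", "sah0", "donor0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_(self, **kwargs) -> "CascadeParams":
        return replace(self, **kwargs)


def cascade_rhs(state, p: CascadeParams) -> np.ndarray:
    """Time derivatives of [S, P, SAM, SAH, D] (uM/s).

    Pointwise conservation: dS + dP = 0 and dSAM + dSAH = 0 exactly; the
    donor feeds the methyl balance D0 - D = dSAM_total + dP_total when
    donor_decay = 0.
    """
    s, prod, sam, sah, donor = np.maximum(np.asarray(state, dtype=float), 0.0)
    denom_s = p.km_s * (1.0 + sah / p.ki_sah) + s
    v_omt = p.kcat_omt * p.e_omt * (s / denom_s if denom_s > 0 else 0.0)
    v_omt *= sam / (p.km_sam + sam) if (p.km_sam + sam) > 0 else 0.0
    v_hmt = p.kcat_hmt * p.e_hmt
    v_hmt *= sah / (p.km_sah + sah) if (p.km_sah + sah) > 0 else 0.0
    v_hmt *= donor / (p.km_donor + donor) if (p.km_donor + donor) > 0 else 0.0
    return np.array([
        -v_omt,
        +v_omt,
        v_hmt - v_omt,
        v_omt - v_hmt,
        -v_hmt - p.donor_decay * donor,
    ])


@dataclass
class CascadeTrajectory:
    """Integrated cascade time course (time in hours, concentrations in uM)."""

    t_h: np.ndarray
    s: np.ndarray
    p: np.ndarray
    sam: np.ndarray
    sah: np.ndarray
    donor: np.ndarray
    params: CascadeParams = field(repr=False, default=None)

    @property
    def conversion(self) -> np.ndarray:
        """Fractional conversion P(t)/S0."""
        return self.p / self.params.s0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_h": self.t_h, "S": self.s, "P": self.p,
                "SAM": self.sam, "SAH": self.sah, "D": self.donor,
                "conversion": self.conversion,
            }
        )


def simulate_cascade(
    p: CascadeParams,
    t_end: float = 8.0,
    t_eval: np.ndarray | None = None,
) -> CascadeTrajectory:
    """Integrate the cascade ODE over [0, t_end] hours.

    Stiff-capable adaptive integration (LSODA, rtol 1e-8, atol 1e-10).
    Conservation of S+P and SAM+SAH holds to ~1e-6 relative.
    """
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 401)
    t_eval = np.asarray(t_eval, dtype=float)
    y0 = [p.s0, p.p0, p.sam0, p.sah0, p.donor0]
    sol = solve_ivp(
        lambda t, y: cascade_rhs(y, p),
        (0.0, t_end * 3600.0),
        y0,
        method="LSODA",
        t_eval=t_eval * 3600.0,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise SimulationError(f"cascade integration failed: {sol.message}")
    return CascadeTrajectory(
        t_h=t_eval, s=sol.y[0], p=sol.y[1], sam=sol.y[2], sah=sol.y[3],
        donor=sol.y[4], params=p,
    )


def simulate_single_enzyme(
    p: CascadeParams,
    t_end: float = 8.0,
    t_eval: np.ndarray | None = None,
    sam_conc: float | None = None,
) -> CascadeTrajectory:
    """Reference single-enzyme curve with a fixed, replete SAM pool.

    Models direct SAM supplementation: [SAM] is clamped at ``sam_conc``
    (default sam0 + sah0, i.e. the total cofactor pool) and no SAH
    accumulates.  This is the limit the full cascade approaches as the HMT
    regeneration capacity grows.
    """
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 401)
    t_eval = np.asarray(t_eval, dtype=float)
    sam = p.sam0 + p.sah0 if sam_conc is None else sam_conc
    sam_term = sam / (p.km_sam + sam)

    def rhs(t, y):
        s = max(y[0], 0.0)
        v = p.kcat_omt * p.e_omt * s / (p.km_s + s) * sam_term
        return [-v, v]

    sol = solve_ivp(rhs, (0.0, t_end * 3600.0), [p.s0, p.p0], method="LSODA",
                    t_eval=t_eval * 3600.0, rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise SimulationError(f"single-enzyme integration failed: {sol.message}")
    n = len(t_eval)
    return CascadeTrajectory(
        t_h=t_eval, s=sol.y[0], p=sol.y[1],
        sam=np.full(n, sam), sah=np.zeros(n), donor=np.full(n, p.donor0),
        params=p,
    )


def time_to_conversion(traj: CascadeTrajectory, frac: float) -> float:
    """First time (hours) at which conversion reaches *frac*, linearly
    interpolated between grid points; ``inf`` if never reached."""
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    conv = traj.conversion
    above = np.nonzero(conv >= frac)[0]
    if above.size == 0:
        return float("inf")
    i = int(above[0])
    if i == 0:
        return float(traj.t_h[0])
    t0, t1 = traj.t_h[i - 1], traj.t_h[i]
    c0, c1 = conv[i - 1], conv[i]
    if c1 == c0:
        return float(t1)
    return float(t0 + (frac - c0) * (t1 - t0) / (c1 - c0))


# ---------------------------------------------------------------------------
# reference parameter values (measured unless flagged as assumptions)
# ---------------------------------------------------------------------------

#: Published kinetic constants for the SmOMT system, plus the values this
#: package derives from them.  Entries marked assumption=True are not
#: measured anywhere and are modelling choices (see docs/methods.md).
REFERENCE_PARAMS: dict[str, dict] = {
    "km_caffeic_acid_uM": {"value": 243.5, "assumption": False},
    "km_gallacetophenone_uM": {"value": 51.7, "assumption": False},
    "km_app_1500uM_SAH_uM": {"value": 2794.0, "assumption": False},
    "sah_conc_uM": {"value": 1500.0, "assumption": False},
    "km_app_coupled_uM": {"value": 499.6, "assumption": False},
    # printed as an efficiency in 1/s/mM; units identify it as kcat/Km
    "kcat_over_km_caffeic_acid_per_s_per_mM": {"value": 0.068, "assumption": False},
    "ki_sah_uM": {"value": 28.3, "assumption": False, "derived": "infer_ki(51.7, 2794, 1500)"},
    "km_sam_uM": {"value": 30.0, "assumption": True},
    "km_sah_hmt_uM": {"value": 10.0, "assumption": True},
    "km_donor_uM": {"value": 100.0, "assumption": True},
    "kcat_omt_per_s": {"value": 0.044, "assumption": True,
                       "note": "calibrated to ~2 h completion with direct SAM"},
    "kcat_hmt_per_s": {"value": 0.0125, "assumption": True,
                       "note": "calibrated to ~8 h completion in the coupled cycle"},
}
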