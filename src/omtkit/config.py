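"""YAML configuration loaders for sites, generators, anchors and kinetics."""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError
from .fusion import AnchorSet, SegmentSpec
from .nac import ReactiveRegion, SiteSpec
from .structio import Selector
from .synth import SiteDistribution

__all__ = [
    "load_yaml",
    "selector_from_dict",
    "load_sites",
    "load_region",
    "load_site_distributions",
    "load_anchors",
]


def load_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")
    return data


def selector_from_dict(d: dict[str, Any]) -> Selector:
    try:
        return Selector(
            chain=d.get("chain"),
            resseq=d.get("resseq"),
            resname=d.get("resname"),
            atom_names=list(d["atom_names"]) if "atom_names" in d else None,
        )
    except (TypeError, ValueError, KeyError) as exc:
        raise ConfigError(f"bad selector {d!r}: {exc}") from exc


def load_sites(cfg: dict) -> list[SiteSpec]:
    """Parse the ``sites:`` list of a NAC config into SiteSpecs."""
    try:
        raw = cfg["sites"]
    except KeyError:
        raise ConfigError("config needs a 'sites' list") from None
    sites = []
    for entry in raw:
        try:
            sites.append(
                SiteSpec(
                    label=str(entry["label"]),
                    o_sel=selector_from_dict(entry["o"]),
                    n_sels=[selector_from_dict(x) for x in entry["n"]],
                    c1_sel=selector_from_dict(entry["c1"]),
                    s_sel=selector_from_dict(entry["s"]),
                    h_sels=[selector_from_dict(x) for x in entry.get("h", [])],
                )
            )
        except KeyError as exc:
            raise ConfigError(f"site entry missing key {exc}: {entry!r}") from exc
    if not sites:
        raise ConfigError("'sites' list is empty")
    return sites


def load_region(cfg: dict, **overrides) -> ReactiveRegion:
    """Reactive region from a config's ``region:`` mapping, with overrides."""
    raw = dict(cfg.get("region") or {})
    raw.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return ReactiveRegion(
            d_max=float(raw.get("d_max", 3.5)),
            theta_min=float(raw.get("theta_min", 125.0)),
            theta_max=float(raw.get("theta_max", 170.0)),
        )
    except ValueError as exc:
        raise ConfigError(f"bad reactive region: {exc}") from exc


def load_site_distributions(cfg: dict) -> list[SiteDistribution]:
    try:
        raw = cfg["sites"]
    except KeyError:
        raise ConfigError("generator config needs a 'sites' list") from None
    dists = []
    for entry in raw:
        try:
            dists.append(
                SiteDistribution(
                    site_label=str(entry["label"]),
                    d_mean=float(entry["d_mean"]),
                    d_sd=float(entry["d_sd"]),
                    theta_mean=float(entry["theta_mean"]),
                    theta_sd=float(entry["theta_sd"]),
                    rho=float(entry.get("rho", 0.0)),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"bad site distribution {entry!r}: {exc}") from exc
    if not dists:
        raise ConfigError("generator 'sites' list is empty")
    return dists


def load_anchors(cfg: dict) -> tuple[str, AnchorSet, AnchorSet, SegmentSpec, SegmentSpec]:
    """Parse a fusion-descriptor anchor config.

    Expected keys: construct, tunnel_a, tunnel_b (selector lists), segment_x
    and segment_y ({start: [...], end: [...]}).
    """
    try:
        construct = str(cfg.get("construct", "construct"))
        tunnel_a = AnchorSet("tunnel_a", [selector_from_dict(x) for x in cfg["tunnel_a"]])
        tunnel_b = AnchorSet("tunnel_b", [selector_from_dict(x) for x in cfg["tunnel_b"]])

        def seg(name: str) -> SegmentSpec:
            raw = cfg[name]
            return SegmentSpec(
                label=name,
                start_anchor=AnchorSet(f"{name}.start", [selector_from_dict(x) for x in raw["start"]]),
                end_anchor=AnchorSet(f"{name}.end", [selector_from_dict(x) for x in raw["end"]]),
            )

        return construct, tunnel_a, tunnel_b, seg("segment_x"), seg("segment_y")
    except KeyError as exc:
        raise ConfigError(f"anchor config missing key {exc}") from exc
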