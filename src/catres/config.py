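"""Run-time configuration for the catres pipeline.

All tunables of the method live here so that the CLI, the library and the
synthetic-data generator agree on one set of defaults: the van der Waals
radii used by the contact rule, the contact threshold (2.0 Å on top of the
radii sum), the number of keyAAs (5), the DNSC attenuation exponent (1) and
hop cutoff (5), and the layered-environment depth (3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

#: Bondi van der Waals radii (Å) for the elements that occur in protein
#: ATOM records.  Unknown elements fall back to ``DEFAULT_VDW_RADIUS``.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}

DEFAULT_VDW_RADIUS: float = 1.70


@dataclass(frozen=True)
class Config:
    """Pipeline parameters with the method's defaults."""

    #: extra distance (Å) added to the vdW-radii sum in the contact rule
    contact_extra: float = 2.0
    #: number of top-closeness residues treated as signal sources
    n_keyaas: int = 5
    #: power-law attenuation exponent ``a`` in the DNSC signal model
    dnsc_exponent: float = 1.0
    #: signal intensity at the source
    dnsc_source_intensity: float = 1.0
    #: hop distances beyond this contribute zero signal
    dnsc_cutoff: int = 5
    #: number of shortest-path layers in the environment encoding
    layer_depth: int = 3
    #: solvent probe radius (Å) for accessible surface area
    asa_probe_radius: float = 1.4
    #: sphere sample points per atom for accessible surface area
    asa_n_points: int = 960
    #: van der Waals radii table (element symbol -> Å)
    vdw_radii: Mapping[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    #: fallback radius for unrecognized elements
    default_vdw_radius: float = DEFAULT_VDW_RADIUS
    #: master seed for stochastic steps (sampling, CV shuffling)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


DEFAULT_CONFIG = Config()
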