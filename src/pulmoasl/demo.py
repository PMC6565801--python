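"""Bundled desk-scale study conditions.

The demo network stands in for a subject-specific imaged lung: ~1000
terminal acinar units in a right-lung half-ellipsoid, each unit lumping
roughly 30 real acini.  At that lumping the feeding "terminal arteriole"
is really a small supernumerary artery, so its radius is set to 0.6 mm --
a 0.1 mm vessel carrying 1/1000 of cardiac output would have a wildly
supra-physiological resistance, while 0.5 mm reproduces small-artery mean
velocities near 100 mm/s.  The sheet conductance is calibrated once
per network so the trunk-to-atrium pressure drop at 5 L/min sits near 10
mmHg, placing most of the pulmonary resistance in the microcirculation as
in life.
"""

from __future__ import annotations



from .geometry import DomainShape, GeometryConfig, VascularNetwork, generate_network
from .hemodynamics import (
    BoundaryConditions,
    SheetParams,
    calibrate_sheet_conductance,
)

DEMO_TERMINAL_RADIUS_MM = 0.5


def demo_domain() -> DomainShape:
    """Right-lung half-ellipsoid, 150 mm wide so five 15 mm sagittal slices
    cover half of the lateral-medial extent on the medial side and the
    default five-slice protocol spans most of the lung."""
    return DomainShape(semi_axes=(75.0, 75.0, 110.0), hilum=(0.0, -22.5, 0.0))


def demo_geometry_config(n_terminals: int = 1000, seed: int = 0) -> GeometryConfig:
    return GeometryConfig(
        n_terminals=n_terminals,
        seed=seed,
        terminal_radius_mm=DEMO_TERMINAL_RADIUS_MM,
    )


def build_demo_network(n_terminals: int = 1000, seed: int = 0) -> VascularNetwork:
    """Generate the bundled synthetic network (deterministic per seed)."""
    return generate_network(demo_domain(), demo_geometry_config(n_terminals, seed))


def demo_sheet_params(network: VascularNetwork,
                      base: SheetParams = SheetParams()) -> SheetParams:
    """Sheet parameters with C_sheet calibrated for this network at CO = 5
    L/min toward a ~10 mmHg trunk-to-atrium drop."""
    return calibrate_sheet_conductance(
        network, BoundaryConditions(cardiac_output_l_min=5.0), sheet=base
    )
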