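"""Shared fixtures: tiny hand-built networks and fabricated flow states."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pulmoasl.asl import MRParams, SlicePlane, VoxelGrid
from pulmoasl.geometry import DomainShape, GeometryConfig, VascularNetwork
from pulmoasl.hemodynamics import FlowSolution


@pytest.fixture
def domain() -> DomainShape:
    return DomainShape(semi_axes=(75.0, 75.0, 110.0), hilum=(0.0, -22.5, 0.0))


def build_network(nodes, elements, inlet, outlet, n_terminals=1,
                  domain=None) -> VascularNetwork:
    """Assemble a VascularNetwork from plain tuples.

    ``nodes``: (id, x, y, z); ``elements``: (id, node_in, node_out, type,
    radius, length).
    """
    return VascularNetwork(
        nodes=pd.DataFrame(nodes, columns=["id", "x_mm", "y_mm", "z_mm"]),
        elements=pd.DataFrame(
            elements,
            columns=["id", "node_in", "node_out", "type", "radius0_mm", "length_mm"],
        ),
        inlet_element=inlet,
        outlet_element=outlet,
        n_terminals=n_terminals,
        domain=domain,
    )


def fabricate_solution(network: VascularNetwork, Q=None, v=None, V_B=None) -> FlowSolution:
    """A FlowSolution with prescribed per-element flow/velocity/volume, for
    testing the imaging stages in isolation from the solver."""
    els = network.elements
    n = len(els)
    r = els["radius0_mm"].to_numpy(dtype=float)
    L = els["length_mm"].to_numpy(dtype=float)
    Q = np.full(n, 100.0) if Q is None else np.asarray(Q, dtype=float)
    if v is None:
        v = Q / (np.pi * r**2)
    if V_B is None:
        V_B = np.pi * r**2 * L
    el_df = pd.DataFrame(
        {
            "id": els["id"].to_numpy(),
            "type": els["type"].to_numpy(),
            "Q_mm3_s": Q,
            "v_mm_s": np.asarray(v, dtype=float),
            "V_B_mm3": np.asarray(V_B, dtype=float),
            "P_in_pa": np.zeros(n),
            "P_out_pa": np.zeros(n),
            "radius_mm": r,
        }
    )
    return FlowSolution(
        nodes=pd.DataFrame({"id": network.nodes["id"], "pressure_pa": 0.0}),
        elements=el_df,
        iterations=1,
        residual=0.0,
        residual_history=[0.0],
    )


def make_grid(capillary, arterial=None, venous=None,
              voxel_dims=(15.0, 3.0, 1.5), ti_ms=800.0) -> VoxelGrid:
    """A VoxelGrid directly from component arrays (full lung mask)."""
    cap = np.atleast_2d(np.asarray(capillary, dtype=float))
    art = np.zeros_like(cap) if arterial is None else np.atleast_2d(
        np.asarray(arterial, dtype=float))
    ven = np.zeros_like(cap) if venous is None else np.atleast_2d(
        np.asarray(venous, dtype=float))
    mask = np.ones_like(cap, dtype=bool)
    return VoxelGrid(
        capillary=cap,
        arterial=art,
        venous=ven,
        volume=np.abs(cap) + np.abs(art) + np.abs(ven),
        mask=mask,
        retained=mask.copy(),
        origin_yz_mm=(0.0, 0.0),
        voxel_dims_mm=voxel_dims,
        ti_ms=ti_ms,
        slice_plane=SlicePlane(index=1, center_x_mm=0.0),
    )


@pytest.fixture
def mr800() -> MRParams:
    return MRParams(ti_ms=800.0)
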