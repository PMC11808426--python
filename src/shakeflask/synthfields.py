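"""Synthetic two-phase flow snapshots with closed-form reference values.

Every post-processing operator in :mod:`shakeflask.fieldpost` can be
exercised on these fields without any CFD run: planar Couette shear and
rigid rotation carry exact strain-rate references, slab and droplet
interfaces carry exact geometric areas, and the annulus mimics the
rotating liquid body of an orbitally shaken flask — a liquid ring against
a cylindrical wall with an optional thinner wall film — with known contact
heights.

Diffuse interfaces use a clipped-linear volume-fraction ramp of prescribed
thickness; the integral of |grad alpha| across any monotone ramp
telescopes to 1, so the recovered interfacial area is independent of the
profile shape. These are geometric stand-ins: no attempt is made to
emulate out-of-phase sloshing dynamics or realistic free-surface shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .fieldpost import FieldGrid

__all__ = ["SyntheticSpec", "generate_field"]

KINDS = ("couette", "rigid_rotation", "annulus", "droplet", "slab_interface")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic snapshot.

    Parameters
    ----------
    kind : one of couette / rigid_rotation / annulus / droplet /
        slab_interface.
    size : box edge lengths (m); a single float means a cube. For the
        annulus the box is horizontal extent x,y and height z.
    resolution : cells per axis (int or per-axis tuple); >= 16 recommended
        for convergence work.
    params : kind-specific parameters, all SI —
        couette: gamma0 (1/s);
        rigid_rotation: omega (1/s);
        slab_interface: liquid_height (m), thickness (m);
        droplet: radius (m), thickness (m);
        annulus: wall_radius (m), ring_width (m), thickness (m), and either
        liquid_height (m) or liquid_volume (m^3); optional film_width (m)
        + film_height (m) for the trailing wall film; optional omega (1/s)
        rigid-rotation rate of the liquid.
    seed : seed for the optional velocity jitter (params key 'jitter',
        m/s amplitude, default 0); identical seeds give bit-identical
        snapshots.
    """

    kind: str
    size: float | tuple[float, float, float] = 0.1
    resolution: int | tuple[int, int, int] = 32
    params: dict = dataclass_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown synthetic field kind {self.kind!r}")

    @property
    def lengths(self) -> tuple[float, float, float]:
        s = self.size
        return (s, s, s) if np.isscalar(s) else tuple(s)

    @property
    def shape(self) -> tuple[int, int, int]:
        r = self.resolution
        return (r, r, r) if np.isscalar(r) else tuple(r)


def _axes(spec: SyntheticSpec):
    (lx, ly, lz), (nx, ny, nz) = spec.lengths, spec.shape
    x = (np.arange(nx) + 0.5) * lx / nx
    y = (np.arange(ny) + 0.5) * ly / ny
    z = (np.arange(nz) + 0.5) * lz / nz
    return x, y, z


def _ramp(signed_dist: np.ndarray, thickness: float) -> np.ndarray:
    """Clipped-linear profile: 1 deep inside (dist>0), 0 outside."""
    return np.clip(0.5 + signed_dist / thickness, 0.0, 1.0)


def _check_thickness(t: float, spec: SyntheticSpec) -> None:
    dmax = max(l / n for l, n in zip(spec.lengths, spec.shape))
    if t < 4.0 * dmax:
        raise ValueError(
            f"interface thickness {t} m thinner than 4 cell spacings "
            f"({4 * dmax:.3g} m); refine the grid or thicken the interface"
        )


def generate_field(spec: SyntheticSpec) -> tuple[FieldGrid, dict]:
    """Build the snapshot and its analytic reference values.

    Returns ``(grid, reference)``. The reference dict carries the exact
    values the post-processing operators should recover, keyed by quantity
    (e.g. ``S_norm``, ``lambda1``, ``area``, ``liquid_volume``,
    ``contact_height_bulk``).
    """
    x, y, z = _axes(spec)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    zeros = np.zeros_like(X)
    p = spec.params
    lx, ly, lz = spec.lengths

    if spec.kind == "couette":
        gamma0 = float(p.get("gamma0", 10.0))
        grid = FieldGrid(
            x, y, z, u=gamma0 * Z, v=zeros.copy(), w=zeros.copy(),
            alpha=np.ones_like(X),
        )
        ref = {
            "S_norm": gamma0,
            "lambda1": gamma0 / 2.0,
            "gamma_strain_norm": gamma0,
            "gamma_eigen": 2.5 * gamma0 / 2.0,
        }

    elif spec.kind == "rigid_rotation":
        omega = float(p.get("omega", 10.0))
        cx, cy = lx / 2.0, ly / 2.0
        grid = FieldGrid(
            x, y, z,
            u=-omega * (Y - cy), v=omega * (X - cx), w=zeros.copy(),
            alpha=np.ones_like(X),
        )
        ref = {"S_norm": 0.0, "lambda1": 0.0}

    elif spec.kind == "slab_interface":
        h0 = float(p.get("liquid_height", lz / 2.0))
        t = float(p.get("thickness", 6.0 * lz / spec.shape[2]))
        _check_thickness(t, spec)
        alpha = _ramp(h0 - Z, t)
        grid = FieldGrid(x, y, z, u=zeros.copy(), v=zeros.copy(),
                         w=zeros.copy(), alpha=alpha)
        ref = {
            "area": lx * ly,
            "liquid_volume": lx * ly * h0,
            "liquid_height": h0,
        }

    elif spec.kind == "droplet":
        r0 = float(p.get("radius", min(lx, ly, lz) / 4.0))
        t = float(p.get("thickness", 6.0 * lz / spec.shape[2]))
        _check_thickness(t, spec)
        dist = np.sqrt((X - lx / 2) ** 2 + (Y - ly / 2) ** 2 + (Z - lz / 2) ** 2)
        alpha = _ramp(r0 - dist, t)
        grid = FieldGrid(x, y, z, u=zeros.copy(), v=zeros.copy(),
                         w=zeros.copy(), alpha=alpha)
        ref = {
            "area": 4.0 * np.pi * r0**2,
            "liquid_volume": 4.0 / 3.0 * np.pi * r0**3,
            "radius": r0,
        }

    elif spec.kind == "annulus":
        R = float(p.get("wall_radius", 0.4 * min(lx, ly)))
        w = float(p.get("ring_width", R / 3.0))
        t = float(p.get("thickness", 6.0 * lz / spec.shape[2]))
        _check_thickness(t, spec)
        cx, cy = lx / 2.0, ly / 2.0
        rad = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
        # radial occupancy of the bulk ring: diffuse inner edge, hard wall
        ring_xy = _ramp(rad - (R - w), t) * (rad <= R)

        dz = lz / spec.shape[2]
        if "liquid_volume" in p:
            # solve A_ring * h0 = VL with the realized (discrete) ring area
            a_ring = float(np.sum(ring_xy[:, :, 0])) * (lx / spec.shape[0]) * (
                ly / spec.shape[1]
            )
            h0 = float(p["liquid_volume"]) / a_ring
        else:
            h0 = float(p.get("liquid_height", lz / 2.0))
        if not (t / 2.0 < h0 < lz - t / 2.0):
            raise ValueError("liquid height (or requested volume) outside grid")
        alpha = ring_xy * _ramp(h0 - Z, t)

        film_w = p.get("film_width")
        h_film = float(p.get("film_height", h0))
        if film_w is not None:
            film_xy = _ramp(rad - (R - float(film_w)), t) * (rad <= R)
            alpha = np.maximum(alpha, film_xy * _ramp(h_film - Z, t))

        omega = float(p.get("omega", 0.0))
        grid = FieldGrid(
            x, y, z,
            u=-omega * (Y - cy), v=omega * (X - cx), w=zeros.copy(),
            alpha=alpha, wall_radius=R, axis_center=(cx, cy),
        )
        ref = {
            "liquid_volume": float(np.sum(alpha)) * grid.cell_volume,
            "contact_height_bulk": h0,
            "contact_height_film": h_film if film_w is not None else None,
            "wall_radius": R,
            "ring_width": w,
            "S_norm": 0.0,  # rigid rotation carries no strain
        }
        del dz

    else:  # pragma: no cover - guarded in SyntheticSpec
        raise ValueError(f"unknown synthetic field kind {spec.kind!r}")

    jitter = float(p.get("jitter", 0.0))
    if jitter > 0:
        rng = np.random.default_rng(spec.seed)
        grid.u = grid.u + jitter * rng.standard_normal(grid.u.shape)
        grid.v = grid.v + jitter * rng.standard_normal(grid.v.shape)
        grid.w = grid.w + jitter * rng.standard_normal(grid.w.shape)

    return grid, ref
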