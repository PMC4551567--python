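"""Tissue layer stack and parametric 3-D electrode geometries.

Coordinate convention used throughout the package: cylindrical coordinates
(r, z) with the symmetry axis through the electrode centre, z = 0 at the
vitreous/nerve-fibre-layer (NFL) interface and z increasing into the retina.
The electrode sits below the retina (z < 0) on an insulating polyimide
substrate.  All lengths are in micrometres, conductivities in S/m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

__all__ = [
    "RETINAL_LAYERS",
    "SIGMA_VITREOUS",
    "SIGMA_PT",
    "SIGMA_PI",
    "Layer",
    "LayerStack",
    "ElectrodeShape",
    "ElectrodeSpec",
    "build_layer_stack",
    "electrode_surface_area",
    "electrode_occupancy",
    "InvalidGeometryError",
]

#: Retinal layers from the inner (vitreal) surface outwards:
#: (name, conductivity S/m, thickness μm).
RETINAL_LAYERS: tuple[tuple[str, float, float], ...] = (
    ("NFL", 0.0126, 24.0),
    ("GCL", 0.0126, 49.0),
    ("IPL", 0.0571, 40.0),
    ("INL", 0.0147, 38.0),
    ("OPL", 0.0571, 30.0),
    ("ONL", 0.0147, 91.0),
    ("OS", 1.0309, 25.0),
    ("RPE", 0.0010, 35.0),
)

SIGMA_VITREOUS = 1.2821  #: vitreous humour conductivity, S/m
SIGMA_PT = 8.9e6  #: platinum electrode metal, S/m
SIGMA_PI = 1.0e-17  #: polyimide substrate, S/m

METAL_THICKNESS_UM = 1.0
SUBSTRATE_THICKNESS_UM = 20.0

#: total retinal tissue thickness, μm
RETINA_THICKNESS_UM = sum(t for _, _, t in RETINAL_LAYERS)


class InvalidGeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric parameters."""


@dataclass(frozen=True)
class Layer:
    name: str
    conductivity: float  # S/m
    z_bottom: float  # μm
    z_top: float  # μm

    @property
    def thickness(self) -> float:
        return self.z_top - self.z_bottom


@dataclass(frozen=True)
class LayerStack:
    """Ordered stack of conductive slabs, bottom (electrode side) to top.

    ``layers`` covers the conductive domain only: the vitreous gap (thickness
    equal to the electrode-retina distance, ERD) followed by the retinal
    layers.  The metal film and insulating substrate below z = -erd are
    handled by electrode occupancy masking, not as stack layers.
    """

    layers: tuple[Layer, ...]
    erd: float  # vitreous gap thickness, μm
    domain_radius: float  # μm

    def __post_init__(self) -> None:
        prev_top = None
        for lay in self.layers:
            if lay.thickness <= 0:
                raise InvalidGeometryError(f"layer {lay.name} has non-positive thickness")
            if prev_top is not None and abs(lay.z_bottom - prev_top) > 1e-9:
                raise InvalidGeometryError(
                    f"layer {lay.name} does not tile: starts at {lay.z_bottom}, previous top {prev_top}"
                )
            prev_top = lay.z_top

    def __iter__(self) -> Iterator[Layer]:
        return iter(self.layers)

    @property
    def z_bottom(self) -> float:
        return self.layers[0].z_bottom

    @property
    def z_top(self) -> float:
        return self.layers[-1].z_top

    @property
    def total_height(self) -> float:
        """Conductive-domain height (vitreous gap + tissue), μm."""
        return self.z_top - self.z_bottom

    def layer_at(self, z: float) -> Layer:
        """Return the unique layer containing depth ``z`` (top-exclusive
        except for the last layer)."""
        if z < self.z_bottom or z > self.z_top:
            raise InvalidGeometryError(f"z={z} outside stack [{self.z_bottom}, {self.z_top}]")
        for lay in self.layers:
            if lay.z_bottom <= z < lay.z_top:
                return lay
        return self.layers[-1]

    def conductivity_at(self, z: float) -> float:
        return self.layer_at(z).conductivity

    def boundaries(self) -> list[float]:
        """All interface depths, bottom to top, μm."""
        return [self.layers[0].z_bottom] + [lay.z_top for lay in self.layers]

    def with_uniform_conductivity(self, sigma: float) -> "LayerStack":
        """Same geometry with every layer set to ``sigma`` (oracle tests)."""
        new = tuple(Layer(l.name, sigma, l.z_bottom, l.z_top) for l in self.layers)
        return LayerStack(new, erd=self.erd, domain_radius=self.domain_radius)


class ElectrodeShape(str, Enum):
    DISK = "disk"
    CONCAVE_HEMISPHERE = "concave_hemisphere"
    CONVEX_HEMISPHERE = "convex_hemisphere"
    CONCAVE_CONE = "concave_cone"
    CONVEX_CONE = "convex_cone"

    @property
    def is_planar(self) -> bool:
        return self is ElectrodeShape.DISK

    @property
    def is_convex(self) -> bool:
        return self in (ElectrodeShape.CONVEX_HEMISPHERE, ElectrodeShape.CONVEX_CONE)

    @property
    def is_concave(self) -> bool:
        return self in (ElectrodeShape.CONCAVE_HEMISPHERE, ElectrodeShape.CONCAVE_CONE)


@dataclass(frozen=True)
class ElectrodeSpec:
    """Stimulating electrode: shape, footprint and placement.

    ``projection_diameter`` is the diameter of the disk projection onto the
    retinal plane.  ``protrusion_height`` is 0 for the disk, the projection
    radius for hemispheres, and equals the projection radius for right-angle
    cones (apex half-angle 45°) unless overridden.  ``erd`` is the shortest
    metal-to-retina distance: measured to the apex for convex shapes and to
    the rim/face plane for the disk and concave shapes (configurable via
    ``erd_reference``).
    """

    shape: ElectrodeShape
    projection_diameter: float  # μm
    erd: float  # μm
    protrusion_height: float | None = None  # μm; default derived from shape
    metal_thickness: float = METAL_THICKNESS_UM
    substrate_thickness: float = SUBSTRATE_THICKNESS_UM
    erd_reference: str = "nearest_metal"  # or "rim_plane"

    def __post_init__(self) -> None:
        if self.projection_diameter <= 0:
            raise InvalidGeometryError("projection diameter must be positive")
        if self.erd <= 0:
            raise InvalidGeometryError("erd must be positive")
        if self.protrusion_height is None:
            object.__setattr__(self, "protrusion_height", self._default_height())
        if self.shape is not ElectrodeShape.DISK and self.protrusion_height <= 0:
            raise InvalidGeometryError("non-planar electrode needs positive protrusion height")

    def _default_height(self) -> float:
        if self.shape is ElectrodeShape.DISK:
            return 0.0
        # hemispheres: height = radius; cones: right-angle, height = radius
        return self.projection_diameter / 2.0

    @property
    def radius(self) -> float:
        return self.projection_diameter / 2.0

    @property
    def height(self) -> float:
        return float(self.protrusion_height)

    @property
    def z_rim(self) -> float:
        """Depth (μm, negative) of the electrode plane nearest the retina.

        For the disk and concave shapes this is the metal face / rim plane at
        z = -erd.  For convex shapes the apex sits at z = -erd when the ERD
        is referenced to the nearest metal point; with ``erd_reference ==
        'rim_plane'`` the base plane sits at -erd instead.
        """
        if self.shape.is_convex and self.erd_reference == "nearest_metal":
            return -self.erd  # apex depth; base plane is z_rim - height
        return -self.erd

    @property
    def z_base(self) -> float:
        """Depth of the substrate-top plane the electrode sits on/in."""
        if self.shape is ElectrodeShape.DISK:
            return -self.erd - self.metal_thickness
        if self.shape.is_convex:
            if self.erd_reference == "nearest_metal":
                return -self.erd - self.height
            return -self.erd
        # concave: rim at -erd, bowl extends a further `height` down,
        # backed by a metal film
        return -self.erd - self.height - self.metal_thickness

    @property
    def z_domain_bottom(self) -> float:
        """Bottom of the conductive computational domain (substrate top /
        metal underside); everything below is the insulating substrate."""
        if self.shape.is_convex:
            return self.z_base - self.metal_thickness
        return self.z_base


def build_layer_stack(erd: float, domain_radius: float = 1400.0) -> LayerStack:
    """Assemble the vitreous + retina conductive stack for a given ERD.

    The vitreous gap (thickness = ERD) spans z in [-erd, 0]; the eight
    retinal layers tile [0, 332] μm.
    """
    if erd <= 0:
        raise InvalidGeometryError("erd must be positive")
    layers = [Layer("vitreous", SIGMA_VITREOUS, -float(erd), 0.0)]
    z = 0.0
    for name, sigma, thick in RETINAL_LAYERS:
        layers.append(Layer(name, sigma, z, z + thick))
        z += thick
    return LayerStack(tuple(layers), erd=float(erd), domain_radius=float(domain_radius))


def electrode_surface_area(spec: ElectrodeSpec) -> float:
    """Geometric (metal/electrolyte) surface area in μm².

    Disk: πr².  Hemisphere: 2πr² (concave and convex are mirror images).
    Cone: lateral area πr√(r²+h²).
    """
    r = spec.radius
    h = spec.height
    if spec.shape is ElectrodeShape.DISK:
        return math.pi * r * r
    if spec.shape in (ElectrodeShape.CONCAVE_HEMISPHERE, ElectrodeShape.CONVEX_HEMISPHERE):
        return 2.0 * math.pi * r * r
    if spec.shape in (ElectrodeShape.CONCAVE_CONE, ElectrodeShape.CONVEX_CONE):
        return math.pi * r * math.sqrt(r * r + h * h)
    raise InvalidGeometryError(f"unknown electrode shape {spec.shape!r}")


def electrode_occupancy(spec: ElectrodeSpec, r: float, z: float) -> str:
    """Classify a point as ``'metal'``, ``'substrate'`` or ``'medium'``.

    Used for grid masking.  Convex shapes protrude into the vitreous toward
    the retina; concave shapes are bowls recessed below the rim plane that
    open toward the retina (the bowl interior is vitreous fluid).
    """
    if r < 0:
        raise InvalidGeometryError("radial coordinate must be non-negative")
    a = spec.radius
    h = spec.height
    if z >= 0:
        return "medium"

    if spec.shape is ElectrodeShape.DISK:
        z_top = -spec.erd
        z_bot = z_top - spec.metal_thickness
        if z_bot <= z <= z_top:
            return "metal" if r <= a else "substrate"
        if z < z_bot:
            return "substrate"
        return "medium"

    if spec.shape.is_convex:
        z_base = spec.z_base
        z_apex = z_base + h
        z_bot = z_base - spec.metal_thickness
        if z < z_bot:
            return "substrate"
        if z_bot <= z <= z_base:
            # backing film under the protrusion
            return "metal" if r <= a else "substrate"
        if z > z_apex:
            return "medium"
        # inside [z_base, z_apex]: inside the solid protrusion -> metal
        if spec.shape is ElectrodeShape.CONVEX_HEMISPHERE:
            # dome centred on the base plane
            if r * r + (z - z_base) ** 2 <= a * a:
                return "metal"
        else:  # convex cone, apex up
            r_max = a * (z_apex - z) / h
            if r <= r_max:
                return "metal"
        return "medium"

    # concave shapes: rim plane at -erd, cavity recessed below, metal shell
    z_rim = -spec.erd
    z_floor = z_rim - h  # deepest point of cavity
    z_bot = z_floor - spec.metal_thickness
    if z > z_rim:
        return "medium"
    if z < z_bot:
        return "substrate"
    if r > a:
        return "substrate"
    # inside the electrode block [z_bot, z_rim] x [0, a]: cavity is medium
    if z >= z_floor:
        if spec.shape is ElectrodeShape.CONCAVE_HEMISPHERE:
            if r * r + (z - z_rim) ** 2 <= a * a:
                return "medium"
        else:  # concave cone, apex down at z_floor
            r_cav = a * (z - z_floor) / h
            if r <= r_cav:
                return "medium"
    return "metal"
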