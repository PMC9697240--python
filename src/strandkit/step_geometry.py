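"""Base-step rigid-body coordinates (mid-frame / CEHS convention).

A step is the rigid relationship between two consecutive base (or base-pair)
reference frames along 5'->3'.  The six step coordinates are measured in the
mid-frame halfway between the two triads: the bending angle gamma between the
z-axes is split symmetrically about the hinge axis z_i x z_j, twist is the
angle between the y-axes after that symmetrisation, and (shift, slide, rise)
are the origin displacement expressed in mid-frame axes.  Roll and tilt are
the decomposition of gamma along the mid-frame y and x directions.

The helical coordinates decompose the same relative rotation as a single
axis-angle pair: helical twist is the rotation angle about the local helical
axis, helical rise the origin displacement projected onto it.  The two sets
coincide exactly when slide, shift, roll and tilt vanish.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from ._geom import rotation_about_axis, signed_angle, unit
from .base_frames import BaseFrame

__all__ = ["StepParameters", "step_parameters", "helical_parameters", "build_step"]

#: relative rotation angles below this (degrees) use the mid-frame z-axis as
#: the helical axis (the pure-translation fallback convention)
HELICAL_ANGLE_CUTOFF = 0.01


@dataclasses.dataclass
class StepParameters:
    """Six rigid step coordinates plus the two helical coordinates.

    Translations (shift, slide, rise, h_rise) in Angstrom, rotations (tilt,
    roll, twist, h_twist) in degrees; twist-like angles lie in (-180, 180].
    """

    shift: float = 0.0
    slide: float = 0.0
    rise: float = 0.0
    tilt: float = 0.0
    roll: float = 0.0
    twist: float = 0.0
    h_rise: Optional[float] = None
    h_twist: Optional[float] = None
    step_label: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.shift, self.slide, self.rise,
                         self.tilt, self.roll, self.twist])

    COLUMNS = ("shift", "slide", "rise", "tilt", "roll", "twist",
               "h_rise", "h_twist")


def _mid_triads(frame_i: BaseFrame, frame_j: BaseFrame):
    """Symmetrise the two triads about the hinge; return (A1, A2, gamma, hinge)."""
    z1, z2 = frame_i.z, frame_j.z
    c = float(np.clip(np.dot(z1, z2), -1.0, 1.0))
    gamma = np.degrees(np.arccos(c))
    if gamma >= 90.0:
        raise ValueError("step undefined: base z-axes are anti-aligned "
                         f"(gamma = {gamma:.1f} degrees >= 90)")
    cross = np.cross(z1, z2)
    if np.linalg.norm(cross) < 1e-12:
        return frame_i.axes, frame_j.axes, 0.0, None
    hinge = unit(cross)
    A1 = rotation_about_axis(hinge, +gamma / 2.0) @ frame_i.axes
    A2 = rotation_about_axis(hinge, -gamma / 2.0) @ frame_j.axes
    return A1, A2, gamma, hinge


def _mid_frame(A1: np.ndarray, A2: np.ndarray, twist: float) -> np.ndarray:
    """Mid-frame: z shared by the symmetrised triads, y halfway along the
    twist (the bisector of the two y-axes, but well-defined at twist 180)."""
    zm = unit(A1[:, 2] + A2[:, 2])
    ym = rotation_about_axis(zm, twist / 2.0) @ A1[:, 1]
    ym = unit(ym - np.dot(ym, zm) * zm)
    xm = unit(np.cross(ym, zm))
    ym = np.cross(zm, xm)  # re-orthogonalise
    return np.column_stack([xm, ym, zm])


def step_parameters(frame_i: BaseFrame, frame_j: BaseFrame,
                    label: str = "") -> StepParameters:
    """Six mid-frame step coordinates + helical coordinates for one step."""
    A1, A2, gamma, hinge = _mid_triads(frame_i, frame_j)
    zm0 = unit(A1[:, 2] + A2[:, 2])
    twist = signed_angle(A1[:, 1], A2[:, 1], zm0)
    Tm = _mid_frame(A1, A2, twist)
    zm = Tm[:, 2]
    disp = frame_j.origin - frame_i.origin
    shift, slide, rise = Tm.T @ disp
    if hinge is None:
        roll = tilt = 0.0
    else:
        phi = signed_angle(Tm[:, 1], hinge, zm)
        roll = gamma * np.cos(np.radians(phi))
        tilt = -gamma * np.sin(np.radians(phi))
    h_rise, h_twist = helical_parameters(frame_i, frame_j)
    return StepParameters(shift=float(shift), slide=float(slide), rise=float(rise),
                          tilt=float(tilt), roll=float(roll), twist=float(twist),
                          h_rise=h_rise, h_twist=h_twist, step_label=label)


def helical_parameters(frame_i: BaseFrame, frame_j: BaseFrame) -> Tuple[float, float]:
    """(helical rise, helical twist) from the axis-angle decomposition.

    The helical axis is the rotation axis of the relative rotation, oriented
    along the 5'->3' advance (positive projection on the average base normal);
    below :data:`HELICAL_ANGLE_CUTOFF` the mid-frame z-axis is used instead.
    """
    R = frame_j.axes @ frame_i.axes.T
    rotvec = Rotation.from_matrix(R).as_rotvec(degrees=True)
    angle = float(np.linalg.norm(rotvec))
    zsum = frame_i.z + frame_j.z
    if angle < HELICAL_ANGLE_CUTOFF:
        axis = unit(zsum)
        h_twist = 0.0
    else:
        axis = rotvec / angle
        h_twist = angle
        if np.dot(axis, zsum) < 0.0:
            axis = -axis
            h_twist = -angle
    h_rise = float(np.dot(frame_j.origin - frame_i.origin, axis))
    return h_rise, float(h_twist)


def build_step(frame_i: BaseFrame, params: StepParameters) -> BaseFrame:
    """Exact inverse of :func:`step_parameters`: the frame one step 3'-ward.

    ``step_parameters(f, build_step(f, p))`` reproduces p to numerical
    precision for any combined bend below 90 degrees.
    """
    gamma = float(np.hypot(params.roll, params.tilt))
    if gamma >= 90.0:
        raise ValueError("combined roll/tilt bend must stay below 90 degrees")
    phi = np.degrees(np.arctan2(-params.tilt, params.roll)) if gamma > 0 else 0.0
    omega = params.twist
    Rz = lambda a: rotation_about_axis([0.0, 0.0, 1.0], a)
    Ry = lambda a: rotation_about_axis([0.0, 1.0, 0.0], a)
    axes_j = frame_i.axes @ Rz(omega / 2 + phi) @ Ry(gamma) @ Rz(omega / 2 - phi)
    Tm = frame_i.axes @ Rz(omega / 2 + phi) @ Ry(gamma / 2) @ Rz(-phi)
    origin_j = frame_i.origin + Tm @ np.array([params.shift, params.slide, params.rise])
    # clean up rounding so chained construction stays orthonormal
    U, _, Vt = np.linalg.svd(axes_j)
    axes_j = U @ Vt
    return BaseFrame(origin=origin_j, axes=axes_j,
                     residue_ref=f"{frame_i.residue_ref}+1")
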