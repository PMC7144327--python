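"""Chromatic-aberration correction: per-channel 3D affine registration.

Multi-colour fiducial beads appear at channel-dependent positions because of
chromatic aberration.  A full 3D affine transform (linear part + translation)
per moving channel is estimated by least squares from matched bead positions
and then applied to that channel's localisations.  An affine subsumes the
shift/scale/shear components of chromatic error; field-dependent (non-affine)
distortion is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import LocalizationTable


class RankError(ValueError):
    """Bead configuration too degenerate to determine an affine transform."""


@dataclass
class ChannelTransform:
    """Affine map p -> A p + t (nm) taking a moving channel onto the reference."""

    channel: str
    matrix: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    residual_rms_nm: float
    n_beads: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("linear part must be invertible")

    @classmethod
    def identity(cls, channel: str = "") -> "ChannelTransform":
        return cls(channel, np.eye(3), np.zeros(3), 0.0, 0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "ChannelTransform":
        inv = np.linalg.inv(self.matrix)
        return ChannelTransform(
            self.channel, inv, -inv @ self.translation, self.residual_rms_nm, self.n_beads
        )

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "residual_rms_nm": self.residual_rms_nm,
            "n_beads": self.n_beads,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelTransform":
        return cls(
            d["channel"],
            np.array(d["matrix"]),
            np.array(d["translation"]),
            float(d["residual_rms_nm"]),
            int(d["n_beads"]),
        )


def estimate_transform(
    ref_points: np.ndarray, moving_points: np.ndarray, channel: str = ""
) -> ChannelTransform:
    """Least-squares affine mapping ``moving_points`` onto ``ref_points``.

    Correspondence is by index; needs >= 4 non-coplanar pairs.
    """
    ref = np.asarray(ref_points, dtype=float).reshape(-1, 3)
    mov = np.asarray(moving_points, dtype=float).reshape(-1, 3)
    if ref.shape != mov.shape:
        raise ValueError("ref and moving point sets must have the same shape")
    n = len(ref)
    if n < 4:
        raise RankError(f"need >= 4 matched beads, got {n}")
    design = np.hstack([mov, np.ones((n, 1))])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(design).max())) < 4:
        raise RankError("bead positions are coplanar; affine transform is underdetermined")
    sol, *_ = np.linalg.lstsq(design, ref, rcond=None)
    matrix = sol[:3].T
    translation = sol[3]
    fitted = design @ sol
    residual = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return ChannelTransform(channel, matrix, translation, residual, n)


def match_beads(
    ref_points: np.ndarray, moving_points: np.ndarray, max_dist_nm: float = 500.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mutual-nearest-neighbour bead correspondence within a distance gate.

    Returns (ref_idx, mov_idx) of matched pairs, for unordered bead tables.
    """
    ref = np.asarray(ref_points, dtype=float).reshape(-1, 3)
    mov = np.asarray(moving_points, dtype=float).reshape(-1, 3)
    if len(ref) == 0 or len(mov) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    d_rm, nn_rm = cKDTree(mov).query(ref)
    _, nn_mr = cKDTree(ref).query(mov)
    ref_idx = []
    mov_idx = []
    for i, (j, d) in enumerate(zip(nn_rm, d_rm)):
        if d <= max_dist_nm and nn_mr[j] == i:
            ref_idx.append(i)
            mov_idx.append(j)
    return np.array(ref_idx, dtype=int), np.array(mov_idx, dtype=int)


def estimate_channel_transforms(
    bead_tables: dict[str, LocalizationTable],
    ref_channel: str,
    max_match_dist_nm: float = 500.0,
) -> dict[str, ChannelTransform]:
    """Per-channel transforms onto ``ref_channel`` from unordered bead tables."""
    if ref_channel not in bead_tables:
        raise ValueError(f"reference channel {ref_channel!r} not among bead tables")
    ref = bead_tables[ref_channel].coords
    out = {ref_channel: ChannelTransform.identity(ref_channel)}
    for ch, table in bead_tables.items():
        if ch == ref_channel:
            continue
        mov = table.coords
        ri, mi = match_beads(ref, mov, max_match_dist_nm)
        out[ch] = estimate_transform(ref[ri], mov[mi], channel=ch)
    return out


def apply_transform(
    table: LocalizationTable,
    transforms: dict[str, ChannelTransform],
    allow_identity: bool = False,
) -> LocalizationTable:
    """Map each channel's coordinates through its transform; all other fields untouched.

    A channel without a transform raises unless ``allow_identity``.
    """
    out = table.copy()
    df = out.df
    for ch in out.channels:
        if ch not in transforms:
            if allow_identity:
                continue
            raise ValueError(
                f"no transform for channel {ch!r} (pass allow_identity=True to skip)"
            )
        mask = (df["channel"] == ch).to_numpy()
        if mask.any():
            df.loc[mask, ["x_nm", "y_nm", "z_nm"]] = transforms[ch].apply(
                df.loc[mask, ["x_nm", "y_nm", "z_nm"]].to_numpy()
            )
    out.meta["registered"] = {
        ch: {"residual_rms_nm": t.residual_rms_nm, "n_beads": t.n_beads}
        for ch, t in sorted(transforms.items())
    }
    return out


def save_transforms(transforms: dict[str, ChannelTransform], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({ch: t.to_dict() for ch, t in sorted(transforms.items())}, fh, indent=1)
        fh.write("\n")


def load_transforms(path) -> dict[str, ChannelTransform]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return {ch: ChannelTransform.from_dict(d) for ch, d in raw.items()}
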