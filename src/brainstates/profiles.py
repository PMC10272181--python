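"""Characterization of state centroids against networks and reference maps.

Each centroid (a length-P activity pattern over parcels) is described
two ways: by its Pearson correlation with the 0/1 membership indicator
of each large-scale network (plus the mean centroid activity over the
network's parcels), and by its correlation with parcel-level reference
maps such as meta-analytic topic maps.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import StateModel
from .errors import ValidationError
from .io import NetworkPartition, ReferenceMap


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise ValidationError("correlation undefined: a vector is constant")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def network_profile(centroid: np.ndarray, partition: NetworkPartition,
                    state_id: int | None = None) -> pd.DataFrame:
    """Correlate one centroid with every network's membership indicator.

    Returns a tidy frame with columns state, network, r, mean_activity,
    one row per network.  Raises on a constant centroid (correlation
    undefined) or a length mismatch with the parcellation.
    """
    centroid = np.asarray(centroid, dtype=float).ravel()
    if centroid.size != partition.n_parcels:
        raise ValidationError(
            f"centroid length {centroid.size} != parcel count {partition.n_parcels}"
        )
    if np.ptp(centroid) == 0:
        raise ValidationError("constant centroid: network correlations undefined")
    rows = []
    for network in partition.networks:
        ind = partition.indicator(network)
        rows.append({
            "state": state_id,
            "network": network,
            "r": _pearson(centroid, ind),
            "mean_activity": float(centroid[ind == 1].mean()),
        })
    return pd.DataFrame(rows)


def functional_profile(centroid: np.ndarray, maps: Sequence[ReferenceMap],
                       state_id: int | None = None) -> pd.DataFrame:
    """Correlate one centroid with each reference map, preserving map
    order.  Raises naming any constant map."""
    centroid = np.asarray(centroid, dtype=float).ravel()
    rows = []
    for m in maps:
        if m.values.size != centroid.size:
            raise ValidationError(
                f"map {m.name!r} has length {m.values.size}, centroid has {centroid.size}"
            )
        if np.ptp(m.values) == 0:
            raise ValidationError(f"reference map {m.name!r} is constant; correlation undefined")
        rows.append({"state": state_id, "map": m.name, "r": _pearson(centroid, m.values)})
    return pd.DataFrame(rows)


def network_profiles(model: StateModel, partition: NetworkPartition) -> pd.DataFrame:
    """Network profile of every state of a fitted model (tidy, stacked)."""
    return pd.concat(
        [network_profile(model.centroids[i], partition, state_id=i + 1) for i in range(model.k)],
        ignore_index=True,
    )


def functional_profiles(model: StateModel, maps: Sequence[ReferenceMap]) -> pd.DataFrame:
    """Functional profile of every state of a fitted model (tidy, stacked)."""
    return pd.concat(
        [functional_profile(model.centroids[i], maps, state_id=i + 1) for i in range(model.k)],
        ignore_index=True,
    )


def project_voxel_map(voxel_image, atlas_image, name: str = "map") -> ReferenceMap:
    """Average a voxel-level map within each parcel of an integer atlas.

    Convenience for building parcel-level reference vectors from
    volumetric maps; accepts nibabel spatial images or plain arrays
    (arrays skip the affine check).  Atlas labels must be 1..P with
    every label present; 0 is background.
    """
    try:
        import nibabel as nib
        is_img = lambda o: isinstance(o, nib.spatialimages.SpatialImage)  # noqa: E731
    except ImportError:  # pragma: no cover - nibabel is a hard dependency
        is_img = lambda o: False  # noqa: E731
    if is_img(voxel_image) and is_img(atlas_image):
        if voxel_image.shape != atlas_image.shape or not np.allclose(
            voxel_image.affine, atlas_image.affine, atol=1e-6
        ):
            raise ValidationError("voxel map and atlas are not on the same grid")
        vox = np.asarray(voxel_image.get_fdata(), dtype=float)
        atlas = np.asarray(atlas_image.get_fdata()).astype(int)
    else:
        vox = np.asarray(voxel_image, dtype=float)
        atlas = np.asarray(atlas_image).astype(int)
        if vox.shape != atlas.shape:
            raise ValidationError("voxel map and atlas have different shapes")
    p = int(atlas.max())
    if p < 1:
        raise ValidationError("atlas contains no positive labels")
    values = np.empty(p)
    for label in range(1, p + 1):
        mask = atlas == label
        if not mask.any():
            raise ValidationError(f"atlas label {label} absent (labels must be contiguous 1..P)")
        values[label - 1] = vox[mask].mean()
    return ReferenceMap(name, values)
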